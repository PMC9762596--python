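"""Cladal taxonomic units: clade enumeration and the ctu abundance matrix.

A clade is an internal node of the rooted ASV tree together with all of
its descendant tips; its abundance in a sample is the sum of the member
tips' counts.  A root-to-tip traversal therefore turns a samples x ASVs
count table into a samples x clades matrix ``ctu`` in which
``ctu[i, j]`` is the abundance of clade ``j`` in sample ``i``.  Tips are
not emitted as clades (their abundances are already ASV rows), so a
fully bifurcating rooted tree over n tips yields exactly n - 1 clades.

Clade identifiers are content hashes of the sorted member tip labels,
so they are stable across reruns and tree-file orderings.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd

from .tables import RANKS, UNKNOWN, AsvTable, TaxonomyTable
from .tree import PhyloTree, ValidationError


def clade_id_for(members) -> str:
    """Stable identifier for a clade: hash of its sorted member tip labels."""
    digest = hashlib.sha1("\x00".join(sorted(members)).encode()).hexdigest()
    return f"c{digest[:12]}"


def enumerate_clades(tree: PhyloTree) -> list[tuple[str, frozenset]]:
    """List (clade_id, member tip set) for every internal node, preorder.

    The root is included, tips are excluded.  Polytomies contribute one
    clade each (no implicit resolution): clades are the monophyletic
    groups actually present in the tree.
    """
    if not tree.rooted:
        raise ValidationError(
            "tree is not rooted; midpoint_root it (or pass rooted=True) first"
        )
    out = []
    seen = set()
    for node in tree.root.preorder(include_self=True):
        if node.is_tip():
            continue
        members = frozenset(t.name for t in node.tips())
        if members in seen:
            raise ValidationError(
                "tree contains unary internal nodes (duplicate clades); "
                "collapse them (e.g. via prune_tips) first"
            )
        seen.add(members)
        out.append((clade_id_for(members), members))
    return out


class CladeMatrix:
    """The ctu matrix plus clade membership and consensus taxonomy."""

    def __init__(self, abundances: pd.DataFrame, members: dict,
                 taxonomy_labels: dict | None = None):
        self.abundances = abundances
        self.members = members
        self.taxonomy_labels = taxonomy_labels or {}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def clade_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_clades(self) -> int:
        return self.abundances.shape[1]

    @property
    def root_clade_id(self) -> str:
        """The clade whose member set covers every tip (first in preorder)."""
        return self.abundances.columns[0]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for cid in self.clade_ids:
            mem = sorted(self.members[cid])
            rows.append({
                "clade_id": cid,
                "n_tips": len(mem),
                "consensus_taxonomy": self.taxonomy_labels.get(cid, ""),
                "member_tips": ",".join(mem),
            })
        return pd.DataFrame(rows).set_index("clade_id")

    def to_tsv(self, path) -> None:
        self.abundances.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<CladeMatrix {len(self.sample_ids)} samples x "
                f"{self.n_clades} clades>")


def build_clade_matrix(tree: PhyloTree, table: AsvTable,
                       tax: TaxonomyTable | None = None) -> CladeMatrix:
    """Root-to-tip traversal summing descendant-tip counts per clade.

    Features in the table but absent from the tree are reported and
    ignored; tree tips absent from the table are an error (the clade
    sums would silently be wrong).
    """
    tips = set(tree.tip_names)
    feats = set(table.feature_ids)
    missing_from_table = sorted(tips - feats)
    if missing_from_table:
        raise ValidationError(
            f"tree tips absent from the count table: {missing_from_table[:10]}"
        )
    extra = sorted(feats - tips)
    if extra:
        warnings.warn(
            f"{len(extra)} feature(s) absent from the tree are ignored: {extra[:5]}...",
            UserWarning,
            stacklevel=2,
        )

    counts = table.counts
    col_index = {f: i for i, f in enumerate(counts.columns)}
    arr = counts.to_numpy()

    # Postorder accumulation: each internal node's vector is the sum of its
    # children's vectors; tips read straight from the table.
    vectors: dict[int, np.ndarray] = {}
    members_by_node: dict[int, frozenset] = {}
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            vectors[id(node)] = arr[:, col_index[node.name]]
            members_by_node[id(node)] = frozenset([node.name])
        else:
            child_vecs = [vectors[id(c)] for c in node.children]
            vectors[id(node)] = np.sum(child_vecs, axis=0)
            members_by_node[id(node)] = frozenset().union(
                *(members_by_node[id(c)] for c in node.children)
            )

    clades = enumerate_clades(tree)
    data = {}
    members = {}
    # map member set -> node vector (clade ids are content-addressed)
    by_members = {members_by_node[id(n)]: vectors[id(n)]
                  for n in tree.root.preorder(include_self=True)
                  if not n.is_tip()}
    for cid, mem in clades:
        data[cid] = by_members[mem]
        members[cid] = mem
    abundances = pd.DataFrame(data, index=counts.index)

    labels = {}
    if tax is not None:
        for cid, mem in clades:
            labels[cid] = clade_consensus_taxonomy(mem, tax)
    return CladeMatrix(abundances, members, labels)


def clade_consensus_taxonomy(members, tax: TaxonomyTable) -> str:
    """Deepest rank at which all member ASVs share one non-unknown value.

    Walks genus -> phylum; returns ``"<rank>:<value>"`` or ``"mixed"``
    when not even the phylum is shared.
    """
    absent = sorted(set(members) - set(tax.asv_ids))
    if absent:
        raise ValidationError(f"member ASVs missing from taxonomy: {absent[:10]}")
    sub = tax.assignments.loc[sorted(members)]
    for rank in reversed(RANKS):
        values = set(sub[rank])
        if len(values) == 1:
            value = values.pop()
            if value != UNKNOWN:
                return f"{rank}:{value}"
    return "mixed"
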