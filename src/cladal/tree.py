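"""Phylogenetic tree I/O and manipulation for ASV-tip trees.

Trees are held as :class:`skbio.TreeNode` objects wrapped in a thin
:class:`PhyloTree` that enforces the invariants the downstream cladal
analysis relies on: unique non-empty tip labels, non-negative branch
lengths, and an explicit rooted/unrooted state.  Midpoint rooting is
implemented here (rather than delegated) so that the equal-longest-path
tie-break is deterministic: among all tip pairs attaining the tree
diameter, the pair whose sorted label tuple is lexicographically
smallest defines the rooting path.
"""

from __future__ import annotations

import io
import warnings
from collections.abc import Iterable

from skbio import TreeNode
from skbio.io import NewickFormatError


class ValidationError(ValueError):
    """Input violates a structural precondition."""


class NewickParseError(ValueError):
    """Newick text could not be parsed."""


_EPS = 1e-9


def _locate_newick_defect(text: str) -> int:
    """Best-effort character offset of a newick syntax defect.

    Scans for unbalanced parentheses or a missing terminal semicolon;
    returns an offset into ``text`` (the end of the string when the
    defect is truncation).
    """
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
        elif ch == ";":
            if depth != 0:
                return i
    return len(text)


class PhyloTree:
    """A (possibly rooted) phylogenetic tree over ASV tips.

    Parameters
    ----------
    root : skbio.TreeNode
        Tree topology; branch lengths on ``length``.
    rooted : bool
        Whether the root node is a meaningful clade boundary (set by
        :func:`midpoint_root` and the simulator; inferred on read).
    """

    def __init__(self, root: TreeNode, rooted: bool = False, validate: bool = True):
        self.root = root
        self.rooted = rooted
        if validate:
            self._validate()

    def _validate(self) -> None:
        labels = [t.name for t in self.root.tips()]
        if any(lab is None or lab == "" for lab in labels):
            raise ValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        missing = False
        for node in self.root.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                missing = True
            elif node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} on node {node.name!r}"
                )
        if self.root.length is None:
            self.root.length = None  # root carries no edge
        if missing:
            warnings.warn(
                "missing branch lengths replaced by 0", UserWarning, stacklevel=3
            )

    # -- basic queries -------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.root.tips())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), rooted=self.rooted, validate=False)

    def tip_distance_matrix(self):
        """Pairwise tip path-length matrix (skbio DistanceMatrix)."""
        return self.root.tip_tip_distances()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {self.n_tips} tips, {state}>"


def read_newick(path_or_text) -> PhyloTree:
    """Read a single newick tree from a file path or raw string.

    Internal node labels are preserved but ignored by the analysis;
    missing branch lengths become 0 with a warning.  Rootedness is
    inferred: a root of degree <= 2 is taken as rooted.
    """
    if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("("):
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    if ";" not in text:
        raise NewickParseError(
            f"newick not terminated by ';' (defect near offset {_locate_newick_defect(text)})"
        )
    try:
        root = TreeNode.read(io.StringIO(text), format="newick")
    except NewickFormatError as exc:
        raise NewickParseError(
            f"malformed newick near offset {_locate_newick_defect(text)}: {exc}"
        ) from exc
    return PhyloTree(root, rooted=len(root.children) <= 2)


def write_newick(tree: PhyloTree, path) -> None:
    """Write the tree (with branch lengths) to a newick file."""
    tree.root.write(str(path), format="newick")


def to_newick(tree: PhyloTree) -> str:
    buf = io.StringIO()
    tree.root.write(buf, format="newick")
    return buf.getvalue()


def _path_edges(a: TreeNode, b: TreeNode) -> list[TreeNode]:
    """Nodes whose parent edges form the a->b path, ordered from a to b.

    Each returned node is the child endpoint of one edge on the path.
    """
    chain_a = [a]
    node = a
    while node.parent is not None:
        node = node.parent
        chain_a.append(node)
    chain_ids = {id(n) for n in chain_a}
    up_b = []
    node = b
    while id(node) not in chain_ids:
        up_b.append(node)
        node = node.parent
    lca = node
    edges = []
    node = a
    while node is not lca:
        edges.append(node)
        node = node.parent
    edges.extend(reversed(up_b))
    return edges


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    Ties between equal-length longest paths are broken by the
    lexicographically smallest sorted endpoint-label pair.  If the
    midpoint falls exactly on an existing node the tree is rooted at
    that node without inserting a zero-length edge.  All pairwise
    tip-to-tip path lengths are preserved.
    """
    if tree.n_tips < 2:
        raise ValidationError("midpoint rooting needs at least 2 tips")
    work = tree.copy()
    dm = work.root.tip_tip_distances()
    ids = list(dm.ids)
    data = dm.data
    diameter = data.max()
    if diameter <= 0:
        raise ValidationError("all branch lengths are zero; midpoint undefined")
    best = None
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if data[i, j] >= diameter - _EPS:
                pair = tuple(sorted((ids[i], ids[j])))
                if best is None or pair < best:
                    best = pair
    a_name, b_name = best
    a = work.root.find(a_name)
    b = work.root.find(b_name)
    edges = _path_edges(a, b)
    total = sum(e.length for e in edges)
    half = total / 2.0

    # Walk from a toward b; `edges` are nodes whose parent-edge is on the
    # path.  Determine, for each step, the child-side node of that edge and
    # whether we enter it from the child end or the parent end.
    node = a
    acc = 0.0
    for edge_child in edges:
        step = edge_child.length
        from_child_end = node is edge_child
        nxt = edge_child.parent if from_child_end else edge_child
        if acc + step >= half - _EPS:
            into = half - acc  # distance walked into this edge from `node`
            if abs(into) <= _EPS:
                root_node = node
            elif abs(step - into) <= _EPS:
                root_node = nxt
            else:
                # split the edge: child-side keeps `child_part` length
                child_part = into if from_child_end else step - into
                parent = edge_child.parent
                mid = TreeNode(length=edge_child.length - child_part)
                edge_child.length = child_part
                parent.remove(edge_child)
                parent.append(mid)
                mid.append(edge_child)
                root_node = mid
            if root_node.is_tip():
                # midpoint on a tip can only happen on pathological trees
                raise ValidationError("midpoint coincides with a tip")
            new_root = work.root.root_at(root_node, reset=True)
            new_root.prune()  # collapse any unary node left at the old root
            new_root.length = None
            return PhyloTree(new_root, rooted=True, validate=False)
        acc += step
        node = nxt
    raise AssertionError("midpoint walk exceeded path length")  # pragma: no cover


def prune_tips(tree: PhyloTree, keep_ids: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``keep_ids``; collapse unary nodes, summing lengths."""
    keep = set(keep_ids)
    if not keep:
        raise ValidationError("keep_ids is empty")
    present = set(tree.tip_names)
    unknown = sorted(keep - present)
    if unknown:
        raise ValidationError(f"unknown tip labels: {unknown}")
    if keep == present:
        return tree.copy()
    sheared = tree.root.copy().shear(keep)
    sheared.prune()
    sheared.length = None
    return PhyloTree(sheared, rooted=tree.rooted and len(sheared.children) <= 2,
                     validate=False)
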