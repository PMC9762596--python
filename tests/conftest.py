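import numpy as np
import pandas as pd
import pytest

from cladal.tables import AsvTable, SampleMetadata, TaxonomyTable
from cladal.tree import PhyloTree, read_newick

from skbio import TreeNode


def random_bifurcating_tree(n_tips: int, rng, prefix: str = "t") -> PhyloTree:
    """Random rooted bifurcating tree by repeated joins (test helper)."""
    nodes = [TreeNode(name=f"{prefix}{i}", length=float(rng.uniform(0.1, 2.0)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root, rooted=True)


@pytest.fixture
def cherry_tree():
    return read_newick("(a:1,b:1);")


@pytest.fixture
def quartet_tree():
    return read_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[2, 3, 0, 1], [0, 5, 1, 4], [7, 0, 0, 2]],
        index=["s1", "s2", "s3"], columns=["a", "b", "c", "d"],
    )
    return AsvTable(counts)


@pytest.fixture
def small_taxonomy():
    df = pd.DataFrame({
        "phylum": ["P1", "P1", "P1", "P2"],
        "class": ["C1", "C1", "C2", "C3"],
        "order": ["O1", "O1", "O2", "O3"],
        "family": ["F1", "F1", "F2", "F3"],
        "genus": ["G1", "unknown", "G2", "unknown"],
    }, index=["a", "b", "c", "d"])
    return TaxonomyTable(df)


def make_metadata(hosts_per_cell=2, il6_by_group=None, seed=0):
    """Minimal valid two-study metadata for battery tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for study, treat in (("ZAM1", "ZS"), ("ZAM2", "ZD")):
        for age in ("young", "old"):
            for diet in ("ZA", treat):
                for h in range(hosts_per_cell):
                    host = f"{study}_{age}_{diet}_h{h}"
                    il6 = float(rng.uniform(20, 150))
                    for tp in ("wk0", "wk6"):
                        rows.append({
                            "sample_id": f"{host}_{tp}", "host_id": host,
                            "age": age, "diet": diet, "study": study,
                            "timepoint": tp,
                            "il6": il6 if tp == "wk6" else np.nan,
                        })
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
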