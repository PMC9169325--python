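import numpy as np
import pandas as pd
import pytest

from intronevo.mapping import IntronSiteMatrix
from intronevo.phylo import TreeIndex

TEN_TAXON_NEWICK = (
    "(((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2):0.2,"
    "((E:0.3,F:0.3):0.2,((G:0.3,H:0.3):0.2,(I:0.3,J:0.3):0.2):0.1):0.1);"
)

QUARTET_NEWICK = "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);"


@pytest.fixture(scope="session")
def ten_taxon_tree() -> TreeIndex:
    return TreeIndex.from_newick(TEN_TAXON_NEWICK)


@pytest.fixture(scope="session")
def quartet_tree() -> TreeIndex:
    return TreeIndex.from_newick(QUARTET_NEWICK)


def matrix_from_frame(df: pd.DataFrame) -> IntronSiteMatrix:
    """Wrap a 0/1/'?' DataFrame (sites x species) into an IntronSiteMatrix."""
    tab = df.astype(str)
    meta = pd.DataFrame(
        {
            "group_id": "g0",
            "aln_column": range(len(tab)),
            "phase": 0,
            "state": "discordant",
        },
        index=tab.index,
    )
    return IntronSiteMatrix(table=tab, metadata=meta)


def random_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random bifurcating newick with branch lengths in (0.05, 1.0)."""
    tips = [f"L{i}" for i in range(n_leaves)]
    while len(tips) > 1:
        i, j = sorted(rng.choice(len(tips), size=2, replace=False))
        a, b = tips[i], tips[j]
        ta, tb = rng.uniform(0.05, 1.0, size=2)
        merged = f"({a}:{ta:.3f},{b}:{tb:.3f})"
        tips = [t for k, t in enumerate(tips) if k not in (i, j)] + [merged]
    return tips[0] + ";"
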