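import numpy as np
import pandas as pd
import pytest

from phylostruct import CommunityMatrix, parse_newick


def random_binary_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary tree as Newick, independent of the package's simulator."""
    nodes = [f"t{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    # strip the root's branch length
    body = nodes[0].rsplit(":", 1)[0]
    return body + ";"


@pytest.fixture
def basic_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_clade_tree():
    # two deep clades of three species each, shallow within-clade structure
    return parse_newick(
        "(((u1:0.2,u2:0.2):0.3,u3:0.5):5.0,((v1:0.2,v2:0.2):0.3,v3:0.5):5.0);"
    )


@pytest.fixture
def two_clade_community(two_clade_tree):
    # three sites on clade u, three on clade v, one mixed
    inc = pd.DataFrame(
        [
            [1, 1, 0, 0, 0, 0],
            [1, 0, 1, 0, 0, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [0, 0, 0, 1, 0, 1],
            [0, 0, 0, 0, 1, 1],
            [1, 0, 0, 1, 0, 0],
        ],
        index=[f"s{i}" for i in range(7)],
        columns=["u1", "u2", "u3", "v1", "v2", "v3"],
    )
    habitat = pd.Series(
        ["one"] * 3 + ["two"] * 3 + ["one"], index=inc.index, name="habitat"
    )
    return CommunityMatrix(incidence=inc, habitat=habitat)
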