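import numpy as np
import pytest

from hemiconn.core_io import Connectome, NodeEntry, NodeTable


@pytest.fixture
def toy_table() -> NodeTable:
    """7-node toy atlas: 3 lateralized regions per side + brainstem."""
    entries = []
    for side, prefix in (("left", "lh"), ("right", "rh")):
        for region in ("a", "b", "c"):
            entries.append(NodeEntry(f"{prefix}-{region}", side, "cortical"))
    entries.append(NodeEntry("brainstem", "midline", "brainstem"))
    homolog = {f"lh-{r}": f"rh-{r}" for r in ("a", "b", "c")}
    return NodeTable(tuple(entries), homolog)


@pytest.fixture
def toy_connectome(toy_table) -> Connectome:
    """Dense asymmetric-across-hemispheres toy weights with interhemispheric
    and brainstem edges; labels: lh-a..c = 0..2, rh-a..c = 3..5, brainstem = 6."""
    w = np.zeros((7, 7))

    def put(i, j, v):
        w[i, j] = w[j, i] = v

    put(0, 1, 2.0)   # lh-a -- lh-b
    put(0, 2, 1.0)   # lh-a -- lh-c
    put(1, 2, 4.0)   # lh-b -- lh-c
    put(3, 4, 3.0)   # rh-a -- rh-b
    put(4, 5, 5.0)   # rh-b -- rh-c
    put(0, 3, 7.0)   # homotopic interhemispheric
    put(1, 5, 6.0)   # heterotopic interhemispheric
    put(2, 6, 8.0)   # lh-c -- brainstem
    put(5, 6, 9.0)   # rh-c -- brainstem
    return Connectome(toy_table, w)


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.5) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    upper = rng.random((n, n)) < density
    weights = rng.lognormal(0.0, 1.0, size=(n, n))
    w = np.triu(upper * weights, k=1)
    return w + w.T
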