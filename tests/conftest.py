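import numpy as np
import pytest

from immune_topo import ClassTable, LabelMask, Role


@pytest.fixture
def table() -> ClassTable:
    return ClassTable()


@pytest.fixture
def two_bar_mask(table) -> LabelMask:
    """Two parallel tumor bars, K17+ on the left, K17- on the right,
    40 px apart at 1 um/px."""
    g = np.zeros((60, 60), dtype=np.uint8)
    g[:, 8] = table.code(Role.TUMOR_K17POS)
    g[:, 48] = table.code(Role.TUMOR_K17NEG)
    return LabelMask(g, 1.0, table)


def random_mask(rng: np.random.Generator, shape=(64, 64), p_tumor=0.04) -> LabelMask:
    """Random sparse tumor mask used by oracle-equivalence checks."""
    table = ClassTable()
    g = np.zeros(shape, dtype=np.uint8)
    g[rng.random(shape) < p_tumor] = table.code(Role.TUMOR_K17POS)
    g[rng.random(shape) < p_tumor] = table.code(Role.TUMOR_K17NEG)
    if not (g > 0).any():
        g[shape[0] // 2, shape[1] // 2] = table.code(Role.TUMOR_K17POS)
    return LabelMask(g, 1.0, table)
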