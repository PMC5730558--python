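import numpy as np
import pandas as pd
import pytest

from gliomaprofiler.datatypes import EventTable, ExpressionStudy


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def make_event_table(arrays: dict, **meta) -> EventTable:
    return EventTable(pd.DataFrame(arrays), **meta)


def make_study(matrix, genes, n_control, n_tumor, name="study") -> ExpressionStudy:
    samples = [f"C{i+1}" for i in range(n_control)] + [
        f"T{i+1}" for i in range(n_tumor)
    ]
    groups = pd.Series(["control"] * n_control + ["tumor"] * n_tumor,
                       index=samples)
    frame = pd.DataFrame(np.asarray(matrix, dtype=float),
                         index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionStudy(frame, groups, name=name)


@pytest.fixture
def small_de_study(rng):
    """20 genes, 4 control vs 3 tumor, genes PL0/PL1 planted at +3/-3."""
    genes = [f"PL{i}" for i in range(2)] + [f"BG{i}" for i in range(18)]
    base = rng.normal(8, 2, size=20)
    matrix = base[:, None] + rng.normal(0, 0.3, size=(20, 7))
    matrix[0, 4:] += 3.0
    matrix[1, 4:] -= 3.0
    return make_study(matrix, genes, 4, 3)
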