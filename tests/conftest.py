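import numpy as np
import pandas as pd
import pytest

from pirna_coreg import coexpression as cx
from pirna_coreg import simulate as sim
from pirna_coreg.matrix import ExpressionMatrix


@pytest.fixture(scope="session")
def reference():
    return sim.make_reference(38, seed=11)


@pytest.fixture(scope="session")
def cohort(reference):
    """One study-scale simulated cohort: counts, RPKM, truth."""
    cfg = sim.SimulationConfig(seed=11)
    counts, rpkm, truth = sim.simulate_expression(cfg, reference)
    return counts, rpkm, truth


@pytest.fixture
def tiny_rpkm():
    """Hand-sized RPKM matrix with two groups of 4 samples."""
    rng = np.random.default_rng(3)
    values = pd.DataFrame(rng.uniform(10, 1000, size=(5, 8)),
                          index=[f"f{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(8)])
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=values.columns)
    return ExpressionMatrix(values, "RPKM", groups=groups)


def correlation_from_values(values: np.ndarray, features, group="A") -> cx.GroupCorrelation:
    """Wrap a raw sample block (features x samples) as a GroupCorrelation."""
    R = np.corrcoef(values)
    return cx.GroupCorrelation(group, pd.DataFrame(R, index=features, columns=features),
                               values.shape[1])


def symmetric_corr(matrix: np.ndarray, features, group="A") -> cx.GroupCorrelation:
    """Wrap an explicit symmetric correlation matrix."""
    return cx.GroupCorrelation(group, pd.DataFrame(matrix, index=features, columns=features),
                               9)
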