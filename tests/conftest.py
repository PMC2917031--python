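import numpy as np
import pandas as pd
import pytest

from methsubtypes.containers import RelativeMatrix
from methsubtypes.simulate import SimulationConfig, simulate, worked_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """The literal 8-CpG x 6-sample hand-checkable bundle."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition simulation shared across tests."""
    return simulate(SimulationConfig(n_cpgs=200, n_genes=100, seed=42))


@pytest.fixture(scope="session")
def strong_cohort():
    """Three major subtypes with many strong planted effects, for
    clustering-recovery checks."""
    return simulate(SimulationConfig(
        n_cpgs=300, n_genes=150,
        n_samples={"basal-like": 25, "lumA": 25, "lumB": 25},
        baseline_meth_prob={"basal-like": 0.28, "lumA": 0.31, "lumB": 0.35},
        n_normal_tissue=0, n_differential_cpgs=120, diff_effect=0.6, seed=4))


def make_relative(values: np.ndarray, genes=None, prefix="c") -> RelativeMatrix:
    """Wrap a plain array as a RelativeMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    if genes is None:
        genes = idx
    return RelativeMatrix(pd.DataFrame(values, index=idx, columns=cols),
                          pd.Series(list(genes), index=idx))
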