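import numpy as np
import pandas as pd
import pytest

from nilgenetics.genotypes import EffectVector, all_genotypes, design_matrix
from nilgenetics.simulate import TrialDesign, py_truth, simulate_nil_trial
from nilgenetics.trial import TRAITS


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def full_design():
    """The complete 27 x 27 design matrix."""
    return design_matrix(all_genotypes())


@pytest.fixture(scope="session")
def blues_all_traits():
    """A synthetic genotype x 15-trait BLUE table with known per-trait truth."""
    rng = np.random.default_rng(7)
    X = design_matrix(all_genotypes())
    truths = {}
    cols = {}
    for trait in TRAITS:
        e = EffectVector.from_array(rng.normal(0, 1, 27))
        truths[trait] = e
        cols[trait] = pd.Series(X.to_numpy() @ e.as_array(), index=X.index)
    table = pd.DataFrame(cols)
    table.attrs["truth"] = truths
    return table


@pytest.fixture(scope="session")
def small_trial():
    """A small but complete simulated trial (PY plant-level, FT plot-level)."""
    design = TrialDesign(plots_per_genotype_per_env=2, plants_per_plot=3)
    truth = {"PY": py_truth(), "FT": py_truth(m=100.0)}
    df = simulate_nil_trial(truth, design, seed=11)
    df.attrs["truth"] = truth
    df.attrs["design"] = design
    return df
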