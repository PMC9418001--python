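import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pyrodom.synthetic import SyntheticDesign, generate_formula_pool, synthesize_peaklists

from _oracles import GridFormulaOracle


@pytest.fixture(scope="session")
def grid_oracle() -> GridFormulaOracle:
    """Session-wide brute-force enumeration of the default CHONSP grid."""
    return GridFormulaOracle()


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """Compact severity-gradient design used across integration tests."""
    return SyntheticDesign(
        n_core_formulas=200,
        n_unique_formulas_per_condition=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    pools = generate_formula_pool(small_design)
    peaklists, ground_truth = synthesize_peaklists(pools, small_design)
    return small_design, pools, peaklists, ground_truth


@pytest.fixture(scope="session")
def mini_result(small_design):
    """Full mini pipeline (generator -> assignment -> presence/metrics)."""
    from _helpers import run_mini_pipeline

    return run_mini_pipeline(small_design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
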