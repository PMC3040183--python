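import numpy as np
import pytest

from mgcnet import HHParams, build_grid
from mgcnet.experiments import exp_population, REFERENCE_CONDUCTANCES


@pytest.fixture(scope="session")
def hh_default() -> HHParams:
    return HHParams()


@pytest.fixture(scope="session")
def spontaneous_params() -> HHParams:
    """The spontaneously active regime: 0.1 nA constant drive."""
    return HHParams(i_inj=0.1)


@pytest.fixture(scope="session")
def reduced_grid():
    """6×6 desk-scale stimulus grid spanning the full rate range."""
    return build_grid(indices=(0, 2, 4, 5, 7, 9))


@pytest.fixture(scope="session")
def grouped_trials_baseline(reduced_grid):
    """Grouped-model trials at the published inter-LN kinetics (α=0.050,
    β=0.025 ms⁻¹); shared between the latency and the correlation checks."""
    df, r_p, _ = exp_population("grouped", n=10, trials=20,
                                conductances=REFERENCE_CONDUCTANCES,
                                inter_ln_alpha=0.050, inter_ln_beta=0.025,
                                grid=reduced_grid, seed=42, eps=3e-5)
    return df, r_p


@pytest.fixture(scope="session")
def grouped_trials_low_alpha(reduced_grid):
    """Grouped-model trials with the inter-LN release rate lowered to 0.042;
    same number of trials and the same trial seeds as the baseline fixture so
    the release-rate comparison is between matched samples."""
    df, r_p, _ = exp_population("grouped", n=10, trials=20,
                                conductances=REFERENCE_CONDUCTANCES,
                                inter_ln_alpha=0.042, inter_ln_beta=0.025,
                                grid=reduced_grid, seed=42, eps=3e-5)
    return df, r_p
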