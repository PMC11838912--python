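import numpy as np
import pytest

from fluctassay.simulate import LDSimParams, simulate_fluctuation_experiment

# Neutral, fully plated, full-growth-mutation parameters at a chosen m:
# the conditions under which the simulator's count law is the MSS pmf.


def neutral_params(m: float, n0: int = 1000, doublings: int = 21) -> LDSimParams:
    nf = n0 * 2**doublings
    return LDSimParams(
        n_initial=n0,
        n_final=nf,
        mu=m / (nf - n0),
        mutant_fitness=1.0,
        induction_generation=0.0,
        plating_fraction_selective=1.0,
    )


@pytest.fixture
def toy_counts():
    """Small printed per-culture count vector used across MLE tests."""
    return np.array([0, 0, 1, 0, 3, 0, 0, 1, 0, 0, 2, 0])


@pytest.fixture
def wt_like_dataset():
    """A 12-culture simulated experiment at m = 2, neutral and fully plated."""
    return simulate_fluctuation_experiment(neutral_params(2.0), 12, seed=42)


# stable hypothesis behaviour across runs
from hypothesis import settings as _hsettings

_hsettings.register_profile("stable", deadline=None, derandomize=True)
_hsettings.load_profile("stable")
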