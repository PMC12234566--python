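import numpy as np
import pandas as pd
import pytest

from enmotion import ObserverParams, psychofit
from enmotion.psychofit import SOUND_CONDITIONS, psychometric_value, PsychometricParams


@pytest.fixture
def unbiased_observer():
    return ObserverParams(sigma_int=9.0, n_samp=10.0, lapse=0.02, beta=2.0)


@pytest.fixture
def biased_observer():
    """Identical sensory parameters in all conditions; decisional bias only."""
    return ObserverParams(
        sigma_int=9.0, n_samp=10.0, lapse=0.02, beta=2.0,
        gamma={"congruent": 0.55, "incongruent": 0.45},
    )


def make_cells(true_params, abs_mu_levels, n_per_cell, seed):
    """Binomial accuracy cells drawn from known psychometric parameters.

    ``true_params``: dict condition -> PsychometricParams.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, pars in true_params.items():
        for m in abs_mu_levels:
            p = psychometric_value(m, pars)
            rows.append({
                "sound": cond, "abs_mu": float(m), "n_trials": n_per_cell,
                "n_correct": int(rng.binomial(n_per_cell, p)),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def cell_factory():
    return make_cells


def standard_truth(gammas=(0.5, 0.5, 0.5, 0.5), alphas=(8.0, 8.0, 6.0, 10.0),
                   beta=2.0, lapse=0.02):
    return {
        c: PsychometricParams(alpha=a, beta=beta, gamma=g, lapse=lapse)
        for c, a, g in zip(SOUND_CONDITIONS, alphas, gammas)
    }


@pytest.fixture
def truth_factory():
    return standard_truth
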