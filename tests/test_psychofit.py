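import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import enmotion as em
from enmotion.psychofit import (
    SOUND_CONDITIONS,
    PsychometricParams,
    fit_joint,
    fit_signed,
    fold_trials,
    bootstrap_fit,
    psychometric_value,
)


class TestPsychometricValue:
    def test_at_threshold_82_percent(self):
        """psi(alpha) with gamma=0.5, lambda=0 is 0.5 + 0.5(1 - 1/e) ~ 0.816."""
        p = PsychometricParams(alpha=4.0, beta=2.0, gamma=0.5, lapse=0.0)
        assert psychometric_value(4.0, p) == pytest.approx(0.5 + 0.5 * (1 - np.exp(-1)))
        # the identity holds for any alpha and beta
        for a, b in [(0.5, 0.7), (12.0, 6.0)]:
            q = PsychometricParams(alpha=a, beta=b, gamma=0.5, lapse=0.0)
            assert psychometric_value(a, q) == pytest.approx(0.81606, abs=1e-5)

    def test_guessing_floor_and_lapse_ceiling(self):
        p = PsychometricParams(alpha=4.0, beta=2.0, gamma=0.55, lapse=0.03)
        assert psychometric_value(1e-9, p) == pytest.approx(0.55, abs=1e-6)
        assert psychometric_value(1e9, p) == pytest.approx(0.97, abs=1e-6)

    def test_nonpositive_x_rejected(self):
        p = PsychometricParams(alpha=4.0, beta=2.0)
        with pytest.raises(ValueError):
            psychometric_value(0.0, p)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        alpha=st.floats(0.1, 30), beta=st.floats(0.2, 15),
        gamma=st.floats(0.0, 0.8), lapse=st.floats(0.0, 0.1),
    )
    def test_monotone_and_bounded(self, alpha, beta, gamma, lapse):
        if gamma + lapse >= 1:
            return
        p = PsychometricParams(alpha=alpha, beta=beta, gamma=gamma, lapse=lapse)
        x = np.geomspace(1e-3, 1e3, 50)
        y = psychometric_value(x, p)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y >= gamma - 1e-12) and np.all(y <= 1 - lapse + 1e-12)


class TestFoldTrials:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["sound", "mu", "correct"])

    def test_signed_levels_combine(self):
        rows = ([("absent", 4.0, True)] * 10 + [("absent", -4.0, True)] * 6
                + [("absent", -4.0, False)] * 4)
        cells = fold_trials(self._records(rows))
        assert len(cells) == 1
        assert cells.loc[0, "n_trials"] == 20
        assert cells.loc[0, "n_correct"] == 16

    def test_counts_conserved_and_order_invariant(self, unbiased_observer):
        d = em.make_session_design(1, 8.0, [0.5, -0.5, 2, -2, 8, -8], 5, 1, seed=0)
        sim = em.simulate_model_faithful(unbiased_observer, d, seed=1)
        cells = fold_trials(sim)
        assert cells["n_trials"].sum() == len(sim)
        shuffled = sim.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(cells, fold_trials(shuffled))
        # 6 signed levels fold to 3 |mu| cells per condition
        assert cells.groupby("sound").size().eq(3).all()

    def test_mu_zero_excluded(self):
        rows = [("absent", 0.0, False)] * 5 + [("absent", 1.0, True)]
        cells = fold_trials(self._records(rows))
        assert cells["n_trials"].sum() == 1

    def test_single_trial(self):
        cells = fold_trials(self._records([("congruent", 2.0, True)]))
        assert cells.loc[0, "n_trials"] == 1 and cells.loc[0, "n_correct"] == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            fold_trials(pd.DataFrame(columns=["sound", "mu", "correct"]))
        bad = pd.DataFrame({"sound": ["absent"] * 2, "mu": [1.0, 1.0],
                            "correct": [True, True], "sd_level": [0.0, 4.0]})
        with pytest.raises(ValueError, match="sd_level"):
            fold_trials(bad)


class TestFitJoint:
    def test_matches_exhaustive_grid(self):
        """On a tiny instance the ML fit beats a dense (alpha, beta) grid."""
        cells = pd.DataFrame({
            "sound": ["absent"] * 2, "abs_mu": [2.0, 8.0],
            "n_trials": [20, 20], "n_correct": [14, 19],
        })
        fit = fit_joint(cells, gamma_mode="fixed", lambda_mode=0.0)
        la = np.linspace(np.log10(0.2), np.log10(80), 500)
        lb = np.linspace(np.log10(0.1), np.log10(20), 500)
        A, B = np.meshgrid(la, lb)
        x = np.array([2.0, 8.0]); n = np.array([20.0, 20.0]); k = np.array([14.0, 19.0])
        F = -np.expm1(-10 ** ((10 ** B)[..., None] * (np.log10(x) - A[..., None])))
        p = np.clip(0.5 + 0.5 * F, 1e-10, 1 - 1e-10)
        ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(-1)
        assert fit.log_likelihood >= ll.max() - 1e-3

    def test_parameter_recovery(self, cell_factory, truth_factory):
        """Known (alpha, beta, gamma, lambda) recovered from 1e4 trials/condition."""
        truth = truth_factory(gammas=(0.5, 0.5, 0.55, 0.45))
        cells = cell_factory(truth, [1, 2, 4, 8, 16, 32], 1667, seed=21)
        fit = fit_joint(cells, gamma_mode="estimated", lambda_mode="free")
        assert fit.converged
        for c in SOUND_CONDITIONS:
            assert fit.params[c].alpha == pytest.approx(truth[c].alpha, rel=0.10)
        assert fit.params["absent"].beta == pytest.approx(2.0, rel=0.25)
        assert fit.params["congruent"].gamma == pytest.approx(0.55, abs=0.05)

    def test_constraints_hold(self, cell_factory, truth_factory):
        cells = cell_factory(truth_factory(), [0.5, 1, 2, 4, 8], 200, seed=2)
        fit = fit_joint(cells, gamma_mode="estimated")
        betas = {p.beta for p in fit.params.values()}
        lapses = {p.lapse for p in fit.params.values()}
        assert len(betas) == 1 and len(lapses) == 1
        assert fit.params["absent"].gamma == 0.5
        assert fit.params["stationary"].gamma == 0.5
        fixed = fit_joint(cells, gamma_mode="fixed")
        assert all(p.gamma == 0.5 for p in fixed.params.values())

    def test_refit_deterministic(self, cell_factory, truth_factory):
        cells = cell_factory(truth_factory(), [1, 2, 4, 8, 16], 100, seed=3)
        f1 = fit_joint(cells, gamma_mode="estimated")
        f2 = fit_joint(cells, gamma_mode="estimated")
        assert f1.log_likelihood == f2.log_likelihood
        assert all(f1.params[c] == f2.params[c] for c in f1.params)

    def test_degenerate_all_correct_flagged(self):
        cells = pd.DataFrame({
            "sound": ["absent"] * 3, "abs_mu": [2.0, 4.0, 8.0],
            "n_trials": [50] * 3, "n_correct": [50] * 3,
        })
        fit = fit_joint(cells, gamma_mode="fixed", lambda_mode=0.0)
        assert fit.boundary

    def test_too_few_levels_rejected(self):
        cells = pd.DataFrame({"sound": ["absent"], "abs_mu": [2.0],
                              "n_trials": [50], "n_correct": [40]})
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_joint(cells, gamma_mode="fixed")


class TestBiasLeak:
    """Fixing gamma at 0.5 for a biased observer pushes the decisional bias
    into the thresholds; estimating gamma absorbs it."""

    def _sim_cells(self, cell_factory, truth_factory, seed):
        truth = truth_factory(gammas=(0.5, 0.5, 0.58, 0.42),
                              alphas=(8.0, 8.0, 8.0, 8.0))
        return cell_factory(truth, [0.5, 1, 2, 4, 8, 16], 400, seed=seed)

    def test_fixed_gamma_manufactures_threshold_difference(
            self, cell_factory, truth_factory):
        n_sims = 20
        lower_fixed, lower_est = 0, 0
        for s in range(n_sims):
            cells = self._sim_cells(cell_factory, truth_factory, 100 + s)
            fx = fit_joint(cells, gamma_mode="fixed", lambda_mode=0.02)
            es = fit_joint(cells, gamma_mode="estimated", lambda_mode=0.02)
            lower_fixed += fx.params["congruent"].alpha < fx.params["incongruent"].alpha
            lower_est += es.params["congruent"].alpha < es.params["incongruent"].alpha
        assert lower_fixed >= 0.9 * n_sims
        assert 0.2 * n_sims <= lower_est <= 0.8 * n_sims

    def test_unbiased_data_same_alphas_either_mode(
            self, cell_factory, truth_factory):
        diffs = []
        for s in range(25):
            cells = cell_factory(truth_factory(alphas=(8.0,) * 4),
                                 [0.5, 1, 2, 4, 8, 16], 400, seed=300 + s)
            fx = fit_joint(cells, gamma_mode="fixed", lambda_mode=0.02)
            es = fit_joint(cells, gamma_mode="estimated", lambda_mode=0.02)
            diffs.append(np.log(fx.params["congruent"].alpha)
                         - np.log(es.params["congruent"].alpha))
        # paired comparison: no systematic alpha shift between modes
        t = sps.ttest_1samp(diffs, 0.0)
        assert abs(np.mean(diffs)) < 0.05
        assert t.pvalue > 0.01


class TestBootstrap:
    def _fit(self, cell_factory, truth_factory, n_per_cell, seed):
        cells = cell_factory(truth_factory(), [0.5, 1, 2, 4, 8, 16],
                             n_per_cell, seed=seed)
        return fit_joint(cells, gamma_mode="fixed", lambda_mode=0.02), cells

    def test_se_shrinks_with_sqrt_n(self, cell_factory, truth_factory):
        fit1, cells1 = self._fit(cell_factory, truth_factory, 420, seed=5)
        fit2, cells2 = self._fit(cell_factory, truth_factory, 840, seed=6)
        b1 = bootstrap_fit(fit1, cells1, n_boot=150, seed=7)
        b2 = bootstrap_fit(fit2, cells2, n_boot=150, seed=8)
        for c in ("absent", "congruent"):
            ratio = b1.se[f"alpha_{c}"] / b2.se[f"alpha_{c}"]
            assert ratio == pytest.approx(np.sqrt(2), rel=0.30)

    def test_p_dev_uniform_under_model(self, cell_factory, truth_factory):
        """For model-consistent data the deviance p-value is ~Uniform(0,1)."""
        pvals = []
        for s in range(60):
            fit, cells = self._fit(cell_factory, truth_factory, 60, seed=1000 + s)
            b = bootstrap_fit(fit, cells, n_boot=40, seed=2000 + s)
            pvals.append(b.p_dev)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_requires_enough_draws(self, cell_factory, truth_factory):
        fit, cells = self._fit(cell_factory, truth_factory, 100, seed=9)
        with pytest.raises(ValueError):
            bootstrap_fit(fit, cells, n_boot=1)


class TestFitSigned:
    def _signed_records(self, pse, sd, n_per_level, seed, swap=False):
        rng = np.random.default_rng(seed)
        mus = np.array([-8, -4, -2, -1, 1, 2, 4, 8], dtype=float)
        rows = []
        for m in mus:
            p = sps.norm.cdf((m - pse) / sd)
            k = rng.binomial(n_per_level, p)
            resp = ["right"] * k + ["left"] * (n_per_level - k)
            mu_out = m
            if swap:  # mirror the left/right convention: flip labels and sign
                resp = ["left" if r == "right" else "right" for r in resp]
                mu_out = -m
            rows += [{"mu": mu_out, "response": r} for r in resp]
        return pd.DataFrame(rows)

    def test_recovery(self):
        rec = self._signed_records(pse=2.0, sd=5.0, n_per_level=1250, seed=4)
        fit = fit_signed(rec)
        assert fit.reliable
        assert fit.pse == pytest.approx(2.0, rel=0.10)
        assert fit.slope_sd == pytest.approx(5.0, rel=0.10)

    def test_symmetric_data_pse_near_zero(self):
        rec = self._signed_records(pse=0.0, sd=4.0, n_per_level=1000, seed=5)
        fit = fit_signed(rec)
        # binomial SE of the PSE at this n is well under 0.3 deg
        assert abs(fit.pse) < 0.3

    def test_label_swap_negates_pse(self):
        rec = self._signed_records(pse=3.0, sd=5.0, n_per_level=800, seed=6)
        f = fit_signed(rec)
        g = fit_signed(self._signed_records(pse=3.0, sd=5.0, n_per_level=800,
                                            seed=6, swap=True))
        assert g.pse == pytest.approx(-f.pse, abs=0.05)

    def test_one_signed_data_flagged(self):
        rec = self._signed_records(pse=0.0, sd=4.0, n_per_level=50, seed=7)
        fit = fit_signed(rec[rec["mu"] > 0])
        assert not fit.reliable
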