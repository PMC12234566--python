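"""Psychometric fitting for 2AFC direction discrimination.

Accuracy data folded over the sign of the mean direction offset are fitted
with

    psi(x; alpha, beta, gamma, lambda) = gamma + (1 - gamma - lambda) * F(x)

where ``F`` is the Weibull on log intensity (the Gumbel / log-Weibull form)

    F(x; alpha, beta) = 1 - exp(-10 ** (beta * (log10(x) - log10(alpha)))),

``alpha`` is the threshold in degrees (at x = alpha, with gamma = 0.5 and
lambda = 0, psi = 0.5 + 0.5*(1 - 1/e) ~ 0.816, i.e. ~82% correct), ``beta``
the slope, ``gamma`` the guessing rate (the lower asymptote: deviations from
0.5 in a 2AFC index decisional response bias) and ``lambda`` the lapse rate
(upper asymptote 1 - lambda).

The four sound conditions (absent, stationary, congruent, incongruent) are
fitted *simultaneously* by maximum likelihood: one alpha per condition, one
shared beta, one shared lapse, and — depending on ``gamma_mode`` — guessing
rates either estimated freely for the congruent/incongruent conditions
(gamma fixed at 0.5 for absent/stationary) or pinned at 0.5 everywhere.
Comparing the two modes exposes how fixing gamma at 0.5 for a biased
observer leaks decisional bias into the threshold estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "SOUND_CONDITIONS",
    "BIASED_CONDITIONS",
    "FoldedCell",
    "PsychometricParams",
    "JointFit",
    "SignedFit",
    "fold_trials",
    "weibull_log10",
    "psychometric_value",
    "fit_joint",
    "fit_observer",
    "bootstrap_fit",
    "fit_signed",
]

SOUND_CONDITIONS = ("absent", "stationary", "congruent", "incongruent")
#: Conditions whose guessing rate may deviate from 0.5 (directional sound).
BIASED_CONDITIONS = ("congruent", "incongruent")

LAPSE_BOUNDS = (0.0, 0.06)
BETA_BOUNDS = (0.1, 20.0)
_PCLIP = 1e-10


@dataclass(frozen=True)
class PsychometricParams:
    """(alpha, beta, gamma, lambda) for one condition; angles in degrees."""

    alpha: float
    beta: float
    gamma: float = 0.5
    lapse: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.lapse <= 1.0):
            raise ValueError("gamma and lapse must lie in [0, 1]")
        if self.gamma + self.lapse >= 1.0:
            raise ValueError("gamma + lapse must be < 1")


@dataclass(frozen=True)
class FoldedCell:
    sound: str
    abs_mu: float
    n_trials: int
    n_correct: int


def weibull_log10(x, alpha, beta):
    """Weibull on log10 intensity: 1 - exp(-10**(beta*(log10 x - log10 alpha)))."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("stimulus intensity must be > 0")
    z = beta * (np.log10(x) - np.log10(alpha))
    return -np.expm1(-(10.0**z))


def psychometric_value(x_deg, params):
    """psi(x) = gamma + (1 - gamma - lambda) F(x; alpha, beta), in [gamma, 1-lambda]."""
    p = params
    out = p.gamma + (1.0 - p.gamma - p.lapse) * weibull_log10(x_deg, p.alpha, p.beta)
    return float(out) if np.ndim(out) == 0 else out


def fold_trials(records):
    """Fold signed mean-direction trials into accuracy cells per (condition, |mu|).

    Up-left and up-right trials at the same absolute offset are combined:
    each cell counts correct responses out of trials at that |mu|.  Trials
    with mu = 0 (no defined correct side) are excluded.

    Parameters
    ----------
    records : pandas.DataFrame
        Trial table with columns ``sound``, ``mu``, ``correct`` sharing a
        single (observer, experiment, sd_level).

    Returns
    -------
    pandas.DataFrame
        Columns ``sound``, ``abs_mu``, ``n_trials``, ``n_correct``.
    """
    if len(records) == 0:
        raise ValueError("empty trial table")
    for col in ("observer", "experiment", "sd_level"):
        if col in records.columns and records[col].nunique() > 1:
            raise ValueError(f"records mix multiple values of {col!r}")
    kept = records[records["mu"] != 0].copy()
    kept["abs_mu"] = kept["mu"].abs()
    cells = (
        kept.groupby(["sound", "abs_mu"], observed=True)["correct"]
        .agg(n_trials="size", n_correct="sum")
        .reset_index()
    )
    cells["n_correct"] = cells["n_correct"].astype(int)
    return cells.sort_values(["sound", "abs_mu"], ignore_index=True)


@dataclass
class JointFit:
    """Simultaneous fit of the four conditions' psychometric functions.

    Invariants: ``beta`` and ``lapse`` are identical across conditions;
    ``gamma`` is exactly 0.5 for absent/stationary (and for all conditions
    under ``gamma_mode='fixed'``).
    """

    params: dict  # condition -> PsychometricParams
    log_likelihood: float
    converged: bool
    gamma_mode: str
    lambda_mode: object  # "free" or the fixed float
    deviance: float
    se: dict = field(default_factory=dict)  # parameter name -> bootstrap SE
    p_dev: float = float("nan")
    boundary: bool = False
    n_boot_failed: int = 0

    @property
    def beta(self):
        return next(iter(self.params.values())).beta

    @property
    def lapse(self):
        return next(iter(self.params.values())).lapse

    def to_dict(self):
        d = {
            c: {"alpha": p.alpha, "beta": p.beta, "gamma": p.gamma, "lambda": p.lapse}
            for c, p in self.params.items()
        }
        return {
            "params": d,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "gamma_mode": self.gamma_mode,
            "lambda_mode": self.lambda_mode,
            "deviance": self.deviance,
            "se": dict(self.se),
            "p_dev": None if np.isnan(self.p_dev) else self.p_dev,
            "boundary": self.boundary,
        }


class _Design:
    """Packed arrays for fast likelihood evaluation of one folded dataset."""

    def __init__(self, cells, gamma_mode, lambda_mode):
        cells = cells[cells["n_trials"] > 0]
        self.conditions = [c for c in SOUND_CONDITIONS if c in set(cells["sound"])]
        extra = set(cells["sound"]) - set(SOUND_CONDITIONS)
        self.conditions += sorted(extra)
        for c in self.conditions:
            if cells.loc[cells["sound"] == c, "abs_mu"].nunique() < 2:
                raise ValueError(
                    f"condition {c!r} has fewer than 2 usable |mu| levels"
                )
        self.cond_idx = np.concatenate(
            [np.full((cells["sound"] == c).sum(), i)
             for i, c in enumerate(self.conditions)]
        )
        ordered = pd.concat(
            [cells[cells["sound"] == c] for c in self.conditions], ignore_index=True
        )
        self.x = ordered["abs_mu"].to_numpy(float)
        self.log10x = np.log10(self.x)
        self.n = ordered["n_trials"].to_numpy(float)
        self.k = ordered["n_correct"].to_numpy(float)
        self.gamma_mode = gamma_mode
        self.lambda_mode = lambda_mode
        self.free_gamma = (
            [c for c in BIASED_CONDITIONS if c in self.conditions]
            if gamma_mode == "estimated" else []
        )
        self.free_lambda = lambda_mode == "free"
        nc = len(self.conditions)
        # theta = [log10 alpha_c ... , log10 beta, gamma_free..., lambda?]
        self.n_alpha = nc
        self.i_beta = nc
        self.i_gamma = nc + 1
        self.i_lambda = nc + 1 + len(self.free_gamma)
        self.n_params = self.i_lambda + (1 if self.free_lambda else 0)
        self.fixed_lambda = 0.0 if self.free_lambda else float(lambda_mode)
        if int(self.n.sum()) <= self.n_params:
            raise ValueError("fewer trials than free parameters")

    def unpack(self, theta):
        la = theta[: self.n_alpha]
        beta = 10.0 ** theta[self.i_beta]
        gam = np.full(len(self.conditions), 0.5)
        for j, c in enumerate(self.free_gamma):
            gam[self.conditions.index(c)] = theta[self.i_gamma + j]
        lam = theta[self.i_lambda] if self.free_lambda else self.fixed_lambda
        return la, beta, gam, lam

    def prob(self, theta):
        la, beta, gam, lam = self.unpack(theta)
        F = -np.expm1(-(10.0 ** (beta * (self.log10x - la[self.cond_idx]))))
        g = gam[self.cond_idx]
        return g + (1.0 - g - lam) * F

    def nll(self, theta):
        p = np.clip(self.prob(theta), _PCLIP, 1.0 - _PCLIP)
        return -float(self.k @ np.log(p) + (self.n - self.k) @ np.log1p(-p))

    def bounds(self):
        b = []
        for i, c in enumerate(self.conditions):
            xs = self.x[self.cond_idx == i]
            b.append((np.log10(0.1 * xs.min()), np.log10(10.0 * xs.max())))
        b.append(tuple(np.log10(BETA_BOUNDS)))
        lam_ub = LAPSE_BOUNDS[1] if self.free_lambda else self.fixed_lambda
        for _ in self.free_gamma:
            b.append((0.0, 1.0 - lam_ub - 1e-6))
        if self.free_lambda:
            b.append(LAPSE_BOUNDS)
        return b

    def heuristic_alpha0(self):
        """Per-condition log10 alpha start: |mu| where accuracy crosses 0.75."""
        out = np.empty(len(self.conditions))
        for i in range(len(self.conditions)):
            m = self.cond_idx == i
            x, acc = self.log10x[m], self.k[m] / self.n[m]
            order = np.argsort(x)
            x, acc = x[order], acc[order]
            out[i] = float(np.interp(0.75, np.maximum.accumulate(acc), x))
        return out

    def saturated_ll(self):
        phat = np.clip(self.k / self.n, _PCLIP, 1.0 - _PCLIP)
        return float(self.k @ np.log(phat) + (self.n - self.k) @ np.log1p(-phat))


def _multistart(design, n_grid=3, gamma_starts=(0.3, 0.7), warm=None):
    """Run L-BFGS-B from a coarse (alpha-scale, beta) log-grid, then refine the
    best solution from off-centre guessing-rate starts; ties broken first-found."""
    bounds = design.bounds()
    la0 = design.heuristic_alpha0()
    alpha_scales = np.linspace(-0.5, 0.5, n_grid)  # x0.32 .. x3.2 around heuristic
    beta_grid = np.linspace(np.log10(1.0), np.log10(4.0), n_grid)

    def clipped(theta):
        return np.clip(theta, [b[0] for b in bounds], [b[1] for b in bounds])

    starts = []
    if warm is not None:
        starts.append(clipped(np.asarray(warm, dtype=float)))
    base = np.zeros(design.n_params)
    if design.free_lambda:
        base[design.i_lambda] = 0.02
    for j, c in enumerate(design.free_gamma):
        base[design.i_gamma + j] = 0.5
    for s, lb in itertools.product(alpha_scales, beta_grid):
        th = base.copy()
        th[: design.n_alpha] = la0 + s
        th[design.i_beta] = lb
        starts.append(clipped(th))

    def run(x0):
        return optimize.minimize(
            design.nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 400},
        )

    results = [run(x0) for x0 in starts]
    best = min(results, key=lambda r: r.fun)
    if design.free_gamma:
        for g in gamma_starts:
            th = best.x.copy()
            for j in range(len(design.free_gamma)):
                th[design.i_gamma + j] = g
            results.append(run(clipped(th)))
        best = min(results, key=lambda r: r.fun)
    ok = any(r.success for r in results)
    return best, ok


def fit_joint(cells, gamma_mode="estimated", lambda_mode="free",
              n_grid=3, warm_start=None):
    """Jointly fit the psychometric functions of all conditions in ``cells``.

    Maximises the binomial log-likelihood over {alpha per condition, shared
    beta, gamma for the congruent/incongruent conditions (if
    ``gamma_mode='estimated'``), shared lapse (if ``lambda_mode='free'``)}.
    ``gamma_mode='fixed'`` pins every gamma at 0.5; passing a float as
    ``lambda_mode`` fixes the lapse at that value (used when the lapse has
    been estimated once per observer from all SD levels pooled).

    Multistart: a ``n_grid`` x ``n_grid`` (alpha, beta) log-grid around a
    heuristic 75%-crossing start, plus guessing-rate restarts at {0.3, 0.7}
    around the best optimum.  Non-convergence is flagged, not raised.

    Returns
    -------
    JointFit
    """
    if gamma_mode not in ("estimated", "fixed"):
        raise ValueError("gamma_mode must be 'estimated' or 'fixed'")
    design = _Design(cells, gamma_mode, lambda_mode)
    best, ok = _multistart(design, n_grid=n_grid, warm=warm_start)
    la, beta, gam, lam = design.unpack(best.x)

    bounds = design.bounds()
    eps = 1e-7
    boundary = any(
        best.x[i] <= bounds[i][0] + eps or best.x[i] >= bounds[i][1] - eps
        for i in range(design.n_alpha + 1)  # alpha and beta at their box edges
    )
    acc = design.k / design.n
    if np.all(acc >= 1.0) or np.all(acc <= 0.0):
        boundary = True

    params = {
        c: PsychometricParams(
            alpha=float(10.0 ** la[i]), beta=float(beta),
            gamma=float(gam[i]), lapse=float(lam),
        )
        for i, c in enumerate(design.conditions)
    }
    ll = -best.fun
    fit = JointFit(
        params=params, log_likelihood=ll, converged=ok,
        gamma_mode=gamma_mode, lambda_mode=lambda_mode,
        deviance=2.0 * (design.saturated_ll() - ll), boundary=boundary,
    )
    fit._theta = best.x.copy()
    fit._design = design
    return fit


def _profile_lambda(cells_by_sd, gamma_mode, n_grid, grid=(0.0, 0.02, 0.04, 0.06)):
    """Profile the shared lapse over its bound: coarse grid of fixed-lambda
    joint fits (summed log-likelihood across SD levels, warm-started), then
    one parabolic refinement through the best three grid points."""
    warm = {}

    def total_ll(lam):
        ll = 0.0
        for sd, cells in cells_by_sd.items():
            fit = fit_joint(cells, gamma_mode=gamma_mode, lambda_mode=lam,
                            n_grid=(n_grid if sd not in warm else 1),
                            warm_start=warm.get(sd))
            warm[sd] = fit._theta
            ll += fit.log_likelihood
        return ll

    lls = [total_ll(l) for l in grid]
    i = int(np.argmax(lls))
    if 0 < i < len(grid) - 1:
        x0, x1, x2 = grid[i - 1], grid[i], grid[i + 1]
        y0, y1, y2 = lls[i - 1], lls[i], lls[i + 1]
        denom = (y0 - 2 * y1 + y2)
        if denom < 0:
            lam = x1 + 0.5 * (x0 - x2) * (y0 - y2) / (2 * denom) * -1.0
            lam = float(np.clip(lam, x0, x2))
        else:
            lam = x1
        if abs(lam - grid[i]) > 1e-4 and total_ll(lam) < lls[i]:
            lam = grid[i]
    else:
        lam = grid[i]
    return float(lam), warm


def fit_observer(records, gamma_mode="estimated", n_grid=3):
    """Fit one observer across all SD levels with a single shared lapse.

    The lapse is held constant per observer: it is profiled once from the
    pooled likelihood of all SD levels, then each SD level's joint fit is
    run with the lapse fixed at that value.

    Parameters
    ----------
    records : pandas.DataFrame
        One observer's full trial table (all SD levels, one experiment).

    Returns
    -------
    (dict, float)
        ``{sd_level: JointFit}`` and the shared lapse estimate.
    """
    cells_by_sd = {
        sd: fold_trials(sub)
        for sd, sub in records.groupby("sd_level", observed=True)
    }
    lam, warm = _profile_lambda(cells_by_sd, gamma_mode, n_grid)
    fits = {
        sd: fit_joint(cells, gamma_mode=gamma_mode, lambda_mode=lam,
                      n_grid=1, warm_start=warm.get(sd))
        for sd, cells in cells_by_sd.items()
    }
    return fits, lam


def _param_vector_names(design):
    names = [f"alpha_{c}" for c in design.conditions] + ["beta"]
    names += [f"gamma_{c}" for c in design.free_gamma]
    if design.free_lambda:
        names.append("lambda")
    return names


def bootstrap_fit(joint_fit, cells, n_boot=1000, seed=0, nonparametric=False):
    """Bootstrap standard errors and goodness of fit for a joint fit.

    Parametric by default: ``n_boot`` datasets are simulated from the fitted
    model at the empirical (condition, |mu|, n_trials) design and refitted;
    the SE of each free parameter is the SD of its bootstrap estimates
    (alpha and beta on their natural degree scale).  ``p_dev`` is the
    fraction of bootstrap deviances at least as large as the observed
    deviance — small values flag a poor fit.  ``nonparametric=True``
    resamples binomial counts from the empirical proportions instead.

    Returns an updated ``JointFit`` (SEs, p_dev, failure count); refit
    failures are counted, not raised.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not joint_fit.converged:
        raise ValueError("cannot bootstrap an unconverged fit")
    design = joint_fit._design
    p_model = np.clip(design.prob(joint_fit._theta), _PCLIP, 1 - _PCLIP)
    p_draw = np.clip(design.k / design.n, _PCLIP, 1 - _PCLIP) if nonparametric else p_model
    rng = np.random.default_rng(seed)
    n = design.n.astype(int)

    estimates, deviances, failed = [], [], 0
    template = cells[cells["n_trials"] > 0].copy()
    ordered = pd.concat(
        [template[template["sound"] == c] for c in design.conditions],
        ignore_index=True,
    )
    for _ in range(n_boot):
        k_star = rng.binomial(n, p_draw)
        boot_cells = ordered.copy()
        boot_cells["n_correct"] = k_star
        try:
            bf = fit_joint(
                boot_cells, gamma_mode=joint_fit.gamma_mode,
                lambda_mode=joint_fit.lambda_mode, n_grid=1,
                warm_start=joint_fit._theta,
            )
        except ValueError:
            failed += 1
            continue
        if not bf.converged:
            failed += 1
            continue
        th = bf._theta.copy()
        th[: design.n_alpha] = 10.0 ** th[: design.n_alpha]
        th[design.i_beta] = 10.0 ** th[design.i_beta]
        estimates.append(th)
        deviances.append(bf.deviance)

    est = np.array(estimates)
    names = _param_vector_names(design)
    se = {nm: float(np.std(est[:, j], ddof=1)) for j, nm in enumerate(names)}
    p_dev = float(np.mean(np.asarray(deviances) >= joint_fit.deviance))
    out = replace(joint_fit, se=se, p_dev=p_dev, n_boot_failed=failed)
    out._theta = joint_fit._theta
    out._design = joint_fit._design
    return out


@dataclass
class SignedFit:
    """Conventional signed-function analysis: cumulative Gaussian fit of
    P(respond right) against signed mu.  The mean is the point of subjective
    equality (PSE, the bias measure) and the SD the threshold-like slope."""

    pse: float
    slope_sd: float
    log_likelihood: float
    converged: bool
    reliable: bool


def fit_signed(records):
    """Fit P(respond 'right') vs signed mu with a cumulative Gaussian by
    binomial maximum likelihood, for one sound condition's trials.

    Data spanning only one sign of mu are fitted but flagged unreliable.
    """
    if len(records) == 0:
        raise ValueError("empty trial table")
    tab = (
        records.assign(right=(records["response"] == "right"))
        .groupby("mu", observed=True)["right"]
        .agg(n="size", k="sum")
        .reset_index()
    )
    mu = tab["mu"].to_numpy(float)
    n = tab["n"].to_numpy(float)
    k = tab["k"].to_numpy(float)
    reliable = (mu.min() < 0) and (mu.max() > 0)

    span = max(mu.max() - mu.min(), 1e-3)

    def nll(theta):
        pse, log_sd = theta
        p = np.clip(sps.norm.cdf((mu - pse) / np.exp(log_sd)), _PCLIP, 1 - _PCLIP)
        return -float(k @ np.log(p) + (n - k) @ np.log1p(-p))

    best = None
    for sd0 in (span / 8, span / 2):
        for pse0 in (0.0, float(np.median(mu))):
            res = optimize.minimize(
                nll, [pse0, np.log(sd0)], method="L-BFGS-B",
                bounds=[(mu.min() - span, mu.max() + span),
                        (np.log(span / 200), np.log(span * 10))],
                options={"ftol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
    return SignedFit(
        pse=float(best.x[0]), slope_sd=float(np.exp(best.x[1])),
        log_likelihood=-float(best.fun), converged=bool(best.success),
        reliable=bool(reliable),
    )
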