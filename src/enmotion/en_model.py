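"""Equivalent-noise (EN) model: decompose direction-discrimination thresholds
into internal noise and sampling efficiency.

The EN paradigm varies the external directional noise sigma_ext (the SD of the
dot-direction distribution) and models the observed threshold as

    sigma_obs = sqrt((sigma_int**2 + sigma_ext**2) / N_samp)

where ``sigma_int`` (degrees) is the observer's intrinsic uncertainty about
individual local motion directions and ``N_samp`` (dimensionless) is the
effective number of local samples pooled into the global direction estimate.
Thresholds are flat while external noise is below internal noise and rise with
slope 1 (log-log) once external noise dominates.

Fitting minimises the sum of squared errors between log-predicted and
log-observed thresholds (natural log; the minimiser is base-invariant),

    SSE = sum_i (log(sigma_pred_i) - log(sigma_obs_i))**2,

over (sigma_int, N_samp), with multistart random restarts in log-parameter
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ENFit",
    "TvNData",
    "en_sigma_obs",
    "fit_en",
    "assemble_tvn",
    "group_tvn",
]

#: Parameter box constraints: sigma_int in (0, 90] degrees, N_samp in [1, 300].
SIGMA_INT_BOUNDS = (1e-3, 90.0)
N_SAMP_BOUNDS = (1.0, 300.0)


def en_sigma_obs(sigma_int, sigma_ext, n_samp):
    """Predicted threshold sqrt((sigma_int^2 + sigma_ext^2) / N_samp).

    Parameters
    ----------
    sigma_int : float or array
        Internal noise in degrees, > 0.
    sigma_ext : float or array
        External noise (direction SD) in degrees, >= 0.
    n_samp : float or array
        Sampling efficiency, >= 1.

    Returns
    -------
    float or ndarray
        Predicted threshold in degrees.  Strictly increasing in both noise
        terms and strictly decreasing in ``n_samp``.
    """
    sigma_int = np.asarray(sigma_int, dtype=float)
    sigma_ext = np.asarray(sigma_ext, dtype=float)
    n_samp = np.asarray(n_samp, dtype=float)
    if np.any(sigma_int <= 0):
        raise ValueError("sigma_int must be > 0")
    if np.any(sigma_ext < 0):
        raise ValueError("sigma_ext must be >= 0")
    if np.any(n_samp < 1):
        raise ValueError("n_samp must be >= 1")
    out = np.sqrt((sigma_int**2 + sigma_ext**2) / n_samp)
    return out if out.ndim else float(out)


@dataclass
class ENFit:
    """Result of an equivalent-noise fit for one sound condition."""

    sigma_int: float
    n_samp: float
    sse: float
    n_starts_converged: int = 0
    converged: bool = True
    at_bounds: bool = False

    def predict(self, sigma_ext):
        return en_sigma_obs(self.sigma_int, sigma_ext, self.n_samp)

    def to_dict(self):
        return {
            "sigma_int": self.sigma_int,
            "n_samp": self.n_samp,
            "sse": self.sse,
            "n_starts_converged": self.n_starts_converged,
            "converged": self.converged,
            "at_bounds": self.at_bounds,
        }


def _sse(log_params, sigma_ext, log_thresh):
    log_si, log_n = log_params
    si2 = np.exp(2.0 * log_si)
    log_pred = 0.5 * np.log(si2 + sigma_ext**2) - 0.5 * log_n
    r = log_pred - log_thresh
    return float(r @ r)


def fit_en(sigma_ext, thresholds, n_starts=20, seed=0):
    """Fit the EN model to one condition's threshold-vs-noise data.

    Least squares on natural-log thresholds, with ``n_starts`` random
    restarts drawn log-uniformly over the parameter box (seeded) in addition
    to a deterministic moment-based start.  The restart count follows the
    convention of repeating the fit 20 times from varied initial guesses and
    keeping the solution with the lowest SSE.

    Parameters
    ----------
    sigma_ext : array-like
        External noise levels in degrees (>= 0); at least 2 points.
    thresholds : array-like
        Observed thresholds in degrees (> 0), same length.
    n_starts : int
        Number of random restarts (besides the deterministic start).
    seed : int
        Seed for the restart draw.

    Returns
    -------
    ENFit
        Best local optimum; ``n_starts_converged`` counts how many starts
        landed within 1% (both parameters) of the best solution.
    """
    sigma_ext = np.asarray(sigma_ext, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    mask = np.isfinite(thresholds) & np.isfinite(sigma_ext)
    sigma_ext, thresholds = sigma_ext[mask], thresholds[mask]
    if sigma_ext.size < 2:
        raise ValueError("need at least two (sigma_ext, threshold) pairs")
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be > 0")
    log_thresh = np.log(thresholds)

    lo = np.log([SIGMA_INT_BOUNDS[0], N_SAMP_BOUNDS[0]])
    hi = np.log([SIGMA_INT_BOUNDS[1], N_SAMP_BOUNDS[1]])
    bounds = list(zip(lo, hi))

    # Moment start: zero-noise point pins sigma_int/sqrt(N); highest-noise
    # point pins the efficiency given sigma_ext >> sigma_int.
    t0 = thresholds[np.argmin(sigma_ext)]
    se_max = max(sigma_ext.max(), 1.0)
    n0 = np.clip((se_max / thresholds[np.argmax(sigma_ext)]) ** 2, *N_SAMP_BOUNDS)
    si0 = np.clip(t0 * np.sqrt(n0), *SIGMA_INT_BOUNDS)
    starts = [np.log([si0, n0])]

    rng = np.random.default_rng(seed)
    starts.extend(rng.uniform(lo, hi, size=(n_starts, 2)))

    results = []
    for x0 in starts:
        res = optimize.minimize(
            _sse, x0, args=(sigma_ext, log_thresh), method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        results.append(res)

    best = min(results, key=lambda r: r.fun)
    si, ns = np.exp(best.x)
    n_close = sum(
        1 for r in results
        if np.all(np.abs(np.exp(r.x) - np.exp(best.x)) <= 0.01 * np.exp(best.x))
    )
    eps = 1e-6
    at_bounds = bool(
        best.x[0] <= lo[0] + eps or best.x[0] >= hi[0] - eps
        or best.x[1] <= lo[1] + eps or best.x[1] >= hi[1] - eps
    )
    return ENFit(
        sigma_int=float(si), n_samp=float(ns), sse=float(best.fun),
        n_starts_converged=n_close, converged=bool(best.success), at_bounds=at_bounds,
    )


@dataclass
class TvNData:
    """Threshold-vs-noise data: per sound condition, thresholds at each
    external-noise (SD) level.  Missing cells are NaN and flagged."""

    sigma_ext: np.ndarray  # shape (n_sd,)
    thresholds: dict = field(default_factory=dict)  # condition -> array (n_sd,)

    @property
    def conditions(self):
        return list(self.thresholds)

    def log_threshold(self, condition):
        """Natural-log thresholds for one condition (NaN where missing)."""
        return np.log(self.thresholds[condition])

    def missing(self, condition):
        return ~np.isfinite(self.thresholds[condition])

    def n_cells(self):
        return sum(np.size(v) for v in self.thresholds.values())

    def fit_condition(self, condition, n_starts=20, seed=0):
        """EN fit for one condition, excluding missing cells from the SSE."""
        th = self.thresholds[condition]
        ok = np.isfinite(th)
        return fit_en(self.sigma_ext[ok], th[ok], n_starts=n_starts, seed=seed)

    def fit_all(self, n_starts=20, seed=0):
        seeds = np.random.SeedSequence(seed).spawn(len(self.thresholds))
        return {
            c: self.fit_condition(c, n_starts=n_starts,
                                  seed=s.generate_state(1)[0] % (2**31))
            for (c, s) in zip(self.thresholds, seeds)
        }


def assemble_tvn(fits_by_sd):
    """Build one observer's TvN data from joint psychometric fits.

    Parameters
    ----------
    fits_by_sd : dict
        Mapping ``sd_level -> JointFit`` (psychofit); the fitted threshold
        alpha of each condition at each SD level becomes one TvN cell.
        With 5 SD levels and 4 sound conditions this yields 20 cells.

    Returns
    -------
    TvNData
        Unconverged or absent cells are NaN (flagged missing, not imputed).
    """
    if len(fits_by_sd) < 3:
        raise ValueError("need fits for at least 3 SD levels")
    sds = np.array(sorted(fits_by_sd), dtype=float)
    conditions = list(fits_by_sd[sorted(fits_by_sd)[0]].params)
    thresholds = {c: np.full(sds.size, np.nan) for c in conditions}
    for i, sd in enumerate(sorted(fits_by_sd)):
        fit = fits_by_sd[sd]
        for c in conditions:
            p = fit.params.get(c)
            if p is not None and fit.converged:
                thresholds[c][i] = p.alpha
    return TvNData(sigma_ext=sds, thresholds=thresholds)


def group_tvn(tvns):
    """Group-level TvN: per-cell mean of natural-log thresholds (i.e. the
    geometric mean threshold) across observers, skipping missing cells."""
    if not tvns:
        raise ValueError("no TvN data given")
    ref = tvns[0]
    for t in tvns[1:]:
        if not np.array_equal(t.sigma_ext, ref.sigma_ext):
            raise ValueError("observers have mismatched SD levels")
    out = {}
    for c in ref.conditions:
        logs = np.stack([t.log_threshold(c) for t in tvns])
        with np.errstate(invalid="ignore"):
            out[c] = np.exp(np.nanmean(logs, axis=0))
    return TvNData(sigma_ext=ref.sigma_ext.copy(), thresholds=out)
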