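"""Within-subject statistics for the equivalent-noise battery.

Implements the repeated-measures toolkit applied to guessing rates, log
thresholds, internal noise and sampling efficiency: one- and two-factor
repeated-measures ANOVA (sum-of-squares decomposition, partial eta squared,
Greenhouse-Geisser sphericity correction gated by Mauchly's test),
Bonferroni-corrected paired post-hoc t-tests with Cohen's d, and the JZS
(Cauchy-prior) Bayes factor for paired contrasts by one-dimensional
numerical integration.

All tables are tidy pandas DataFrames: one row per effect or contrast.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

__all__ = [
    "rm_anova",
    "gg_epsilon",
    "mauchly_test",
    "posthoc_paired",
    "jzs_bf_paired",
    "bf10_bic_from_f",
]


def _pivot(data, dv, within, subject):
    """Balanced subject x cells matrix; raises on missing/duplicate cells."""
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean", observed=True)
    full = data.groupby([subject] + within, observed=True)[dv].count()
    if (full != 1).any():
        raise ValueError("design must have exactly one observation per cell")
    if wide.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return wide


def _orthonormal_contrasts(k):
    """(k-1) x k orthonormal contrast matrix (Helmert, normalised)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def gg_epsilon(matrix):
    """Greenhouse-Geisser epsilon for an n-subjects x k-levels matrix.

    Computed from the eigenvalues of the double-centered covariance of the
    level scores: epsilon = (sum lam)^2 / ((k-1) * sum lam^2), bounded in
    [1/(k-1), 1]; identically 1 when k = 2.
    """
    y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if k < 2:
        raise ValueError("need at least 2 levels")
    c = _orthonormal_contrasts(k)
    s = np.cov(y @ c.T, rowvar=False).reshape(k - 1, k - 1)
    tr = np.trace(s)
    denom = (k - 1) * np.trace(s @ s)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(matrix):
    """Mauchly's sphericity test for an n x k within-subject matrix.

    Returns (W, chi2, df, p) using the standard chi-square approximation.
    For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    y = np.asarray(matrix, dtype=float)
    n, k = y.shape
    p = k - 1
    if p < 2:
        return 1.0, 0.0, 0, 1.0
    c = _orthonormal_contrasts(k)
    s = np.cov(y @ c.T, rowvar=False)
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 1e-300):
        return 0.0, np.inf, p * (p + 1) // 2 - 1, 0.0
    w = float(np.prod(eig) / (np.mean(eig) ** p))
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    df = p * (p + 1) // 2 - 1
    return w, float(chi2), int(df), float(sps.chi2.sf(chi2, df))


def _effect_row(name, ss_eff, ss_err, df1, df2, eff_matrix):
    """Assemble one ANOVA row; eff_matrix is the subject x cells matrix the
    sphericity quantities are computed from (levels of this effect)."""
    if ss_err <= 0 and ss_eff <= 0:
        warnings.warn(f"effect {name!r}: no variance; F defined as 0")
        f = 0.0
    elif ss_err <= 0:
        f = np.inf
    else:
        f = (ss_eff / df1) / (ss_err / df2)
    k = eff_matrix.shape[1]
    eps = gg_epsilon(eff_matrix) if k > 2 else 1.0
    w, chi2, mdf, mp = mauchly_test(eff_matrix)
    p_unc = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    p_gg = float(sps.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else 0.0
    sphericity_violated = mp < 0.05
    return {
        "effect": name,
        "F": float(f),
        "df_num": float(df1),
        "df_den": float(df2),
        "epsilon_gg": float(eps),
        "df_num_gg": float(df1 * eps),
        "df_den_gg": float(df2 * eps),
        "p_uncorrected": p_unc,
        "p_gg": p_gg,
        "p": p_gg if sphericity_violated else p_unc,
        "sphericity_violated": bool(sphericity_violated),
        "mauchly_W": float(w),
        "mauchly_p": float(mp),
        "eta_p_sq": float(ss_eff / (ss_eff + ss_err)) if (ss_eff + ss_err) > 0 else 0.0,
    }


def rm_anova(data, dv, within, subject="subject"):
    """One- or two-factor repeated-measures ANOVA (fully within-subject).

    Parameters
    ----------
    data : pandas.DataFrame
        Tidy long table: one row per (subject, cell), balanced and complete.
    dv : str
        Dependent-variable column.
    within : str or list of str
        One or two within-subject factor columns.
    subject : str
        Subject-identifier column.

    Returns
    -------
    pandas.DataFrame
        One row per effect with F, degrees of freedom, Greenhouse-Geisser
        epsilon and corrected dfs/p, Mauchly's test, uncorrected and
        corrected p (the ``p`` column is the corrected one when sphericity
        is rejected at 0.05), and partial eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("one or two within-subject factors supported")

    if len(within) == 1:
        wide = _pivot(data, dv, within, subject)
        y = wide.to_numpy(float)
        n, k = y.shape
        grand = y.mean()
        ss_eff = n * ((y.mean(axis=0) - grand) ** 2).sum()
        ss_sub = k * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_eff - ss_sub
        row = _effect_row(within[0], ss_eff, max(ss_err, 0.0),
                          k - 1, (n - 1) * (k - 1), y)
        return pd.DataFrame([row])

    fa, fb = within
    wide = _pivot(data, dv, within, subject)
    levels_a = wide.columns.get_level_values(0).unique()
    levels_b = wide.columns.get_level_values(1).unique()
    a, b = len(levels_a), len(levels_b)
    n = wide.shape[0]
    y = wide.to_numpy(float).reshape(n, a, b)

    grand = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_s = y.mean(axis=(1, 2))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (y - m_ab[None] - m_sa[:, :, None] - m_sb[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - grand)
    ss_abs = (resid**2).sum()

    rows = [
        _effect_row(fa, ss_a, ss_as, a - 1, (n - 1) * (a - 1), m_sa),
        _effect_row(fb, ss_b, ss_bs, b - 1, (n - 1) * (b - 1), m_sb),
    ]
    # Interaction sphericity from the doubly-contrasted cell scores.
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    c_ab = np.kron(ca, cb)
    inter = y.reshape(n, a * b) @ c_ab.T
    row_ab = _effect_row(f"{fa}*{fb}", ss_ab, ss_abs,
                         (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1),
                         np.zeros((n, 2)))  # placeholder, replaced below
    if inter.shape[1] > 1:
        s = np.cov(inter, rowvar=False)
        tr = np.trace(s)
        d2 = inter.shape[1] * np.trace(s @ s)
        eps = float(np.clip(tr**2 / d2, 1.0 / inter.shape[1], 1.0)) if d2 > 0 else 1.0
    else:
        eps = 1.0
    eig_ok = inter.shape[1] >= 2
    if eig_ok:
        eigv = np.linalg.eigvalsh(np.atleast_2d(np.cov(inter, rowvar=False)))
        if np.any(eigv <= 1e-300):
            w, mp = 0.0, 0.0
        else:
            p_ = inter.shape[1]
            w = float(np.prod(eigv) / np.mean(eigv) ** p_)
            d = 1.0 - (2.0 * p_**2 + p_ + 2.0) / (6.0 * p_ * (n - 1.0))
            chi2 = -(n - 1.0) * d * np.log(w)
            mp = float(sps.chi2.sf(chi2, p_ * (p_ + 1) // 2 - 1))
    else:
        w, mp = 1.0, 1.0
    df1, df2 = (a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1)
    f_ab = row_ab["F"]
    row_ab.update({
        "epsilon_gg": eps, "df_num_gg": df1 * eps, "df_den_gg": df2 * eps,
        "p_gg": float(sps.f.sf(f_ab, df1 * eps, df2 * eps)) if np.isfinite(f_ab) else 0.0,
        "mauchly_W": w, "mauchly_p": mp, "sphericity_violated": bool(mp < 0.05),
    })
    row_ab["p"] = row_ab["p_gg"] if row_ab["sphericity_violated"] else row_ab["p_uncorrected"]
    rows.append(row_ab)
    return pd.DataFrame(rows)


def posthoc_paired(data, dv, within, subject="subject", correction="bonferroni",
                   bf_scale=np.sqrt(2) / 2):
    """All pairwise paired t-tests (two-tailed) between factor levels.

    Cohen's d is the mean difference divided by the SD of the differences;
    the Bonferroni multiplier is the number of pairwise contrasts, with
    corrected p capped at 1.  A JZS Bayes factor accompanies each contrast.
    Zero-variance differences leave t/d undefined (NaN, flagged).
    """
    wide = _pivot(data, dv, [within], subject)
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for x, yl in pairs:
        d = wide[x].to_numpy(float) - wide[yl].to_numpy(float)
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            # No variance in the differences: a strictly null contrast
            # (all zero) reports t = d = 0; a constant nonzero difference
            # leaves them undefined.
            null = bool(np.all(d == 0))
            rows.append({
                "A": x, "B": yl, "n": n,
                "t": 0.0 if null else np.nan, "df": n - 1,
                "p_uncorrected": 1.0 if null else np.nan,
                "p_bonferroni": 1.0 if null else np.nan,
                "cohens_d": 0.0 if null else np.nan,
                "bf10": np.nan, "degenerate": True,
            })
            continue
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
        rows.append({
            "A": x, "B": yl, "n": n, "t": float(t), "df": n - 1,
            "p_uncorrected": float(p),
            "p_bonferroni": float(min(1.0, m * p)) if correction == "bonferroni" else float(p),
            "cohens_d": float(d.mean() / sd),
            "bf10": jzs_bf_paired(wide[x].to_numpy(float), wide[yl].to_numpy(float),
                                  scale=bf_scale),
            "degenerate": False,
        })
    return pd.DataFrame(rows)


def _jzs_bf10_from_t(t, n, scale):
    """JZS Bayes factor from a one-sample/paired t statistic.

    Cauchy(0, scale) prior on the standardised effect, expressed as the
    usual inverse-gamma(1/2, 1/2) mixture over the prior variance g and
    integrated numerically.
    """
    nu = n - 1.0

    def integrand(g):
        c = 1.0 + n * g * scale**2
        return (
            c**-0.5
            * (1.0 + t**2 / (c * nu)) ** (-(nu + 1.0) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0:
        raise FloatingPointError("JZS integration failed")
    den = (1.0 + t**2 / nu) ** (-(nu + 1.0) / 2.0)
    return float(num / den)


def jzs_bf_paired(a, b=None, scale=np.sqrt(2) / 2):
    """JZS Bayes factor (BF10) for a paired (or one-sample) t contrast.

    ``a`` and ``b`` are paired samples (``b`` omitted: test ``a`` against
    zero).  ``scale`` is the Cauchy prior scale on the standardised effect
    (default sqrt(2)/2, the conventional 'medium' prior).  BF10 > 1 favours
    the alternative.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    return _jzs_bf10_from_t(float(t), float(n), float(scale))


def bf10_bic_from_f(f, df1, df2, n_obs):
    """Rough BIC-approximated Bayes factor for an ANOVA effect.

    Uses the unit-information approximation BF10 ~ exp((BIC_0 - BIC_1)/2)
    with the residual-variance ratio implied by F.  This is a coarse
    approximation (it ignores the within-subject prior structure); use it
    for orientation only, not as a substitute for a full model comparison.
    """
    if f < 0 or n_obs <= 0:
        raise ValueError("invalid inputs")
    return float((1.0 + f * df1 / df2) ** (n_obs / 2.0) * n_obs ** (-df1 / 2.0))
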