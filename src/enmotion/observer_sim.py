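"""Synthetic 2AFC sessions for the audiovisual equivalent-noise task.

Observers discriminate whether the mean direction of a random-dot motion
field tilts up-left or up-right (responding with the left/right arrow key)
while a task-irrelevant sound is absent, stationary, congruent with the
visual direction, or incongruent.  Directions of individual dots are drawn
from Normal(mu, sigma_ext); the external noise sigma_ext is fixed within a
run and the four sound conditions are intermixed trial by trial, so the
sound is informative only by chance.

Two generative observers are provided:

* :func:`simulate_model_faithful` draws correctness directly from the
  psychometric model psi(|mu|) with threshold alpha = sigma_obs(sigma_int,
  sigma_ext, N_samp) per condition — the exact inverse of the fitted model,
  which makes parameter recovery well-posed.  Decisional bias enters as a
  condition-specific guessing rate (gamma > 0.5 congruent, < 0.5
  incongruent for an observer who leans toward the sound when unsure).
* :func:`simulate_mechanistic` implements the process story: sample N_samp
  dot directions, corrupt each with internal noise, average, add a signed
  criterion shift toward the sound's lateral direction, respond by sign.
  It is used for realism cross-checks, not quantitative recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .en_model import en_sigma_obs

__all__ = [
    "SOUNDS",
    "ObserverParams",
    "EXPERIMENTS",
    "make_session_design",
    "make_experiment_design",
    "choose_mu_magnitudes",
    "sample_dot_directions",
    "simulate_model_faithful",
    "simulate_mechanistic",
    "speaker_angular_speed",
    "speaker_diagonal",
    "write_trials",
    "read_trials",
]

SOUNDS = ("absent", "stationary", "congruent", "incongruent")

#: CSV schema for trial tables (angles in degrees).
TRIAL_COLUMNS = [
    "experiment", "observer", "run", "trial",
    "sd_level", "mu", "sound", "response", "correct",
]

#: Study templates for the two experiments: dot/element counts, stimulus
#: duration, external-noise levels, candidate |mu| magnitudes, repetition
#: structure, and speaker geometry.  Every constant can be overridden.
EXPERIMENTS = {
    1: {
        "n_dots": 100,
        "duration_s": 0.8,
        "sd_levels": (0.0, 4.0, 8.0, 16.0, 32.0),
        "mu_magnitudes": (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
        "n_mu_magnitudes": 5,          # 5 magnitudes -> 10 signed levels
        "include_mu_zero": False,
        "reps_per_condition": 10,
        "n_runs": 4,
        "speaker_separation_cm": 56.5,
        "speaker_distance_cm": 70.0,
    },
    2: {
        "n_dots": 300,
        "duration_s": 0.5,
        "sd_levels": (0.0, 4.0, 8.0, 16.0, 32.0),
        "mu_magnitudes": (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
        "n_mu_magnitudes": 5,          # plus mu = 0 -> 11 signed levels
        "include_mu_zero": True,
        "reps_per_condition": 10,
        "n_runs": 4,
        "speaker_horizontal_cm": 39.0,
        "speaker_vertical_cm": 52.0,
        "speaker_distance_cm": 85.0,
    },
}


@dataclass
class ObserverParams:
    """Generative parameters of one simulated observer.

    ``sigma_int`` and ``n_samp`` may be a single float (shared across sound
    conditions) or a dict mapping condition names to values.  ``gamma`` is
    the guessing rate per condition; absent and stationary default to (and
    ordinarily stay at) 0.5, since only a directional sound can bias the
    left/right guess.  ``beta`` is the true psychometric slope used by the
    model-faithful generator; ``criterion_shift`` (degrees) is the additive
    decisional shift toward the sound's direction used by the mechanistic
    generator.
    """

    sigma_int: object = 9.0
    n_samp: object = 10.0
    gamma: dict = field(default_factory=dict)
    lapse: float = 0.02
    beta: float = 2.0
    criterion_shift: float = 0.0
    name: str = "obs1"

    def __post_init__(self):
        g = {c: 0.5 for c in SOUNDS}
        g.update(self.gamma)
        self.gamma = g
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        for c in SOUNDS:
            if not 0.0 <= self.gamma[c] <= 1.0:
                raise ValueError("gamma must lie in [0, 1]")
        for c in SOUNDS:
            if self.sigma_int_for(c) <= 0:
                raise ValueError("sigma_int must be > 0")
            if self.n_samp_for(c) < 1:
                raise ValueError("n_samp must be >= 1")

    def _per_cond(self, value, cond):
        return float(value[cond]) if isinstance(value, dict) else float(value)

    def sigma_int_for(self, cond):
        return self._per_cond(self.sigma_int, cond)

    def n_samp_for(self, cond):
        return self._per_cond(self.n_samp, cond)

    def alpha_for(self, cond, sd_level):
        """True threshold at one external-noise level for one condition."""
        return en_sigma_obs(self.sigma_int_for(cond), sd_level, self.n_samp_for(cond))


def choose_mu_magnitudes(expected_threshold, candidates, n=5):
    """Pick the n candidate |mu| magnitudes closest (in log distance) to an
    anticipated threshold — the per-observer level selection used when
    charting a psychometric function with constant stimuli."""
    candidates = np.asarray(sorted(candidates), dtype=float)
    if n >= candidates.size:
        return candidates.tolist()
    d = np.abs(np.log(candidates) - np.log(expected_threshold))
    keep = np.sort(np.argsort(d, kind="stable")[:n])
    return candidates[keep].tolist()


def make_session_design(experiment, sd_level, mu_levels, reps_per_condition=10,
                        n_runs=1, seed=0, observer="obs1"):
    """Build the trial list for one external-noise level.

    Each run crosses every signed mu level with the four sound conditions,
    ``reps_per_condition`` times (10 levels x 4 sounds x 10 reps = 400
    trials per run in the full design), and shuffles the order with a
    seeded permutation so the sound conditions are intermixed trial by
    trial.  The same seed reproduces the same order.

    Returns
    -------
    pandas.DataFrame
        Columns experiment, observer, run, trial, sd_level, mu, sound.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment id {experiment!r}")
    mu_levels = list(mu_levels)
    if not mu_levels:
        raise ValueError("mu_levels must be non-empty")
    if reps_per_condition < 1 or n_runs < 1:
        raise ValueError("reps_per_condition and n_runs must be >= 1")
    if sd_level < 0:
        raise ValueError("sd_level must be >= 0")

    rng = np.random.default_rng(seed)
    block = [
        (mu, sound)
        for mu in mu_levels
        for sound in SOUNDS
        for _ in range(reps_per_condition)
    ]
    frames = []
    for run in range(1, n_runs + 1):
        order = rng.permutation(len(block))
        mus = np.array([block[i][0] for i in order], dtype=float)
        snd = np.array([block[i][1] for i in order], dtype=object)
        frames.append(pd.DataFrame({
            "experiment": experiment,
            "observer": observer,
            "run": run,
            "trial": np.arange(1, len(block) + 1),
            "sd_level": float(sd_level),
            "mu": mus,
            "sound": snd,
        }))
    return pd.concat(frames, ignore_index=True)


def make_experiment_design(experiment, observer=None, seed=0, overrides=None):
    """Full protocol for one observer: every SD level x ``n_runs`` runs.

    The |mu| magnitudes at each SD level are chosen around the observer's
    anticipated threshold there (mirroring per-participant level selection);
    without an observer the geometric mid-range is used.  The full
    Experiment-1 protocol yields 5 SD levels x 4 runs x 400 trials = 8,000
    trials.
    """
    tpl = dict(EXPERIMENTS[experiment])
    if overrides:
        tpl.update(overrides)
    child = np.random.SeedSequence(seed).spawn(len(tpl["sd_levels"]))
    frames = []
    name = observer.name if observer is not None else "obs1"
    for sd, ss in zip(tpl["sd_levels"], child):
        if observer is not None:
            anticipated = np.mean([observer.alpha_for(c, sd) for c in SOUNDS])
        else:
            anticipated = math.sqrt(
                min(tpl["mu_magnitudes"]) * max(tpl["mu_magnitudes"])
            )
        mags = choose_mu_magnitudes(
            anticipated, tpl["mu_magnitudes"], tpl["n_mu_magnitudes"]
        )
        levels = [-m for m in mags[::-1]] + ([0.0] if tpl["include_mu_zero"] else []) + mags
        frames.append(make_session_design(
            experiment, sd, levels,
            reps_per_condition=tpl["reps_per_condition"],
            n_runs=tpl["n_runs"],
            seed=int(ss.generate_state(1)[0] % (2**31)),
            observer=name,
        ))
    return pd.concat(frames, ignore_index=True)


def sample_dot_directions(mu, sigma_ext, n_dots, seed=0):
    """Draw the per-dot motion directions of one stimulus frame set.

    Directions (degrees from vertical; positive = up-right) are sampled from
    Normal(mu, sigma_ext).  No circular wrapping is applied: with
    sigma_ext <= 32 degrees the wrap probability is negligible.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    if sigma_ext < 0:
        raise ValueError("sigma_ext must be >= 0")
    rng = np.random.default_rng(seed)
    return mu + sigma_ext * rng.standard_normal(n_dots)


def _sound_side(mu, sound, rng):
    """Lateral direction of the sound: matches sign(mu) when congruent,
    opposes it when incongruent, 0 for non-directional sounds.  For mu = 0
    the directional sound's side is drawn at random."""
    side = np.zeros(len(mu))
    directional = np.isin(sound, ("congruent", "incongruent"))
    s = np.sign(mu)
    s[s == 0] = rng.choice([-1.0, 1.0], size=int((s == 0).sum()))
    side[directional] = s[directional]
    side[sound == "incongruent"] *= -1.0
    return side


def simulate_model_faithful(observer, trials, seed=0):
    """Simulate responses by drawing correctness from the psychometric model.

    For each trial, P(correct) = gamma_c + (1 - gamma_c - lambda) *
    F(|mu|; alpha_c, beta) where alpha_c = sigma_obs(sigma_int_c, sigma_ext,
    N_samp_c) for that trial's sound condition c and external noise, and F
    is the Weibull on log10 intensity.  Trials with mu = 0 carry no signal
    and are routed to pure guessing, P(correct) = gamma_c; they are flagged
    ``excluded`` (no defined correct side) with a response drawn at random.

    Returns a copy of ``trials`` with ``response``, ``correct`` and
    ``excluded`` columns.
    """
    from .psychofit import psychometric_value, PsychometricParams

    out = trials.copy()
    rng = np.random.default_rng(seed)
    mu = out["mu"].to_numpy(float)
    sd = out["sd_level"].to_numpy(float)
    sound = out["sound"].to_numpy(object)

    p = np.empty(len(out))
    for c in np.unique(sound):
        m = sound == c
        gam = observer.gamma[c]
        for s in np.unique(sd[m]):
            mm = m & (sd == s)
            alpha = observer.alpha_for(c, s)
            pars = PsychometricParams(alpha=alpha, beta=observer.beta,
                                      gamma=gam, lapse=observer.lapse)
            x = np.abs(mu[mm])
            pc = np.full(x.size, gam)
            nz = x > 0
            pc[nz] = psychometric_value(x[nz], pars)
            p[mm] = pc

    correct = rng.random(len(out)) < p
    sign = np.sign(mu)
    zero = sign == 0
    sign[zero] = rng.choice([-1.0, 1.0], size=int(zero.sum()))
    resp_sign = np.where(correct, sign, -sign)
    out["response"] = np.where(resp_sign > 0, "right", "left")
    out["correct"] = np.where(zero, False, correct)
    out["excluded"] = zero
    return out


def simulate_mechanistic(observer, trials, seed=0):
    """Simulate responses from the sampling process itself.

    Per trial: draw round(N_samp) dot directions from Normal(mu, sigma_ext),
    add independent Normal(0, sigma_int) internal noise to each, average,
    add ``criterion_shift`` degrees toward the sound's lateral side on
    congruent/incongruent trials, and respond by the sign of the result.
    With probability lambda the response is instead uniform (a lapse).  With
    no shift and no lapse, accuracy at offset mu follows Phi(mu / sigma_obs)
    with sigma_obs from the variance-summation rule.
    """
    out = trials.copy()
    rng = np.random.default_rng(seed)
    mu = out["mu"].to_numpy(float)
    sd = out["sd_level"].to_numpy(float)
    sound = out["sound"].to_numpy(object)

    est = np.empty(len(out))
    for c in np.unique(sound):
        m = sound == c
        n_pool = int(round(observer.n_samp_for(c)))
        exp_ids = out.loc[m, "experiment"].unique()
        n_avail = min(EXPERIMENTS[int(e)]["n_dots"] for e in exp_ids)
        if n_pool > n_avail:
            raise ValueError(
                f"N_samp={n_pool} exceeds the {n_avail} dots available"
            )
        k = int(m.sum())
        dots = mu[m, None] + sd[m, None] * rng.standard_normal((k, n_pool))
        dots += observer.sigma_int_for(c) * rng.standard_normal((k, n_pool))
        est[m] = dots.mean(axis=1)

    est += observer.criterion_shift * _sound_side(mu, sound, rng)
    resp_sign = np.where(est > 0, 1.0, -1.0)
    lapse = rng.random(len(out)) < observer.lapse
    resp_sign[lapse] = rng.choice([-1.0, 1.0], size=int(lapse.sum()))
    out["response"] = np.where(resp_sign > 0, "right", "left")
    out["correct"] = (resp_sign == np.sign(mu)) & (mu != 0)
    out["excluded"] = mu == 0
    return out


def speaker_angular_speed(separation_cm, distance_cm, duration_s):
    """Angular and linear speed of a sound sweeping between two speakers.

    The sound traverses the angle subtended by the speaker pair,
    2*arctan((separation/2)/distance), in ``duration_s`` seconds.

    Returns
    -------
    (float, float)
        Speed in degrees/s and in m/s.
    """
    if separation_cm <= 0 or distance_cm <= 0 or duration_s <= 0:
        raise ValueError("geometry and duration must be positive")
    angle_deg = 2.0 * math.degrees(math.atan((separation_cm / 2.0) / distance_cm))
    return angle_deg / duration_s, (separation_cm / 100.0) / duration_s


def speaker_diagonal(horizontal_cm, vertical_cm):
    """Diagonal separation of a corner-mounted speaker pair (cm)."""
    if horizontal_cm <= 0 or vertical_cm <= 0:
        raise ValueError("spacings must be positive")
    return math.hypot(horizontal_cm, vertical_cm)


def write_trials(trials, path):
    """Write a trial table as CSV with the canonical column order."""
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    cols += [c for c in trials.columns if c not in cols]
    trials[cols].to_csv(path, index=False)


def read_trials(path):
    """Read a trial-table CSV (same schema as :func:`write_trials`)."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - {"response", "correct"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(bool)
    return df
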