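# Methods

## Task and model

The task is 2AFC discrimination of a global motion direction: on each trial
the dot field's mean direction μ tilts up-left (μ < 0) or up-right (μ > 0)
by |μ| degrees, individual dot directions are drawn from Normal(μ, σ_ext),
and a task-irrelevant sound is absent, stationary, congruent or
incongruent with the visual tilt. Sessions follow the method of constant
stimuli: σ_ext fixed within a run, signed μ levels crossed with the four
sound conditions and shuffled trial by trial (10 levels × 4 sounds ×
10 reps = 400 trials per run; 5 σ_ext levels × 4 runs = 8,000 trials per
observer in the Experiment-1 template; the Experiment-2 template adds a
μ = 0 level, generated but flagged excluded from analysis).

Accuracy folded over the sign of μ is modelled by
ψ(x) = γ + (1 − γ − λ)·F(x; α, β) with F the Weibull on log₁₀ intensity
(the Gumbel / log-Weibull form). The log-intensity form is required
because the |μ| levels span two decades down to 0.25°, where a plain
Weibull in linear degrees mis-shapes the lower tail; α is reported back in
degrees. At x = α the exponent is 1, so with γ = 0.5, λ = 0 the function
passes through 0.5 + 0.5(1 − e⁻¹) ≈ 0.816 — thresholds are "the ~82%
point" by construction.

Thresholds as a function of σ_ext (the TvN function) are decomposed with
the equivalent-noise model σ_obs = √((σ_int² + σ_ext²)/N_samp). The fitted
ψ-threshold α is equated with σ_obs; the unknown criterion constant
between the 82%-threshold convention and the SD of an equivalent Gaussian
decision variable is absorbed into N_samp. N_samp is therefore an
*effective* efficiency on the threshold scale — comparisons across
conditions are meaningful, its absolute value carries that caveat.

## Generative observers

`simulate_model_faithful` draws correctness directly from ψ(|μ|) with
α = σ_obs(σ_int, σ_ext, N_samp) per condition and a configurable true
slope β (default 2, a typical psychometric slope). Decisional bias enters
as condition-specific guessing rates; the defaults describe an observer
who leans toward the sound's direction when unsure (γ > 0.5 congruent,
< 0.5 incongruent, exactly 0.5 for non-directional sounds). Because this
generator is the exact inverse of the fitted model, parameter recovery is
well-posed: the fitting chain should return the generating values up to
sampling error, and the recovery tests quantify exactly that. Trials with
μ = 0 have no correct side; they are generated with a random response,
marked incorrect and flagged `excluded`.

`simulate_mechanistic` implements the process account instead: draw
round(N_samp) directions from the stimulus distribution, corrupt each with
Normal(0, σ_int) internal noise, average, add a criterion shift (degrees)
toward the sound's lateral side on directional-sound trials, respond by
sign, and lapse uniformly with probability λ. With no shift it reproduces
Φ(μ/σ_obs) — verified against that closed form — but its bias mechanism
(an additive criterion shift) is *not* identical to the guessing-rate
mechanism, so it serves realism cross-checks, not quantitative recovery.

Default generator conditions mirror the study template: σ_ext ∈ {0, 4, 8,
16, 32}°, candidate |μ| ∈ {0.25, …, 16}° with the 5 magnitudes nearest the
observer's anticipated threshold selected per σ_ext level (emulating
per-participant level selection), σ_int ≈ 9–13°, N_samp ≈ 10–32 (the
magnitudes typical of human observers in this paradigm), λ = 0.02, bias
γ = 0.55/0.45 where a biased roster is wanted.

What the generator does **not** emulate: dot positions and limited
lifetimes (the decision model uses directions only), circular wrapping of
directions (negligible at σ_ext ≤ 32°), sequential effects, learning or
fatigue, reaction times, and any audio signal processing. Passing
recovery tests therefore shows the analysis chain is self-consistent and
unbiased under the model's own assumptions — not that real observers
satisfy those assumptions.

## Fitting

**Joint psychometric fit.** Binomial maximum likelihood over {α × 4
conditions, shared β, γ_congruent and γ_incongruent (mode `estimated`),
shared λ}. Parameters are optimised as log₁₀α and log₁₀β by L-BFGS-B with
box bounds: α within [0.1·min|μ|, 10·max|μ|] per condition, β ∈ [0.1, 20],
γ ∈ [0, 1 − λ_max), λ ∈ [0, 0.06]. Multistart: an n×n (default 3×3) grid
crossing α-scale factors {×0.32, ×1, ×3.2} around a heuristic
75%-crossing start with β starts {1, 2, 4}, then guessing-rate restarts at
{0.3, 0.7} around the incumbent; ties go to the first-found optimum, so
refits are deterministic. Convergence failures are flagged, not raised;
fits with α or β at their box edge, or degenerate all-correct/all-wrong
data, set `boundary=True`.

**Shared lapse.** λ is one value per observer: it is profiled on the
pooled likelihood of all σ_ext levels (fixed-λ joint fits summed across
levels, warm-started) over a coarse grid {0, 0.02, 0.04, 0.06} with one
parabolic refinement through the best three points, then each level is
refitted at the profiled λ. The parabolic step resolves λ to ~10⁻³, well
below its influence on α.

**Bootstrap.** Parametric by default: counts are redrawn from the fitted
cell probabilities at the empirical design and refitted (warm-started);
SEs are the SDs of the bootstrap estimates, and the deviance p-value is
the fraction of bootstrap deviances at least as large as observed (small
values flag misfit; under the model it is uniform, which the suite checks
by a Kolmogorov–Smirnov test). Nonparametric resampling from the
empirical proportions is available behind a flag. The conventional 1,000
draws are the default; tests use fewer.

**Signed-function analysis.** The conventional alternative charts
P(respond right) against signed μ and fits a cumulative Gaussian by
binomial ML; its mean is the PSE (bias) and its SD the threshold-like
slope. It cannot estimate bias and threshold per sound condition within
one folded function, which is why the joint ψ fit is the primary path;
one-signed data are fitted but flagged unreliable.

**EN fit.** SSE on natural-log thresholds (the minimiser is base
invariant), optimised as (log σ_int, log N_samp) by L-BFGS-B within
σ_int ∈ (0, 90°], N_samp ∈ [1, 300], from one moment-based start plus 20
random starts drawn log-uniformly over the box with a fixed seed. The fit
reports how many starts landed within 1% of the best optimum and flags
boundary solutions. Missing or unconverged threshold cells are excluded
from the SSE, never imputed. Group-level TvN data are per-cell means of
log thresholds (geometric means) across observers.

## Statistical battery

Four analyses, all within-subject: Congruency × SD on the estimated
guessing rates; Sound × SD on log₁₀ thresholds (per γ mode); one-way
Sound on σ_int and on N_samp. The rm-ANOVA uses the standard
sum-of-squares decomposition with each effect tested against its
effect-by-subject interaction; ηp² = SS_effect/(SS_effect + SS_error).
Greenhouse–Geisser ε comes from the eigenvalues of the
contrast-transformed covariance (Kronecker contrasts for the
interaction); both uncorrected and GG-corrected p are always reported,
with the headline `p` switching to the corrected value when Mauchly's
test rejects sphericity at 0.05. Mauchly's p uses the plain chi-square
approximation; the W statistic matches pingouin's to machine precision,
the p-value differs in the higher-order correction term pingouin adds
(same decisions in practice). Post-hoc contrasts are two-tailed paired
t-tests with the Bonferroni multiplier equal to the number of pairwise
contrasts and Cohen's d = mean difference / SD of differences.

JZS Bayes factors for paired contrasts integrate the
Cauchy-prior (default scale √2/2) likelihood ratio by quadrature over the
inverse-gamma mixture representation; the implementation reproduces the
classic worked value (t = 2.03, n = 80, unit-information prior →
BF01 ≈ 1.56) and agrees with pingouin. Bayes factors for whole ANOVA
designs are out of scope; `bf10_bic_from_f` offers a clearly-labelled
rough BIC approximation only.

## Numerical and design choices

- One explicit seed per stochastic call; nested stages derive child seeds
  via `SeedSequence.spawn`. The contract is reproducibility given (seed,
  library version), not cross-library bit equality.
- Likelihood cells with zero trials are dropped silently; a condition with
  fewer than two usable |μ| levels aborts the joint fit with a structured
  error.
- Probabilities are clipped at 10⁻¹⁰ inside log-likelihoods.
- γ has no sum constraint across congruent/incongruent (none is imposed by
  the design); its bound is [0, 1 − λ_max) so γ + λ < 1 always holds.
- Degenerate post-hoc contrasts: all-zero differences report t = d = 0
  (a null contrast); constant nonzero differences leave them NaN, flagged.
- The two stimulus-geometry helpers compute the angular sweep
  2·arctan((separation/2)/distance)/duration and the corner-speaker
  diagonal; the Experiment-2 template treats its printed auditory speed as
  a stimulus constant rather than deriving it from geometry, which does
  not reproduce it.

## Problem sizes in the test suite

The suites exercise the full Experiment-1 protocol (8,000 trials per
simulated observer). The end-to-end recovery study runs 50 replicate
observers (25 each at σ_int = 9, N_samp = 10 and σ_int = 13, N_samp = 32)
and requires median absolute relative error ≤ 20% on both EN parameters;
the spurious-bias property runs 20 seeded full-protocol replicates per γ
mode; ANOVA calibration uses 2,000 null replicates of a 6-subject 2×5
design; bootstrap-uniformity and SE-scaling checks use reduced draw
counts (40–150) chosen to keep the default run brisk while the
statistical assertions retain power.

## Known limitations

- N_samp is identified only up to the threshold-criterion constant (see
  above); treat absolute efficiencies with care.
- The EN model assumes noise-invariant pooling; violations of that
  assumption are not modelled or tested.
- The mechanistic observer's criterion shift and the model-faithful
  observer's guessing-rate bias are different bias mechanisms; only the
  latter is used for quantitative recovery claims.
- The rm-ANOVA covers balanced, complete, fully-within designs only — no
  missing cells, between-subject factors or mixed models.
- Sample GG ε is biased downward by O(1/n); with small rosters expect
  conservative corrected p-values even under sphericity.
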