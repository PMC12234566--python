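# enmotion

Equivalent-noise analysis of audiovisual global-motion discrimination.

Observers in a two-alternative forced-choice (2AFC) task judge whether the
mean direction of a random-dot motion field tilts up-left or up-right while
a task-irrelevant sound is **absent**, **stationary**, **congruent** with
the visual direction, or **incongruent**. Because a directional sound can
sway the *guess* without touching the *percept*, threshold-based analyses
must separate decisional bias from sensory sensitivity. `enmotion`
implements that separation end to end:

- **simulate** trial-level 2AFC sessions from parameterised observers
  (`enmotion.observer_sim`),
- **fit** jointly constrained psychometric functions in which the guessing
  rate is a free decisional-bias parameter (`enmotion.psychofit`),
- **decompose** thresholds into internal noise and sampling efficiency with
  the equivalent-noise model (`enmotion.en_model`),
- **test** effects with a within-subject statistical battery
  (`enmotion.stats`), and
- **orchestrate** the whole chain, including the headline bias-estimated
  vs bias-fixed comparison (`enmotion.pipeline`, `enmotion` CLI).

## The model

Accuracy at absolute direction offset *x* (degrees) follows

ψ(x; α, β, γ, λ) = γ + (1 − γ − λ) · F(x; α, β),
  F(x; α, β) = 1 − exp(−10^(β·(log₁₀x − log₁₀α)))

a Weibull on log intensity with threshold α (at x = α, with γ = 0.5 and
λ = 0, ψ ≈ 0.816 — the ~82%-correct point), slope β, guessing rate γ and
lapse rate λ. The four sound conditions are fitted **simultaneously** by
maximum likelihood: one α per condition, a shared β, a shared λ per
observer, and γ either estimated freely for the congruent/incongruent
conditions (fixed at 0.5 for absent/stationary) or pinned at 0.5
everywhere for comparison.

Thresholds across external-noise levels σ_ext ∈ {0°, 4°, 8°, 16°, 32°}
(the SD of the dot-direction distribution) are then decomposed with the
variance-summation equivalent-noise (EN) model

σ_obs = √((σ_int² + σ_ext²) / N_samp)

by least squares on log thresholds: σ_int is the internal noise on
individual local directions, N_samp the effective number of local samples
pooled into the global estimate.

The central methodological point, reproduced here as a property of the
code: for an observer whose *only* condition difference is a guessing-rate
bias (γ = 0.55 congruent, 0.45 incongruent), fitting with γ fixed at 0.5
systematically lowers the congruent threshold — a spurious "sensory"
effect that disappears when γ is estimated.

## Worked example

```python
import enmotion as em

observer = em.ObserverParams(sigma_int=9.0, n_samp=10.0, lapse=0.02)
design   = em.make_experiment_design(1, observer=observer, seed=20)   # 8,000 trials
trials   = em.simulate_model_faithful(observer, design, seed=21)

fits, lapse = em.fit_observer(trials, gamma_mode="estimated")
tvn = em.assemble_tvn(fits)          # 4 conditions x 5 SD levels = 20 thresholds
for cond, en in tvn.fit_all(seed=22).items():
    print(cond, round(en.sigma_int, 2), round(en.n_samp, 2))
```

prints (`examples/03_equivalent_noise.py`):

```
shared lapse estimate: 0.020
  absent       sigma_int = 10.12 deg, N_samp = 10.69, SSE = 0.0240
  stationary   sigma_int =  9.83 deg, N_samp = 10.11, SSE = 0.0166
  congruent    sigma_int =  9.38 deg, N_samp = 10.66, SSE = 0.0730
  incongruent  sigma_int =  9.91 deg, N_samp = 12.11, SSE = 0.0140
```

i.e. from one simulated 8,000-trial protocol the chain recovers the true
internal noise (9°) and sampling efficiency (10) in every sound condition
to within sampling error. The other scripts in `examples/` walk through
session simulation, joint fitting with bootstrap uncertainty, the
bias-fixed vs bias-estimated comparison, and the statistical battery.

A thin CLI wraps the pipeline for shell use:

```bash
enmotion run --config config.yaml --seed 1 --out results/
enmotion recover --config config.yaml --n-replicates 50
```

The YAML config holds the experiment template, the observer roster (fields
of `ObserverParams`, guessing rates nested per sound condition), gamma
modes, seeds and output directory; `tests/test_pipeline.py` and
`examples/05_stats_battery.py` contain complete configurations.

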