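"""The headline methodological point: fixing the guessing rate at 0.5 for a
biased observer manufactures a spurious sensory effect.

The simulated observer has *identical* sensory parameters in all four sound
conditions; only the guessing rate differs (0.55 congruent, 0.45
incongruent — a decisional lean toward the sound's direction when unsure).
Fitting with gamma pinned at 0.5 pushes that bias into the thresholds,
making the congruent threshold look lower; estimating gamma absorbs it.
"""

import numpy as np

import enmotion as em

observer = em.ObserverParams(
    sigma_int=9.0, n_samp=10.0, lapse=0.02,
    gamma={"congruent": 0.55, "incongruent": 0.45}, name="biased",
)
design = em.make_experiment_design(1, observer=observer, seed=30)
trials = em.simulate_model_faithful(observer, design, seed=31)

for mode in ("fixed", "estimated"):
    fits, _ = em.fit_observer(trials, gamma_mode=mode)
    print(f"\ngamma {mode}:")
    for cond in ("congruent", "incongruent"):
        mean_log_alpha = np.mean([np.log10(f.params[cond].alpha)
                                  for f in fits.values()])
        print(f"  {cond:12s} mean log10 threshold = {mean_log_alpha:.3f}")
    tvn = em.assemble_tvn(fits)
    en = tvn.fit_all(seed=32)
    for cond in ("congruent", "incongruent"):
        print(f"  {cond:12s} N_samp = {en[cond].n_samp:5.2f}")

print("\nWith gamma fixed, the congruent condition shows a lower threshold "
      "and inflated efficiency despite identical sensory parameters — a "
      "purely decisional artifact.  With gamma estimated the conditions agree.")
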