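"""Simulate a synthetic patient and fit the SIR parameters to their pattern.

Walks through the first half of the modeling pipeline: generate an
exponential-distance-rule connectome, plant a seizure with known
parameters, then grid-search beta / gamma / network density against the
recorded pattern with the resection area as the epidemic seed. The fit
landscape is degenerate along the spreading-to-recovery ridge beta*kappa/
gamma, so that is the quantity to compare against the ground truth.

Run:  python examples/01_simulate_and_fit.py
"""

import numpy as np

from epispread import fit_patient, make_edr_network, make_patient

# --- a synthetic patient with known ground truth -------------------------
# study-scale atlas: the generating parameters sit in the partial-
# propagation regime there, so the pattern is informative
net, pos = make_edr_network(n=246, rng_seed=1)
pat = make_patient(net, pos, rng_seed=2, outcome_label="SF")
tp = pat.true_params
print(f"true parameters: beta={tp.beta:g} gamma={tp.gamma:g} "
      f"theta={tp.kappa_frac:g}")
print(f"true seed: {pat.true_seed}, resection area: {pat.ra}")
print(f"{len(pat.sampled_rois)} sampled ROIs, "
      f"{len(pat.seeg_pattern.steps)} active in the recorded pattern")

# --- grid fit (reduced realization count for a quick demo) ---------------
fm = fit_patient(net.weights, pat.ra, pat.seeg_pattern,
                 n_realizations=500, n_fit_iterations=2, rng_seed=3)
best = fm.best_params
print("\nbest-fit point:")
for k in ("beta", "gamma", "kappa_frac", "kappa", "C"):
    print(f"  {k:11s} = {best[k]:.4g}")

from epispread import threshold_network  # noqa: E402

true_kappa = threshold_network(net.weights, tp.kappa_frac).mean_degree
true_ratio = tp.beta * true_kappa / tp.gamma
print(f"\nridge ratio beta*kappa/gamma: fitted {best['ratio']:.3g}, "
      f"true {true_ratio:.3g} "
      f"({abs(np.log10(best['ratio'] / true_ratio)):.2f} decades apart)")
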