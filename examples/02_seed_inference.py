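"""Locate the seizure-onset zone with the seed-likelihood map.

With the global parameters frozen (here: the generating ones, standing in
for a patient's best fit), every ROI is scored as an alternative single
epidemic seed; the spreading rate is rescaled by the out-connectivity
ratio so seeds of different connectedness are comparable. The map's
argmax should land on the planted seed or one of its direct neighbors.
A greedy recursive optimization then grows multi-ROI seeds.

Run:  python examples/02_seed_inference.py
"""

import numpy as np

from epispread import (make_edr_network, make_patient,
                       recursive_seed_optimization, seed_likelihood_map,
                       threshold_network)

net, pos = make_edr_network(n=120, rng_seed=11)
pat = make_patient(net, pos, rng_seed=12, outcome_label="SF",
                   true_seed_size=1)
tp = pat.true_params
true = pat.true_seed[0]
thr = threshold_network(net.weights, tp.kappa_frac)

smap = seed_likelihood_map(thr, pat.seeg_pattern, tp.beta, tp.gamma,
                           pat.ra, n_realizations=300, rng_seed=13)
t = smap.table[~smap.table["excluded"]]
top = t.nlargest(5, "C_R")
print("top-5 single seeds (C_R):")
for _, row in top.iterrows():
    mark = " <- true seed" if row["roi"] == true else ""
    print(f"  roi {int(row['roi']):3d}  C_R = {row['C_R']:.3f}"
          f"{'  (in RA)' if row['in_RA'] else ''}{mark}")
neigh = set(np.nonzero(thr.weights[true] > 0)[0].tolist())
hit = smap.argmax == true or smap.argmax in neigh
print(f"argmax {smap.argmax} is the true seed or a neighbor: {hit}")

nested = recursive_seed_optimization(
    thr, pat.seeg_pattern, tp.beta, tp.gamma, pat.ra, max_size=3,
    n_realizations=300, scan_realizations=100, rng_seed=14,
    best_single=smap.argmax)
print("\ngreedy nested seeds:")
for seed, c in zip(nested.seeds, nested.c_values):
    print(f"  size {len(seed)}: {seed}  C = {c:.3f}")
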