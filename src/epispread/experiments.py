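"""Ground-truth validation experiments on synthetic cohorts.

Each function runs one self-contained recovery or equivalence experiment
against the known ground truth of the synthetic generator and returns the
measured quantities.  They are used by the test suite and by the
reproduction script, and double as worked examples of the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .fitting import fit_patient, population_fit
from .network import BrainNetwork, threshold_network
from .patterns import total_correlation
from .resection import stepwise_regression, virtual_resection_effect
from .seeds import seed_likelihood_map
from .sir import (SpreadParams, exact_sir_enumeration, run_sir,
                  sir_state_trace)
from .stats import roc_auc
from .synth import TrueParams, make_cohort, make_edr_network, make_patient


def _oracle_fixtures() -> List[Tuple[BrainNetwork, list, SpreadParams]]:
    """Small SIR instances (n <= 5, T <= 5) for oracle comparisons."""
    path3 = BrainNetwork(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
    w_star = np.zeros((5, 5))
    w_star[0, 1:] = w_star[1:, 0] = [1.0, 0.8, 0.6, 0.4]
    star5 = BrainNetwork(w_star)
    w_tri = np.zeros((4, 4))
    for (i, j, w) in [(0, 1, 1.0), (1, 2, 0.7), (0, 2, 0.5), (2, 3, 0.9)]:
        w_tri[i, j] = w_tri[j, i] = w
    tri_tail = BrainNetwork(w_tri)
    return [
        (path3, [0], SpreadParams(beta=0.5, gamma=1.0, T=5)),
        (path3, [0], SpreadParams(beta=0.3, gamma=0.4, T=4)),
        (star5, [0], SpreadParams(beta=0.5, gamma=0.5, T=4)),
        (star5, [2], SpreadParams(beta=0.7, gamma=0.3, T=3)),
        (tri_tail, [0], SpreadParams(beta=0.6, gamma=0.5, T=4)),
    ]


def sir_oracle_comparison(n_realizations: int = 10_000,
                          rng_seed: int = 0) -> Dict[str, float]:
    """Monte-Carlo vs exact-enumeration infection probabilities.

    Returns the largest deviation across all fixtures, expressed in
    binomial standard errors of the Monte-Carlo estimate.
    """
    worst = 0.0
    for k, (net, seed, params) in enumerate(_oracle_fixtures()):
        exact = exact_sir_enumeration(net, seed, params)
        mc = run_sir(net, seed, params.replace(
            n_realizations=n_realizations, rng_seed=rng_seed + k))
        se = np.sqrt(np.maximum(exact.p_infected * (1 - exact.p_infected),
                                1e-12) / n_realizations)
        dev = np.abs(mc.p_infected - exact.p_infected) / np.maximum(se, 1e-12)
        dev[exact.p_infected * (1 - exact.p_infected) == 0] = \
            np.abs(mc.p_infected - exact.p_infected)[
                exact.p_infected * (1 - exact.p_infected) == 0] * 1e6
        worst = max(worst, float(dev.max()))
    return {"max_dev_binomial_se": worst, "n_fixtures": len(_oracle_fixtures())}


def closed_form_checks(rng_seed: int = 0) -> Dict[str, float]:
    """Exact limits of the SIR dynamics on a surrogate network.

    * beta = 0: the epidemic size is |seed|/n in every realization;
    * beta = 1, gamma = 0, unit weights: the first-infection step equals
      the hop distance from the seed exactly;
    * compartment conservation: #S + #I + #R = n at every step of the
      step-synchronous reference realization, across parameter regimes.

    Returns the largest absolute deviation observed for each limit (all
    must be exactly 0).
    """
    import scipy.sparse.csgraph as csg
    from scipy.sparse import csr_matrix

    net, _ = make_edr_network(n=40, rng_seed=rng_seed)
    thr = threshold_network(net.weights, 0.2)

    # beta = 0 floor
    res0 = run_sir(thr, [0, 3], SpreadParams(beta=0.0, gamma=0.3, T=50,
                                             n_realizations=500,
                                             rng_seed=rng_seed))
    floor_dev = float(np.abs(res0.per_realization_sizes - 2 / 40).max())

    # deterministic wavefront on the unit-weight backbone
    unit = BrainNetwork((thr.weights > 0).astype(float))
    resw = run_sir(unit, [0], SpreadParams(beta=1.0, gamma=0.0, T=100,
                                           n_realizations=20,
                                           rng_seed=rng_seed))
    hops = csg.shortest_path(csr_matrix((thr.weights > 0).astype(float)),
                             unweighted=True, indices=0)
    reach = np.isfinite(hops)
    wave_dev = float(np.abs(resw.mean_activation[reach] - hops[reach]).max())

    # conservation in the step-synchronous reference
    cons_dev = 0
    for k, (beta, gamma) in enumerate([(0.3, 0.1), (1.0, 0.0), (0.05, 0.5)]):
        trace = sir_state_trace(thr, [0, 1], SpreadParams(
            beta=beta, gamma=gamma, T=50, rng_seed=rng_seed + k))
        cons_dev = max(cons_dev,
                       int(np.abs(trace["counts"].sum(axis=1) - 40).max()))
    return {"beta0_floor_max_dev": floor_dev,
            "wavefront_max_dev": wave_dev,
            "conservation_max_dev": float(cons_dev)}


def fit_identity_checks(rng_seed: int = 0, n_random: int = 50) -> Dict[str, float]:
    """Exact identities of the total-correlation statistic.

    C = C_w * P_overlap holds exactly on random inputs; the deterministic
    self-match gives C = 1; the reversed-order equal-extension case gives
    C = -1; and the four-ROI worked example (active pair matched in order,
    half-probability halo) gives P_overlap = 0.75 and C = 0.75.
    """
    from .patterns import SeizurePattern
    from .sir import SimulationResult

    def sim(p, t):
        return SimulationResult(p_infected=np.asarray(p, float),
                                mean_activation=np.asarray(t, float),
                                epidemic_size=float(np.mean(p)))

    rng = np.random.default_rng(rng_seed)
    identity_dev = 0.0
    for _ in range(n_random):
        n = 12
        active = rng.choice(n, size=int(rng.integers(2, 8)), replace=False)
        steps = {int(a): int(rng.integers(0, 5)) for a in active}
        fr = total_correlation(
            SeizurePattern(sampled=np.arange(n), steps=steps),
            sim(rng.random(n), rng.random(n) * 10))
        identity_dev = max(identity_dev, abs(fr.c - fr.c_w * fr.p_overlap))

    match = total_correlation(
        SeizurePattern(sampled=[0, 1, 2, 3], steps={0: 0, 1: 1}),
        sim([1, 1, 0, 0], [0.0, 1.0, np.nan, np.nan]))
    reverse = total_correlation(
        SeizurePattern(sampled=[0, 1, 2, 3], steps={0: 0, 1: 1, 2: 2}),
        sim([1, 1, 1, 0], [2.0, 1.0, 0.0, np.nan]))
    worked = total_correlation(
        SeizurePattern(sampled=[0, 1, 2, 3], steps={0: 1, 1: 2}),
        sim([1.0, 0.5, 0.5, 0.0], [0.0, 1.4, 2.0, np.nan]))
    return {
        "identity_max_dev": identity_dev,
        "self_match_C": match.c,
        "reversed_C": reverse.c,
        "worked_example_P_overlap": worked.p_overlap,
        "worked_example_C": worked.c,
    }


def _true_ridge_ratio(pat) -> float:
    tp = pat.true_params
    thr = threshold_network(pat.network.weights, tp.kappa_frac)
    return tp.beta * thr.mean_degree / tp.gamma


def parameter_recovery(n_patients: int = 10,
                       n_realizations: int = 1000,
                       n_fit_iterations: int = 2,
                       rng_seed: int = 0,
                       n_rois: int = 246) -> Dict[str, float]:
    """Fit SF-like patients generated at a grid-interior point.

    The identifiable combination is the spreading-to-recovery ratio
    beta*kappa/gamma (the fit landscape is degenerate along it); recovery
    counts a patient whose fitted ratio lies within one grid step (a factor
    of 10) of the generating ratio.  The per-patient maps are then averaged
    into the population model and the same ridge check applied to its
    optimum.
    """
    ss = np.random.SeedSequence(rng_seed)
    hits = 0
    fitmaps = []
    best_cs = []
    pop_truth = None
    for k in range(n_patients):
        s1, s2, s3 = (int(x % (2 ** 31)) for x in ss.spawn(1)[0].generate_state(3))
        net, pos = make_edr_network(n=n_rois, rng_seed=s1)
        pat = make_patient(net, pos, rng_seed=s2, outcome_label="SF")
        fm = fit_patient(net.weights, pat.ra, pat.seeg_pattern,
                         n_realizations=n_realizations,
                         n_fit_iterations=n_fit_iterations, rng_seed=s3)
        fitmaps.append(fm)
        bp = fm.best_params
        best_cs.append(bp["C"])
        true_ratio = _true_ridge_ratio(pat)
        pop_truth = true_ratio
        if abs(np.log10(bp["ratio"] / true_ratio)) <= 1.0 + 1e-9:
            hits += 1
    pop = population_fit(fitmaps)
    pop_bp = pop.best_params
    pop_err = abs(np.log10(pop_bp["ratio"] / pop_truth))
    return {
        "recovery_fraction": hits / n_patients,
        "n_patients": n_patients,
        "population_ratio_log10_error": float(pop_err),
        "population_best_C": pop_bp["C"],
        "mean_best_C": float(np.mean(best_cs)),
    }


def seed_recovery(n_patients: int = 20,
                  n_realizations: int = 300,
                  n_iterations: int = 3,
                  rng_seed: int = 0,
                  n_rois: int = 246) -> Dict[str, float]:
    """Single-seed patients: does the seed-likelihood map point home?

    A patient counts as recovered when the map's argmax is the true seed
    ROI or one of its direct neighbors in the thresholded network.  The
    map averages ``n_iterations`` independent evaluations per ROI, which
    suppresses the winner's-curse noise of taking an argmax over hundreds
    of candidate seeds at a reduced realization count.
    """
    ss = np.random.SeedSequence(rng_seed)
    hits = 0
    for k in range(n_patients):
        s1, s2, s3 = (int(x % (2 ** 31)) for x in ss.spawn(1)[0].generate_state(3))
        net, pos = make_edr_network(n=n_rois, rng_seed=s1)
        pat = make_patient(net, pos, rng_seed=s2, outcome_label="SF",
                           true_seed_size=1)
        s = pat.true_seed[0]
        tp = pat.true_params
        thr = threshold_network(net.weights, tp.kappa_frac)
        smap = seed_likelihood_map(thr, pat.seeg_pattern, tp.beta, tp.gamma,
                                   pat.true_seed, n_realizations=n_realizations,
                                   n_iterations=n_iterations, rng_seed=s3)
        am = smap.argmax
        neighbors = set(np.nonzero(thr.weights[s] > 0)[0].tolist())
        if am == s or am in neighbors:
            hits += 1
    return {"recovery_fraction": hits / n_patients, "n_patients": n_patients}


def cohort_group_separation(n_replicates: int = 10,
                            n_sf: int = 11, n_nsf: int = 4,
                            n_realizations: int = 300,
                            rng_seed: int = 0,
                            n_rois: int = 246) -> Dict[str, float]:
    """SF/NSF classification by model fit and by resection effect.

    For each cohort replicate, every patient's C is evaluated with their
    resection area as the epidemic seed at the cohort's shared generating
    parameters, and delta_R from resecting the RA with the true seed
    seeding the epidemic.  Returns the median AUCs over replicates.
    """
    ss = np.random.SeedSequence(rng_seed)
    auc_c, auc_d = [], []
    delta_sf, delta_nsf = [], []
    for rep in range(n_replicates):
        s1, s2 = (int(x % (2 ** 31)) for x in ss.spawn(1)[0].generate_state(2))
        cohort = make_cohort(n_sf=n_sf, n_nsf=n_nsf, rng_seed=s1,
                             n_rois=n_rois)
        cs, drs, labels = [], [], []
        for pat in cohort:
            tp = pat.true_params
            thr = threshold_network(pat.network.weights, tp.kappa_frac)
            params = SpreadParams(beta=tp.beta, gamma=tp.gamma,
                                  n_realizations=n_realizations, rng_seed=s2)
            sim = run_sir(thr, pat.ra, params)
            cs.append(total_correlation(pat.seeg_pattern, sim).c)
            oc = virtual_resection_effect(thr, pat.ra, pat.true_seed, params)
            drs.append(oc.delta_r)
            labels.append(pat.outcome_label == "SF")
        labels = np.asarray(labels)
        drs = np.asarray(drs)
        auc_c.append(roc_auc(cs, labels).auc)
        auc_d.append(roc_auc(drs, labels).auc)
        delta_sf.append(float(drs[labels].mean()))
        delta_nsf.append(float(drs[~labels].mean()))
    return {
        "auc_fit_median": float(np.median(auc_c)),
        "auc_delta_r_median": float(np.median(auc_d)),
        "delta_r_sf_mean": float(np.mean(delta_sf)),
        "delta_r_nsf_mean": float(np.mean(delta_nsf)),
        "n_replicates": n_replicates,
    }


def resection_floor_check(n_realizations: int = 10_000,
                          rng_seed: int = 0) -> Dict[str, float]:
    """Isolating the seed must pin IR_R at |seed|/n exactly.

    Star network, seed = one leaf, resection = the hub: the resected
    network is edgeless, so every realization infects exactly the seed.
    The baseline epidemic size is cross-checked against exact enumeration.
    """
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    star = BrainNetwork(w)
    params = SpreadParams(beta=0.5, gamma=0.5, T=5,
                          n_realizations=n_realizations, rng_seed=rng_seed)
    oc = virtual_resection_effect(star, [0], [1], params)
    exact = exact_sir_enumeration(star, [1], params)
    floor_error = abs(oc.ir_resected - 1 / 5)
    delta_identity_error = abs(
        oc.delta_r - (1 - (1 / 5) / oc.ir_baseline))
    ir0_se = float(np.std(run_sir(star, [1], params).per_realization_sizes)
                   / np.sqrt(n_realizations))
    return {
        "ir_resected": oc.ir_resected,
        "floor_abs_error": float(floor_error),
        "delta_identity_error": float(delta_identity_error),
        "ir_baseline_mc": oc.ir_baseline,
        "ir_baseline_exact": exact.epidemic_size,
        "ir_baseline_se": ir0_se,
    }


def make_regression_replicate(n_obs: int = 75, noise_scale: float = 0.65,
                              n_noise_covariates: int = 2,
                              rng=None) -> Tuple[np.ndarray, pd.DataFrame]:
    """One synthetic regression data set: a single generative covariate
    (slope 1, residual sd ``noise_scale``, giving r^2 near 0.7) plus
    independent pure-noise covariates."""
    rng = rng if rng is not None else np.random.default_rng(0)
    x = rng.normal(size=n_obs)
    y = x + rng.normal(scale=noise_scale, size=n_obs)
    cols = {"generative": x}
    for k in range(n_noise_covariates):
        cols[f"noise{k + 1}"] = rng.normal(size=n_obs)
    return y, pd.DataFrame(cols)


def stepwise_recovery(n_replicates: int = 100, n_obs: int = 75,
                      rng_seed: int = 0) -> Dict[str, float]:
    """How often stepwise selection returns exactly the generative term."""
    rng = np.random.default_rng(rng_seed)
    exact = 0
    generative_in = 0
    noise_in = 0
    for rep in range(n_replicates):
        y, X = make_regression_replicate(n_obs=n_obs, rng=rng)
        sel = set(stepwise_regression(y, X).selected)
        generative_in += "generative" in sel
        noise_in += bool(sel - {"generative"})
        exact += sel == {"generative"}
    return {
        "exact_recovery_fraction": exact / n_replicates,
        "generative_included_fraction": generative_in / n_replicates,
        "noise_included_fraction": noise_in / n_replicates,
        "n_replicates": n_replicates,
    }
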