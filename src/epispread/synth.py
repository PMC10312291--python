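"""Synthetic patient cohorts with known ground truth.

Clinical MEG/SEEG data cannot be shared, so the pipeline is exercised on
synthetic patients that emulate the study's data-generating reality:

* a connectivity backbone following the exponential distance rule (EDR),
  w_ij = exp(-alpha * d_ij) with decay exponent alpha = 0.052 mm^-1, over
  ROI centroids placed in a spherical shell with pairwise distances
  spanning roughly 0-160 mm;
* a ground-truth seed of a few spatially contiguous ROIs;
* sparse electrode sampling of ~30-60 of the ROIs, biased toward the
  neighborhood of the hypothesized onset zone, as electrode placement is
  in the clinic;
* a recorded seizure pattern generated by one realization of the SIR
  dynamics at the ground-truth parameters, discretized to integer steps;
* a resection area of 3-13 ROIs that either contains the true seed
  (seizure-free-like, "SF") or misses it (non-seizure-free-like, "NSF").

Every generated quantity is recorded in a manifest so tests can assert
expected labels without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .network import BrainNetwork, threshold_network
from .patterns import SeizurePattern
from .sir import SpreadParams, run_sir

#: EDR decay exponent (mm^-1) matching the functional-structural coupling fit
DEFAULT_ALPHA = 0.052
DEFAULT_N_ROIS = 246


@dataclass
class TrueParams:
    """Ground-truth generating point; grid-interior so fits can recover it.

    The default sits in the partial-propagation regime (the simulated
    seizure involves some but not all sampled ROIs, as recorded seizure
    patterns do), which keeps both the activation order and the seizure
    extension informative about the parameters.
    """

    beta: float = 1e-3
    gamma: float = 1e-3
    kappa_frac: float = 0.10


@dataclass
class SyntheticPatient:
    network: BrainNetwork            # full (unthresholded) EDR weights
    positions: np.ndarray            # (n, 3) ROI centroids, mm
    true_seed: List[int]
    true_params: TrueParams
    sampled_rois: List[int]
    seeg_pattern: SeizurePattern
    ra: List[int]
    outcome_label: str               # "SF" or "NSF"

    def manifest(self) -> dict:
        return {
            "n_rois": self.network.n_nodes,
            "true_seed": list(map(int, self.true_seed)),
            "true_params": {
                "beta": self.true_params.beta,
                "gamma": self.true_params.gamma,
                "kappa_frac": self.true_params.kappa_frac,
            },
            "sampled_rois": list(map(int, self.sampled_rois)),
            "ra": list(map(int, self.ra)),
            "outcome_label": self.outcome_label,
            "seeg_steps": {int(k): int(v) for k, v in self.seeg_pattern.steps.items()},
        }


def make_edr_network(n: int = DEFAULT_N_ROIS, alpha: float = DEFAULT_ALPHA,
                     noise_sd: float = 0.1, rng_seed: int = 0,
                     r_inner: float = 30.0, r_outer: float = 80.0
                     ) -> Tuple[BrainNetwork, np.ndarray]:
    """Exponential-distance-rule surrogate connectome.

    ROI centroids are drawn uniformly in a spherical shell of radii
    [r_inner, r_outer] mm (pairwise distances span ~0-160 mm, matching the
    mm^-1 scale of alpha); weights are w_ij = exp(-alpha d_ij + eps) with
    eps ~ N(0, noise_sd^2), clipped to (0, 1].
    """
    if n < 10:
        raise ValueError("need at least 10 ROIs")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(rng_seed)
    for _ in range(100):
        u = rng.random(n)
        radii = (r_inner ** 3 + u * (r_outer ** 3 - r_inner ** 3)) ** (1 / 3)
        vec = rng.normal(size=(n, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        pos = radii[:, None] * vec
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        off = d[np.triu_indices(n, 1)]
        if off.min() > 1e-6:
            break
    else:
        raise RuntimeError("could not place distinct ROI centroids")
    w = np.exp(-alpha * d)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=(n, n))
        eps = (eps + eps.T) / np.sqrt(2.0)  # symmetric, per-pair sd preserved
        w = w * np.exp(eps)
    w = np.minimum(w, 1.0)
    np.fill_diagonal(w, 0.0)
    return BrainNetwork(w, density=None), pos


def contiguous_cluster(positions: np.ndarray, center: int, size: int) -> List[int]:
    """The ``size`` spatially nearest ROIs to ``center`` (inclusive)."""
    d = np.linalg.norm(positions - positions[center], axis=1)
    return sorted(int(i) for i in np.argsort(d, kind="stable")[:size])


def make_patient(net: BrainNetwork, positions: np.ndarray,
                 true_params: TrueParams = None,
                 true_seed_size: int = 3,
                 n_sampled: Optional[int] = None,
                 outcome_label: str = "SF",
                 ra_size: Optional[int] = None,
                 rng_seed: int = 0,
                 seed_neighborhood: int = 40,
                 neighborhood_fraction: float = 0.75,
                 min_active_sampled: int = 5,
                 max_tries: int = 20,
                 pattern_T: int = 1000) -> SyntheticPatient:
    """One synthetic patient with known ground truth.

    The recorded pattern is one realization of the SIR dynamics at the
    true parameters from the true seed, restricted to the sampled ROIs;
    realization first-infection steps are integers already, so they become
    the activation steps directly (seed ROIs at step 0).  Realizations in
    which the seizure fails to propagate to at least ``min_active_sampled``
    sampled ROIs are redrawn.
    """
    if outcome_label not in ("SF", "NSF"):
        raise ValueError("outcome_label must be 'SF' or 'NSF'")
    rng = np.random.default_rng(rng_seed)
    n = net.n_nodes
    tp = true_params or TrueParams()

    seed_center = int(rng.integers(n))
    true_seed = contiguous_cluster(positions, seed_center, true_seed_size)

    # electrode sampling: always covers the seed, biased to its neighborhood
    if n_sampled is None:
        n_sampled = int(rng.integers(30, 61))
    n_sampled = min(n_sampled, n)
    hood = contiguous_cluster(positions, seed_center, min(seed_neighborhood, n))
    hood_extra = [r for r in hood if r not in true_seed]
    n_hood = min(int(round(neighborhood_fraction * len(hood_extra))),
                 max(n_sampled - len(true_seed), 0))
    picked = list(true_seed) + list(
        rng.choice(hood_extra, size=n_hood, replace=False)) if n_hood else list(true_seed)
    rest = [r for r in range(n) if r not in picked]
    n_rest = max(n_sampled - len(picked), 0)
    if n_rest:
        picked += list(rng.choice(rest, size=min(n_rest, len(rest)), replace=False))
    sampled = sorted(int(r) for r in picked[:max(n_sampled, len(true_seed))])

    # resection area
    if ra_size is None:
        ra_size = int(rng.integers(3, 14))
    if outcome_label == "SF":
        ra_size = max(ra_size, true_seed_size)
        ra = contiguous_cluster(positions, seed_center, ra_size)
        # contiguous growth from the seed center contains the seed by design
        assert set(true_seed) <= set(ra)
    else:
        # a cluster at moderate distance that misses the seed entirely
        d = np.linalg.norm(positions - positions[seed_center], axis=1)
        order = np.argsort(d, kind="stable")
        non_seed = [int(i) for i in order if int(i) not in true_seed]
        candidates = non_seed[min(len(hood), len(non_seed) - 1):][:60]
        if not candidates:  # small networks: fall back to the farthest ROIs
            candidates = non_seed[-max(ra_size, 1):]
        ra_center = int(rng.choice(candidates))
        ra = [r for r in contiguous_cluster(positions, ra_center, ra_size + true_seed_size)
              if r not in true_seed][:ra_size]
        ra = sorted(ra)

    # recorded pattern: one SIR realization at the true parameters
    thr = threshold_network(net.weights, tp.kappa_frac, node_labels=net.node_labels)
    pattern = None
    for attempt in range(max_tries):
        params = SpreadParams(beta=tp.beta, gamma=tp.gamma, T=pattern_T,
                              n_realizations=1,
                              rng_seed=int(rng.integers(2 ** 31)))
        sim = run_sir(thr, true_seed, params)
        active = np.nonzero(sim.p_infected > 0)[0]
        steps = {int(i): int(sim.mean_activation[i]) for i in active}
        active_sampled = [r for r in sampled if r in steps]
        if len(active_sampled) >= min_active_sampled \
                and len(set(steps[r] for r in active_sampled)) >= 2:
            pattern = SeizurePattern(
                sampled=np.asarray(sampled),
                steps={r: steps[r] for r in active_sampled})
            break
    if pattern is None:
        raise RuntimeError(
            "seizure failed to propagate beyond the seed at the chosen "
            "parameters after retries; pick parameters with more spreading")
    return SyntheticPatient(network=net, positions=positions,
                            true_seed=true_seed, true_params=tp,
                            sampled_rois=sampled, seeg_pattern=pattern,
                            ra=ra, outcome_label=outcome_label)


def make_cohort(n_sf: int = 11, n_nsf: int = 4,
                true_params: TrueParams = None,
                per_patient_params: Optional[Sequence[TrueParams]] = None,
                n_rois: int = DEFAULT_N_ROIS,
                alpha: float = DEFAULT_ALPHA,
                noise_sd: float = 0.1,
                rng_seed: int = 0,
                **patient_kwargs) -> List[SyntheticPatient]:
    """A reproducible cohort (default 11 SF-like + 4 NSF-like patients).

    Each patient receives an independent EDR network.  With
    ``per_patient_params`` unset, all patients share ``true_params``, which
    supports population-model recovery experiments.
    """
    if n_sf + n_nsf < 2:
        raise ValueError("cohort needs at least two patients")
    labels = ["SF"] * n_sf + ["NSF"] * n_nsf
    if per_patient_params is not None and len(per_patient_params) != len(labels):
        raise ValueError("per_patient_params length must match cohort size")
    ss = np.random.SeedSequence(rng_seed)
    cohort = []
    for k, label in enumerate(labels):
        sub = ss.spawn(1)[0]
        s_net, s_pat = (int(x % (2 ** 31)) for x in sub.generate_state(2))
        net, pos = make_edr_network(n=n_rois, alpha=alpha, noise_sd=noise_sd,
                                    rng_seed=s_net)
        tp = per_patient_params[k] if per_patient_params is not None \
            else (true_params or TrueParams())
        cohort.append(make_patient(net, pos, true_params=tp,
                                   outcome_label=label, rng_seed=s_pat,
                                   **patient_kwargs))
    return cohort
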