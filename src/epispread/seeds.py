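"""Seed (seizure-onset-zone) inference: likelihood maps and greedy seeds.

Once a patient's global parameters (kappa, beta, gamma) are fitted with the
resection area as the seed, every ROI can be scored as an alternative
single seed: its *seed likelihood* C_R is the total correlation obtained
when that ROI alone seeds the epidemic, with the spreading rate rescaled by
the out-connectivity ratio E_RA / E_R so that the initial spreading level
is preserved.  The global parameters are deliberately NOT refitted per
seed.  Multi-ROI seeds are grown greedily from the best single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .network import BrainNetwork, out_connectivity
from .patterns import SeizurePattern, total_correlation
from .sir import SpreadParams, rescale_beta_for_seed, run_sir


@dataclass
class SeedLikelihoodMap:
    """Per-ROI seed likelihood C_R at the patient's best-fit parameters."""

    table: pd.DataFrame  # roi, C_R, in_RA, excluded

    @property
    def argmax(self) -> int:
        valid = self.table[~self.table["excluded"]]
        return int(valid.loc[valid["C_R"].idxmax(), "roi"])

    def c_of(self, roi: int) -> float:
        row = self.table[self.table["roi"] == roi]
        return float(row["C_R"].iloc[0])


def _eval_seed(net: BrainNetwork, seed: Sequence[int], seeg: SeizurePattern,
               beta_ra: float, e_ra: int, gamma: float, T: int,
               n_realizations: int, rng_seed: int,
               active_threshold: float = 0.0) -> float:
    """Total correlation with ``seed`` as epidemic seed, beta rescaled."""
    e_seed = out_connectivity(net, seed)
    if e_seed == 0:
        raise ValueError("seed has no outgoing links")
    beta = rescale_beta_for_seed(beta_ra, e_ra, e_seed)
    params = SpreadParams(beta=beta, gamma=gamma, T=T,
                          n_realizations=n_realizations, rng_seed=rng_seed)
    sim = run_sir(net, seed, params)
    return total_correlation(seeg, sim, active_threshold).c


def seed_likelihood_map(net: BrainNetwork, seeg: SeizurePattern,
                        beta: float, gamma: float, ra: Sequence[int],
                        T: int = 1000, n_realizations: int = 10_000,
                        n_iterations: int = 1,
                        rng_seed: int = 0,
                        active_threshold: float = 0.0) -> SeedLikelihoodMap:
    """Score every ROI as the single epidemic seed.

    ``beta``/``gamma`` are the patient's best-fit global rates (with beta
    referring to the RA as seed); ``net`` must already be thresholded at
    the best-fit density.  ROIs without any link cannot spread and are
    excluded (flagged).

    ``C_R`` is the mean over ``n_iterations`` independent evaluations.
    Weak seeds have heavy-tailed single-evaluation C estimates (few
    realizations reach the recorded region), and the argmax over many
    candidate ROIs amplifies that noise; averaging independent iterations
    tames it at reduced per-evaluation sample sizes.
    """
    ra = sorted(set(int(r) for r in ra))
    e_ra = out_connectivity(net, ra)
    ra_set = set(ra)
    ss = np.random.SeedSequence(rng_seed)
    subs = ss.generate_state(net.n_nodes * n_iterations).reshape(
        net.n_nodes, n_iterations) % (2 ** 31)
    rows = []
    for r in range(net.n_nodes):
        e_r = out_connectivity(net, [r])
        if e_r == 0:
            rows.append(dict(roi=r, C_R=np.nan, in_RA=r in ra_set, excluded=True))
            continue
        cs = [_eval_seed(net, [r], seeg, beta, e_ra, gamma, T,
                         n_realizations, int(subs[r, i]), active_threshold)
              for i in range(n_iterations)]
        rows.append(dict(roi=r, C_R=float(np.mean(cs)), in_RA=r in ra_set,
                         excluded=False))
    return SeedLikelihoodMap(table=pd.DataFrame(rows))


@dataclass
class SeedSummaries:
    best: float          # max over single-ROI seeds
    best_roi: int
    ra_as_seed: float    # full RA as one seed
    ra_mean: float       # <RA>: mean of the RA members' single-seed fits
    rnd_mean: float      # mean over random same-size seeds
    rnd_values: np.ndarray


def seed_summaries(smap: SeedLikelihoodMap, net: BrainNetwork,
                   seeg: SeizurePattern, beta: float, gamma: float,
                   ra: Sequence[int], n_random: int = 20,
                   T: int = 1000, n_realizations: int = 10_000,
                   rng_seed: int = 0,
                   active_threshold: float = 0.0) -> SeedSummaries:
    """Best / RA / <RA> / RND comparison of seed choices."""
    ra = sorted(set(int(r) for r in ra))
    if not ra:
        raise ValueError("resection area must be nonempty")
    e_ra = out_connectivity(net, ra)
    t = smap.table
    valid = t[~t["excluded"]]
    best_row = valid.loc[valid["C_R"].idxmax()]
    ra_rows = valid[valid["in_RA"]]
    ra_mean = float(ra_rows["C_R"].mean()) if len(ra_rows) else np.nan

    rng = np.random.default_rng(rng_seed)
    c_ra = _eval_seed(net, ra, seeg, beta, e_ra, gamma, T,
                      n_realizations, int(rng.integers(2 ** 31)),
                      active_threshold)
    rnd_vals = []
    for _ in range(n_random):
        cand = rng.choice(net.n_nodes, size=len(ra), replace=False)
        try:
            c = _eval_seed(net, cand, seeg, beta, e_ra, gamma, T,
                           n_realizations, int(rng.integers(2 ** 31)),
                           active_threshold)
        except ValueError:
            c = np.nan  # isolated random seed cannot spread
        rnd_vals.append(c)
    rnd_vals = np.asarray(rnd_vals)
    return SeedSummaries(
        best=float(best_row["C_R"]), best_roi=int(best_row["roi"]),
        ra_as_seed=c_ra, ra_mean=ra_mean,
        rnd_mean=float(np.nanmean(rnd_vals)), rnd_values=rnd_vals)


@dataclass
class NestedSeeds:
    """Greedy nested seeds of sizes 1..max_size with their fit values."""

    seeds: List[List[int]]
    c_values: List[float]
    stopped_early: Optional[str] = None


def recursive_seed_optimization(net: BrainNetwork, seeg: SeizurePattern,
                                beta: float, gamma: float, ra: Sequence[int],
                                max_size: int = 5,
                                T: int = 1000,
                                n_realizations: int = 10_000,
                                scan_realizations: int = 1000,
                                rng_seed: int = 0,
                                best_single: Optional[int] = None,
                                active_threshold: float = 0.0) -> NestedSeeds:
    """Grow an optimized seed one ROI at a time.

    Starting from the best single seed, every augmentation of the current
    seed with one further ROI is scored (at the reduced ``scan_realizations``
    sample size) and the best is kept; the kept seed is then re-scored at
    the full ``n_realizations``.  Ties are broken toward the lower ROI index
    after rounding C to 6 decimals, for determinism.  Global parameters stay
    frozen; only the out-connectivity beta rescaling varies with the seed.
    """
    ra = sorted(set(int(r) for r in ra))
    e_ra = out_connectivity(net, ra)
    ss = np.random.SeedSequence(rng_seed)

    def stream():
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    if best_single is None:
        smap = seed_likelihood_map(net, seeg, beta, gamma, ra, T=T,
                                   n_realizations=scan_realizations,
                                   rng_seed=stream(),
                                   active_threshold=active_threshold)
        best_single = smap.argmax
    current = [int(best_single)]
    c_full = _eval_seed(net, current, seeg, beta, e_ra, gamma, T,
                        n_realizations, stream(), active_threshold)
    seeds = [list(current)]
    c_values = [c_full]
    stopped = None
    while len(current) < max_size:
        scan_seed = stream()
        best_c, best_node = -np.inf, None
        for v in range(net.n_nodes):
            if v in current:
                continue
            cand = current + [v]
            try:
                c = _eval_seed(net, cand, seeg, beta, e_ra, gamma, T,
                               scan_realizations, scan_seed,
                               active_threshold)
            except ValueError:
                continue
            c = round(c, 6)
            if c > best_c or (c == best_c and (best_node is None or v < best_node)):
                best_c, best_node = c, v
        if best_node is None:
            stopped = "no augmentation yields valid spreading"
            break
        current = sorted(current + [best_node])
        c_full = _eval_seed(net, current, seeg, beta, e_ra, gamma, T,
                            n_realizations, stream(), active_threshold)
        seeds.append(list(current))
        c_values.append(c_full)
    return NestedSeeds(seeds=seeds, c_values=c_values, stopped_early=stopped)
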