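"""Per-patient parameter fitting and the population model.

The three free parameters are the spreading rate beta, the recovery rate
gamma and the network density (expressed as the mean degree kappa via the
link-density fraction theta = kappa_frac).  For every grid point the
network is thresholded, the SIR dynamics is run with the resection area as
seed, and the total correlation C against the recorded pattern is averaged
over several independent fit iterations; the grid of mean C values is the
patient's fit map.  The population model averages the per-patient maps
point by point and takes the overall argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import BrainNetwork, threshold_network
from .patterns import SeizurePattern, total_correlation
from .sir import SpreadParams, run_sir

#: the default parameter grids (beta, gamma, and kappa as a fraction of n)
DEFAULT_BETA_GRID = (1e-4, 1e-3, 1e-2, 1e-1)
DEFAULT_GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1)
DEFAULT_KAPPA_FRAC_GRID = (0.025, 0.05, 0.10, 0.20, 0.30)


@dataclass
class ParameterGrid:
    beta: Tuple[float, ...] = DEFAULT_BETA_GRID
    gamma: Tuple[float, ...] = DEFAULT_GAMMA_GRID
    kappa_frac: Tuple[float, ...] = DEFAULT_KAPPA_FRAC_GRID

    def __post_init__(self):
        if not (len(self.beta) and len(self.gamma) and len(self.kappa_frac)):
            raise ValueError("parameter grid must be nonempty on every axis")
        self.beta = tuple(float(b) for b in self.beta)
        self.gamma = tuple(float(g) for g in self.gamma)
        self.kappa_frac = tuple(float(k) for k in self.kappa_frac)

    @property
    def n_points(self) -> int:
        return len(self.beta) * len(self.gamma) * len(self.kappa_frac)


@dataclass
class FitMap:
    """C(kappa, beta, gamma) over a full grid, with per-point uncertainty."""

    table: pd.DataFrame  # kappa_frac, kappa, beta, gamma, C_mean, C_sd, flag
    grid: ParameterGrid

    def __post_init__(self):
        expected = self.grid.n_points
        if len(self.table) != expected:
            raise ValueError(
                f"fit map has {len(self.table)} points, grid has {expected}")

    @property
    def argmax(self) -> pd.Series:
        valid = self.table[self.table["C_mean"].notna()]
        if valid.empty:
            raise ValueError("fit map has no valid points")
        return valid.loc[valid["C_mean"].idxmax()]

    @property
    def best_params(self) -> dict:
        row = self.argmax
        out = {
            "beta": float(row["beta"]),
            "gamma": float(row["gamma"]),
            "kappa_frac": float(row["kappa_frac"]),
            "kappa": float(row["kappa"]),
            "C": float(row["C_mean"]),
            "C_sd": float(row["C_sd"]),
        }
        out["beta_kappa"] = out["beta"] * out["kappa"]
        out["ratio"] = out["beta_kappa"] / out["gamma"]
        return out


def fit_patient(raw_weights: np.ndarray,
                ra: Sequence[int],
                seeg: SeizurePattern,
                grid: ParameterGrid = None,
                n_realizations: int = 10_000,
                n_fit_iterations: int = 10,
                T: int = 1000,
                rng_seed: int = 0,
                active_threshold: float = 0.0) -> FitMap:
    """Grid-search the SIR parameters against one patient's seizure pattern.

    ``raw_weights`` is the full (unthresholded) rescaled coupling matrix;
    the resection area ``ra`` is used as the epidemic seed.  Each grid point
    is scored ``n_fit_iterations`` times at ``n_realizations`` realizations;
    the map stores the mean and standard deviation of C.  Grid points where
    the seed is completely disconnected are recorded as missing.
    """
    grid = grid or ParameterGrid()
    ra = sorted(set(int(r) for r in ra))
    if not ra:
        raise ValueError("seed (resection area) must be nonempty")
    n = raw_weights.shape[0]
    rows = []
    ss = np.random.SeedSequence(rng_seed)
    for kf in grid.kappa_frac:
        net = threshold_network(raw_weights, kf)
        kappa = net.mean_degree
        seed_connected = np.count_nonzero(net.weights[ra, :]) > 0
        for beta in grid.beta:
            for gamma in grid.gamma:
                if not seed_connected:
                    rows.append(dict(kappa_frac=kf, kappa=kappa, beta=beta,
                                     gamma=gamma, C_mean=np.nan, C_sd=np.nan,
                                     flag="seed_disconnected"))
                    continue
                cs = []
                degen = False
                for it in range(n_fit_iterations):
                    sub = ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31)
                    params = SpreadParams(beta=beta, gamma=gamma, T=T,
                                          n_realizations=n_realizations,
                                          rng_seed=int(sub))
                    sim = run_sir(net, ra, params)
                    fr = total_correlation(seeg, sim, active_threshold)
                    cs.append(fr.c)
                    degen = degen or fr.degenerate
                cs = np.asarray(cs)
                rows.append(dict(
                    kappa_frac=kf, kappa=kappa, beta=beta, gamma=gamma,
                    C_mean=float(cs.mean()),
                    C_sd=float(cs.std(ddof=1)) if len(cs) > 1 else 0.0,
                    flag="degenerate_cw" if degen else ""))
    return FitMap(table=pd.DataFrame(rows), grid=grid)


def population_fit(fitmaps: Sequence[FitMap]) -> FitMap:
    """Average the per-patient fit maps point by point.

    All maps must share one grid; the returned map's C_mean is the across-
    patient mean and C_sd the across-patient standard deviation.  Points
    missing for any patient are averaged over the patients that have them.
    """
    if not fitmaps:
        raise ValueError("need at least one fit map")
    g0 = fitmaps[0].grid
    for fm in fitmaps[1:]:
        if (fm.grid.beta != g0.beta or fm.grid.gamma != g0.gamma
                or fm.grid.kappa_frac != g0.kappa_frac):
            raise ValueError("fit maps use different parameter grids")
    keys = ["kappa_frac", "beta", "gamma"]
    stacked = pd.concat([fm.table for fm in fitmaps], ignore_index=True)
    agg = stacked.groupby(keys, sort=False).agg(
        kappa=("kappa", "mean"),
        C_mean=("C_mean", "mean"),
        C_sd=("C_mean", lambda s: s.std(ddof=1) if s.notna().sum() > 1 else 0.0),
    ).reset_index()
    agg["flag"] = ""
    # restore the canonical column order of per-patient maps
    agg = agg[["kappa_frac", "kappa", "beta", "gamma", "C_mean", "C_sd", "flag"]]
    return FitMap(table=agg, grid=g0)


def per_patient_c_at(fitmaps: Sequence[FitMap], beta: float, gamma: float,
                     kappa_frac: float) -> np.ndarray:
    """Each patient's C at one grid point (for group statistics)."""
    out = []
    for fm in fitmaps:
        t = fm.table
        m = t[(t["beta"] == beta) & (t["gamma"] == gamma)
              & (t["kappa_frac"] == kappa_frac)]
        if m.empty:
            raise ValueError("grid point not present in a fit map")
        out.append(float(m["C_mean"].iloc[0]))
    return np.asarray(out)
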