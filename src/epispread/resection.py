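"""Virtual resections: effect on spreading and its network correlates.

A virtual resection disconnects the resection-area ROIs (all their links
set to zero, nodes kept) and the epidemic is re-run with identical
parameters and seeding.  The effect is the normalized decrease in spreading

    delta_R = (IR_0 - IR_R) / IR_0,

with IR the mean fraction of nodes ever infected.  Each outcome carries the
network covariates of the resection area, the seed (pre, post and their
difference) and the whole network, plus the model's spreading-to-recovery
ratio beta*kappa/gamma, so that the drivers of the resection effect can be
examined by pairwise correlation and stepwise linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .network import BrainNetwork, MetricSet, node_set_metrics, resect
from .sir import SpreadParams, run_sir

#: covariates of the pairwise scan and the regression, in reporting order
COVARIATE_COLUMNS = [
    "ratio",                                    # beta*kappa/gamma
    "S_RA", "E_RA", "BC_RA", "c_RA", "F_RA",    # resection area, baseline
    "S_seed", "E_seed_0", "BC_seed_0", "c_seed_0", "F_seed_0",
    "c_net_0", "F_net_0",                       # baseline network averages
    "E_seed_R", "BC_seed_R", "c_seed_R", "F_seed_R",
    "c_net_R", "F_net_R",                       # after the resection
    "dE_seed", "dBC_seed", "dc_seed", "dF_seed",
    "dc_net", "dF_net",                         # decreases (pre - post)
]


@dataclass
class ResectionOutcome:
    ir_baseline: float
    ir_resected: float
    delta_r: float
    covariates: Dict[str, float]
    seed_isolated: bool = False

    def row(self) -> dict:
        out = dict(IR_0=self.ir_baseline, IR_R=self.ir_resected,
                   delta_R=self.delta_r, seed_isolated=self.seed_isolated)
        out.update(self.covariates)
        return out


def virtual_resection_effect(net: BrainNetwork, ra: Sequence[int],
                             seed: Sequence[int], params: SpreadParams,
                             kappa: Optional[float] = None) -> ResectionOutcome:
    """delta_R of resecting ``ra`` with the epidemic seeded at ``seed``.

    Baseline and resected runs use the same parameters and the same master
    seed handling.  Seed nodes stay infectable as seed even when the
    resection disconnects them, so IR_R >= |seed| / n always.
    """
    ra = sorted(set(int(r) for r in ra))
    seed = sorted(set(int(s) for s in seed))
    base_sim = run_sir(net, seed, params)
    cut = resect(net, ra)
    res_sim = run_sir(cut, seed, params)
    ir0 = base_sim.epidemic_size
    irr = res_sim.epidemic_size
    # an empty resection leaves the network untouched: delta_R is exactly 0
    delta = 0.0 if not ra else (ir0 - irr) / ir0
    isolated = np.count_nonzero(cut.weights[seed, :]) == 0

    kappa = kappa if kappa is not None else net.mean_degree
    cache0: dict = {}
    cache_r: dict = {}
    m_ra = (MetricSet(size=0, out_connectivity=0, betweenness=np.nan,
                      clustering=np.nan, efficiency=np.nan)
            if not ra else node_set_metrics(net, ra, _cache=cache0))
    m_seed0 = node_set_metrics(net, seed, _cache=cache0)
    m_net0 = node_set_metrics(net, None, _cache=cache0)
    m_seed_r = node_set_metrics(cut, seed, _cache=cache_r)
    m_net_r = node_set_metrics(cut, None, _cache=cache_r)
    cov = {
        "ratio": params.beta * kappa / params.gamma if params.gamma > 0 else np.inf,
        "S_RA": m_ra.size, "E_RA": m_ra.out_connectivity,
        "BC_RA": m_ra.betweenness, "c_RA": m_ra.clustering, "F_RA": m_ra.efficiency,
        "S_seed": m_seed0.size, "E_seed_0": m_seed0.out_connectivity,
        "BC_seed_0": m_seed0.betweenness, "c_seed_0": m_seed0.clustering,
        "F_seed_0": m_seed0.efficiency,
        "c_net_0": m_net0.clustering, "F_net_0": m_net0.efficiency,
        "E_seed_R": m_seed_r.out_connectivity, "BC_seed_R": m_seed_r.betweenness,
        "c_seed_R": m_seed_r.clustering, "F_seed_R": m_seed_r.efficiency,
        "c_net_R": m_net_r.clustering, "F_net_R": m_net_r.efficiency,
    }
    cov["dE_seed"] = cov["E_seed_0"] - cov["E_seed_R"]
    cov["dBC_seed"] = cov["BC_seed_0"] - cov["BC_seed_R"]
    cov["dc_seed"] = cov["c_seed_0"] - cov["c_seed_R"]
    cov["dF_seed"] = cov["F_seed_0"] - cov["F_seed_R"]
    cov["dc_net"] = cov["c_net_0"] - cov["c_net_R"]
    cov["dF_net"] = cov["F_net_0"] - cov["F_net_R"]
    return ResectionOutcome(ir_baseline=ir0, ir_resected=irr, delta_r=delta,
                            covariates=cov, seed_isolated=isolated)


def log_delta_r(delta: np.ndarray) -> np.ndarray:
    """log(delta_R) with nonpositive values floored.

    Sampling noise at tiny effects can push delta_R to or below 0; such
    rows are floored at one tenth of the smallest positive observation and
    the caller is warned.
    """
    delta = np.asarray(delta, float)
    pos = delta[delta > 0]
    if pos.size == 0:
        raise ValueError("no positive resection effects to take logs of")
    floor = pos.min() / 10.0
    if np.any(delta <= 0):
        warnings.warn(f"{int((delta <= 0).sum())} nonpositive delta_R values "
                      f"floored at {floor:g} before the log transform")
    return np.log(np.maximum(delta, floor))


def resection_covariate_scan(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each covariate with log(delta_R).

    ``outcomes`` is the tidy table of `ResectionOutcome.row()` records
    pooled across patients and seed sizes.  Constant covariates are skipped
    with a note.
    """
    y = log_delta_r(outcomes["delta_R"].to_numpy())
    rows = []
    for col in COVARIATE_COLUMNS:
        if col not in outcomes.columns:
            continue
        x = outcomes[col].to_numpy(float)
        if not np.all(np.isfinite(x)) or np.isclose(x.std(), 0.0):
            rows.append(dict(covariate=col, sign="", r2=np.nan, p=np.nan,
                             note="constant or non-finite, skipped"))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append(dict(covariate=col, sign="+" if r >= 0 else "-",
                         r2=r * r, p=p, note=""))
    return pd.DataFrame(rows)


@dataclass
class StepwiseResult:
    selected: List[str]
    model: object                      # statsmodels RegressionResults
    r2: float
    r2_adj: float
    f_vs_constant: float
    f_pvalue: float
    dropped_collinear: List[str] = field(default_factory=list)
    added_variable_data: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _drop_collinear(X: pd.DataFrame) -> tuple:
    """Drop columns that do not increase the design-matrix rank."""
    keep: List[str] = []
    dropped: List[str] = []
    base = np.ones((len(X), 1))
    for col in X.columns:
        cand = np.column_stack([base] + [X[c].to_numpy(float) for c in keep]
                               + [X[col].to_numpy(float)])
        if np.linalg.matrix_rank(cand) > 1 + len(keep):
            keep.append(col)
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"collinear covariates dropped before selection: {dropped}")
    return X[keep], dropped


def stepwise_regression(y: np.ndarray, X: pd.DataFrame,
                        p_enter: float = 0.05,
                        p_remove: float = 0.10) -> StepwiseResult:
    """Bidirectional stepwise OLS on linear terms only.

    Terms enter when their partial-F p-value is below ``p_enter`` and leave
    when it rises above ``p_remove``; iteration stops at a fixed point.
    The scan order is the (sorted) column order, making the outcome
    invariant to how the caller arranged the columns.
    """
    y = np.asarray(y, float)
    X = X[sorted(X.columns)]
    X, dropped = _drop_collinear(X)
    included: List[str] = []
    while True:
        changed = False
        # forward step
        candidates = [c for c in X.columns if c not in included]
        best_p, best_c = None, None
        for c in candidates:
            design = sm.add_constant(X[included + [c]].to_numpy(float))
            res = sm.OLS(y, design).fit()
            p = res.pvalues[-1]  # partial F with 1 df == squared t
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            changed = True
        # backward step
        if included:
            design = sm.add_constant(X[included].to_numpy(float))
            res = sm.OLS(y, design).fit()
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                included.pop(worst)
                changed = True
        if not changed:
            break
    design = sm.add_constant(X[included].to_numpy(float)) if included \
        else np.ones((len(y), 1))
    final = sm.OLS(y, design).fit()
    # added-variable (partial regression) data per selected term
    av: Dict[str, pd.DataFrame] = {}
    for c in included:
        others = [o for o in included if o != c]
        base = sm.add_constant(X[others].to_numpy(float)) if others \
            else np.ones((len(y), 1))
        ry = y - sm.OLS(y, base).fit().fittedvalues
        xc = X[c].to_numpy(float)
        rx = xc - sm.OLS(xc, base).fit().fittedvalues
        av[c] = pd.DataFrame({"adjusted_x": rx, "adjusted_y": ry})
    return StepwiseResult(
        selected=included, model=final,
        r2=float(final.rsquared) if included else 0.0,
        r2_adj=float(final.rsquared_adj) if included else 0.0,
        f_vs_constant=float(final.fvalue) if included else np.nan,
        f_pvalue=float(final.f_pvalue) if included else np.nan,
        dropped_collinear=dropped, added_variable_data=av)
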