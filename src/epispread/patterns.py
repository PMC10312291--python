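"""Seizure-propagation patterns and the total-correlation fit statistic.

A *seizure pattern* records, over the ROIs sampled by depth electrodes, which
ROIs became ictal (the active set S) and at which integer activation step,
the remaining sampled ROIs forming the inactive set H.  A simulated pattern
carries, over the same sampled ROIs, the infection probability P_IR(i) and
the real-valued mean activation time.

The goodness of fit between a recorded and a simulated pattern is the total
correlation

    C = C_w * P_overlap,

where C_w is the weighted Pearson correlation between the activation orders
of the ROIs active in both patterns (weights P_IR(i)), and

    P_overlap = N_sampled^-1 [ sum_{i in S} P_IR(i) + sum_{i in H} (1 - P_IR(i)) ]

rewards agreement in seizure *extension*: C = 1 for identical patterns,
-1 for equal extension with exactly reversed activation order, and ~0 when
the patterns share no structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .sir import SimulationResult


@dataclass
class SeizurePattern:
    """Activation record over an electrode-sampled ROI subset.

    sampled : node indices covered by electrodes (N_sampled of them).
    steps : mapping node -> integer activation step for the active set;
        ties (several ROIs per step) are allowed.  Sampled nodes absent
        from `steps` form the inactive set.
    """

    sampled: np.ndarray
    steps: Dict[int, int]

    def __post_init__(self):
        self.sampled = np.asarray(sorted(set(int(i) for i in self.sampled)), dtype=int)
        self.steps = {int(k): int(v) for k, v in self.steps.items()}
        extra = set(self.steps) - set(self.sampled.tolist())
        if extra:
            raise ValueError(f"active nodes not in the sampled set: {sorted(extra)}")
        if len(self.steps) == 0:
            raise ValueError("seizure pattern has an empty active set")

    @property
    def active(self) -> np.ndarray:
        return np.asarray(sorted(self.steps), dtype=int)

    @property
    def inactive(self) -> np.ndarray:
        return np.asarray(sorted(set(self.sampled.tolist()) - set(self.steps)), dtype=int)

    @property
    def n_sampled(self) -> int:
        return int(self.sampled.size)


@dataclass
class SimPattern:
    """Simulated pattern restricted to the sampled ROIs."""

    sampled: np.ndarray
    p_infected: np.ndarray      # aligned with `sampled`
    activation_time: np.ndarray  # aligned with `sampled`; NaN if never infected
    active_threshold: float = 0.0

    @property
    def active_mask(self) -> np.ndarray:
        return self.p_infected > self.active_threshold


@dataclass
class FitResult:
    """Total correlation between a recorded and a simulated pattern."""

    c_w: float
    p_overlap: float
    p_act: float
    p_inact: float
    c: float
    degenerate: bool = False

    def __post_init__(self):
        assert abs(self.c - self.c_w * self.p_overlap) < 1e-12


def sir_pattern(sim: SimulationResult, sampled: Sequence[int],
                active_threshold: float = 0.0) -> SimPattern:
    """Subsample a simulation to the electrode-covered ROIs.

    The active set of the simulated pattern holds the sampled ROIs with
    P_IR above `active_threshold` (default: infected in at least one
    realization); the mean activation time is the ordering variable.
    """
    sampled = np.asarray(sorted(set(int(i) for i in sampled)), dtype=int)
    if sampled.size and sampled.max() >= sim.p_infected.size:
        raise ValueError("sampled set exceeds the simulated network")
    return SimPattern(
        sampled=sampled,
        p_infected=sim.p_infected[sampled],
        activation_time=sim.mean_activation[sampled],
        active_threshold=active_threshold,
    )


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with weighted means and variances.

    Raises ValueError when fewer than two points carry positive weight or
    either weighted variance is zero (callers map that to a degenerate
    C_w = 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.count_nonzero(w > 0) < 2:
        raise ValueError("fewer than two points with positive weight")
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    cov = (w * (x - mx) * (y - my)).sum()
    return float(cov / np.sqrt(vx * vy))


def total_correlation(seeg: SeizurePattern, sim,
                      active_threshold: float = 0.0) -> FitResult:
    """Total correlation C = C_w * P_overlap between patterns (Eqs. above).

    `sim` may be a SimulationResult (subsampled here) or a SimPattern
    already restricted to `seeg.sampled`.
    """
    if isinstance(sim, SimulationResult):
        simp = sir_pattern(sim, seeg.sampled, active_threshold)
    else:
        simp = sim
        if not np.array_equal(simp.sampled, seeg.sampled):
            raise ValueError("patterns are defined on different sampled sets")

    pos = {int(r): k for k, r in enumerate(simp.sampled)}
    p_ir = simp.p_infected

    # extension overlap (Eq. 5)
    act_idx = [pos[r] for r in seeg.active]
    inact_idx = [pos[r] for r in seeg.inactive]
    p_act = float(p_ir[act_idx].sum()) / seeg.n_sampled
    p_inact = float((1.0 - p_ir[inact_idx]).sum()) / seeg.n_sampled
    p_overlap = p_act + p_inact

    # order correlation over ROIs active in both patterns
    both = [r for r in seeg.active
            if p_ir[pos[r]] > simp.active_threshold
            and np.isfinite(simp.activation_time[pos[r]])]
    degenerate = False
    if len(both) < 2:
        c_w = 0.0
        degenerate = True
    else:
        x = np.array([seeg.steps[r] for r in both], float)
        y = np.array([simp.activation_time[pos[r]] for r in both], float)
        w = np.array([p_ir[pos[r]] for r in both], float)
        try:
            c_w = weighted_pearson(x, y, w)
        except ValueError:
            c_w = 0.0
            degenerate = True
    return FitResult(c_w=c_w, p_overlap=p_overlap, p_act=p_act,
                     p_inact=p_inact, c=c_w * p_overlap, degenerate=degenerate)
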