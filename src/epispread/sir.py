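"""Discrete-time stochastic SIR spreading on weighted brain networks.

The seizure is modeled as a Susceptible-Infected-Recovered epidemic: S is
the preictal (healthy) state, I the ictal state, R the postictal state.
At each step every infected node i attempts to infect each susceptible
neighbor j independently with probability beta * w_ij (which realizes the
"infected by any neighbor" probability 1 - prod_j (1 - beta w_ij)), and
every node that was infected at the *start* of the step recovers with
probability gamma.  A node infected in the current step cannot recover in
that same step.

`run_sir` is a Monte-Carlo estimator over N_R independent realizations;
`exact_sir_enumeration` sums over every stochastic branch of tiny instances
and serves as an independent oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .network import BrainNetwork, out_connectivity


@dataclass
class SpreadParams:
    """Global SIR parameters.

    beta, gamma : spreading and recovery probabilities per step, in [0, 1].
    T : maximum number of steps per realization.
    n_realizations : Monte-Carlo sample size N_R.
    rng_seed : master seed; realizations use independent substreams.
    """

    beta: float
    gamma: float
    T: int = 1000
    n_realizations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.beta <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("beta and gamma must lie in [0, 1]")
        if self.T < 1 or self.n_realizations < 1:
            raise ValueError("T and n_realizations must be >= 1")

    def replace(self, **kw) -> "SpreadParams":
        d = dict(beta=self.beta, gamma=self.gamma, T=self.T,
                 n_realizations=self.n_realizations, rng_seed=self.rng_seed)
        d.update(kw)
        return SpreadParams(**d)


@dataclass
class SimulationResult:
    """Aggregated outcome of the SIR realizations.

    p_infected : per-node probability of ever entering state I (P_IR).
    mean_activation : per-node mean first-infection step among realizations
        in which the node was infected; NaN where p_infected == 0.
        Seed nodes have activation step 0.
    epidemic_size : mean fraction of nodes ever infected (IR).
    per_realization_sizes : epidemic-size distribution, for error bars.
    truncated_fraction : fraction of realizations in which the epidemic
        was still growing at the step limit (some node would have become
        infected after step T).
    """

    p_infected: np.ndarray
    mean_activation: np.ndarray
    epidemic_size: float
    per_realization_sizes: np.ndarray = field(repr=False, default=None)
    truncated_fraction: float = 0.0

    def to_frame(self, node_labels=None):
        import pandas as pd
        n = self.p_infected.size
        labels = node_labels if node_labels is not None else [f"roi{i}" for i in range(n)]
        return pd.DataFrame({
            "roi": labels,
            "p_infected": self.p_infected,
            "mean_activation": self.mean_activation,
        })

    def summary(self) -> dict:
        return {
            "epidemic_size_mean": float(self.epidemic_size),
            "epidemic_size_sd": float(np.std(self.per_realization_sizes))
            if self.per_realization_sizes is not None else np.nan,
            "truncated_fraction": float(self.truncated_fraction),
        }


@njit(cache=True)
def _sir_kernel(indptr, indices, weights, seed_nodes, beta, gamma, T,
                n_real, realization_seeds):  # pragma: no cover - numba
    """Event-driven realization of the synchronous SIR step process.

    A node infected at step t attempts to infect each susceptible neighbor
    in each of the following steps until it recovers; the attempts on one
    link are i.i.d. Bernoulli(beta * w), so the step at which the link
    transmits is 1 + Geometric, and the number of attack rounds before
    recovery is Geometric(gamma).  Sampling those delays directly and
    propagating first-infection times with a time-bucket queue gives the
    same distribution as stepping the chain, at a cost proportional to the
    number of links touched instead of T times the edge count.
    """
    n = indptr.size - 1
    n_edges = indices.size
    ever_count = np.zeros(n, dtype=np.int64)
    first_sum = np.zeros(n, dtype=np.float64)
    sizes = np.empty(n_real, dtype=np.float64)
    n_trunc = 0

    t_inf = np.empty(n, dtype=np.int64)
    cand = np.empty(n, dtype=np.int64)
    late = np.empty(n, dtype=np.uint8)
    head = np.empty(T + 1, dtype=np.int64)
    pool_cap = n_edges + n + 1
    pool_node = np.empty(pool_cap, dtype=np.int64)
    pool_next = np.empty(pool_cap, dtype=np.int64)

    log1m_gamma = np.log(1.0 - gamma) if 0.0 < gamma < 1.0 else 0.0
    BIG = np.int64(2 ** 62)

    for r in range(n_real):
        np.random.seed(realization_seeds[r])
        for i in range(n):
            t_inf[i] = -1
            cand[i] = BIG
            late[i] = 0
        for t in range(T + 1):
            head[t] = -1
        pool_len = 0
        for s in seed_nodes:
            cand[s] = 0
            pool_node[pool_len] = s
            pool_next[pool_len] = head[0]
            head[0] = pool_len
            pool_len += 1
        n_ever = 0
        for t in range(T + 1):
            ptr = head[t]
            while ptr != -1:
                j = pool_node[ptr]
                ptr = pool_next[ptr]
                if t_inf[j] != -1 or cand[j] != t:
                    continue  # stale queue entry
                t_inf[j] = t
                ever_count[j] += 1
                first_sum[j] += t
                n_ever += 1
                # attack rounds before recovery (>= 1: a node cannot
                # recover in the step it attempts first)
                if gamma <= 0.0:
                    rounds = np.float64(1e18)
                elif gamma >= 1.0:
                    rounds = np.float64(1.0)
                else:
                    rounds = 1.0 + np.floor(
                        np.log(np.random.random()) / log1m_gamma)
                for p in range(indptr[j], indptr[j + 1]):
                    k = indices[p]
                    if t_inf[k] != -1:
                        continue
                    pw = beta * weights[p]
                    if pw <= 0.0:
                        continue
                    if pw >= 1.0:
                        delay = np.float64(1.0)
                    else:
                        delay = 1.0 + np.floor(
                            np.log(np.random.random()) / np.log(1.0 - pw))
                    if delay > rounds:
                        continue  # source recovers before transmitting
                    tt_f = t + delay
                    if tt_f > T:
                        late[k] = 1  # would be infected past the horizon
                        continue
                    tt = np.int64(tt_f)
                    if tt < cand[k]:
                        cand[k] = tt
                        if pool_len < pool_cap:
                            pool_node[pool_len] = k
                            pool_next[pool_len] = head[tt]
                            head[tt] = pool_len
                            pool_len += 1
        sizes[r] = n_ever / n
        truncated = False
        for k in range(n):
            if late[k] == 1 and t_inf[k] == -1:
                truncated = True
                break
        if truncated:
            n_trunc += 1
    return ever_count, first_sum, sizes, n_trunc


def _csr_arrays(net: BrainNetwork):
    w = net.weights
    n = net.n_nodes
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_list = []
    wt_list = []
    for i in range(n):
        nz = np.nonzero(w[i] > 0)[0]
        idx_list.append(nz.astype(np.int64))
        wt_list.append(w[i, nz])
        indptr[i + 1] = indptr[i] + nz.size
    indices = np.concatenate(idx_list) if idx_list else np.empty(0, np.int64)
    wts = np.concatenate(wt_list) if wt_list else np.empty(0, float)
    return indptr, indices, wts


def run_sir(net: BrainNetwork, seed: Sequence[int],
            params: SpreadParams) -> SimulationResult:
    """Monte-Carlo SIR spreading from a seed set.

    Returns per-node infection probabilities P_IR, mean first-infection
    steps, and the epidemic-size distribution over realizations.
    """
    seed = np.asarray(sorted(set(int(s) for s in seed)), dtype=np.int64)
    if seed.size == 0:
        raise ValueError("seed set must be nonempty")
    if seed.min() < 0 or seed.max() >= net.n_nodes:
        raise ValueError("seed contains nodes not in the network")
    indptr, indices, wts = _csr_arrays(net)
    ss = np.random.SeedSequence(params.rng_seed)
    real_seeds = ss.generate_state(params.n_realizations).astype(np.uint32)
    ever, first_sum, sizes, n_trunc = _sir_kernel(
        indptr, indices, wts, seed,
        float(params.beta), float(params.gamma), int(params.T),
        int(params.n_realizations), real_seeds)
    n_real = params.n_realizations
    p_inf = ever / n_real
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_act = np.where(ever > 0, first_sum / np.maximum(ever, 1), np.nan)
    return SimulationResult(
        p_infected=p_inf,
        mean_activation=mean_act,
        epidemic_size=float(np.mean(sizes)),
        per_realization_sizes=sizes,
        truncated_fraction=n_trunc / n_real,
    )


def exact_sir_enumeration(net: BrainNetwork, seed: Sequence[int],
                          params: SpreadParams,
                          max_nodes: int = 6, max_T: int = 6) -> SimulationResult:
    """Exact SIR outcome distribution by summing all stochastic branches.

    Feasible only for tiny instances (n <= 6, T <= 6).  Uses the same step
    ordering as `run_sir`: infections from start-of-step infected nodes,
    then recovery of those same nodes, then promotion of new infections.
    """
    n = net.n_nodes
    if n > max_nodes or params.T > max_T:
        raise ValueError("instance too large for exact enumeration")
    seed = sorted(set(int(s) for s in seed))
    if not seed or min(seed) < 0 or max(seed) >= n:
        raise ValueError("invalid seed set")
    w = net.weights
    beta, gamma, T = params.beta, params.gamma, params.T

    p_ir = np.zeros(n)
    t_sum = np.zeros(n)
    e_size = 0.0
    trunc_mass = 0.0

    for s in seed:
        p_ir[s] = 1.0

    def spread_possible(state):
        return any(state[i] == 1 and any(state[j] == 0 and w[i, j] > 0
                                         for j in range(n))
                   for i in range(n))

    stack = [(tuple(1 if i in seed else 0 for i in range(n)), 0, 1.0)]
    while stack:
        state, t, prob = stack.pop()
        inf_nodes = [i for i in range(n) if state[i] == 1]
        if not inf_nodes:
            frac = sum(1 for x in state if x != 0) / n
            e_size += prob * frac
            continue
        if t >= T:
            frac = sum(1 for x in state if x != 0) / n
            e_size += prob * frac
            if spread_possible(state):
                trunc_mass += prob
            continue
        sus = [j for j in range(n) if state[j] == 0]
        # per-susceptible infection probability this step
        p_inf = {}
        for j in sus:
            q = 1.0
            for i in inf_nodes:
                if w[i, j] > 0:
                    q *= 1.0 - beta * w[i, j]
            if q < 1.0:
                p_inf[j] = 1.0 - q
        cand = list(p_inf)
        if not cand and gamma == 0:
            # absorbing: nobody new can be infected, nobody recovers
            frac = sum(1 for x in state if x != 0) / n
            e_size += prob * frac
            continue
        for r_inf in itertools.product([0, 1], repeat=len(cand)):
            p1 = prob
            for j, got in zip(cand, r_inf):
                p1 *= p_inf[j] if got else (1.0 - p_inf[j])
            if p1 == 0.0:
                continue
            new_inf = [j for j, got in zip(cand, r_inf) if got]
            for r_rec in itertools.product([0, 1], repeat=len(inf_nodes)):
                p2 = p1
                for rec in r_rec:
                    p2 *= gamma if rec else (1.0 - gamma)
                if p2 == 0.0:
                    continue
                new_state = list(state)
                for i, rec in zip(inf_nodes, r_rec):
                    if rec:
                        new_state[i] = 2
                for j in new_inf:
                    new_state[j] = 1
                stack.append((tuple(new_state), t + 1, p2))
            # first-infection bookkeeping: accumulate with the infection
            # branch probability only (recovery branching sums to 1)
            for j in new_inf:
                p_ir[j] += p1
                t_sum[j] += p1 * (t + 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_act = np.where(p_ir > 0, t_sum / np.where(p_ir > 0, p_ir, 1), np.nan)
    return SimulationResult(
        p_infected=p_ir,
        mean_activation=mean_act,
        epidemic_size=float(e_size),
        per_realization_sizes=None,
        truncated_fraction=float(trunc_mass),
    )


def sir_state_trace(net: BrainNetwork, seed: Sequence[int],
                    params: SpreadParams) -> dict:
    """One step-synchronous realization with full per-step state counts.

    A slow reference implementation that literally steps the chain: every
    infected node attempts each susceptible neighbor with probability
    beta * w, start-of-step infected nodes recover with probability gamma,
    and new infections are promoted afterwards.  Returns the (T+1, 3) array
    of S/I/R counts plus per-node outcomes, so callers can check invariants
    such as compartment conservation against the event-driven estimator.
    """
    seed = sorted(set(int(s) for s in seed))
    if not seed or min(seed) < 0 or max(seed) >= net.n_nodes:
        raise ValueError("invalid seed set")
    n = net.n_nodes
    w = net.weights
    rng = np.random.default_rng(params.rng_seed)
    state = np.zeros(n, dtype=np.int8)  # 0 = S, 1 = I, 2 = R
    state[seed] = 1
    first = np.full(n, -1, dtype=np.int64)
    first[seed] = 0
    counts = np.zeros((params.T + 1, 3), dtype=np.int64)
    counts[0] = [(state == k).sum() for k in (0, 1, 2)]
    for t in range(1, params.T + 1):
        inf = np.nonzero(state == 1)[0]
        sus = np.nonzero(state == 0)[0]
        newly = []
        for j in sus:
            p_miss = np.prod(1.0 - params.beta * w[inf, j])
            if rng.random() < 1.0 - p_miss:
                newly.append(j)
        recover = inf[rng.random(inf.size) < params.gamma]
        state[recover] = 2
        for j in newly:
            state[j] = 1
            first[j] = t
        counts[t] = [(state == k).sum() for k in (0, 1, 2)]
    return {"counts": counts, "state": state, "first_infection": first}


def rescale_beta_for_seed(beta_ra: float, e_ra: int, e_seed: int) -> float:
    """Rescale the spreading rate by the out-connectivity ratio E_RA / E_seed.

    Keeps the expected initial spreading level comparable when a seed with a
    different out-connectivity than the resection area is used.
    """
    if e_seed <= 0:
        raise ValueError("seed is fully isolated (E_seed = 0): cannot spread")
    beta = beta_ra * (e_ra / e_seed)
    if beta > 1.0:
        warnings.warn("rescaled beta exceeded 1 and was clipped")
        beta = 1.0
    elif beta < 0.0:
        beta = 0.0
    return beta
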