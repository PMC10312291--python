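import numpy as np
import pytest

from epispread import (SeizurePattern, SpreadParams, make_edr_network,
                       make_patient, recursive_seed_optimization, run_sir,
                       seed_likelihood_map, seed_summaries, sir_pattern,
                       threshold_network)


@pytest.fixture(scope="module")
def seed_case():
    """A small network with a pattern generated from a known single seed."""
    net, pos = make_edr_network(n=30, rng_seed=21)
    thr = threshold_network(net.weights, 0.15)
    beta, gamma = 0.3, 0.1
    true_seed = 4
    sim = run_sir(thr, [true_seed], SpreadParams(beta=beta, gamma=gamma,
                                                 T=100, n_realizations=2000,
                                                 rng_seed=22))
    sampled = np.arange(30)
    sp = sir_pattern(sim, sampled)
    steps = {}
    for k, r in enumerate(sp.sampled):
        if sp.active_mask[k] and np.isfinite(sp.activation_time[k]):
            steps[int(r)] = int(round(sp.activation_time[k]))
    seeg = SeizurePattern(sampled=sampled, steps=steps)
    ra = [true_seed] + np.nonzero(thr.weights[true_seed] > 0)[0][:2].tolist()
    return thr, seeg, beta, gamma, true_seed, ra


class TestSeedLikelihoodMap:
    def test_shape_and_flags(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        smap = seed_likelihood_map(thr, seeg, beta, gamma, ra,
                                   T=100, n_realizations=200, rng_seed=1)
        t = smap.table
        assert len(t) == thr.n_nodes
        assert t["in_RA"].sum() == len(set(ra))
        assert t.loc[~t["excluded"], "C_R"].notna().all()

    def test_recovers_neighborhood_of_true_seed(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        smap = seed_likelihood_map(thr, seeg, beta, gamma, ra,
                                   T=100, n_realizations=500, rng_seed=2)
        neighbors = set(np.nonzero(thr.weights[s] > 0)[0].tolist())
        assert smap.argmax == s or smap.argmax in neighbors

    def test_isolated_roi_excluded(self, seed_case):
        _, seeg, beta, gamma, s, ra = seed_case
        # keep only one link: all other nodes become isolated
        w = np.zeros((30, 30))
        w[0, 1] = w[1, 0] = 1.0
        from epispread import BrainNetwork
        net = BrainNetwork(w)
        smap = seed_likelihood_map(net, seeg, beta, gamma, [0],
                                   T=20, n_realizations=50, rng_seed=3)
        t = smap.table
        assert t["excluded"].sum() == 28
        assert t.loc[t["excluded"], "C_R"].isna().all()
        assert smap.argmax in (0, 1)

    def test_reproducible(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        kw = dict(T=100, n_realizations=200, rng_seed=9)
        a = seed_likelihood_map(thr, seeg, beta, gamma, ra, **kw)
        b = seed_likelihood_map(thr, seeg, beta, gamma, ra, **kw)
        assert np.array_equal(a.table["C_R"].fillna(9).to_numpy(),
                              b.table["C_R"].fillna(9).to_numpy())


class TestSeedSummaries:
    def test_invariants(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        smap = seed_likelihood_map(thr, seeg, beta, gamma, ra,
                                   T=100, n_realizations=300, rng_seed=4)
        summ = seed_summaries(smap, thr, seeg, beta, gamma, ra,
                              n_random=10, T=100, n_realizations=300,
                              rng_seed=5)
        # Best is the map maximum, so it dominates the RA members' mean
        assert summ.best >= summ.ra_mean
        assert summ.best == smap.table.loc[
            ~smap.table["excluded"], "C_R"].max()
        assert summ.rnd_values.size == 10
        assert np.isfinite(summ.ra_as_seed)

    def test_empty_ra_rejected(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        smap = seed_likelihood_map(thr, seeg, beta, gamma, ra,
                                   T=100, n_realizations=100, rng_seed=6)
        with pytest.raises(ValueError):
            seed_summaries(smap, thr, seeg, beta, gamma, [], rng_seed=7)


class TestRecursiveSeedOptimization:
    def test_nested_growth(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        nested = recursive_seed_optimization(
            thr, seeg, beta, gamma, ra, max_size=3, T=100,
            n_realizations=400, scan_realizations=100, rng_seed=8)
        assert [len(sd) for sd in nested.seeds] == [1, 2, 3]
        for small, big in zip(nested.seeds, nested.seeds[1:]):
            assert set(small) <= set(big)
        assert len(nested.c_values) == 3
        assert all(np.isfinite(c) for c in nested.c_values)

    def test_max_size_one(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        nested = recursive_seed_optimization(
            thr, seeg, beta, gamma, ra, max_size=1, T=100,
            n_realizations=200, scan_realizations=100, rng_seed=9)
        assert len(nested.seeds) == 1 and len(nested.seeds[0]) == 1

    def test_respects_given_best_single(self, seed_case):
        thr, seeg, beta, gamma, s, ra = seed_case
        nested = recursive_seed_optimization(
            thr, seeg, beta, gamma, ra, max_size=2, T=100,
            n_realizations=200, scan_realizations=100, rng_seed=10,
            best_single=s)
        assert nested.seeds[0] == [s]
        assert s in nested.seeds[1]
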