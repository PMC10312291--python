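import numpy as np
import pytest

from epispread import (BrainNetwork, SpreadParams, exact_sir_enumeration,
                       rescale_beta_for_seed, run_sir, sir_state_trace,
                       threshold_network)
from epispread.experiments import _oracle_fixtures


class TestExactEnumeration:
    def test_isolated_seed(self):
        net = BrainNetwork(np.zeros((3, 3)))
        res = exact_sir_enumeration(net, [1], SpreadParams(beta=0.5, gamma=0.5, T=3))
        assert res.p_infected[1] == 1.0
        assert res.p_infected[0] == res.p_infected[2] == 0.0
        assert res.epidemic_size == pytest.approx(1 / 3)

    def test_path_closed_form(self, path3):
        """beta=0.5, gamma=1 on A-B-C from A: P_IR = (1, 1/2, 1/4), E[IR]=7/12."""
        res = exact_sir_enumeration(net=path3, seed=[0],
                                    params=SpreadParams(beta=0.5, gamma=1.0, T=5))
        assert np.allclose(res.p_infected, [1.0, 0.5, 0.25])
        assert res.epidemic_size == pytest.approx(7 / 12)
        assert res.mean_activation[0] == 0.0
        assert res.mean_activation[1] == pytest.approx(1.0)
        assert res.mean_activation[2] == pytest.approx(2.0)

    def test_deterministic_wavefront(self, path3):
        res = exact_sir_enumeration(path3, [0], SpreadParams(beta=1, gamma=0, T=4))
        assert np.allclose(res.p_infected, 1.0)
        assert np.allclose(res.mean_activation, [0, 1, 2])

    def test_probability_mass_conserved(self, star5):
        res = exact_sir_enumeration(star5, [0], SpreadParams(beta=0.4, gamma=0.6, T=4))
        assert np.all(res.p_infected <= 1 + 1e-12)
        assert np.all(res.p_infected >= 0)
        # epidemic size is the mean of the per-node infection probabilities
        assert res.epidemic_size == pytest.approx(res.p_infected.mean())

    def test_refuses_large_instances(self):
        net = BrainNetwork(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            exact_sir_enumeration(net, [0], SpreadParams(beta=0.5, gamma=0.5, T=3))


class TestRunSir:
    def test_matches_oracle_within_3_se(self):
        n_r = 10_000
        for k, (net, seed, params) in enumerate(_oracle_fixtures()):
            exact = exact_sir_enumeration(net, seed, params)
            mc = run_sir(net, seed, params.replace(n_realizations=n_r,
                                                   rng_seed=77 + k))
            se = np.sqrt(exact.p_infected * (1 - exact.p_infected) / n_r)
            assert np.all(np.abs(mc.p_infected - exact.p_infected)
                          <= 3 * se + 1e-12)

    def test_no_transmission_floor(self, star5):
        res = run_sir(star5, [0, 3], SpreadParams(beta=0.0, gamma=0.3, T=10,
                                                  n_realizations=200, rng_seed=1))
        assert np.all(res.per_realization_sizes == 2 / 5)
        assert res.epidemic_size == pytest.approx(2 / 5)

    def test_wavefront_hop_distance(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        # unit weights so beta*w = 1: the epidemic is a deterministic wave
        thr = BrainNetwork((thr.weights > 0).astype(float))
        res = run_sir(thr, [0], SpreadParams(beta=1.0, gamma=0.0, T=100,
                                             n_realizations=20, rng_seed=2))
        import scipy.sparse.csgraph as csg
        from scipy.sparse import csr_matrix
        hops = csg.shortest_path(csr_matrix((thr.weights > 0).astype(float)),
                                 unweighted=True, indices=0)
        reachable = np.isfinite(hops)
        assert np.all(res.p_infected[reachable] == 1.0)
        assert np.allclose(res.mean_activation[reachable], hops[reachable])

    def test_seed_invariants(self, star5):
        res = run_sir(star5, [2], SpreadParams(beta=0.3, gamma=0.5, T=20,
                                               n_realizations=500, rng_seed=3))
        assert res.p_infected[2] == 1.0
        assert res.mean_activation[2] == 0.0
        assert np.all(res.per_realization_sizes >= 1 / 5)
        assert np.all((res.p_infected >= 0) & (res.p_infected <= 1))

    def test_monotone_in_beta(self, star5):
        p = dict(gamma=0.3, T=20, n_realizations=20_000)
        lo = run_sir(star5, [0], SpreadParams(beta=0.2, rng_seed=5, **p))
        hi = run_sir(star5, [0], SpreadParams(beta=0.6, rng_seed=6, **p))
        assert np.all(hi.p_infected >= lo.p_infected - 0.02)
        assert hi.epidemic_size > lo.epidemic_size

    def test_bit_identical_reproducibility(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        p = SpreadParams(beta=0.05, gamma=0.02, T=200, n_realizations=300,
                         rng_seed=9)
        a = run_sir(thr, [1, 2], p)
        b = run_sir(thr, [1, 2], p)
        assert np.array_equal(a.p_infected, b.p_infected)
        assert np.array_equal(a.per_realization_sizes, b.per_realization_sizes)
        arr_a = a.mean_activation
        arr_b = b.mean_activation
        assert np.array_equal(np.nan_to_num(arr_a), np.nan_to_num(arr_b))

    def test_truncation_flagged(self, path3):
        # slow spreading, no recovery, T too small to reach the far node
        res = run_sir(path3, [0], SpreadParams(beta=0.2, gamma=0.0, T=2,
                                               n_realizations=2000, rng_seed=4))
        assert res.truncated_fraction > 0

    def test_errors(self, path3):
        with pytest.raises(ValueError):
            run_sir(path3, [], SpreadParams(beta=0.1, gamma=0.1))
        with pytest.raises(ValueError):
            run_sir(path3, [7], SpreadParams(beta=0.1, gamma=0.1))


class TestStateTrace:
    def test_conservation_every_step(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        trace = sir_state_trace(thr, [0, 1], SpreadParams(beta=0.3, gamma=0.1,
                                                          T=50, rng_seed=0))
        assert np.all(trace["counts"].sum(axis=1) == 40)

    def test_monotone_compartments(self, small_edr):
        net, _ = small_edr
        thr = threshold_network(net.weights, 0.2)
        trace = sir_state_trace(thr, [2], SpreadParams(beta=0.5, gamma=0.2,
                                                       T=50, rng_seed=1))
        counts = trace["counts"]
        assert np.all(np.diff(counts[:, 0]) <= 0)  # S never grows
        assert np.all(np.diff(counts[:, 2]) >= 0)  # R never shrinks

    def test_first_infection_consistency(self, path3):
        trace = sir_state_trace(path3, [0], SpreadParams(beta=1.0, gamma=0.0,
                                                         T=5, rng_seed=2))
        assert np.array_equal(trace["first_infection"], [0, 1, 2])
        assert np.all(trace["state"] == 1)  # gamma = 0: nobody recovers


class TestRescaleBeta:
    @pytest.mark.parametrize("beta,e_ra,e_seed,expected", [
        (0.05, 30, 30, 0.05),
        (0.01, 40, 20, 0.02),
        (0.1, 10, 1000, 0.001),
    ])
    def test_ratio(self, beta, e_ra, e_seed, expected):
        assert rescale_beta_for_seed(beta, e_ra, e_seed) == pytest.approx(expected)

    def test_clip_warns(self):
        with pytest.warns(UserWarning):
            assert rescale_beta_for_seed(0.5, 100, 10) == 1.0

    def test_isolated_seed_rejected(self):
        with pytest.raises(ValueError):
            rescale_beta_for_seed(0.1, 10, 0)
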