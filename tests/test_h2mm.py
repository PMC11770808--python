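"""Photon-by-photon HMM: likelihood oracle, EM, Viterbi, K_C."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import logsumexp

from fretkin import h2mm, synth, bursts
from fretkin.h2mm import H2MMModel
from fretkin.photons import BurstPhotons

CLOCK = 25e-9


def brute_force_loglik(model, burst, clock_period):
    """Independent oracle: explicit sum over all per-photon state paths,
    propagating with repeated per-tick matrix products."""
    A = expm(model.Q * clock_period)
    pi0 = model.start_distribution()
    gaps = np.diff(burst.ticks)
    n = len(burst.ticks)
    props = [np.linalg.matrix_power(A, int(g)) for g in gaps]

    def emis(state, color):
        return model.E[state] if color == 1 else 1.0 - model.E[state]

    total = 0.0
    for path in itertools.product(range(model.n_states), repeat=n):
        p = pi0[path[0]] * emis(path[0], burst.color[0])
        for k in range(1, n):
            p *= props[k - 1][path[k - 1], path[k]] * emis(path[k], burst.color[k])
        total += p
    return np.log(total)


def _toy_bursts():
    return [
        BurstPhotons(np.array([0, 13, 40]), np.array([1, 0, 1], dtype=np.uint8)),
        BurstPhotons(np.array([5, 6, 100, 211]), np.array([0, 0, 1, 1], dtype=np.uint8)),
        BurstPhotons(np.array([7]), np.array([1], dtype=np.uint8)),
        BurstPhotons(np.array([0, 1]), np.array([1, 1], dtype=np.uint8)),
    ]


class TestForwardLoglik:
    def test_matches_exhaustive_path_enumeration(self):
        model = H2MMModel(np.array([0.37, 0.72]),
                          np.array([[-3e4, 3e4], [5e4, -5e4]]))
        toys = _toy_bursts()
        expect = sum(brute_force_loglik(model, b, CLOCK) for b in toys)
        got = h2mm.forward_loglik(model, toys, CLOCK)
        assert abs(got - expect) < 1e-10

    def test_single_state_closed_form(self):
        model = H2MMModel(np.array([0.6]), np.array([[0.0]]))
        burst = BurstPhotons(np.array([0, 10, 20, 30, 40]),
                             np.array([1, 1, 1, 0, 0], dtype=np.uint8))
        expect = 3 * np.log(0.6) + 2 * np.log(0.4)
        assert h2mm.forward_loglik(model, [burst], CLOCK) == pytest.approx(expect, abs=1e-12)

    def test_frozen_states_mixture_closed_form(self):
        # Q = 0: loglik = logsumexp over states of binomial likelihood + log pi0
        e = np.array([0.2, 0.9])
        pi0 = np.array([0.3, 0.7])
        model = H2MMModel(e, np.zeros((2, 2)), pi0=pi0)
        burst = BurstPhotons(np.arange(0, 480, 40), np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 1, 0, 1], dtype=np.uint8))
        n_a = int(burst.color.sum())
        n_d = len(burst.color) - n_a
        expect = logsumexp(np.log(pi0) + n_a * np.log(e) + n_d * np.log(1 - e))
        assert h2mm.forward_loglik(model, [burst], CLOCK) == pytest.approx(expect, abs=1e-10)

    def test_empty_dataset_zero(self):
        model = H2MMModel(np.array([0.5]), np.array([[0.0]]))
        assert h2mm.forward_loglik(model, [], CLOCK) == 0.0

    def test_state_relabeling_invariance(self):
        toys = _toy_bursts()
        m1 = H2MMModel(np.array([0.3, 0.8]), np.array([[-2e4, 2e4], [4e4, -4e4]]))
        m2 = H2MMModel(np.array([0.8, 0.3]), np.array([[-4e4, 4e4], [2e4, -2e4]]))
        assert h2mm.forward_loglik(m1, toys, CLOCK) == pytest.approx(
            h2mm.forward_loglik(m2, toys, CLOCK), abs=1e-10)


class TestEMFit:
    def test_single_state_mle_closed_form(self):
        rng = np.random.default_rng(0)
        bursts_ = [
            BurstPhotons(np.sort(rng.integers(0, 10_000, 50)),
                         (rng.random(50) < 0.55).astype(np.uint8))
            for _ in range(20)
        ]
        init = H2MMModel(np.array([0.2]), np.array([[0.0]]))
        model, record = h2mm.em_fit(init, bursts_, CLOCK, tol=1e-12, max_iter=50)
        n_a = sum(b.color.sum() for b in bursts_)
        n_tot = sum(len(b) for b in bursts_)
        assert model.E[0] == pytest.approx(n_a / n_tot, abs=1e-6)

    def test_loglik_trace_monotone(self, fitted_small):
        _, record = fitted_small
        trace = np.array(record.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9 * np.abs(trace[:-1]))

    def test_recovers_generator_parameters(self, small_sim, fitted_small):
        cfg, *_ = small_sim
        model, _ = fitted_small
        order = np.argsort(model.E)
        assert model.E[order[0]] == pytest.approx(cfg.E_open, abs=0.03)
        assert model.E[order[1]] == pytest.approx(cfg.E_closed, abs=0.03)
        k_close = model.Q[order[0], order[1]]
        k_open = model.Q[order[1], order[0]]
        assert k_close == pytest.approx(cfg.k_close, rel=0.30)
        assert k_open == pytest.approx(cfg.k_open, rel=0.30)

    def test_degenerate_init_perturbed(self, small_sim):
        _, ds, _, photons = small_sim
        init = H2MMModel(np.array([0.5, 0.5]), np.array([[-1e4, 1e4], [1e4, -1e4]]))
        model, _ = h2mm.em_fit(init, photons[:100], ds.clock_period, max_iter=30)
        assert model.E[0] != model.E[1]

    def test_empty_dataset_rejected(self):
        init = H2MMModel(np.array([0.3, 0.7]), np.array([[-1e4, 1e4], [1e4, -1e4]]))
        with pytest.raises(ValueError):
            h2mm.em_fit(init, [], CLOCK)


class TestGlobalFit:
    def test_single_dataset_matches_em_fit(self, small_sim):
        _, ds, _, photons = small_sim
        sub = photons[:150]
        init = H2MMModel(np.array([0.3, 0.7]), np.array([[-1e4, 1e4], [1e4, -1e4]]))
        m_single, r_single = h2mm.em_fit(init, sub, ds.clock_period, tol=1e-7)
        models, r_glob = h2mm.global_fit([sub], ds.clock_period, init=init, tol=1e-7)
        assert r_glob.loglik == pytest.approx(r_single.loglik, rel=1e-6)
        assert np.allclose(np.sort(models[0].E), np.sort(m_single.E), atol=1e-3)

    def test_shared_e_with_different_rates(self):
        datasets = []
        rates = [(2e4, 2e4), (5e4, 2.5e4)]
        for i, (ko, kc) in enumerate(rates):
            cfg = synth.SimConfig(n_bursts=2500, seed=31 + i, k_open=ko, k_close=kc,
                                  burst_duration_mean=3e-4)
            ds = synth.simulate_dataset(cfg)
            table = bursts.find_bursts(ds.stream)
            datasets.append(bursts.extract_burst_photons(ds, table))
        models, record = h2mm.global_fit(datasets, CLOCK, share_E=True)
        assert np.allclose(models[0].E, models[1].E)  # shared efficiencies
        order = np.argsort(models[0].E)
        assert models[0].E[order[0]] == pytest.approx(0.37, abs=0.02)
        assert models[0].E[order[1]] == pytest.approx(0.72, abs=0.02)
        for m, (ko, kc) in zip(models, rates):
            assert m.Q[order[1], order[0]] == pytest.approx(ko, rel=0.2)
            assert m.Q[order[0], order[1]] == pytest.approx(kc, rel=0.2)

    def test_fixed_e_mode_keeps_e(self, small_sim):
        _, ds, _, photons = small_sim
        e_fixed = np.array([0.37, 0.72])
        models, _ = h2mm.global_fit([photons[:200]], ds.clock_period, fix_E=e_fixed)
        assert np.array_equal(models[0].E, e_fixed)


class TestViterbi:
    def test_frozen_pure_acceptor_burst(self):
        model = H2MMModel(np.array([0.1, 0.9]), np.zeros((2, 2)),
                          pi0=np.array([0.5, 0.5]))
        burst = BurstPhotons(np.arange(0, 200, 20), np.ones(10, dtype=np.uint8))
        paths, _ = h2mm.viterbi(model, [burst], CLOCK)
        assert np.all(paths[0] == 1)

    def test_path_loglik_below_forward(self, small_sim, fitted_small):
        _, ds, _, photons = small_sim
        model, _ = fitted_small
        sub = photons[:100]
        _, path_ll = h2mm.viterbi(model, sub, ds.clock_period)
        for i, b in enumerate(sub):
            assert path_ll[i] <= h2mm.forward_loglik(model, [b], ds.clock_period) + 1e-9

    def test_slow_switching_state_accuracy(self):
        from conftest import true_states_for_bursts

        # dwells ~2 ms >> photon spacing ~4 us
        cfg = synth.SimConfig(n_bursts=300, seed=33, k_open=500.0, k_close=500.0,
                              burst_duration_mean=5e-4)
        ds = synth.simulate_dataset(cfg)
        table = bursts.find_bursts(ds.stream)
        photons = bursts.extract_burst_photons(ds, table)
        model = H2MMModel(np.array([0.37, 0.72]),
                          np.array([[-500.0, 500.0], [500.0, -500.0]]))
        paths, _ = h2mm.viterbi(model, photons, ds.clock_period)
        truth = true_states_for_bursts(ds, table)
        hit = np.concatenate([p == t for p, t in zip(paths, truth)])
        assert hit.mean() > 0.95


class TestPopulationsKC:
    def test_symmetric_rates(self):
        model = H2MMModel(np.array([0.37, 0.72]),
                          np.array([[-4e4, 4e4], [4e4, -4e4]]))
        p_open, p_closed, kc = h2mm.populations_kc(model)
        assert p_open == pytest.approx(0.5)
        assert p_closed == pytest.approx(0.5)
        assert kc == pytest.approx(1.0)

    def test_apo_like_ratio(self):
        # k_close/k_open = 0.16 -> K_C = 0.16
        model = H2MMModel(np.array([0.37, 0.72]),
                          np.array([[-6.4e3, 6.4e3], [4e4, -4e4]]))
        *_, kc = h2mm.populations_kc(model)
        assert kc == pytest.approx(0.16, abs=1e-12)

    def test_equal_efficiencies_rejected(self):
        model = H2MMModel(np.array([0.5, 0.5]),
                          np.array([[-1e4, 1e4], [1e4, -1e4]]))
        with pytest.raises(ValueError):
            h2mm.populations_kc(model)

    def test_viterbi_dwell_kc_agrees_with_rate_ratio(self, small_sim, fitted_small):
        _, ds, _, photons = small_sim
        model, _ = fitted_small
        paths, _ = h2mm.viterbi(model, photons, ds.clock_period)
        *_, kc_rates = h2mm.populations_kc(model)
        kc_viterbi = h2mm.kc_from_paths(paths, model)
        assert kc_viterbi == pytest.approx(kc_rates, rel=0.10)


class TestModelValidation:
    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            H2MMModel(np.array([0.3, 0.7]), np.array([[-1e4, 2e4], [1e4, -1e4]]))
        with pytest.raises(ValueError):
            H2MMModel(np.array([0.3, 0.7]), np.array([[1e4, -1e4], [-1e4, 1e4]]))

    def test_json_round_trip(self):
        model = H2MMModel(np.array([0.37, 0.72]),
                          np.array([[-3e4, 3e4], [5e4, -5e4]]), pi0=np.array([0.4, 0.6]))
        clone = H2MMModel.from_json(model.to_json())
        assert np.allclose(clone.E, model.E)
        assert np.allclose(clone.Q, model.Q)
        assert np.allclose(clone.pi0, model.pi0)
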