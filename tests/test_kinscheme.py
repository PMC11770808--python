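"""The 12-state turnover model: generator, steady state, fluxes, scans."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fretkin import kinscheme as ks
from fretkin.kinscheme import (
    IDX_E_OPEN,
    SPECIES,
    KineticScheme,
    apparent_conf_rates,
    build_generator,
    isolate_urea_effect,
    optimal_kc_scan,
    pathway_flux,
    random_scheme,
    scan_common_scaling,
    steady_state,
    steady_state_ode,
    velocity,
    wild_type_scheme,
)


class TestGenerator:
    def test_rows_sum_to_zero_random_schemes(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            G = build_generator(random_scheme(rng), 10 ** rng.uniform(0, 4),
                                10 ** rng.uniform(0, 4))
            assert np.abs(G.sum(axis=1)).max() < 1e-9 * np.abs(G).max()

    def test_zero_concentrations_reduce_to_apo_two_states(self):
        scheme = wild_type_scheme()
        G = build_generator(scheme, 0.0, 0.0)
        p = steady_state(G)
        # only the apo open/closed pair communicates
        assert p[:2].sum() == pytest.approx(1.0)
        expect_closed = scheme.k_close["E"] / (scheme.k_close["E"] + scheme.k_open["E"])
        assert p[1] == pytest.approx(expect_closed, abs=1e-12)

    def test_blocked_m_path_is_dead_end(self):
        scheme = dataclasses.replace(wild_type_scheme(), k_r_M=0.0)
        G = build_generator(scheme, 1000.0, 1000.0)
        i = ks.IDX_EMTI_OPEN
        targets = np.flatnonzero(G[i] > 0)
        # EMTi_open exits only via unbinding (to EM_open) or closing
        assert set(targets) <= {ks.state_index("EM", "open"), i + 1}

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            build_generator(wild_type_scheme(), -1.0, 0.0)


class TestSteadyState:
    def test_symmetric_two_state_half(self):
        scheme = KineticScheme(k_close={"E": 1e4}, k_open={"E": 1e4}, k_cat=0.0)
        p = steady_state(build_generator(scheme, 0.0, 0.0))
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(0.5)

    def test_matches_stiff_ode_integration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            G = build_generator(random_scheme(rng), 10 ** rng.uniform(0, 4),
                                10 ** rng.uniform(0, 4))
            assert np.abs(steady_state(G) - steady_state_ode(G)).max() < 1e-8

    def test_probability_simplex(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = steady_state(build_generator(random_scheme(rng), 500.0, 500.0))
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_detailed_balance_without_catalysis(self):
        # binding/rearrangement/catalysis off: each species pair satisfies
        # Boltzmann occupancy k_close/k_open within its own two states
        scheme = wild_type_scheme()
        frozen = dataclasses.replace(scheme, k_r_T=0.0, k_r_M=0.0, k_cat=0.0, k_on=0.0)
        G = build_generator(frozen, 1000.0, 1000.0)
        # chain is reducible; check the communicating class containing apo
        p = steady_state(G)
        assert p[1] / p[0] == pytest.approx(scheme.k_close["E"] / scheme.k_open["E"],
                                            rel=1e-9)


class TestVelocityAndFlux:
    def test_zero_kcat_zero_velocity(self):
        scheme = dataclasses.replace(wild_type_scheme(), k_cat=0.0)
        assert velocity(scheme, 1000.0, 1000.0) == 0.0

    def test_no_amp_no_turnover(self):
        assert velocity(wild_type_scheme(), 1000.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_substrate_inhibition_non_monotonic(self):
        amps = np.geomspace(50, 30_000, 30)
        v = np.array([velocity(wild_type_scheme(), 1000.0, a) for a in amps])
        peak = int(np.argmax(v))
        assert 0 < peak < len(amps) - 1
        assert v[-1] < 0.7 * v[peak]

    def test_flux_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            scheme = random_scheme(rng)
            atp, amp = 10 ** rng.uniform(1, 4), 10 ** rng.uniform(1, 4)
            j_t, j_m = pathway_flux(scheme, atp, amp)
            v = velocity(scheme, atp, amp)
            assert j_t + j_m == pytest.approx(v, rel=1e-8, abs=1e-12)

    def test_blocked_m_path_carries_all_flux_on_t_path(self):
        scheme = dataclasses.replace(wild_type_scheme(), k_r_M=0.0)
        j_t, j_m = pathway_flux(scheme, 1000.0, 1000.0)
        assert j_m == 0.0
        assert j_t == pytest.approx(velocity(scheme, 1000.0, 1000.0), rel=1e-8)

    def test_low_amp_flux_through_atp_first_path(self):
        scheme = wild_type_scheme()
        j_t, j_m = pathway_flux(scheme, 1000.0, 30.0)  # amp << Kd_AMP
        assert j_t / (j_t + j_m) > 0.9


class TestApparentRates:
    def test_uniform_rates_pass_through(self):
        scheme = KineticScheme(
            k_close={s: 3e4 for s in SPECIES}, k_open={s: 1e4 for s in SPECIES})
        kc, ko = apparent_conf_rates(scheme, 700.0, 700.0)
        assert kc == pytest.approx(3e4)
        assert ko == pytest.approx(1e4)

    def test_two_species_weighted_mean(self):
        # saturating ATP, no AMP: only E and ET populated; hand-weighted mean
        scheme = wild_type_scheme()
        G = build_generator(scheme, 5000.0, 0.0)
        p = steady_state(G)
        w = p[0::2] / p[0::2].sum()
        kc_arr, _ = scheme.conf_arrays()
        kc, _ = apparent_conf_rates(scheme, 5000.0, 0.0)
        assert kc == pytest.approx(float(w @ kc_arr), rel=1e-12)

    def test_closing_rate_rises_with_amp(self):
        # ternary species close faster than apo/ET: apparent closing rate
        # increases as AMP loads the ternary complexes
        scheme = wild_type_scheme()
        kc_low, _ = apparent_conf_rates(scheme, 1000.0, 50.0)
        kc_high, _ = apparent_conf_rates(scheme, 1000.0, 10_000.0)
        assert kc_high > kc_low


class TestScans:
    def test_factor_one_is_baseline(self):
        scheme = wild_type_scheme()
        base = velocity(scheme, 1000.0, 10_000.0)
        assert scan_common_scaling(scheme, [1.0])[0] == pytest.approx(base, rel=1e-12)

    def test_fast_dynamics_common_scaling_invariant(self):
        scheme = wild_type_scheme(k_open=3e5)  # rates >= 100 x k_cat
        base = velocity(scheme, 1000.0, 10_000.0)
        v = scan_common_scaling(scheme, [10.0, 100.0], which="both")
        assert np.abs(v / base - 1).max() < 0.01

    def test_slow_dynamics_become_rate_limiting(self):
        # scaling microsecond rates down makes domain cycling rate-limiting
        scheme = wild_type_scheme()
        base = velocity(scheme, 1000.0, 10_000.0)
        v001, v01 = scan_common_scaling(scheme, [0.001, 0.01], which="both")
        assert v001 < v01 < 0.9 * base

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            scan_common_scaling(wild_type_scheme(), [0.0])

    def test_urea_affinity_only_crossover(self):
        amps = np.geomspace(50, 30_000, 25)
        s0, s8 = wild_type_scheme(0.0), wild_type_scheme(0.8)
        v0 = np.array([velocity(s0, 1000.0, a) for a in amps])
        aff = isolate_urea_effect(s0, s8, "affinity_only", amps)
        assert aff[0] < v0[0]  # low AMP: losing affinity hurts
        assert np.any(aff > v0)  # intermediate AMP: pathway shift helps

    def test_urea_dynamics_only_helps_at_high_amp(self):
        amps = np.geomspace(50, 30_000, 25)
        s0, s8 = wild_type_scheme(0.0), wild_type_scheme(0.8)
        v0 = np.array([velocity(s0, 1000.0, a) for a in amps])
        dyn = isolate_urea_effect(s0, s8, "dynamics_only", amps)
        assert dyn[-1] > v0[-1]

    def test_urea_both_equals_urea_scheme(self):
        amps = np.array([200.0, 2000.0])
        s0, s8 = wild_type_scheme(0.0), wild_type_scheme(0.8)
        both = isolate_urea_effect(s0, s8, "both", amps)
        direct = np.array([velocity(s8, 1000.0, a) for a in amps])
        assert np.allclose(both, direct)

    def test_urea_invariant_params_enforced(self):
        s0 = wild_type_scheme(0.0)
        s8 = dataclasses.replace(wild_type_scheme(0.8), k_cat=9999.0)
        with pytest.raises(ValueError, match="urea-invariant"):
            isolate_urea_effect(s0, s8, "both", [100.0])

    def test_optimal_scan_argmax_property(self):
        scheme = wild_type_scheme()
        factors = np.logspace(-2, 2, 21)
        best, kc_opt, v = optimal_kc_scan(scheme, factors=factors)
        assert v.max() == v[np.flatnonzero(factors == best)[0]]
        # optimum stable under grid refinement (within one coarse step)
        fine = np.logspace(-2, 2, 81)
        best_fine, _, _ = optimal_kc_scan(scheme, factors=fine)
        assert abs(np.log10(best_fine) - np.log10(best)) <= 4 / 20 + 1e-9


class TestSchemeProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_generator_and_flux_invariants(self, seed):
        rng = np.random.default_rng(seed)
        scheme = random_scheme(rng)
        atp, amp = 10 ** rng.uniform(1, 4), 10 ** rng.uniform(1, 4)
        G = build_generator(scheme, atp, amp)
        assert np.abs(G.sum(axis=1)).max() < 1e-9 * np.abs(G).max()
        p = steady_state(G)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-10)
        j_t, j_m = pathway_flux(scheme, atp, amp)
        assert j_t + j_m == pytest.approx(velocity(scheme, atp, amp), rel=1e-8, abs=1e-12)
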