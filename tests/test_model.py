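import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hergkit.model import (
    NOISELESS_CELL,
    CellConfig,
    VariantParams,
    WT_GATING,
    gate_steady_state,
    generate_fixture_set,
    mix_heterozygous,
    mixture_conductance,
    simulate_current,
)
from hergkit.protocols import Subprotocol, VoltageProtocol, VoltageSegment
from hergkit.variants import make_variant_params


def step_protocol(steps, dt=0.1, name="steps"):
    segs = tuple(
        VoltageSegment(f"s{i}", "step", dur, v) for i, (v, dur) in enumerate(steps)
    )
    return VoltageProtocol(name, (Subprotocol("SP_TEST", segs),), dt)


class TestSteadyState:
    def test_midpoint_and_saturation(self):
        a, h = gate_steady_state(WT_GATING, WT_GATING.v_half_act_mV)
        assert a == pytest.approx(0.5)
        a_hi, h_hi = gate_steady_state(WT_GATING, 500.0)
        assert a_hi > 0.999 and h_hi < 1e-6

    def test_wt_activation_midpoint_calibration(self):
        a, _ = gate_steady_state(WT_GATING, -19.5)
        assert a == pytest.approx(0.5, abs=1e-12)

    @given(v=st.floats(-140, 70), dv=st.floats(0.5, 30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_directions(self, v, dv):
        a1, h1 = gate_steady_state(WT_GATING, v)
        a2, h2 = gate_steady_state(WT_GATING, v + dv)
        assert a2 > a1 and h2 < h1
        assert 0 < a1 < 1 and 0 < h1 < 1

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            gate_steady_state(WT_GATING, float("inf"))


class TestSimulateCurrent:
    def test_zero_driving_force_gives_zero_current(self):
        proto = step_protocol([(-90.0, 200.0)])
        b = simulate_current(WT_GATING, proto, NOISELESS_CELL)
        assert np.allclose(b.current_pA, 0.0, atol=1e-9)

    def test_zero_conductance_gives_zero_current(self):
        proto = step_protocol([(-80.0, 100.0), (0.0, 200.0)])
        gp = replace(WT_GATING, g_max_nS=0.0)
        b = simulate_current(gp, proto, NOISELESS_CELL)
        assert np.allclose(b.current_pA, 0.0)

    def test_matches_ode_oracle_on_piecewise_constant_protocol(self):
        """Independent oracle: stiff ODE integration of the two-gate system."""
        steps = [(-80.0, 50.0), (0.0, 100.0), (40.0, 30.0), (-120.0, 80.0), (-80.0, 40.0)]
        proto = step_protocol(steps)
        b = simulate_current(WT_GATING, proto, NOISELESS_CELL)
        t, vcmd = proto.command_series()
        edges = np.cumsum([0.0] + [d for _, d in steps])

        def v_of_t(tt):
            i = np.searchsorted(edges, tt, side="right") - 1
            return steps[min(i, len(steps) - 1)][0]

        def rhs(tt, y):
            v = v_of_t(tt)
            return [
                (float(WT_GATING.a_inf(v)) - y[0]) / float(WT_GATING.tau_a(v)),
                (float(WT_GATING.h_inf(v)) - y[1]) / float(WT_GATING.tau_h(v)),
            ]

        y0 = [float(WT_GATING.a_inf(-80.0)), float(WT_GATING.h_inf(-80.0))]
        sol = solve_ivp(rhs, (0.0, t[-1]), y0, t_eval=t, max_step=1.0,
                        rtol=1e-10, atol=1e-12)
        oracle = WT_GATING.g_max_nS * sol.y[0] * sol.y[1] * (vcmd - WT_GATING.E_K_mV)
        scale = float(np.max(np.abs(oracle)))
        assert np.max(np.abs(b.current_pA - oracle)) / scale < 1e-3

    def test_current_linear_in_g_max(self):
        proto = step_protocol([(-80.0, 50.0), (20.0, 100.0), (-50.0, 100.0)])
        b1 = simulate_current(WT_GATING, proto, NOISELESS_CELL)
        b2 = simulate_current(replace(WT_GATING, g_max_nS=WT_GATING.g_max_nS * 3), proto, NOISELESS_CELL)
        assert np.allclose(b2.current_pA, 3.0 * b1.current_pA, rtol=1e-12)

    def test_gates_bounded_on_ap_clamp(self, optimised_protocol):
        from hergkit.model import _gate_trajectories

        _, v = optimised_protocol.command_series()
        a, h = _gate_trajectories(WT_GATING, optimised_protocol, v)
        assert np.all((a >= 0) & (a <= 1)) and np.all((h >= 0) & (h <= 1))

    @given(
        seed=st.integers(0, 10_000),
        steps=st.lists(
            st.tuples(st.floats(-130, 70), st.sampled_from([20.0, 50.0, 150.0])),
            min_size=1, max_size=5,
        ),
    )
    @settings(max_examples=20, deadline=None)
    def test_gates_bounded_for_arbitrary_step_trains(self, seed, steps):
        from hergkit.model import _gate_trajectories

        proto = step_protocol(steps)
        _, v = proto.command_series()
        a, h = _gate_trajectories(WT_GATING, proto, v)
        assert np.all((a >= 0) & (a <= 1)) and np.all((h >= 0) & (h <= 1))

    def test_out_of_range_voltage_rejected(self):
        # -150 mV is a legal command but far outside the tau tables
        proto = step_protocol([(-150.0, 50.0)])
        with pytest.raises(ValueError, match="tau-table range"):
            simulate_current(WT_GATING, proto, NOISELESS_CELL)

    def test_noise_is_seed_deterministic(self):
        proto = step_protocol([(0.0, 50.0)])
        cell = CellConfig(noise_sd_pA=5.0, seed=7)
        b1 = simulate_current(WT_GATING, proto, cell)
        b2 = simulate_current(WT_GATING, proto, cell)
        assert np.array_equal(b1.current_pA, b2.current_pA)


class TestVariantRegistry:
    def test_no_current_variants_have_zero_conductance(self):
        for name in ("T74R", "R534C", "A561V", "R835P"):
            assert make_variant_params(name).conductance_scale == 0.0

    def test_d591h_inactivation_midpoint(self):
        gp = make_variant_params("D591H").to_gating(WT_GATING)
        assert gp.v_half_inact_mV == pytest.approx(-67.1)

    def test_wt_is_identity(self):
        p = make_variant_params("WT")
        assert p.conductance_scale == 1.0 and p.d_v_half_inact_mV == 0.0
        assert p.to_gating(WT_GATING) == WT_GATING

    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(KeyError, match="WT"):
            make_variant_params("Q999X")


class TestHeterozygousMixing:
    def test_full_poisoning_of_a_dead_variant_leaves_one_sixteenth(self):
        var = VariantParams(name="x", conductance_scale=0.0, dn_poisoning_p=1.0)
        mix = mix_heterozygous(WT_GATING, var)
        assert mixture_conductance(mix) == pytest.approx(WT_GATING.g_max_nS / 16.0)

    def test_neutral_variant_is_indistinguishable(self):
        var = VariantParams(name="x", conductance_scale=1.0, dn_poisoning_p=0.0)
        mix = mix_heterozygous(WT_GATING, var)
        assert mixture_conductance(mix) == pytest.approx(WT_GATING.g_max_nS)

    def test_dead_variant_without_poisoning_halves_conductance(self):
        var = VariantParams(name="x", conductance_scale=0.0, dn_poisoning_p=0.0)
        mix = mix_heterozygous(WT_GATING, var)
        assert mixture_conductance(mix) == pytest.approx(0.5 * WT_GATING.g_max_nS)

    def test_binomial_weights(self):
        mix = mix_heterozygous(WT_GATING, make_variant_params("T74R"))
        weights = [w for w, _ in mix.components]
        assert weights == pytest.approx([1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16])


class TestFixtureSet:
    def test_single_cell_without_jitter_equals_simulate(self):
        proto = step_protocol([(-80.0, 50.0), (0.0, 100.0)])
        cell = CellConfig(noise_sd_pA=0.0, g_leak_nS=0.0)
        [b] = generate_fixture_set(WT_GATING, proto, cell, 1, seed=3, cv_g=0.0, cv_cm=0.0)
        ref = simulate_current(WT_GATING, proto, cell)
        assert np.allclose(b.current_pA, ref.current_pA)

    def test_same_seed_reproduces_bundles(self):
        proto = step_protocol([(0.0, 100.0)])
        cell = CellConfig(noise_sd_pA=2.0)
        a = generate_fixture_set(WT_GATING, proto, cell, 3, seed=11)
        b = generate_fixture_set(WT_GATING, proto, cell, 3, seed=11)
        for x, y in zip(a, b):
            assert np.array_equal(x.current_pA, y.current_pA)

    def test_peak_current_cv_tracks_conductance_cv(self):
        proto = step_protocol([(-80.0, 100.0), (20.0, 300.0)])
        cell = CellConfig(noise_sd_pA=0.0, g_leak_nS=0.0)
        bundles = generate_fixture_set(
            WT_GATING, proto, cell, 50, seed=42, cv_g=0.3, cv_cm=0.0
        )
        peaks = np.array([float(np.max(b.current_pA)) for b in bundles])
        cv = peaks.std() / peaks.mean()
        assert 0.2 < cv < 0.4

    def test_rejects_empty_cohort(self):
        proto = step_protocol([(0.0, 50.0)])
        with pytest.raises(ValueError):
            generate_fixture_set(WT_GATING, proto, CellConfig(), 0, seed=1)
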