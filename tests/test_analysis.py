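import math
from dataclasses import replace

import numpy as np
import pytest

from hergkit.analysis import (
    FitError,
    QCThresholds,
    SegmentationError,
    SubprotocolSlice,
    amplitude_gate,
    analyse_classical_activation,
    analyse_classical_inactivation,
    analyse_optimised,
    compensate_deactivation,
    fit_boltzmann,
    fit_kinetics,
    repolarisation_power,
    segment_recording,
    stability_check,
    subtract_leak,
    tail_amplitude,
)
from hergkit.model import NOISELESS_CELL, WT_GATING, simulate_current
from hergkit.protocols import Subprotocol, VoltageProtocol, VoltageSegment
from hergkit.variants import make_variant_params


def synthetic_window(t, y, label="w"):
    sub = Subprotocol(
        "SYN", (VoltageSegment("s", "step", float(t[-1] + 1.0), 0.0),),
        ((label, 0.0, float(t[-1] + 1.0)),),
    )
    return SubprotocolSlice(
        id="SYN", time_ms=np.asarray(t, float), command_mV=np.zeros_like(t),
        current_pA=np.asarray(y, float), sub=sub,
    )


class TestSegmentRecording:
    def test_slices_partition_the_recording(self, wt_bundle, optimised_protocol):
        sl = segment_recording(wt_bundle, optimised_protocol)
        assert set(sl) == {f"SP{i}" for i in range(1, 8)}
        total = sum(len(s.time_ms) for s in sl.values())
        assert total == len(wt_bundle.time_ms)

    def test_sp1_holds_three_cycles(self, wt_bundle, optimised_protocol):
        sp1 = segment_recording(wt_bundle, optimised_protocol)["SP1"]
        assert len(sp1.time_ms) * optimised_protocol.sample_interval_ms == pytest.approx(3000.0)
        assert len(sp1.sub.measure_windows) == 3

    def test_truncated_bundle_rejected(self, wt_bundle, optimised_protocol):
        import dataclasses

        short = dataclasses.replace(
            wt_bundle,
            time_ms=wt_bundle.time_ms[:-100],
            command_mV=wt_bundle.command_mV[:-100],
            current_pA=wt_bundle.current_pA[:-100],
        )
        with pytest.raises(SegmentationError, match="expected"):
            segment_recording(short, optimised_protocol)

    def test_protocol_mismatch_rejected(self, wt_bundle, classical_protocols):
        with pytest.raises(SegmentationError, match="recorded under"):
            segment_recording(wt_bundle, classical_protocols[0])


class TestTailAmplitude:
    def test_recovers_known_decay_amplitude(self):
        t = np.arange(0.0, 30.0, 0.1)
        tau, A = 2.0, 850.0
        win = synthetic_window(t, A * np.exp(-t / tau))
        m = tail_amplitude(win, tau_hint_ms=tau)
        assert m.amplitude_pA == pytest.approx(A, rel=5e-3)
        assert not m.low_signal

    def test_flat_trace_is_flagged_low_signal(self):
        t = np.arange(0.0, 30.0, 0.1)
        m = tail_amplitude(synthetic_window(t, np.zeros_like(t)))
        assert m.amplitude_pA == 0.0 and m.low_signal

    def test_offset_is_included_in_the_extrapolation(self):
        t = np.arange(0.0, 30.0, 0.1)
        win = synthetic_window(t, 100.0 * np.exp(-t / 1.5) + 40.0)
        m = tail_amplitude(win, tau_hint_ms=1.5)
        assert m.amplitude_pA == pytest.approx(140.0, rel=1e-2)


class TestCompensateDeactivation:
    def test_infinite_tau_is_identity(self):
        out, unreliable = compensate_deactivation(123.0, 15.0, 1e12)
        assert out == pytest.approx(123.0)
        assert not unreliable

    def test_half_life_doubles_the_amplitude(self):
        tau = 40.0
        out, _ = compensate_deactivation(50.0, tau * math.log(2.0), tau)
        assert out == pytest.approx(100.0)

    def test_large_corrections_are_flagged(self):
        _, unreliable = compensate_deactivation(1.0, 100.0, 10.0)
        assert unreliable

    def test_matches_deactivation_disabled_simulation(self):
        """Compensating the −130 mV pulse with the known tau reproduces the
        amplitude of a paired simulation in which deactivation is switched
        off (<2%)."""
        segs = (
            VoltageSegment("hold", "step", 100.0, -80.0),
            VoltageSegment("open", "step", 500.0, 70.0),
            VoltageSegment("pulse", "step", 15.0, -130.0),
            VoltageSegment("meas", "step", 30.0, 70.0),
        )
        sub = Subprotocol("SP_TEST", segs, (("tail", 615.0, 645.0),))
        proto = VoltageProtocol("mini-sp3", (sub,), 0.1)

        def tail(gating):
            b = simulate_current(gating, proto, NOISELESS_CELL)
            sl = segment_recording(b, proto)["SP_TEST"]
            return tail_amplitude(
                sl.window("tail"), tau_hint_ms=1.5, guard_ms=0.5, fit_span_ms=8.0
            ).amplitude_pA

        raw = tail(WT_GATING)
        no_deact = replace(
            WT_GATING,
            tau_deact_table={v: tau * 1e6 for v, tau in WT_GATING.tau_deact_table.items()},
        )
        reference = tail(no_deact)
        compensated, _ = compensate_deactivation(
            raw, 15.0, float(WT_GATING.tau_a(-130.0))
        )
        assert compensated == pytest.approx(reference, rel=0.02)


class TestBoltzmannFit:
    def test_exact_model_data_recovered_to_machine_precision(self):
        v = np.arange(-80.0, 41.0, 10.0)
        y = 1.0 / (1.0 + np.exp(-(v - (-20.0)) / 10.0))
        f = fit_boltzmann(list(zip(v, y)), "activation")
        assert f.v_half_mV == pytest.approx(-20.0, abs=1e-6)
        assert f.k_mV == pytest.approx(10.0, abs=1e-6)
        assert f.I_max == pytest.approx(1.0, abs=1e-6)

    def test_inactivation_direction_reports_positive_k(self):
        v = np.arange(-130.0, 41.0, 20.0)
        y = 2500.0 / (1.0 + np.exp((v - (-84.0)) / 18.0))
        f = fit_boltzmann(list(zip(v, y)), "inactivation")
        assert f.v_half_mV == pytest.approx(-84.0, abs=1e-6)
        assert f.k_mV == pytest.approx(18.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann([(-20, 0.5), (0, 0.9), (20, 1.0)], "activation")


class TestFitKinetics:
    def test_exact_exponential_recovered(self):
        t = np.arange(0.0, 300.0, 0.1)
        win = synthetic_window(t, 200.0 * np.exp(-t / 50.0) + 5.0)
        f = fit_kinetics(win, "deactivation", -110.0)
        assert f.tau_ms == pytest.approx(50.0, rel=1e-6)

    def test_deactivation_t_half_is_tau_log_two(self):
        t = np.arange(0.0, 300.0, 0.1)
        tau = 60.0
        win = synthetic_window(t, 400.0 * np.exp(-t / tau))
        f = fit_kinetics(win, "deactivation", -120.0)
        assert f.t_half_ms == pytest.approx(tau * math.log(2.0), abs=0.2)

    def test_unknown_process_rejected(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError):
            fit_kinetics(synthetic_window(t, t), "gating", 0.0)


class TestWTPipeline:
    def test_sp2_activation_matches_calibration(self, wt_result):
        assert wt_result.act.v_half_mV == pytest.approx(-19.5, abs=1.0)
        assert wt_result.act.k_mV == pytest.approx(11.6, abs=1.0)

    def test_sp3_inactivation_matches_calibration(self, wt_result):
        assert wt_result.inact.v_half_mV == pytest.approx(-83.6, abs=1.0)
        assert wt_result.inact.k_mV == pytest.approx(17.8, abs=1.0)

    def test_stability_passes(self, wt_result):
        assert wt_result.stability_pass
        assert wt_result.stability_variation_frac < 0.10

    def test_deactivation_tau_recovered_within_ten_percent(self, wt_result):
        fits = {f.voltage_mV: f.tau_ms for f in wt_result.kinetics["deactivation"]}
        assert fits[-120.0] == pytest.approx(float(WT_GATING.tau_a(-120.0)), rel=0.10)

    def test_sp2_tails_are_much_larger_than_classical_tails(
        self, wt_bundle, optimised_protocol, classical_protocols
    ):
        """The relief-then-+70 measurement yields roughly ten-fold larger
        tails than the classical −50 mV tails."""
        act_p, _ = classical_protocols
        sl = segment_recording(subtract_leak(wt_bundle, optimised_protocol), optimised_protocol)
        sp2 = tail_amplitude(
            sl["SP2"].window("act_tail@+70"), tau_hint_ms=1.5, guard_ms=0.5, fit_span_ms=8.0
        ).amplitude_pA
        fa = analyse_classical_activation(
            simulate_current(WT_GATING, act_p, NOISELESS_CELL), act_p
        )
        assert 5.0 <= sp2 / fa.I_max <= 15.0


class TestVariantRoundTrip:
    def test_configured_gating_recovered_for_analysable_variants(self, variant_results):
        """Variants with >20% of WT conductance must give back their
        configured Boltzmann parameters within 1.5 mV (noiseless)."""
        for name, res in variant_results.items():
            params = make_variant_params(name)
            if params.conductance_scale <= 0.2 and name != "WT":
                continue
            gp = params.to_gating(WT_GATING)
            assert res.act.v_half_mV == pytest.approx(gp.v_half_act_mV, abs=1.5), name
            assert res.act.k_mV == pytest.approx(gp.k_act_mV, abs=1.5), name
            assert res.inact.v_half_mV == pytest.approx(gp.v_half_inact_mV, abs=1.5), name
            assert res.inact.k_mV == pytest.approx(gp.k_inact_mV, abs=1.5), name

    def test_kinetic_time_constants_recovered_within_fifteen_percent(self, variant_results):
        for name in ("WT", "K93E", "D591H"):
            gp = make_variant_params(name).to_gating(WT_GATING)
            res = variant_results[name]
            for f in res.kinetics["deactivation"]:
                assert f.tau_ms == pytest.approx(float(gp.tau_a(f.voltage_mV)), rel=0.15), name
            for f in res.kinetics["activation"]:
                assert f.tau_ms == pytest.approx(float(gp.tau_a(f.voltage_mV)), rel=0.15), name
            for f in res.kinetics["inactivation"]:
                assert f.tau_ms == pytest.approx(float(gp.tau_h(f.voltage_mV)), rel=0.15), name
            for f in res.kinetics["recovery"]:
                if f.voltage_mV == -90.0:
                    continue  # no driving force at E_K
                assert f.tau_ms == pytest.approx(float(gp.tau_h(f.voltage_mV)), rel=0.15), name

    def test_dead_variants_are_not_analysable(self, variant_results):
        for name in ("T74R", "R534C", "A561V", "R835P"):
            res = variant_results[name]
            assert res.analysable is False
            assert res.density_pA_per_pF == 0.0

    def test_low_density_variants_fail_the_gate(self, variant_results):
        for name in ("C64Y", "I96T", "P1026L"):
            assert variant_results[name].analysable is False


class TestRepolarisationPower:
    def test_zero_current_gives_zero(self, wt_bundle, optimised_protocol):
        import dataclasses

        sl = segment_recording(
            dataclasses.replace(wt_bundle, current_pA=np.zeros_like(wt_bundle.current_pA)),
            optimised_protocol,
        )
        assert repolarisation_power(sl["SP1"], 15.0) == 0.0

    def test_linear_in_conductance(self, wt_bundle, optimised_protocol):
        from dataclasses import replace as drep

        gp2 = drep(WT_GATING, g_max_nS=2 * WT_GATING.g_max_nS)
        b2 = simulate_current(gp2, optimised_protocol, NOISELESS_CELL)
        rp1 = repolarisation_power(
            segment_recording(wt_bundle, optimised_protocol)["SP1"], 15.0
        )
        rp2 = repolarisation_power(
            segment_recording(b2, optimised_protocol)["SP1"], 15.0
        )
        assert rp2 == pytest.approx(2 * rp1, rel=1e-9)

    def test_d591h_ratio_matches_gain_of_function(self, variant_results):
        ratio = (
            variant_results["D591H"].repolarisation_power_pC_per_pF
            / variant_results["WT"].repolarisation_power_pC_per_pF
        )
        assert ratio == pytest.approx(2.6, rel=0.15)

    def test_zero_conductance_leaves_leak_only_baseline(self, variant_results):
        assert abs(variant_results["T74R"].repolarisation_power_pC_per_pF) < 1e-3


class TestStabilityCheck:
    def _slice_with_peaks(self, p1, p2, p3):
        dt = 0.1
        n = int(1000 / dt)
        y = np.zeros(3 * n)
        for i, p in enumerate((p1, p2, p3)):
            y[i * n + n // 2] = p
        sub = Subprotocol(
            "SP1", tuple(VoltageSegment(f"ap{i}", "step", 1000.0, -80.0) for i in (1, 2, 3)),
            tuple((f"ap{i}", (i - 1) * 1000.0, i * 1000.0) for i in (1, 2, 3)),
        )
        t = np.arange(3 * n) * dt
        return SubprotocolSlice("SP1", t, np.zeros_like(t), y, sub)

    def test_identical_cycles_pass(self):
        var, ok = stability_check(self._slice_with_peaks(100, 100, 100), 15.0)
        assert var == 0.0 and ok

    def test_fifteen_percent_change_fails(self):
        var, ok = stability_check(self._slice_with_peaks(100, 85, 100), 15.0)
        assert var == pytest.approx(0.15)
        assert not ok

    def test_zero_reference_cycle_fails_with_flag(self):
        var, ok = stability_check(self._slice_with_peaks(10, 5, 0), 15.0)
        assert not ok and math.isinf(var)


class TestAmplitudeGate:
    @pytest.mark.parametrize("ratio, expected", [(0.19, False), (0.20, True), (1.0, True)])
    def test_threshold_inclusive(self, ratio, expected):
        assert amplitude_gate(ratio * 100.0, 100.0) is expected

    def test_requires_positive_reference(self):
        with pytest.raises(ValueError):
            amplitude_gate(10.0, 0.0)


@pytest.fixture(scope="module")
def classical_fits(classical_protocols):
    act_p, inact_p = classical_protocols
    fa = analyse_classical_activation(
        simulate_current(WT_GATING, act_p, NOISELESS_CELL), act_p
    )
    fi = analyse_classical_inactivation(
        simulate_current(WT_GATING, inact_p, NOISELESS_CELL), inact_p
    )
    return fa, fi


class TestClassicalVsOptimised:
    def test_classical_activation_is_steeper_not_more_negative(self, classical_fits, wt_result):
        fa, _ = classical_fits
        assert fa.k_mV < wt_result.act.k_mV
        assert fa.v_half_mV >= wt_result.act.v_half_mV

    def test_inactivation_midpoints_agree_within_three_millivolts(self, classical_fits, wt_result):
        _, fi = classical_fits
        assert abs(fi.v_half_mV - wt_result.inact.v_half_mV) < 3.0
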