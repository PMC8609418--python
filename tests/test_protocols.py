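import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergkit.protocols import (
    OptimisedConfig,
    ProtocolError,
    apply_junction_correction,
    build_ap_waveform,
    build_classical_protocols,
    build_optimised_protocol,
)


class TestAPWaveform:
    def test_template_extrema_and_cycle(self):
        ap = build_ap_waveform()
        v = ap.samples_mV
        assert v.max() == pytest.approx(36.0)
        assert v.min() == pytest.approx(-88.0)
        assert len(v) * ap.sample_interval_ms == pytest.approx(1000.0)

    def test_fast_monotone_upstroke(self):
        ap = build_ap_waveform()
        dt = ap.sample_interval_ms
        i_peak = int(np.argmax(ap.samples_mV))
        assert i_peak * dt <= 5.0
        assert np.all(np.diff(ap.samples_mV[: i_peak + 1]) >= 0)

    def test_single_global_maximum_and_flat_diastole(self):
        ap = build_ap_waveform()
        v = ap.samples_mV
        i_peak = int(np.argmax(v))
        # strictly decreasing after the peak until flat diastole
        assert np.all(np.diff(v[i_peak:]) <= 1e-12)
        last_100ms = v[-int(100 / ap.sample_interval_ms):]
        assert np.max(np.abs(last_100ms - (-88.0))) < 0.1

    def test_apd90_honoured(self):
        for apd90 in (180.0, 230.0, 320.0):
            ap = build_ap_waveform(apd90_ms=apd90)
            i90 = int(round(apd90 / ap.sample_interval_ms))
            v90 = -88.0 + 0.1 * (36.0 + 88.0)
            assert ap.samples_mV[i90] == pytest.approx(v90, abs=0.2)

    @pytest.mark.parametrize(
        "kwargs", [{"sample_interval_ms": 0.0}, {"sample_interval_ms": 2.0},
                   {"apd90_ms": 100.0}, {"apd90_ms": 600.0}]
    )
    def test_out_of_range_parameters(self, kwargs):
        with pytest.raises(ValueError):
            build_ap_waveform(**kwargs)


class TestOptimisedProtocol:
    def test_total_duration_and_subprotocol_count(self, optimised_protocol):
        assert optimised_protocol.total_duration_ms == pytest.approx(35000.0)
        assert len(optimised_protocol.subprotocols) == 7
        assert [sp.id for sp in optimised_protocol.subprotocols] == [
            f"SP{i}" for i in range(1, 8)
        ]

    def test_sp1_is_three_ap_cycles(self, optimised_protocol):
        sp1 = optimised_protocol.subprotocol("SP1")
        assert sp1.duration_ms == pytest.approx(3000.0)
        assert len(sp1.segments) == 3
        assert all(s.kind == "waveform" for s in sp1.segments)

    def test_measure_windows_inside_spans(self, optimised_protocol):
        for sp in optimised_protocol.subprotocols:
            for label, t0, t1 in sp.measure_windows:
                assert 0.0 <= t0 < t1 <= sp.duration_ms

    def test_command_series_reproduces_segment_boundaries(self, optimised_protocol):
        t, v = optimised_protocol.command_series()
        dt = optimised_protocol.sample_interval_ms
        assert len(t) == optimised_protocol.n_samples
        for row in optimised_protocol.segment_table():
            if row["kind"] != "step":
                continue
            i0 = int(round(row["t_start_ms"] / dt))
            i1 = i0 + int(round(row["duration_ms"] / dt))
            assert np.all(v[i0:i1] == row["voltage_mV"])

    def test_retiming_override_rejected(self):
        cfg = OptimisedConfig(sp2_durations_ms=(100.0,) * 11)
        with pytest.raises(ProtocolError):
            build_optimised_protocol(cfg)

    def test_retiming_override_allowed_with_flag(self):
        cfg = OptimisedConfig(sp2_durations_ms=(100.0,) * 11, allow_retiming=True)
        proto = build_optimised_protocol(cfg)
        assert proto.total_duration_ms < 35000.0


class TestClassicalProtocols:
    def test_activation_step_and_sweep_timing(self, classical_protocols):
        act, _ = classical_protocols
        sp = act.subprotocol("CLASSICAL_ACT")
        conds = [s for s in sp.segments if s.label.startswith("cond@")]
        assert all(s.duration_ms == 2000.0 for s in conds)
        # one sweep every 8 s
        starts = sp.segment_starts()
        cond_starts = [t for t, s in zip(starts, sp.segments) if s.label.startswith("cond@")]
        assert np.allclose(np.diff(cond_starts), 8000.0)

    def test_inactivation_sweep_timing(self, classical_protocols):
        _, inact = classical_protocols
        sp = inact.subprotocol("CLASSICAL_INACT")
        starts = sp.segment_starts()
        cond_starts = [t for t, s in zip(starts, sp.segments) if s.label.startswith("cond@")]
        assert np.allclose(np.diff(cond_starts), 5000.0)
        conds = [s for s in sp.segments if s.label.startswith("cond@")]
        assert all(s.duration_ms == 500.0 and s.voltage_mV == 40.0 for s in conds)


class TestJunctionCorrection:
    @pytest.mark.parametrize(
        "vp, offset, expected",
        [(0.0, 8.2, -8.2), (-80.0, 8.2, -88.2), (12.5, 0.0, 12.5)],
    )
    def test_examples(self, vp, offset, expected):
        assert apply_junction_correction(vp, offset) == pytest.approx(expected)

    @given(
        vp=st.floats(-150, 80),
        offset=st.floats(-20, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_is_a_pure_shift(self, vp, offset):
        assert apply_junction_correction(vp, offset) == pytest.approx(vp - offset)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            apply_junction_correction(float("nan"))
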