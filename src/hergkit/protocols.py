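"""Voltage-clamp protocol construction.

The package works with three command-voltage designs:

* the *optimised* 35-s protocol — seven consecutive subprotocols (SP1..SP7)
  that extract action-potential-clamp currents, steady-state activation and
  inactivation, and the four kinetic processes of the hERG channel in a
  single sweep;
* the *classical* activation protocol (2-s conditioning steps, one sweep
  every 8 s) and the *classical* inactivation protocol (brief test pulses
  from a +40 mV conditioning level, one sweep every 5 s).

All potentials are command potentials in mV, all times in ms.  A protocol is
an ordered list of :class:`Subprotocol` objects, each an ordered list of
:class:`VoltageSegment` (constant steps or sampled waveforms) plus labelled
measurement windows that the analysis module consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoltageSegment",
    "Subprotocol",
    "VoltageProtocol",
    "APWaveform",
    "JUNCTION_OFFSET_MV",
    "apply_junction_correction",
    "build_ap_waveform",
    "build_optimised_protocol",
    "build_classical_protocols",
    "OptimisedConfig",
]

#: Liquid-junction offset between pipette and membrane potential,
#: V_m = V_p − 8.2 mV.
JUNCTION_OFFSET_MV = 8.2

HOLDING_MV = -80.0

_V_MIN, _V_MAX = -150.0, 80.0


class ProtocolError(ValueError):
    """Raised for inconsistent protocol definitions."""


@dataclass(frozen=True)
class VoltageSegment:
    """One command segment: a constant step or a reference to a waveform."""

    label: str
    kind: str  # "step" | "waveform"
    duration_ms: float
    voltage_mV: float | None = None
    waveform_ref: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "waveform"):
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if not self.duration_ms > 0:
            raise ProtocolError(f"segment {self.label!r}: duration must be > 0")
        if self.kind == "step":
            v = self.voltage_mV
            if v is None or not np.isfinite(v) or not (_V_MIN <= v <= _V_MAX):
                raise ProtocolError(
                    f"segment {self.label!r}: step voltage {v} outside "
                    f"[{_V_MIN}, {_V_MAX}] mV"
                )
        elif self.waveform_ref is None:
            raise ProtocolError(f"segment {self.label!r}: waveform_ref required")


@dataclass(frozen=True)
class Subprotocol:
    """Ordered segments plus measurement windows (relative to subprotocol start).

    Window labels follow the convention ``"<quantity>@<voltage>"``, e.g.
    ``"act_tail@-50"`` is the +70 mV tail-measurement window that follows the
    −50 mV conditioning step of SP2.
    """

    id: str
    segments: tuple[VoltageSegment, ...]
    measure_windows: tuple[tuple[str, float, float], ...] = ()

    @property
    def duration_ms(self) -> float:
        return float(sum(s.duration_ms for s in self.segments))

    def __post_init__(self) -> None:
        dur = self.duration_ms
        for label, t0, t1 in self.measure_windows:
            if not (0.0 <= t0 < t1 <= dur + 1e-9):
                raise ProtocolError(
                    f"{self.id}: window {label!r} [{t0}, {t1}] outside 0..{dur} ms"
                )

    def segment_starts(self) -> np.ndarray:
        """Start time of each segment relative to the subprotocol start."""
        return np.concatenate(
            ([0.0], np.cumsum([s.duration_ms for s in self.segments])[:-1])
        )

    def window(self, label: str) -> tuple[float, float]:
        for lab, t0, t1 in self.measure_windows:
            if lab == label:
                return t0, t1
        raise KeyError(f"{self.id}: no measure window {label!r}")


@dataclass(frozen=True)
class APWaveform:
    """One sampled human ventricular action-potential cycle.

    The template spans −88 mV (diastole) to +36 mV (overshoot) over a 1-s
    cycle; ``apd90_ms`` parameterises the time at which the template has
    repolarised by 90%.
    """

    samples_mV: np.ndarray
    sample_interval_ms: float
    apd90_ms: float
    cycle_length_ms: float = 1000.0
    v_rest_mV: float = -88.0
    v_peak_mV: float = 36.0


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered list of subprotocols sharing one sample interval."""

    name: str
    subprotocols: tuple[Subprotocol, ...]
    sample_interval_ms: float
    waveforms: dict[str, APWaveform] = field(default_factory=dict)

    @property
    def total_duration_ms(self) -> float:
        return float(sum(sp.duration_ms for sp in self.subprotocols))

    def __post_init__(self) -> None:
        ids = [sp.id for sp in self.subprotocols]
        if len(set(ids)) != len(ids):
            raise ProtocolError(f"duplicate subprotocol ids in {self.name!r}")

    def subprotocol(self, sp_id: str) -> Subprotocol:
        for sp in self.subprotocols:
            if sp.id == sp_id:
                return sp
        raise KeyError(f"{self.name}: no subprotocol {sp_id!r}")

    def subprotocol_starts(self) -> dict[str, float]:
        starts, t = {}, 0.0
        for sp in self.subprotocols:
            starts[sp.id] = t
            t += sp.duration_ms
        return starts

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_ms / self.sample_interval_ms))

    def command_series(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample the command voltage; returns ``(time_ms, voltage_mV)``.

        Sample *i* lies at ``i * sample_interval_ms``; each segment owns the
        half-open interval ``[t_start, t_end)`` so segment boundaries are
        reproduced exactly.
        """
        dt = self.sample_interval_ms
        chunks: list[np.ndarray] = []
        for sp in self.subprotocols:
            for seg in sp.segments:
                n = int(round(seg.duration_ms / dt))
                if abs(n * dt - seg.duration_ms) > 1e-6:
                    raise ProtocolError(
                        f"{sp.id}/{seg.label}: duration {seg.duration_ms} ms is "
                        f"not a multiple of the sample interval {dt} ms"
                    )
                if seg.kind == "step":
                    chunks.append(np.full(n, seg.voltage_mV, dtype=float))
                else:
                    wf = self.waveforms[seg.waveform_ref]
                    if abs(wf.sample_interval_ms - dt) > 1e-9:
                        raise ProtocolError(
                            f"waveform {seg.waveform_ref!r} sampled at "
                            f"{wf.sample_interval_ms} ms, protocol at {dt} ms"
                        )
                    if len(wf.samples_mV) != n:
                        raise ProtocolError(
                            f"{sp.id}/{seg.label}: waveform length mismatch"
                        )
                    chunks.append(np.asarray(wf.samples_mV, dtype=float))
        v = np.concatenate(chunks)
        t = np.arange(v.size) * dt
        return t, v

    def segment_table(self) -> list[dict]:
        """Flat description of every segment with absolute start times."""
        rows, t = [], 0.0
        for sp in self.subprotocols:
            for seg in sp.segments:
                rows.append(
                    {
                        "subprotocol": sp.id,
                        "label": seg.label,
                        "kind": seg.kind,
                        "t_start_ms": t,
                        "duration_ms": seg.duration_ms,
                        "voltage_mV": seg.voltage_mV,
                        "waveform_ref": seg.waveform_ref,
                    }
                )
                t += seg.duration_ms
        return rows


def apply_junction_correction(
    v_pipette_mV: float, offset_mV: float = JUNCTION_OFFSET_MV
):
    """Convert a pipette potential to a membrane potential, Vm = Vp − offset."""
    v = np.asarray(v_pipette_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("pipette potential must be finite")
    out = v - offset_mV
    return float(out) if out.ndim == 0 else out


def build_ap_waveform(
    sample_interval_ms: float = 0.1, apd90_ms: float = 230.0
) -> APWaveform:
    """Build the in-silico ventricular AP template (one 1-s cycle).

    The cycle rises from −88 mV to a +36 mV overshoot within 2 ms, drops to
    a slowly decaying plateau and then repolarises through a brisk sigmoidal
    phase 3, reaching 90% repolarisation at ``apd90_ms`` and settling onto a
    flat diastole at −88 mV for the remainder of the second.
    """
    if not (0.01 < sample_interval_ms <= 1.0):
        raise ValueError("sample_interval_ms must lie in (0.01, 1] ms")
    if not (150.0 < apd90_ms < 500.0):
        raise ValueError("apd90_ms must lie in (150, 500) ms")

    dt = sample_interval_ms
    cycle = 1000.0
    n = int(round(cycle / dt))
    t = np.arange(n) * dt
    v_rest, v_peak = -88.0, 36.0
    amp = v_peak - v_rest

    t_up = 2.0  # upstroke duration, well under the 5-ms bound
    v = np.empty(n)
    up = t < t_up
    # half-cosine upstroke: smooth, monotone, exact extrema
    v[up] = v_rest + amp * 0.5 * (1.0 - np.cos(np.pi * t[up] / t_up))

    # plateau (early repolarisation to ~0 mV, slow linear sag) times a
    # sigmoidal phase-3 repolarisation whose centre is solved so the template
    # is exactly 90% repolarised at apd90_ms
    s = t[~up] - t_up
    s90 = apd90_ms - t_up
    w3 = 12.0  # phase-3 steepness, ms

    def plateau(x):
        return (0.72 + 0.28 * np.exp(-x / 25.0)) * (
            1.0 - 0.35 * np.minimum(x / s90, 1.2)
        )

    p90 = float(plateau(np.array([s90]))[0])
    # r(s90) = p90 / (1 + exp((s90 - c)/w3)) = 0.1  ->  solve for c
    c = s90 - w3 * math.log(p90 / 0.1 - 1.0)
    r = plateau(s) / (1.0 + np.exp(np.clip((s - c) / w3, -50.0, 50.0)))
    v[~up] = v_rest + amp * r

    # exact template extrema (guard against sampling missing the crest)
    v[np.argmax(v)] = v_peak
    return APWaveform(
        samples_mV=v, sample_interval_ms=dt, apd90_ms=apd90_ms
    )


# --------------------------------------------------------------------------
# optimised 35-s protocol
# --------------------------------------------------------------------------

#: SP2 conditioning potentials and durations.  Durations approximate five
#: activation time constants of the WT channel at each potential, so the
#: activation gate reaches steady state before the tail measurement.
SP2_STEPS_MV = (-50.0, -40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 50.0, 70.0)
SP2_DURATIONS_MS = (2500.0, 2000.0, 1600.0, 1200.0, 900.0, 700.0, 500.0, 400.0, 300.0, 200.0, 150.0)
SP2_RELIEF_MV = -110.0
SP2_RELIEF_MS = 5.0
SP2_MEASURE_MV = 70.0
SP2_MEASURE_MS = 30.0
SP2_GAP_MS = 100.0

#: SP3 inactivation test potentials, +50 → −130 mV in −20 mV decrements.
SP3_PULSES_MV = tuple(np.arange(50.0, -131.0, -20.0))
SP3_PULSE_MS = 15.0
SP3_RETURN_MS = 20.0

SP4_TAILS_MV = (-120.0, -110.0, -100.0)
SP5_STEPS_MV = (40.0, 20.0, 0.0, -20.0)
SP6_STEPS_MV = (-50.0, -70.0, -90.0, -110.0, -130.0)
SP7_STEPS_MV = (70.0, 0.0)


@dataclass(frozen=True)
class OptimisedConfig:
    """Tunable knobs of the optimised protocol (defaults are canonical)."""

    sample_interval_ms: float = 0.1
    apd90_ms: float = 230.0
    sp2_steps_mV: tuple = SP2_STEPS_MV
    sp2_durations_ms: tuple = SP2_DURATIONS_MS
    allow_retiming: bool = False


def _sp1(cfg: OptimisedConfig) -> tuple[Subprotocol, APWaveform]:
    wf = build_ap_waveform(cfg.sample_interval_ms, cfg.apd90_ms)
    segs = tuple(
        VoltageSegment(f"ap{i}", "waveform", 1000.0, waveform_ref="ap")
        for i in (1, 2, 3)
    )
    wins = tuple((f"ap{i}", (i - 1) * 1000.0, i * 1000.0) for i in (1, 2, 3))
    return Subprotocol("SP1", segs, wins), wf


def _fmt(v: float) -> str:
    return f"{v:+g}"


def _sp2(cfg: OptimisedConfig) -> Subprotocol:
    if len(cfg.sp2_steps_mV) != len(cfg.sp2_durations_ms):
        raise ProtocolError("SP2 step/duration tables differ in length")
    segs = [VoltageSegment("lead", "step", 65.0, HOLDING_MV)]
    wins = []
    t = 65.0
    for v, dur in zip(cfg.sp2_steps_mV, cfg.sp2_durations_ms):
        tag = _fmt(v)
        segs += [
            VoltageSegment(f"cond@{tag}", "step", dur, v),
            VoltageSegment(f"relief@{tag}", "step", SP2_RELIEF_MS, SP2_RELIEF_MV),
            VoltageSegment(f"meas@{tag}", "step", SP2_MEASURE_MS, SP2_MEASURE_MV),
            VoltageSegment(f"gap@{tag}", "step", SP2_GAP_MS, HOLDING_MV),
        ]
        t_cond_end = t + dur
        t_meas = t_cond_end + SP2_RELIEF_MS
        wins.append((f"act_tail@{tag}", t_meas, t_meas + SP2_MEASURE_MS))
        if v in (-50.0, -30.0, -10.0):
            # activation-kinetics windows re-used by the kinetics analysis
            wins.append((f"act_onset@{tag}", t, t_cond_end))
        t = t_meas + SP2_MEASURE_MS + SP2_GAP_MS
    return Subprotocol("SP2", tuple(segs), tuple(wins))


def _sp3() -> Subprotocol:
    segs = [
        VoltageSegment("lead", "step", 100.0, HOLDING_MV),
        VoltageSegment("open", "step", 500.0, 70.0),
    ]
    wins = []
    t = 600.0
    for v in SP3_PULSES_MV:
        tag = _fmt(v)
        segs += [
            VoltageSegment(f"pulse@{tag}", "step", SP3_PULSE_MS, v),
            VoltageSegment(f"meas@{tag}", "step", SP3_RETURN_MS, 70.0),
        ]
        wins.append((f"inact_pulse@{tag}", t, t + SP3_PULSE_MS))
        wins.append(
            (f"inact_tail@{tag}", t + SP3_PULSE_MS, t + SP3_PULSE_MS + SP3_RETURN_MS)
        )
        t += SP3_PULSE_MS + SP3_RETURN_MS
    segs.append(VoltageSegment("pad", "step", 3500.0 - t, HOLDING_MV))
    return Subprotocol("SP3", tuple(segs), tuple(wins))


def _sp4() -> Subprotocol:
    segs = [VoltageSegment("lead", "step", 300.0, HOLDING_MV)]
    wins = []
    t = 300.0
    for v in SP4_TAILS_MV:
        tag = _fmt(v)
        segs += [
            VoltageSegment(f"act@{tag}", "step", 600.0, 20.0),
            VoltageSegment(f"tail@{tag}", "step", 600.0, v),
            VoltageSegment(f"gap@{tag}", "step", 200.0, HOLDING_MV),
        ]
        wins.append((f"deact_tail@{tag}", t + 600.0, t + 1200.0))
        t += 1400.0
    return Subprotocol("SP4", tuple(segs), tuple(wins))


def _sp5() -> Subprotocol:
    segs = [VoltageSegment("lead", "step", 100.0, HOLDING_MV)]
    wins = []
    t = 100.0
    for v in SP5_STEPS_MV:
        tag = _fmt(v)
        segs += [
            VoltageSegment(f"hold@{tag}", "step", 150.0, HOLDING_MV),
            VoltageSegment(f"open@{tag}", "step", 200.0, 70.0),
            VoltageSegment(f"relief@{tag}", "step", 10.0, -110.0),
            VoltageSegment(f"test@{tag}", "step", 40.0, v),
        ]
        t_test = t + 360.0
        wins.append((f"inact_onset@{tag}", t_test, t_test + 40.0))
        t += 400.0
    segs.append(VoltageSegment("pad", "step", 4000.0 - t, HOLDING_MV))
    return Subprotocol("SP5", tuple(segs), tuple(wins))


def _sp6() -> Subprotocol:
    segs = [VoltageSegment("lead", "step", 100.0, HOLDING_MV)]
    wins = []
    t = 100.0
    for v in SP6_STEPS_MV:
        tag = _fmt(v)
        segs += [
            VoltageSegment(f"hold@{tag}", "step", 150.0, HOLDING_MV),
            VoltageSegment(f"inact@{tag}", "step", 300.0, 70.0),
            VoltageSegment(f"test@{tag}", "step", 40.0, v),
        ]
        t_test = t + 450.0
        wins.append((f"rec_onset@{tag}", t_test, t_test + 40.0))
        t += 490.0
    segs.append(VoltageSegment("pad", "step", 4000.0 - t, HOLDING_MV))
    return Subprotocol("SP6", tuple(segs), tuple(wins))


def _sp7() -> Subprotocol:
    segs = [
        VoltageSegment("lead", "step", 100.0, HOLDING_MV),
        VoltageSegment("act@+70", "step", 200.0, 70.0),
        VoltageSegment("deact", "step", 800.0, HOLDING_MV),
        VoltageSegment("act@+0", "step", 700.0, 0.0),
        VoltageSegment("pad", "step", 2200.0, HOLDING_MV),
    ]
    wins = (
        ("act_onset@+70", 100.0, 300.0),
        ("act_onset@+0", 1100.0, 1800.0),
    )
    return Subprotocol("SP7", tuple(segs), wins)


def build_optimised_protocol(
    config: OptimisedConfig | None = None,
) -> VoltageProtocol:
    """Construct the 35-s optimised protocol (SP1..SP7).

    Raises a :class:`ProtocolError` when overrides break the 35-s total,
    unless ``config.allow_retiming`` is set.
    """
    cfg = config or OptimisedConfig()
    sp1, ap = _sp1(cfg)
    proto = VoltageProtocol(
        name="optimised",
        subprotocols=(sp1, _sp2(cfg), _sp3(), _sp4(), _sp5(), _sp6(), _sp7()),
        sample_interval_ms=cfg.sample_interval_ms,
        waveforms={"ap": ap},
    )
    if not cfg.allow_retiming and abs(proto.total_duration_ms - 35000.0) > 1e-6:
        raise ProtocolError(
            f"optimised protocol totals {proto.total_duration_ms} ms, "
            "expected 35000 ms (set allow_retiming to override)"
        )
    return proto


# --------------------------------------------------------------------------
# classical protocols
# --------------------------------------------------------------------------

CLASSICAL_ACT_STEPS_MV = tuple(np.arange(-80.0, 61.0, 10.0))
CLASSICAL_ACT_STEP_MS = 2000.0
CLASSICAL_ACT_TAIL_MV = -50.0
CLASSICAL_ACT_TAIL_MS = 2000.0
CLASSICAL_ACT_SWEEP_MS = 8000.0

CLASSICAL_INACT_STEPS_MV = tuple(np.arange(-130.0, 41.0, 10.0))
CLASSICAL_INACT_COND_MV = 40.0
CLASSICAL_INACT_COND_MS = 500.0
CLASSICAL_INACT_PULSE_MS = 20.0
CLASSICAL_INACT_RETURN_MS = 20.0
CLASSICAL_INACT_SWEEP_MS = 5000.0


def build_classical_protocols(
    sample_interval_ms: float = 0.1,
) -> tuple[VoltageProtocol, VoltageProtocol]:
    """Build the classical activation and inactivation protocols.

    Both are continuous multi-sweep designs: the inter-sweep interval (8 s
    activation, 5 s inactivation) is spent at the −80 mV holding potential so
    gating relaxes between sweeps exactly as in the recorded experiment.
    """
    # activation: hold −80, 2-s steps −80..+60, 2-s tail at −50
    segs, wins = [], []
    t = 0.0
    for v in CLASSICAL_ACT_STEPS_MV:
        tag = _fmt(v)
        rest = CLASSICAL_ACT_SWEEP_MS - CLASSICAL_ACT_STEP_MS - CLASSICAL_ACT_TAIL_MS
        segs += [
            VoltageSegment(f"cond@{tag}", "step", CLASSICAL_ACT_STEP_MS, v),
            VoltageSegment(
                f"tail@{tag}", "step", CLASSICAL_ACT_TAIL_MS, CLASSICAL_ACT_TAIL_MV
            ),
            VoltageSegment(f"rest@{tag}", "step", rest, HOLDING_MV),
        ]
        t_tail = t + CLASSICAL_ACT_STEP_MS
        wins.append((f"act_tail@{tag}", t_tail, t_tail + CLASSICAL_ACT_TAIL_MS))
        t += CLASSICAL_ACT_SWEEP_MS
    act = VoltageProtocol(
        name="classical-act",
        subprotocols=(Subprotocol("CLASSICAL_ACT", tuple(segs), tuple(wins)),),
        sample_interval_ms=sample_interval_ms,
    )

    # inactivation: 500 ms at +40, 20-ms test pulse, return to +40
    segs, wins = [], []
    t = 0.0
    for v in CLASSICAL_INACT_STEPS_MV:
        tag = _fmt(v)
        rest = (
            CLASSICAL_INACT_SWEEP_MS
            - CLASSICAL_INACT_COND_MS
            - CLASSICAL_INACT_PULSE_MS
            - CLASSICAL_INACT_RETURN_MS
        )
        segs += [
            VoltageSegment(
                f"cond@{tag}", "step", CLASSICAL_INACT_COND_MS, CLASSICAL_INACT_COND_MV
            ),
            VoltageSegment(f"pulse@{tag}", "step", CLASSICAL_INACT_PULSE_MS, v),
            VoltageSegment(
                f"meas@{tag}",
                "step",
                CLASSICAL_INACT_RETURN_MS,
                CLASSICAL_INACT_COND_MV,
            ),
            VoltageSegment(f"rest@{tag}", "step", rest, HOLDING_MV),
        ]
        t_pulse = t + CLASSICAL_INACT_COND_MS
        t_meas = t_pulse + CLASSICAL_INACT_PULSE_MS
        wins.append((f"inact_pulse@{tag}", t_pulse, t_meas))
        wins.append((f"inact_tail@{tag}", t_meas, t_meas + CLASSICAL_INACT_RETURN_MS))
        t += CLASSICAL_INACT_SWEEP_MS
    inact = VoltageProtocol(
        name="classical-inact",
        subprotocols=(Subprotocol("CLASSICAL_INACT", tuple(segs), tuple(wins)),),
        sample_interval_ms=sample_interval_ms,
    )
    return act, inact
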