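"""Automated analysis of optimised- and classical-protocol recordings.

The routine mirrors what an electrophysiologist would do by hand, in a fixed
order: estimate and subtract linear leak, cut the continuous sweep into
subprotocols by the protocol's time table, extrapolate tail amplitudes at the
+70 mV measurement steps back to step onset (mono-exponential), compensate
the deactivation that occurs during the most negative steady-state
inactivation pulses, fit Boltzmann curves, fit per-process exponential
kinetics, and integrate the third AP-clamp cycle into the repolarisation
power.

Quality gates: current stability between AP cycles 2 and 3 must vary by less
than 10%, and a variant is analysable for voltage dependence only when its
current density reaches at least 20% of the WT reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .model import TraceBundle
from .protocols import (
    SP2_RELIEF_MS,
    SP2_RELIEF_MV,
    SP2_STEPS_MV,
    SP3_PULSE_MS,
    SP3_PULSES_MV,
    SP3_RETURN_MS,
    SP4_TAILS_MV,
    SP5_STEPS_MV,
    SP6_STEPS_MV,
    CLASSICAL_ACT_STEPS_MV,
    CLASSICAL_INACT_STEPS_MV,
    CLASSICAL_INACT_PULSE_MS,
    Subprotocol,
    VoltageProtocol,
)

__all__ = [
    "QCThresholds",
    "BoltzmannFit",
    "KineticsFit",
    "TailMeasure",
    "PhenotypeResult",
    "SegmentationError",
    "segment_recording",
    "tail_amplitude",
    "compensate_deactivation",
    "fit_boltzmann",
    "fit_kinetics",
    "repolarisation_power",
    "stability_check",
    "amplitude_gate",
    "subtract_leak",
    "analyse_optimised",
    "analyse_classical_activation",
    "analyse_classical_inactivation",
]


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds of the pipeline."""

    ap_stability_frac: float = 0.10
    amplitude_gate_frac: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.ap_stability_frac < 1 and 0 < self.amplitude_gate_frac < 1):
            raise ValueError("QC thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class BoltzmannFit:
    v_half_mV: float
    k_mV: float
    I_max: float
    direction: str  # "activation" | "inactivation"
    rmse: float
    n_points: int


@dataclass(frozen=True)
class KineticsFit:
    process: str
    voltage_mV: float
    tau_ms: float
    rmse: float
    t_half_ms: float | None = None
    flagged: bool = False


@dataclass(frozen=True)
class TailMeasure:
    amplitude_pA: float
    tau_ms: float
    low_signal: bool
    compensated: bool = False
    unreliable: bool = False


@dataclass
class SubprotocolSlice:
    """One subprotocol's samples, with time relative to its own start."""

    id: str
    time_ms: np.ndarray
    command_mV: np.ndarray
    current_pA: np.ndarray
    sub: Subprotocol

    def window(self, label: str) -> "SubprotocolSlice":
        t0, t1 = self.sub.window(label)
        m = (self.time_ms >= t0 - 1e-9) & (self.time_ms < t1 - 1e-9)
        return SubprotocolSlice(
            id=f"{self.id}/{label}",
            time_ms=self.time_ms[m] - t0,
            command_mV=self.command_mV[m],
            current_pA=self.current_pA[m],
            sub=self.sub,
        )


@dataclass
class PhenotypeResult:
    """All per-cell biophysics extracted by the optimised-protocol analysis."""

    variant: str
    zygosity: str
    act: BoltzmannFit | None
    inact: BoltzmannFit | None
    density_pA_per_pF: float
    repolarisation_power_pC_per_pF: float
    stability_variation_frac: float
    stability_pass: bool
    analysable: bool | None  # None when no WT reference was supplied
    kinetics: dict[str, list[KineticsFit]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


class SegmentationError(ValueError):
    pass


def segment_recording(
    bundle: TraceBundle, protocol: VoltageProtocol
) -> dict[str, SubprotocolSlice]:
    """Cut a continuous recording into its subprotocols.

    Uses the protocol's time table ("time conversion rule"): each sample
    belongs to exactly one subprotocol, so the slices partition the input.
    """
    if bundle.protocol_name != protocol.name:
        raise SegmentationError(
            f"bundle was recorded under {bundle.protocol_name!r}, "
            f"not {protocol.name!r}"
        )
    if abs(bundle.sample_interval_ms - protocol.sample_interval_ms) > 1e-9:
        raise SegmentationError("sample interval mismatch")
    n_expected = protocol.n_samples
    if len(bundle.time_ms) != n_expected:
        raise SegmentationError(
            f"expected {n_expected} samples for {protocol.name!r}, "
            f"got {len(bundle.time_ms)}"
        )
    out: dict[str, SubprotocolSlice] = {}
    i = 0
    for sp in protocol.subprotocols:
        n = int(round(sp.duration_ms / protocol.sample_interval_ms))
        sl = slice(i, i + n)
        out[sp.id] = SubprotocolSlice(
            id=sp.id,
            time_ms=bundle.time_ms[sl] - bundle.time_ms[i],
            command_mV=bundle.command_mV[sl],
            current_pA=bundle.current_pA[sl],
            sub=sp,
        )
        i += n
    return out


# --------------------------------------------------------------------------
# leak subtraction
# --------------------------------------------------------------------------


def subtract_leak(bundle: TraceBundle, protocol: VoltageProtocol) -> TraceBundle:
    """Estimate and subtract linear leak (reversal assumed at 0 mV).

    The leak conductance is read from the late diastolic plateau of the
    first AP cycle (last 80 ms before the cycle ends), where the command sits
    within 2 mV of E_K and the hERG component is negligible.
    """
    dt = protocol.sample_interval_ms
    sp1_start = protocol.subprotocol_starts().get("SP1")
    if sp1_start is None:  # classical protocols: use the leading holding level
        i0, i1 = 0, int(round(5.0 / dt))
    else:
        i0 = int(round((sp1_start + 920.0) / dt))
        i1 = int(round((sp1_start + 1000.0) / dt))
    v_ref = float(np.mean(bundle.command_mV[i0:i1]))
    i_ref = float(np.mean(bundle.current_pA[i0:i1]))
    if abs(v_ref) < 1.0:
        g_leak = 0.0
    else:
        g_leak = i_ref / v_ref
    corrected = bundle.current_pA - g_leak * bundle.command_mV
    return TraceBundle(
        time_ms=bundle.time_ms,
        command_mV=bundle.command_mV,
        current_pA=corrected,
        protocol_name=bundle.protocol_name,
        cell=bundle.cell,
        variant=bundle.variant,
        zygosity=bundle.zygosity,
        junction_corrected=bundle.junction_corrected,
        sweep_bounds_ms=bundle.sweep_bounds_ms,
    )


# --------------------------------------------------------------------------
# primitive fits
# --------------------------------------------------------------------------


def _exp_decay(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def tail_amplitude(
    win: SubprotocolSlice,
    tau_hint_ms: float | None = None,
    guard_ms: float = 1.0,
    fit_span_ms: float | None = 15.0,
    noise_floor_pA: float = 1.0,
) -> TailMeasure:
    """Tail amplitude extrapolated to the measurement-step onset.

    A mono-exponential decay with offset is fitted to the samples from
    ``guard_ms`` (settling guard) to ``fit_span_ms`` after the step, and the
    decaying component is extrapolated back to t = 0.  Flat traces below the
    noise floor return 0 with ``low_signal`` set.
    """
    t, y = win.time_ms, win.current_pA
    m = t >= guard_ms
    if fit_span_ms is not None:
        m &= t <= fit_span_ms + guard_ms
    t, y = t[m], y[m]
    if len(t) < 5:
        raise ValueError("measurement window too short to fit")
    span = float(np.ptp(y))
    if span < noise_floor_pA and float(np.max(np.abs(y))) < 2 * noise_floor_pA:
        return TailMeasure(0.0, math.nan, low_signal=True)
    tau0 = tau_hint_ms or _tau_guess(t, y)
    A0 = (y[0] - y[-1]) / max(math.exp(-t[0] / tau0) - math.exp(-t[-1] / tau0), 1e-9)
    try:
        popt, _ = curve_fit(
            _exp_decay,
            t,
            y,
            p0=(A0, tau0, y[-1]),
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return TailMeasure(0.0, math.nan, low_signal=True)
    A, tau, C = popt
    # the availability signal is the whole extrapolated current at step
    # onset: the decaying component plus the steady (non-inactivated) floor
    return TailMeasure(float(A + C), float(tau), low_signal=False)


def _tau_guess(t: np.ndarray, y: np.ndarray) -> float:
    """1/e-crossing estimate of a decay (or rise) time constant."""
    y0, y1 = y[0], y[-1]
    target = y1 + (y0 - y1) / math.e
    sign = 1.0 if y0 > y1 else -1.0
    below = np.nonzero(sign * (y - target) < 0)[0]
    if below.size:
        return max(float(t[below[0]] - t[0]), float(t[1] - t[0]))
    return float((t[-1] - t[0]) / 3.0)


def compensate_deactivation(
    raw_amplitude_pA: float,
    pulse_t_ms: float,
    tau_deact_ms: float,
) -> tuple[float, bool]:
    """Correct a tail amplitude for channels that deactivated during the
    preceding test pulse: divide by exp(−t/τ_deact).

    Returns ``(compensated, unreliable)``; the correction is flagged
    unreliable when the factor exceeds 5.
    """
    if tau_deact_ms <= 0:
        raise ValueError("tau_deact must be positive")
    factor = math.exp(pulse_t_ms / tau_deact_ms)
    return raw_amplitude_pA * factor, factor > 5.0


def _boltz_act(v, I_max, v_half, k):
    return I_max / (1.0 + np.exp(-(v - v_half) / k))


def _boltz_inact(v, I_max, v_half, k):
    return I_max / (1.0 + np.exp((v - v_half) / k))


class FitError(RuntimeError):
    pass


def fit_boltzmann(points, direction: str) -> BoltzmannFit:
    """Least-squares Boltzmann fit of (V, I) points.

    ``direction`` selects the increasing ("activation") or decreasing
    ("inactivation") sigmoid; k is reported positive in both conventions.
    """
    pts = sorted((float(v), float(i)) for v, i in points)
    if len(pts) < 5:
        raise FitError("need at least 5 points for a Boltzmann fit")
    v = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    model = _boltz_act if direction == "activation" else _boltz_inact
    I0 = float(np.max(np.abs(y))) * np.sign(y[np.argmax(np.abs(y))])
    # initial guesses from the half-maximum crossing and the 25–75% spread
    yn = y / I0 if I0 != 0 else y
    order = np.argsort(yn)
    v_half0 = float(np.interp(0.5, yn[order], v[order]))
    v25 = float(np.interp(0.25, yn[order], v[order]))
    v75 = float(np.interp(0.75, yn[order], v[order]))
    k0 = max(abs(v75 - v25) / 2.2, 1.0)
    try:
        popt, _ = curve_fit(
            model, v, y, p0=(I0, v_half0, k0),
            bounds=([-np.inf, -200.0, 0.1], [np.inf, 150.0, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as e:
        raise FitError(f"Boltzmann fit failed: {e}") from None
    I_max, v_half, k = popt
    resid = y - model(v, *popt)
    return BoltzmannFit(
        v_half_mV=float(v_half),
        k_mV=float(k),
        I_max=float(I_max),
        direction=direction,
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(pts),
    )


def fit_kinetics(
    win: SubprotocolSlice,
    process: str,
    voltage_mV: float,
    guard_ms: float | None = None,
    detrend_tau_ms: float | None = None,
) -> KineticsFit:
    """Mono-exponential fit of one kinetic process in a measurement window.

    * ``activation``: rising fit after an initial guard that lets the fast
      inactivation transient settle.
    * ``deactivation``: decay fitted after the hook peak of the tail;
      additionally reports t_half, the time from the peak to half-decay.
    * ``inactivation``: decay at the test potential.
    * ``recovery``: rise at the test potential, fitted up to the current
      extremum (beyond it the slow deactivation of the activation gate takes
      over).
    """
    t, y = win.time_ms, win.current_pA
    if process == "activation":
        # generous guard: the fast inactivation gate must settle before the
        # slow activation relaxation is fitted
        g = 80.0 if guard_ms is None else guard_ms
        g = min(g, 0.4 * float(t[-1] - t[0]))
        m = t >= g
        t, y = t[m], y[m]
    elif process == "inactivation":
        g = 0.5 if guard_ms is None else guard_ms
        m = t >= g
        t, y = t[m], y[m]
    elif process == "deactivation":
        ipk = int(np.argmax(np.abs(y)))
        t, y = t[ipk:], y[ipk:]
    elif process == "recovery":
        # fit only the rising limb, up to 95% of the extremum: beyond it the
        # slow deactivation of the activation gate dominates the shape.
        # When the deactivation time constant is known the window is
        # detrended by it first, which removes that bias.
        g = 0.3 if guard_ms is None else guard_ms
        if detrend_tau_ms is not None and detrend_tau_ms > 0:
            y = y * np.exp(t / detrend_tau_ms)
        ipk = int(np.argmax(np.abs(y)))
        if abs(y[ipk]) <= 0:
            raise FitError(f"recovery@{voltage_mV}: no measurable current")
        above = np.nonzero(np.abs(y) >= 0.95 * abs(y[ipk]))[0]
        stop = above[0] if above.size else ipk
        m = (t >= g) & (t <= t[stop])
        t, y = t[m], y[m]
    else:
        raise ValueError(f"unknown process {process!r}")
    if len(t) < 5:
        raise FitError(f"{process}@{voltage_mV}: window too short")
    if float(np.ptp(y)) < 0.02:
        raise FitError(f"{process}@{voltage_mV}: no measurable relaxation")
    t = t - t[0]
    tau0 = _tau_guess(t, y)
    try:
        popt, _ = curve_fit(
            _exp_decay, t, y, p0=(y[0] - y[-1], tau0, y[-1]),
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e5, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as e:
        raise FitError(f"{process}@{voltage_mV}: {e}") from None
    A, tau, C = popt
    resid = y - _exp_decay(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    flagged = abs(A) > 0 and rmse > 0.2 * abs(A)
    t_half = None
    if process == "deactivation":
        # measured, not fitted: time from tail peak to half of (peak - asymptote)
        target = C + 0.5 * (y[0] - C)
        sign = 1.0 if y[0] > C else -1.0
        idx = np.nonzero(sign * (y - target) <= 0)[0]
        t_half = float(t[idx[0]]) if idx.size else float(tau * math.log(2.0))
    return KineticsFit(
        process=process,
        voltage_mV=voltage_mV,
        tau_ms=float(tau),
        rmse=rmse,
        t_half_ms=t_half,
        flagged=bool(flagged),
    )


# --------------------------------------------------------------------------
# AP-clamp quantities
# --------------------------------------------------------------------------


def _cycle_peaks(sp1: SubprotocolSlice, C_m_pF: float) -> list[float]:
    peaks = []
    for lab in ("ap1", "ap2", "ap3"):
        w = sp1.window(lab)
        peaks.append(float(np.max(w.current_pA)) / C_m_pF)
    return peaks


def stability_check(
    sp1: SubprotocolSlice, C_m_pF: float, threshold: float = 0.10
) -> tuple[float, bool]:
    """Relative change of peak outward current density between AP cycles 2
    and 3; passes when below ``threshold`` (default 10%)."""
    _, p2, p3 = _cycle_peaks(sp1, C_m_pF)
    if p3 == 0:
        return math.inf, False
    var = abs(p3 - p2) / abs(p3)
    return float(var), bool(var < threshold)


def repolarisation_power(sp1: SubprotocolSlice, C_m_pF: float) -> float:
    """Time integral of current density over the third AP cycle (pC/pF).

    The first two cycles bring the gates to their periodic steady state; the
    third is the one analysed.
    """
    labels = [lab for lab, _, _ in sp1.sub.measure_windows if lab.startswith("ap")]
    if len(labels) < 3:
        raise ValueError("repolarisation power needs at least 3 AP cycles")
    w = sp1.window("ap3")
    # pA * ms / pF = fC/pF; /1000 -> pC/pF
    return float(np.trapezoid(w.current_pA, w.time_ms)) / C_m_pF / 1000.0


def amplitude_gate(
    variant_density: float, wt_reference_density: float, threshold: float = 0.20
) -> bool:
    """Analysability gate: at least 20% of the WT current density."""
    if wt_reference_density <= 0:
        raise ValueError("WT reference density must be positive")
    return bool(variant_density / wt_reference_density >= threshold)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def _tau_deact_extrapolator(deact_fits: list[KineticsFit]):
    """Log-linear (in V) extrapolation of the fitted deactivation taus."""
    vs = np.array([f.voltage_mV for f in deact_fits])
    taus = np.array([f.tau_ms for f in deact_fits])
    if len(vs) >= 2:
        slope, intercept = np.polyfit(vs, np.log(taus), 1)
    else:
        slope, intercept = 0.0, math.log(float(taus[0]))
    return lambda v: math.exp(intercept + slope * v)


def _tau_a_estimator(
    deact_fits: list[KineticsFit], act_fits: list[KineticsFit]
):
    """Activation-gate time-constant estimate across the whole voltage range,
    assembled from the cell's own deactivation (SP4) and activation
    (SP2/SP7) fits: monotone-cubic in log tau between fitted points,
    quadratic log-extrapolation below the deactivation range, constant above.
    """
    pts = sorted(
        {f.voltage_mV: f.tau_ms for f in (*deact_fits, *act_fits) if f.tau_ms > 0}.items()
    )
    if len(pts) < 2:
        return None
    vs = np.array([p[0] for p in pts])
    lt = np.log([p[1] for p in pts])
    core = PchipInterpolator(vs, lt, extrapolate=False)
    coef_lo = None
    if len(deact_fits) >= 3:
        dv = np.array([f.voltage_mV for f in deact_fits])
        coef_lo = np.polyfit(dv, np.log([f.tau_ms for f in deact_fits]), 2)

    if len(vs) >= 2:
        slope_hi = (lt[-1] - lt[-2]) / (vs[-1] - vs[-2])
    else:
        slope_hi = 0.0

    def tau(v: float) -> float:
        if v < vs[0]:
            if coef_lo is not None:
                return float(np.exp(np.polyval(coef_lo, v)))
            return float(np.exp(lt[0]))
        if v > vs[-1]:
            # log-linear continuation of the last fitted segment
            return max(float(np.exp(lt[-1] + slope_hi * (v - vs[-1]))), 1.0)
        return float(np.exp(core(v)))

    return tau


def _tau_h_interpolator(fits: list[KineticsFit]):
    """Piecewise log-linear interpolation of the inactivation-gate tau from
    the cell's own SP5 (onset) and SP6 (recovery) fits; constant beyond the
    fitted range.  Implausible fits (flagged, or far outside the fast
    inactivation-gate range) are excluded."""
    pts = sorted(
        (f.voltage_mV, f.tau_ms)
        for f in fits
        if 0 < f.tau_ms < 100 and not f.flagged
    )
    if len(pts) < 2:
        return None
    vs = np.array([p[0] for p in pts])
    lt = np.log([p[1] for p in pts])
    return lambda v: float(np.exp(np.interp(v, vs, lt)))


def _compensate_relaxation(amp: float, pulse_t_ms: float, tau_h_ms: float) -> float:
    """Correct an availability point for incomplete relaxation of the
    inactivation gate during a finite test pulse: the measured level is
    h_inf·(1 − exp(−T/τ_h)) (the carried-in availability is negligible), so
    divide by the completion factor."""
    completion = 1.0 - math.exp(-pulse_t_ms / tau_h_ms)
    return amp / completion if completion > 0.2 else amp


def analyse_optimised(
    bundle: TraceBundle,
    protocol: VoltageProtocol,
    wt_reference_density: float | None = None,
    qc: QCThresholds = QCThresholds(),
    leak_subtract: bool = True,
) -> PhenotypeResult:
    """Full automated analysis of one optimised-protocol recording."""
    if leak_subtract:
        bundle = subtract_leak(bundle, protocol)
    sl = segment_recording(bundle, protocol)
    C_m = bundle.cell.C_m_pF
    notes: list[str] = []

    variation, stable = stability_check(sl["SP1"], C_m, qc.ap_stability_frac)
    rp = repolarisation_power(sl["SP1"], C_m)

    # SP4 deactivation kinetics first: SP3 compensation needs tau_deact(V)
    kinetics: dict[str, list[KineticsFit]] = {
        "activation": [],
        "deactivation": [],
        "inactivation": [],
        "recovery": [],
    }
    low_signal = False
    for v in SP4_TAILS_MV:
        try:
            kinetics["deactivation"].append(
                fit_kinetics(sl["SP4"].window(f"deact_tail@{v:+g}"), "deactivation", v)
            )
        except FitError as e:
            notes.append(str(e))

    # SP2 steady-state activation from relief-extrapolated +70 mV tails
    act_pts = []
    for v in SP2_STEPS_MV:
        tm = tail_amplitude(
            sl["SP2"].window(f"act_tail@{v:+g}"),
            tau_hint_ms=1.5, guard_ms=0.5, fit_span_ms=8.0,
        )
        low_signal |= tm.low_signal
        act_pts.append((v, tm.amplitude_pA))
    act_fit = None
    if not all(a == 0 for _, a in act_pts):
        try:
            act_fit = fit_boltzmann(act_pts, "activation")
        except FitError as e:
            notes.append(f"SP2 activation: {e}")

    # activation kinetics next: the SP3 compensation reconstructs the
    # activation-gate trajectory from the cell's own tau_a(V) and a_inf(V)
    for v, win, guard in (
        (70.0, sl["SP7"].window("act_onset@+70"), 30.0),
        (0.0, sl["SP7"].window("act_onset@+0"), 80.0),
        (-10.0, sl["SP2"].window("act_onset@-10"), 80.0),
        (-30.0, sl["SP2"].window("act_onset@-30"), 80.0),
        (-50.0, sl["SP2"].window("act_onset@-50"), 80.0),
    ):
        try:
            kinetics["activation"].append(
                fit_kinetics(win, "activation", v, guard_ms=guard)
            )
        except FitError as e:
            notes.append(str(e))

    # SP5/SP6 inactivation-gate kinetics: the SP3 relaxation-completion
    # correction uses the cell's own tau_h(V).  Recovery fits are detrended
    # by the estimated deactivation time constant at the test potential.
    tau_a = _tau_a_estimator(kinetics["deactivation"], kinetics["activation"])
    for v in SP5_STEPS_MV:
        try:
            kinetics["inactivation"].append(
                fit_kinetics(sl["SP5"].window(f"inact_onset@{v:+g}"), "inactivation", v)
            )
        except FitError as e:
            notes.append(str(e))
    for v in SP6_STEPS_MV:
        try:
            kinetics["recovery"].append(
                fit_kinetics(
                    sl["SP6"].window(f"rec_onset@{v:+g}"), "recovery", v,
                    detrend_tau_ms=tau_a(v) if tau_a is not None else None,
                )
            )
        except FitError as e:
            notes.append(str(e))

    # SP3 steady-state inactivation.  Each availability point is corrected
    # for (i) incomplete relaxation of the inactivation gate within the
    # 15-ms pulse and (ii) the activation-gate level at the end of the
    # pulse — deactivation during the most negative pulses plus the
    # incomplete re-activation carried over between pulses — reconstructed
    # recursively from the fitted tau_a(V)/a_inf(V) of the same cell.
    tau_h = _tau_h_interpolator(kinetics["inactivation"] + kinetics["recovery"])
    a_inf_hat = None
    if act_fit is not None:
        a_inf_hat = lambda v: 1.0 / (
            1.0 + math.exp(-(v - act_fit.v_half_mV) / act_fit.k_mV)
        )
    inact_pts = []
    a_gate = 1.0  # fully activated by the 500-ms +70 mV opening step
    for v in SP3_PULSES_MV:
        tm = tail_amplitude(
            sl["SP3"].window(f"inact_tail@{v:+g}"),
            tau_hint_ms=1.5, guard_ms=0.5, fit_span_ms=8.0,
        )
        low_signal |= tm.low_signal
        amp = tm.amplitude_pA
        if tau_h is not None and not tm.low_signal:
            amp = _compensate_relaxation(amp, SP3_PULSE_MS, tau_h(v))
        if tau_a is not None and a_inf_hat is not None:
            ainf = a_inf_hat(v)
            a_end = ainf + (a_gate - ainf) * math.exp(-SP3_PULSE_MS / tau_a(v))
            if not tm.low_signal:
                if a_end < 0.2:
                    notes.append(f"SP3 compensation at {v:+g} mV unreliable (>5x)")
                amp = amp / max(a_end, 0.2)
            # recovery of the activation gate during the +70 mV measurement
            a_gate = 1.0 + (a_end - 1.0) * math.exp(-SP3_RETURN_MS / tau_a(70.0))
        inact_pts.append((v, amp))
    inact_fit = None
    density = 0.0
    if not all(a == 0 for _, a in inact_pts):
        try:
            inact_fit = fit_boltzmann(inact_pts, "inactivation")
            density = abs(inact_fit.I_max) / C_m
        except FitError as e:
            notes.append(f"SP3 inactivation: {e}")

    # Second-pass SP2 refinement: the 5-ms relief step leaves a small
    # conditioning-dependent residue of inactivation in each tail; with the
    # availability curve and tau_h now known, divide each SP2 amplitude by
    # its relief-end availability and refit.
    if (
        act_fit is not None
        and inact_fit is not None
        and tau_h is not None
        and not any(a == 0 for _, a in act_pts)
    ):
        e_r = math.exp(-SP2_RELIEF_MS / tau_h(SP2_RELIEF_MV))
        h_rel = 1.0 / (
            1.0 + math.exp((SP2_RELIEF_MV - inact_fit.v_half_mV) / inact_fit.k_mV)
        )

        def h_inf_hat(v: float) -> float:
            return 1.0 / (1.0 + math.exp((v - inact_fit.v_half_mV) / inact_fit.k_mV))

        refined = [
            (v, a / (h_rel + (h_inf_hat(v) - h_rel) * e_r)) for v, a in act_pts
        ]
        try:
            act_fit = fit_boltzmann(refined, "activation")
        except FitError as e:
            notes.append(f"SP2 relief refinement: {e}")

    analysable = (
        amplitude_gate(density, wt_reference_density, qc.amplitude_gate_frac)
        if wt_reference_density is not None
        else None
    )

    return PhenotypeResult(
        variant=bundle.variant,
        zygosity=bundle.zygosity,
        act=act_fit,
        inact=inact_fit,
        density_pA_per_pF=density,
        repolarisation_power_pC_per_pF=rp,
        stability_variation_frac=variation,
        stability_pass=stable,
        analysable=analysable,
        kinetics=kinetics,
        notes=notes,
    )


def analyse_classical_activation(
    bundle: TraceBundle, protocol: VoltageProtocol
) -> BoltzmannFit:
    """Activation curve from classical 2-s steps and −50 mV tails.

    The slow tail decay after the recovery hook is fitted and extrapolated
    back to the tail onset, so every sweep is read at the same effective
    point regardless of where its hook peaks.
    """
    bundle = subtract_leak(bundle, protocol)
    sl = segment_recording(bundle, protocol)["CLASSICAL_ACT"]
    pts = []
    for v in CLASSICAL_ACT_STEPS_MV:
        w = sl.window(f"act_tail@{v:+g}")
        t, y = w.time_ms, w.current_pA
        ipk = int(np.argmax(y))
        t_fit, y_fit = t[ipk:], y[ipk:]
        stop = np.searchsorted(t_fit, t_fit[0] + 800.0)
        t_fit, y_fit = t_fit[:stop], y_fit[:stop]
        if float(np.ptp(y_fit)) < 0.02:
            pts.append((v, 0.0))
            continue
        try:
            popt, _ = curve_fit(
                _exp_decay, t_fit, y_fit,
                p0=(y_fit[0] - y_fit[-1], 400.0, y_fit[-1]),
                bounds=([-np.inf, 1.0, -np.inf], [np.inf, 1e5, np.inf]),
                maxfev=20000,
            )
            # evaluate the fitted decay at the tail onset (t = 0)
            pts.append((v, float(_exp_decay(0.0, *popt))))
        except RuntimeError:
            pts.append((v, float(np.max(y))))
    return fit_boltzmann(pts, "activation")


def analyse_classical_inactivation(
    bundle: TraceBundle, protocol: VoltageProtocol
) -> BoltzmannFit:
    """Availability curve from the classical protocol's +40 mV return tails.

    Deactivation during the 20-ms test pulses is compensated with time
    constants fitted from the pulses' own current decay at the most negative
    potentials (where the driving force is large), extrapolated across the
    pulse range in log tau.
    """
    bundle = subtract_leak(bundle, protocol)
    sl = segment_recording(bundle, protocol)["CLASSICAL_INACT"]

    # Deactivation taus from the three most negative pulses.  The pulse
    # current is the product of the fast recovery hook and the slow
    # deactivation decay, B·(1 − exp(−t/tau_r))·exp(−t/tau_d); fitting that
    # product yields tau_d without waiting for the hook to settle.
    def _hook_decay(t, B, tau_r, tau_d):
        return B * (1.0 - np.exp(-t / tau_r)) * np.exp(-t / tau_d)

    taus: list[tuple[float, float]] = []
    for v in CLASSICAL_INACT_STEPS_MV[:3]:
        w = sl.window(f"inact_pulse@{v:+g}")
        t, y = w.time_ms, w.current_pA
        m = t >= 0.3
        t, y = t[m], y[m]
        if float(np.ptp(y)) < 0.05:
            continue
        try:
            popt, _ = curve_fit(
                _hook_decay, t, y, p0=(2.0 * y[-1], 3.0, 30.0),
                bounds=([-np.inf, 0.2, 1.0], [np.inf, 50.0, 1e4]),
                maxfev=20000,
            )
            taus.append((v, float(popt[2])))
        except RuntimeError:
            continue
    tau_d = None
    if len(taus) >= 2:
        vs = np.array([p[0] for p in taus])
        lt = np.log([p[1] for p in taus])
        coef = np.polyfit(vs, lt, min(2, len(taus) - 1))
        v_hi, lt_hi = float(vs.max()), float(lt.max())

        def tau_d(v: float) -> float:
            # deactivation only slows with depolarisation: above the fitted
            # pulses the correction never exceeds the last fitted one
            lo = lt_hi if v > v_hi else float(lt.min()) - 1.0
            return float(np.exp(np.clip(np.polyval(coef, v), lo, 13.0)))

    pts = []
    for v in CLASSICAL_INACT_STEPS_MV:
        tm = tail_amplitude(
            sl.window(f"inact_tail@{v:+g}"), tau_hint_ms=3.0,
            guard_ms=0.5, fit_span_ms=10.0,
        )
        amp = tm.amplitude_pA
        if tau_d is not None and v <= -50.0 and not tm.low_signal:
            amp, _ = compensate_deactivation(amp, CLASSICAL_INACT_PULSE_MS, tau_d(v))
        pts.append((v, amp))
    return fit_boltzmann(pts, "inactivation")
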