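"""Packaged registry of the 13 clinical hERG variants plus WT.

Each entry couples the amino-acid substitution (hERG protein numbering,
NM_000238.4 translation) with the calibrated functional parameter set used
by the simulator, the trafficking calibration used by the pHluorin
generator, and pass-through clinical/structural metadata for the severity
report.

Functional calibration notes
----------------------------
* ``conductance_scale`` encodes the measured current-density ratio to WT;
  variants with no measurable current are 0, variants below the 20%
  analysability gate carry their (small) density ratio with WT gating.
* D591H, the short-QT variant, carries the depolarising shift of
  steady-state inactivation (V_half −67.1 mV, k 22.1 mV) together with
  slower inactivation onset, slower recovery from inactivation and faster
  deactivation; the kinetic scale factors are calibrated so the AP-clamp
  repolarisation-power ratio to WT is ~2.6.
* G584S carries the hyperpolarising inactivation shift (−92.6 mV) with
  faster inactivation; R176W faster inactivation and a shallower
  inactivation slope; R35W/K93E/R176W/D591H faster deactivation.
* ``structural_score``/``structural_colour`` are precomputed on the hERG
  cryo-EM structure and shipped as metadata: recompute them with
  :mod:`hergkit.structscore` when a structure file is available.  Positions
  inside the unresolved spans (140–341, 870–1006) are ``not_visible``.

Trafficking calibration: ``traffic_quench_pct`` is the background-corrected
percent fluorescence variation of the variant cohort; the generator's
membrane fraction is ``(traffic_quench_pct + background)/100``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import VariantParams

__all__ = ["VariantRecord", "REGISTRY", "VARIANT_NAMES", "make_variant_params", "get_record"]


@dataclass(frozen=True)
class VariantRecord:
    """One registry row: substitution, calibrations and clinical metadata."""

    name: str
    wild_aa: str
    position: int
    target_aa: str
    domain: str
    hgvs_c: str
    params: VariantParams
    traffic_quench_pct: float
    traffic_dn_retention: float  # factor on WT membrane fraction when co-expressed
    structural_score: int | None  # None -> position not resolved in the structure
    acmg_class: int | None = None
    schwartz_score: float | None = None
    qtc_ms: float | None = None


def _rec(
    name,
    domain,
    hgvs_c,
    quench,
    structural,
    acmg=None,
    schwartz=None,
    qtc=None,
    dn_retention=1.0,
    **params,
) -> VariantRecord:
    wild, pos, target = name[0], int(name[1:-1]), name[-1]
    return VariantRecord(
        name=name,
        wild_aa=wild,
        position=pos,
        target_aa=target,
        domain=domain,
        hgvs_c=hgvs_c,
        params=VariantParams(name=name, **params),
        traffic_quench_pct=quench,
        traffic_dn_retention=dn_retention,
        structural_score=structural,
        acmg_class=acmg,
        schwartz_score=schwartz,
        qtc_ms=qtc,
    )


WT_RECORD = VariantRecord(
    name="WT",
    wild_aa="-",
    position=0,
    target_aa="-",
    domain="-",
    hgvs_c="-",
    params=VariantParams(name="WT"),
    traffic_quench_pct=35.1,
    traffic_dn_retention=1.0,
    structural_score=0,
)


REGISTRY: dict[str, VariantRecord] = {
    "WT": WT_RECORD,
    "R35W": _rec(
        "R35W", "PAS", "c.103C>T", quench=34.0, structural=4, acmg=5, schwartz=0,
        qtc=396.0,
        conductance_scale=0.52, tau_deact_scale=0.75,
    ),
    "C64Y": _rec(
        "C64Y", "PAS", "c.191G>A", quench=15.5, structural=4, acmg=5, schwartz=4,
        qtc=509.0,
        conductance_scale=0.10,
    ),
    "T74R": _rec(
        "T74R", "PAS", "c.221C>G", quench=10.3, structural=4, acmg=5,
        conductance_scale=0.0, dn_poisoning_p=0.5, dn_retention=0.5,
    ),
    "K93E": _rec(
        "K93E", "PAS", "c.277A>G", quench=35.0, structural=3, acmg=3, schwartz=3,
        qtc=459.0,
        tau_deact_scale=0.8, d_k_act_mV=-1.5,
    ),
    "I96T": _rec(
        "I96T", "PAS", "c.287T>C", quench=14.3, structural=1, acmg=5, schwartz=5,
        qtc=492.0,
        conductance_scale=0.12, dn_poisoning_p=0.35,
    ),
    "R176W": _rec(
        "R176W", "N-linker", "c.526C>T", quench=9.2, structural=None, acmg=5,
        schwartz=7, qtc=570.0,
        conductance_scale=0.29, tau_deact_scale=0.8, tau_inact_scale=0.7,
        d_k_inact_mV=2.5,
    ),
    "R328C": _rec(
        "R328C", "N-linker", "c.982C>T", quench=24.6, structural=None, acmg=2,
        schwartz=3, qtc=485.0,
        conductance_scale=0.55,
    ),
    "R534C": _rec(
        "R534C", "VSD", "c.1600C>T", quench=10.6, structural=4, acmg=5, schwartz=1,
        qtc=450.0,
        conductance_scale=0.0,
    ),
    "A561V": _rec(
        "A561V", "pore", "c.1682C>T", quench=14.3, structural=2, acmg=5, schwartz=4,
        qtc=575.0,
        conductance_scale=0.0,
    ),
    "G584S": _rec(
        "G584S", "pore", "c.1750G>A", quench=26.3, structural=3, acmg=5, schwartz=4.5,
        qtc=470.0,
        conductance_scale=0.42, d_v_half_inact_mV=-9.0, tau_inact_scale=0.7,
        d_k_act_mV=-1.5,
    ),
    "D591H": _rec(
        "D591H", "pore", "c.1771G>C", quench=35.0, structural=2, acmg=3,
        qtc=421.0,
        d_v_half_inact_mV=16.5, d_k_inact_mV=4.3,
        tau_inact_scale=1.8, tau_rec_scale=1.2, tau_deact_scale=0.75,
    ),
    "R835P": _rec(
        "R835P", "CNBHD", "c.2504G>C", quench=12.4, structural=4, acmg=5, schwartz=1,
        qtc=440.0,
        conductance_scale=0.0, dn_poisoning_p=0.5, dn_retention=0.5,
    ),
    "P1026L": _rec(
        "P1026L", "C-tail", "c.3077C>T", quench=6.6, structural=None, acmg=3,
        schwartz=4, qtc=531.0,
        conductance_scale=0.08, dn_poisoning_p=0.05, dn_retention=0.9,
    ),
}

VARIANT_NAMES: tuple[str, ...] = tuple(n for n in REGISTRY if n != "WT")


def get_record(name: str) -> VariantRecord:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; valid names: {', '.join(REGISTRY)}"
        ) from None


def make_variant_params(name: str) -> VariantParams:
    """Packaged calibrated parameter set for ``name`` ('WT' or a variant)."""
    return get_record(name).params
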