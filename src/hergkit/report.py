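"""Severity binning and the per-variant pathogenicity report.

Functional and trafficking changes are expressed as percent change relative
to the WT cohort mean and mapped to 1–5 severity scores in 20%-wide,
left-closed bins (0–20% → 1 ... 80–100% → 5).  Gains of function (negative
loss) are flagged rather than scored on the loss scale; their magnitude is
binned on |change| for reference.  The report row mirrors the three
pathogenicity indexes (structural modelling, repolarisation power,
trafficking) plus pass-through clinical metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SeverityBins", "VariantReportRow", "severity_bin", "build_report"]


@dataclass(frozen=True)
class SeverityBins:
    edges: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)

    def score(self, percent: float) -> int:
        """Left-closed bin index, 1..5; values >= 100 score 5."""
        p = min(max(percent, 0.0), 100.0)
        for i in range(len(self.edges) - 1):
            if self.edges[i] <= p < self.edges[i + 1]:
                return i + 1
        return len(self.edges) - 1  # p == 100


DEFAULT_BINS = SeverityBins()


def severity_bin(
    percent_change: float, direction: str = "loss", bins: SeverityBins = DEFAULT_BINS
) -> tuple[int, bool]:
    """Map a percent change to a 1–5 severity score.

    ``direction="loss"`` bins the loss directly; ``direction="gain"`` (or a
    negative loss) bins |change| and sets the gain flag.
    """
    if not math.isfinite(percent_change):
        raise ValueError("percent change must be finite")
    if direction not in ("loss", "gain"):
        raise ValueError("direction must be 'loss' or 'gain'")
    gain = direction == "gain" or percent_change < 0.0
    return bins.score(abs(percent_change)), gain


@dataclass
class VariantReportRow:
    variant: str
    modelling_score: int | None  # None -> not visible in the structure
    repolarisation_score: int
    repolarisation_score_het: int | None
    trafficking_score: int
    trafficking_score_het: int | None
    gain_of_function: bool
    percent_function_change: float
    percent_trafficking_change: float
    acmg_class: int | None = None
    schwartz_score: float | None = None
    qtc_ms: float | None = None


@dataclass
class VariantAssembly:
    """Input record for one report row: measured quantities plus metadata."""

    variant: str
    repolarisation_power: float | None = None
    repolarisation_power_het: float | None = None
    trafficking_quench_pct: float | None = None
    trafficking_quench_pct_het: float | None = None
    structural_score: int | None = None
    structural_visible: bool = True
    clinical: dict = field(default_factory=dict)


def build_report(assemblies: list[VariantAssembly]) -> pd.DataFrame:
    """Assemble the severity table from per-variant measured results.

    The list must contain a ``WT`` entry providing the reference
    repolarisation power and trafficking quench (cohort means); every other
    entry yields one row.
    """
    if not assemblies:
        raise ValueError("no variants to report")
    by_name = {a.variant: a for a in assemblies}
    wt = by_name.get("WT")
    if wt is None or wt.repolarisation_power in (None, 0) or not wt.trafficking_quench_pct:
        raise ValueError("a WT reference with repolarisation power and quench is required")

    rows = []
    for a in assemblies:
        if a.variant == "WT":
            continue
        if a.repolarisation_power is None and a.trafficking_quench_pct is None and a.structural_score is None:
            raise ValueError(f"{a.variant}: no scores available")

        def pct_loss(value, ref):
            return 100.0 * (1.0 - value / ref)

        f_change = pct_loss(a.repolarisation_power or 0.0, wt.repolarisation_power)
        rp_score, gain = severity_bin(f_change)
        rp_het = None
        if a.repolarisation_power_het is not None:
            rp_het = severity_bin(pct_loss(a.repolarisation_power_het, wt.repolarisation_power))[0]
        t_change = pct_loss(a.trafficking_quench_pct or 0.0, wt.trafficking_quench_pct)
        tr_score, _ = severity_bin(max(t_change, 0.0))
        tr_het = None
        if a.trafficking_quench_pct_het is not None:
            tr_het = severity_bin(
                max(pct_loss(a.trafficking_quench_pct_het, wt.trafficking_quench_pct), 0.0)
            )[0]
        clin = a.clinical or {}
        rows.append(
            VariantReportRow(
                variant=a.variant,
                modelling_score=a.structural_score if a.structural_visible else None,
                repolarisation_score=rp_score,
                repolarisation_score_het=rp_het,
                trafficking_score=tr_score,
                trafficking_score_het=tr_het,
                gain_of_function=gain,
                percent_function_change=f_change,
                percent_trafficking_change=t_change,
                acmg_class=clin.get("acmg_class"),
                schwartz_score=clin.get("schwartz_score"),
                qtc_ms=clin.get("qtc_ms"),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows])
    df["modelling_score"] = [
        "not_visible" if r.modelling_score is None else int(r.modelling_score)
        for r in rows
    ]
    return df
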