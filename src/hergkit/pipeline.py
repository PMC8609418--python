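"""End-to-end run: simulate → analyse → trafficking → report.

:class:`RunConfig` (pydantic, unknown keys rejected) drives a deterministic
pipeline over a list of registry variants.  All randomness flows from
``seed``; artifacts (per-cell phenotypes, trafficking summaries and the
Table-style severity report) land in ``out_dir`` as JSON/CSV plus a log
recording package version, configuration hash and per-stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .analysis import analyse_optimised
from .model import CellConfig, mix_heterozygous, simulate_current, WT_GATING
from .protocols import build_optimised_protocol
from .report import VariantAssembly, build_report
from .trafficking import trafficking_cohort
from .variants import REGISTRY, get_record

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variants: list[str] = Field(default_factory=lambda: ["WT"])
    heterozygous: bool = False
    seed: int = 0
    C_m_pF: float = 15.0
    g_leak_nS: float = 0.0
    noise_sd_pA: float = 0.0
    traffic_n_cells: int = 18
    junction_corrected: bool = True
    out_dir: str = "hergkit-run"


def _severity_inputs(name: str, cfg: RunConfig, protocol, cell, wt_density):
    rec = get_record(name)
    gating = rec.params.to_gating(WT_GATING)
    bundle = simulate_current(gating, protocol, cell, variant=name)
    pheno = analyse_optimised(bundle, protocol, wt_reference_density=wt_density)
    rp_het = None
    quench_het = None
    if cfg.heterozygous and name != "WT" and rec.params.dn_poisoning_p > 0:
        mix = mix_heterozygous(WT_GATING, rec.params)
        b_het = simulate_current(mix, protocol, cell, variant=name, zygosity="heterozygous")
        ph = analyse_optimised(b_het, protocol, wt_reference_density=wt_density)
        rp_het = ph.repolarisation_power_pC_per_pF
        wt_rec = get_record("WT")
        quench_het = wt_rec.traffic_quench_pct * rec.traffic_dn_retention
    _, quench = trafficking_cohort(name, cfg.traffic_n_cells, seed=cfg.seed + rec.position)
    return pheno, rp_het, quench, quench_het


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the pipeline; returns the output directory."""
    t_start = time.monotonic()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    protocol = build_optimised_protocol()
    cell = CellConfig(
        C_m_pF=cfg.C_m_pF,
        g_leak_nS=cfg.g_leak_nS,
        noise_sd_pA=cfg.noise_sd_pA,
        seed=cfg.seed,
    )

    names = list(dict.fromkeys(["WT", *cfg.variants]))
    for n in names:
        get_record(n)  # fail fast on unknown names

    t0 = time.monotonic()
    wt_pheno, _, wt_quench, _ = _severity_inputs("WT", cfg, protocol, cell, None)
    wt_density = wt_pheno.density_pA_per_pF
    timings["wt_reference_s"] = time.monotonic() - t0

    assemblies = [
        VariantAssembly(
            variant="WT",
            repolarisation_power=wt_pheno.repolarisation_power_pC_per_pF,
            trafficking_quench_pct=wt_quench,
        )
    ]
    phenos = {"WT": wt_pheno}
    t0 = time.monotonic()
    for name in names:
        if name == "WT":
            continue
        rec = get_record(name)
        pheno, rp_het, quench, quench_het = _severity_inputs(
            name, cfg, protocol, cell, wt_density
        )
        phenos[name] = pheno
        assemblies.append(
            VariantAssembly(
                variant=name,
                repolarisation_power=pheno.repolarisation_power_pC_per_pF,
                repolarisation_power_het=rp_het,
                trafficking_quench_pct=quench,
                trafficking_quench_pct_het=quench_het,
                structural_score=rec.structural_score,
                structural_visible=rec.structural_score is not None,
                clinical={
                    "acmg_class": rec.acmg_class,
                    "schwartz_score": rec.schwartz_score,
                    "qtc_ms": rec.qtc_ms,
                },
            )
        )
    timings["variants_s"] = time.monotonic() - t0

    report = build_report(assemblies)
    report.to_csv(out / "report.csv", index=False)
    report.to_json(out / "report.json", orient="records", indent=2)

    pheno_json = {
        name: _jsonable(dataclasses.asdict(p)) for name, p in phenos.items()
    }
    (out / "phenotypes.json").write_text(json.dumps(pheno_json, indent=2, sort_keys=True))

    cfg_json = cfg.model_dump_json()
    log = {
        "version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "timings_s": {**timings, "total_s": time.monotonic() - t_start},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return obj if obj == obj and abs(obj) != float("inf") else None
    return obj
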