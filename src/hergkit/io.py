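"""File formats: trace-bundle containers, protocol serialisation, results.

A :class:`~hergkit.model.TraceBundle` travels either as an HDF5 container
(datasets ``time_ms``/``command_mV``/``current_pA`` plus metadata
attributes) or as a flat CSV (one row per sample) with a ``# key: value``
metadata header.  Protocols serialise to a key/value + segment-table text
document and to a two-column sampled command file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import CellConfig, TraceBundle
from .protocols import VoltageProtocol

__all__ = [
    "write_trace_bundle",
    "read_trace_bundle",
    "write_trace_csv",
    "read_trace_csv",
    "write_protocol_text",
    "write_command_series",
    "FormatError",
]


class FormatError(ValueError):
    pass


_CELL_FIELDS = ("C_m_pF", "g_leak_nS", "E_leak_mV", "noise_sd_pA", "seed")


def write_trace_bundle(bundle: TraceBundle, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("time_ms", data=bundle.time_ms, compression="gzip")
        f.create_dataset("command_mV", data=bundle.command_mV, compression="gzip")
        f.create_dataset("current_pA", data=bundle.current_pA, compression="gzip")
        f.attrs["protocol_name"] = bundle.protocol_name
        f.attrs["variant"] = bundle.variant
        f.attrs["zygosity"] = bundle.zygosity
        f.attrs["junction_corrected"] = bundle.junction_corrected
        f.attrs["sweep_bounds"] = json.dumps(
            [[sp, t0, t1] for sp, t0, t1 in bundle.sweep_bounds_ms]
        )
        for k in _CELL_FIELDS:
            f.attrs[f"cell_{k}"] = getattr(bundle.cell, k)


def read_trace_bundle(path) -> TraceBundle:
    with h5py.File(str(path), "r") as f:
        for name in ("time_ms", "command_mV", "current_pA"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
        missing = [k for k in _CELL_FIELDS if f"cell_{k}" not in f.attrs]
        if missing:
            raise FormatError(f"{path}: missing cell metadata {missing}")
        cell = CellConfig(**{k: f.attrs[f"cell_{k}"] for k in _CELL_FIELDS})
        bounds = tuple(
            (str(sp), float(t0), float(t1))
            for sp, t0, t1 in json.loads(f.attrs.get("sweep_bounds", "[]"))
        )
        return TraceBundle(
            time_ms=f["time_ms"][:],
            command_mV=f["command_mV"][:],
            current_pA=f["current_pA"][:],
            protocol_name=str(f.attrs["protocol_name"]),
            cell=cell,
            variant=str(f.attrs.get("variant", "WT")),
            zygosity=str(f.attrs.get("zygosity", "homozygous")),
            junction_corrected=bool(f.attrs.get("junction_corrected", False)),
            sweep_bounds_ms=bounds,
        )


def write_trace_csv(bundle: TraceBundle, path) -> None:
    meta = {
        "protocol_name": bundle.protocol_name,
        "variant": bundle.variant,
        "zygosity": bundle.zygosity,
        "junction_corrected": bundle.junction_corrected,
        "sweep_bounds": [[sp, t0, t1] for sp, t0, t1 in bundle.sweep_bounds_ms],
        **{f"cell_{k}": getattr(bundle.cell, k) for k in _CELL_FIELDS},
    }
    with open(str(path), "w") as fh:
        fh.write(f"# hergkit-trace {json.dumps(meta)}\n")
        pd.DataFrame(
            {
                "time_ms": bundle.time_ms,
                "command_mV": bundle.command_mV,
                "current_pA": bundle.current_pA,
            }
        ).to_csv(fh, index=False)


def read_trace_csv(path) -> TraceBundle:
    with open(str(path)) as fh:
        header = fh.readline()
        if not header.startswith("# hergkit-trace "):
            raise FormatError(f"{path}: not a hergkit trace CSV")
        meta = json.loads(header[len("# hergkit-trace "):])
        df = pd.read_csv(fh)
    try:
        cell = CellConfig(**{k: meta[f"cell_{k}"] for k in _CELL_FIELDS})
    except KeyError as e:
        raise FormatError(f"{path}: missing cell metadata {e}") from None
    return TraceBundle(
        time_ms=df["time_ms"].to_numpy(),
        command_mV=df["command_mV"].to_numpy(),
        current_pA=df["current_pA"].to_numpy(),
        protocol_name=meta["protocol_name"],
        cell=cell,
        variant=meta.get("variant", "WT"),
        zygosity=meta.get("zygosity", "homozygous"),
        junction_corrected=bool(meta.get("junction_corrected", False)),
        sweep_bounds_ms=tuple(
            (str(sp), float(t0), float(t1)) for sp, t0, t1 in meta.get("sweep_bounds", [])
        ),
    )


def write_protocol_text(protocol: VoltageProtocol, path) -> None:
    """Structured text: key/value header plus a segment table."""
    lines = [
        f"name: {protocol.name}",
        f"sample_interval_ms: {protocol.sample_interval_ms}",
        f"total_duration_ms: {protocol.total_duration_ms}",
        f"n_subprotocols: {len(protocol.subprotocols)}",
        "",
        "subprotocol\tlabel\tkind\tt_start_ms\tduration_ms\tvoltage_mV\twaveform_ref",
    ]
    for row in protocol.segment_table():
        lines.append(
            "\t".join(
                str(row[k]) if row[k] is not None else "-"
                for k in (
                    "subprotocol", "label", "kind", "t_start_ms",
                    "duration_ms", "voltage_mV", "waveform_ref",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_command_series(protocol: VoltageProtocol, path) -> None:
    """Two-column sampled command file (time_ms, voltage_mV)."""
    t, v = protocol.command_series()
    pd.DataFrame({"time_ms": t, "voltage_mV": v}).to_csv(str(path), index=False)
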