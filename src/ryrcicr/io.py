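"""File I/O for the analysis pipeline: binding CSVs, summary TSVs, configs.

Formats:

* binding data — long-format CSV with columns genotype, condition, pCa (or
  ca_M with ``ca_unit="M"``), replicate_id, B;
* saturation series — CSV with columns free_nM, bound;
* buffer systems — JSON {chelators: [{name, total_M, Kd_Ca_M, Kd_Mg_M?,
  pKa?}], total_Ca_M, total_Mg_M, pH, mode?};
* summary tables — TSV with 6 significant digits (full precision lives in
  the per-fit JSON records).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding_fit import BindingCurve, FitResult, SaturationSeries, SensitizationSummary
from .buffer_chem import BufferSystem, ChelatorSpec


class SchemaError(ValueError):
    """An input file violates its declared schema."""


_BINDING_COLUMNS = ["genotype", "condition", "pCa", "replicate_id", "B"]


def read_binding_csv(path: str | Path, ca_unit: str = "pCa") -> list[BindingCurve]:
    """Read long-format binding data into one BindingCurve per genotype x condition.

    With ``ca_unit="M"`` the concentration column is named ca_M (mol/L) and is
    converted to pCa on read.
    """
    if ca_unit not in ("pCa", "M"):
        raise SchemaError(f"ca_unit must be 'pCa' or 'M', got {ca_unit!r}")
    df = pd.read_csv(path)
    ca_col = "pCa" if ca_unit == "pCa" else "ca_M"
    required = {"genotype", "condition", ca_col, "replicate_id", "B"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    for col in (ca_col, "B"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df["B"].isna() | df[ca_col].isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric values at data lines {list(bad + 2)}")
    if ca_unit == "M":
        if (df[ca_col] <= 0).any():
            raise SchemaError(f"{path}: ca_M values must be > 0")
        df = df.assign(pCa=-np.log10(df[ca_col]))
    curves = []
    for (genotype, condition), group in df.groupby(["genotype", "condition"], sort=False):
        data = group.rename(columns={"replicate_id": "replicate"})[
            ["pCa", "replicate", "B"]
        ].reset_index(drop=True)
        curves.append(BindingCurve(str(genotype), str(condition), data))
    return curves


def write_binding_csv(curves: Sequence[BindingCurve], path: str | Path) -> None:
    frames = []
    for curve in curves:
        frame = curve.data.rename(columns={"replicate": "replicate_id"}).copy()
        frame.insert(0, "genotype", curve.genotype)
        frame.insert(1, "condition", curve.condition)
        frames.append(frame[_BINDING_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_saturation_csv(path: str | Path) -> SaturationSeries:
    df = pd.read_csv(path)
    missing = {"free_nM", "bound"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return SaturationSeries(df["free_nM"].to_numpy(), df["bound"].to_numpy())


def read_buffer_json(path: str | Path) -> BufferSystem:
    with open(path) as fh:
        cfg = json.load(fh)
    chelators = [
        ChelatorSpec(
            name=c["name"],
            total=c["total_M"],
            Kd_Ca=c["Kd_Ca_M"],
            Kd_Mg=c.get("Kd_Mg_M"),
            proton_pKas=c.get("pKa", []),
        )
        for c in cfg.get("chelators", [])
    ]
    return BufferSystem(
        chelators=chelators,
        total_Ca=cfg.get("total_Ca_M", 0.0),
        total_Mg=cfg.get("total_Mg_M", 0.0),
        pH=cfg.get("pH", 7.0),
        mode=cfg.get("mode", "apparent-constants"),
    )


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.6g}"


def fit_to_record(fit: FitResult) -> dict:
    """Full-precision JSON-serializable record of one fit."""
    record = {
        "genotype": fit.genotype,
        "condition": fit.condition,
        "status": fit.status,
        "converged": fit.converged,
        "n_points": fit.n_points,
        "pCa50": fit.pCa50,
        "r_squared": fit.r_squared,
        "stderr": fit.stderr,
    }
    if fit.params is not None:
        record["params"] = json.loads(fit.params.to_json())
    return record


def write_fits_json(fits: Sequence[FitResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([fit_to_record(f) for f in fits], fh, indent=1)
        fh.write("\n")


def write_summary_tsv(
    rows: Sequence[SensitizationSummary],
    path: str | Path,
    fits: Sequence[FitResult] = (),
) -> None:
    """Per-genotype TSV summary (6 significant digits)."""
    detail = {(f.genotype, f.condition): f for f in fits}
    with open(path, "w") as fh:
        fh.write(
            "genotype\tpCa50_control\tpCa50_caffeine\tdelta_pCa50\t"
            "resting_fold_vs_wt\tSE_control\tR2_control\tstatus\n"
        )
        for row in rows:
            ctrl = detail.get((row.genotype, "control"))
            fh.write(
                "\t".join(
                    [
                        row.genotype,
                        _fmt(row.pCa50_control),
                        _fmt(row.pCa50_caffeine),
                        _fmt(row.delta_pCa50),
                        _fmt(row.resting_fold_vs_wt),
                        _fmt(ctrl.stderr.get("pKA") if ctrl else None),
                        _fmt(ctrl.r_squared if ctrl else None),
                        row.status,
                    ]
                )
                + "\n"
            )


def write_trace_csv(traces, path: str | Path) -> None:
    frames = []
    for i, trace in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {"time_s": trace.time, "F": trace.F,
                 "channel": trace.channel, "cell_id": i}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
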