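"""File formats: Ct tables, calibration tables, score and evaluation reports.

All formats are plain CSV/TSV/JSON with fixed, documented headers.  Serialized
precision follows instrument convention: Ct and CM to 1 decimal, ΔCt and M to
4 decimals, probabilities and AUC to 3 decimals.  Writers emit rows in a
deterministic order so identical inputs produce identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .cm_scoring import CalibrationTable, SampleScore
from .core_model import (
    DEFAULT_CONSTANTS,
    DEFAULT_LAYOUT,
    DEFAULT_PANEL,
    AlgorithmConstants,
    CartridgeLayout,
    ConfigurationError,
    GenePanel,
    SampleRun,
    SchemaError,
    StructuralError,
    CtMeasurement,
    validate_sample_run,
)
from .evaluation import EvaluationReport, TrajectorySummary

CT_TABLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "group_label",
    "matrix",
    "draw_day",
    "cartridge_id",
    "gene",
    "ct",
    "no_signal",
)


def write_ct_table(runs: Sequence[SampleRun], path: Union[str, Path]) -> None:
    """Write runs as a long-format Ct table, one row per (sample, cartridge, gene)."""
    rows = []
    for run in sorted(runs, key=lambda r: r.sample_id):
        for m in sorted(run.measurements, key=lambda m: (m.cartridge_id, m.gene)):
            rows.append(
                {
                    "sample_id": run.sample_id,
                    "subject_id": run.subject_id or "",
                    "group_label": run.group_label,
                    "matrix": run.matrix,
                    "draw_day": "" if run.draw_day is None else run.draw_day,
                    "cartridge_id": m.cartridge_id,
                    "gene": m.gene,
                    "ct": "" if m.no_signal else f"{m.ct:.1f}",
                    "no_signal": "true" if m.no_signal else "false",
                }
            )
    pd.DataFrame(rows, columns=list(CT_TABLE_COLUMNS)).to_csv(path, index=False)


def _parse_bool(value: str, line: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise SchemaError(f"line {line}: cannot parse no_signal value {value!r}")


def read_ct_table(
    path: Union[str, Path],
    panel: GenePanel = DEFAULT_PANEL,
    layout: CartridgeLayout = DEFAULT_LAYOUT,
) -> list[SampleRun]:
    """Read and validate a Ct table into SampleRuns.

    The header must match :data:`CT_TABLE_COLUMNS` exactly.  Parse errors name
    the offending file line (header = line 1); structural errors name the
    sample and missing/duplicated (cartridge, gene) cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != CT_TABLE_COLUMNS:
        raise SchemaError(
            f"{path}: header must be exactly {','.join(CT_TABLE_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    by_sample: dict[str, dict] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # 1-based, after header
        sid = row["sample_id"].strip()
        if not sid:
            raise SchemaError(f"line {line}: empty sample_id")
        no_signal = _parse_bool(row["no_signal"], line)
        ct_text = row["ct"].strip()
        if no_signal:
            if ct_text not in ("", "45", "45.0"):
                raise SchemaError(
                    f"line {line}: no-signal row must leave ct empty or 45, got {ct_text!r}"
                )
            measurement = CtMeasurement.no_signal_measurement(
                row["gene"], row["cartridge_id"].strip()
            )
        else:
            try:
                ct = float(ct_text)
            except ValueError:
                raise SchemaError(f"line {line}: cannot parse ct value {ct_text!r}") from None
            if not 0.0 < ct < 45.0:
                raise SchemaError(f"line {line}: ct must lie in (0, 45), got {ct}")
            measurement = CtMeasurement(
                gene=row["gene"], cartridge_id=row["cartridge_id"].strip(), ct=ct
            )
        day_text = row["draw_day"].strip()
        try:
            draw_day = None if day_text == "" else int(day_text)
        except ValueError:
            raise SchemaError(f"line {line}: cannot parse draw_day {day_text!r}") from None
        meta = {
            "subject_id": row["subject_id"].strip() or None,
            "group_label": row["group_label"].strip() or "unknown",
            "matrix": row["matrix"].strip() or "plasma",
            "draw_day": draw_day,
        }
        if sid not in by_sample:
            by_sample[sid] = {"meta": meta, "measurements": []}
            order.append(sid)
        elif by_sample[sid]["meta"] != meta:
            raise StructuralError(
                f"line {line}: sample {sid!r} has inconsistent metadata across rows"
            )
        by_sample[sid]["measurements"].append(measurement)
    runs = []
    for sid in order:
        entry = by_sample[sid]
        run = SampleRun(
            sample_id=sid, measurements=tuple(entry["measurements"]), **entry["meta"]
        )
        runs.append(validate_sample_run(run, layout, panel))
    return runs


CALIBRATION_COLUMNS = ("gene", "median_delta_ct_300", "shift_constant")


def write_calibration(table: CalibrationTable, path: Union[str, Path]) -> None:
    rows = [
        {
            "gene": gene,
            "median_delta_ct_300": f"{table.median_delta_ct_300[gene]:.4f}",
            "shift_constant": table.shift(gene),
        }
        for gene in sorted(table.median_delta_ct_300)
    ]
    pd.DataFrame(rows, columns=list(CALIBRATION_COLUMNS)).to_csv(path, index=False)


def read_calibration(
    path: Union[str, Path], censor_offset: float = 13.0
) -> CalibrationTable:
    df = pd.read_csv(path, dtype={"gene": str})
    if tuple(df.columns) != CALIBRATION_COLUMNS:
        raise SchemaError(
            f"{path}: calibration header must be {','.join(CALIBRATION_COLUMNS)}"
        )
    medians = dict(zip(df["gene"], df["median_delta_ct_300"].astype(float)))
    shifts = dict(zip(df["gene"], df["shift_constant"].astype(int)))
    return CalibrationTable(
        median_delta_ct_300=medians, shift_constant=shifts, censor_offset=censor_offset
    )


def score_report_columns(panel: GenePanel = DEFAULT_PANEL) -> list[str]:
    cols = ["sample_id", "subject_id", "group_label", "matrix", "draw_day"]
    cols += [f"delta_ct_{g}" for g in panel.targets]
    cols += [f"m_{g}" for g in panel.targets]
    cols += ["cm", "valid", "invalid_reason"]
    return cols


def write_score_report(
    scores: Sequence[SampleScore],
    path: Union[str, Path],
    panel: GenePanel = DEFAULT_PANEL,
    json_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write per-sample scores as CSV (rows sorted by sample_id) and optional JSON.

    ΔCt and M are serialized to 4 decimals, CM to 1 decimal; the JSON mirror
    carries the identical rounded values.
    """
    rows = []
    for s in sorted(scores, key=lambda s: s.sample_id):
        row: dict = {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id or "",
            "group_label": s.group_label,
            "matrix": s.matrix,
            "draw_day": "" if s.draw_day is None else s.draw_day,
        }
        for g in panel.targets:
            row[f"delta_ct_{g}"] = (
                f"{s.delta_ct[g]:.4f}" if g in s.delta_ct else ""
            )
        for g in panel.targets:
            row[f"m_{g}"] = f"{s.methylation[g]:.4f}" if g in s.methylation else ""
        row["cm"] = "" if math.isnan(s.cumulative_methylation) else f"{s.cumulative_methylation:.1f}"
        row["valid"] = "true" if s.valid else "false"
        row["invalid_reason"] = s.invalid_reason or ""
        rows.append(row)
    pd.DataFrame(rows, columns=score_report_columns(panel)).to_csv(path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")


def read_score_report(
    path: Union[str, Path], panel: GenePanel = DEFAULT_PANEL
) -> pd.DataFrame:
    """Read a score report CSV back into a typed DataFrame."""
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str}, keep_default_na=False)
    expected = score_report_columns(panel)
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: unexpected score report columns")
    df["cm"] = pd.to_numeric(df["cm"], errors="coerce")
    if df["valid"].dtype != bool:  # pandas may or may not infer bools here
        df["valid"] = df["valid"].astype(str).str.lower() == "true"
    df["draw_day"] = pd.to_numeric(df["draw_day"], errors="coerce")
    return df


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def evaluation_report_dict(report: EvaluationReport) -> dict:
    d = dataclasses.asdict(report)
    d["roc"]["auc"] = round(report.roc.auc, 3)
    return _round_floats(d)


def write_evaluation_report(
    report: EvaluationReport,
    json_path: Union[str, Path],
    tsv_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write an evaluation report as JSON plus a human-readable TSV summary."""
    Path(json_path).write_text(
        json.dumps(evaluation_report_dict(report), indent=2) + "\n"
    )
    if tsv_path is None:
        return
    lines = ["metric\tgroup\tvalue"]
    for group, desc in report.descriptives.items():
        for name in ("n", "minimum", "q25", "median", "q75", "maximum", "mean"):
            value = getattr(desc, name)
            text = str(value) if name == "n" else f"{value:.1f}"
            lines.append(f"{name}\t{group}\t{text}")
        lines.append(
            f"mean_95ci\t{group}\t{desc.mean_ci[0]:.1f} to {desc.mean_ci[1]:.1f}"
        )
    mw, roc, cf = report.mann_whitney, report.roc, report.confusion
    lines.append(f"mann_whitney_u\tall\t{mw.u:.1f}")
    lines.append(f"mann_whitney_p\tall\t{mw.p_value:.4g}")
    lines.append(f"auc\tall\t{roc.auc:.3f}")
    lines.append(f"auc_95ci\tall\t{roc.auc_ci[0]:.3f} to {roc.auc_ci[1]:.3f}")
    lines.append(f"threshold\tall\t{report.threshold:.1f}")
    lines.append(f"threshold_derived\tall\t{str(report.threshold_derived).lower()}")
    for name in ("tp", "fn", "tn", "fp"):
        lines.append(f"{name}\tall\t{getattr(cf, name)}")
    lines.append(f"sensitivity\tall\t{cf.sensitivity:.3f}")
    lines.append(f"specificity\tall\t{cf.specificity:.3f}")
    lines.append(f"accuracy\tall\t{cf.accuracy:.3f}")
    lr = cf.positive_likelihood_ratio
    lines.append(f"positive_lr\tall\t{'undefined' if lr is None else f'{lr:.1f}'}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")


def write_trajectories(
    summaries: Sequence[TrajectorySummary], path: Union[str, Path]
) -> None:
    """Trajectory table: one row per draw with baseline delta and interval direction."""
    rows = []
    for s in sorted(summaries, key=lambda s: s.subject_id):
        for i, (day, cm, delta) in enumerate(zip(s.days, s.cm, s.delta_from_baseline)):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "draw_day": day,
                    "cm": f"{cm:.1f}",
                    "delta_from_baseline": f"{delta:.1f}",
                    "direction": "baseline" if i == 0 else s.directions[i - 1],
                }
            )
    pd.DataFrame(
        rows, columns=["subject_id", "draw_day", "cm", "delta_from_baseline", "direction"]
    ).to_csv(path, index=False)


def default_config() -> dict:
    """The shipped assay configuration (panel, cartridge layout, constants)."""
    return {
        "panel": {
            "targets": list(DEFAULT_PANEL.targets),
            "reference": DEFAULT_PANEL.reference,
        },
        "layout": {cid: list(genes) for cid, genes in DEFAULT_LAYOUT.cartridges.items()},
        "constants": {
            "no_signal_ct": DEFAULT_CONSTANTS.no_signal_ct,
            "censor_offset": DEFAULT_CONSTANTS.censor_offset,
            "m_scale": DEFAULT_CONSTANTS.m_scale,
            "cm_threshold": DEFAULT_CONSTANTS.cm_threshold,
        },
    }


def load_config(
    path: Optional[Union[str, Path]] = None,
) -> tuple[GenePanel, CartridgeLayout, AlgorithmConstants]:
    """Load a YAML/JSON assay configuration; None returns the shipped default."""
    if path is None:
        doc = default_config()
    else:
        text = Path(path).read_text()
        doc = yaml.safe_load(text)  # YAML superset also parses JSON
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")
    panel_doc = doc.get("panel", {})
    panel = GenePanel(
        targets=tuple(panel_doc.get("targets", DEFAULT_PANEL.targets)),
        reference=panel_doc.get("reference", DEFAULT_PANEL.reference),
    )
    layout_doc = doc.get("layout")
    layout = (
        CartridgeLayout({cid: tuple(genes) for cid, genes in layout_doc.items()})
        if layout_doc
        else DEFAULT_LAYOUT
    )
    layout.validate_against(panel)
    constants = AlgorithmConstants(**doc.get("constants", {}))
    return panel, layout, constants


def write_manifest(
    output_dir: Union[str, Path],
    stage: str,
    seed: Optional[int] = None,
    config_path: Optional[str] = None,
    inputs: Sequence[str] = (),
    outputs: Sequence[str] = (),
) -> Path:
    """Record how a stage was run so its outputs can be reproduced."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "ctmeth",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "config": config_path,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = output_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
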