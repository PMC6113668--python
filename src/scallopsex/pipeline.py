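"""End-to-end orchestration: plate table -> QC -> quantification -> score ->
time course, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PipelineError, ValidationError
from .qpcr_io import aggregate_replicates, check_controls, fit_standard_curve, read_ct_table
from .relquant import relative_expression_table
from .dimorphism import screen_panel
from .sexscore import Thresholds, call_samples
from .timecourse import detect_switch, pool_phases, summarize_by_month

logger = logging.getLogger(__name__)

#: Per-module defaults; a user config JSON overrides keys section by section.
DEFAULT_CONFIG: dict = {
    "io": {"sep": ",", "max_sd": 0.5, "min_ntc_ct": 35.0, "dilution_factor": 2.0},
    # "none" = reference-only normalisation (2^-dCt): the only calibrator
    # convention under which the score's absolute 0/2 thresholds are portable.
    "relquant": {"reference_gene": "EF1A", "calibrator": "none", "calibrator_arg": None},
    "dimorphism": {"alpha": 0.01, "transform": "log10"},
    "sexscore": {"female_max": 0.0, "undiff_min": 0.0, "undiff_max": 1.0, "male_min": 2.0},
    "timecourse": {"alpha": 0.05},
}

FLOAT_FORMAT = "%.6g"  # fixed output precision keeps regression tests bit-stable


def merge_config(user: dict | None) -> dict:
    config = {section: dict(values) for section, values in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        config.setdefault(section, {}).update(values)
    return config


def _write_table(frame: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, float) and np.isnan(x):
        return None
    raise TypeError(f"not JSON serialisable: {type(x)}")


def write_manifest(outdir: Path, command: str, config: dict, input_paths: list[str], seed=None) -> dict:
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": config,
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "input_paths": [str(p) for p in input_paths],
        "versions": {
            "scallopsex": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamps": {"written": datetime.now(timezone.utc).isoformat()},
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def run_pipeline(
    ct_table: str | Path,
    metadata: str | Path | None,
    outdir: str | Path,
    config: dict | None = None,
) -> dict:
    """Run every applicable stage and write a report bundle under ``outdir``.

    Stages: plate parsing and QC -> replicate aggregation -> standard curves
    (if standard wells are present) -> relative expression -> dimorphism
    screen (if the metadata provides female/male labels) -> sex scoring ->
    per-month time course (if the metadata provides month ages).  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}
    stage = "read"
    try:
        records = read_ct_table(ct_table, sep=cfg["io"]["sep"])
        if not records:
            raise ValidationError(f"{ct_table}: no data rows")
        meta = None
        if metadata is not None:
            meta = pd.read_csv(metadata, dtype={"sample_id": str})
            if "sample_id" not in meta.columns:
                raise ValidationError("metadata must have a sample_id column")
        summary["stages"].append(stage)

        stage = "qc"
        qc = check_controls(records, min_ntc_ct=cfg["io"]["min_ntc_ct"])
        _write_json(qc, outdir / "qc_report.json")
        summary["qc"] = {"n_controls": qc["n_controls"], "n_fail": qc["n_fail"]}
        summary["stages"].append(stage)

        stage = "standard_curves"
        standard_genes = sorted({r.gene for r in records if r.role == "standard"})
        if standard_genes:
            curves = {
                g: fit_standard_curve(records, g, dilution_factor=cfg["io"]["dilution_factor"]).as_dict()
                for g in standard_genes
            }
            _write_json(curves, outdir / "standard_curves.json")
            summary["standard_curves"] = {g: c["efficiency"] for g, c in curves.items()}
            summary["stages"].append(stage)

        stage = "aggregate"
        unknowns = [r for r in records if r.role == "unknown"]
        agg = aggregate_replicates(unknowns, max_sd=cfg["io"]["max_sd"])
        _write_table(agg, outdir / "aggregated_ct.tsv")
        summary["stages"].append(stage)

        stage = "relquant"
        rel = relative_expression_table(
            agg,
            reference_gene=cfg["relquant"]["reference_gene"],
            calibrator=cfg["relquant"]["calibrator"],
            calibrator_arg=cfg["relquant"]["calibrator_arg"],
        )
        _write_table(rel, outdir / "rel_expression.tsv")
        _write_json(
            {"calibrator": cfg["relquant"]["calibrator"], "reference_gene": cfg["relquant"]["reference_gene"]},
            outdir / "rel_expression_meta.json",
        )
        summary["stages"].append(stage)

        stage = "dimorphism"
        if meta is not None and "sex" in meta.columns:
            labels = meta.set_index("sample_id")["sex"].dropna()
            labels = labels[labels.isin(["female", "male"])]
            if (labels == "female").sum() >= 2 and (labels == "male").sum() >= 2:
                screen = screen_panel(
                    rel,
                    labels,
                    alpha=cfg["dimorphism"]["alpha"],
                    transform=cfg["dimorphism"]["transform"],
                )
                _write_table(screen, outdir / "dimorphism.tsv")
                flagged = screen.loc[screen["dimorphic"], "gene"].tolist()
                _write_json({"alpha": cfg["dimorphism"]["alpha"], "flagged": flagged}, outdir / "dimorphism.json")
                summary["dimorphic_genes"] = flagged
                summary["stages"].append(stage)

        stage = "sexscore"
        thresholds = Thresholds(**cfg["sexscore"])
        scores = call_samples(rel, thresholds)
        _write_table(scores, outdir / "scores.tsv")
        summary["calls"] = scores["call"].value_counts().to_dict()
        summary["stages"].append(stage)

        stage = "timecourse"
        if meta is not None and "month_age" in meta.columns and meta["month_age"].notna().any():
            logexpr = rel[rel["gene"].isin(["FOXL2", "DMRT1L"])].pivot(
                index="sample_id", columns="gene", values="rel_expr"
            )
            scored = scores.merge(meta[["sample_id", "month_age"]], on="sample_id", how="inner")
            scored["log_foxl2"] = np.log10(logexpr["FOXL2"].reindex(scored["sample_id"]).to_numpy())
            scored["log_dmrt1l"] = np.log10(logexpr["DMRT1L"].reindex(scored["sample_id"]).to_numpy())
            scored["month_age"] = scored["month_age"].astype(int)
            summaries = summarize_by_month(scored)
            table = pd.DataFrame([s.as_dict() for s in summaries])
            _write_table(table, outdir / "timecourse_summary.tsv")
            fits = pool_phases(summaries, scored)
            _write_json(
                {k: (None if v is None else asdict(v)) for k, v in fits.items()},
                outdir / "phase_regressions.json",
            )
            if len(summaries) >= 2:
                _write_json(detect_switch(summaries, alpha=cfg["timecourse"]["alpha"]), outdir / "switch_report.json")
            summary["differentiation_rate"] = {
                int(s.month_age): s.differentiation_rate for s in summaries
            }
            summary["stages"].append(stage)
        elif meta is not None:
            logger.warning("metadata has no month_age column: time-course stage skipped")

        _write_json(summary, outdir / "summary.json")
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
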