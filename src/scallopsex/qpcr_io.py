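"""Ct-level plate I/O, replicate aggregation, run QC and standard-curve fits.

A plate table is delimited text with a header row and the columns
``sample_id, gene, replicate, ct, role, dilution_step``.  ``ct`` holds the
cycle-threshold value of one well; non-numeric tokens such as the instrument's
``Undetermined`` are read as missing, never as a pseudo-Ct.  ``role`` marks the
well as an ``unknown`` sample, a no-template control (``ntc``), a no-reverse-
transcription control (``no_rt``) or a dilution-series ``standard``; only
standards carry ``dilution_step`` (step *k* of a ``dilution_factor**k``-fold
series).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidCurveError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

ROLES = ("unknown", "ntc", "no_rt", "standard")
REQUIRED_COLUMNS = ("sample_id", "gene", "replicate", "ct", "role", "dilution_step")

#: Ct-field tokens treated as a missing measurement (case-insensitive).
MISSING_CT_TOKENS = frozenset({"", "undetermined", "undet", "na", "nan", "n/a"})


@dataclass(frozen=True)
class CtRecord:
    """One well: a single Ct measurement with its plate role."""

    sample_id: str
    gene: str
    replicate: int
    ct: float | None  # cycles; None = not detected / undetermined
    role: str = "unknown"
    dilution_step: int | None = None  # only for role="standard"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role {self.role!r} (expected one of {ROLES})")
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")
        if self.ct is not None and not (math.isfinite(self.ct) and self.ct > 0):
            raise ValidationError(f"ct must be finite and > 0 when present, got {self.ct}")
        if (self.role == "standard") != (self.dilution_step is not None):
            raise ValidationError(
                "dilution_step must be present exactly when role='standard' "
                f"(sample {self.sample_id!r}, gene {self.gene!r})"
            )
        if self.dilution_step is not None and self.dilution_step < 0:
            raise ValidationError("dilution_step must be >= 0")


@dataclass(frozen=True)
class StandardCurve:
    """Per-gene dilution-series fit; efficiency E = 10**(-1/slope) - 1."""

    gene: str
    slope: float  # cycles per log10 relative input (< 0 for a valid curve)
    intercept: float  # cycles at log10(input) = 0
    r_squared: float
    efficiency: float  # fractional scale: 1.00 = perfect doubling
    n_steps: int
    flag: str | None = None  # "efficiency_out_of_range" when E outside [0, 1.2]

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "efficiency": self.efficiency,
            "n_steps": self.n_steps,
            "flag": self.flag,
        }


def _parse_ct(token: str) -> float | None:
    if token.strip().lower() in MISSING_CT_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        return None


def read_ct_table(path: str | Path, sep: str = ",") -> list[CtRecord]:
    """Parse a delimited Ct table into :class:`CtRecord` rows.

    Non-numeric Ct fields (``Undetermined`` etc.) become records with a
    missing ``ct`` and are counted in a warning.  A missing required column
    raises :class:`SchemaError`; duplicate wells (same sample, gene,
    replicate, role and dilution step) raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"{path.name}: missing required column(s) {missing_cols}")

    records: list[CtRecord] = []
    seen: set[tuple] = set()
    n_undetermined = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        role = str(row.role).strip().lower()
        if role not in ROLES:
            raise ValidationError(f"{path.name} line {idx}: unknown role {row.role!r}")
        try:
            replicate = int(str(row.replicate).strip())
        except ValueError as exc:
            raise ValidationError(f"{path.name} line {idx}: bad replicate {row.replicate!r}") from exc
        step_token = str(row.dilution_step).strip()
        step = int(step_token) if step_token else None
        ct = _parse_ct(str(row.ct))
        if ct is None and str(row.ct).strip() != "":
            n_undetermined += 1
        key = (str(row.sample_id), str(row.gene), replicate, role, step)
        if key in seen:
            raise ValidationError(
                f"{path.name} line {idx}: duplicate well for sample={row.sample_id!r} "
                f"gene={row.gene!r} replicate={replicate}"
            )
        seen.add(key)
        records.append(
            CtRecord(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                replicate=replicate,
                ct=ct,
                role=role,
                dilution_step=step,
            )
        )
    if n_undetermined:
        logger.warning("%s: %d well(s) with undetermined Ct read as missing", path.name, n_undetermined)
    return records


def write_ct_table(records: Iterable[CtRecord], path: str | Path, sep: str = ",") -> None:
    """Write records back to the plate-table format (round-trips bit-exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(REQUIRED_COLUMNS) + "\n")
        for r in records:
            ct = "Undetermined" if r.ct is None else repr(float(r.ct))
            step = "" if r.dilution_step is None else str(r.dilution_step)
            fh.write(sep.join([r.sample_id, r.gene, str(r.replicate), ct, r.role, step]) + "\n")


def records_to_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "gene": [r.gene for r in records],
            "replicate": [r.replicate for r in records],
            "ct": [np.nan if r.ct is None else r.ct for r in records],
            "role": [r.role for r in records],
            "dilution_step": [np.nan if r.dilution_step is None else r.dilution_step for r in records],
        }
    )


def aggregate_replicates(records: Sequence[CtRecord], max_sd: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, gene) over technical replicates of unknown wells.

    Missing Cts are excluded from the mean; groups whose replicates are all
    missing are reported with a missing mean (flag ``all_missing``), never as
    zero.  SD uses ddof=1; groups with SD above ``max_sd`` cycles are flagged
    (``high_sd``) but kept.
    """
    if any(r.role != "unknown" for r in records):
        raise ValidationError("aggregate_replicates expects role='unknown' wells only")
    if not records:
        raise ValidationError("no records to aggregate")
    frame = records_to_frame(records)
    grouped = frame.groupby(["sample_id", "gene"], sort=True)["ct"]
    out = grouped.agg(
        mean_ct="mean",
        sd_ct=lambda s: s.std(ddof=1),
        n_used="count",
        n_total="size",
    ).reset_index()
    flags = []
    for _, row in out.iterrows():
        if row.n_used == 0:
            flags.append("all_missing")
        elif np.isfinite(row.sd_ct) and row.sd_ct > max_sd:
            flags.append("high_sd")
        else:
            flags.append("")
    out["flag"] = flags
    n_all_missing = int((out["flag"] == "all_missing").sum())
    if n_all_missing:
        logger.warning("%d (sample, gene) group(s) with all replicates missing", n_all_missing)
    return out


def check_controls(records: Sequence[CtRecord], min_ntc_ct: float = 35.0) -> dict:
    """Report pass/fail per negative-control well.

    An NTC or no-RT well with a present Ct below ``min_ntc_ct`` indicates
    contamination (or genomic carryover) and is flagged ``fail``; missing Ct
    (no amplification) passes.  Report-only: nothing is dropped.
    """
    controls = [r for r in records if r.role in ("ntc", "no_rt")]
    wells = []
    n_fail = 0
    for r in controls:
        ok = r.ct is None or r.ct >= min_ntc_ct
        n_fail += not ok
        wells.append(
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "replicate": r.replicate,
                "role": r.role,
                "ct": r.ct,
                "status": "pass" if ok else "fail",
            }
        )
    report = {
        "min_ntc_ct": min_ntc_ct,
        "n_controls": len(controls),
        "n_fail": n_fail,
        "wells": wells,
    }
    if not controls:
        report["note"] = "no controls found"
    return report


def fit_standard_curve(
    records: Sequence[CtRecord], gene: str, dilution_factor: float = 2.0
) -> StandardCurve:
    """OLS fit of mean Ct against log10 relative input of a dilution series.

    Relative input at step *k* of the series is ``dilution_factor**(-k)``.
    Efficiency is derived from the slope as ``E = 10**(-1/slope) - 1``: a
    slope of -1/log10(2) (Ct up one cycle per twofold dilution) gives E = 1,
    perfect doubling.
    """
    if dilution_factor <= 1:
        raise ValidationError(f"dilution_factor must be > 1, got {dilution_factor}")
    rows = [r for r in records if r.role == "standard" and r.gene == gene]
    by_step: dict[int, list[float]] = {}
    for r in rows:
        if r.ct is not None:
            by_step.setdefault(r.dilution_step, []).append(r.ct)
    if len(by_step) < 3:
        raise InsufficientDataError(
            f"gene {gene!r}: need >=3 dilution steps with measurable Ct, got {len(by_step)}"
        )
    steps = np.array(sorted(by_step), dtype=float)
    mean_ct = np.array([np.mean(by_step[int(k)]) for k in steps])
    log_input = -steps * math.log10(dilution_factor)
    fit = stats.linregress(log_input, mean_ct)
    if fit.slope >= 0:
        raise InvalidCurveError(
            f"gene {gene!r}: fitted slope {fit.slope:.4g} >= 0; Ct must decrease with input"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    flag = None
    if not (0.0 <= efficiency <= 1.2):
        flag = "efficiency_out_of_range"
        logger.warning("gene %s: amplification efficiency %.3f outside [0, 1.2]", gene, efficiency)
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
        n_steps=len(steps),
        flag=flag,
    )
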