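"""Relative quantification by the 2^-ddCt method, normalised to *EF1A*.

For each sample, dCt = Ct(target) - Ct(reference); relative expression is
``2**-(dCt - dCt_calibrator)``.  The calibrator may be the per-gene mean dCt
of the batch (keeps values centred near 1), a designated sample (whose
rel_expr is then exactly 1), or ``none`` (calibrator dCt = 0, i.e. pure
reference-gene normalisation).  Downstream ratios between samples are
calibrator-invariant; the ``none`` convention additionally keeps the
DMRT1L/FOXL2 score on the absolute scale its thresholds were defined on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

CALIBRATORS = ("mean_of_group", "designated_sample", "none")


@dataclass(frozen=True)
class RelExpression:
    """Per-sample, per-gene relative expression on the 2^-ddCt scale."""

    sample_id: str
    gene: str
    delta_ct: float  # Ct_gene - Ct_reference, cycles
    rel_expr: float  # 2**-(delta_ct - calibrator_delta_ct)
    calibrator_delta_ct: float


def delta_ct(mean_ct_gene: float, mean_ct_reference: float) -> float:
    """Ct difference target minus reference; missing inputs propagate as NaN."""
    if mean_ct_gene is None or mean_ct_reference is None:
        return math.nan
    return float(mean_ct_gene) - float(mean_ct_reference)


def relative_expression(
    delta_cts: Mapping[str, float] | pd.Series,
    calibrator: str = "mean_of_group",
    calibrator_arg: str | None = None,
    base: float = 2.0,
) -> pd.DataFrame:
    """2^-ddCt for one gene across samples.

    ``delta_cts`` maps sample_id -> dCt (NaN allowed; propagates).  ``base``
    is 2 for the canonical method; pass ``1 + E`` for efficiency-corrected
    quantification.
    """
    series = pd.Series(dict(delta_cts), dtype=float)
    if series.empty or series.notna().sum() == 0:
        raise ValidationError("relative_expression: no non-missing dCt values")
    if calibrator == "mean_of_group":
        cal = float(series.mean())  # nan-skipping mean
    elif calibrator == "designated_sample":
        if calibrator_arg is None or calibrator_arg not in series.index:
            raise ValidationError(f"designated calibrator sample {calibrator_arg!r} not found")
        cal = float(series[calibrator_arg])
        if not math.isfinite(cal):
            raise ValidationError(f"designated calibrator sample {calibrator_arg!r} has missing dCt")
    elif calibrator == "none":
        cal = 0.0
    else:
        raise ValidationError(f"unknown calibrator mode {calibrator!r} (expected one of {CALIBRATORS})")
    rel = np.power(base, -(series - cal))
    return pd.DataFrame(
        {
            "sample_id": series.index,
            "delta_ct": series.values,
            "rel_expr": rel.values,
            "calibrator_delta_ct": cal,
        }
    )


def relative_expression_table(
    aggregated: pd.DataFrame,
    reference_gene: str = "EF1A",
    calibrator: str = "mean_of_group",
    calibrator_arg: str | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Long table of relative expression for every non-reference gene.

    ``aggregated`` is the output of :func:`scallopsex.qpcr_io.aggregate_replicates`
    (columns sample_id, gene, mean_ct).  Samples missing the reference Ct, or
    a gene Ct, propagate as missing rows and are counted in a log message.
    When ``efficiencies`` is given (gene -> E), the base becomes ``1 + E``
    per gene; otherwise the canonical base 2 is used.
    """
    if "mean_ct" not in aggregated.columns:
        raise ValidationError("expected an aggregated table with a mean_ct column")
    wide = aggregated.pivot(index="sample_id", columns="gene", values="mean_ct")
    if reference_gene not in wide.columns:
        raise ValidationError(f"reference gene {reference_gene!r} absent from the table")
    genes = [g for g in wide.columns if g != reference_gene]
    pieces = []
    n_missing = 0
    for gene in genes:
        dct = wide[gene] - wide[reference_gene]
        n_missing += int(dct.isna().sum())
        base = 2.0 if efficiencies is None else 1.0 + float(efficiencies[gene])
        piece = relative_expression(dct, calibrator=calibrator, calibrator_arg=calibrator_arg, base=base)
        piece.insert(1, "gene", gene)
        pieces.append(piece)
    if n_missing:
        logger.warning("%d sample-gene pair(s) with missing dCt propagated as missing", n_missing)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["gene", "sample_id"], ignore_index=True)
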