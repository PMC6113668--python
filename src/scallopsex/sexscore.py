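"""The LOG10(DMRT1L/FOXL2) sex score and its threshold classifier.

The score is the base-10 log of the ratio of relative expressions of the
testis marker *DMRT1L* to the ovary marker *FOXL2*.  In differentiated
gonads it is always below 0 for ovaries and above 2 for testes; juveniles
that have not yet differentiated sit in the closed band [0, 1].  Scores in
the unassigned gap (1, 2) are labelled ``intermediate`` - candidates for
atypical states such as sex reversal in species where it occurs - and never
silently merged into a sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, ValidationError

CALLS = ("female", "male", "undifferentiated", "intermediate", "missing")


@dataclass(frozen=True)
class Thresholds:
    """Score bands: female strict < female_max; undifferentiated closed
    [undiff_min, undiff_max]; male strict > male_min; gaps -> intermediate."""

    female_max: float = 0.0
    undiff_min: float = 0.0
    undiff_max: float = 1.0
    male_min: float = 2.0

    def __post_init__(self):
        if not (self.female_max <= self.undiff_min <= self.undiff_max <= self.male_min):
            raise ConfigError(
                "thresholds must satisfy female_max <= undiff_min <= undiff_max <= male_min, "
                f"got {self}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.female_max, self.undiff_min, self.undiff_max, self.male_min)


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    score: float  # NaN when either marker is missing/nonpositive
    call: str
    thresholds_used: Thresholds = field(default=DEFAULT_THRESHOLDS)
    reason: str | None = None  # why the score is missing, if it is


def sex_score(rel_dmrt1l: float, rel_foxl2: float) -> float:
    """log10(rel_DMRT1L / rel_FOXL2); NaN if either input is missing or <= 0."""
    if rel_dmrt1l is None or rel_foxl2 is None:
        return math.nan
    d, f = float(rel_dmrt1l), float(rel_foxl2)
    if not (math.isfinite(d) and math.isfinite(f)) or d <= 0 or f <= 0:
        return math.nan
    return math.log10(d) - math.log10(f)


def _missing_reason(rel_dmrt1l, rel_foxl2) -> str | None:
    for name, v in (("DMRT1L", rel_dmrt1l), ("FOXL2", rel_foxl2)):
        if v is None or not math.isfinite(float(v)):
            return f"{name}_missing"
        if float(v) <= 0:
            return f"{name}_nonpositive"
    return None


def classify(score: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Deterministic banding of a score; total over the reals (NaN -> missing)."""
    if score is None or math.isnan(score):
        return "missing"
    if score < thresholds.female_max:
        return "female"
    if thresholds.undiff_min <= score <= thresholds.undiff_max:
        return "undifferentiated"
    if score > thresholds.male_min:
        return "male"
    return "intermediate"


def call_sample(
    sample_id: str,
    rel_dmrt1l: float,
    rel_foxl2: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SexCall:
    score = sex_score(rel_dmrt1l, rel_foxl2)
    return SexCall(
        sample_id=sample_id,
        score=score,
        call=classify(score, thresholds),
        thresholds_used=thresholds,
        reason=_missing_reason(rel_dmrt1l, rel_foxl2) if math.isnan(score) else None,
    )


def call_samples(
    expr: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    dmrt_gene: str = "DMRT1L",
    foxl_gene: str = "FOXL2",
) -> pd.DataFrame:
    """Score and classify every sample of a long relative-expression table.

    ``expr`` has columns sample_id, gene, rel_expr and must contain both
    marker genes.  Returns a table sample_id, score, call, reason.
    """
    wide = expr.pivot(index="sample_id", columns="gene", values="rel_expr")
    for g in (dmrt_gene, foxl_gene):
        if g not in wide.columns:
            raise ValidationError(f"marker gene {g!r} absent from expression table")
    rows = []
    for sample_id in wide.index:
        d = wide.at[sample_id, dmrt_gene]
        f = wide.at[sample_id, foxl_gene]
        d = None if pd.isna(d) else float(d)
        f = None if pd.isna(f) else float(f)
        c = call_sample(str(sample_id), d, f, thresholds)
        rows.append({"sample_id": c.sample_id, "score": c.score, "call": c.call, "reason": c.reason})
    return pd.DataFrame(rows)
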