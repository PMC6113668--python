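"""Sexually-dimorphic-expression screen across a candidate-gene panel.

Each gene is tested between ovary and testis groups with Welch's unequal-
variance t-test, by default on log10(relative expression) since qPCR fold
changes are log-normal-like.  The dimorphic flag uses the raw p-value at
alpha (default 0.01, the study-wide convention for this screen); Benjamini-
Hochberg adjusted p-values are reported alongside for reuse with larger
panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError

SEX_LABELS = ("female", "male")


@dataclass(frozen=True)
class DimorphismResult:
    gene: str
    n_female: int
    n_male: int
    mean_female: float
    mean_male: float
    t_statistic: float
    p_value: float
    adjusted_p: float
    dimorphic: bool
    direction: str  # ovary_biased / testis_biased / none


def welch_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom.

    Degenerate case: both groups with zero variance and equal means returns
    (0, 1) by convention; zero variance with different means returns an
    infinite statistic and p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(f"welch_test needs >=2 values per group, got {len(a)} and {len(b)}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (float(np.inf) if a.mean() > b.mean() else float(-np.inf), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def screen_panel(
    expr: pd.DataFrame,
    sex_labels: Mapping[str, str] | pd.Series,
    alpha: float = 0.01,
    transform: str = "log10",
) -> pd.DataFrame:
    """Welch screen of every gene in a long relative-expression table.

    ``expr`` has columns sample_id, gene, rel_expr; ``sex_labels`` maps
    sample_id -> "female" | "male".  Returns one row per gene with group
    means on the tested scale, Welch t and p, BH-adjusted p, the dimorphic
    flag (raw p < alpha) and its direction from the group means.
    """
    labels = pd.Series(dict(sex_labels))
    bad = sorted(set(labels.unique()) - set(SEX_LABELS))
    if bad:
        raise ValidationError(f"unknown sex label(s) {bad}; expected {SEX_LABELS}")
    if transform not in ("log10", "none"):
        raise ValidationError(f"unknown transform {transform!r}")

    frame = expr.copy()
    frame["sex"] = frame["sample_id"].map(labels)
    frame = frame.dropna(subset=["sex", "rel_expr"])
    if transform == "log10":
        frame = frame[frame["rel_expr"] > 0]
        frame["value"] = np.log10(frame["rel_expr"])
    else:
        frame["value"] = frame["rel_expr"]

    rows = []
    for gene, sub in frame.groupby("gene", sort=True):
        fem = sub.loc[sub.sex == "female", "value"].to_numpy()
        mal = sub.loc[sub.sex == "male", "value"].to_numpy()
        t, p = welch_test(fem, mal)
        rows.append(
            {
                "gene": gene,
                "n_female": len(fem),
                "n_male": len(mal),
                "mean_female": fem.mean(),
                "mean_male": mal.mean(),
                "t_statistic": t,
                "p_value": p,
            }
        )
    if not rows:
        raise ValidationError("no genes to screen")
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["dimorphic"] = out["p_value"] < alpha
    direction = np.where(
        ~out["dimorphic"], "none", np.where(out["mean_female"] > out["mean_male"], "ovary_biased", "testis_biased")
    )
    out["direction"] = direction
    return out


def results_from_frame(frame: pd.DataFrame) -> list[DimorphismResult]:
    """Typed view of a screen_panel frame."""
    return [DimorphismResult(**row) for row in frame.to_dict(orient="records")]
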