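"""Seeded generator of synthetic Ct-level qPCR cohorts.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without the study's (undeposited) raw
plates:

* a 9-gene panel (8 candidates + the *EF1A* reference) in which only
  *FOXL2* (ovary-biased) and *DMRT1L* (testis-biased) are sexually
  dimorphic;
* undifferentiated individuals whose marker pair lies around the line
  log10(DMRT1L) = 1.018 * log10(FOXL2) + 0.370 with strongly positive
  correlation, produced by a shared latent-activity factor;
* differentiated individuals clustered by sex on the antagonistic line
  log10(DMRT1L) = -0.684 * log10(FOXL2) + 1.584, placed so ovary scores
  fall below 0 and testis scores above 2;
* a month ladder of differentiation probabilities rising from 0 to 1;
* Ct emission that inverts the 2^-ddCt model: the reference gene is
  anchored near 20 cycles and each target well's Ct is offset by
  -log2(10^log10expr), plus replicate noise, in triplicate.

All randomness flows from one ``numpy.random.Generator``; the same seed
reproduces output bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .qpcr_io import CtRecord

REFERENCE_GENE = "EF1A"
PANEL_GENES = ("FOXL2", "WNT4", "FST", "beta-catenin", "DMRT1L", "DAX1", "SOXE", "SOXH")

#: Primer amplification efficiencies used for synthetic dilution series.
DEFAULT_EFFICIENCIES = {
    "EF1A": 1.02,
    "FOXL2": 1.00,
    "WNT4": 0.97,
    "FST": 1.04,
    "beta-catenin": 1.03,
    "DMRT1L": 0.98,
    "DAX1": 0.98,
    "SOXE": 1.01,
    "SOXH": 0.99,
}

LOG2_10 = math.log2(10.0)


@dataclass(frozen=True)
class UndiffModel:
    """Latent-activity model for undifferentiated gonads.

    A shared factor a ~ N(latent_mean, latent_sd) drives both markers:
    logF = a + e1, logD = slope*a + intercept + e2, e ~ N(0, noise_sd),
    inducing a positive correlation with closed-form control of both the
    pooled regression slope and r.
    """

    slope: float = 1.018
    intercept: float = 0.370
    latent_mean: float = 1.0
    latent_sd: float = 0.55
    noise_sd: float = 0.065


@dataclass(frozen=True)
class DiffModel:
    """Per-sex clusters on the antagonistic post-differentiation line.

    logF ~ N(sex mean, spread_sd); logD = slope*logF + intercept + e.
    With the shipped defaults the score logD - logF is centred at -0.942
    (ovary) and 2.426 (testis) with SD ~ 0.1, keeping ovaries < 0 and
    testes > 2 essentially surely.
    """

    slope: float = -0.684
    intercept: float = 1.584
    female_logf_mean: float = 1.5
    male_logf_mean: float = -0.5
    spread_sd: float = 0.05
    noise_sd: float = 0.05


@dataclass(frozen=True)
class Emission:
    """Ct-level read-out parameters."""

    ref_ct_mean: float = 20.0  # cycles; arbitrary anchor, cancels in dCt
    ct_noise_sd: float = 0.15  # per-well replicate noise, cycles
    replicates: int = 3


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    #: (month_age, n) pairs; defaults to the study layout of 8 per month, 5-13.
    months: tuple = tuple((m, 8) for m in range(5, 14))
    #: P(differentiated by that month); monotone ladder 0 -> 1.
    diff_prob: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.0, 6: 0.0, 7: 0.25, 8: 0.5, 9: 0.75, 10: 0.75, 11: 1.0, 12: 1.0, 13: 1.0}
    )
    sex_ratio: float = 0.5  # P(female | differentiated)
    undiff: UndiffModel = field(default_factory=UndiffModel)
    diff: DiffModel = field(default_factory=DiffModel)
    #: non-marker panel genes: base log10 expression and sex effect
    #: (log10 units; > 0 = ovary-biased, < 0 = testis-biased).
    panel_base: Mapping[str, float] = field(default_factory=lambda: {g: 0.0 for g in PANEL_GENES})
    panel_effect: Mapping[str, float] = field(default_factory=lambda: {"FOXL2": 3.0, "DMRT1L": -3.0})
    panel_sd: float = 0.3  # within-group SD of panel log10 expression
    emission: Emission = field(default_factory=Emission)

    def __post_init__(self):
        for name, sd in (
            ("latent_sd", self.undiff.latent_sd),
            ("undiff.noise_sd", self.undiff.noise_sd),
            ("spread_sd", self.diff.spread_sd),
            ("diff.noise_sd", self.diff.noise_sd),
            ("panel_sd", self.panel_sd),
            ("ct_noise_sd", self.emission.ct_noise_sd),
        ):
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0, got {sd}")
        for m, p in self.diff_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"diff_prob[{m}] = {p} outside [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError(f"sex_ratio {self.sex_ratio} outside [0, 1]")
        if self.emission.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["months"] = [list(m) for m in self.months]
        d["diff_prob"] = {str(k): v for k, v in dict(self.diff_prob).items()}
        d["panel_base"] = dict(self.panel_base)
        d["panel_effect"] = dict(self.panel_effect)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "months" in d:
            d["months"] = tuple((int(m), int(n)) for m, n in d["months"])
        if "diff_prob" in d:
            d["diff_prob"] = {int(k): float(v) for k, v in d["diff_prob"].items()}
        for key, typ in (("undiff", UndiffModel), ("diff", DiffModel), ("emission", Emission)):
            if key in d and isinstance(d[key], Mapping):
                d[key] = typ(**d[key])
        return cls(**d)


STATES = ("undiff", "female", "male")


def simulate_individual(state: str, config: SimConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one individual's (log10 FOXL2, log10 DMRT1L) marker pair."""
    if state == "undiff":
        m = config.undiff
        a = rng.normal(m.latent_mean, m.latent_sd)
        log_f = a + rng.normal(0.0, m.noise_sd)
        log_d = m.slope * a + m.intercept + rng.normal(0.0, m.noise_sd)
    elif state in ("female", "male"):
        m = config.diff
        mean = m.female_logf_mean if state == "female" else m.male_logf_mean
        log_f = rng.normal(mean, m.spread_sd)
        log_d = m.slope * log_f + m.intercept + rng.normal(0.0, m.noise_sd)
    else:
        raise ConfigError(f"unknown state {state!r}; expected one of {STATES}")
    return float(log_f), float(log_d)


def _emit_wells(
    sample_id: str,
    log_exprs: Mapping[str, float],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[CtRecord]:
    """Triplicate Ct wells for one sample: reference + every panel gene."""
    em = config.emission
    ref_center = rng.normal(em.ref_ct_mean, em.ct_noise_sd)
    records = []
    for gene in (REFERENCE_GENE,) + PANEL_GENES:
        true_ct = ref_center - LOG2_10 * log_exprs.get(gene, 0.0)
        noise = rng.normal(0.0, em.ct_noise_sd, size=em.replicates)
        for rep in range(em.replicates):
            records.append(
                CtRecord(
                    sample_id=sample_id,
                    gene=gene,
                    replicate=rep + 1,
                    ct=float(true_ct + noise[rep]),
                    role="unknown",
                )
            )
    return records


def simulate_cohort(config: SimConfig) -> tuple[list[CtRecord], pd.DataFrame]:
    """Simulate the month ladder: Ct records plus a truth table.

    For each month and individual, the differentiated state is drawn with
    probability ``diff_prob[month]``, the sex with ``sex_ratio``; marker
    expressions come from :func:`simulate_individual` and the six
    non-marker candidates stay at their (sex-independent) base level in
    juveniles.  Returns (records, truth) where truth has columns
    sample_id, month_age, state, log_foxl2, log_dmrt1l.
    """
    rng = np.random.default_rng(config.seed)
    records: list[CtRecord] = []
    truth_rows = []
    for month, n in config.months:
        p_diff = config.diff_prob.get(month, 0.0)
        for i in range(n):
            if rng.random() < p_diff:
                state = "female" if rng.random() < config.sex_ratio else "male"
            else:
                state = "undiff"
            log_f, log_d = simulate_individual(state, config, rng)
            log_exprs = {"FOXL2": log_f, "DMRT1L": log_d}
            for gene in PANEL_GENES:
                if gene in ("FOXL2", "DMRT1L"):
                    continue
                log_exprs[gene] = config.panel_base.get(gene, 0.0) + rng.normal(0.0, config.panel_sd)
            sample_id = f"m{month:02d}_s{i:02d}"
            records.extend(_emit_wells(sample_id, log_exprs, config, rng))
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "month_age": month,
                    "state": state,
                    "log_foxl2": log_f,
                    "log_dmrt1l": log_d,
                }
            )
    return records, pd.DataFrame(truth_rows)


def simulate_panel(
    config: SimConfig, n_per_sex: int = 7, seed: int | None = None
) -> tuple[list[CtRecord], pd.DataFrame]:
    """Simulate a resting-stage adult panel for the dimorphism screen.

    Every gene's log10 expression is its base plus, for the dimorphic
    markers, the sex effect from ``panel_effect`` (positive = added in
    ovaries, negative = magnitude added in testes), plus N(0, panel_sd)
    individual noise.  Returns (records, labels) with labels columns
    sample_id, sex.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[CtRecord] = []
    label_rows = []
    for sex in ("female", "male"):
        for i in range(n_per_sex):
            log_exprs = {}
            for gene in PANEL_GENES:
                effect = config.panel_effect.get(gene, 0.0)
                shift = max(effect, 0.0) if sex == "female" else max(-effect, 0.0)
                log_exprs[gene] = config.panel_base.get(gene, 0.0) + shift + rng.normal(0.0, config.panel_sd)
            sample_id = f"{sex[0]}{i:02d}"
            records.extend(_emit_wells(sample_id, log_exprs, config, rng))
            label_rows.append({"sample_id": sample_id, "sex": sex})
    return records, pd.DataFrame(label_rows)


def simulate_dilution_series(
    gene: str,
    efficiency: float,
    n_steps: int = 6,
    base_ct: float = 15.0,
    dilution_factor: float = 2.0,
    ct_noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> list[CtRecord]:
    """Standard wells with Ct(k) = base_ct + k*log(dilution_factor)/log(1+E).

    With zero noise the standard-curve fit inverts this exactly, recovering
    ``efficiency`` to numerical precision.
    """
    if efficiency <= 0:
        raise ConfigError("efficiency must be > 0")
    rng = np.random.default_rng(seed)
    step_cycles = math.log(dilution_factor) / math.log(1.0 + efficiency)
    records = []
    for k in range(n_steps):
        true_ct = base_ct + k * step_cycles
        for rep in range(replicates):
            ct = true_ct + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            records.append(
                CtRecord(
                    sample_id=f"std_{gene}",
                    gene=gene,
                    replicate=rep + 1,
                    ct=float(ct),
                    role="standard",
                    dilution_step=k,
                )
            )
    return records


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic child seed below 2**31 for multi-seed experiments."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))
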