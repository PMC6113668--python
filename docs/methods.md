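# Methods

## Relative quantification

Each gene's expression is quantified by the 2^−ΔΔCt method. Technical
replicates (triplicate wells by default) are aggregated as the arithmetic
mean of Ct with the sample SD (ddof = 1) — the field convention for qPCR,
where Ct is already a log2-scale quantity. Wells reported as
`Undetermined` are treated as missing and excluded from the mean; a
(sample, gene) group whose replicates are all missing propagates as missing
expression downstream, never as zero or as a pseudo-Ct of 40, which would
silently fabricate fold changes. Replicate SDs above 0.5 cycles (configurable)
are flagged but not excluded; there is no principled universal cutoff, so the
gate is advisory.

ΔCt is the target Ct minus the *EF1A* reference Ct per sample. Three
calibrator conventions are supported for the second Δ:

* `mean_of_group` — per-gene mean ΔCt of the batch (keeps values near 1);
* `designated_sample` — a named calibrator sample (its rel_expr is 1);
* `none` — calibrator ΔCt ≡ 0, i.e. pure reference-gene normalisation
  (2^−ΔCt).

Fold-change *ratios* between samples are identical under all three. The
pipeline's scoring path defaults to `none` because the sex score uses fixed
absolute thresholds: under a batch-dependent calibrator the score of every
sample is shifted by the batch-mean score, making the 0/1/2 bands
incomparable across cohorts, while under reference-only normalisation the
reference Ct cancels in the DMRT1L/FOXL2 ratio and the score equals
log10(DMRT1L) − log10(FOXL2) exactly. The calibrator actually used is
recorded in the run manifest. The canonical base is exactly 2; an
efficiency-corrected base (1 + E per gene) is available but off by default,
as the panel's primer efficiencies are all within a few percent of 1.

## Standard curves and amplification efficiency

For a dilution series with factor *d* (default twofold), the relative input
at step *k* is *d*^−k. Ordinary least squares of mean Ct on log10(input)
gives a slope *m* < 0 and the efficiency E = 10^(−1/m) − 1 on the
fractional scale (E = 1.00 means perfect doubling; a primer table entry of
"1.02" reads directly as E = 1.02; the alternative "amplification factor
≈ 2" convention is deliberately not used). Efficiency depends only on the
slope, so the fit is invariant to row order and to uniform Ct shifts.
Curves need ≥ 3 steps with measurable Ct; non-negative slopes are rejected
as invalid rather than reported. Efficiencies outside [0, 1.2] are flagged.

## Dimorphism screen

Each candidate gene is compared between ovary and testis groups with
Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite df). The
test is applied to log10 relative expression by default: qPCR fold changes
are approximately log-normal, and the log scale makes the group-mean
difference the log fold change (`transform="none"` reproduces a raw-scale
test). The dimorphic flag uses the raw p-value at alpha = 0.01 — faithful to
small fixed panels screened without multiplicity correction — while
Benjamini–Hochberg adjusted p-values are reported in the same row for
honest reuse with larger panels. Degenerate inputs follow explicit
conventions: both groups constant and equal → p = 1; constant but different
→ infinite t, p = 0; any group smaller than 2 is an error.

## The sex score and its bands

The score is s = log10(relDMRT1L / relFOXL2). Classification is a total
deterministic step function: female for s < 0 (strict), undifferentiated
for the closed band 0 ≤ s ≤ 1, male for s > 2 (strict), and `intermediate`
for the gap (1, 2] that differentiated gonads do not occupy. Boundary ties
go to the closed undifferentiated band, matching the strict "below 0" /
"above 2" phrasing of the sex bands. Intermediate calls are surfaced, not
merged: in species capable of sex change they are exactly the individuals
worth flagging. A sample missing either marker (or with non-positive
relative expression) gets a missing score with a reason code. Thresholds
are configurable for recalibrated datasets and echoed into every output.

## Time course and the correlation switch

A month's differentiation rate is (n_female + n_male) / n_called;
`intermediate` counts as not-yet-differentiated (conservative — a
dichotomised rate should not be inflated by unclassifiable samples).
Within each month, Pearson's r between log10(FOXL2) and log10(DMRT1L) is
computed with a two-sided t-based p (≥ 3 pairs required; zero variance
yields a missing r rather than an arbitrary sign).

Phase regressions pool per-sample points (not per-month means) across fully
undifferentiated months (rate 0) and fully differentiated months (rate 1);
partially differentiated months belong to neither pool because their
mixture of states would blend two different generating lines. The fit is
OLS of log10(DMRT1L) on log10(FOXL2) — the conventional y = ax + b
reporting — not orthogonal regression.

The switch report is descriptive: the positive regime is the initial run of
months with significantly positive r (alpha = 0.05), and the switch is
bracketed between the last month of that regime and the first month with
r ≤ 0. No change-point test or comparison-of-correlations test is
performed; months with insignificant r of either sign between the brackets
are left visible in the per-month listing.

## Synthetic cohorts

The simulator generates data at the Ct level so that every pipeline stage —
parsing, aggregation, normalisation, scoring — is exercised, not just the
statistics.

**Undifferentiated individuals** follow a latent-activity construction: a
shared factor a ~ N(latent_mean, latent_sd) drives both markers,
logF = a + e₁ and logD = slope·a + intercept + e₂ with
e ~ N(0, noise_sd) and the pre-differentiation line slope = 1.018,
intercept = 0.370. This is one of many models producing a positive
coexpression regime; it is used because slope and correlation have closed
forms (r ≈ slope·σa² / √((σa²+σe²)(slope²σa²+σe²))), so the defaults can be
placed analytically. Shipped values latent_mean = 1.0, latent_sd = 0.55,
noise_sd = 0.065 give a population correlation ≈ 0.986 (within the
0.94–0.995 band the positive regime occupies) and a score distribution of
mean 0.39, SD ≈ 0.10 — comfortably inside the undifferentiated band, with
P(outside [0, 1]) ≈ 5×10⁻⁵ per individual.

**Differentiated individuals** form per-sex clusters on the antagonistic
line: logF ~ N(1.5, spread_sd) for females, N(−0.5, spread_sd) for males,
and logD = −0.684·logF + 1.584 + e. The score is then
(slope − 1)·logF + intercept + e, centred at −0.942 (ovary) and +2.426
(testis). Because |slope − 1| ≈ 1.68 amplifies the logF spread into the
score, the cluster SDs must be small for the bands to be essentially
sure: with spread_sd = noise_sd = 0.05 the score SD is ≈ 0.105 and the
tighter (testis) margin of 0.426 sits 4 SDs from its threshold
(per-individual leak ≈ 2×10⁻⁵). Larger, more realistic per-sex spreads are
incompatible with the always-in-band property given sex means only two
log10 units apart; this compression is a deliberate idealisation.

**Cohorts** draw each individual's differentiated state from a monotone
per-month probability ladder (defaults 0, 0, 0.25, 0.5, 0.75, 0.75, 1, 1, 1
for months 5–13 — a qualitative transcription of the observed 0% → 100%
time course, not figure-read ground truth), sex from sex_ratio = 0.5, and
six non-marker candidate genes from sex-independent base levels. The
**panel generator** for the dimorphism screen instead injects a 3-log10
sex effect into FOXL2 (ovary side) and DMRT1L (testis side) over a
within-group SD of 0.3, with 7 adults per sex.

**Ct emission** inverts the quantification model: a per-sample reference
centre Ct ~ N(20, 0.15) cycles, target wells offset by −log2(10^logexpr),
and N(0, 0.15)-cycle replicate noise per well, in triplicate. The 20-cycle
anchor is arbitrary and immaterial (uniform Ct shifts cancel in ΔCt); with
zero emission noise the pipeline recovers the generating log expressions
exactly. All randomness flows from a single seeded
`numpy.random.Generator`; identical configs and seeds reproduce output
files bit-exactly (fixed iteration order, 6-significant-digit table
formatting).

**What the simulator does not emulate:** amplification-efficiency
differences between genes at the emission step (Ct is strictly base-2),
inter-plate batch effects, partial degradation/inhibition, hermaphrodites
or sex-reversal trajectories, and realistic biological spread within
differentiated sexes (see above). Passing tests therefore demonstrate the
pipeline's correctness and the internal consistency of the model — not that
field samples will be this well separated.

## Problem sizes

Defaults mirror the study design: 8 individuals per month over months 5–13,
7 adults per sex for the screen, triplicate wells. Multi-seed checks use
200 seeds for parameter-recovery medians, 50 seeds for end-to-end state
recovery, and 10,000 replicates for the screen's type-I error, all driven
from spawned child seeds of one base seed.

## Known limitations

* The score's absolute location depends on the calibration convention;
  cross-study comparisons require the reference-only (`none`) calibrator or
  a shared designated calibrator batch.
* Threshold values are fixed inputs, not learned; a calibration helper for
  species with different band locations is future work.
* The switch report orders months and assumes one positive-to-negative
  transition; oscillating regimes are reported but only the first
  transition is bracketed.
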