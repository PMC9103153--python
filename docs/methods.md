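# Methods

## The sponge screen

### Model and assumptions

The ceRNA hypothesis predicts that a lncRNA acting as a miRNA sponge
induces *positive* co-expression between itself and the targets of the
miRNAs it sequesters. The screen operationalizes that prediction as a
location shift in absolute correlation: for candidate miRNA *m* with
measured, evidence-intersected target set T_m and common background B
(the union of all candidates' target sets),

- x = {|r_g| : g ∈ T_m},  y = {|r_g| : g ∈ B},

where r_g is the Pearson correlation of gene g with the lncRNA across
samples. A Welch two-sample t-test compares x and y; Benjamini–Hochberg
adjusts across the tested miRNAs; a miRNA is called significant when
p_adj < α **and** mean(x) > mean(y).

Assumptions worth stating:

- **Log-scale input.** Pearson correlation on expression is only sensible
  on a variance-stabilized (log) scale; the readers require it and do not
  transform.
- **One common background.** A miRNA's own targets are *not* removed from
  B when testing that miRNA. With |T_m| ≪ |B| the overlap makes the test
  mildly conservative (the target mean and the background mean share
  |T_m| of |B| observations, so their difference has slightly smaller
  variance than the Welch standard error assumes). We keep the common
  background because it is the natural formulation of "targets vs. all
  potential targets", and quantify the conservatism empirically: at the
  default simulation geometry (20 miRNAs × 30 targets, background 600)
  the pre-adjustment type-I error sits near 0.047 rather than 0.05.
- **Independence across miRNAs is not assumed to be exact.** Target sets
  may overlap and all tests share one correlation vector; BH is applied
  regardless, as is standard for positively dependent test families.
- **Two-sided test with an explicit direction gate.** Sidedness is not
  folded into the p-value; the directional requirement
  mean(x) > mean(y) is reported as its own column, which keeps the p
  interpretable and makes anti-enriched target sets visible (they get a
  small two-sided p with a negative t and are *not* called significant).

### Test-level significance

The α threshold applies to the BH-adjusted p, not the raw p. The two
gates (p_adj < α, positive direction) are both monotone, so raising α
never removes a significant miRNA.

### Gene-level network membership

Gene nodes are targets of at least one significant miRNA with per-gene
correlation p < α and r > 0. The positivity requirement comes from the
sponge model itself — a de-repressed target must co-express positively
with the sponge. Node order is deterministic (miRNAs by p_adj then id,
genes by r descending then id), so repeated runs write identical tables.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_sources` | 2 | databases that must support a miRNA→gene pair |
| `alpha` | 0.05 | significance level for p_adj and per-gene p |
| `min_target_set` | 5 | measured targets required for a miRNA to be testable; a location test on fewer observations is too unstable to interpret |
| `min_group_frac` | 0.10 | minimum fraction of the cohort on each side of an admissible survival cutoff; prevents degenerate one-patient groups |
| `collapse_method` | max-variance | duplicate-probe rule: keep the most variable row (ties → first occurrence); `mean` and `first` are available |

Missing expression values are handled pairwise-complete: a gene is
correlated over the samples where both it and the lncRNA are non-missing,
and excluded (with a log line) below 3 complete pairs or at zero variance.

## Survival stratification

`km_estimate` is the product-limit estimator (censored subjects leave the
risk set without creating a step; subjects censored exactly at an event
time remain at risk at that time). `logrank_test` accumulates observed
minus expected events and the hypergeometric variance over distinct event
times, referring (O−E)²/V to χ²(1). `optimal_cutoff` evaluates the
log-rank p at every midpoint between consecutive distinct marker values
whose split respects `min_group_frac`, and returns the argmin; ties are
broken toward the cutoff nearest the median marker value, then toward the
smaller value. The reported minimum p is **unadjusted** for the scan:
under a null marker its distribution is stochastically smaller than
uniform, and the package documents rather than corrects this (the scan is
a hypothesis-generating device; confirmatory use needs an independent
cohort or an explicit correction).

Kaplan–Meier and log-rank are implemented in-package — the scan evaluates
the statistic at every admissible threshold, and a thin closed-form
implementation keeps that loop cheap — and are cross-checked against
lifelines in the test suite, alongside hand-computed product-limit and
O/E/V fixtures.

## qPCR arithmetic

`delta_delta_ct`: replicates are averaged on the CT scale first (the
standard derivation differences mean CTs); ΔCT = CT_target − CT_ref per
sample; ΔΔCT subtracts the control group's mean ΔCT per gene; fold change
is 2^(−ΔΔCT) with amplification efficiency fixed at 2. Any per-sample
additive CT offset (loading/pipetting artifact) cancels in ΔCT, which the
tests assert as an invariance. The control group's *geometric* mean fold
change is 1 by construction. `median_normalize` centers each sample's CT
vector at its median (miRNA-panel normalization). `rip_enrichment` first
normalizes each immunoprecipitate CT to its matched input fraction
(ΔCT = CT_IP − CT_input per sample and gene), then applies ΔΔCT against
the IgG control group; IP measurements without a matched input are a hard
error naming the sample.

`rnascope_score` multiplies the two ordinal sub-scores (quality 0–3:
signal intensity per cell; quantity 0–4: fraction of positive cells) and
bands the total: 0 absent, 1–4 weak, 5–8 moderate, 9–12 strong. The bands
tile 0–12 exactly, so every one of the 20 input pairs lands in exactly
one category.

## The synthetic generators

### Sponge model

Linear-Gaussian by design: per sample, L ~ N(0,1) is the lncRNA; a
sponged miRNA's activity is a = m − θ·L (m ~ N(0,1)), an unsponged one's
is a = m; a target of miRNA j is x = −β·a_j + ε with ε ~ N(0, σ²); null
genes are pure noise. A kinetic titration model would be more literal
biology, but the screen's statistic only sees correlation structure, and
linearity gives a closed form to test against:

    corr(x, L) = βθ / √(β²(1+θ²) + σ²)  →  θ/√(1+θ²)  as σ → 0.

Defaults (50 samples, 20 miRNAs, 5 sponged, 30 targets each, 500 null
genes, θ = 0.5, β = 0.8, σ = 1) put the planted target correlation near
0.30 — a realistic effect size for a cohort of tens of samples — and are
the conditions under which the calibration and recovery properties are
asserted. Prediction tables list every true pair in 2 or 3 of the 3
sources and twice as many decoy pairs in exactly one source, so the
evidence intersection is exercised non-trivially; the binding table lists
every miRNA against the lncRNA.

What the generator does **not** emulate: measurement-level artifacts
(probe saturation, batch effects), correlated null genes, shared targets
between miRNAs, miRNA-family/mature-name ambiguity, and any sequence-level
structure. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the stated model — not that the screen is
robust to array artifacts or annotation noise in a real cohort.

A geometric caveat the tests respect: targets of one miRNA share the
latent draw m_j, so their sample correlations co-fluctuate. The sample
correlation of m_j with L has sd ≈ 1/√(n−1) ≈ 0.14 at n = 50, and an
unlucky draw ~2 sd high erases a single miRNA's planted margin in that
replicate. Recovery is therefore asserted *across* replicates (rank-sum
of planted vs. null p-values; per-miRNA mean target-minus-background gap
over 200 replicates), which is the claim the generator's own geometry
supports.

### Survival and qPCR

`simulate_survival`: expression ~ N(0,1); event time exponential with
hazard λ·hr^[expr>θ] (λ = 0.1); with probability `censor_rate` the subject
is right-censored at a U(0, t_event) time. `simulate_qpcr`: CT =
sample_offset + gene_baseline − log2(abundance) + noise, with random
per-sample offsets so the ΔΔCT invariance is exercised, baselines drawn
once per gene in 18–28 cycles, and planted fold changes applied in the
treated group.

All generators are pure functions of their configuration including the
seed.

## Numerical choices

- Correlation p-values use the exact t-transform of r with n−2 df; |r| is
  clipped into [−1, 1] against floating-point overshoot, and perfect
  linear relations report p = 0.
- Welch's statistic, Satterthwaite df and p come from scipy; BH from
  statsmodels. Both are verified against independently coded brute-force
  oracles (direct formula; min-over-suffix definition) to 1e−10 on ≥1,000
  randomized inputs.
- Zero variance in one Welch sample is computed normally (df collapses to
  the other sample's n−1); zero variance in both with equal means is an
  error; with unequal means the statistic is ±∞ with p = 0.
- Probe collapsing ties (equal variance) keep the first occurrence;
  sample order is never changed by any reader or transformation.
- Monte-Carlo assertions fix their seeds and state their tolerances as
  ±3 standard errors of the relevant estimate.

## Problem sizes used by the test suite

Oracle equivalence uses 1,000 randomized small inputs per statistic; null
calibration 2,000 replicate screens at the default geometry; recovery 200
replicates; the cutoff-scan recovery 100 replicates at n = 200, hr = 4;
the closed-form limit one draw at n = 2,000 samples and σ = 0.01 (a large
n is the appropriate way to examine an asymptotic statement; the
tolerance is 10% of the analytic value, dominated by the shared-draw
fluctuation described above).

## Known limitations

- Identifier matching is exact-string after case normalization; no alias
  or miRNA-family resolution.
- No partial-correlation or conditional ceRNA scores; no modeling of
  measured miRNA abundance.
- The optimal-cutoff p is anti-conservative (by design, documented).
- The enrichment test inherits mild conservatism from the target⊂background
  overlap (quantified above) and ignores target-set overlap between
  miRNAs, testing each independently.
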