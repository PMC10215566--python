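# Methods

`csfmark` models a two-phase cerebrospinal-fluid (CSF) biomarker study for
amyotrophic lateral sclerosis (ALS): an unbiased discovery phase using
11-plex tandem-mass-tag (TMT) quantitative proteomics on 20 ALS / 20
healthy-control (HC) samples, followed by targeted validation with parallel
reaction monitoring (PRM) against stable-isotope-labeled (SIL) spike-in
peptides on 30 ALS / 31 HC samples. Every stage is exercised on synthetic
data with known ground truth, so the statistical machinery is testable
without the original cohort.

## Discovery-phase model

### Synthetic TMT data

Protein log2 abundance of protein *i* in sample *j* of batch *b* is

    x_ij = mu_i + delta_i * 1[j in ALS] + beta_ib + eps_ij,
    eps_ij ~ N(0, sigma^2)

with

- `mu_i` — protein baseline, uniform on log2 [10, 30] (~6 orders of
  magnitude on the natural scale), chosen so that dropout and PRM
  detectability can depend on abundance;
- `delta_i` — the true log2 fold change (ALS/HC), zero except for proteins
  in the configured effect table. The default effect table of the pipeline
  is the packaged 53-protein discovery fixture with its reported fold
  changes (|log2FC| 0.46–4.0);
- `beta_ib ~ N(0, batch_effect_sd)` — additive per-protein, per-batch
  offsets (default SD 0.3 log2 units), removable by master-pool
  normalization by construction;
- `sigma = 0.24` — the within-group SD on the log2 scale used for power
  planning, matching in-house TMT variability of CSF proteins.

Each of the 4 batches holds 10 samples (balanced ALS/HC) plus one
master-pool (MP) channel (131C in the 11-plex layout). The MP carries the
natural-scale mean of all 40 discovery samples' true abundances times the
batch offset, perturbed only by its own measurement noise
(`mp_noise_sd_log2`, default 0.05; the appropriate value is not
well-determined, so it is exposed rather than asserted). In the noiseless
limit the MP channel therefore equals the cohort mean exactly, which is the
property the normalization tests rely on.

Missingness is protein-by-batch: a whole protein row drops out of a batch
with logistic probability in its baseline log2 abundance (midpoint 13,
scale 1.5 by default). This produces the characteristic batch-overlap
(Venn) structure — only a core of proteins is quantified in all four
batches — without modeling peptide-level censoring.

### Normalization chain

`tmt.normalize_to_master_pool → merge_batches → median_normalize →
log2_zscore`, with a transform ledger that enforces exactly this order:

1. **MP ratio** — each sample channel divided by the batch's MP channel;
   cancels `beta_ib`. Proteins with zero/missing MP become missing and are
   logged, never silently dropped.
2. **Merge** — batch columns concatenated; `intersection` mode (default)
   keeps the all-batch core for differential testing, `union` keeps
   everything. Remaining missing cells can be imputed with the observed
   minimum (per protein row by default, global matrix minimum as fallback
   or by option). Imputation is applied after merging and before
   statistics; the ordering is configurable because the original
   processing order is not documented.
3. **Median scaling** — each sample column divided by its own median;
   corrects loading differences. Note this assumes differential proteins
   are a small minority; when ~half the matrix carries effects the column
   median itself shifts and null proteins acquire a compensating bias (we
   keep simulated effect fractions below ~15% for this reason).
4. **log2 + z-score** — log2 transform, then each protein row centered and
   scaled to sample SD 1 (ddof = 1) across samples (row-wise orientation;
   column-wise available). The pre-z-score log2 matrix is retained because
   fold changes must be read off it — z-scoring destroys the scale.

### Differential statistics

- **Test** — equal-variance two-sample Student t-test per protein
  (location/scale invariant, so identical on the log2 or z-scored matrix).
  Fold change is the log2 mean difference ALS − HC (the ratio-of-means
  alternative differs only off the log scale and is not used). Proteins
  with zero pooled variance get p = 1 and a flag.
- **Permutation FDR (SAM-style)** — the same statistic is recomputed under
  random group-label permutations (1000 by default, seedable; exhaustive
  enumeration replaces sampling when all distinct arrangements fit under a
  cap). The FDR at a protein's observed |t| is the aggregated count of
  permuted statistics at least as extreme divided by the observed count at
  least as extreme, clipped to [0, 1]; the q-value is the running minimum
  of this over all thresholds that still include the protein, making q
  non-increasing in |t|. The default aggregation is the **mean** permuted
  count (the expected-false-call formulation): under a complete null the
  expected number of permuted exceedances of the observed maximum is ~1,
  so top-ranked null proteins keep q near 1. The median-count variant is
  selectable but is anticonservative at the extreme ranks (the top protein
  gets q = 0 whenever more than half the permutations have no exceedance,
  which happens with probability ~0.4 under the null) and fails the
  null-calibration property we require. An SAM `s0` statistic offset is
  exposed (default 0; rows are variance-standardized upstream, so `s0`
  mostly re-ranks nothing).
- **Power-based sample sizing** — solves the two-sided two-sample t-test
  power equation on the noncentral t distribution (df = 2n − 2,
  noncentrality (delta/sigma)·sqrt(n/2)) for real-valued n by Brent
  root-finding. At delta = 0.585 (log2 of 1.5), sigma = 0.24, alpha = 1e-4,
  power = 0.8 it returns n = 11.299. The negligible opposite-tail term can
  underflow to NaN in scipy's noncentral t and is treated as zero — the
  same defect makes `statsmodels`' own solver return a wrong root at these
  settings, so tests compare against its power *evaluations*, not its
  solver.
- **Normality screen** — Shapiro–Wilk per protein on within-group-centered
  residuals (default) or per group; reports the fraction with p > 0.05.

### Candidate selection

Two-tier rule: tier 1 = q < 0.05; tier 2 = q < 0.1; the PRM panel is tier 2
intersected with PRM-detectable proteins. In the synthetic pipeline
detectability is abundance-thresholded (baseline log2 ≥ 18 by default,
giving roughly the 60% detectable fraction seen in practice).

## Validation-phase model

### Synthetic PRM data

Each panel peptide is monitored as a ladder of fragment y ions (y3 upward)
for both the endogenous ("light") peptide and its SIL ("heavy") standard.
Chromatographic peaks are Gaussian on a uniform retention-time grid (60 s
window, 1 s spacing, apex 30 s, width 3 s); peak shape carries no
information here, only area does. Ion-level relative efficiencies are
random but identical between light and heavy, so per-ion ratios are
preserved. Replicate noise is multiplicative lognormal, split into an
injection factor common to both isotopes (cancels in the ratio) and a
ratio-level factor, so the replicate CV of the light/heavy ratio equals the
configured `noise_cv` (default 10%). Spikes follow the study rule: SIL
amount = endogenous estimate, floored at 5 pmol/mL. Three technical
replicates share the truth and differ only in noise.

Validation-cohort true concentrations are lognormal per peptide with ALS
samples shifted by the parent protein's log2FC and per-sample biological
variation of SD 1.0 log2 units by default. This between-subject SD is a
different and larger quantity than the technical sigma 0.24: the printed
discovery table's (log2FC, p) pairs at 20v20 jointly imply within-group SDs
of ~0.5–2.6 for the validated proteins, and 1.0 is a central choice.

Response series measure the heavy standard over spike levels 0.01–10,000
fmol; the measured signal is the linear response clipped above by a
saturation ceiling with an additive noise floor. The generator's
ground-truth linear range is defined as what an ideal noise-free
measurement of that expected curve would be assigned under the default
linearity criteria — self-consistent with the estimator it is used to
validate, so the recovery tests measure robustness to noise, not the
criteria themselves.

### Quantification

- **Integration** — trapezoidal area over an rt interval (default: full
  window, which is equivalent to a wide fixed window around the simulated
  apex); exactly additive under interval splits.
- **Ion rule** — default `ladder` sums y3 through the last observed y ion
  in both channels, the usual PRM practice; `third_last` instead takes the
  single third-from-last observed ion, the alternative reading of
  "third-to-last fragment y ions".
- **Ratio and concentration** — light AUC / heavy AUC within each
  replicate, times the spike concentration; a zero heavy area flags a
  quantification failure rather than dividing. Replicates are summarized
  as mean concentration ± CV%, and group testing uses one value per
  biological sample (the replicate mean) to avoid pseudo-replication.
- **Linear range** — on the log10–log10 spike/response plane, the longest
  contiguous run of ≥3 levels with least-squares slope in [0.8, 1.2] and
  R² ≥ 0.98 (all configurable); "no linear range" is a result, not an
  exception.
- **Group test** — unpaired two-tailed t-test on per-sample concentrations
  with significance stars at p < 0.05 / 0.01 / 0.0001.

## Biomarker evaluation

- **ROC AUC** — Mann–Whitney U scaled by n1·n2 (ties ½), auto-oriented so
  the reported AUC ≥ 0.5 with the orientation recorded. Verified against
  exhaustive pair counting and the Gaussian closed form
  AUC = Φ(d/√2).
- **Bootstrap CI** — 500 stratified within-class resamples; bootstrap mean
  AUC with percentile 2.5/97.5 bounds; seeded.
- **PLS-DA** — NIPALS partial least squares against a 0/1 class response,
  2 latent variables by default, features standardized internally and
  constant features dropped with a warning. Component scores are mutually
  orthogonal and match scikit-learn's PLS regression to 1e-6 up to sign
  (scikit-learn is used only as a cross-check, never as the
  implementation). Feature importance is VIP, normalized so
  mean(VIP²) = 1; predictions cut the fitted response at 0.5
  (equivalently nearest class mean).
- **MCCV panel evaluation** — per repeat (default 100, chosen for stable
  percentile intervals; the source procedure says only "repeated several
  times"): a stratified 2/3 training split ranks all features by VIP
  computed on the training data only, a PLS-DA model on the top-k features
  scores the held-out 1/3, and the held-out continuous response yields AUC
  (not re-oriented, so signal-free panels stay at 0.5) and accuracy. Per
  panel size: mean AUC, percentile interval over repeats, mean accuracy;
  importance is the cross-repeat mean VIP. The default panel-size grid
  (3, 5, 10, 15) is configurable since the original grid is not fully
  documented.
- **Discovery–validation concordance** — Pearson correlation of matched
  per-protein log2 fold changes between the discovery table and the
  PRM-derived ratios.

A dedicated generator (`simulate_biomarker_panel`) builds validation
feature matrices whose per-feature discriminability is *implied by printed
discovery statistics*: from each (log2FC, p) pair at 20v20 the t statistic
gives the within-group SD, and features are drawn N(0, sd) / N(log2FC, sd)
plus measurement noise. This puts single-feature AUCs on the scale the
study reports (≈0.77–0.87 for the strongest markers) without tuning any
free noise knob.

## Problem sizes and determinism

Default study conditions are the real design: 3000 proteins, 4×11-plex
discovery (20v20), 61-sample validation with 3 technical replicates. The
test suite and end-to-end examples use reduced sizes (hundreds of proteins,
tens of MCCV repeats, 100–300 permutations) that keep every distributional
check within its binomial tolerance. All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration objects;
identical configuration reproduces byte-identical outputs.

## Known limitations

- Spectrum-level effects (isotope envelopes, co-isolation interference,
  retention-time drift) are not modeled; traces are ideal Gaussians.
- Dropout is protein-by-batch; peptide- and cell-level missingness in real
  TMT data is richer.
- The q = 0 entries and one p/q non-monotonicity in the packaged discovery
  table are preserved verbatim from the source table; the loader does not
  "repair" them, and the permutation machinery here will not numerically
  reproduce them (they depend on the original raw data and permutation
  draw).
- Real-cohort AUCs cannot be reproduced without the deposited raw data;
  the evaluation stage is validated on simulation truth and closed-form
  oracles instead.
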