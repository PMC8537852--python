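# Methods

This note documents the models, numerical choices and limitations behind
`uroprot`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic data model

The generators exist because the patient-level data this kind of study
produces is typically not public; they emulate the statistical structure
the analysis must cope with, with ground truth returned for every run.

**Discovery matrices.** Log2 intensities are additive:

    log2 x_ij = b_i + e_i·[j is case] + h_j·[j is case] + ε_ij

with per-protein baselines `b_i ~ N(baseline_log2_mean, baseline_log2_sd²)`
(defaults 20, 2 — typical LFQ dynamic range), planted effects `e_i`
uniform on `de_log2fc_range` (default [1.5, 3], sign flipped for the
downregulated set), a case-only proteinuria shift
`h_j ~ N(proteinuria_log2_mean, proteinuria_log2_sd²)` (defaults 1.0,
0.25 log2 units — cases carry roughly double the protein load), and
technical noise `ε ~ N(0, 0.5²)`. Intensities are `2^(log2 x)`, so raw
values are log-normal. Missingness is left-censored MNAR: a value is
dropped with probability `logistic((missing_midpoint_log2 − log2 x)/
missing_slope)` (defaults 16, 1 → ~5% missing overall, concentrated in
low-abundance proteins). Default scale: 1108 proteins, 12 cases vs 12
controls, 53 up / 9 down planted.

**PRM chromatograms.** Each (sample, peptide, transition) trace is a
Gaussian peak of width `peak_sigma` (default 0.05 min) on a fixed
retention-time window (`rt_grid` holds offsets relative to the peptide's
expected RT; the default window is ±0.75 min at 0.01-min steps), plus
half-normal baseline noise (`noise_sd`, default 25 counts against peak
heights of ~10⁴–10⁶) and a per-sample RT jitter (0.02 min). Peak height
factors: abundance × fixed per-peptide response (0.6/0.4 for the two
quantifiers) × fixed transition share (geometric 0.5/0.3/0.2) ×
per-sample loading factor × per-sample drift factor. iRT standards are
spiked after loading is fixed, so they carry drift only; the BTD
reference protein is endogenous and carries loading like every target.
This is the minimal mechanism under which iRT-median normalization
removes drift and subsequent BTD normalization removes loading.

**Longitudinal cohorts.** Per (subject, protein) random intercepts
(`subject_log2_sd`, workflow default 0.4) are shared across timepoints;
planted effects enter per timepoint through an effect schedule; matrices
are complete (no MNAR), reflecting targeted acquisition. The packaged
longitudinal workflow sets the proteinuria shift to zero because its
samples represent collection weeks before clinical onset.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: correlated protein modules, heavy-tailed or
protein-dependent technical variance, interfering/co-eluting peaks and
tailing peak shapes, batch effects, peptide-level missingness in PRM,
and digestion variability. Results on real cohorts depend on those
factors; the tests certify the statistical machinery, not field
performance.

## Discovery statistics

- Fold changes and tests use observed values only (available-case);
  missing values are imputed (half the per-sample observed minimum) only
  for PCA and clustering, which need complete vectors.
- The quantification filter keeps proteins observed in ≥ `min_fraction`
  (default 0.5) of at least one group's samples and ≥ 2 values per
  group (the minimum for a variance).
- z-centering operates on log2 fold changes, not raw ratios: the volcano
  representation is log2 and up/down symmetry requires the log scale.
  sd uses the n−1 denominator; an all-identical fold-change vector is a
  degenerate-input error.
- The moderated test follows the standard empirical-Bayes scheme:
  pooled per-protein variance s² on d = n₁+n₂−2 df; prior (d0, s0²)
  fitted by method of moments on `log s²` using digamma/trigamma
  corrections, with the trigamma inverse solved by Newton iteration
  (tolerance 1e−12); when the empirical spread of log-variances does not
  exceed the sampling contribution, d0 = ∞ and the posterior variance is
  s0² for every protein (p-values then come from the normal
  distribution). d0 = 0 reduces exactly to the classical pooled t-test.
- The test is computed on log2 intensities; z enters only the selection
  rule, and both selection inequalities are strict.
- Selection uses all filtered proteins in one two-group design; matching
  covariates are not modeled.
- Shortlist ranking: peptides with oxidized methionine or missed
  cleavages are ineligible as quantifiers; proteins need ≥ 2 surviving
  peptides; survivors rank by log2FC then summed eligible-peptide
  intensity (both descending, stable mergesort so equal keys keep a
  deterministic order); each candidate carries its two highest-intensity
  eligible peptides. The true ranking used in practice is
  study-specific; this rule is documented and deterministic.
- Clustering is complete-linkage on Euclidean distances over
  protein-centered log2 intensities (scipy's implementation; its
  tie-handling is deterministic for fixed input order). PCA centers
  proteins and uses a full SVD; components are reported with explained
  variance ratios.

## Targeted quantification

- Peak integration: apex = maximum within `window` (default 0.5 min) of
  the expected RT; boundaries walk outward to the first local minimum
  below 1% of apex or the window edge; a linear baseline between the
  boundary intensities is subtracted; area is trapezoidal, floored at 0.
  The 1%-of-apex rule is a documented stand-in for a vendor peak model;
  it is exact for isolated peaks and configurable in code.
- Best transition = largest area / noise, noise = 1.4826 × MAD of the
  off-peak (outside the integration boundaries) signal, floored at
  1e−9; ties break to the lexicographically smallest transition id;
  all-zero trace sets return the first transition flagged zero-area.
- Normalization order is fixed: iRT median first, then the summed BTD
  quantifier-peptide signal computed **after** iRT normalization. BTD
  combination by sum was chosen (vs mean or single peptide) because it
  is the same operation as the protein roll-up; any per-sample scalar
  cancels identically under all three.
- Roll-up: protein = peptide₁ + peptide₂; if one peptide is missing or
  zero-flagged the other is used alone and the entry is logged as a
  partial roll-up; both missing → NaN.
- Ratios are ratios of group means (stable under small denominators);
  Welch tests run on the normalized linear scale by default with a
  log2-scale option (`log_scale=True`), since the scale used for the
  reference tables of this design is not standardized.

## Screening evaluation

- ROC uses the `score ≥ threshold` rule; AUC is the midrank
  (Mann–Whitney) estimator, identical to the tie-aware trapezoidal
  integral of the curve.
- CI/p default to Hanley–McNeil's exponential approximation with a
  normal test of AUC = 0.5 because that is what standard clinical
  statistics packages report for single-marker ROC curves; DeLong's
  structural-components SE is available (`ci_method="delong"`). At
  AUC = 1 the SE degenerates to 0 and the CI clips at 1.
- Detection at fixed FPR f: threshold = the ⌈(1−f)·n₀⌉-th smallest
  control score, positives are *strictly* greater, so the achieved FPR
  (reported alongside) never exceeds f; no interpolation.
- A longitudinal "both-timepoint marker" must be significant (p < 0.05)
  **and** upregulated (ratio > 1) at every timepoint, since the
  screening endpoint is upregulation; `require_upregulated=False`
  restores a pure significance rule. Marker ROC curves are evaluated
  per protein; a joint multi-protein classifier is out of scope.

## Workflows and reproducibility

One global seed is expanded into independent per-stage seeds (integers
below 2³¹ drawn from a generator seeded with the global seed), so stages
can be re-run individually with unchanged results. Manifests record the
configuration, package version and SHA-256 checksums of every output;
they contain no timestamps, so identical (config, seed) runs are
bit-identical. All tables are UTF-8 TSV ("." decimals, empty cell =
missing); ground truth and manifests are JSON.

The packaged validation and longitudinal workflows plant the panel's
reference PE/CTL ratios (see `panels.py`) as true effects, so simulated
cohorts reproduce the panel's effect-size structure; per-sample
biological variability defaults to 0.5 log2 units (validation) and
0.4 log2 units between subjects (longitudinal) — moderate values for
normalized urine protein levels. Problem sizes in the test suite and
acceptance script match the packaged study scale (1108 proteins, 12 vs
12; 21 targets + BTD + 11 iRT; 10 vs 20 at two timepoints), with 20-seed
replication where a property is statistical.

## Known limitations

- The empirical-Bayes prior fit assumes roughly exchangeable variances;
  strongly protein-dependent variance structure would call for trended
  priors, which are not implemented.
- Peak integration assumes one isolated peak per window; co-eluting
  interferences are neither simulated nor handled.
- Welch tests on linear log-normal intensities are slightly conservative
  at small n; the log-scale option trades this for exactness under the
  generative model.
- Hanley–McNeil CIs can exceed [0,1] before clipping and are symmetric;
  for AUCs near 1 with small n, exact or bootstrap intervals would be
  preferable.
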