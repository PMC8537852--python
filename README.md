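# uroprot

Urine proteomics biomarker pipeline for case/control studies of
preeclampsia (PE) and fetal growth restriction: discovery-stage
label-free differential abundance that is robust to proteinuria,
targeted parallel-reaction-monitoring (PRM) quantification with dual
normalization, and ROC-based evaluation of candidate screening markers.
A synthetic-data module generates every input with known ground truth,
so the whole chain is testable without patient data.

## Who it is for

Proteomics analysts running the classic three-stage urine biomarker
design: an untargeted LFQ discovery cohort, a targeted PRM validation
cohort on a shortlist of candidates, and a longitudinal pre-symptomatic
cohort in which the surviving markers are evaluated as screening tests.

## The statistics at the core

**Proteinuria-robust selection (discovery).** PE inflates total urine
protein, so every protein's case/control fold change carries a common
upward shift. Per protein the pipeline computes the log2 fold change
`FC_i = mean(log2 x_case) − mean(log2 x_ctrl)` over observed values,
then centers across proteins:

    z_i = (FC_i − mean(FC)) / sd(FC)

Any global multiplicative shift of the case samples cancels exactly in
`z`. In parallel an empirical-Bayes moderated t-test shrinks each
protein's residual variance s²_i (d degrees of freedom) toward a prior
(d0, s0²) fitted by method of moments on log variances:

    s̃²_i = (d0·s0² + d·s²_i) / (d0 + d),   t_i = FC_i / (s̃_i·√(1/n₁+1/n₂))

with p-values from t(d0+d) and Benjamini–Hochberg q-values. A protein is
called regulated iff |z| > 1.96 **and** q < 0.05 (strict).

**Dual-normalized PRM quantification (validation).** Per sample and
peptide the best precursor/fragment transition (area / MAD-noise) is
integrated (trapezoidal, linear baseline). Areas are divided first by
the per-sample **median of spiked iRT standard peptide areas** (LC–MS/MS
drift; iRT standards are added at fixed concentration so they carry no
loading variation) and then by the **summed biotinidase (BTD) reference
peptide signal** (protein-loading/Bradford variation). Each protein's
two quantifier peptides are summed; groups are compared by Welch's
t-test and the PE/CTL ratio of group means. Multiplying every trace of
one sample by any constant leaves its protein intensities unchanged.

**Screening evaluation (longitudinal).** AUC is the Mann–Whitney
probability that a case outscores a control (ties ½), with Hanley–McNeil
SE, normal 95% CI clipped to [0,1] and a test of AUC = 0.5 (DeLong
optional). The detection rate at a fixed false-positive rate uses the
empirical order-statistic threshold — with 20 controls and a 10% target,
exactly 2 controls may exceed it.

## Worked example

```python
from uroprot import CohortConfig, differential_abundance, generate_discovery_cohort

config = CohortConfig(seed=1)           # 1108 proteins, 12 vs 12, 53 up / 9 down planted
matrix, samples, truth = generate_discovery_cohort(config)
records = differential_abundance(matrix, samples)
```

Running `python examples/01_discovery_differential_abundance.py` prints:

```
proteins tested after filtering: 1100
selected as regulated: 52 up, 8 down
planted effects recovered: 60/62
false selections: 0
```

1100 of 1108 simulated proteins survive the quantification filter; the
dual |z| & q rule recovers 60 of the 62 planted effects with no false
selections, despite the ~1 log2-unit proteinuria shift planted in all
case samples. The other examples cover PRM quantification
(`02_prm_quantification.py`), ROC screening (`03_screening_roc.py`,
e.g. `CP 20-24 wk: AUC 0.77 (95% CI 0.58-0.96, p=0.006)`), and the full
seeded pipeline (`04_full_pipeline.py`).

A thin CLI mirrors the workflows:

```sh
uroprot simulate-discovery --seed 1 --out sim/
uroprot discover --matrix sim/matrix.tsv --samples sim/samples.tsv --out results.tsv
uroprot run-all --seed 1 --out run/
```

## Layout

- `src/uroprot/synthetic.py` — cohort, chromatogram and longitudinal generators with ground truth
- `src/uroprot/discovery.py` — filtering, fold changes, z-centering, moderated test, BH, shortlist, PCA, clustering
- `src/uroprot/targeted.py` — peak integration, transition choice, dual normalization, roll-up, Welch/ratios
- `src/uroprot/screening.py` — ROC, AUC inference, fixed-FPR detection, longitudinal tables
- `src/uroprot/workflows.py`, `io.py`, `cli.py` — seeded end-to-end runs, TSV/JSON formats, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
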