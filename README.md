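# rppaflow

A tested, reusable implementation of a proteomic/transcriptomic NSCLC
analysis chain:

- **synthetic_data** — generators with known ground truth for every input:
  5-point dilution-series slides (undiluted anchor, 1:2–1:16), two-cohort
  log2 expression matrices with planted SCC vs non-SCC fold-changes and 10%
  duplicate samples, median-effect dose–response plates, and longitudinal
  tumor-volume trajectories starting near 200 mm³.
- **supercurve** — joint logistic-curve quantification of dilution series:
  all spots of an antibody slide are pooled into one sigmoid; each sample's
  relative log2 concentration is read off as its horizontal offset
  (block-coordinate descent, mean-0 identifiability constraint).
- **normalization** — per-sample loading adjustment against the whole
  antibody set, per-protein median centering, duplicate averaging.
- **differential** — pooled-variance two-group t-tests with the signed
  fold-change display convention, beta-uniform-mixture (BUM) modelling of
  the p-value distribution, FDR-controlled rejection thresholds, top-hit
  selection, and average-linkage clustering at 1 − Pearson distance with
  Newick export.
- **validation** — cross-cohort concordance classification (same-direction
  significant / same-direction p ≤ 0.20 / no trend / opposite) and
  expression-probe quality scoring.
- **combination** — median-effect dose–response fits, IC50 percentile
  summaries, Wilcoxon rank-sum comparison (exact by enumeration at small
  n), and the two-term Loewe interaction index with the ±0.05 additive
  band.
- **growth** — generalized-least-squares growth curves
  (volume ~ group + day + group:day) with independence, compound-symmetry,
  or AR(1) residual blocks per mouse, AIC structure selection, and Tukey
  HSD contrasts at an evaluation day.
- **cli_io** — plain-TSV readers/writers for every artifact, YAML pipeline
  configuration, and the `rppaflow` command-line interface.

## CLI

Each stage is a subcommand over TSV artifacts; `simulate` produces every
input with known ground truth:

```sh
rppaflow simulate --seed 1 --out-dir sim
rppaflow quantify sim/slides.tsv --out sim/quantified.tsv
rppaflow normalize sim/matrix.tsv --out sim/normalized.tsv
rppaflow diffexp sim/normalized.tsv --out sim/results.tsv
rppaflow concord sim/results.tsv sim/results_validation.tsv --out sim/concordance.tsv
rppaflow combo sim/plates.tsv --out sim/combination.tsv
rppaflow growth sim/growth.tsv --out sim/growth_report.tsv --day 21
rppaflow all --seed 1 --out-dir run     # everything end to end
```

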