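# mesodx

A two-class molecular differential-diagnosis pipeline for mesothelial
expression panels: nCounter-style count normalization with QC exclusion,
Mann-Whitney differential expression, Pearson-correlation hierarchical
clustering, and an Uncorrelated Shrunken Centroid (USC) classifier with
leave-one-out cross-validated hyperparameters.  A synthetic nCounter-like
data generator makes the whole pipeline runnable and testable without any
instrument data.

## What is in the box

| module                | purpose                                                                 |
|-----------------------|-------------------------------------------------------------------------|
| `mesodx.core`         | probe catalog (CodeSet), sample metadata, staged CountMatrix            |
| `mesodx.rcc`          | RCC lane-file reader/writer, TSV count matrices, lane assembly          |
| `mesodx.normalization`| background subtraction, positive-control and housekeeping scaling, QC   |
| `mesodx.diffexp`      | tie/continuity-corrected Mann-Whitney z and p, Spearman age correlation |
| `mesodx.clustering`   | deterministic UPGMA on 1 − Pearson r, two-way trees, 2-cluster cut      |
| `mesodx.usc`          | centroid shrinkage, greedy correlation filter, LOOCV grid search        |
| `mesodx.simulate`     | negative-binomial cohort generator with planted effects and QC failures |
| `mesodx.pipeline` / `mesodx.cli` | end-to-end orchestration and the `mesodx` command          |
| `mesodx.fixtures`     | packaged reference tables (panel, per-gene z/p, classifier parameter sets) |

The packaged panel has 117 endogenous genes, 6 housekeeping genes
(CLTC, GAPDH, GUSB, HPRT1, PGK1, TUBB), 6 positive spike-ins on a
geometric ladder and 8 negative spike-ins.

## CLI

```sh
mesodx simulate --out raw/ --seed 42 --n-a 25 --n-b 15   # RCC lanes + truth
mesodx normalize raw/ --labels raw/labels.tsv --out norm/
mesodx de norm/normalized_counts.tsv --labels raw/labels.tsv --out de.tsv
mesodx cluster norm/normalized_counts.tsv --labels raw/labels.tsv --out clus/
mesodx train norm/normalized_counts.tsv --labels raw/labels.tsv --out model/
mesodx predict norm/normalized_counts.tsv --model model/model.json --out preds.tsv
mesodx run --out run/ --seed 42          # the whole chain in one go
mesodx verify-tables                      # packaged reference-table checks
```

Exit codes: 0 ok, 2 validation error, 3 stage failure.

Key conventions:

* Counts move forward through stages `raw → background_subtracted →
  tech_normalized → bio_normalized`; samples whose positive-control factor
  leaves [0.3, 3] or whose housekeeping factor leaves [0.1, 10] are
  excluded irrevocably.
* The Mann-Whitney z is signed so genes higher in MPM get negative z
  (MH is the first group).
* Classification runs on log2(count + 1); the discriminant score reported
  per sample is the nonnegative margin between the losing and winning
  class scores.
* LOOCV hyperparameter ties prefer sparser models (larger delta, then
  smaller rho).

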