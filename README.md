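# hlpatterns

Time-course gene-expression **pattern analysis** for designs with one
sequencing library per time point — the setting of chronic-exposure
carcinogenesis models such as Barrett's-epithelium cells sampled at
0/20/40/60 weeks of acid-and-bile-salt exposure, where the question is not
"which genes are differentially expressed" but **when** the transcriptome
changes and **what shape** each gene's trajectory has.

## The method

Given an integer read-count matrix over T ordered time points (no
replicates), the pipeline:

1. **Filters** genes with fewer than `min_reads` (default 5) reads in every
   sample.
2. **Normalizes** by median-of-ratios size factors and transforms to
   `v_gj = (1 − s)·log2(c_gj/f_j + pc) + s·mean_j log2(c_gj/f_j + pc)` — a
   transparent regularized-log-style transform with pseudocount `pc` and
   shrinkage `s ∈ [0, 1)` toward the gene mean (default `s = 0`, plain log2).
3. **Selects** genes with `max_j v_gj − min_j v_gj ≥ log2(fold)` (default
   twofold).
4. **Codes** each selected gene's profile as a length-T string over {H, L}:
   `H` where the value is strictly above the gene's own cross-time-point
   mean, `L` otherwise. The all-H/all-L codes are degenerate, leaving
   `2^T − 2` admissible categories (14 for T = 4); genes are tabulated per
   category. In the emulated design the dominant categories are HHLL and
   LLHH — genes that switch level exactly once, at the same boundary.
5. **Locates the change window**: the adjacent time-point pair with the
   largest between-sample distance (euclidean on gene-centered log2 values
   by default), corroborated by the 2-cluster cut of a complete-linkage
   dendrogram over the samples. This flags the interval interpreted as the
   "point of no return" of the time course.
6. Optionally scores result gene lists by **hypergeometric
   over-representation** (`p = P(X ≥ k)`, BH q-values) against user-supplied
   GMT collections, with the min-read-filtered gene list as the default
   universe, and compares phenotype-assay replicate groups with two-sided
   two-sample t-tests.

A seeded negative-binomial simulator (`SimConfig` / `generate_counts`)
plants gene cohorts on chosen H/L codes at a controlled log2 effect size
inside a sub-twofold noise majority, so every stage — and the pipeline end
to end — is verifiable without access to real sequencing data.

## Worked example

```python
from hlpatterns import (SimConfig, generate_counts, evaluate_recovery,
                        TimeCoursePatternModel)

cfg = SimConfig(seed=7, n_noise=3000, planted={"HHLL": 150, "LLHH": 150})
matrix, truth = generate_counts(cfg)
results = TimeCoursePatternModel(matrix).fit()
print(results.summary())
```

```text
Time-course H/L pattern analysis
================================================
samples (time order):  BEC0W, BEC20W, BEC40W, BEC60W
thresholds:            min_reads=5, fold=2
transform:             pseudocount=1, shrinkage=0
size factors:          0.9620, 1.2620, 0.7744, 1.0633
------------------------------------------------
genes total:               3300
  excluded (<5 reads in every sample): 0
  kept:                    3300
  >= 2-fold variation:   1444
------------------------------------------------
top categories:
  LLHH     289
  HHLL     272
  LHHL     131
  LHLH     129
------------------------------------------------
maximal-change window: BEC20W -> BEC40W
consecutive distances: BEC0W->BEC20W: 28.95, BEC20W->BEC40W: 45.46, BEC40W->BEC60W: 29.51
2-cluster cut:         {BEC0W, BEC20W} vs {BEC40W, BEC60W}
changed >= 2-fold in window: 645 (310 up + 335 down)
```

The two planted categories dominate the table, the flagged window is the
boundary the planted codes switch at, and the 2-cluster cut separates the
early from the late samples. Recovery against the planted truth:

```python
report = evaluate_recovery(truth, results.codes, results.survivors)
print(report.per_code.to_string(index=False))
```

```text
code  planted  recovered   recall  precision
HHLL      150        149 0.993333   0.547794
LLHH      150        150 1.000000   0.519031
```

Recall is near-perfect at the default fourfold effect; precision is lower
because NB sampling noise pushes a fraction of background genes over the
twofold filter, where their (weak) profiles still get coded — the same
behaviour the fold filter has on real data.

The same workflow runs from the shell:

```sh
hlpatterns simulate --seed 7 --planted HHLL:150,LLHH:150 --noise 3000 --out sim/
hlpatterns run --counts sim/counts.tsv --samples BEC0W,BEC20W,BEC40W,BEC60W --out out/
hlpatterns evaluate --counts sim/counts.tsv --truth sim/truth.tsv
```

`run` writes the report bundle (accounting, category table + per-code gene
lists, per-interval up/down lists, window report, newick dendrogram,
resolved-config run log) into `out/`.

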