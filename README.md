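# quantdeg

Identification of differentially expressed genes (DEGs) between two
experimental conditions by distance-based outlier detection in
quantile-difference space, calibrated by a sample-permutation null.
Intended for bulk (or pseudobulked single-cell) expression matrices
that have already been normalized/transformed; no pre-processing is
included.

## The method

Let `M1` (n × s1) and `M2` (n × s2) be the expression matrices of the
two conditions.  Each gene *g* is represented by its quantile-difference
vector

&nbsp;&nbsp;&nbsp;&nbsp;v_gp = F̂⁻¹_{X_g}(p) − F̂⁻¹_{Y_g}(p),&nbsp;&nbsp;p ∈ C_p = {0.25, 0.5, 0.75},

where F̂⁻¹ is the empirical quantile function (linear interpolation of
order statistics).  Non-DE genes cluster around the origin of this
space; DEGs are outliers.  The analysis has two steps.

**Step 1 — potential DEGs.**  Each gene's outlier index is

&nbsp;&nbsp;&nbsp;&nbsp;OR(g) = median_{h≠g} d(v_g, v_h) / median over all pairs d(v_g, v_h),

with d a weighted Euclidean distance (default weights 0.25/0.5/0.25,
columns scaled by the original data's per-column sd).  A null
distribution of OR is built from B = 100 permutations of the pooled
sample labels; genes whose OR exceeds the (1 − α) = 95% percentile of
the pooled null values are *potential* DEGs.

**Step 2 — validation and clustering.**  Null cases that also cleared
the threshold are known false positives.  The B replicates are split
into 10 folds; per fold, each potential gene's K = 10 nearest
neighbours (among fellow candidates plus that fold's retained null
cases) yield FP, the number of null neighbours, and dFP, their
inverse-distance density.  The **strong** selection keeps genes with
mean FP = 0; the **relaxed** selection keeps genes with mean FP below
the uniform-mixing reference K·P/(P + n_potential).  Finally the
candidates are clustered on z-scored (OR, FP, dFP) with PAM, the
cluster count chosen by mean silhouette, clusters ordered by
decreasing mean OR.

A built-in simulator generates benchmark studies (default: 1000 genes,
100 DE with shifts Δ ∈ {1.5, 2, 3}, N(0,1) vs N(μ,1) with |μ| = Δ, 30
samples per condition) with ground truth for scoring.

## Worked example

```python
from quantdeg import MethodConfig, detection_table, run_pipeline, simulate_study

study = simulate_study(seed=1, delta_counts={3.0: 35, 2.0: 32, 1.5: 33})
result = run_pipeline(study.pair, MethodConfig(seed=1, workers=1))
```

Running `python examples/simulate_and_detect.py` (about two minutes)
prints:

```
potential DEGs flagged: 112
expected false-positive neighbours: 8.17 (null proportion 81.67%)
relaxed selection: 98 genes, strong: 39
against ground truth: TP=97 FP=1 FN=3
clusters: k=2, sizes=(95, 17)
         mean_OR  sd_OR  mean_FP  sd_FP  mean_dFP  sd_dFP
cluster                                                  
1           5.23   1.47     0.43   0.92      1.74    3.84
2           2.13   0.39     9.36   0.92     92.23   46.22
```

Of 1000 genes, 112 cleared the permutation threshold.  Among all
candidate neighbours ~82% are retained null cases, so under uniform
mixing 8.17 of a gene's 10 nearest neighbours would be false positives;
the relaxed rule keeps the 98 genes below that reference, 97 of which
are truly DE (one false positive, three weak-shift Δ = 1.5 genes
missed).  Cluster 1 holds the clear signal (high OR, near-zero FP);
cluster 2 collects borderline candidates embedded among null cases.

Other examples: `examples/null_calibration.py` (false-positive control
with no true signal), `examples/cluster_structure.py` (clusters vs
true effect size, plus the diagnostic scatter).

A thin CLI mirrors the library:

```sh
quantdeg simulate --genes 1000 --de 100 --out study.tsv
quantdeg run --cond1 cond1.tsv --cond2 cond2.tsv --seed 0 --out results/
quantdeg plot --result results/ --out scores.png
```

Given a seed, results are bitwise identical for any `--workers` count.

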