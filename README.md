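# owclust — outcome-weighted integrative clustering for multimodal feature matrices

Tumour subtyping pipelines routinely cluster high-dimensional feature blocks
(for instance radiomic features extracted from two MRI sequences) and only
afterwards ask whether the clusters differ in survival.  `owclust` turns
that around: it builds the clustering *metric* from the outcome, so that
subtypes with genuine prognostic differences emerge by construction, while
features carrying no survival information are down-weighted out of the
geometry.  It is written for biostatisticians and imaging researchers who
need a tested, scriptable implementation of the whole analysis — subtype
discovery, cluster-number selection, subtype evaluation, feature
enrichment, biomarker prediction and pathway-activity scoring — plus a
synthetic-cohort generator so every stage is testable without patient data.

## The method

For each z-scored feature x_j a univariate Cox model
h(t | x_j) = h0(t)·exp(β_j x_j) yields the weight w_j = |β_j|.  Within each
modality m the weighted distance between samples a, b is

    d_w(a, b) = sqrt( Σ_j w_j (a_j − b_j)² ),

and the M modality matrices are averaged, γ_m = 1/M:

    I_w = Σ_m γ_m D_m.

I_w is embedded by classical MDS and clustered by k-means (k-means++, 100
starts, centroid-displacement tolerance 1e-5).  Because survival defines the
metric, labels come from 3-fold cross-validation — weights estimated on
training folds only, held-out samples assigned to the nearest training
centroid — and the final labels are a majority vote across 50
Hungarian-aligned rounds.  The number of clusters is chosen where the sum of
the (rescaled) cross-validated prediction index and gap statistic peaks.
Downstream modules reproduce the companion analyses: Yates-corrected
chi-square / Kruskal–Wallis subtype comparisons, Kaplan–Meier and log-rank
with a five-year cutoff, multivariable Cox with Schoenfeld diagnostics and
events-per-variable, z-score (±0.6) hypergeometric feature enrichment with a
2/3-within / <1/3-elsewhere representativeness rule, L1-logistic stability
selection (80/20 splits, 10-fold-CV penalty, ≥10 % frequency), a
four-classifier harness with eight metrics and Dunnett comparisons, and
per-sample pathway activity as OLS slope t-values against pathway-gene
weights.  See `docs/methods.md` for assumptions and design choices.

## Worked example

```python
from owclust import SimulationConfig, generate_cohort, SurvClust

cohort = generate_cohort(SimulationConfig(seed=3))   # 200 samples, 2 blocks
model = SurvClust(cohort.feature_blocks, cohort.survival)

ksel = model.select_k(range(2, 9), seed=5)
print("selected k =", ksel.k_selected)

res = model.fit(k=ksel.k_selected, n_rounds=50, n_folds=3, seed=1)
print(res.summary())
```

prints

```
selected k = 2
Outcome-weighted integrative clustering (consensus over 50 rounds, 3-fold CV)
  samples: 200   modalities: 2   k: 2
  within-cluster SS (full-cohort embedding): 1059
  mean consensus agreement: 1.000
  cluster sizes: 1: 95, 2: 105
  log-rank (5-year cutoff): chi2 = 19.173, df = 1, p = 1.19e-05
```

The selected k matches the two planted subtypes; the consensus labels agree
unanimously across rounds (agreement 1.000) and recover the ground-truth
partition, and the log-rank test confirms the subtypes separate survival
(the generator gave subtype 2 a log hazard ratio of 1).  `res.labels` is a
pandas Series of 1-based labels; `res.agreement` holds the per-sample vote
fractions; `res.logrank()` and `res.to_frame()` expose the diagnostics.

The same pipeline runs from the shell on delimited text files:

```bash
owclust simulate --outdir cohort --seed 3
owclust cluster --features cohort/features_modality1.tsv \
                --features cohort/features_modality2.tsv \
                --survival cohort/survival.tsv \
                --k 2 --rounds 50 --seed 1 --out labels.tsv
```

Other subcommands: `select-k`, `evaluate`, `enrich`, `stability-select`,
`predict`, `pathway-score`, and `run` (full pipeline from a YAML config).

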