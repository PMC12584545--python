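# Methods

## The model

`owclust` discovers survival-linked subtypes from multimodal feature matrices
(the motivating use case is radiomic blocks extracted from two MRI sequences
of low-grade glioma patients, but the features are treated as opaque numeric
columns).  The estimator has five coupled stages:

1. **Feature weighting.**  For each z-scored feature column x_j, a univariate
   Cox proportional-hazards model h(t | x_j) = h0(t) exp(beta_j x_j) is fitted
   by partial-likelihood maximisation; the feature weight is w_j = |beta_j|,
   the absolute log hazard ratio.  Features carrying no outcome information
   get weights near zero and contribute little to the metric.  The baseline
   hazard h0 cancels in the partial likelihood and is never estimated.
2. **Weighted distances.**  Within each modality m, pairwise distances are
   d_w(a, b) = sqrt(sum_j w_j (a_j - b_j)^2), i.e. Euclidean distance after
   scaling each column by sqrt(w_j).
3. **Integration.**  The per-modality matrices are averaged with uniform
   mixing weights gamma_m = 1/M into an integrated matrix I_w.  Distances
   (not squared distances) are averaged, following the printed definition of
   the method; weights are used raw, not normalised.
4. **Embedding and clustering.**  I_w is realised in Euclidean space by
   classical multidimensional scaling (double-centre -D^2/2, eigendecompose,
   keep eigenvalues > 1e-8) and clustered by k-means with k-means++
   initialisation, 100 random starts, at most 100 Lloyd iterations, and
   convergence declared when every centroid moves less than 1e-5.  The MDS
   step is this package's realisation of "k-means on a distance matrix": it
   preserves the weighted geometry exactly when I_w is Euclidean-embeddable
   (the average of Euclidean metrics is generically *slightly* non-Euclidean;
   the discarded negative eigenvalue energy is logged) and makes
   nearest-centroid assignment of held-out samples well defined.
5. **Cross-validation and consensus.**  Because survival drives the metric,
   labelling a sample with weights estimated from its own outcome would
   overfit.  Samples are therefore split into K = 3 folds; per fold, weights
   come from the training folds only, the embedding spans all samples,
   centroids are fitted on training rows, and held-out samples are assigned
   to the nearest centroid.  One round labels every sample exactly once
   (as a held-out sample).  Fifty independent rounds are aligned to the first
   round by Hungarian assignment on the label confusion matrix and combined
   by per-sample majority vote (ties toward the smaller label index); the
   per-sample agreement fraction is a confidence diagnostic.

### Design choices in the open corners

* **Fold alignment inside a round.**  The held-out assignments of different
  folds come from independent k-means runs whose cluster indices are
  arbitrary.  Fold f is aligned to fold 1 by Hungarian assignment on the
  full-sample nearest-centroid labelings of the two folds before the
  held-out pieces are stitched together.  Without this the per-round labels
  would be index-scrambled across folds.
* **Order canonicalisation.**  The model internally sorts samples by their
  identifier, so seeded splits and k-means draws depend only on the sample
  *set*; permuting input rows permutes the output labels bitwise-identically.
* **Weight capping.**  Non-convergent or separating univariate fits get
  weight 0; converged |beta| is capped at 10 so no single feature can
  dominate the metric.
* **Degenerate survival times.**  Times must be positive; event = 1 means
  death; the month is the working time unit.

## Choosing the number of clusters

Two criteria are computed over a k grid (default 2–8):

* **CPI** — cross-validated prediction index: over m = 20 random 50/50
  splits, weights/embedding/centroids are estimated on the training half and
  the held-out half contributes its squared distance to the nearest centroid;
  CPI(k) is the average held-out within-cluster sum of squares (smaller is
  better generalisation).
* **Gap statistic** — log within-cluster dispersion of the embedded data
  compared with its expectation under B = 50 uniform draws over the bounding
  box of the embedding coordinates; se_gap = sd · sqrt(1 + 1/B).  Reference
  datasets are clustered with 10 k-means starts (the observed data keeps
  100): the reference term is an average over 50 draws, so per-draw start
  noise is negligible, and this keeps the selection loop affordable.

The selected k maximises the *sum of the two criteria after each is
min–max rescaled to [0, 1] over the grid* (CPI enters negated, being an
error); ties go to the smaller k.  A raw error-scale CPI cannot literally be
summed with the gap, so the rescaling is this package's documented
interpretation; the raw values are always retained for audit.  In practice
the held-out WSS is nearly flat in k on the synthetic cohorts and the gap
term drives the choice.

## Subtype evaluation

Categorical factors are tested with the Pearson chi-square (Yates continuity
correction, max(|O−E|−0.5, 0), applied to 2×2 tables — this choice reproduces
the published 2×2 statistics, e.g. 10.62 for the MGMT-IDH table whose
uncorrected value is 11.75); continuous factors with the tie-corrected
Kruskal–Wallis H (df = groups − 1).  Survival differences use Kaplan–Meier
curves and the log-rank test after administrative censoring at a five-year
cutoff (60 months; events after the cutoff are recoded censored).  The
multivariable Cox model (lifelines, Efron ties) reports B, SE, Wald
(B/SE)^2, HR = exp(B) and CI95 = exp(B ± 1.96 SE), the events-per-variable
ratio, and Schoenfeld residual tests (KM time transform by default; the
global value combines per-covariate chi-squares with df = p and is an
approximation that ignores their correlation).

## Feature screening and enrichment

Differential features are screened per modality by Kruskal–Wallis across
subtype labels with Benjamini–Hochberg adjustment (selected at P_adj < 0.05).
For enrichment, a feature is over-/under-expressed in a sample when its
cohort z-score is ≥ +0.6 / ≤ −0.6 (the boundary is inclusive; the threshold
is configurable).  Each (subtype, feature, direction) cell gets an upper-tail
hypergeometric p with the whole cohort as population; BH runs across
features within each subtype × direction family.  A feature is
*representative* of a subtype when q < 0.05, at least 2/3 of the subtype's
samples are flagged, and fewer than 1/3 are flagged in every other subtype —
a rule that makes representative sets of distinct subtypes disjoint.

## Biomarker prediction harness

The binary target mirrors a combined molecular label (e.g. MGMT-promoter-
methylated & IDH-mutant vs others).  Stability selection repeats stratified
80/20 splits (seeds s … s+n−1, 100 splits by default); per split an
L1-penalised logistic regression is fitted on the training part with the
penalty chosen by 10-fold cross-validated binomial deviance over a 100-point
log-spaced grid from the data-driven lambda_max down to 1e-4·lambda_max
(the grid walk stops early once the CV deviance has not improved for 10
consecutive points — the deviance path is U-shaped, so this preserves the
argmin while skipping the expensive weakly-penalised tail).  Features with
selection frequency ≥ 10 % survive.

The evaluation harness refits logistic regression, random forest (100
trees), an RBF SVM (scored through its decision function via a
rank-preserving logistic link) and 5-NN over repeated stratified 80/20
splits (1000 by default) and reports eight metrics per split — AUC
(mid-rank Mann–Whitney), Se, Sp, ACC, Youden = Se + Sp − 1, F-measure, MCC
and G-means = sqrt(Se·Sp) — thresholding scores at 0.5.  Splits with a
single-class test part are recorded missing and excluded from means.
Per-split AUCs are compared by one-way ANOVA followed by Dunnett many-to-one
tests against the best-mean model.  The model panel is pluggable: any
estimator with fit and predict_proba (or a decision function) can be added,
which is where a kernel-PLS-type model would slot in.  A Kaplan–Meier check
runs the log-rank test on groups defined by true and by predicted labels
side by side.

## Pathway activity

Expression preprocessing averages duplicate genes and samples, removes genes
and then samples with more than 30 % zeros, and applies log2(x + 1)
(idempotent on an already-processed matrix).  Pathway-gene weight tables
retain the 100 most significant genes per pathway.  Per sample, the gene
vector is regressed on the weight columns (OLS with intercept); the slope
t-values are the activity scores, positive meaning activation.  Group
contrasts are Welch t-tests of per-sample scores (non-reference minus
reference subtype) with BH adjustment across pathways.  Differential-gene
pre-selection is out of scope here, so the gene universe defaults to all
retained genes (a user-supplied gene list can restrict it).

## Synthetic cohorts

The generator draws latent subtypes from the mixing proportions, Gaussian
feature blocks in which only the informative subset carries a between-
subtype mean shift (adjacent subtypes differ by `effect_size` SD),
exponential event times with per-sample rate exp(log-HR of the subtype) /
`baseline_scale` (the simplest law satisfying proportional hazards, which
the weighting stage assumes), and independent exponential censoring whose
rate is found by bisection on the exact censoring probability
E[c/(c + lambda_i)].  A binary marker agrees with a subtype-linked label
with probability `marker_assoc` and shifts a sparse marker-linked feature
set, giving stability selection a recoverable target.  An optional
confounder plants an outcome-irrelevant 50/50 partition in chosen features.
All draws descend deterministically from one seed via per-stage derived
generators.

Defaults describe the study conditions the package is exercised under:
n = 200 samples, two modalities of 50 features with 10 informative each
(20 %), effect size 2 SD, subtype log hazard ratio (0, 1), baseline scale 60
months, censoring 65 % (roughly 56 observed deaths per 162 patients),
marker agreement 0.8.  What the generator does *not* emulate: the heavy-
tailed, highly collinear distributions of real radiomic features, scanner
batch effects, non-proportional hazards, informative censoring.  Passing
tests therefore demonstrate correctness of the machinery and its behaviour
under the model's own assumptions, not performance on real imaging cohorts.

For the outcome-weighting demonstration the confounded cohort uses block A =
40 features with 20 informative and block B = 40 features with 30 confounded
(shift 2.5 SD) at 20 % censoring.  Null-feature Cox weights shrink only like
1/sqrt(events), so the weighted metric separates the two structures reliably
when the survival signal is estimated from enough events and enough
informative features; with only 10 informative features and 65 % censoring
the confounder wins regardless of weighting, which is a property of the
cohort, not of the estimator.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the simulations at the
cohort sizes above (n = 200, 50-feature blocks; 10–20 seeds per property;
stability selection at 50 splits; classifier evaluation at 50–200 splits),
which keeps every statistic stable to well within its test tolerance while
staying desk-scale.  Other numerics: k-means Lloyd iterations are batched
across starts (one GEMM per assignment step); MDS keeps eigenvalues above
1e-8; univariate Cox Newton steps are clipped to ±1 with convergence at
1e-9; liblinear tolerance 1e-4 in the selection path.  Zero-variance and
> 95 %-zero feature columns are removed before standardisation, mirroring
how all-zero texture features are dropped from real extraction output.

## Known limitations

* Continuous feature blocks only; categorical/mutation-matrix distances are
  out of scope.
* The global Schoenfeld test is an uncorrelated-sum approximation.
* The gap statistic's uniform-box reference is taken over the embedding
  coordinates, not the raw features.
* CPI is nearly uninformative about k on these cohorts; it is retained for
  audit and summed per the selection rule, but the gap term decides.
* The prediction harness fixes sensible classifier defaults and does no
  hyperparameter search.
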