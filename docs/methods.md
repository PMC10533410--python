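# Methods

`icbspatial` re-implements, as a reusable tested pipeline, the spatial
feature derivation and response-prediction analysis used in longitudinal
multiplexed-imaging studies of neoadjuvant immunotherapy in triple-negative
breast cancer: two randomized arms (chemotherapy `C` vs chemotherapy +
anti-PD-L1 `C&I`), tumours sampled at baseline / early on-treatment /
post-treatment, each sample imaged as one or more regions of interest
(ROIs) of segmented single cells, and a binary clinical endpoint
(pathological complete response, pCR, vs residual disease, RD).

## Preprocessing

* **Spillover correction.** Channel crosstalk is described by a spillover
  matrix S (rows = source channels, unit diagonal, non-negative
  fractions). Observed mean ion counts per cell are modelled as x·S and
  inverted by per-cell non-negative least squares,
  x̂ = argmin_{x≥0} ‖x·S − observed‖². Matrices with condition number
  above 10⁶ are rejected rather than silently inverted.
* **Drug-channel correction.** Platinum (carboplatin) signal bleeding into
  antibody channels is removed by pooling all cells and fitting ordinary
  least squares of log(channel+1) on log(carboplatin+1); residuals are the
  corrected values. A zero-variance drug channel degrades gracefully to
  centred log values with a flag.
* **Size filter.** Cells with area < 31 µm² are excluded (strict
  inequality; 31.0 µm² is retained).
* **Compartment gates.** The cytokeratin gate fits a two-component 1-D
  Gaussian mixture to log(Σ cytokeratins + 1); cells whose posterior
  favours the higher-mean component are cytokeratin-positive (posterior
  tie → positive, k-means initialisation at a fixed seed, EM tolerance
  1e-6, ≤500 iterations, so the call is deterministic). The mask gate
  calls a cell epithelial-mask-positive when at least 30% of its pixels
  overlap the epithelial region (inclusive threshold). When curated
  compartment labels are supplied they are consumed directly; the
  GMM+mask rules are the automated path.
* **Marker positivity.** A cell is positive for a marker when its
  intensity is strictly above the global (whole-cohort) q-quantile,
  computed with the linear-interpolation (type-7) convention. Ties at the
  quantile are negative, so a constant marker yields no positives. Ki67
  positivity for proliferative fractions uses this gate.

All log transforms of ion counts use log(x+1), since mean counts can be 0.

## Tissue features

Per tumour per timepoint, with E epithelial and T TME phenotypes
(default 17 + 20):

* **Densities** (E+T): phenotype count divided by tissue area in mm².
  Tissue area per ROI is the convex hull of cell centroids; multi-ROI
  tumours pool counts and **sum per-ROI hull areas** (ROIs are spatially
  disjoint, so a cross-ROI hull would fabricate tissue). Degenerate hulls
  (<3 cells, collinear) mark the tumour's densities missing.
* **Interaction metrics** (2·(E+T)): cells interact when their whole-cell
  masks touch — 8-connectivity on label masks, or centroid distance ≤
  contact radius (inclusive) for point-pattern data. Four flavours, each
  the count of qualifying unordered contact edges divided by the
  tumour's total cell count (both compartments): epithelial-homotypic
  (focal epithelial phenotype ↔ any epithelial cell),
  epithelial-heterotypic (any epithelial ↔ focal TME phenotype),
  TME-homotypic (focal TME ↔ any TME), TME-heterotypic (any TME ↔ focal
  epithelial phenotype). Each unordered edge counts once; a
  multi-contact cell therefore contributes once per distinct contact,
  which up-weights highly connected cells. Whether contacts should
  instead be counted directionally (each edge twice) is genuinely open;
  the once-per-edge convention is the minimal reading and is what the
  brute-force oracles in the tests pin down. An absent focal phenotype
  gives a metric of 0.
* **Proliferative fractions** (E+T): share of Ki67⁺ cells per phenotype;
  absent phenotype → 0.

This yields 4·(E+T) = 148 features per timepoint with the default
registry, 296 when baseline and on-treatment are combined.

## Association statistics

Predictors are square-root transformed and modelled as continuous;
proliferative fractions are additionally scaled ×10 and interaction
metrics ×100 for interpretable odds ratios (p-values are unaffected
because sqrt(c·x)=√c·√x). Per feature:

* arm-specific OR and 95% Wald CI from univariate logistic regression
  restricted to that arm;
* `p_interaction` — Wald p of the feature×treatment coefficient in
  pCR ~ feature + arm + feature:arm. A Wald (not likelihood-ratio) test
  is used as the standard GLM-summary convention; on saturated 2×2×2
  tables the interaction coefficient equals the difference of
  contingency log-odds-ratios, which the tests verify exactly;
* Benjamini–Hochberg FDR within each feature family × timepoint group
  (the family boundaries mirror how such scans are reported per figure
  panel; exact boundaries are a convention, not a given).

Complete separation (|coef| > 15 on the transformed scale, or failed
MLE) is flagged and excluded from FDR pooling rather than shrunk.

**Differential abundance** uses a binomial GLM with logit link on
per-tumour within-compartment phenotype proportions, weighted by each
tumour's total cell count (`var_weights`), so well-sampled tumours carry
proportionally more information; coefficients are reported as log2 odds
ratios. A continuous predictor (e.g. stromal lymphocyte score) is
supported by the same kernel.

**Contact-linked activation**: per tumour, mean activation-marker
expression (TOX, PD-1, GZMB, OX40, ICOS) of T cells in contact with
epithelium vs not; the two per-tumour mean distributions are compared by
a two-sided Wilcoxon rank-sum test (exact for small tie-free samples,
normal approximation with tie correction otherwise). Tumours lacking a
group are dropped and logged; fewer than 3 usable tumours is an error.

## Treatment dynamics

Phenotypes map to three categories — epithelial (all cancer phenotypes),
stromal (fibroblasts, myofibroblasts, PDPN⁺ stromal, endothelium) and
immune (all remaining TME phenotypes) — giving per-tumour proportions
that sum to 1. Trend summaries compute, per phenotype, mean
within-compartment proportions over timepoint × arm × response groups,
Z-scored across groups with the **sample (n−1) standard deviation**
(a convention; the population-sd alternative differs only by √(k/(k−1))).
The scaled variance reported per group is the group variance divided by
the maximum across that phenotype's groups, used inversely for circle
sizes in trend plots. An optional flag removes responder × post-treatment
epithelial rows (after complete response, residual "epithelial"
detections are spurious); default off.

## Multivariate prediction and importance

* Features with ≤ 6 unique values are dropped (strict "more than six").
* Features correlated at Spearman ρ > 0.95 (strict) are grouped by
  Louvain community detection on the correlation graph (edge weight = ρ)
  and one representative per community is kept, chosen by a seeded RNG;
  isolated features always survive.
* **Prediction**: 100 stratified random 75/25 train/test splits; per
  split, features are standardized on the training fold and an
  L1-penalized logistic regression is fit with the shrinkage factor
  chosen to minimize cross-validated deviance (5-fold, 15-point
  log-spaced grid); the held-out quarter is scored by ROC AUC. The
  summary is the mean AUC and the 2.5/97.5-percentile interval of the
  100 repeat AUCs. The lasso (rather than elastic-net) penalty is the
  default because a single shrinkage knob is being tuned; the grid and
  folds are exposed. Tumours with any missing modelled feature are
  dropped per run (complete case, logged).
* **Shadow-feature importance** (Boruta-style): per run, every predictor
  is duplicated as a randomly permuted shadow, doubling the matrix; a
  bagged forest of decision trees (default 500 trees, √m features per
  split) is fit, and every column's importance is computed as the
  out-of-bag permutation increase in misclassification rate, averaged
  over trees and divided by its standard error across trees (0 when the
  spread is exactly zero). A real feature scores a hit when its
  importance exceeds the maximum over all shadows. Hits across runs
  (default 1000; shuffles are redrawn every run) are tested one-sided
  against Binomial(n_runs, 0.5), Bonferroni-corrected across features,
  selected at P < 0.01, and ranked by their importance distribution.
  The bagging loop is implemented directly (bootstrap +
  `DecisionTreeClassifier` per tree) because the importance definition
  requires per-tree out-of-bag permutation errors.

## Synthetic cohorts

The generator emulates the study's data hierarchy: tumours randomized
1:1 to two arms, sampled at up to three timepoints, each sample
contributing 1–3 ROIs of a 500×500 µm window with 200–400 cells.
Per-tumour composition is an epithelial fraction (Beta(8,6)) times
Dirichlet weights (concentration 2) within each compartment; Ki67 rates
are per-phenotype cohort baselines (uniform on [0.05, 0.30]) with
tumour-level logit-normal spread (sd 0.5) so proliferative fractions
vary between tumours; marker intensities are lognormal with
lineage-marker elevations, and T cells touching epithelium get a +0.5
log-unit shift on activation markers. Contacts come from centroid
distance ≤ 15 µm (poisson mode) or from rendered Voronoi-disk label
masks (clustered mode). Response labels follow a logistic link on
standardized realized tumour features with optionally arm-restricted
coefficients; the realized truth table is persisted with the cohort. All
randomness descends from one root seed via `SeedSequence` splitting, so
an identical configuration reproduces the cohort bit for bit.

What the generator does **not** emulate: segmentation errors, spatial
niches and recurrent multicellular structures, realistic contact-degree
distributions (no published values exist to match), marker correlation
structure beyond lineage elevations, or per-ROI tissue-composition
gradients. Passing tests therefore demonstrate correctness of the
computations and calibration of the statistics under the stated
generative assumptions, not biological validity on real cohorts.

## Problem sizes and numerical choices

Stochastic validation experiments use these sizes, chosen to give stable
verdicts with desk-scale compute: interaction-test calibration over
1000 null cohorts of 150 tumours/arm (tumour-level fast path —
standard-normal features through the same logistic link — since image
rendering adds nothing to a calibration of the regression kernel);
arm-specific effect recovery with a log-odds coefficient of 2.0 per SD
of the planted proliferative fraction, 120 tumours/arm, one 500 µm ROI
of 120–180 cells each, over 100 cohort seeds (flagging at BH FDR < 0.1
within the 37-feature family); shadow importance at 100 runs with
50-tree forests for the sensitivity/specificity checks (library
defaults remain 1000 runs / 500 trees). Tolerances: spillover inversion
must round-trip to ≤1e-8 relative error; GMM gating must misassign <1%
of a well-separated mixture (log-means 0 and 3, sd 0.5); closed-form
oracles are matched to 1e-6 relative.

Degenerate inputs are handled explicitly rather than silently: empty
cohorts pass through filters, degenerate hulls mark densities missing,
constant predictors / separated fits are flagged, a constant marker
yields no positives, zero-variance Z-scores are set missing and flagged.

## Known limitations

* Real phenotype labels are consumed as given; the SOM/graph-based
  phenotype clustering of the original workflow is out of scope.
* The once-per-edge contact convention cannot be confirmed against the
  original counts; a directed variant would scale heterotypic metrics by
  2 and leave inference qualitatively unchanged.
* FDR family boundaries and the Wald-vs-LRT choice for `p_interaction`
  are documented conventions.
* The per-image visual curation steps of the original workflow
  (method selection per image, cluster rescue) are not implementable
  from data alone and are replaced by the automated gates above.
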