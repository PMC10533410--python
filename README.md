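# icbspatial

Spatial tissue-feature derivation and immunotherapy-response prediction
for multiplexed imaging cohorts.

In neoadjuvant trials of immune checkpoint blockade (ICB) in
triple-negative breast cancer, tumours are sampled at baseline, early
on-treatment and post-treatment, imaged at single-cell resolution (for
example by imaging mass cytometry), and scored by pathological complete
response (pCR) versus residual disease (RD). `icbspatial` turns
per-image single-cell tables (and optional segmentation label masks)
into tumour-level tissue features, tests which features predict response
differentially between treatment arms, summarizes treatment-induced
composition dynamics, and builds multivariate predictive models with
variable-importance selection. A synthetic cohort generator with known
ground truth makes every stage testable without access to patient data.

It is aimed at computational biologists analysing multiplexed imaging
trials, and at methodologists who need a calibrated, fully seeded
re-implementation of this analysis style.

## The features and statistics

Per tumour and timepoint, with E epithelial and T TME (tumour
microenvironment) phenotypes — default 17 + 20, hence 148 features per
timepoint and 296 for two:

* **densities** — phenotype counts per mm² of tissue (convex hull of
  cell centroids per region of interest, hull areas summed over a
  tumour's images);
* **homotypic / heterotypic cell–cell interaction metrics** — counts of
  touching cell pairs (8-connected mask contact, or centroid distance ≤
  r) qualifying for a focal phenotype within / between compartments,
  divided by the tumour's total cell count;
* **proliferative fractions** — share of Ki67⁺ cells per phenotype.

Each feature x is tested by arm-restricted univariate logistic
regression (OR = e^β on √x, with ×10/×100 scaling for fractions /
interactions) and by the trivariate interaction model

    logit P(pCR) = β₀ + β₁·√x + β₂·arm + β₃·(√x · arm)

whose Wald p-value for β₃ (`p_interaction`) asks whether the
feature–response association differs between chemotherapy and
chemo+immunotherapy; Benjamini–Hochberg FDR is applied within feature
family × timepoint. Multivariate prediction uses L1-regularized
logistic regression (λ by cross-validation) over 100 stratified 75/25
splits, reporting mean test AUC with a percentile 95% CI; dominant
predictors are found by Boruta-style shadow-feature importance
(out-of-bag permutation importance scaled by its standard error,
binomial test on hit counts, Bonferroni P < 0.01).

## Worked example

```python
import icbspatial as icb
from icbspatial.simulate import SyntheticConfig, Effect

cfg = SyntheticConfig(
    seed=7, n_tumours_per_arm=100, timepoints=("baseline",),
    images_per_tumour=(1, 1), cells_per_image=(120, 180),
    effect_spec=(Effect("proliferative_fraction", "CD8_TCF1_T",
                        "baseline", 2.0, "C&I"),),
)
cohort = icb.simulate_cohort(cfg)
table, meta = icb.build_feature_table(
    cohort.cells, cohort.contacts, cohort.images, cfg.registry, ("baseline",)
)
res = icb.associate_features(table, meta, cohort.samples)
print(res.nsmallest(3, "p_interaction")[
    ["feature", "or_c", "or_ci_arm", "p_interaction", "fdr"]
].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

prints

```
                                     feature  or_c  or_ci_arm  p_interaction   fdr
proliferative_fraction__CD8_TCF1_T__baseline  1.09       1.53        0.00637 0.236
               homotypic__CD15_Epi__baseline  1.09      0.977         0.0128 0.472
                     density__Treg__baseline  1.23       0.84         0.0245 0.727
```

The cohort was generated with one planted immunotherapy-arm effect: a
log-odds coefficient of 2 per SD of the CD8⁺TCF1⁺ T-cell proliferative
fraction, applied only in the C&I arm. The scan ranks exactly that
feature first: its odds ratio is null in the chemotherapy arm (1.09)
but 1.53 per transformed unit under immunotherapy, with the smallest
interaction p-value of all 148 features (0.0064). The two runner-up
rows are noise (at 100 tumours per arm a single cohort rarely clears
family-wise FDR < 0.1; the acceptance experiments show the planted
feature is recovered at FDR < 0.1 in ~87–90% of cohorts with 120 per
arm).

The same workflow is available from the shell:

```sh
icbspatial run-all --seed 7 --outdir run/
```

which writes the synthetic inputs, processed cells, feature table,
association scan, dynamics summaries, per-arm AUCs, importance table and
a reproducibility manifest (config hash + seeds; re-running an unchanged
config reproduces every CSV byte for byte).

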