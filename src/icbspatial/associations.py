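"""Per-feature response association testing.

For each tissue feature the analysis reports

* an odds ratio (and 95% Wald CI) for pCR from a univariate logistic
  regression restricted to each treatment arm,
* a treatment-interaction p-value (``p_interaction``) from a trivariate
  logistic model pCR ~ feature + arm + feature:arm (Wald test of the
  interaction coefficient), and
* a Benjamini–Hochberg FDR computed within a feature family × timepoint
  group.

Predictors are square-root transformed and modelled as continuous, with
proliferative fractions additionally scaled ×10 and interaction metrics
×100 so odds ratios are interpretable per readable unit. Since
sqrt(c·x) = √c·sqrt(x), the multipliers rescale coefficients but leave
p-values untouched.

Also here: compositional differential abundance (weighted binomial GLM,
reported as log2 odds ratios) and contact-linked activation comparisons
(two-sided Wilcoxon rank-sum on per-tumour means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .registry import PhenotypeRegistry

logger = logging.getLogger(__name__)

#: |coefficient| above this (on transformed predictors) is treated as separation
_SEP_COEF = 15.0
_SEP_SE = 100.0

TRANSFORM_SCALE = {
    "density": 1.0,
    "proliferative_fraction": 10.0,
    "heterotypic": 100.0,
    "homotypic": 100.0,
}


def transform_predictor(values: np.ndarray | pd.Series, family: str) -> np.ndarray:
    """Square-root transform with family-specific scaling."""
    if family not in TRANSFORM_SCALE:
        raise ValueError(f"unknown feature family {family!r}")
    v = np.asarray(values, dtype=float)
    if np.nanmin(v) < 0:
        raise ValueError("feature values must be non-negative")
    return TRANSFORM_SCALE[family] * np.sqrt(v)


@dataclass
class LogisticFit:
    coef: float
    se: float
    p: float
    separated: bool = False
    converged: bool = True

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            lo = float(np.exp(self.coef - 1.96 * self.se))
            hi = float(np.exp(self.coef + 1.96 * self.se))
        return lo, hi


def _fit_logit(y: np.ndarray, X: np.ndarray, coef_index: int) -> LogisticFit:
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(np.nan, np.nan, np.nan, separated=True, converged=False)
    coef = float(res.params[coef_index])
    se = float(res.bse[coef_index])
    separated = (not np.isfinite(coef)) or abs(coef) > _SEP_COEF or se > _SEP_SE
    return LogisticFit(
        coef=coef,
        se=se,
        p=float(res.pvalues[coef_index]),
        separated=separated,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def fit_arm_specific_or(
    feature: np.ndarray | pd.Series, outcome: np.ndarray | pd.Series
) -> LogisticFit:
    """Univariate logistic OR for pCR within one arm's patients.

    ``outcome`` is 0/1 (1 = pCR). Requires ≥ 2 outcomes of each class;
    a constant predictor or separated fit is returned flagged.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two outcomes of each class in the arm")
    if np.ptp(x) == 0:
        return LogisticFit(np.nan, np.nan, np.nan, separated=True, converged=False)
    X = sm.add_constant(x)
    return _fit_logit(y, X, coef_index=1)


def treatment_interaction_test(
    feature: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    arm: np.ndarray | pd.Series,
    immunotherapy_arm: str = "C&I",
) -> LogisticFit:
    """Wald test of the feature × treatment interaction term.

    Fits pCR ~ feature + arm + feature:arm over both arms; the returned
    fit describes the interaction coefficient (its exp is the ratio of
    per-arm odds ratios).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(outcome, dtype=int)
    a = (np.asarray(arm) == immunotherapy_arm).astype(float)
    if a.min() == a.max():
        raise ValueError("both treatment arms must be present")
    X = np.column_stack([np.ones_like(x), x, a, x * a])
    return _fit_logit(y, X, coef_index=3)


def adjust_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class AssociationResult:
    feature: str
    family: str
    timepoint: str
    or_c: float
    or_c_ci: tuple[float, float]
    p_c: float
    or_ci_arm: float
    or_ci_arm_ci: tuple[float, float]
    p_ci_arm: float
    p_interaction: float
    separated: bool
    fdr: float = np.nan


def associate_features(
    feature_table: pd.DataFrame,
    feature_meta: pd.DataFrame,
    samples: pd.DataFrame,
    immunotherapy_arm: str = "C&I",
) -> pd.DataFrame:
    """Full association scan over a feature table.

    ``samples`` carries tumour_id, arm and response ('pCR'/'RD').
    FDR is adjusted within each (family × timepoint) group. Rows with a
    missing feature value are dropped per feature (complete case).
    """
    s = samples.set_index("tumour_id")
    y_all = (s["response"] == "pCR").astype(int)
    arm_all = s["arm"]
    rows = []
    for rec in feature_meta.itertuples():
        col = rec.column
        vals = feature_table[col].reindex(s.index)
        keep = vals.notna()
        x = transform_predictor(vals[keep], rec.family)
        y = y_all[keep].to_numpy()
        arm = arm_all[keep]
        fits = {}
        for label, mask in (
            ("C", (arm != immunotherapy_arm).to_numpy()),
            ("CI", (arm == immunotherapy_arm).to_numpy()),
        ):
            try:
                fits[label] = fit_arm_specific_or(x[mask], y[mask])
            except ValueError:
                fits[label] = LogisticFit(np.nan, np.nan, np.nan, separated=True)
        try:
            inter = treatment_interaction_test(x, y, arm, immunotherapy_arm)
        except ValueError:
            inter = LogisticFit(np.nan, np.nan, np.nan, separated=True)
        sep = fits["C"].separated or fits["CI"].separated or inter.separated
        rows.append(
            AssociationResult(
                feature=col,
                family=rec.family,
                timepoint=rec.timepoint,
                or_c=fits["C"].odds_ratio,
                or_c_ci=fits["C"].ci,
                p_c=fits["C"].p,
                or_ci_arm=fits["CI"].odds_ratio,
                or_ci_arm_ci=fits["CI"].ci,
                p_ci_arm=fits["CI"].p,
                p_interaction=inter.p,
                separated=sep,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["fdr"] = np.nan
    for (_, _), idx in df.groupby(["family", "timepoint"]).groups.items():
        sub = df.loc[idx]
        usable = sub.index[~sub["separated"]]
        df.loc[usable, "fdr"] = adjust_fdr(df.loc[usable, "p_interaction"])
    return df


@dataclass
class AbundanceResult:
    phenotype: str
    log2_odds_ratio: float
    p: float
    separated: bool
    fdr: float = np.nan


def differential_abundance_glm(
    proportions: np.ndarray | pd.Series,
    totals: np.ndarray | pd.Series,
    predictor: np.ndarray | pd.Series,
    phenotype: str = "",
) -> AbundanceResult:
    """Weighted binomial GLM for compositional differential abundance.

    Per-tumour phenotype proportions (within a compartment) are modelled
    on a binary or continuous predictor under a logit link, weighted by
    the tumour's total cell count so better-sampled tumours count more.
    The coefficient is reported as a log2 odds ratio.
    """
    prop = np.asarray(proportions, dtype=float)
    tot = np.asarray(totals, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if ((prop < 0) | (prop > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    if (tot < 1).any():
        raise ValueError("totals must be ≥ 1")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("predictor must take at least two values")
    if len(uniq) == 2:
        for g in uniq:
            if not ((x == g).any()):
                raise ValueError("one predictor group is empty")
        # pooled-proportion separation check
        for g in uniq:
            m = x == g
            pooled = (prop[m] * tot[m]).sum() / tot[m].sum()
            if pooled in (0.0, 1.0):
                return AbundanceResult(phenotype, np.nan, np.nan, separated=True)
    X = sm.add_constant(x)
    res = sm.GLM(prop, X, family=sm.families.Binomial(), var_weights=tot).fit()
    coef = float(res.params[1])
    sep = not np.isfinite(coef) or abs(coef) > _SEP_COEF
    return AbundanceResult(
        phenotype=phenotype,
        log2_odds_ratio=coef / np.log(2),
        p=float(res.pvalues[1]),
        separated=sep,
    )


def abundance_scan(
    proportion_table: pd.DataFrame,
    totals: pd.Series,
    predictor: pd.Series,
) -> pd.DataFrame:
    """Differential abundance across all phenotype columns, BH-adjusted."""
    rows = []
    common = proportion_table.index
    for ph in proportion_table.columns:
        try:
            r = differential_abundance_glm(
                proportion_table[ph], totals.loc[common], predictor.loc[common], ph
            )
        except ValueError:
            r = AbundanceResult(ph, np.nan, np.nan, separated=True)
        rows.append(r)
    df = pd.DataFrame([r.__dict__ for r in rows])
    ok = df.index[~df["separated"]]
    df.loc[ok, "fdr"] = adjust_fdr(df.loc[ok, "p"])
    return df


def compare_groups_wilcoxon(
    a: np.ndarray | pd.Series, b: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) between two samples.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_contact_activation(
    cells: pd.DataFrame,
    markers: list[str],
    registry: PhenotypeRegistry,
    tumour_col: str = "tumour_id",
    contact_col: str = "epithelial_contact",
    min_tumours: int = 3,
) -> pd.DataFrame:
    """Activation of T cells in contact with cancer cells vs not.

    Per tumour, computes mean expression of each activation marker for T
    cells with ≥1 epithelial contact and for those without; the two
    per-tumour mean distributions are compared by a two-sided Wilcoxon
    test. Tumours lacking either group are dropped (logged). The same
    kernel serves Ki67⁺-proportion comparisons by passing a 0/1 column
    as a marker.
    """
    t = cells[cells["phenotype"].isin(registry.t_cells)]
    rows = []
    for marker in markers:
        means = (
            t.groupby([tumour_col, contact_col], observed=True)[marker]
            .mean()
            .unstack(contact_col)
        )
        if True not in means.columns or False not in means.columns:
            raise ValueError("no tumours contain both contact groups")
        complete = means.dropna()
        dropped = len(means) - len(complete)
        if dropped:
            logger.info("contact-activation: dropped %d tumours missing a group", dropped)
        if len(complete) < min_tumours:
            raise ValueError(
                f"need ≥ {min_tumours} tumours with both T-cell groups, got {len(complete)}"
            )
        stat, p = compare_groups_wilcoxon(complete[True], complete[False])
        rows.append(
            {
                "marker": marker,
                "n_tumours": len(complete),
                "mean_in_contact": float(complete[True].mean()),
                "mean_not_in_contact": float(complete[False].mean()),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
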