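"""Treatment-course composition summaries.

Tracks how tumour composition shifts across timepoint × treatment arm ×
response groups: coarse compartment proportions (epithelial / immune /
stromal), leukocyte proportions relative to all TME cells, and Z-scored
per-phenotype trend summaries for trend plots (circle sizes inversely
proportional to scaled variance).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .associations import compare_groups_wilcoxon  # shared test kernel
from .registry import PhenotypeRegistry

logger = logging.getLogger(__name__)

CATEGORIES = ("epithelial", "immune", "stromal")

__all__ = [
    "compartment_proportions",
    "phenotype_proportions",
    "phenotype_trends",
    "compare_groups_wilcoxon",
    "plot_trends",
]


def compartment_proportions(
    cells: pd.DataFrame,
    category_map: Mapping[str, str],
    tumour_col: str = "tumour_id",
) -> pd.DataFrame:
    """Per-tumour epithelial/immune/stromal proportions (rows sum to 1).

    Tumours with zero cells simply do not appear; an unmapped phenotype
    is an error.
    """
    unmapped = set(cells["phenotype"].unique()) - set(category_map)
    if unmapped:
        raise KeyError(f"phenotypes missing from category map: {sorted(unmapped)}")
    cat = cells["phenotype"].map(category_map)
    counts = (
        pd.crosstab(cells[tumour_col], cat)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def phenotype_proportions(
    cells: pd.DataFrame,
    registry: PhenotypeRegistry,
    compartment: str,
    tumour_col: str = "tumour_id",
) -> pd.DataFrame:
    """Within-compartment phenotype proportions per tumour.

    ``compartment`` is 'epithelial' or 'TME'; proportions are of that
    compartment's cells only, so each row sums to 1 (tumours without any
    cell of the compartment are dropped).
    """
    phenos = registry.epithelial if compartment == "epithelial" else registry.tme
    sub = cells[cells["phenotype"].isin(phenos)]
    counts = pd.crosstab(sub[tumour_col], sub["phenotype"]).reindex(
        columns=list(phenos), fill_value=0
    )
    return counts.div(counts.sum(axis=1), axis=0)


def phenotype_trends(
    proportions: pd.DataFrame,
    groups: pd.DataFrame,
    min_groups: int = 2,
) -> pd.DataFrame:
    """Trend summary: group means Z-scored per phenotype.

    ``proportions`` is tumour × phenotype (within-compartment
    proportions); ``groups`` assigns each tumour a timepoint, arm and
    response. For every phenotype the mean proportion per
    (timepoint, arm, response) group is computed, then Z-scored across
    groups using the sample (n−1) standard deviation. The scaled
    variance (per-group variance divided by the maximum across that
    phenotype's groups) supports circle sizing in trend plots. Phenotypes
    absent everywhere are dropped with a log entry; a phenotype whose
    group means are constant gets missing Z-scores (flagged degenerate).
    """
    needed = {"timepoint", "arm", "response"}
    if not needed <= set(groups.columns):
        raise ValueError(f"groups requires columns {sorted(needed)}")
    common = proportions.index.intersection(groups.index)
    props = proportions.loc[common]
    g = groups.loc[common, ["timepoint", "arm", "response"]]
    key = pd.MultiIndex.from_frame(g)
    rows = []
    for ph in props.columns:
        vals = props[ph]
        if (vals.fillna(0) == 0).all():
            logger.info("phenotype %s absent everywhere; dropped from trends", ph)
            continue
        by_group = vals.groupby(key)
        means = by_group.mean()
        if len(means) < min_groups:
            raise ValueError(f"phenotype {ph} has fewer than {min_groups} groups")
        sd = means.std(ddof=1)
        degenerate = not np.isfinite(sd) or sd == 0
        z = (means - means.mean()) / sd if not degenerate else means * np.nan
        var = by_group.var(ddof=1)
        vmax = var.max()
        scaled_var = var / vmax if vmax and np.isfinite(vmax) and vmax > 0 else var * np.nan
        n = by_group.size()
        for grp in means.index:
            tp, arm, resp = grp
            rows.append(
                {
                    "phenotype": ph,
                    "timepoint": tp,
                    "arm": arm,
                    "response": resp,
                    "mean_proportion": float(means[grp]),
                    "z": float(z[grp]) if np.isfinite(z[grp]) else np.nan,
                    "scaled_variance": float(scaled_var[grp])
                    if np.isfinite(scaled_var[grp])
                    else np.nan,
                    "n_patients": int(n[grp]),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def exclude_spurious_epithelial(
    proportions: pd.DataFrame,
    groups: pd.DataFrame,
    timepoint: str = "post_treatment",
    response: str = "pCR",
) -> pd.DataFrame:
    """Optionally drop epithelial rows for responders post-treatment.

    After a complete response no invasive cancer remains, so apparent
    epithelial detections in responder post-treatment samples are
    spurious; this removes those tumours' rows from an epithelial
    proportion table. Off by default in the pipeline.
    """
    bad = groups[(groups["timepoint"] == timepoint) & (groups["response"] == response)]
    return proportions.drop(index=bad.index, errors="ignore")


def plot_trends(trends: pd.DataFrame, path: str) -> None:
    """Line plot of Z-scored phenotype trends per arm × response group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = {"baseline": 0, "on_treatment": 1, "post_treatment": 2}
    fig, ax = plt.subplots(figsize=(7, 5))
    for (ph, arm, resp), sub in trends.groupby(["phenotype", "arm", "response"]):
        sub = sub.sort_values("timepoint", key=lambda s: s.map(order))
        size = 40 * (1.0 / (0.2 + sub["scaled_variance"].fillna(1.0)))
        ax.plot(sub["timepoint"], sub["z"], alpha=0.4, label=f"{ph} {arm} {resp}")
        ax.scatter(sub["timepoint"], sub["z"], s=size, alpha=0.6)
    ax.set_ylabel("Z-scored mean proportion")
    ax.set_xlabel("timepoint")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
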