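"""Single-cell preprocessing: spillover correction, drug-channel
correction, size filtering, compartment assignment and marker gating.

All log transforms of ion counts use log(x + 1), since mean ion counts can
be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.mixture import GaussianMixture

#: cells smaller than this (µm², strict) are excluded from all analyses
MIN_CELL_AREA_UM2 = 31.0

#: minimum fraction of a cell's pixels inside the epithelial region mask
MASK_OVERLAP_THRESHOLD = 0.30

_COND_LIMIT = 1e6


def correct_spillover(observed: np.ndarray, spillover: np.ndarray) -> np.ndarray:
    """Invert channel crosstalk by per-cell non-negative least squares.

    The spillover matrix S (rows = source channels, unit diagonal) maps
    true signal x to observations x·S; each corrected row is
    argmin_{x ≥ 0} ‖x·S − observed‖². Channel order of both inputs must
    match.
    """
    obs = np.asarray(observed, dtype=float)
    S = np.asarray(spillover, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("spillover matrix must be square")
    if obs.ndim == 1:
        obs = obs[None, :]
    if obs.shape[1] != S.shape[0]:
        raise ValueError(
            f"channel mismatch: observed has {obs.shape[1]}, spillover {S.shape[0]}"
        )
    if not np.isfinite(obs).all():
        raise ValueError("observed intensities must be finite")
    if np.linalg.cond(S) > _COND_LIMIT:
        raise ValueError("spillover matrix is ill-conditioned (cond > 1e6)")
    A = S.T  # x·S = (Sᵀ xᵀ)ᵀ
    out = np.empty_like(obs)
    for i in range(obs.shape[0]):
        out[i], _ = nnls(A, obs[i])
    return out


@dataclass
class CarboplatinCorrection:
    """OLS fit of log marker expression on the drug channel, per channel."""

    residuals: pd.DataFrame
    slopes: dict[str, float]
    intercepts: dict[str, float]
    degenerate: bool = False


def correct_carboplatin(
    cells: pd.DataFrame,
    channels: list[str],
    carboplatin_channel: str = "Carboplatin",
) -> CarboplatinCorrection:
    """Remove platinum contamination from antibody channels.

    Pooling all cells, fits ordinary least squares of log(channel + 1) on
    log(carboplatin + 1) and returns the residuals as corrected values.
    A zero-variance drug channel yields centred log values with the
    ``degenerate`` flag set.
    """
    if carboplatin_channel not in cells.columns:
        raise KeyError(f"missing carboplatin channel {carboplatin_channel!r}")
    x = np.log1p(cells[carboplatin_channel].to_numpy(dtype=float))
    resid = {}
    slopes, intercepts = {}, {}
    degenerate = bool(np.ptp(x) == 0)
    if degenerate:
        warnings.warn("carboplatin channel has zero variance; returning centred logs")
    for ch in channels:
        ylog = np.log1p(cells[ch].to_numpy(dtype=float))
        if degenerate:
            resid[ch] = ylog - ylog.mean()
            slopes[ch], intercepts[ch] = 0.0, float(ylog.mean())
            continue
        slope, intercept = np.polyfit(x, ylog, 1)
        resid[ch] = ylog - (intercept + slope * x)
        slopes[ch], intercepts[ch] = float(slope), float(intercept)
    return CarboplatinCorrection(
        residuals=pd.DataFrame(resid, index=cells.index),
        slopes=slopes,
        intercepts=intercepts,
        degenerate=degenerate,
    )


def filter_small_cells(
    cells: pd.DataFrame, min_area: float = MIN_CELL_AREA_UM2
) -> pd.DataFrame:
    """Drop cells with area strictly below ``min_area`` (31 µm² default).

    A cell of exactly 31 µm² is retained.
    """
    if len(cells) == 0:
        return cells
    return cells[cells["area_um2"] >= min_area].reset_index(drop=True)


def classify_compartment_gmm(
    cells: pd.DataFrame,
    cytokeratin_channels: list[str],
    seed: int = 0,
) -> np.ndarray:
    """Cytokeratin gate: two-component Gaussian mixture on the log sum.

    Fits a 1-D two-component GMM to log(sum of cytokeratins + 1); cells
    whose posterior favours the higher-mean component are called
    cytokeratin-positive (posterior tie 0.5 counts as positive).
    Deterministic for a given seed (k-means init, EM tolerance 1e-6).
    """
    if len(cells) < 50:
        raise ValueError("need at least 50 cells for a stable mixture fit")
    if not cytokeratin_channels:
        raise ValueError("need at least one cytokeratin channel")
    total = cells[cytokeratin_channels].sum(axis=1).to_numpy(dtype=float)
    x = np.log1p(total)[:, None]
    if np.ptp(x) == 0:
        raise ValueError(
            "all cytokeratin sums identical; mixture undefined — set a manual threshold"
        )
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=1e-6,
        max_iter=500,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
    ).fit(x)
    high = int(np.argmax(gmm.means_.ravel()))
    post = gmm.predict_proba(x)[:, high]
    return post >= 0.5


def assign_mask_positive(
    overlap_fraction: np.ndarray | pd.Series,
    threshold: float = MASK_OVERLAP_THRESHOLD,
) -> np.ndarray:
    """Mask gate: positive iff ≥ ``threshold`` of the cell's pixels lie in
    the epithelial region (inclusive: exactly 30% is positive)."""
    f = np.asarray(overlap_fraction, dtype=float)
    if ((f < 0) | (f > 1)).any() or not np.isfinite(f).all():
        raise ValueError("overlap fractions must lie in [0, 1]")
    return f >= threshold


def threshold_positivity(
    values: np.ndarray | pd.Series, quantile: float
) -> np.ndarray:
    """Quantile gate: positive iff strictly above the global q-quantile.

    The quantile is the linear-interpolation (type-7) quantile over all
    provided values; ties at the threshold are negative, so a constant
    marker yields no positive cells. Used for Ki67 gating among others.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    thr = np.quantile(v, quantile)
    return v > thr


def preprocess_cells(
    cells: pd.DataFrame,
    min_area: float = MIN_CELL_AREA_UM2,
    ki67_channel: str = "Ki67",
    ki67_quantile: float | None = None,
) -> pd.DataFrame:
    """Standard per-cohort preprocessing: size filter, optional Ki67 gate.

    When ``ki67_quantile`` is given, the boolean ``ki67_positive`` column
    is (re)derived from the global quantile gate on the Ki67 channel.
    """
    out = filter_small_cells(cells, min_area=min_area)
    if ki67_quantile is not None:
        if ki67_channel not in out.columns:
            raise KeyError(f"missing marker channel {ki67_channel!r}")
        out = out.copy()
        out["ki67_positive"] = threshold_positivity(
            out[ki67_channel], ki67_quantile
        )
    return out
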