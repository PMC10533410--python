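"""Synthetic tumour-cohort generator.

Emulates the data structure of a two-arm neoadjuvant trial profiled by
multiplexed imaging: tumours randomized to chemotherapy (``C``) or
chemotherapy + immunotherapy (``C&I``), each sampled at up to three
timepoints (baseline, on-treatment, post-treatment), each sample
contributing one or more ~500×500 µm regions of interest with hundreds of
segmented cells. Cells carry a phenotype drawn from a tumour-level
composition (Dirichlet within each compartment), a Ki67 proliferation
flag, lognormal marker intensities, and a spatial position from which a
contact graph is derived.

Response labels (pCR vs residual disease) are generated from a logistic
link on standardized realized tumour features, with coefficients that may
be restricted to one arm — the ground truth for treatment-interaction
recovery experiments. The realized truth table is part of the cohort so
downstream checks never re-derive ground truth from pipeline outputs.

All randomness flows from one root seed through documented
``numpy.random.SeedSequence`` stream splitting; an identical config yields
a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit, logit

from .features import ContactGraph, contacts_from_label_mask
from .registry import EPITHELIAL, TME, PhenotypeRegistry

ARMS = ("C", "C&I")
TIMEPOINTS = ("baseline", "on_treatment", "post_treatment")

#: linear predictors are clipped here before the logistic link
LP_CAP = 30.0


@dataclass(frozen=True)
class Effect:
    """One response-generating coefficient.

    ``family``/``phenotype``/``timepoint`` name a tumour feature;
    ``coef`` is the log-odds change per SD of that feature (features are
    standardized across the cohort before entering the link);
    ``arm`` restricts the coefficient to one arm (None = both).
    """

    family: str
    phenotype: str
    timepoint: str = "baseline"
    coef: float = 1.0
    arm: str | None = None

    @property
    def feature(self) -> str:
        return f"{self.family}__{self.phenotype}__{self.timepoint}"


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_tumours_per_arm: int = 20
    timepoints: tuple[str, ...] = ("baseline", "on_treatment")
    images_per_tumour: tuple[int, int] = (1, 2)
    cells_per_image: tuple[int, int] = (200, 400)
    window_um: float = 500.0
    contact_radius_um: float = 15.0
    spatial_mode: str = "poisson"  # or "clustered"
    registry: PhenotypeRegistry = field(default_factory=PhenotypeRegistry)
    epithelial_fraction_beta: tuple[float, float] = (8.0, 6.0)
    composition_alpha_epithelial: float = 2.0
    composition_alpha_tme: float = 2.0
    ki67_rate_range: tuple[float, float] = (0.05, 0.30)
    ki67_tumour_sd: float = 0.5  # logit-scale tumour-level spread
    mean_cell_area_um2: float = 70.0
    log_area_sd: float = 0.25
    marker_log_sd: float = 0.4
    contact_activation_shift: float = 0.5
    effect_spec: tuple[Effect, ...] = ()
    response_intercept: float = 0.0

    def __post_init__(self):
        if self.n_tumours_per_arm < 1:
            raise ValueError("need at least one tumour per arm")
        if self.contact_radius_um < 0:
            raise ValueError("contact_radius_um must be >= 0")
        if self.cells_per_image[0] < 10:
            raise ValueError("cells_per_image minimum is 10")
        if self.spatial_mode not in ("poisson", "clustered"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        if not set(self.timepoints) <= set(TIMEPOINTS):
            raise ValueError(f"timepoints must be among {TIMEPOINTS}")
        lo, hi = self.ki67_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ki67_rate_range must lie in [0, 1]")
        for eff in self.effect_spec:
            if not np.isfinite(eff.coef):
                raise ValueError(f"non-finite coefficient for {eff.feature}")


@dataclass
class Cohort:
    config: SyntheticConfig
    samples: pd.DataFrame  # tumour_id, arm, response, per_protocol
    images: pd.DataFrame  # image_id, tumour_id, timepoint
    cells: dict[str, pd.DataFrame]
    contacts: dict[str, ContactGraph]
    truth: dict


def _phenotype_baselines(registry: PhenotypeRegistry) -> dict[tuple[str, str], float]:
    """Default lognormal log-means per (phenotype, marker).

    Most (phenotype, marker) pairs sit at a common background log-mean 0;
    lineage markers are elevated in the phenotypes that define them, and
    T-cell activation markers sit modestly above background in T cells so
    the contact shift acts on a realistic base.
    """
    mu: dict[tuple[str, str], float] = {}
    for p in registry.epithelial:
        for m in registry.cytokeratins:
            mu[(p, m)] = 2.5
    for p in registry.t_cells:
        if p.startswith("CD8"):
            mu[(p, "CD8a")] = 2.0
        else:
            mu[(p, "CD4")] = 2.0
        for m in registry.activation_markers:
            mu[(p, m)] = 0.5
    for p in registry.tme:
        if "B" in p or "Plasma" in p:
            mu[(p, "CD20")] = 2.0
    return mu


def simulate_image(
    rng: np.random.Generator,
    n_cells: int,
    composition: pd.Series,
    config: SyntheticConfig,
    ki67_rates: Mapping[str, float],
    image_id: str = "img",
    carboplatin_logmean: float = 0.0,
) -> tuple[pd.DataFrame, ContactGraph]:
    """Simulate one region of interest: a cell table and its contact graph.

    Positions are uniform in the window (``poisson`` mode; contacts are
    centroid pairs at distance ≤ contact radius, inclusive) or drawn
    around cluster centres (``clustered`` mode; contacts come from a
    rendered label mask under 8-connectivity). T cells with at least one
    epithelial contact get ``contact_activation_shift`` added to the log
    intensity of every activation marker.
    """
    if n_cells < 10:
        raise ValueError("cells_per_image minimum is 10")
    reg = config.registry
    window = config.window_um
    if n_cells * config.mean_cell_area_um2 > window * window:
        raise ValueError(
            f"window {window}×{window} µm too small for {n_cells} cells of "
            f"mean area {config.mean_cell_area_um2} µm²"
        )
    phenos = np.asarray(composition.index)
    probs = composition.to_numpy(dtype=float)
    labels = rng.choice(phenos, size=n_cells, p=probs / probs.sum())
    comp = np.array(
        [EPITHELIAL if p in reg.epithelial else TME for p in labels], dtype=object
    )

    if config.spatial_mode == "poisson":
        xy = rng.uniform(0.0, window, size=(n_cells, 2))
    else:
        n_clusters = max(1, n_cells // 40)
        centres = rng.uniform(0.0, window, size=(n_clusters, 2))
        which = rng.integers(0, n_clusters, size=n_cells)
        xy = centres[which] + rng.normal(0.0, window / 12.0, size=(n_cells, 2))
        xy = np.clip(xy, 0.0, np.nextafter(window, 0.0))

    areas = np.exp(
        rng.normal(np.log(config.mean_cell_area_um2), config.log_area_sd, n_cells)
    )
    ki67 = np.array(
        [rng.random() < ki67_rates[p] for p in labels], dtype=bool
    )
    cell_ids = np.arange(1, n_cells + 1)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "area_um2": areas,
            "phenotype": labels,
            "compartment": comp,
            "ki67_positive": ki67,
        }
    )
    # fraction of each cell's pixels inside the epithelial region mask
    overlap = np.where(
        comp == EPITHELIAL,
        rng.uniform(0.5, 1.0, n_cells),
        rng.uniform(0.0, 0.2, n_cells),
    )
    cells["mask_overlap_fraction"] = overlap

    if config.spatial_mode == "poisson":
        if config.contact_radius_um > 0:
            tree = cKDTree(xy)
            pairs = tree.query_pairs(config.contact_radius_um, output_type="ndarray")
            edges = {(int(cell_ids[i]), int(cell_ids[j])) for i, j in pairs}
        else:
            edges = set()
        graph = ContactGraph.from_pairs(image_id, edges)
    else:
        mask = render_label_mask(cells, pixel_size_um=2.0, window_um=window)
        graph = contacts_from_label_mask(mask, image_id)

    # marker intensities: lognormal per (phenotype, marker)
    mu0 = _phenotype_baselines(reg)
    logint = {}
    for m in reg.markers:
        if m == "Carboplatin":
            base = np.full(n_cells, carboplatin_logmean)
        elif m == "Ki67":
            base = np.where(ki67, 2.0, 0.0)
        else:
            base = np.array([mu0.get((p, m), 0.0) for p in labels])
        logint[m] = base + rng.normal(0.0, config.marker_log_sd, n_cells)
    # platinum contamination of Vimentin/Calponin channels (for the
    # carboplatin-residual correction step)
    for m in ("Vimentin", "Calponin"):
        if m in logint:
            logint[m] = logint[m] + 0.3 * logint["Carboplatin"]

    # contact-linked activation: T cells touching an epithelial cell
    if config.contact_activation_shift != 0 and len(graph):
        by_id = dict(zip(cell_ids, range(n_cells)))
        is_t = np.isin(labels, list(reg.t_cells))
        epi_contact = np.zeros(n_cells, dtype=bool)
        for a, b in graph.edges:
            ia, ib = by_id[a], by_id[b]
            if comp[ia] == EPITHELIAL:
                epi_contact[ib] = True
            if comp[ib] == EPITHELIAL:
                epi_contact[ia] = True
        shift_rows = is_t & epi_contact
        for m in reg.activation_markers:
            logint[m] = logint[m] + np.where(
                shift_rows, config.contact_activation_shift, 0.0
            )
        cells["epithelial_contact"] = epi_contact
    else:
        cells["epithelial_contact"] = False

    for m in reg.markers:
        cells[m] = np.exp(logint[m])
    return cells, graph


def render_label_mask(
    cells: pd.DataFrame, pixel_size_um: float, window_um: float
) -> np.ndarray:
    """Render a 16-bit label mask: each cell is the Voronoi region of its
    centroid clipped to a disk matching its area; background is 0."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    areas = cells["area_um2"].to_numpy(dtype=float)
    ids = cells["cell_id"].to_numpy()
    if (areas <= 0).any():
        raise ValueError("cell areas must be positive")
    if len(np.unique(xy, axis=0)) < len(xy):
        raise ValueError("duplicate cell centroids cannot be rendered")
    if ids.max() > np.iinfo(np.uint16).max:
        raise ValueError("cell ids exceed 16-bit label range")
    n_px = int(np.ceil(window_um / pixel_size_um))
    coords = (np.arange(n_px) + 0.5) * pixel_size_um
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(xy)
    dist, nearest = tree.query(grid)
    radius = np.sqrt(areas / np.pi)
    label = ids[nearest].astype(np.uint16)
    label[dist > radius[nearest]] = 0
    return label.reshape(n_px, n_px)


def simulate_spillover_fixture(
    n_channels: int, rng: np.random.Generator, n_cells: int = 200,
    max_spill: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(true intensities, spillover matrix, observed = true · S) fixture.

    The spillover matrix has unit diagonal and off-diagonal crosstalk
    fractions in [0, ``max_spill``]; rows are source channels.
    """
    if n_channels < 2:
        raise ValueError("need at least two channels")
    S = np.eye(n_channels)
    off = rng.uniform(0.0, max_spill, size=(n_channels, n_channels))
    S = S + off * (1 - np.eye(n_channels))
    true = np.exp(rng.normal(0.0, 1.0, size=(n_cells, n_channels)))
    observed = true @ S
    return true, S, observed


def simulate_response(
    truth_features: Mapping[str, float] | pd.Series,
    effect_spec: Sequence[Effect],
    arm: str,
    rng: np.random.Generator,
    intercept: float = 0.0,
) -> tuple[int, float]:
    """Draw one response label from the logistic link.

    P(pCR) = logistic(intercept + Σ coef·feature), each coefficient
    applied only when its arm restriction matches (or is None). Feature
    values are used as given (callers standardize across the cohort).
    """
    lp = intercept
    for eff in effect_spec:
        if eff.arm is not None and eff.arm != arm:
            continue
        if eff.feature not in truth_features:
            raise KeyError(f"effect references unknown feature {eff.feature!r}")
        lp += eff.coef * float(truth_features[eff.feature])
    p = float(expit(np.clip(lp, -LP_CAP, LP_CAP)))
    return int(rng.random() < p), p


def _truth_features_for_tumour(
    cells_by_image: Mapping[str, pd.DataFrame],
    contacts: Mapping[str, ContactGraph],
    image_ids_by_tp: Mapping[str, list[str]],
    registry: PhenotypeRegistry,
) -> dict[str, float]:
    """Realized per-tumour feature values by direct counting.

    Intentionally a plain re-count (not the feature-table builder) so the
    persisted truth stays independent of the pipeline implementation.
    """
    out: dict[str, float] = {}
    for tp, imgs in image_ids_by_tp.items():
        frames = [cells_by_image[i] for i in imgs]
        all_cells = pd.concat(frames, ignore_index=True)
        n_total = len(all_cells)
        counts = all_cells["phenotype"].value_counts()
        ki = all_cells.groupby("phenotype", observed=True)["ki67_positive"].mean()
        # per-image hull areas via the shoelace formula on the hull polygon
        area = 0.0
        for f in frames:
            pts = f[["x_um", "y_um"]].to_numpy()
            area += _hull_area_shoelace(pts)
        het: dict[str, float] = {p: 0.0 for p in registry.all_phenotypes}
        hom: dict[str, float] = {p: 0.0 for p in registry.all_phenotypes}
        for img in imgs:
            lookup_ph = dict(
                zip(cells_by_image[img]["cell_id"], cells_by_image[img]["phenotype"])
            )
            epi = set(registry.epithelial)
            for a, b in contacts[img].edges:
                pa, pb = lookup_ph[a], lookup_ph[b]
                ca = EPITHELIAL if pa in epi else TME
                cb = EPITHELIAL if pb in epi else TME
                if ca == cb:
                    hom[pa] += 1.0
                    if pb != pa:
                        hom[pb] += 1.0
                else:
                    het[pa] += 1.0
                    het[pb] += 1.0
        for p in registry.all_phenotypes:
            out[f"density__{p}__{tp}"] = (
                counts.get(p, 0) / (area / 1e6) if area > 0 else np.nan
            )
            out[f"heterotypic__{p}__{tp}"] = het[p] / n_total
            out[f"homotypic__{p}__{tp}"] = hom[p] / n_total
            out[f"proliferative_fraction__{p}__{tp}"] = float(ki.get(p, 0.0))
    return out


def _hull_area_shoelace(pts: np.ndarray) -> float:
    """Convex-hull area (µm²) via monotone chain + shoelace; 0 if degenerate."""
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        return 0.0
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def half(points):
        chain: list[np.ndarray] = []
        for p in points:
            while len(chain) >= 2:
                u = chain[-1] - chain[-2]
                v = p - chain[-2]
                if u[0] * v[1] - u[1] * v[0] <= 0:
                    chain.pop()
                else:
                    break
            chain.append(p)
        return chain

    hull = half(pts)[:-1] + half(pts[::-1])[:-1]
    if len(hull) < 3:
        return 0.0
    h = np.array(hull)
    x, y = h[:, 0], h[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def simulate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort (samples, images, cells, contacts, truth)."""
    reg = config.registry
    root = np.random.SeedSequence(config.seed)
    ss_comp, ss_img, ss_resp = root.spawn(3)
    rng_comp = np.random.default_rng(ss_comp)
    rng_resp = np.random.default_rng(ss_resp)

    # cohort-level phenotype Ki67 base rates
    lo, hi = config.ki67_rate_range
    base_ki67 = {
        p: rng_comp.uniform(lo, hi) for p in reg.all_phenotypes
    }

    samples_rows = []
    images_rows = []
    cells: dict[str, pd.DataFrame] = {}
    contacts: dict[str, ContactGraph] = {}
    truth_rows: dict[str, dict[str, float]] = {}

    img_streams = iter(ss_img.spawn(2 * config.n_tumours_per_arm))
    carbo_mu = {"baseline": 0.0, "on_treatment": 1.5, "post_treatment": 1.5}

    for arm in ARMS:
        for t in range(config.n_tumours_per_arm):
            tum = f"{'C' if arm == 'C' else 'CI'}_T{t + 1:03d}"
            rng_t = np.random.default_rng(next(img_streams))
            a, b = config.epithelial_fraction_beta
            epi_frac = rng_comp.beta(a, b)
            comp_epi = rng_comp.dirichlet(
                np.full(len(reg.epithelial), config.composition_alpha_epithelial)
            )
            comp_tme = rng_comp.dirichlet(
                np.full(len(reg.tme), config.composition_alpha_tme)
            )
            composition = pd.Series(
                np.concatenate([epi_frac * comp_epi, (1 - epi_frac) * comp_tme]),
                index=list(reg.all_phenotypes),
            )
            # tumour-level Ki67 rates: logit-normal spread around cohort base
            ki67_rates = {
                p: float(
                    expit(logit(base_ki67[p]) + rng_comp.normal(0, config.ki67_tumour_sd))
                )
                for p in reg.all_phenotypes
            }
            image_ids_by_tp: dict[str, list[str]] = {}
            for tp in config.timepoints:
                n_imgs = int(
                    rng_t.integers(
                        config.images_per_tumour[0], config.images_per_tumour[1] + 1
                    )
                )
                ids = []
                for k in range(n_imgs):
                    img_id = f"{tum}_{tp}_R{k + 1}"
                    n_cells = int(
                        rng_t.integers(
                            config.cells_per_image[0], config.cells_per_image[1] + 1
                        )
                    )
                    tbl, graph = simulate_image(
                        rng_t,
                        n_cells,
                        composition,
                        config,
                        ki67_rates,
                        image_id=img_id,
                        carboplatin_logmean=carbo_mu[tp],
                    )
                    cells[img_id] = tbl
                    contacts[img_id] = graph
                    images_rows.append(
                        {"image_id": img_id, "tumour_id": tum, "timepoint": tp}
                    )
                    ids.append(img_id)
                image_ids_by_tp[tp] = ids
            truth_rows[tum] = _truth_features_for_tumour(
                cells, contacts, image_ids_by_tp, reg
            )
            samples_rows.append({"tumour_id": tum, "arm": arm, "per_protocol": True})

    samples = pd.DataFrame(samples_rows)
    images = pd.DataFrame(images_rows)
    truth_features = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth_features.index.name = "tumour_id"

    # standardize effect features across the cohort, then draw responses
    z = {}
    for eff in config.effect_spec:
        if eff.feature not in truth_features.columns:
            raise KeyError(f"effect references unknown feature {eff.feature!r}")
        col = truth_features[eff.feature]
        sd = col.std(ddof=0)
        z[eff.feature] = (col - col.mean()) / sd if sd > 0 else col * 0.0

    responses, probs = [], []
    for row in samples.itertuples():
        feats = {k: v.loc[row.tumour_id] for k, v in z.items()}
        label, p = simulate_response(
            feats, config.effect_spec, row.arm, rng_resp, config.response_intercept
        )
        responses.append("pCR" if label else "RD")
        probs.append(p)
    samples["response"] = responses

    truth = {
        "features": truth_features,
        "standardized_effect_features": pd.DataFrame(z),
        "effect_spec": list(config.effect_spec),
        "response_intercept": config.response_intercept,
        "p_pcr": pd.Series(probs, index=samples["tumour_id"].to_numpy()),
        "response": pd.Series(
            samples["response"].to_numpy(), index=samples["tumour_id"].to_numpy()
        ),
    }
    return Cohort(
        config=config,
        samples=samples,
        images=images,
        cells=cells,
        contacts=contacts,
        truth=truth,
    )


def simulate_feature_cohort(
    n_per_arm: int,
    n_features: int,
    rng: np.random.Generator,
    effect_spec: Sequence[tuple[int, float, str | None]] = (),
    intercept: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Tumour-level fast path: standard-normal features + logistic responses.

    Used for large-replicate calibration studies where rendering images
    would add nothing: features are already the unit-scale quantities the
    association tests consume. ``effect_spec`` entries are
    (feature index, log-odds coefficient, arm restriction or None).

    Returns (features, outcome 0/1, arm labels).
    """
    n = 2 * n_per_arm
    X = pd.DataFrame(
        rng.standard_normal((n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    arm = pd.Series(["C"] * n_per_arm + ["C&I"] * n_per_arm, name="arm")
    lp = np.full(n, intercept)
    for idx, coef, arm_r in effect_spec:
        mask = np.ones(n, dtype=bool) if arm_r is None else (arm == arm_r).to_numpy()
        lp = lp + np.where(mask, coef * X.iloc[:, idx].to_numpy(), 0.0)
    p = expit(np.clip(lp, -LP_CAP, LP_CAP))
    y = pd.Series((rng.random(n) < p).astype(int), name="pCR")
    return X, y, arm
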