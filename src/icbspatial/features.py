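"""Tissue features per tumour per timepoint.

Four feature families are derived from segmented single cells and their
contact graph:

* **density** — cells of a phenotype per mm² of tissue, where the tissue
  area of each image is the convex hull of its cell centroids (summed over
  a tumour's images).
* **heterotypic / homotypic interaction metrics** — counts of qualifying
  cell–cell contacts for a focal phenotype, normalized by the total number
  of cells in the tumour sample (epithelial and TME combined). A cell with
  several contacts contributes once per distinct contact, so multi-contact
  cells carry more weight.
* **proliferative_fraction** — proportion of a phenotype's cells positive
  for the proliferation marker Ki67.

With E epithelial and T TME phenotypes a single timepoint yields
``2*(E+T)`` interaction columns + ``E+T`` densities + ``E+T`` fractions =
``4*(E+T)`` features (148 for the default 17+20 registry).

Contacts are unordered, irreflexive cell-id pairs. From label masks, two
cells are in contact when their pixel regions touch under 8-connectivity
(edge- or corner-adjacent); from point patterns, when centroid distance is
at most the contact radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .registry import EPITHELIAL, TME, PhenotypeRegistry

FAMILIES = ("density", "heterotypic", "homotypic", "proliferative_fraction")

FLAVOURS = (
    "epithelial_homotypic",
    "epithelial_heterotypic",
    "tme_homotypic",
    "tme_heterotypic",
)


@dataclass(frozen=True)
class ContactGraph:
    """Per-image set of touching cell pairs (symmetric, irreflexive)."""

    image_id: str
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-contact for cell {a} in {self.image_id}")
            norm.add((a, b) if a < b else (b, a))
        object.__setattr__(self, "edges", frozenset(norm))

    def __len__(self) -> int:
        return len(self.edges)

    @classmethod
    def from_pairs(cls, image_id: str, pairs: Iterable[tuple[int, int]]) -> "ContactGraph":
        return cls(image_id=image_id, edges=frozenset(tuple(p) for p in pairs))


def contacts_from_label_mask(label_image: np.ndarray, image_id: str = "") -> ContactGraph:
    """Extract the contact graph from a segmentation label mask.

    Two labelled regions are in contact when any pixel of one is
    8-adjacent to a pixel of the other. Background is label 0.
    """
    img = np.asarray(label_image)
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {img.dtype}")
    pairs: set[tuple[int, int]] = set()
    # four unique neighbour offsets cover all 8-adjacencies once
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if di == 0:
            a = img[:, :-dj]
            b = img[:, dj:]
        elif dj == 1:
            a = img[:-di, :-dj]
            b = img[di:, dj:]
        elif dj == -1:
            a = img[:-di, 1:]
            b = img[di:, :-1]
        else:
            a = img[:-di, :]
            b = img[di:, :]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            av, bv = a[sel], b[sel]
            lo = np.minimum(av, bv)
            hi = np.maximum(av, bv)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return ContactGraph.from_pairs(image_id, pairs)


def tissue_area_convex_hull(xy_um: np.ndarray) -> float:
    """Convex-hull area of cell centroids, in mm².

    Returns NaN for degenerate inputs (<3 cells or collinear centroids),
    which marks the tumour's density features as missing downstream.
    """
    xy = np.asarray(xy_um, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) centroid array in µm")
    if len(xy) < 3:
        return float("nan")
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return float("nan")
    area_um2 = hull.volume  # 2-D hull: 'volume' is the area
    if area_um2 <= 0:
        return float("nan")
    return area_um2 / 1e6


def phenotype_densities(
    cells: pd.DataFrame, area_mm2: float, phenotypes: Sequence[str]
) -> pd.Series:
    """Cells per mm² for each phenotype; absent phenotypes get 0."""
    counts = cells["phenotype"].value_counts()
    out = pd.Series(0.0, index=list(phenotypes), name="density")
    if not np.isfinite(area_mm2) or area_mm2 <= 0:
        return pd.Series(np.nan, index=list(phenotypes), name="density")
    for p in phenotypes:
        out[p] = counts.get(p, 0) / area_mm2
    return out


def _edge_frame(
    cells: pd.DataFrame, edges: Iterable[tuple[int, int]]
) -> pd.DataFrame:
    """Annotate edges with endpoint compartments/phenotypes."""
    idx = cells.set_index("cell_id")
    comp = idx["compartment"]
    phen = idx["phenotype"]
    e = np.asarray(sorted(edges), dtype=int).reshape(-1, 2)
    return pd.DataFrame(
        {
            "comp_a": comp.reindex(e[:, 0]).to_numpy(),
            "comp_b": comp.reindex(e[:, 1]).to_numpy(),
            "ph_a": phen.reindex(e[:, 0]).to_numpy(),
            "ph_b": phen.reindex(e[:, 1]).to_numpy(),
        }
    )


def interaction_metric(
    cells: pd.DataFrame,
    edges: Iterable[tuple[int, int]],
    flavour: str,
    focal_phenotype: str,
    registry: PhenotypeRegistry,
) -> float:
    """One interaction metric: qualifying contacts / total cells.

    Flavours (focal phenotype in parentheses):

    * ``epithelial_homotypic`` (epithelial) — contacts between the focal
      epithelial phenotype and any epithelial cell.
    * ``epithelial_heterotypic`` (TME) — contacts between any epithelial
      cell and the focal TME phenotype.
    * ``tme_homotypic`` (TME) — contacts between the focal TME phenotype
      and any TME cell.
    * ``tme_heterotypic`` (epithelial) — contacts between any TME cell and
      the focal epithelial phenotype.

    Each unordered edge counts once. An absent or unknown focal phenotype
    yields 0 (with a warning when unknown), mirroring the proliferative-
    fraction convention for absent phenotypes.
    """
    if flavour not in FLAVOURS:
        raise ValueError(f"unknown flavour {flavour!r}")
    if focal_phenotype not in registry.all_phenotypes:
        warnings.warn(f"focal phenotype {focal_phenotype!r} not in registry; metric is 0")
        return 0.0
    n_total = len(cells)
    if n_total == 0:
        return 0.0
    e = _edge_frame(cells, edges)
    if flavour == "epithelial_homotypic":
        q = (
            ((e.ph_a == focal_phenotype) & (e.comp_b == EPITHELIAL))
            | ((e.ph_b == focal_phenotype) & (e.comp_a == EPITHELIAL))
        )
    elif flavour == "epithelial_heterotypic":
        q = (
            ((e.comp_a == EPITHELIAL) & (e.ph_b == focal_phenotype))
            | ((e.comp_b == EPITHELIAL) & (e.ph_a == focal_phenotype))
        )
    elif flavour == "tme_homotypic":
        q = (
            ((e.ph_a == focal_phenotype) & (e.comp_b == TME))
            | ((e.ph_b == focal_phenotype) & (e.comp_a == TME))
        )
    else:  # tme_heterotypic
        q = (
            ((e.comp_a == TME) & (e.ph_b == focal_phenotype))
            | ((e.comp_b == TME) & (e.ph_a == focal_phenotype))
        )
    return float(q.sum()) / n_total


def interaction_metrics_all(
    cells: pd.DataFrame,
    edges: Iterable[tuple[int, int]],
    registry: PhenotypeRegistry,
) -> tuple[pd.Series, pd.Series]:
    """All heterotypic and homotypic metrics for a tumour, vectorized.

    Returns (heterotypic, homotypic) Series indexed by focal phenotype.
    Heterotypic focal phenotypes span both compartments: a TME focal
    phenotype gives the epithelial-heterotypic metric, an epithelial focal
    phenotype the TME-heterotypic one; likewise homotypic metrics use the
    focal phenotype's own compartment perspective.
    """
    phenos = list(registry.all_phenotypes)
    het = pd.Series(0.0, index=phenos)
    hom = pd.Series(0.0, index=phenos)
    n_total = len(cells)
    edges = list(edges)
    if n_total == 0 or not edges:
        return het, hom
    e = _edge_frame(cells, edges)

    both_epi = (e.comp_a == EPITHELIAL) & (e.comp_b == EPITHELIAL)
    both_tme = (e.comp_a == TME) & (e.comp_b == TME)
    mixed = ~both_epi & ~both_tme & e.comp_a.notna() & e.comp_b.notna()

    # homotypic: edges within a compartment where focal ∈ {ph_a, ph_b}
    for mask in (both_epi, both_tme):
        sub = e[mask]
        if sub.empty:
            continue
        ca = sub.ph_a.value_counts()
        cb = sub.ph_b.value_counts()
        cboth = sub[sub.ph_a == sub.ph_b].ph_a.value_counts()
        tot = ca.add(cb, fill_value=0).sub(cboth, fill_value=0)
        hom = hom.add(tot.reindex(phenos).fillna(0.0), fill_value=0.0)

    # heterotypic: epithelial–TME edges, attributed to each endpoint's phenotype
    sub = e[mixed]
    if not sub.empty:
        a_is_epi = sub.comp_a == EPITHELIAL
        epi_ph = sub.ph_a.where(a_is_epi, sub.ph_b)
        tme_ph = sub.ph_b.where(a_is_epi, sub.ph_a)
        het = het.add(tme_ph.value_counts().reindex(phenos).fillna(0.0), fill_value=0.0)
        het = het.add(epi_ph.value_counts().reindex(phenos).fillna(0.0), fill_value=0.0)

    return het / n_total, hom / n_total


def proliferative_fractions(
    cells: pd.DataFrame, phenotypes: Sequence[str]
) -> pd.Series:
    """Fraction of Ki67⁺ cells per phenotype; absent phenotypes get 0."""
    out = pd.Series(0.0, index=list(phenotypes), name="proliferative_fraction")
    if len(cells) == 0:
        return out
    grp = cells.groupby("phenotype", observed=True)["ki67_positive"].mean()
    for p in phenotypes:
        if p in grp.index:
            out[p] = float(grp[p])
    return out


def feature_name(family: str, phenotype: str, timepoint: str) -> str:
    return f"{family}__{phenotype}__{timepoint}"


def feature_metadata(
    registry: PhenotypeRegistry, timepoints: Sequence[str]
) -> pd.DataFrame:
    """Column metadata for the feature table (family/perspective/phenotype/timepoint)."""
    rows = []
    for tp in timepoints:
        for family in FAMILIES:
            for p in registry.all_phenotypes:
                comp = registry.compartment_of(p)
                if family == "heterotypic":
                    # focal TME phenotype -> epithelial perspective, and vice versa
                    perspective = EPITHELIAL if comp == TME else TME
                else:
                    perspective = comp
                rows.append(
                    {
                        "column": feature_name(family, p, tp),
                        "family": family,
                        "perspective": perspective,
                        "phenotype": p,
                        "timepoint": tp,
                    }
                )
    return pd.DataFrame(rows)


def tumour_timepoint_features(
    cell_tables: Mapping[str, pd.DataFrame],
    contact_graphs: Mapping[str, ContactGraph],
    image_ids: Sequence[str],
    registry: PhenotypeRegistry,
) -> dict[str, float]:
    """Features for one tumour×timepoint, pooling its images.

    Cell counts and contact edges are pooled across images; tissue areas
    are convex hulls computed per image and summed (regions of interest
    are spatially disjoint, so a cross-image hull would fabricate area).
    """
    tables = []
    pooled_edges: list[tuple[int, int]] = []
    area = 0.0
    area_ok = True
    offset = 0
    for img in image_ids:
        t = cell_tables[img]
        a = tissue_area_convex_hull(t[["x_um", "y_um"]].to_numpy())
        if np.isnan(a):
            area_ok = False
        else:
            area += a
        t2 = t.copy()
        t2["cell_id"] = t2["cell_id"].to_numpy() + offset
        g = contact_graphs.get(img)
        if g is not None:
            pooled_edges.extend((a_ + offset, b_ + offset) for a_, b_ in g.edges)
        offset += int(t["cell_id"].max()) + 1 if len(t) else 0
        tables.append(t2)
    cells = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["cell_id", "phenotype", "compartment", "ki67_positive"]
    )
    phenos = registry.all_phenotypes
    dens = phenotype_densities(cells, area if area_ok and area > 0 else float("nan"), phenos)
    het, hom = interaction_metrics_all(cells, pooled_edges, registry)
    prolif = proliferative_fractions(cells, phenos)
    out: dict[str, float] = {}
    for p in phenos:
        out[("density", p)] = float(dens[p])
        out[("heterotypic", p)] = float(het[p])
        out[("homotypic", p)] = float(hom[p])
        out[("proliferative_fraction", p)] = float(prolif[p])
    return out


def build_feature_table(
    cell_tables: Mapping[str, pd.DataFrame],
    contact_graphs: Mapping[str, ContactGraph],
    image_meta: pd.DataFrame,
    registry: PhenotypeRegistry,
    timepoints: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the tumour × feature matrix.

    ``image_meta`` maps image_id → (tumour_id, timepoint). Returns the
    wide feature table (one row per tumour, ``4*(E+T)`` columns per
    timepoint) and its column-metadata frame. Tumours missing a timepoint
    get NaN for that timepoint's columns.
    """
    meta = feature_metadata(registry, timepoints)
    required = {"image_id", "tumour_id", "timepoint"}
    if not required <= set(image_meta.columns):
        raise ValueError(f"image_meta requires columns {sorted(required)}")
    dup = image_meta.duplicated("image_id")
    if dup.any():
        raise ValueError(
            f"duplicate image ids: {image_meta.loc[dup, 'image_id'].tolist()}"
        )
    tumours = list(dict.fromkeys(image_meta["tumour_id"]))
    rows = {}
    for tum in tumours:
        row: dict[str, float] = {}
        for tp in timepoints:
            imgs = image_meta.query("tumour_id == @tum and timepoint == @tp")[
                "image_id"
            ].tolist()
            if not imgs:
                for fam in FAMILIES:
                    for p in registry.all_phenotypes:
                        row[feature_name(fam, p, tp)] = np.nan
                continue
            vals = tumour_timepoint_features(
                cell_tables, contact_graphs, imgs, registry
            )
            for (fam, p), v in vals.items():
                row[feature_name(fam, p, tp)] = v
        rows[tum] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[meta["column"].tolist()]
    table.index.name = "tumour_id"
    return table, meta
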