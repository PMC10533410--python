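"""Feature derivation: mask contact extraction, hull areas, densities,
the four interaction-metric flavours and the assembled feature table."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_cells
from icbspatial.features import (
    ContactGraph,
    build_feature_table,
    contacts_from_label_mask,
    feature_metadata,
    interaction_metric,
    interaction_metrics_all,
    phenotype_densities,
    proliferative_fractions,
    tissue_area_convex_hull,
)
from icbspatial.registry import EPITHELIAL, TME, PhenotypeRegistry, make_generic_registry


def pixel_scan_contacts(img):
    """Exhaustive per-pixel 8-neighbourhood oracle (pure python)."""
    rows = img.tolist()
    H, W = img.shape
    edges = set()
    for i in range(H):
        for j in range(W):
            v = rows[i][j]
            if v == 0:
                continue
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W:
                        w = rows[ii][jj]
                        if w != 0 and w != v:
                            edges.add((min(v, w), max(v, w)))
    return edges


class TestMaskContacts:
    def test_background_gap_breaks_contact(self):
        img = np.zeros((3, 5), dtype=np.uint16)
        img[:, 0:2] = 1
        img[:, 3:5] = 2
        assert len(contacts_from_label_mask(img)) == 0

    def test_diagonal_corner_counts_as_contact(self):
        img = np.zeros((2, 2), dtype=np.uint16)
        img[0, 0] = 1
        img[1, 1] = 2
        assert contacts_from_label_mask(img).edges == frozenset({(1, 2)})

    def test_non_integer_image_raises(self):
        with pytest.raises(ValueError, match="integer"):
            contacts_from_label_mask(np.zeros((4, 4), dtype=float))

    def test_voronoi_mask_matches_pixel_scan_oracle(self, rng):
        from icbspatial.simulate import render_label_mask

        xy = rng.uniform(5, 195, size=(200, 2))
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, 201),
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "area_um2": rng.uniform(60, 150, 200),
            }
        )
        img = render_label_mask(cells, pixel_size_um=1.0, window_um=200.0)
        assert set(contacts_from_label_mask(img).edges) == pixel_scan_contacts(img)


class TestHullArea:
    def test_unit_square_mm2(self):
        pts = np.array([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], float)
        assert tissue_area_convex_hull(pts) == pytest.approx(1.0)

    def test_collinear_cells_give_missing(self):
        pts = np.array([[0, 0], [10, 10], [20, 20]], float)
        assert np.isnan(tissue_area_convex_hull(pts))

    def test_fewer_than_three_cells_missing(self):
        assert np.isnan(tissue_area_convex_hull(np.array([[0, 0], [5, 5]], float)))

    def test_hull_inside_known_triangle(self, rng):
        tri = np.array([[0, 0], [1000, 0], [0, 1000]], float)
        w = rng.dirichlet(np.ones(3), size=100)
        pts = w @ tri
        area = tissue_area_convex_hull(pts)
        tri_area = 0.5  # mm²
        assert area <= tri_area + 1e-12
        # including the vertices reaches the triangle area exactly (shoelace)
        assert tissue_area_convex_hull(np.vstack([pts, tri])) == pytest.approx(tri_area)


class TestDensities:
    def test_simple_count_over_area(self):
        cells = toy_cells([(1, "P", EPITHELIAL)] * 4)
        d = phenotype_densities(cells, 1.0, ["P", "Q"])
        assert d["P"] == 4.0 and d["Q"] == 0.0

    def test_pooled_images_sum_counts_and_areas(self):
        # two images: areas 0.5 + 0.25 mm², counts 3 + 3 → 6 / 0.75 = 8
        cells = toy_cells([(i, "P", EPITHELIAL) for i in range(6)])
        d = phenotype_densities(cells, 0.5 + 0.25, ["P"])
        assert d["P"] == pytest.approx(8.0)

    def test_density_invariant_to_rigid_motion(self, rng):
        xy = rng.uniform(0, 500, size=(50, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = xy @ R.T + np.array([123.0, -77.0])
        assert tissue_area_convex_hull(xy) == pytest.approx(
            tissue_area_convex_hull(moved)
        )


REG4 = PhenotypeRegistry(
    epithelial=("E1", "E2"), tme=("T1", "T2"), stromal=(), t_cells=("T1",)
)


class TestInteractionMetrics:
    def toy(self):
        cells = toy_cells(
            [(1, "E1", EPITHELIAL), (2, "E2", EPITHELIAL), (3, "T1", TME), (4, "T2", TME)]
        )
        edges = [(1, 2), (1, 3), (2, 3), (3, 4)]
        return cells, edges

    @pytest.mark.parametrize(
        "flavour,focal,expected",
        [
            ("epithelial_homotypic", "E1", 0.25),  # edge A–B
            ("epithelial_heterotypic", "T1", 0.5),  # edges A–C, B–C
            ("tme_homotypic", "T1", 0.25),  # edge C–D
            ("tme_heterotypic", "E1", 0.25),  # edge A–C only
        ],
    )
    def test_toy_graph_values(self, flavour, focal, expected):
        cells, edges = self.toy()
        assert interaction_metric(cells, edges, flavour, focal, REG4) == expected

    def test_no_edges_all_zero(self):
        cells, _ = self.toy()
        for fl, focal in [("epithelial_homotypic", "E1"), ("tme_heterotypic", "E2")]:
            assert interaction_metric(cells, [], fl, focal, REG4) == 0.0

    def test_pure_homotypic_graph_is_k_over_n(self):
        cells = toy_cells([(i, "E1", EPITHELIAL) for i in range(1, 7)])
        edges = [(1, 2), (3, 4), (5, 6), (1, 3)]
        m = interaction_metric(cells, edges, "epithelial_homotypic", "E1", REG4)
        assert m == pytest.approx(4 / 6)

    def test_unknown_focal_warns_and_is_zero(self):
        cells, edges = self.toy()
        with pytest.warns(UserWarning):
            assert interaction_metric(cells, edges, "tme_homotypic", "T9", REG4) == 0.0

    def test_bulk_metrics_match_single_calls(self, rng):
        cells, edges = _random_graph(rng, 120)
        het, hom = interaction_metrics_all(cells, edges, REG4)
        for p in REG4.all_phenotypes:
            comp = REG4.compartment_of(p)
            het_fl = "epithelial_heterotypic" if comp == TME else "tme_heterotypic"
            hom_fl = "epithelial_homotypic" if comp == EPITHELIAL else "tme_homotypic"
            assert het[p] == pytest.approx(
                interaction_metric(cells, edges, het_fl, p, REG4)
            )
            assert hom[p] == pytest.approx(
                interaction_metric(cells, edges, hom_fl, p, REG4)
            )

    def test_heterotypic_sum_identity(self, rng):
        """Σ over TME focal phenotypes of epithelial-heterotypic × n equals
        the number of epithelial–TME edges (each has one TME endpoint)."""
        cells, edges = _random_graph(rng, 200)
        het, _ = interaction_metrics_all(cells, edges, REG4)
        ph = dict(zip(cells.cell_id, cells.phenotype))
        epi = set(REG4.epithelial)
        mixed = sum(1 for a, b in edges if (ph[a] in epi) != (ph[b] in epi))
        total_from_tme_focals = sum(het[p] for p in REG4.tme) * len(cells)
        assert total_from_tme_focals == pytest.approx(mixed)


def _random_graph(rng, n):
    phenos = ["E1", "E2", "T1", "T2"]
    labels = rng.choice(phenos, n)
    cells = toy_cells(
        [
            (i + 1, labels[i], EPITHELIAL if labels[i].startswith("E") else TME)
            for i in range(n)
        ]
    )
    n_edges = int(rng.integers(n, 3 * n))
    edges = set()
    while len(edges) < n_edges:
        a, b = rng.integers(1, n + 1, 2)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return cells, sorted(edges)


class TestProliferativeFractions:
    def test_absent_phenotype_is_zero(self):
        cells = toy_cells([(1, "E1", EPITHELIAL, True)])
        f = proliferative_fractions(cells, ["E1", "E2"])
        assert f["E2"] == 0.0

    def test_all_positive_is_one(self):
        cells = toy_cells([(i, "E1", EPITHELIAL, True) for i in range(5)])
        assert proliferative_fractions(cells, ["E1"])["E1"] == 1.0

    def test_count_oracle(self):
        recs = [(i, "E1", EPITHELIAL, i < 3) for i in range(12)]
        assert proliferative_fractions(toy_cells(recs), ["E1"])["E1"] == 0.25

    def test_fractions_bounded(self, small_cohort):
        reg = small_cohort.config.registry
        for cells in small_cohort.cells.values():
            f = proliferative_fractions(cells, reg.all_phenotypes)
            assert ((f >= 0) & (f <= 1)).all()


class TestFeatureTable:
    def test_default_registry_counts(self, small_cohort):
        c = small_cohort
        reg = c.config.registry
        tbl, meta = build_feature_table(
            c.cells, c.contacts, c.images, reg, ("baseline",)
        )
        assert tbl.shape[1] == 148
        tbl2, _ = build_feature_table(
            c.cells, c.contacts, c.images, reg, ("baseline", "on_treatment")
        )
        assert tbl2.shape[1] == 296

    def test_minimal_registry_column_formula(self, small_registry):
        reg = make_generic_registry(1, 1)
        meta = feature_metadata(reg, ("baseline",))
        assert len(meta) == 8  # 4 families × (1 epithelial + 1 TME)

    def test_duplicate_image_rows_raise(self, small_cohort):
        c = small_cohort
        bad = pd.concat([c.images, c.images.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(c.cells, c.contacts, bad, c.config.registry, ("baseline",))

    def test_missing_timepoint_yields_nan(self, small_cohort):
        c = small_cohort
        imgs = c.images[c.images["timepoint"] == "baseline"]
        tbl, _ = build_feature_table(
            c.cells, c.contacts, imgs, c.config.registry,
            ("baseline", "on_treatment"),
        )
        on_cols = [col for col in tbl.columns if col.endswith("on_treatment")]
        assert tbl[on_cols].isna().all().all()

    def test_values_nonnegative(self, small_cohort):
        c = small_cohort
        tbl, _ = build_feature_table(
            c.cells, c.contacts, c.images, c.config.registry, ("baseline",)
        )
        assert (tbl.fillna(0) >= 0).all().all()
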