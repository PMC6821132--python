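"""Voronoi regularity, engulfment classification, lysosome index,
coverage, thresholding, and debris localization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from astroclear import spatial_quant as sq
from astroclear.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
)
from astroclear.synthetic_data import generate_mosaic, generate_quant_scene


WINDOW = (0.0, 0.0, 1.0, 1.0)


def jittered_lattice(n_side, jitter, seed=0):
    rng = np.random.default_rng(seed)
    xs = (np.arange(n_side) + 0.5) / n_side
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts + rng.normal(0.0, jitter, pts.shape)


class TestVoronoiRegularity:
    def test_perfect_lattice_is_degenerate(self):
        analysis = sq.voronoi_regularity(jittered_lattice(12, 0.0), WINDOW)
        assert analysis.degenerate
        assert analysis.regularity_index is None

    def test_index_grows_as_jitter_vanishes(self):
        ri_small = sq.voronoi_regularity(jittered_lattice(12, 0.002, seed=1), WINDOW)
        ri_big = sq.voronoi_regularity(jittered_lattice(12, 0.02, seed=1), WINDOW)
        assert ri_small.regularity_index > ri_big.regularity_index

    def test_random_pattern_within_monte_carlo_band(self):
        # oracle: empirical distribution of the index over 200 independent
        # binomial patterns brackets the value for a fresh pattern
        indices = [
            sq.voronoi_regularity(
                generate_mosaic(300, 0.0, WINDOW, seed=1000 + s), WINDOW
            ).regularity_index
            for s in range(200)
        ]
        lo, hi = np.quantile(indices, [0.005, 0.995])
        fresh = sq.voronoi_regularity(
            generate_mosaic(300, 0.0, WINDOW, seed=7), WINDOW
        ).regularity_index
        assert lo <= fresh <= hi

    def test_repulsion_raises_regularity(self):
        # paired simulation over 50 seeds: hard-core index strictly above random
        diffs = []
        for s in range(50):
            rnd = generate_mosaic(300, 0.0, WINDOW, seed=s)
            hc = generate_mosaic(300, 0.04, WINDOW, seed=10_000 + s)
            diffs.append(
                sq.voronoi_regularity(hc, WINDOW).regularity_index
                - sq.voronoi_regularity(rnd, WINDOW).regularity_index
            )
        assert np.mean(diffs) > 0
        assert np.min(diffs) > 0  # strictly larger in every pair at this n

    def test_scale_invariance(self):
        pts = generate_mosaic(300, 0.0, WINDOW, seed=3)
        a = sq.voronoi_regularity(pts, WINDOW).regularity_index
        b = sq.voronoi_regularity(pts * 7.5, tuple(7.5 * np.array(WINDOW))).regularity_index
        assert a == pytest.approx(b, rel=1e-9)

    def test_too_few_interior_polygons(self):
        with pytest.raises(InsufficientDataError):
            sq.voronoi_regularity(generate_mosaic(12, 0.0, WINDOW, seed=4), WINDOW)


class TestClassifyEngulfment:
    @pytest.mark.parametrize(
        "fraction,label",
        [
            (0.0, "none"),
            (0.01, "touched"),
            (0.49, "touched"),
            (0.5, "partially_enveloped"),
            (0.9, "partially_enveloped"),
            (1.0 - sq.FULL_ENVELOPMENT_EPSILON, "fully_enveloped"),
            (1.0, "fully_enveloped"),
        ],
    )
    def test_boundary_mapping(self, fraction, label):
        assert sq.classify_engulfment(fraction) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            sq.classify_engulfment(1.2)
        with pytest.raises(DomainError):
            sq.classify_engulfment(-0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(f=hst.floats(0.0, 1.0))
    def test_partition_and_monotonicity(self, f):
        """Every fraction maps to exactly one label, and labels are ordered
        monotonically in the fraction."""
        label = sq.classify_engulfment(f)
        assert label in sq.ENGULFMENT_LABELS
        rank = sq.ENGULFMENT_LABELS.index(label)
        rank_higher = sq.ENGULFMENT_LABELS.index(sq.classify_engulfment(min(f + 0.1, 1.0)))
        assert rank_higher >= rank


class TestLysosomeIndexAndNormalization:
    def test_pixels_per_cell(self):
        assert sq.lysosome_index(0, 10) == 0.0
        assert sq.lysosome_index(5000, 10) == 500.0

    def test_zero_cells_undefined(self):
        with pytest.raises(DegenerateInputError):
            sq.lysosome_index(100, 0)

    def test_scene_truth_exact(self, puncta_scene):
        idx = sq.lysosome_index(
            int(puncta_scene.marker_mask.sum()), puncta_scene.truths["n_microglia"]
        )
        expected = puncta_scene.truths["marker_pixels"] / puncta_scene.truths["n_microglia"]
        assert idx == expected

    def test_normalize_series_examples(self):
        assert np.allclose(sq.normalize_series([2.0, 4.0]), [50.0, 100.0])
        assert np.allclose(sq.normalize_series([3.0, 3.0]), [100.0, 100.0])

    def test_normalize_preserves_order_and_is_idempotent(self):
        vals = [3.0, 9.0, 1.0, 7.0]
        out = sq.normalize_series(vals)
        assert np.all(np.argsort(out) == np.argsort(vals))
        assert np.allclose(sq.normalize_series(out), out)

    def test_all_zero_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            sq.normalize_series([0.0, 0.0])


class TestNetworkCoverage:
    def test_full_and_half_masks(self):
        assert sq.network_coverage(np.ones((10, 10), dtype=bool)) == 100.0
        half = np.zeros((10, 10), dtype=bool)
        half[:5] = True
        assert sq.network_coverage(half) == 50.0

    def test_complement_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((64, 64)) > 0.7
        assert sq.network_coverage(mask) + sq.negative_space_percent(mask) == 100.0

    def test_arbor_scene_truth(self, arbor_scene):
        measured = sq.network_coverage(arbor_scene.marker_mask)
        assert measured == pytest.approx(arbor_scene.truths["coverage_percent"], abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            sq.network_coverage(np.empty((0, 0), dtype=bool))


class TestAutoThreshold:
    def test_bimodal_image_exact_foreground(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[8:16, 8:16] = 255
        for method in ("li", "triangle"):
            fg = sq.auto_threshold(img, method)
            assert np.array_equal(fg, img == 255)

    def test_noisy_blob_area_within_five_percent(self):
        rng = np.random.default_rng(1)
        img = np.full((128, 128), 20.0)
        rr, cc = np.ogrid[:128, :128]
        blob = (rr - 64) ** 2 + (cc - 64) ** 2 < 30**2
        img[blob] = 200.0
        img += rng.normal(0.0, 5.0, img.shape)
        fg = sq.auto_threshold(img, "li")
        assert fg.sum() == pytest.approx(blob.sum(), rel=0.05)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            sq.auto_threshold(np.full((16, 16), 7.0))

    def test_unknown_method_rejected(self):
        with pytest.raises(DomainError):
            sq.auto_threshold(np.arange(16.0).reshape(4, 4), "otsu")


class TestDebrisLocalization:
    def test_all_in_one_class(self):
        scene = generate_quant_scene(
            seed=1, n_debris=10,
            debris_class_probs={"microglia": 1.0, "astrocyte": 0.0, "unassigned": 0.0},
        )
        fr = sq.debris_localization(scene.debris_points, scene.class_masks)
        assert fr["microglia"] == 1.0
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_straddling_punctum_not_enclosed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, :10] = True
        rr = np.array([5, 5, 5])
        cc = np.array([8, 9, 10])  # last pixel outside the mask
        fr = sq.debris_localization([(rr, cc)], {"microglia": mask})
        assert fr["microglia"] == 0.0
        assert fr["unassigned"] == 1.0
        # centroid mode assigns it, since the centroid pixel is inside
        fr_c = sq.debris_localization([(rr, cc)], {"microglia": mask}, mode="centroid")
        assert fr_c["microglia"] == 1.0

    def test_mutant_like_scene_matches_truth_exactly(self):
        # majority of debris inside astrocytes, as when microglia are absent
        scene = generate_quant_scene(
            seed=9, n_debris=50,
            debris_class_probs={"microglia": 0.06, "astrocyte": 0.80, "unassigned": 0.14},
        )
        fr = sq.debris_localization(scene.debris_points, scene.class_masks)
        truth = scene.truths["debris_fractions"]
        for cls, val in truth.items():
            assert fr.get(cls, 0.0) == val
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_empty_debris_rejected(self):
        with pytest.raises(InsufficientDataError):
            sq.debris_localization([], {"microglia": np.zeros((4, 4), dtype=bool)})


def test_normalize_by_litter_control():
    vals = [10.0, 12.0, 20.0, 5.0, 6.0, 9.0]
    litters = ["a", "a", "a", "b", "b", "b"]
    ctrl = [True, True, False, True, False, False]
    out = sq.normalize_by_litter_control(vals, litters, ctrl)
    assert np.allclose(out[:3], [10 / 11, 12 / 11, 20 / 11])
    assert np.allclose(out[3:], [1.0, 1.2, 1.8])
    with pytest.raises(InsufficientDataError):
        sq.normalize_by_litter_control([1.0], ["x"], [False])
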