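"""Canopy phenotypes: segmentation, histograms, percentiles, biomass."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stereocanopy as sc
from stereocanopy.traits import BiomassInputs, biomass, canopy_height, coverage


def nearest_rank_oracle(heights, top_fraction):
    """Brute force: walk the sorted multiset until 1 - top_fraction of the
    weight is at or below the candidate."""
    h = sorted(heights)
    n = len(h)
    need = (1.0 - top_fraction) * n
    count = 0
    for i, v in enumerate(h):
        count += 1
        if count >= need:
            return v
    return h[-1]


class TestSegmentation:
    def test_matches_truth_mask(self, mixed_scene):
        _, truth, pair = mixed_scene
        mask = sc.segment_plant_pixels(pair.left)
        inter = (mask & truth.plant_mask).sum()
        union = (mask | truth.plant_mask).sum()
        assert inter / union >= 0.95

    def test_all_ground_scene_empty_mask(self, flat_ground_scene):
        _, _, pair = flat_ground_scene
        assert not sc.segment_plant_pixels(pair.left).any()

    def test_all_canopy_scene_full_mask(self, slab_scene):
        _, _, pair = slab_scene
        assert sc.segment_plant_pixels(pair.left).mean() > 0.99

    def test_grayscale_input_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            sc.segment_plant_pixels(np.zeros((10, 10), dtype=np.uint8))


class TestHeightHistogram:
    def test_single_bin_holds_all(self):
        hmap = np.full((10, 10), 505.0)  # mm -> 50.5 cm
        hist = sc.height_histogram(hmap, np.ones((10, 10), bool))
        assert hist.total == 100
        assert hist.weights[50] == 100
        assert hist.weights.sum() == hist.total

    def test_empty_mask_flagged(self):
        hist = sc.height_histogram(np.zeros((5, 5)), np.zeros((5, 5), bool))
        assert hist.total == 0
        assert hist.meta.get("empty")

    def test_spike_layer_is_minor_mode(self, rig):
        spec = sc.SceneSpec(
            shape=(240, 320),
            coverage=0.8,
            canopy_family="slab",
            canopy_mode_mm=500.0,
            spike_fraction=0.015,
            spike_offset_mm=150.0,
            seed=9,
        )
        truth = sc.generate_scene(spec)
        hist = sc.height_histogram(truth.height_mm, truth.plant_mask)
        assert hist.weights[50] > 0 and hist.weights[65] > 0
        minor = hist.weights[55:].argmax() + 55
        assert minor == 65  # minor mode at the spike height
        assert hist.weights[65] == pytest.approx(0.015 * hist.total, rel=0.05)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            sc.height_histogram(np.zeros((5, 5)), np.ones((5, 5), bool), bin_width_cm=0.0)


class TestCanopyHeight:
    def test_hundred_pixel_example(self):
        heights = np.arange(1.0, 101.0)  # 1..100 cm
        assert canopy_height(heights, 0.02) == 98.0
        assert canopy_height(heights, 0.50) == 50.0

    @settings(deadline=None, max_examples=40)
    @given(
        n=st.integers(5, 400),
        top=st.floats(0.01, 0.6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_oracle(self, n, top, seed):
        h = np.random.default_rng(seed).uniform(0, 120, n)
        assert canopy_height(h, top) == nearest_rank_oracle(h, top)

    def test_sparse_spikes_excluded_from_top2(self):
        # flat canopy at 50 cm plus 1.5% spikes at 65 cm
        heights = np.concatenate([np.full(985, 50.0), np.full(15, 65.0)])
        assert canopy_height(heights, 0.02) == 50.0

    def test_monotone_in_threshold(self, mixed_scene):
        _, truth, _ = mixed_scene
        h = truth.height_mm[truth.plant_mask] / 10.0
        assert canopy_height(h, 0.50) <= canopy_height(h, 0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            canopy_height(np.array([]), 0.02)

    def test_histogram_quantile_agrees_within_bin(self, mixed_scene):
        _, truth, _ = mixed_scene
        h = truth.height_mm[truth.plant_mask] / 10.0
        hist = sc.height_histogram(truth.height_mm, truth.plant_mask)
        assert abs(canopy_height(hist, 0.02) - canopy_height(h, 0.02)) <= 1.0


class TestSpikeRobustness:
    """Spike layers move the median almost nothing, and move the top-2%
    threshold only when they exceed the 2% allowance."""

    @staticmethod
    def _scene(spike_fraction, seed=21):
        spec = sc.SceneSpec(
            shape=(240, 320),
            coverage=0.8,
            canopy_family="slab",
            canopy_mode_mm=500.0,
            spike_fraction=spike_fraction,
            spike_offset_mm=150.0,
            seed=seed,
        )
        truth = sc.generate_scene(spec)
        return truth.height_mm[truth.plant_mask] / 10.0

    def test_top2_stable_below_allowance(self):
        base = canopy_height(self._scene(0.0), 0.02)
        with_spikes = canopy_height(self._scene(0.015), 0.02)
        assert abs(with_spikes - base) < 1.0

    def test_top2_jumps_above_allowance(self):
        tall = canopy_height(self._scene(0.05), 0.02)
        assert tall == pytest.approx(65.0, abs=1.0)

    def test_median_stable_at_ten_percent_spikes(self):
        base = canopy_height(self._scene(0.0), 0.50)
        with_spikes = canopy_height(self._scene(0.10), 0.50)
        assert abs(with_spikes - base) < 0.5


class TestNormalization:
    def test_ground_depth_uniform_footprint(self, rig_500px):
        hmap = np.zeros((10, 10))
        hist = sc.normalize_histogram(hmap, np.ones((10, 10), bool), rig_500px)
        assert hist.unit == "area_mm2"
        assert hist.total == pytest.approx(100 * 0.16, rel=1e-3)

    def test_half_depth_quarter_footprint(self, rig_500px):
        hmap = np.full((10, 10), 950.0)
        hist = sc.normalize_histogram(hmap, np.ones((10, 10), bool), rig_500px)
        assert hist.total == pytest.approx(100 * 0.04, rel=1e-3)

    def test_camera_height_invariance(self):
        """The same physical slab imaged from 190 cm and 150 cm: area totals
        agree within 2%, pixel counts differ by the footprint ratio."""
        slab_mm, window_mm = 500.0, (600.0, 800.0)
        totals_px, totals_area = [], []
        for H in (1900.0, 1500.0):
            rig = sc.CameraRig(18.0, 200.0, H, sc.default_rig().pixel_pitch)
            # pixels imaging the slab: window size over the footprint at
            # the slab's depth, not at the ground
            foot = (H - slab_mm) * rig.pixel_pitch / rig.focal_length
            n_r, n_c = round(window_mm[0] / foot), round(window_mm[1] / foot)
            hmap = np.full((n_r, n_c), slab_mm)
            mask = np.ones((n_r, n_c), bool)
            hist_px = sc.height_histogram(hmap, mask)
            hist_area = sc.normalize_histogram(hmap, mask, rig)
            totals_px.append(hist_px.total)
            totals_area.append(hist_area.total)
        assert abs(totals_area[0] / totals_area[1] - 1.0) < 0.02
        assert abs(totals_px[0] / totals_px[1] - 1.0) > 0.10

    def test_ranking_preserved_for_constant_depth(self, rig_500px):
        rng = np.random.default_rng(4)
        hmap = rng.choice([100.0, 200.0, 300.0], (40, 40), p=[0.5, 0.3, 0.2])
        mask = np.ones((40, 40), bool)
        px = sc.height_histogram(hmap, mask)
        # per-bin ranking must survive unit conversion when all pixels in a
        # bin share one depth
        ar = sc.normalize_histogram(hmap, mask, rig_500px)
        n = min(px.weights.size, ar.weights.size)
        assert np.array_equal(np.argsort(px.weights[:n]), np.argsort(ar.weights[:n]))


class TestBiomass:
    @staticmethod
    def _uniform_inputs(A=200.0, T=40, rho=1.5):
        edges = np.arange(T + 1.0)
        return BiomassInputs(edges, {"all": np.full(T, A)}, {"all": rho})

    def test_uniform_canopy_equals_naive_block(self):
        # a uniform distribution is the one case where rho*A*T is exact
        A, T, rho = 200.0, 40, 1.5
        assert biomass(self._uniform_inputs(A, T, rho)) == pytest.approx(rho * A * T)

    def test_nonuniform_below_naive_block(self):
        rng = np.random.default_rng(8)
        A, T, rho = 200.0, 40, 1.5
        a = rng.uniform(0, A, T)
        a[3] = A / 2  # ensure strictly below the envelope somewhere
        m = biomass(BiomassInputs(np.arange(T + 1.0), {"all": a}, {"all": rho}))
        assert m < rho * A * T

    def test_three_tissue_toy_against_quadrature(self):
        from scipy.integrate import quad

        edges = np.arange(21.0)
        a_lf = np.where(edges[:-1] < 10, 1.0, 0.0)
        a_st = np.full(20, 2.0)
        inputs = BiomassInputs(
            edges,
            {"leaf": a_lf, "stem": a_st, "spike": np.zeros(20)},
            {"leaf": 1.0, "stem": 0.5, "spike": 1.0},
        )
        oracle = (
            1.0 * quad(lambda h: 1.0 if h < 10 else 0.0, 0, 20)[0]
            + 0.5 * quad(lambda h: 2.0, 0, 20)[0]
        )
        assert biomass(inputs) == pytest.approx(oracle) == pytest.approx(30.0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            BiomassInputs(np.arange(3.0), {"all": np.ones(2)}, {"all": -1.0})

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            BiomassInputs(np.arange(3.0), {"all": np.array([1.0, -2.0])}, {"all": 1.0})


class TestCoverage:
    def test_empty_histogram_zero(self):
        hist = sc.height_histogram(np.zeros((4, 4)), np.zeros((4, 4), bool))
        assert coverage(hist) == 0

    def test_pixel_and_area_totals(self, rig_500px):
        hmap = np.zeros((10, 10))
        mask = np.ones((10, 10), bool)
        assert coverage(sc.height_histogram(hmap, mask)) == 100
        assert coverage(sc.normalize_histogram(hmap, mask, rig_500px)) == pytest.approx(
            16.0, rel=1e-3
        )

    def test_doubling_coverage_fraction_doubles_area(self, rig):
        totals = []
        for cov in (0.3, 0.6):
            spec = sc.SceneSpec(shape=(240, 320), coverage=cov, seed=13)
            truth = sc.generate_scene(spec)
            hist = sc.normalize_histogram(truth.height_mm, truth.plant_mask, rig)
            totals.append(hist.total)
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.05)


class TestExtractTraits:
    def test_traits_from_truth(self, mixed_scene, rig):
        _, truth, _ = mixed_scene
        traits = sc.extract_traits(truth.height_mm, truth.plant_mask, rig)
        h = truth.height_mm[truth.plant_mask] / 10.0
        assert traits.canopy_height_cm == pytest.approx(canopy_height(h, 0.02), abs=0.05)
        assert traits.median_canopy_height_cm <= traits.canopy_height_cm
        assert traits.coverage_pixels == truth.plant_mask.sum()

    def test_below_ground_clamped_and_counted(self, rig):
        hmap = np.array([[-30.0, 200.0, 400.0, 600.0]])
        traits = sc.extract_traits(hmap, np.ones((1, 4), bool), rig)
        assert traits.clamped_below_ground == 1
        assert traits.median_canopy_height_cm >= 0.0

    def test_empty_mask_rejected(self, rig):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                sc.extract_traits(np.zeros((4, 4)), np.zeros((4, 4), bool), rig)
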