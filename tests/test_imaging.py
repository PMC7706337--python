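import numpy as np
import pytest
from hypothesis import given, strategies as st

from phytosense.design import CONTROL, STRESSED
from phytosense.imaging import (
    EmptyMaskError,
    PlantImageSet,
    PlantMask,
    compute_biovolume,
    compute_compactness,
    compute_green_index,
    compute_height,
    compute_nir_index,
    extract_indices,
    segment_plant,
)
from phytosense.render import BACKGROUND_RGB, GREEN_RGB, render_plant_images
from phytosense.synthetic import GeneratorConfig, simulate_latent_states


def _mask(arr):
    return PlantMask(np.asarray(arr, dtype=bool), "side0")


class TestSegmentation:
    def test_recovers_renderer_ground_truth(self, gen_config, main_design):
        states = simulate_latent_states(gen_config, main_design)
        for day in (0, 8, 16):
            iset = render_plant_images(states[-1], gen_config, day)
            for view in ("side0", "side90", "top"):
                truth = iset.truth_masks[view]
                for modality in ("rgb", "nir"):
                    m = segment_plant(iset.images[(view, modality)], modality)
                    iou = (m.mask & truth).sum() / (m.mask | truth).sum()
                    assert iou >= 0.99, (view, modality, day)

    def test_pure_background_flagged_empty(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:, :] = BACKGROUND_RGB
        assert segment_plant(img, "rgb").empty

    def test_salt_noise_removed_by_largest_component(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:, :] = BACKGROUND_RGB
        img[20:40, 20:40] = GREEN_RGB  # the plant
        img[5, 5] = GREEN_RGB          # isolated plant-coloured speck
        m = segment_plant(img, "rgb")
        assert m.area_px == 400
        assert not m.mask[5, 5]


class TestBiovolume:
    @pytest.mark.parametrize(
        "a0, a90, at, expected",
        [
            (1000, 1000, 1000, (1000 + 1000 + 3) / 3),
            (10000, 8000, 10000, (10000 + 8000 + 4) / 3),
            (0, 0, 1, 0.0),
        ],
    )
    def test_printed_expression(self, a0, a90, at, expected):
        assert compute_biovolume(a0, a90, at) == pytest.approx(expected)

    def test_zero_top_area_flagged(self):
        with pytest.warns(UserWarning, match="log term"):
            v = compute_biovolume(100, 100, 0)
        assert v == pytest.approx(200 / 3)

    def test_strictly_increasing_in_each_argument(self):
        base = compute_biovolume(500, 400, 300)
        assert compute_biovolume(501, 400, 300) > base
        assert compute_biovolume(500, 401, 300) > base
        assert compute_biovolume(500, 400, 301) > base


class TestHeight:
    def test_row_extent(self):
        m = np.zeros((80, 40), dtype=bool)
        m[10:60, 5:10] = True
        assert compute_height(_mask(m), _mask(m)) == 50

    def test_single_pixel(self):
        m = np.zeros((20, 20), dtype=bool)
        m[7, 7] = True
        assert compute_height(_mask(m), None) == 1

    def test_mean_of_two_views(self):
        m1 = np.zeros((80, 40), dtype=bool)
        m1[0:50, 5] = True
        m2 = np.zeros((80, 40), dtype=bool)
        m2[10:70, 5] = True
        assert compute_height(_mask(m1), _mask(m2)) == 55

    def test_both_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            compute_height(_mask(np.zeros((4, 4))), None)


class TestCompactness:
    def test_filled_rectangle_exactly_one(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:20, 3:17] = True
        assert compute_compactness(_mask(m)) == pytest.approx(1.0)

    def test_plus_pentomino_against_polygon_oracle(self):
        from shapely.geometry import box
        from shapely.ops import unary_union

        m = np.zeros((10, 10), dtype=bool)
        cells = [(4, 4), (3, 4), (5, 4), (4, 3), (4, 5)]
        for r, c in cells:
            m[r, c] = True
        hull = unary_union([box(c, r, c + 1, r + 1) for r, c in cells]).convex_hull
        assert compute_compactness(_mask(m)) == pytest.approx(5.0 / hull.area)

    def test_disk_more_compact_than_ring(self):
        from skimage.draw import disk as sk_disk

        full = np.zeros((64, 64), dtype=bool)
        rr, cc = sk_disk((32, 32), 15)
        full[rr, cc] = True
        ring = full.copy()
        rr, cc = sk_disk((32, 32), 9)
        ring[rr, cc] = False
        assert compute_compactness(_mask(full)) > compute_compactness(_mask(ring))

    def test_never_exceeds_one(self, rng):
        for _ in range(20):
            m = rng.random((16, 16)) > 0.6
            if m.sum() < 2:
                continue
            assert compute_compactness(_mask(m)) <= 1.0 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            compute_compactness(_mask(np.zeros((4, 4))))


class TestGreenIndex:
    def _plant(self, n_green, n_yellow):
        img = np.zeros((1, n_green + n_yellow, 3), dtype=np.uint8)
        img[0, :n_green] = (40, 160, 40)    # hue 120
        img[0, n_green:] = (210, 180, 30)   # hue 50
        mask = _mask(np.ones((1, n_green + n_yellow), dtype=bool))
        return img, mask

    def test_all_green(self):
        img, mask = self._plant(50, 0)
        assert compute_green_index(img, mask) == 1.0

    def test_mixture_fraction(self):
        img, mask = self._plant(30, 70)
        assert compute_green_index(img, mask) == pytest.approx(0.30, abs=0.02)

    def test_necrotic_brown_scores_zero(self):
        img = np.zeros((1, 40, 3), dtype=np.uint8)
        img[0, :] = (120, 70, 20)  # brown, hue ~30
        assert compute_green_index(img, _mask(np.ones((1, 40)))) == 0.0


class TestNirIndex:
    def test_uniform_intensity_maps_to_bin_center(self):
        img = np.full((10, 10), 128, dtype=np.uint8)
        assert compute_nir_index(img, _mask(np.ones((10, 10)))) == pytest.approx(129.0)

    def test_bimodal_average(self):
        img = np.zeros((2, 10), dtype=np.uint8)
        img[1, :] = 254
        assert compute_nir_index(img, _mask(np.ones((2, 10)))) == pytest.approx(128.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            compute_nir_index(np.zeros((4, 4), dtype=np.uint8), _mask(np.zeros((4, 4))))

    @given(st.integers(min_value=0, max_value=10**6))
    def test_within_half_bin_of_plain_mean(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
        value = compute_nir_index(img, _mask(np.ones((12, 12))))
        assert abs(value - img.mean()) <= 1.0


class TestExtractIndices:
    def test_control_biovolume_grows(self, main_run):
        idx = main_run["indices"]
        ctrl = idx[idx["plant_id"].str.startswith("C")]
        series = ctrl.groupby("day")["biovolume"].mean()
        assert np.all(np.diff(series.to_numpy()) > 0)

    def test_identical_side_views_give_symmetric_height(self, gen_config, main_design):
        states = simulate_latent_states(gen_config, main_design)
        iset = render_plant_images(states[0], gen_config, 6)
        clone = PlantImageSet(
            plant_id="X",
            day=6,
            images={
                ("side0", "rgb"): iset.images[("side0", "rgb")],
                ("side90", "rgb"): iset.images[("side0", "rgb")],
                ("top", "rgb"): iset.images[("top", "rgb")],
                ("side0", "nir"): iset.images[("side0", "nir")],
                ("side90", "nir"): iset.images[("side0", "nir")],
                ("top", "nir"): iset.images[("top", "nir")],
            },
        )
        rec = extract_indices(clone)
        m = segment_plant(iset.images[("side0", "rgb")], "rgb")
        rows = np.nonzero(m.mask.any(axis=1))[0]
        assert rec.height_px == rows[-1] - rows[0] + 1

    def test_chlorosis_and_hydration_gradients_recovered(self, gen_config):
        from scipy.stats import spearmanr

        from phytosense.render import render_view

        rng = np.random.default_rng(0)
        greens, nirs = [], []
        chl_grid = np.linspace(0.0, 0.45, 10)
        hyd_grid = np.linspace(0.3, 1.0, 10)
        for chl, hyd in zip(chl_grid, hyd_grid):
            rgb, nir, _ = render_view("side0", 160, 1200, 80, 1.0, chl, hyd, rng)
            m = segment_plant(rgb, "rgb")
            greens.append(compute_green_index(rgb, m))
            mn = segment_plant(nir, "nir")
            nirs.append(compute_nir_index(nir, mn))
        assert spearmanr(chl_grid, greens).statistic <= -0.95
        assert spearmanr(hyd_grid, nirs).statistic >= 0.95

    def test_missing_view_yields_missing_fields(self, gen_config, main_design):
        states = simulate_latent_states(gen_config, main_design)
        iset = render_plant_images(states[0], gen_config, 4)
        partial = PlantImageSet(
            plant_id="X",
            day=4,
            images={
                k: v for k, v in iset.images.items() if k[0] != "top"
            },
        )
        rec = extract_indices(partial)
        assert rec.biovolume is None
        assert rec.compactness is None  # default compactness view is top
        assert rec.height_px is not None
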