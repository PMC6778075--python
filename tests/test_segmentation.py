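import numpy as np
import pytest

import tilebayes as tb
from tilebayes.synthetic import default_texture_specs
from tilebayes.segmentation import (
    class_area_statistics,
    render_segmentation,
    segment_slide,
    tile_image,
)

from conftest import MODEL4


class MeanColourOracle:
    """Perfect classifier for synthetic slides: nearest class mean colour.

    Implements the same probabilistic-classifier protocol as a trained
    model (``config`` plus ``mc_posterior_batch``) but returns one-hot
    posteriors, so segmentation recovers the layout exactly.
    """

    class config:  # noqa: N801 - mimics ModelConfig attribute access
        input_size = 16
        n_classes = 2

    def __init__(self, n_classes=2):
        self.config.n_classes = n_classes
        specs = default_texture_specs(n_classes)
        self.refs = np.array(
            [(np.asarray(s.palette[0]) + np.asarray(s.palette[1])) / 2 for s in specs]
        )

    def mc_posterior_batch(self, x, T, rngs):
        means = x.reshape(len(x), -1, 3).mean(axis=1) * 255.0
        dists = ((means[:, None, :] - self.refs[None]) ** 2).sum(axis=2)
        out = np.zeros((len(x), T, len(self.refs)))
        out[np.arange(len(x)), :, dists.argmin(axis=1)] = 1.0
        return out


class TestTiling:
    def test_exact_grid_counts(self):
        slide = np.zeros((100, 100, 3), np.uint8)
        tiles = tile_image(slide, 50)
        assert len(tiles) == 4
        assert (tiles[-1].row, tiles[-1].col) == (1, 1)

    def test_partial_edge_tiles_are_dropped(self):
        slide = np.zeros((170, 120, 3), np.uint8)
        tiles = tile_image(slide, 50)
        assert len(tiles) == (170 // 50) * (120 // 50) == 6

    def test_tile_larger_than_slide_rejected(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((40, 100, 3), np.uint8), 50)

    def test_tiling_partitions_the_cropped_slide(self):
        rng = np.random.default_rng(0)
        slide = rng.integers(0, 256, size=(64, 96, 3), dtype=np.uint8)
        tiles = tile_image(slide, 32)
        rebuilt = np.zeros((64, 96, 3), np.uint8)
        for t in tiles:
            rebuilt[t.row * 32 : (t.row + 1) * 32, t.col * 32 : (t.col + 1) * 32] = t.pixels
        np.testing.assert_array_equal(rebuilt, slide)


class TestSegmentSlide:
    def test_single_class_layout_gives_constant_grid(self):
        layout = tb.SlideLayout(
            height=64, width=64, regions=(tb.Region(0, 0, 64, 64, 1),)
        )
        slide, _ = tb.generate_slide(layout, seed=0)
        seg = segment_slide(slide, MeanColourOracle(), tile_size=16, T=2, seed=0)
        assert (seg.grid == 1).all()

    def test_oracle_recovers_checkerboard_areas_exactly(self):
        layout = tb.checkerboard_layout(128, 128, 4, (0, 1))  # 32 px cells
        slide, _ = tb.generate_slide(layout, seed=1)
        seg = segment_slide(slide, MeanColourOracle(), tile_size=32, T=2, seed=0)
        areas = class_area_statistics(seg)
        assert areas[0] == pytest.approx(50.0)
        assert areas[1] == pytest.approx(50.0)

    def test_trained_model_matches_ground_truth_grid(self):
        train = tb.generate_dataset(2, 50, size=16, seed=11)
        model = tb.build_classifier(
            tb.ModelConfig(n_classes=2, input_size=16, filters=(8, 16)), seed=0
        )
        tb.train_classifier(model, train, tb.TrainConfig(epochs=12, seed=0))
        layout = tb.checkerboard_layout(160, 160, 4, (0, 1))  # 40 px cells
        slide, mask = tb.generate_slide(layout, seed=12)
        seg = segment_slide(slide, model, tile_size=40, T=8, seed=0)
        truth = mask[::40, ::40]
        assert (seg.grid == truth).mean() >= 0.9

    def test_uncertainty_never_influences_the_class_grid(self):
        layout = tb.checkerboard_layout(96, 96, 2, (0, 1))
        slide, _ = tb.generate_slide(layout, seed=3)
        seg_on = segment_slide(slide, MeanColourOracle(), 48, T=4, seed=5, compute_uncertainty=True)
        seg_off = segment_slide(slide, MeanColourOracle(), 48, T=4, seed=5, compute_uncertainty=False)
        np.testing.assert_array_equal(seg_on.grid, seg_off.grid)
        assert np.isnan(seg_off.uncertainty_grid).all()
        assert np.isfinite(seg_on.uncertainty_grid).all()


class TestRendering:
    def _segmap(self):
        grid = np.array([[0, 1], [1, 0]])
        unc = np.zeros((2, 2))
        return tb.SegmentationMap(grid=grid, uncertainty_grid=unc, tile_size=10, n_classes=2)

    def test_unblurred_render_is_exact_blocks(self):
        catalog = tb.default_catalog(2)
        img = render_segmentation(self._segmap(), catalog, blur_sigma=0)
        assert img.shape == (20, 20, 3)
        np.testing.assert_array_equal(img[0, 0], catalog.colors[0])
        np.testing.assert_array_equal(img[0, 19], catalog.colors[1])
        for r in range(2):
            for c in range(2):
                block = img[r * 10 : (r + 1) * 10, c * 10 : (c + 1) * 10]
                assert (block == block[0, 0]).all()

    def test_blur_only_affects_tile_boundaries(self):
        catalog = tb.default_catalog(2)
        seg = self._segmap()
        sigma = 2.0
        sharp = render_segmentation(seg, catalog, blur_sigma=0).astype(int)
        soft = render_segmentation(seg, catalog, blur_sigma=sigma).astype(int)
        diff = np.abs(sharp - soft).max(axis=2) > 1
        yy, xx = np.mgrid[0:20, 0:20]
        near_boundary = (np.abs(yy - 9.5) <= 3 * sigma + 0.5) | (
            np.abs(xx - 9.5) <= 3 * sigma + 0.5
        )
        assert not diff[~near_boundary].any()


class TestAreaStatistics:
    def test_constant_grid_is_all_one_class(self):
        seg = tb.SegmentationMap(
            grid=np.ones((5, 5), int), uncertainty_grid=np.zeros((5, 5)),
            tile_size=10, n_classes=3,
        )
        areas = class_area_statistics(seg)
        assert areas == {0: 0.0, 1: 100.0, 2: 0.0}

    def test_half_half_grid(self):
        grid = np.zeros((100, 100), int)
        grid[:, 50:] = 1
        seg = tb.SegmentationMap(
            grid=grid, uncertainty_grid=np.zeros_like(grid, float),
            tile_size=50, n_classes=2,
        )
        areas = class_area_statistics(seg)
        assert areas[0] == pytest.approx(50.0)
        assert areas[1] == pytest.approx(50.0)

    def test_percentages_conserve_total(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 5, size=(13, 7))
        seg = tb.SegmentationMap(
            grid=grid, uncertainty_grid=np.zeros_like(grid, float),
            tile_size=10, n_classes=6,
        )
        assert sum(class_area_statistics(seg).values()) == pytest.approx(100.0, abs=1e-9)
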