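"""LFB color-threshold segmentation, mask filtering and stain features."""

import numpy as np
import pytest
from scipy import ndimage

from cslim.dry_mass import integrate_mass, phase_to_density
from cslim.errors import ValidationError
from cslim.image_io import QuantMap, RgbFrame
from cslim.phantom import PhantomSpec, make_phantom
from cslim.stain_segmentation import (
    StainMask,
    apply_mask,
    filter_mask,
    hyperstain_flag,
    myelin_mask,
    stain_features,
)


def _frame_of(rgb, shape=(16, 16)):
    return RgbFrame(np.full(shape + (3,), rgb))


class TestColorThreshold:
    def test_pure_blue_in_pure_white_out(self):
        assert myelin_mask(_frame_of((0.0, 0.0, 1.0)), sat_min=0.15).mask.all()
        assert not myelin_mask(_frame_of((1.0, 1.0, 1.0)), sat_min=0.15).mask.any()

    def test_all_red_frame_empty_mask(self):
        assert not myelin_mask(_frame_of((1.0, 0.0, 0.0)), sat_min=0.15).mask.any()

    def test_phantom_fibers_recovered(self, small_phantom):
        mask = filter_mask(myelin_mask(small_phantom.stain_rgb))
        truth = small_phantom.fiber_mask
        iou = (mask.mask & truth).sum() / (mask.mask | truth).sum()
        assert iou >= 0.95

    def test_cells_excluded_from_mask(self, small_phantom):
        mask = filter_mask(myelin_mask(small_phantom.stain_rgb))
        overlap = (mask.mask & small_phantom.cell_mask).sum()
        assert overlap <= 0.02 * max(1, small_phantom.cell_mask.sum())

    def test_params_recorded(self):
        m = myelin_mask(_frame_of((0, 0, 1.0)), hue_window=(200, 260), sat_min=0.2)
        assert (m.params.hue_min_deg, m.params.hue_max_deg, m.params.sat_min) == (200, 260, 0.2)


class TestFiltering:
    def test_isolated_pixel_removed(self):
        m = np.zeros((32, 32), dtype=bool)
        m[5, 5] = True
        out = filter_mask(StainMask(m, _params()), 50, 0)
        assert not out.mask.any()

    def test_solid_block_retained(self):
        m = np.zeros((32, 32), dtype=bool)
        m[10:20, 10:20] = True
        out = filter_mask(StainMask(m, _params()), 50, 0)
        assert (out.mask == m).all()

    def test_component_exactly_at_min_area_kept(self):
        m = np.zeros((32, 32), dtype=bool)
        m[0:5, 0:10] = True  # exactly 50 px
        out = filter_mask(StainMask(m, _params()), 50, 0)
        assert (out.mask == m).all()

    def test_matches_labeling_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.random((64, 64)) > 0.7
        out = filter_mask(StainMask(m, _params()), min_area_px=10, closing_radius_px=0)
        # oracle: 8-connected labeling + size filter
        labels, n = ndimage.label(m, structure=np.ones((3, 3)))
        keep = np.zeros_like(m)
        for k in range(1, n + 1):
            comp = labels == k
            if comp.sum() >= 10:
                keep |= comp
        assert (out.mask == keep).all()

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        m = rng.random((64, 64)) > 0.6
        once = filter_mask(StainMask(m, _params()), 20, 1)
        twice = filter_mask(once, 20, 1)
        assert (once.mask == twice.mask).all()

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            filter_mask(StainMask(np.zeros((4, 4), dtype=bool), _params()), -1, 0)


class TestApplyAndFeatures:
    def test_all_ones_mask_identity(self, gradient_map):
        m = StainMask(np.ones(gradient_map.shape, dtype=bool), _params())
        assert (apply_mask(gradient_map, m).values == gradient_map.values).all()

    def test_all_zero_mask_annihilates(self, gradient_map):
        m = StainMask(np.zeros(gradient_map.shape, dtype=bool), _params())
        assert (apply_mask(gradient_map, m).values == 0).all()

    def test_checkerboard_sum(self, gradient_map):
        board = np.indices(gradient_map.shape).sum(axis=0) % 2 == 1
        masked = apply_mask(gradient_map, StainMask(board, _params()))
        assert masked.values.sum() == pytest.approx(gradient_map.values[board].sum())

    def test_masked_mass_never_exceeds_unmasked(self, small_phantom):
        rho = phase_to_density(small_phantom.phase)
        mask = filter_mask(myelin_mask(small_phantom.stain_rgb))
        assert (
            integrate_mass(rho, mask.mask).total_mass_pg <= integrate_mass(rho).total_mass_pg
        )

    def test_area_arithmetic(self):
        m = np.zeros((16, 16), dtype=bool)
        m.ravel()[:72] = True
        frame = RgbFrame(np.zeros((16, 16, 3)), pixel_pitch=7.2)
        feats = stain_features(frame, StainMask(m, _params()))
        assert feats.mask_area_um2 == pytest.approx(72 / 7.2**2)
        assert feats.mean_stain_intensity == pytest.approx(1.0)  # black pixels

    def test_empty_mask_features(self, white_frame):
        feats = stain_features(
            white_frame, StainMask(np.zeros((32, 32), dtype=bool), _params())
        )
        assert feats == type(feats)(0.0, 0.0)

    def test_features_increase_with_fiber_count(self):
        """More fibers → more masked mass, area and stain darkness (Fig-8-style)."""
        masses, areas, intensities = [], [], []
        for n in (5, 15, 30, 50):
            truth = make_phantom(PhantomSpec(n_fibers=n, seed=7))
            mask = filter_mask(myelin_mask(truth.stain_rgb))
            feats = stain_features(truth.stain_rgb, mask)
            rho = phase_to_density(truth.phase)
            masses.append(integrate_mass(rho, mask.mask).total_mass_pg)
            areas.append(feats.mask_area_um2)
            intensities.append(feats.mean_stain_intensity)
        for series in (masses, areas, intensities):
            assert all(b > a for a, b in zip(series, series[1:]))

    def test_hyperstain_flag(self):
        full = StainMask(np.ones((8, 8), dtype=bool), _params())
        empty = StainMask(np.zeros((8, 8), dtype=bool), _params())
        assert hyperstain_flag(full) and not hyperstain_flag(empty)


def _params():
    from cslim.stain_segmentation import MaskParams

    return MaskParams(170, 280, 0.15)
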