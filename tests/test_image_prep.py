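"""Geometry pipeline: registration, segmentation, axis, zones, traces, profiles."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import transform

from spindleflux.image_prep import (
    LineProfile,
    SpindleAxis,
    compartmentalize,
    extract_profile,
    extract_zone_traces,
    find_axis,
    measure_spindle_length,
    register_stack,
    segment_spindle,
    spindle_bound_ratio,
)
from spindleflux.stack import ImageStack
from spindleflux.synthetic import _reference_envelope, SimulationConfig


def ellipse_image(shape=(90, 140), center=(45, 70), a=55, b=25, amp=100.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    r2 = ((xx - center[1]) / a) ** 2 + ((yy - center[0]) / b) ** 2
    return np.where(r2 <= 1.0, amp, 0.0), r2 <= 1.0


def envelope_frame(seed=0, noise=2.0):
    cfg = SimulationConfig(rng_seed=0)
    env = _reference_envelope(cfg) + 20.0
    rng = np.random.default_rng(seed)
    return cfg, env + rng.normal(0, noise, env.shape)


class TestRegistration:
    def _stack_of(self, frames):
        pix = np.stack([np.stack([f, f]) for f in frames])
        return ImageStack(pix, 0.1, np.arange(len(frames)) * 5.0)

    def test_known_translation_recovered(self):
        _, f0 = envelope_frame(0)
        shifted = ndimage.shift(f0, (-2, 3), order=1)
        _, tfs = register_stack(self._stack_of([f0, shifted]))
        angle, dy, dx = tfs[1]
        assert abs(dy - 2) < 0.5 and abs(dx + 3) < 0.5

    def test_known_rotation_recovered(self):
        _, f0 = envelope_frame(1)
        rotated = transform.rotate(f0, 5.0, preserve_range=True)
        _, tfs = register_stack(self._stack_of([f0, rotated]))
        angle, dy, dx = tfs[1]
        assert abs(angle - 5.0) < 0.5

    def test_aligned_stack_gives_identity(self):
        _, f0 = envelope_frame(2)
        _, tfs = register_stack(self._stack_of([f0, f0]))
        angle, dy, dx = tfs[1]
        assert abs(angle) < 0.1 and abs(dy) < 0.1 and abs(dx) < 0.1

    def test_constant_reference_rejected(self):
        flat = np.ones((40, 60))
        with pytest.raises(ValueError, match="constant"):
            register_stack(self._stack_of([flat, flat]))


class TestSegmentation:
    def test_bright_ellipse_iou(self):
        img, truth = ellipse_image()
        mask = segment_spindle(img + np.random.default_rng(0).normal(0, 2, img.shape))
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_largest_component_kept(self):
        img, _ = ellipse_image()
        img[5:10, 5:10] = 100.0  # small distractor blob
        mask = segment_spindle(img)
        assert not mask[5:10, 5:10].any()
        assert mask[45, 70]

    def test_inverted_contrast_rejected(self):
        img, _ = ellipse_image()
        with pytest.raises(ValueError):
            segment_spindle(img.max() - img)


class TestAxis:
    def test_simulated_envelope_poles_within_2px(self):
        cfg, frame = envelope_frame(3)
        mask = segment_spindle(frame)
        axis = find_axis(mask, frame, cfg.pixel_size)
        ax_true, ay = cfg.um_to_px(-cfg.spindle_length / 2, 0.0)
        bx_true, _ = cfg.um_to_px(cfg.spindle_length / 2, 0.0)
        assert np.hypot(axis.pole_a[0] - ax_true, axis.pole_a[1] - ay) <= 2
        assert np.hypot(axis.pole_b[0] - bx_true, axis.pole_b[1] - ay) <= 2

    def test_chrom_edges_symmetric_for_symmetric_spindle(self):
        cfg, frame = envelope_frame(4, noise=0.5)
        mask = segment_spindle(frame)
        axis = find_axis(mask, frame, cfg.pixel_size)
        mid = axis.length_um / 2
        lo, hi = axis.chrom_edges
        assert abs((mid - lo) - (hi - mid)) <= 2 * cfg.pixel_size

    def test_user_supplied_edges_echoed(self):
        cfg, frame = envelope_frame(5)
        mask = segment_spindle(frame)
        axis = find_axis(mask, None, cfg.pixel_size, chrom_edges=(4.0, 6.0))
        assert axis.chrom_edges == (4.0, 6.0)

    def test_round_mask_rejected(self):
        yy, xx = np.mgrid[:60, :60]
        disk = (xx - 30) ** 2 + (yy - 30) ** 2 <= 20 ** 2
        with pytest.raises(ValueError, match="round"):
            find_axis(disk, None, 0.1, chrom_edges=(1.0, 2.0))


class TestZones:
    def _rect_setup(self):
        mask = np.zeros((30, 120), bool)
        mask[10:20, 10:110] = True
        axis = SpindleAxis((10.0, 14.0), (109.0, 14.0), (4.0, 6.0), 0.1)
        bleach = np.zeros_like(mask)
        bleach[:, :60] = True
        return mask, axis, bleach

    def test_rectangle_zones_equal_areas(self):
        mask, axis, bleach = self._rect_setup()
        zones = compartmentalize(mask, axis, bleach)
        counts = [(zones.labels == lab).sum() for lab in range(1, 7)]
        assert max(counts) - min(counts) <= 0.05 * np.mean(counts) + 10

    def test_partition_law(self):
        mask, axis, bleach = self._rect_setup()
        zones = compartmentalize(mask, axis, bleach)
        assert np.array_equal(zones.labels > 0, mask)
        # disjointness holds by construction (one label per pixel);
        # check the rois() view agrees
        rois = zones.rois()
        total = sum(rois[n].sum() for n in rois if n.endswith(("pole", "intermediate", "chromosome")))
        assert total == mask.sum()

    def test_bleached_side_follows_geometry(self):
        mask, axis, bleach = self._rect_setup()
        zones = compartmentalize(mask, axis, bleach)
        assert zones.bleached_side == "a"
        assert zones.mask("bleached_pole")[14, 12]
        zones2 = compartmentalize(mask, axis, ~bleach)
        assert zones2.bleached_side == "b"

    def test_straddling_bleach_rejected(self):
        mask, axis, _ = self._rect_setup()
        straddle = np.zeros_like(mask)
        straddle[:, 35:85] = True  # 50/50 across the midline
        with pytest.raises(ValueError, match="straddles"):
            compartmentalize(mask, axis, straddle)


class TestTraces:
    def _uniform_stack(self, value=7.0, n=3):
        pix = np.full((n, 2, 20, 30), value)
        pix[:, 1] += 1.0
        return ImageStack(pix, 0.1, np.arange(n) * 2.0)

    def test_uniform_image_constant_trace(self):
        stack = self._uniform_stack(7.0)
        roi = np.zeros((20, 30), bool)
        roi[5:10, 5:10] = True
        bg = np.zeros((20, 30), bool)
        bg[0:2, 0:2] = True
        (trace,) = extract_zone_traces(stack, {"roi": roi}, bg)
        assert np.allclose(trace.mean_intensity, 7.0)

    def test_trace_linearity(self):
        stack = self._uniform_stack(4.0, n=2)
        stack.pixels[1] *= 2
        roi = np.ones((20, 30), bool)
        (trace,) = extract_zone_traces(stack, {"roi": roi},
                                       np.ones((20, 30), bool))
        assert trace.mean_intensity[1] == pytest.approx(2 * trace.mean_intensity[0])

    def test_checkerboard_mean(self):
        pix = np.zeros((1, 2, 8, 8))
        pix[0, 0, ::2, ::2] = 10.0
        pix[0, 0, 1::2, 1::2] = 10.0
        stack = ImageStack(pix, 0.1, [0.0])
        roi = np.ones((8, 8), bool)
        bg = np.zeros((8, 8), bool)
        bg[0, 1] = True
        (trace,) = extract_zone_traces(stack, {"roi": roi}, bg)
        assert trace.mean_intensity[0] == pytest.approx(5.0)

    def test_empty_roi_rejected(self):
        stack = self._uniform_stack()
        with pytest.raises(ValueError, match="empty"):
            extract_zone_traces(stack, {"roi": np.zeros((20, 30), bool)})


class TestProfiles:
    def _axis(self):
        return SpindleAxis((10.0, 25.0), (110.0, 25.0), (4.0, 6.0), 0.1)

    def test_uniform_image_flat_profile(self):
        prof = extract_profile(np.full((50, 130), 3.0), self._axis())
        assert np.allclose(prof.intensities, 3.0)

    def test_bright_line_peak_position(self):
        img = np.zeros((50, 130))
        img[:, 50] = 100.0  # 40% of the 10 um span from pole_a at x=10
        prof = extract_profile(img, self._axis())
        frac = prof.positions[np.argmax(prof.intensities)] / prof.positions[-1]
        assert frac == pytest.approx(0.4, abs=0.02)

    def test_width_invariance_on_uniform_image(self):
        img = np.full((50, 130), 2.5)
        p1 = extract_profile(img, self._axis(), width_um=2.0)
        p2 = extract_profile(img, self._axis(), width_um=4.0)
        assert np.allclose(p1.intensities, p2.intensities)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, (50, 130))
        p1 = extract_profile(img, self._axis())
        p3 = extract_profile(3 * img, self._axis())
        assert np.allclose(p3.intensities, 3 * p1.intensities)


class TestScalars:
    def test_three_four_five_length(self):
        axis = SpindleAxis((0.0, 0.0), (30.0, 40.0), (2.0, 3.0), 0.1)
        assert measure_spindle_length(axis) == pytest.approx(5.0)

    def test_length_scales_with_pixel_size(self):
        a1 = SpindleAxis((0.0, 0.0), (30.0, 40.0), (2.0, 3.0), 0.1)
        a2 = SpindleAxis((0.0, 0.0), (30.0, 40.0), (4.0, 6.0), 0.2)
        assert measure_spindle_length(a2) == pytest.approx(2 * measure_spindle_length(a1))

    def test_coincident_poles_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SpindleAxis((5.0, 5.0), (5.0, 5.0), (1.0, 2.0), 0.1)

    @pytest.mark.parametrize("rep,ref,expected", [(8.0, 4.0, 2.0), (4.0, 4.0, 1.0),
                                                  (10.0, 4.0, 2.5)])
    def test_bound_ratio(self, rep, ref, expected):
        mask = np.ones((10, 10), bool)
        got = spindle_bound_ratio(np.full((10, 10), rep), np.full((10, 10), ref), mask)
        assert got == pytest.approx(expected)

    def test_bound_ratio_nonpositive_reference_rejected(self):
        mask = np.ones((5, 5), bool)
        with pytest.raises(ValueError, match="reference"):
            spindle_bound_ratio(np.ones((5, 5)), np.zeros((5, 5)), mask)
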