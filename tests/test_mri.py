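"""Segmentation, volumetry, cyst detection and the 10-grade severity rubric."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dice, two_lesion_spec
from cryosci.mri import (
    CystConfig,
    LesionQuantification,
    ScoringRubric,
    SegmentationConfig,
    compute_volume,
    detect_cyst,
    hyper_hypo_ratio,
    quantify_timepoint,
    segment_lesions,
    severity_score,
)
from cryosci.synth import Ellipsoid, PhantomSpec, PhantomVolume, generate_phantom

EXPLICIT = SegmentationConfig(low_threshold=80.0, high_threshold=120.0)


class TestSegmentation:
    def test_uniform_volume_yields_empty_masks(self):
        vol = PhantomVolume(np.full((16, 16, 8), 100.0), (0.5, 0.5, 0.5))
        hypo, hyper = segment_lesions(vol)
        assert not hypo.any() and not hyper.any()

    def test_noiseless_explicit_thresholds_recover_ground_truth(self):
        phantom = generate_phantom(two_lesion_spec(noise_sigma=0.0))
        hypo, hyper = segment_lesions(phantom.volume, EXPLICIT)
        assert np.array_equal(hypo, phantom.hypo_mask)
        assert np.array_equal(hyper, phantom.hyper_mask)

    def test_mad_mode_noisy_phantom_dice(self):
        """Noise at 0.1x the lesion offset still gives Dice >= 0.9 for both masks."""
        phantom = generate_phantom(two_lesion_spec(noise_sigma=4.0, seed=21))
        hypo, hyper = segment_lesions(phantom.volume)
        assert dice(hypo, phantom.hypo_mask) >= 0.9
        assert dice(hyper, phantom.hyper_mask) >= 0.9

    def test_masks_disjoint(self):
        phantom = generate_phantom(two_lesion_spec(noise_sigma=4.0))
        hypo, hyper = segment_lesions(phantom.volume)
        assert not (hypo & hyper).any()

    def test_idempotence_on_thresholded_volume(self):
        """Rebuilding a volume from its own masks and re-segmenting reproduces them."""
        phantom = generate_phantom(two_lesion_spec(noise_sigma=0.0))
        hypo, hyper = segment_lesions(phantom.volume, EXPLICIT)
        rebuilt = PhantomVolume(
            100.0 - 40.0 * hypo + 40.0 * hyper, phantom.volume.spacing_mm
        )
        hypo2, hyper2 = segment_lesions(rebuilt, EXPLICIT)
        assert np.array_equal(hypo, hypo2) and np.array_equal(hyper, hyper2)

    def test_nonpositive_min_size_rejected(self):
        vol = PhantomVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="min_voxels"):
            segment_lesions(vol, SegmentationConfig(min_voxels=0))


class TestVolumetry:
    def test_empty_mask_zero_volume(self):
        assert compute_volume(np.zeros((4, 4, 4), bool), (0.5, 0.5, 0.5)) == 0.0

    def test_eight_half_mm_voxels_are_one_mm3(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2, :2, :2] = True
        assert compute_volume(mask, (0.5, 0.5, 0.5)) == pytest.approx(1.0)

    def test_additivity_for_disjoint_masks(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8)) < 0.3
        b = (rng.random((8, 8, 8)) < 0.3) & ~a
        sp = (0.25, 0.25, 0.5)
        assert compute_volume(a | b, sp) == pytest.approx(
            compute_volume(a, sp) + compute_volume(b, sp)
        )

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            compute_volume(np.ones((2, 2, 2), bool), (0.5, -0.5, 0.5))

    def test_ratio_conventions(self):
        assert hyper_hypo_ratio(4.0, 2.0) == 2.0
        assert math.isnan(hyper_hypo_ratio(0.0, 0.0))
        assert math.isinf(hyper_hypo_ratio(5.0, 0.0))
        with pytest.raises(ValueError):
            hyper_hypo_ratio(-1.0, 2.0)


class TestCystDetection:
    def test_cyst_bearing_phantom_detected(self):
        phantom = generate_phantom(two_lesion_spec(noise_sigma=4.0, cyst=True, seed=4))
        _, hyper = segment_lesions(phantom.volume)
        assert detect_cyst(phantom.volume, hyper)

    def test_cyst_free_phantom_not_detected(self):
        phantom = generate_phantom(two_lesion_spec(noise_sigma=4.0, cyst=False, seed=4))
        _, hyper = segment_lesions(phantom.volume)
        assert not detect_cyst(phantom.volume, hyper)

    def test_elongated_hyper_component_rejected_by_sphericity(self):
        # axis ratio 3:1, volume inside the plausible-cyst bounds
        spec = PhantomSpec(hyper=Ellipsoid((8.0, 8.0, 12.0), (3.0, 1.0, 1.0), +40.0))
        phantom = generate_phantom(spec)
        _, hyper = segment_lesions(phantom.volume, EXPLICIT)
        assert not detect_cyst(phantom.volume, hyper)

    def test_empty_mask_is_false(self):
        vol = PhantomVolume(np.full((8, 8, 8), 100.0), (0.5, 0.5, 0.5))
        assert not detect_cyst(vol, np.zeros((8, 8, 8), bool))


def quant(v_hyper, v_hypo, cyst=False):
    return LesionQuantification(
        v_hypo_mm3=v_hypo,
        v_hyper_mm3=v_hyper,
        ratio=hyper_hypo_ratio(v_hyper, v_hypo),
        cyst_present=cyst,
    )


class TestSeverityScore:
    def test_maximal_configuration_scores_ten(self):
        s = severity_score(quant(12.0, 6.0, cyst=True))
        # ratio 2.0 -> 1 point under the closed-bracket convention
        assert (s.hyper_points, s.hypo_points, s.ratio_points, s.cyst_points) == (3, 3, 1, 1)
        assert s.total == 8
        s_max = severity_score(quant(20.0, 6.0, cyst=True))  # ratio 3.33 -> 3
        assert s_max.total == 10

    def test_no_lesion_scores_zero(self):
        assert severity_score(quant(0.0, 0.0)).total == 0

    @pytest.mark.parametrize(
        "v_hyper,expected", [(0.0, 0), (3.0, 1), (5.0, 2), (7.0, 2), (10.0, 2), (10.5, 3)]
    )
    def test_hyper_bracket_convention(self, v_hyper, expected):
        assert severity_score(quant(v_hyper, 0.0)).hyper_points == expected

    @pytest.mark.parametrize(
        "v_hypo,expected", [(0.0, 0), (1.0, 1), (2.0, 2), (5.0, 2), (5.5, 3)]
    )
    def test_hypo_bracket_convention(self, v_hypo, expected):
        assert severity_score(quant(0.0, v_hypo)).hypo_points == expected

    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.0, 0), (1.0, 0), (1.5, 1), (2.0, 1), (2.5, 2), (3.0, 2), (3.5, 3)],
    )
    def test_ratio_bracket_convention(self, ratio, expected):
        q = LesionQuantification(1.0, ratio, ratio, False)
        assert severity_score(q).ratio_points == expected

    def test_infinite_ratio_scores_top_bracket(self):
        assert severity_score(quant(5.0, 0.0)).ratio_points == 3

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            quant(-1.0, 2.0)

    @given(
        v_hyper=st.floats(0, 50),
        v_hypo=st.floats(0, 50),
        cyst=st.booleans(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_always_in_range(self, v_hyper, v_hypo, cyst):
        s = severity_score(quant(v_hyper, v_hypo, cyst))
        assert 0 <= s.total <= 10
        assert s.total == s.hyper_points + s.hypo_points + s.ratio_points + s.cyst_points

    @given(lo=st.floats(0, 50), delta=st.floats(0, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_per_criterion_monotonicity(self, lo, delta):
        """Raising one criterion's value never lowers that criterion's points."""
        hi = lo + delta
        assert (
            severity_score(quant(hi, 0.0)).hyper_points
            >= severity_score(quant(lo, 0.0)).hyper_points
        )
        assert (
            severity_score(quant(0.0, hi)).hypo_points
            >= severity_score(quant(0.0, lo)).hypo_points
        )
        q_lo = LesionQuantification(1.0, 1.0, lo, False)
        q_hi = LesionQuantification(1.0, 1.0, hi, False)
        assert severity_score(q_hi).ratio_points >= severity_score(q_lo).ratio_points


class TestQuantifyTimepoint:
    def test_noiseless_two_lesion_phantom_matches_ground_truth(self):
        phantom = generate_phantom(two_lesion_spec(noise_sigma=0.0))
        quant_, score = quantify_timepoint(phantom.volume, EXPLICIT)
        voxvol = phantom.volume.voxel_volume_mm3
        assert quant_.v_hypo_mm3 == pytest.approx(phantom.hypo_mask.sum() * voxvol)
        assert quant_.v_hyper_mm3 == pytest.approx(phantom.hyper_mask.sum() * voxvol)
        assert not quant_.cyst_present
        assert score.total == score.hyper_points + score.hypo_points + score.ratio_points

    def test_cyst_adds_exactly_one_point(self):
        with_cyst = generate_phantom(two_lesion_spec(noise_sigma=0.0, cyst=True))
        without = generate_phantom(two_lesion_spec(noise_sigma=0.0, cyst=False))
        _, s_with = quantify_timepoint(with_cyst.volume, EXPLICIT)
        _, s_without = quantify_timepoint(without.volume, EXPLICIT)
        assert s_with.cyst_points == 1
        assert s_with.total >= s_without.total

    def test_shrinking_hypo_series_has_nonincreasing_hypo_points(self):
        points = []
        for semi in [(2.0, 1.3, 1.0), (1.5, 1.0, 0.8), (1.0, 0.7, 0.55), (0.6, 0.5, 0.5)]:
            spec = PhantomSpec(hypo=Ellipsoid((8.0, 8.0, 5.5), semi, -40.0))
            phantom = generate_phantom(spec)
            _, score = quantify_timepoint(phantom.volume, EXPLICIT)
            points.append(score.hypo_points)
        assert points == sorted(points, reverse=True)
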