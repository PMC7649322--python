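import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from mtsurround.config import ModelParams
from mtsurround.stimuli import (FrameSequence, GeometryError, StimulusSpec,
                                crossing_bars, direction_channel, grating,
                                occluded_plaid, plaid_spec, single_bar)


@pytest.fixture(scope="module")
def p():
    return ModelParams()


class TestSpecValidation:
    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            StimulusSpec(kind="single_bar", speed=0.0)

    def test_contrast_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            StimulusSpec(kind="crossing_bars", contrasts=(1.2, 0.5))

    def test_identical_orientations_rejected_for_two_bars(self):
        with pytest.raises(ValueError, match="distinct"):
            StimulusSpec(kind="crossing_bars", orientations=(45.0, 225.0))

    def test_frame_sequence_rejects_out_of_range_intensity(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            FrameSequence(np.full((3, 32, 32), 1.5), 0.25, 0.01)


class TestCrossingBars:
    def test_zero_contrast_gives_constant_background(self, p):
        spec = StimulusSpec(kind="crossing_bars", contrasts=(0.0, 0.0),
                            n_frames=10)
        seq, _ = crossing_bars(spec, p)
        assert np.all(seq.frames == 0.0)

    def test_determinism_bit_identical(self, p):
        spec = StimulusSpec(kind="crossing_bars", n_frames=12)
        a, _ = crossing_bars(spec, p)
        b, _ = crossing_bars(spec, p)
        assert np.array_equal(a.frames, b.frames)

    def test_ground_truth_channels(self, p):
        spec = StimulusSpec(kind="crossing_bars", n_frames=8)
        _, gt = crossing_bars(spec, p)
        # 135-degree bar moves right (channel 0), 45-degree bar left (4)
        assert gt.true_channels == [0, 4]

    def test_masks_translate_with_bars(self, p):
        spec = StimulusSpec(kind="crossing_bars", n_frames=120)
        _, gt = crossing_bars(spec, p)
        for b, sign in ((0, +1), (1, -1)):
            cols = [np.nonzero(gt.on_bar[b][t])[1].mean() for t in (0, 119)]
            drift = cols[1] - cols[0]
            expected = sign * spec.speed * 119 * p.dt / p.deg_per_pixel
            assert drift == pytest.approx(expected, abs=0.8)

    def test_intrinsic_and_extrinsic_masks_disjoint(self, p):
        spec = StimulusSpec(kind="crossing_bars", n_frames=8)
        _, gt = crossing_bars(spec, p)
        assert not np.any(gt.intrinsic & gt.extrinsic)

    def test_unequal_contrast_brighter_bar_in_front_at_junction(self, p):
        spec = StimulusSpec(kind="crossing_bars", contrasts=(1.0, 0.4),
                            n_frames=8)
        seq, gt = crossing_bars(spec, p)
        t = 4
        overlap = gt.on_bar[0][t] & gt.on_bar[1][t]
        if overlap.any():
            assert seq.frames[t][overlap].min() > 0.6

    def test_bar_leaving_frame_raises_with_frame_index(self, p):
        spec = StimulusSpec(kind="crossing_bars", bar_length=15.5,
                            speed=20.0, n_frames=100)
        with pytest.raises(GeometryError, match="frame"):
            crossing_bars(spec, p)


class TestSingleBar:
    def test_centroid_speed_matches_spec(self, p):
        spec = StimulusSpec(kind="single_bar", orientations=(45.0,),
                            directions=(0.0,), n_frames=120)
        seq, _ = single_bar(spec, p)
        cols = np.arange(seq.frames.shape[2])
        cx = (seq.frames * cols).sum(axis=(1, 2)) / seq.frames.sum(axis=(1, 2))
        per_frame = (cx[-1] - cx[0]) / 119
        assert per_frame == pytest.approx(spec.speed * p.dt / p.deg_per_pixel,
                                          rel=0.05)

    def test_two_terminator_components(self, p):
        spec = StimulusSpec(kind="single_bar", orientations=(45.0,),
                            directions=(0.0,), n_frames=8)
        _, gt = single_bar(spec, p)
        for t in range(8):
            _, n = ndimage.label(gt.intrinsic[t])
            assert n == 2


class TestOccludedPlaid:
    def test_intrinsic_mask_empty_all_frames(self, p):
        _, gt = occluded_plaid(plaid_spec(n_frames=12), p)
        assert not gt.intrinsic.any()

    def test_frames_match_crossing_bars_outside_occluders(self, p):
        spec = plaid_spec(n_frames=12)
        plaid, _ = occluded_plaid(spec, p)
        bars, _ = crossing_bars(dataclasses.replace(spec,
                                                    kind="crossing_bars"), p)
        diff_anywhere = np.any(plaid.frames != bars.frames, axis=0)
        # pixels that ever differ form the static occluder zone; inside it
        # the plaid shows the occluder intensity over otherwise-bar pixels
        assert diff_anywhere.any()
        same = ~diff_anywhere
        assert np.array_equal(plaid.frames[:, same], bars.frames[:, same])

    def test_background_occluder_hides_terminators(self, p):
        spec = plaid_spec(n_frames=6, occluder_intensity=0.0)
        seq, _ = occluded_plaid(spec, p)
        bars, gtb = crossing_bars(dataclasses.replace(spec,
                                                      kind="crossing_bars"), p)
        # every hidden-terminator pixel is at background level
        assert np.all(seq.frames[gtb.intrinsic] == 0.0)

    def test_too_small_occluder_raises(self, p):
        with pytest.raises(GeometryError, match="occluder"):
            occluded_plaid(plaid_spec(n_frames=160, occluder_size=2.0), p)


class TestGrating:
    def test_temporal_periodicity(self, p):
        period_frames = 20
        speed = 1.0 / (p.f * period_frames * p.dt)
        spec = StimulusSpec(kind="grating", directions=(0.0,), speed=speed,
                            n_frames=period_frames + 1)
        seq = grating(spec, p)
        np.testing.assert_allclose(seq.frames[period_frames], seq.frames[0],
                                   atol=1e-9)

    def test_intensity_range_and_contrast(self, p):
        spec = StimulusSpec(kind="grating", directions=(90.0,), speed=2.0,
                            contrasts=(0.5,), n_frames=5)
        seq = grating(spec, p)
        assert seq.frames.min() >= 0.25 - 1e-9
        assert seq.frames.max() <= 0.75 + 1e-9


@pytest.mark.parametrize("angle,channel", [
    (0, 0), (45, 1), (90, 2), (180, 4), (270, 6), (337.4, 7), (359, 0)])
def test_direction_channel_mapping(angle, channel):
    assert direction_channel(angle) == channel
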