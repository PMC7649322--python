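import math

import numpy as np
import pytest

from mtsurround.config import ModelParams
from mtsurround.stimuli import StimulusSpec, grating
from mtsurround.v1_motion_energy import (border_width, calibration_constant,
                                         complex_v1_response, gabor_bank,
                                         raw_motion_energy, temporal_kernel)


@pytest.fixture(scope="module")
def p():
    return ModelParams()


class TestTemporalKernel:
    def test_zero_at_origin(self):
        for n in (6, 9):
            k = temporal_kernel(n, 0.01, 0.01)
            assert k.weights[0] == 0.0

    def test_known_value_order_six(self):
        # g_6(0.06) with tau_g = 0.01: direct evaluation of the closed form
        s = 6.0
        expected = s ** 6 * math.exp(-s) * (1 / math.factorial(6)
                                            - s ** 2 / math.factorial(8))
        k = temporal_kernel(6, 0.01, 0.01)
        assert k.weights[6] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0574, abs=5e-4)

    @pytest.mark.parametrize("n", [6, 9])
    def test_biphasic_single_sign_change(self, n):
        w = temporal_kernel(n, 0.01, 0.01).weights
        nz = w[np.abs(w) > 1e-12]
        changes = np.sum(np.diff(np.sign(nz)) != 0)
        assert changes == 1

    def test_decays_below_tolerance_at_window_end(self):
        w = temporal_kernel(9, 0.01, 0.01).weights
        assert abs(w[-1]) < 1e-6 * np.abs(w).max()

    def test_window_too_small_raises(self):
        with pytest.raises(ValueError, match="t_max"):
            temporal_kernel(6, 0.01, 0.01, t_max=0.05)


class TestGaborBank:
    def test_odd_kernels_sum_to_zero(self, p):
        for k in gabor_bank(p):
            if k.phase == "odd":
                assert abs(k.weights.sum()) < 1e-10

    def test_even_kernels_identical_for_opposite_directions(self, p):
        bank = {(k.direction, k.phase): k.weights for k in gabor_bank(p)}
        for theta in (0.0, 45.0, 90.0, 135.0):
            np.testing.assert_array_almost_equal(
                bank[(theta, "even")], bank[(theta + 180.0, "even")],
                decimal=12)

    def test_odd_kernels_negate_for_opposite_directions(self, p):
        bank = {(k.direction, k.phase): k.weights for k in gabor_bank(p)}
        for theta in (0.0, 45.0, 90.0, 135.0):
            np.testing.assert_array_almost_equal(
                bank[(theta, "odd")], -bank[(theta + 180.0, "odd")],
                decimal=12)

    def test_energy_rotation_invariant_on_fine_grid(self, p):
        fine = p.replace(deg_per_pixel=0.05)
        energies = {}
        for k in gabor_bank(fine):
            energies.setdefault(k.direction, 0.0)
            energies[k.direction] += float((k.weights ** 2).sum())
        vals = np.array(list(energies.values()))
        assert vals.std() / vals.mean() < 1e-6


class TestComplexResponse:
    def test_constant_luminance_gives_zero(self, p):
        frames = np.full((50, 48, 48), 0.5)
        assert np.all(complex_v1_response(frames, p) == 0.0)

    def test_output_in_unit_interval(self, p):
        spec = StimulusSpec(kind="grating", directions=(0.0,), speed=3.0,
                            n_frames=50, height=48, width=48)
        v = complex_v1_response(grating(spec, p).frames, p)
        assert v.min() >= 0.0 and v.max() <= 1.0

    @pytest.mark.parametrize("direction,channel", [(0.0, 0), (90.0, 2),
                                                   (225.0, 5)])
    def test_drifting_grating_peaks_in_matching_channel(self, p, direction,
                                                        channel):
        spec = StimulusSpec(kind="grating", directions=(direction,),
                            speed=3.0 / p.f, n_frames=60, height=48, width=48)
        raw = raw_motion_energy(grating(spec, p).frames, p)
        b = border_width(p)
        means = raw[30:, b:-b, b:-b].mean(axis=(0, 1, 2))
        assert means.argmax() == channel

    def test_opponency_time_reversal_swaps_opposite_channels(self, p):
        spec = StimulusSpec(kind="grating", directions=(0.0,), speed=3.0 / p.f,
                            n_frames=60, height=48, width=48)
        frames = grating(spec, p).frames
        fwd = raw_motion_energy(frames, p)
        rev = raw_motion_energy(frames[::-1], p)
        b = border_width(p)
        f0 = fwd[30:, b:-b, b:-b, 0].mean()
        r4 = rev[30:, b:-b, b:-b, 4].mean()
        assert r4 == pytest.approx(f0, rel=0.05)
        # and the reversed stimulus is decoded as leftward
        assert rev[30:, b:-b, b:-b].mean(axis=(0, 1, 2)).argmax() == 4

    def test_shift_equivariance_in_interior(self, p, rng):
        frames = rng.random((40, 48, 48))
        shift = 3
        shifted = np.roll(frames, shift, axis=2)
        a = raw_motion_energy(frames, p)
        b_resp = raw_motion_energy(shifted, p)
        m = border_width(p) + shift + 1
        np.testing.assert_allclose(
            np.roll(a, shift, axis=2)[:, m:-m, m:-m],
            b_resp[:, m:-m, m:-m], atol=1e-9)

    def test_calibration_constant_positive_and_cached(self, p):
        c1 = calibration_constant(p)
        c2 = calibration_constant(p)
        assert c1 > 0 and c1 == c2

    def test_aperture_signature_on_oblique_bar(self, p, single_bar_stimulus):
        # a 45-degree bar translating rightward: mid-edge locations respond
        # in the edge-normal channel (315 deg -> 7), not the true channel
        _, seq, gt = single_bar_stimulus
        v = complex_v1_response(seq.frames, p)
        t = 100
        mid = gt.mid_edge[t]
        means = v[t][mid].mean(axis=0)
        assert means.argmax() == 7
        assert means[7] > means[0]
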