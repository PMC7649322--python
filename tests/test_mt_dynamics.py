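import numpy as np
import pytest

from mtsurround.config import ModelParams
from mtsurround.mt_dynamics import (MTState, interdirectional_inhibition,
                                    lateral_excitation, longrange_inhibition,
                                    mt_step, run_model, saturate)

P = ModelParams()


def zero_drives(shape):
    z = np.zeros(shape)
    return {"v_cx": z.copy(), "v_es": z.copy(), "kappa": z.copy(),
            "chi": z.copy(), "lam_ex": z.copy(),
            "gamma_delayed": z.copy(), "xi_delayed": z.copy()}


class TestInteractionFields:
    def test_lateral_zero_for_silent_population(self):
        v = np.zeros((20, 20, 8))
        cs = np.ones((20, 20, 4))
        assert np.all(lateral_excitation(v, cs, P) == 0.0)

    def test_lateral_blocked_by_closed_form_gate(self, rng):
        v = rng.random((20, 20, 8))
        cs = np.zeros((20, 20, 4))
        assert np.all(lateral_excitation(v, cs, P) == 0.0)
        assert lateral_excitation(v, cs, P, gate_open=True).max() > 0

    def test_lateral_window_sum_value(self):
        # all 49 window units at 0.1 with open gate: sum 4.9 and the
        # sum-minus-center condition holds
        v = np.full((20, 20, 8), 0.1)
        cs = np.ones((20, 20, 4))
        lam = lateral_excitation(v, cs, P)
        assert lam[10, 10, 0] == pytest.approx(4.9)

    def test_interdirectional_counts_other_channels(self):
        v = np.zeros((5, 5, 8))
        v[2, 2, 3] = 0.5
        g = interdirectional_inhibition(v)
        assert g[2, 2, 0] == pytest.approx(0.5)
        assert g[2, 2, 3] == pytest.approx(0.0)
        assert np.all(interdirectional_inhibition(np.ones((3, 3, 8))) == 7.0)

    def test_longrange_single_source_covers_window(self):
        v = np.zeros((30, 30, 8))
        v[15, 15, 2] = 0.3
        xi = longrange_inhibition(v, P)
        assert xi[15 + P.phi, 15 + P.phi, 0] == pytest.approx(0.3)
        assert xi[15 + P.phi + 1, 15, 0] == 0.0
        assert xi[15, 15, 2] == 0.0  # same channel excluded

    def test_longrange_saturated_field_value(self):
        v = np.ones((40, 40, 8))
        xi = longrange_inhibition(v, P)
        assert xi[20, 20, 0] == pytest.approx(7 * (2 * P.phi + 1) ** 2)
        assert xi[20, 20, 0] == pytest.approx(1183.0)


class TestMTStep:
    def test_rest_with_no_drive_stays_rest(self):
        state = MTState.zeros((6, 6, 8), P)
        state = mt_step(state, zero_drives((6, 6, 8)), P)
        assert np.all(state.v_mt == 0.0)

    def test_upper_saturation(self):
        state = MTState.zeros((4, 4, 8), P)
        state.v_mt[...] = 1.0
        drives = zero_drives((4, 4, 8))
        drives["v_cx"][...] = 1.0  # rhs >= 0
        state = mt_step(state, drives, P)
        assert np.all(state.v_mt == 1.0)

    def test_hand_computed_update(self):
        # v = 0.5, v_cx = 0.2, everything else 0:
        # rhs = 0.5*0.2 - 0.01*0.5 = 0.095 -> v' = 0.50095
        state = MTState.zeros((1, 1, 1), P)
        state.v_mt[0, 0, 0] = 0.5
        drives = zero_drives((1, 1, 1))
        drives["v_cx"][0, 0, 0] = 0.2
        state = mt_step(state, drives, P)
        assert state.v_mt[0, 0, 0] == pytest.approx(0.50095, abs=1e-12)

    def test_suppressive_surround_keeps_rest_at_rest(self):
        # sliding mode: weak base drive cannot overcome a suppressive
        # surround, so a resting unit stays exactly at rest
        state = MTState.zeros((1, 1, 1), P)
        drives = zero_drives((1, 1, 1))
        drives["v_cx"][...] = 0.5   # base drive 0.25
        drives["chi"][...] = 0.9    # suppression exceeds it
        state = mt_step(state, drives, P)
        assert state.v_mt[0, 0, 0] == 0.0

    def test_rho_es_threshold_applied_to_endstopped_drive(self):
        shape = (1, 1, 1)
        below = MTState.zeros(shape, P)
        drives = zero_drives(shape)
        drives["v_es"][...] = P.rho_es - 0.01
        below = mt_step(below, drives, P)
        assert below.v_mt[0, 0, 0] == 0.0
        above = MTState.zeros(shape, P)
        drives["v_es"][...] = P.rho_es + 0.1
        above = mt_step(above, drives, P)
        assert above.v_mt[0, 0, 0] > 0.0

    def test_literal_derivative_saturation_mode(self):
        p = P.replace(literal_derivative_saturation=True)
        state = MTState.zeros((1, 1, 1), p)
        drives = zero_drives((1, 1, 1))
        drives["gamma_delayed"][...] = 5.0  # rhs < 0 -> h(rhs) = 0
        state = mt_step(state, drives, p)
        assert state.v_mt[0, 0, 0] == 0.0


class TestDelayBuffer:
    def test_buffer_length_matches_delay(self):
        state = MTState.zeros((3, 3, 8), P)
        assert state.buffer.shape[0] == 40 == P.delay_steps

    def test_delayed_returns_state_forty_steps_back_bit_exact(self):
        state = MTState.zeros((2, 2, 1), P)
        pushed = []
        for i in range(90):
            assert np.array_equal(
                state.delayed(),
                pushed[i - 40] if i >= 40 else np.zeros((2, 2, 1)))
            arr = np.full((2, 2, 1), float(i))
            pushed.append(arr)
            state.push(arr)


class TestRunModel:
    def test_blank_stimulus_silent(self):
        from mtsurround.stimuli import FrameSequence
        seq = FrameSequence(np.zeros((45, 48, 48)), P.deg_per_pixel, P.dt)
        trace = run_model(seq, P, mode="component")
        assert np.all(trace.v_mt == 0.0)

    def test_invalid_mode_rejected(self):
        from mtsurround.stimuli import FrameSequence
        seq = FrameSequence(np.zeros((5, 32, 32)), P.deg_per_pixel, P.dt)
        with pytest.raises(ValueError, match="mode"):
            run_model(seq, P, mode="banana")

    def test_boundedness_on_real_run(self, bars_trace):
        trace, _ = bars_trace
        for field in (trace.v_mt, trace.v_cx, trace.v_es):
            assert field.min() >= 0.0 and field.max() <= 1.0

    def test_trace_metadata(self, bars_trace):
        trace, _ = bars_trace
        assert trace.mode == "component"
        assert trace.meta["gcsmt"] == P.Gcsmt
        assert trace.buffer.shape[0] == P.delay_steps

    def test_delayed_inhibition_consistency(self, bars_trace):
        # the state pushed before step t is v_mt[t-1]; the inhibition at
        # step t is computed from the push made 40 steps earlier, i.e.
        # from v_mt[t-41]; spot-check via the recorded final buffer, which
        # holds the last 40 pre-update states in chronological order
        trace, _ = bars_trace
        np.testing.assert_array_equal(trace.buffer[-1], trace.v_mt[-2])
        np.testing.assert_array_equal(trace.buffer[0],
                                      trace.v_mt[-41])


def test_saturate_is_unit_clip():
    x = np.array([-0.5, 0.0, 0.4, 1.0, 1.7])
    np.testing.assert_array_equal(saturate(x), [0.0, 0.0, 0.4, 1.0, 1.0])
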