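"""Network construction and cycle dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmnet.params import ModelParameters, ConfigurationError
from pmnet.stimuli import Stimulus, Response
from pmnet.network import (standard_geometry, build_weight_matrix,
                           build_bias_vector, compute_net_inputs,
                           update_activation, apply_noise_and_clip,
                           select_response, run_trial, run_trials,
                           TrialResult)

GEOM = standard_geometry()


class TestWeightMatrix:
    def test_left_right_symmetry(self, params):
        W = build_weight_matrix(params)
        left, right, _ = GEOM.output_idx
        # upper-case-left "A" (unit 0) -> Left equals upper-case-right
        # "A" (unit 6) -> Right
        for letter in range(3):
            assert W[left, 2 * letter] == W[right, 6 + 2 * letter]
            assert W[left, 2 * letter] == params.w_input_ongoing
            # and no cross-wiring
            assert W[right, 2 * letter] == 0.0
            assert W[left, 6 + 2 * letter] == 0.0

    def test_one_detector_per_letter(self, params):
        W = build_weight_matrix(params)
        det_a, det_b, det_c = GEOM.detector_idx
        a_left = 1  # lower-case "a" at the left position
        assert W[det_a, a_left] == params.w_input_detector
        assert W[det_b, a_left] == 0.0
        assert W[det_c, a_left] == 0.0
        # every input feeds exactly one detector
        input_to_det = W[np.ix_(GEOM.detector_idx, GEOM.input_idx)]
        assert np.all((input_to_det > 0).sum(axis=0) == 1)

    def test_output_lateral_inhibition_block(self, params):
        W = build_weight_matrix(params)
        block = W[np.ix_(GEOM.output_idx, GEOM.output_idx)]
        assert np.all(np.diag(block) == 0.0)
        off = block[~np.eye(3, dtype=bool)]
        assert np.all(off == params.w_lateral_output)
        assert np.all(off < 0)

    def test_monitor_connects_only_to_detectors(self, params):
        W = build_weight_matrix(params)
        incoming_from_monitor = W[:, GEOM.monitor_idx]
        expected = np.zeros(GEOM.n_units)
        expected[GEOM.detector_idx] = params.w_monitor_detector
        assert np.array_equal(incoming_from_monitor, expected)
        # the monitoring unit receives nothing
        assert np.all(W[GEOM.monitor_idx] == 0.0)

    def test_construction_is_deterministic(self, params):
        assert np.array_equal(build_weight_matrix(params),
                              build_weight_matrix(params))

    def test_invalid_pathway_sign_rejected(self, params):
        with pytest.raises(ConfigurationError):
            params.replace(w_input_detector=-0.5)
        with pytest.raises(ConfigurationError):
            params.replace(w_lateral_output=0.5)
        with pytest.raises(ConfigurationError):
            params.replace(detector_bias=0.1)


class TestNetInputs:
    def test_zero_state_leaves_only_bias(self, params):
        W = build_weight_matrix(params)
        bias = build_bias_vector(params)
        net = compute_net_inputs(np.zeros(19), W, bias)
        assert np.allclose(net[GEOM.detector_idx], params.detector_bias)
        assert np.allclose(net[GEOM.output_idx], 0.0)

    def test_target_trial_detector_drive(self, params):
        # both active inputs of a target feed the same detector
        W = build_weight_matrix(params)
        bias = build_bias_vector(params)
        act = np.zeros(19)
        act[list(Stimulus.from_label("A a").active_units)] = 1.0
        net = compute_net_inputs(act, W, bias)
        det_a = GEOM.detector_idx[0]
        assert net[det_a] == pytest.approx(
            2 * params.w_input_detector + params.detector_bias)

    def test_nontarget_trial_splits_detector_drive(self, params):
        W = build_weight_matrix(params)
        bias = build_bias_vector(params)
        act = np.zeros(19)
        act[list(Stimulus.from_label("A c").active_units)] = 1.0
        net = compute_net_inputs(act, W, bias)
        det_a, det_b, det_c = GEOM.detector_idx
        assert net[det_a] == pytest.approx(
            params.w_input_detector + params.detector_bias)
        assert net[det_c] == pytest.approx(
            params.w_input_detector + params.detector_bias)
        assert net[det_b] == pytest.approx(params.detector_bias)


class TestActivationUpdate:
    def test_zero_net_leaves_activation(self, params):
        assert update_activation(0.3, 0.0, params) == 0.3

    def test_saturation_at_ceiling(self, params):
        assert update_activation(params.act_max, 0.7, params) == params.act_max

    def test_closed_form_increment(self):
        p = ModelParameters(step_size=0.05, noise_sd=0.0)
        # step * net * (max - act) = 0.05 * 0.5 * 1.0
        assert update_activation(0.0, 0.5, p) == pytest.approx(0.025)

    @given(act=st.floats(-0.16, 1.0), net=st.floats(-3.0, 3.0))
    def test_update_respects_bounds(self, act, net):
        p = ModelParameters()
        new = update_activation(act, net, p)
        assert p.act_min - 1e-12 <= new <= p.act_max + 1e-12


class TestNoiseAndClip:
    def test_zero_noise_is_identity_within_bounds(self, quiet_params, rng):
        act = np.linspace(quiet_params.act_min, quiet_params.act_max, 19)
        assert np.array_equal(
            apply_noise_and_clip(act, quiet_params, rng), act)

    def test_result_always_within_bounds(self, params, rng):
        act = np.full(19, params.act_max)
        out = apply_noise_and_clip(act, params, rng)
        assert np.all(out >= params.act_min)
        assert np.all(out <= params.act_max)

    def test_noise_sd_matches_parameter(self, rng):
        # far from the bounds the added noise must have SD noise_sd
        p = ModelParameters(noise_sd=0.02)
        act = np.zeros(100_000)
        out = apply_noise_and_clip(act, p, rng)
        assert out.std() == pytest.approx(0.02, rel=0.02)


class TestResponseRule:
    def test_clear_winner(self, rng):
        p = ModelParameters(response_threshold=0.15)
        assert select_response([0.60, 0.10, 0.10], p) is Response.LEFT

    def test_exact_tie_returns_none(self):
        p = ModelParameters(response_threshold=0.15)
        assert select_response([0.4, 0.4, 0.1], p) is None

    def test_difference_equal_to_threshold_returns_none(self):
        p = ModelParameters(response_threshold=0.25)
        # 0.5 - 0.25 equals the threshold exactly (both binary-exact)
        assert select_response([0.50, 0.25, 0.0], p) is None
        assert select_response([0.50, 0.125, 0.0], p) is not None


class TestRunTrial:
    def test_zero_noise_nontarget_is_deterministic(self, quiet_params):
        stim = Stimulus.from_label("A c")
        r1 = run_trial(stim, quiet_params)
        r2 = run_trial(stim, quiet_params)
        assert r1.response is Response.LEFT
        assert r1.rt_cycles == r2.rt_cycles

    def test_zero_noise_high_monitoring_target_yields_pm(self, quiet_params):
        p = quiet_params.replace(monitoring_activation=1.0)
        result = run_trial(Stimulus.from_label("a A"), p)
        assert result.response is Response.PM

    def test_unreachable_threshold_times_out(self, quiet_params):
        p = quiet_params.replace(
            response_threshold=quiet_params.act_max
            - quiet_params.act_min + 1.0)
        result = run_trial(Stimulus.from_label("A c"), p)
        assert result.response is Response.TIMEOUT
        assert result.rt_cycles is None

    def test_rt_never_exceeds_max_cycles(self, params, rng):
        for result in run_trials(
                [Stimulus.from_label("a A")] * 50, params, rng):
            if result.response is not Response.TIMEOUT:
                assert 1 <= result.rt_cycles <= params.max_cycles

    def test_timeout_result_requires_absent_rt(self):
        with pytest.raises(ValueError):
            TrialResult(Response.TIMEOUT, 500)
        with pytest.raises(ValueError):
            TrialResult(Response.LEFT, None)

    def test_activations_bounded_on_every_cycle(self, params):
        result = run_trial(Stimulus.from_label("a A"),
                           params.replace(monitoring_activation=1.0),
                           rng=np.random.default_rng(7),
                           record_trajectory=True)
        traj = result.trajectory
        assert np.all(traj >= params.act_min - 1e-12)
        assert np.all(traj <= params.act_max + 1e-12)

    def test_target_trial_shows_response_competition(self, quiet_params):
        # on a zero-noise target trial both the PM output and the
        # correct ongoing output build positive activation
        result = run_trial(Stimulus.from_label("a A"), quiet_params,
                           record_trajectory=True)
        left, right, pm = GEOM.output_idx
        traj = result.trajectory
        assert traj[:, pm].max() > 0.1
        assert traj[:, right].max() > 0.1

    def test_identical_seeds_reproduce_trial_sequences(self, params):
        stims = [Stimulus.from_label("A c"), Stimulus.from_label("a A")] * 10
        res1 = run_trials(stims, params, np.random.default_rng(99))
        res2 = run_trials(stims, params, np.random.default_rng(99))
        assert res1 == res2


def _reference_cycle(act, clamp12, monitoring, W, bias, params, noise):
    """Straight-line, non-vectorized reference for one cycle
    (net -> update non-clamped -> re-clamp -> add noise -> clip)."""
    n = len(act)
    net = [0.0] * n
    for i in range(12, 18):           # detectors and outputs
        total = bias[i]
        for j in range(n):
            total += W[i][j] * act[j]
        net[i] = total
    new = list(act)
    for i in range(12, 18):
        if net[i] > 0:
            new[i] = act[i] + params.step_size * net[i] * (params.act_max - act[i])
        else:
            new[i] = act[i] + params.step_size * net[i] * (act[i] - params.act_min)
    for i in range(12):
        new[i] = clamp12[i]
    new[18] = monitoring
    for i in range(n):
        value = new[i] + noise[i]
        new[i] = min(max(value, params.act_min), params.act_max)
    return np.array(new)


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 2**31 - 1),
       label=st.sampled_from(["A c", "a A", "B b", "c B"]),
       n_cycles=st.integers(1, 5))
def test_production_cycle_matches_straight_line_reference(seed, label,
                                                          n_cycles):
    """Oracle equivalence: the vectorized engine agrees cycle-by-cycle
    with an index-by-index reference implementation (the noise after
    cycle 1 makes the later states effectively arbitrary)."""
    from pmnet.network import simulate_batch

    params = ModelParameters()
    stim = Stimulus.from_label(label)
    clamp12 = np.zeros(12)
    clamp12[list(stim.active_units)] = params.input_activation
    W = build_weight_matrix(params)
    bias = build_bias_vector(params)

    blocked = params.replace(
        max_cycles=n_cycles,
        response_threshold=params.act_max - params.act_min + 1)
    _, _, traj = simulate_batch(
        W, bias, standard_geometry(), clamp12[None, :],
        params.monitoring_activation, blocked,
        np.random.default_rng(seed), record_trajectory=True)

    # reference: same initial clamped state, same noise stream
    noise_rng = np.random.default_rng(seed)
    state = np.zeros(19)
    state[:12] = clamp12
    state[18] = params.monitoring_activation
    for cycle in range(1, n_cycles + 1):
        noise = noise_rng.normal(0, params.noise_sd, (1, 19))[0]
        state = _reference_cycle(state, clamp12,
                                 params.monitoring_activation,
                                 W, bias, params, noise)
        np.testing.assert_allclose(traj[cycle], state, atol=1e-12)
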