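"""The interactive-activation network core.

The standard model has 19 units: 12 stimulus input units (six letter
tokens at each of two positions), 3 target-detection units (one per
letter), 3 output units (Left, Right, PM) and 1 top-down monitoring
unit.  Activation spreads along four positive pathways — input->ongoing
output (direct stimulus-response), input->detector, detector->PM output,
monitor->detector — while lateral inhibition within the output and
detector layers drives winner-take-all competition.

Dynamics.  All activations start at zero.  Each cycle, the net input of
every non-clamped unit is the weighted sum of all current activations
(detectors additionally receive a negative bias), activations are
updated with the interactive-activation rule

    d_act = step * net * (act_max - act)   if net > 0
    d_act = step * net * (act - act_min)   otherwise,

the stimulus input and monitoring units are re-clamped to their external
levels, independent Gaussian noise is added to every unit (clamped ones
included, so their slightly noisy value is what other units read on the
following cycle), activations are reset to the nearest bound where they
exceed it, and the response rule is tested: if the most active output
unit exceeds the second most active by strictly more than the response
threshold, the trial ends and the cycle count is the RT.  Trials that
never reach threshold within ``max_cycles`` cycles are timeout errors
with no RT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pmnet.params import ModelParameters, ConfigurationError
from pmnet.stimuli import Stimulus, Response

__all__ = [
    "NetworkGeometry",
    "standard_geometry",
    "build_weight_matrix",
    "build_bias_vector",
    "TrialResult",
    "run_trial",
    "run_trials",
    "simulate_batch",
    "simulate_batch_dual",
]

#: Output-unit order within any geometry: Left, Right, PM.
OUTPUT_RESPONSES = (Response.LEFT, Response.RIGHT, Response.PM)


@dataclass(frozen=True)
class NetworkGeometry:
    """Index layout of a model variant's unit vector.

    The standard model and the single-detector encoding variant share
    the same cycle dynamics and differ only in unit counts and indices.
    """

    n_units: int
    input_idx: np.ndarray      # 12 stimulus input units
    detector_idx: np.ndarray   # target-detection units
    output_idx: np.ndarray     # Left, Right, PM (in that order)
    monitor_idx: int

    @property
    def updatable_idx(self) -> np.ndarray:
        """Units whose activation evolves (detectors + outputs)."""
        return np.concatenate([self.detector_idx, self.output_idx])


def standard_geometry() -> NetworkGeometry:
    """The 19-unit layout: inputs 0-11, detectors 12-14, outputs 15-17
    (Left, Right, PM), monitoring unit 18."""
    return NetworkGeometry(
        n_units=19,
        input_idx=np.arange(12),
        detector_idx=np.arange(12, 15),
        output_idx=np.arange(15, 18),
        monitor_idx=18,
    )


def build_weight_matrix(params: ModelParameters,
                        geometry: NetworkGeometry | None = None) -> np.ndarray:
    """Construct the signed connection matrix of the standard model.

    ``W[i, j]`` is the weight of the connection from unit ``j`` to unit
    ``i``.  Upper-case-left inputs project to the Left output and
    upper-case-right inputs to the Right output (the direct ongoing
    pathway); each input projects to its letter's detection unit; all
    detectors project to the PM output; the monitoring unit projects to
    all detectors; the off-diagonals of the output and detector blocks
    carry the negative lateral-inhibition weights.  Everything else is
    zero.
    """
    params.validate()
    geom = geometry or standard_geometry()
    W = np.zeros((geom.n_units, geom.n_units))

    left, right, pm = geom.output_idx
    # Direct ongoing pathway: upper-case tokens are at within-position
    # offsets 0, 2, 4 (A, B, C); left position occupies inputs 0-5.
    for letter in range(3):
        W[left, 2 * letter] = params.w_input_ongoing        # upper at left
        W[right, 6 + 2 * letter] = params.w_input_ongoing   # upper at right

    # Input -> detector: both cases, both positions, one detector per letter.
    for letter in range(3):
        det = geom.detector_idx[letter]
        for unit in (2 * letter, 2 * letter + 1,
                     6 + 2 * letter, 6 + 2 * letter + 1):
            W[det, unit] = params.w_input_detector

    # Detector -> PM output, monitor -> detector.
    W[pm, geom.detector_idx] = params.w_detector_pm
    W[np.ix_(geom.detector_idx, [geom.monitor_idx])] = params.w_monitor_detector

    # Lateral inhibition: off-diagonal within the output and detector blocks.
    for block, weight in ((geom.output_idx, params.w_lateral_output),
                          (geom.detector_idx, params.w_lateral_detector)):
        sub = np.full((len(block), len(block)), weight)
        np.fill_diagonal(sub, 0.0)
        W[np.ix_(block, block)] = sub

    return W


def build_bias_vector(params: ModelParameters,
                      geometry: NetworkGeometry | None = None) -> np.ndarray:
    """Net-input bias per unit: ``detector_bias`` at detectors, else 0."""
    geom = geometry or standard_geometry()
    bias = np.zeros(geom.n_units)
    bias[geom.detector_idx] = params.detector_bias
    return bias


def compute_net_inputs(activations: np.ndarray, weights: np.ndarray,
                       bias: np.ndarray) -> np.ndarray:
    """Net input of every unit from the current activation vector.

    The net input of a unit is the sum of every other unit's activation
    times the corresponding connection weight, plus the unit's bias
    (the negative ``detector_bias`` for target-detection units, zero
    elsewhere).  Computed synchronously: all net inputs derive from the
    same activation snapshot.
    """
    return weights @ np.asarray(activations, dtype=float) + bias


def update_activation(act: float | np.ndarray, net: float | np.ndarray,
                      params: ModelParameters) -> float | np.ndarray:
    """One interactive-activation update step.

    Excitatory net input drives the activation towards ``act_max`` in
    proportion to the remaining headroom; inhibitory net input drives
    it towards ``act_min`` in proportion to the remaining floor room.
    """
    act = np.asarray(act, dtype=float)
    net = np.asarray(net, dtype=float)
    delta = np.where(net > 0.0,
                     params.step_size * net * (params.act_max - act),
                     params.step_size * net * (act - params.act_min))
    out = act + delta
    return float(out) if out.ndim == 0 else out


def apply_noise_and_clip(activations: np.ndarray, params: ModelParameters,
                         rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise to every unit, then reset activations
    outside ``[act_min, act_max]`` to the nearest bound."""
    act = np.asarray(activations, dtype=float)
    if params.noise_sd > 0.0:
        act = act + rng.normal(0.0, params.noise_sd, act.shape)
    return np.clip(act, params.act_min, params.act_max)


def select_response(output_activations: np.ndarray,
                    params: ModelParameters) -> Response | None:
    """The winner-take-all response rule.

    Returns the response of the most active output unit iff it exceeds
    the second most active by strictly more than the response
    threshold; ties and sub-threshold differences return ``None`` (the
    trial keeps cycling).
    """
    outs = np.asarray(output_activations, dtype=float)
    order = np.argsort(outs)
    if outs[order[-1]] - outs[order[-2]] > params.response_threshold:
        return OUTPUT_RESPONSES[order[-1]]
    return None


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial.

    ``rt_cycles`` is ``None`` exactly when the response is a timeout
    (the trial is recorded as an error without an RT).
    """

    response: Response
    rt_cycles: int | None
    trajectory: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if (self.response is Response.TIMEOUT) != (self.rt_cycles is None):
            raise ValueError("rt_cycles must be absent iff the trial timed out")


def _clamp_matrix(stimuli: list[Stimulus], params: ModelParameters) -> np.ndarray:
    """Per-trial clamp levels of the 12 input units (active units at
    ``input_activation``, all others at 0)."""
    clamp = np.zeros((len(stimuli), 12))
    for i, stim in enumerate(stimuli):
        clamp[i, list(stim.active_units)] = params.input_activation
    return clamp


def simulate_batch(
    W: np.ndarray,
    bias: np.ndarray,
    geom: NetworkGeometry,
    clamp_inputs: np.ndarray,
    monitoring_level: float,
    params: ModelParameters,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Run many trials of the cycle dynamics in parallel.

    Parameters
    ----------
    clamp_inputs:
        Array of shape ``(n_trials, 12)`` giving each trial's clamp
        levels for the stimulus input units.  (The encoding variant
        passes per-trial perturbed clamp vectors here.)
    monitoring_level:
        Clamp level of the monitoring unit for every trial.

    Returns
    -------
    responses, rts, trajectory
        ``responses``: int array, index into ``geom.output_idx``'s
        Left/Right/PM order, or -1 for timeout.  ``rts``: int array of
        cycle counts (0 where timeout).  ``trajectory`` is the per-cycle
        activation record (``max_cycles+1 x n_units``), only for a
        single trial when ``record_trajectory`` is set.
    """
    n = clamp_inputs.shape[0]
    if record_trajectory and n != 1:
        raise ValueError("trajectory recording requires a single trial")
    upd = geom.updatable_idx
    W_upd = W[upd]
    bias_upd = bias[upd]
    out_idx = geom.output_idx

    act = np.zeros((n, geom.n_units))
    act[:, geom.input_idx] = clamp_inputs
    act[:, geom.monitor_idx] = monitoring_level

    responses = np.full(n, -1, dtype=np.int64)
    rts = np.zeros(n, dtype=np.int64)
    alive = np.arange(n)
    trajectory = None
    if record_trajectory:
        trajectory = np.zeros((params.max_cycles + 1, geom.n_units))
        trajectory[0] = act[0]

    step = params.step_size
    amax, amin = params.act_max, params.act_min
    for cycle in range(1, params.max_cycles + 1):
        A = act[alive]
        net = A @ W_upd.T + bias_upd
        cur = A[:, upd]
        delta = np.where(net > 0.0,
                         step * net * (amax - cur),
                         step * net * (cur - amin))
        A[:, upd] = cur + delta
        # re-clamp externals, then noise every unit, then bound
        A[:, geom.input_idx] = clamp_inputs[alive]
        A[:, geom.monitor_idx] = monitoring_level
        if params.noise_sd > 0.0:
            A += rng.normal(0.0, params.noise_sd, A.shape)
        np.clip(A, amin, amax, out=A)
        act[alive] = A
        if record_trajectory:
            trajectory[cycle] = act[0]

        outs = A[:, out_idx]
        order = np.argsort(outs, axis=1)
        top = order[:, -1]
        rows = np.arange(len(alive))
        diff = outs[rows, top] - outs[rows, order[:, -2]]
        done = diff > params.response_threshold
        if done.any():
            done_idx = alive[done]
            responses[done_idx] = top[done]
            rts[done_idx] = cycle
            alive = alive[~done]
            if alive.size == 0:
                break

    if record_trajectory and responses[0] >= 0:
        trajectory = trajectory[: rts[0] + 1]
    return responses, rts, trajectory


def _results_from_arrays(responses: np.ndarray, rts: np.ndarray,
                         trajectory=None) -> list[TrialResult]:
    out = []
    for i, resp in enumerate(responses):
        if resp < 0:
            out.append(TrialResult(Response.TIMEOUT, None))
        else:
            out.append(TrialResult(OUTPUT_RESPONSES[resp], int(rts[i]),
                                   trajectory if len(responses) == 1 else None))
    return out


def run_trial(
    stimulus: Stimulus,
    params: ModelParameters,
    weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    record_trajectory: bool = False,
) -> TrialResult:
    """Simulate a single trial of the standard model.

    With ``noise_sd = 0`` the dynamics are deterministic and the result
    is a pure function of the stimulus and parameters.
    """
    geom = standard_geometry()
    if weights is None:
        weights = build_weight_matrix(params, geom)
    _validate_weight_signs(weights, geom)
    if rng is None:
        rng = np.random.default_rng()
    clamp = _clamp_matrix([stimulus], params)
    responses, rts, traj = simulate_batch(
        weights, build_bias_vector(params, geom), geom, clamp,
        params.monitoring_activation, params, rng,
        record_trajectory=record_trajectory)
    return _results_from_arrays(responses, rts, traj)[0]


def run_trials(
    stimuli: list[Stimulus],
    params: ModelParameters,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> list[TrialResult]:
    """Simulate one trial per listed stimulus (vectorized internally)."""
    geom = standard_geometry()
    if weights is None:
        weights = build_weight_matrix(params, geom)
    clamp = _clamp_matrix(stimuli, params)
    responses, rts, _ = simulate_batch(
        weights, build_bias_vector(params, geom), geom, clamp,
        params.monitoring_activation, params, rng)
    return _results_from_arrays(responses, rts)


def _validate_weight_signs(W: np.ndarray, geom: NetworkGeometry) -> None:
    out_block = W[np.ix_(geom.output_idx, geom.output_idx)]
    off = out_block[~np.eye(3, dtype=bool)]
    if np.any(off > 0):
        raise ConfigurationError("output lateral weights must be <= 0")


def simulate_batch_dual(
    W: np.ndarray,
    bias: np.ndarray,
    geom: NetworkGeometry,
    clamp_inputs: np.ndarray,
    monitoring_level: float,
    params: ModelParameters,
    pm_response_threshold: float,
    rng: np.random.Generator,
    pm_window: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run trials of the dual-task (noncompetitive) variant.

    The ongoing and PM pathways are fully decoupled: the caller passes a
    weight matrix without output-layer lateral inhibition, the ongoing
    response is selected when the more active of the Left/Right units
    exceeds the other by strictly more than ``response_threshold``, and
    the PM response is emitted independently when the PM unit's
    activation exceeds ``pm_response_threshold``.  A single trial may
    therefore record both responses, each with its own RT.

    Returns ``(ongoing_responses, ongoing_rts, pm_made, pm_rts)`` where
    ``ongoing_responses`` indexes Left=0/Right=1 (-1 if never selected)
    and ``pm_made`` is boolean.
    """
    n = clamp_inputs.shape[0]
    upd = geom.updatable_idx
    W_upd = W[upd]
    bias_upd = bias[upd]
    left, right, pm = geom.output_idx

    act = np.zeros((n, geom.n_units))
    act[:, geom.input_idx] = clamp_inputs
    act[:, geom.monitor_idx] = monitoring_level

    ongoing_resp = np.full(n, -1, dtype=np.int64)
    ongoing_rt = np.zeros(n, dtype=np.int64)
    pm_made = np.zeros(n, dtype=bool)
    pm_rt = np.zeros(n, dtype=np.int64)
    alive = np.arange(n)

    step = params.step_size
    amax, amin = params.act_max, params.act_min
    for cycle in range(1, params.max_cycles + 1):
        A = act[alive]
        net = A @ W_upd.T + bias_upd
        cur = A[:, upd]
        delta = np.where(net > 0.0,
                         step * net * (amax - cur),
                         step * net * (cur - amin))
        A[:, upd] = cur + delta
        A[:, geom.input_idx] = clamp_inputs[alive]
        A[:, geom.monitor_idx] = monitoring_level
        if params.noise_sd > 0.0:
            A += rng.normal(0.0, params.noise_sd, A.shape)
        np.clip(A, amin, amax, out=A)
        act[alive] = A

        need_ongoing = ongoing_resp[alive] < 0
        lr = A[:, [left, right]]
        diff = np.abs(lr[:, 0] - lr[:, 1])
        ongoing_now = need_ongoing & (diff > params.response_threshold)
        if ongoing_now.any():
            idx = alive[ongoing_now]
            ongoing_resp[idx] = (lr[ongoing_now, 1]
                                 > lr[ongoing_now, 0]).astype(np.int64)
            ongoing_rt[idx] = cycle

        in_window = pm_window is None or cycle <= pm_window
        need_pm = ~pm_made[alive] if in_window else np.zeros(len(alive), bool)
        pm_now = need_pm & (A[:, pm] > pm_response_threshold)
        if pm_now.any():
            idx = alive[pm_now]
            pm_made[idx] = True
            pm_rt[idx] = cycle

        pm_settled = pm_made[alive] | (not (pm_window is None or cycle < pm_window))
        finished = (ongoing_resp[alive] >= 0) & pm_settled
        # PM responses are optional: a trial also ends once the ongoing
        # response has been made and the PM unit is decaying (we keep
        # cycling until max_cycles so late PM responses can register).
        if finished.all():
            break
        alive = alive[~finished]
        if alive.size == 0:
            break

    return ongoing_resp, ongoing_rt, pm_made, pm_rt
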