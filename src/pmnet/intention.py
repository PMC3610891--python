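"""Hebbian intention encoding, retrieval similarity, and deactivation.

A single-detector variant of the model simulates the dynamic encoding
of a new PM target: both hard-wired input->detector connections and two
of the three detection units are removed, leaving 17 units.  To encode
an intention, the target stimulus is presented (its two input units at
1, all 12 input units perturbed by Gaussian noise simulating perceptual
and contextual variability), the detector is clamped to 1, and one-shot
Hebbian learning sets each input->detector weight to the product of the
two activation levels (learning rate 1; the new weights replace any
previous intention).

At test, every trial's input clamp receives a fresh perturbation of the
same kind, fixed for the duration of the trial, on top of the per-cycle
dynamic noise.  Encoding-retrieval similarity is the Pearson correlation
between the 12 perturbed input levels at encoding and on a given target
trial; the model reproduces higher similarity for PM hits than misses.
Deactivation is simulated by switching monitoring off (and optionally
decaying the learned weights) and running a post-PM block, in which PM
responses to the previous target are commission errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmnet.params import ModelParameters
from pmnet.stimuli import Stimulus, enumerate_stimuli
from pmnet.network import NetworkGeometry, simulate_batch

__all__ = [
    "EncodingConfig",
    "LearnedIntention",
    "SingleDetectorModel",
    "single_detector_geometry",
    "build_single_detector_model",
    "encode_target",
    "run_encoding_experiment",
    "deactivation_experiment",
]


@dataclass(frozen=True)
class EncodingConfig:
    """Settings of the encoding simulation.

    ``encode_noise_sd`` is the SD of the Gaussian perturbation applied
    to each of the 12 stimulus input units both at encoding and on
    every test trial; ``learning_rate`` scales the Hebbian product (1
    reproduces the unscaled update); the detector is clamped to
    ``detector_clamp`` during encoding.
    """

    encode_noise_sd: float = 0.15
    learning_rate: float = 1.0
    detector_clamp: float = 1.0

    def __post_init__(self) -> None:
        if self.encode_noise_sd < 0:
            raise ValueError("encode_noise_sd must be >= 0")


@dataclass(frozen=True)
class LearnedIntention:
    """Result of one-shot Hebbian encoding of a target stimulus."""

    stimulus: Stimulus
    weights: np.ndarray           # 12 input->detector weights
    encoding_vector: np.ndarray   # the perturbed 12-unit input pattern


def single_detector_geometry() -> NetworkGeometry:
    """17-unit layout: inputs 0-11, detector 12, outputs 13-15
    (Left, Right, PM), monitoring unit 16."""
    return NetworkGeometry(
        n_units=17,
        input_idx=np.arange(12),
        detector_idx=np.array([12]),
        output_idx=np.arange(13, 16),
        monitor_idx=16,
    )


@dataclass
class SingleDetectorModel:
    """The encoding variant: architecture and weights.

    Apart from the removed detectors and the zero-initialized (learned)
    input->detector weights, all connection weights and parameters equal
    the base model's.
    """

    params: ModelParameters
    geometry: NetworkGeometry
    weights: np.ndarray
    bias: np.ndarray
    intention: LearnedIntention | None = None

    def with_intention(self, intention: LearnedIntention,
                       decay_factor: float = 1.0) -> "SingleDetectorModel":
        """Copy with the learned input->detector row installed
        (optionally decayed, simulating trace decay)."""
        W = self.weights.copy()
        det = self.geometry.detector_idx[0]
        W[det, self.geometry.input_idx] = decay_factor * intention.weights
        return SingleDetectorModel(self.params, self.geometry, W,
                                   self.bias, intention)


def build_single_detector_model(params: ModelParameters) -> SingleDetectorModel:
    """Construct the 17-unit variant with empty input->detector weights."""
    params.validate()
    geom = single_detector_geometry()
    W = np.zeros((geom.n_units, geom.n_units))
    left, right, pm = geom.output_idx
    det = geom.detector_idx[0]
    for letter in range(3):
        W[left, 2 * letter] = params.w_input_ongoing
        W[right, 6 + 2 * letter] = params.w_input_ongoing
    W[pm, det] = params.w_detector_pm
    W[det, geom.monitor_idx] = params.w_monitor_detector
    sub = np.full((3, 3), params.w_lateral_output)
    np.fill_diagonal(sub, 0.0)
    W[np.ix_(geom.output_idx, geom.output_idx)] = sub
    bias = np.zeros(geom.n_units)
    bias[det] = params.detector_bias
    return SingleDetectorModel(params, geom, W, bias)


def encode_target(model: SingleDetectorModel, stimulus: Stimulus,
                  config: EncodingConfig,
                  rng: np.random.Generator) -> LearnedIntention:
    """One-shot Hebbian encoding of ``stimulus`` as the PM target.

    The input pattern is 1 at the stimulus's two active units and 0
    elsewhere, perturbed unit-wise by N(0, ``encode_noise_sd``); the
    detector is clamped to 1, and each input->detector weight is set to
    ``learning_rate`` x input x detector activation (overwriting any
    previous intention).
    """
    pattern = np.zeros(12)
    pattern[list(stimulus.active_units)] = 1.0
    if config.encode_noise_sd > 0:
        pattern = pattern + rng.normal(0.0, config.encode_noise_sd, 12)
    weights = config.learning_rate * pattern * config.detector_clamp
    return LearnedIntention(stimulus, weights, pattern)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between x (n, k) and y (k,)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    return (xc @ yc) / denom


def _test_block(model: SingleDetectorModel, target: Stimulus,
                n_per_other: int, config: EncodingConfig,
                rng: np.random.Generator):
    """Run one test block: every non-target stimulus ``n_per_other``
    times and the target as often as all others summed.  Returns
    (stimuli batch, is_target mask, clamp matrix, responses, rts)."""
    others = [s for s in enumerate_stimuli() if s.label != target.label]
    batch = []
    for s in others:
        batch.extend([s] * n_per_other)
    n_target = len(others) * n_per_other
    batch.extend([target] * n_target)
    is_target = np.zeros(len(batch), dtype=bool)
    is_target[-n_target:] = True

    clamp = np.zeros((len(batch), 12))
    rows = np.arange(len(batch))
    active = np.array([s.active_units for s in batch])
    clamp[rows[:, None], active] = model.params.input_activation
    if config.encode_noise_sd > 0:
        clamp = clamp + rng.normal(0.0, config.encode_noise_sd,
                                   clamp.shape)
    responses, rts, _ = simulate_batch(
        model.weights, model.bias, model.geometry, clamp,
        model.params.monitoring_activation, model.params, rng)
    return batch, is_target, clamp, responses, rts


def _block_frame(batch, is_target, responses, rts) -> pd.DataFrame:
    correct_side = np.array([0 if s.correct_ongoing.value == "Left" else 1
                             for s in batch])
    pm = responses == 2
    timeout = responses < 0
    ongoing_ok = (~pm) & (~timeout) & (responses == correct_side)
    return pd.DataFrame({
        "is_target": is_target,
        "pm_response": pm,
        "timeout": timeout,
        "ongoing_correct_side": ongoing_ok,
        "rt_cycles": np.where(timeout, np.nan, rts.astype(float)),
    })


def _pooled_cv(rts: np.ndarray) -> float:
    rts = rts[~np.isnan(rts)]
    return float(rts.std(ddof=1) / rts.mean()) if rts.size >= 2 else np.nan


def run_encoding_experiment(
    params: ModelParameters,
    config: EncodingConfig | None = None,
    n_reps: int = 1000,
    n_per_nontarget: int = 100,
    seed: int = 0,
) -> dict:
    """The full encoding simulation.

    Each repetition picks a random target stimulus, encodes it, then
    runs a test block in which each of the 17 other stimuli appears
    ``n_per_nontarget`` times and the target as often as all the others
    summed.  Per-trial input perturbations (same SD as at encoding) are
    fixed for the trial, with per-cycle dynamic noise on top.

    Returns a dict with pooled behavioural statistics (hit rate, false
    alarm rate, ongoing accuracy, RTs and CVs per trial type) and the
    encoding-retrieval ``similarity`` records, one row per target trial
    (repetition, outcome, Pearson r against the encoding vector).
    """
    if config is None:
        config = EncodingConfig()
    if n_reps < 1 or n_per_nontarget < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    base = build_single_detector_model(params)
    stimuli = enumerate_stimuli()

    frames = []
    sim_rows = []
    for rep in range(n_reps):
        target = stimuli[rng.integers(len(stimuli))]
        intention = encode_target(base, target, config, rng)
        model = base.with_intention(intention)
        batch, is_target, clamp, responses, rts = _test_block(
            model, target, n_per_nontarget, config, rng)
        frame = _block_frame(batch, is_target, responses, rts)
        frame["rep"] = rep
        frames.append(frame)
        # encoding-retrieval similarity on target trials
        t_mask = is_target
        r = _pearson_rows(clamp[t_mask], intention.encoding_vector)
        outcome = np.where(frame.loc[t_mask, "pm_response"], "hit",
                           np.where(frame.loc[t_mask, "timeout"],
                                    "timeout", "miss"))
        sim_rows.append(pd.DataFrame(
            {"rep": rep, "outcome": outcome, "r": r}))

    trials = pd.concat(frames, ignore_index=True)
    similarity = pd.concat(sim_rows, ignore_index=True)

    targets = trials[trials.is_target]
    nontargets = trials[~trials.is_target]
    hits = targets[targets.pm_response]
    misses = targets[~targets.pm_response & ~targets.timeout]
    ongoing = nontargets[nontargets.ongoing_correct_side]

    return {
        "hit_rate": float(targets.pm_response.mean()),
        "false_alarm_rate": float(nontargets.pm_response.mean()),
        "ongoing_accuracy": float(nontargets.ongoing_correct_side.mean()),
        "ongoing_rt": float(ongoing.rt_cycles.mean()),
        "pm_miss_rt": float(misses.rt_cycles.mean()),
        "pm_hit_rt": float(hits.rt_cycles.mean()),
        "cv_ongoing": _pooled_cv(ongoing.rt_cycles.to_numpy()),
        "cv_pm_hit": _pooled_cv(hits.rt_cycles.to_numpy()),
        "cv_pm_miss": _pooled_cv(misses.rt_cycles.to_numpy()),
        "similarity_hits": float(
            similarity.loc[similarity.outcome == "hit", "r"].mean()),
        "similarity_misses": float(
            similarity.loc[similarity.outcome == "miss", "r"].mean()),
        "similarity": similarity,
        "n_reps": n_reps,
        "n_per_nontarget": n_per_nontarget,
    }


def deactivation_experiment(
    params: ModelParameters,
    config: EncodingConfig | None = None,
    decay_factor: float = 1.0,
    n_reps: int = 1000,
    n_per_nontarget: int = 100,
    seed: int = 0,
) -> dict:
    """Post-PM block: the intention is no longer relevant.

    Each repetition encodes a random target, then runs a block with the
    monitoring level set to zero and the learned input->detector
    weights multiplied by ``decay_factor`` (1.0 = intact trace, 0.5 =
    50% decay).  PM responses to the previous target are commission
    errors.  Reports the commission-error rate, the false-alarm rate on
    other stimuli, and ongoing RT for previous-target vs nontarget
    trials.
    """
    if config is None:
        config = EncodingConfig()
    if decay_factor < 0:
        raise ValueError("decay_factor must be >= 0")
    rng = np.random.default_rng(seed)
    post_params = params.replace(monitoring_activation=0.0)
    base = build_single_detector_model(post_params)
    stimuli = enumerate_stimuli()

    frames = []
    for rep in range(n_reps):
        target = stimuli[rng.integers(len(stimuli))]
        intention = encode_target(base, target, config, rng)
        model = base.with_intention(intention, decay_factor=decay_factor)
        batch, is_target, _, responses, rts = _test_block(
            model, target, n_per_nontarget, config, rng)
        frame = _block_frame(batch, is_target, responses, rts)
        frame["rep"] = rep
        frames.append(frame)

    trials = pd.concat(frames, ignore_index=True)
    prev = trials[trials.is_target]       # previous-target trials
    others = trials[~trials.is_target]
    prev_ongoing = prev[prev.ongoing_correct_side]
    other_ongoing = others[others.ongoing_correct_side]
    return {
        "decay_factor": decay_factor,
        "commission_rate": float(prev.pm_response.mean()),
        "false_alarm_rate": float(others.pm_response.mean()),
        "previous_target_rt": float(prev_ongoing.rt_cycles.mean()),
        "nontarget_rt": float(other_ongoing.rt_cycles.mean()),
        "n_reps": n_reps,
        "n_per_nontarget": n_per_nontarget,
    }
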