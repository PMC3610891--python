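"""Batch simulation experiments and derived effect measures.

This module reproduces the model's simulation studies: sweeps over the
monitoring level (no / standard / high), stimulus degradation, the
intention-superiority effect and the intention-maintenance cost, plus
the noncompetitive dual-task architectural variant.

Trial-level results are plain :class:`pandas.DataFrame` tables with the
columns ``trial, condition, stimulus, is_target, response, rt_cycles,
trial_class, seed`` (``rt_cycles`` is missing on timeout trials, which
are recorded as errors without an RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmnet.params import ModelParameters
from pmnet.stimuli import Stimulus, Response, TrialClass, enumerate_stimuli, classify_trial
from pmnet.network import (
    NetworkGeometry,
    standard_geometry,
    build_weight_matrix,
    build_bias_vector,
    simulate_batch,
    simulate_batch_dual,
    OUTPUT_RESPONSES,
)

TRIAL_COLUMNS = ["trial", "condition", "stimulus", "is_target",
                 "response", "rt_cycles", "trial_class", "seed"]


def _build_stimulus_batch(n_per_nontarget: int, n_per_target: int
                          ) -> tuple[list[Stimulus], np.ndarray]:
    """Every stimulus repeated its per-type count (targets last)."""
    stimuli = enumerate_stimuli()
    nontargets = [s for s in stimuli if not s.is_target]
    targets = [s for s in stimuli if s.is_target]
    batch: list[Stimulus] = []
    for s in nontargets:
        batch.extend([s] * n_per_nontarget)
    for s in targets:
        batch.extend([s] * n_per_target)
    clamp_rows = np.array([s.active_units for s in batch])
    return batch, clamp_rows


def run_condition(
    params: ModelParameters,
    n_per_nontarget: int,
    n_per_target: int,
    seed: int,
    condition: str = "standard",
) -> pd.DataFrame:
    """Simulate a full condition and return the trial table.

    Each of the 12 nontarget stimuli is run ``n_per_nontarget`` times
    and each of the 6 target stimuli ``n_per_target`` times; running
    targets at twice the nontarget count therefore yields equal total
    numbers of target and nontarget trials.  The table is fully
    determined by ``seed``.
    """
    if n_per_nontarget <= 0 or n_per_target <= 0:
        raise ValueError("per-stimulus trial counts must be > 0")
    geom = standard_geometry()
    W = build_weight_matrix(params, geom)
    bias = build_bias_vector(params, geom)
    batch, active = _build_stimulus_batch(n_per_nontarget, n_per_target)
    clamp = np.zeros((len(batch), 12))
    clamp[np.arange(len(batch))[:, None], active] = params.input_activation
    rng = np.random.default_rng(seed)
    responses, rts, _ = simulate_batch(
        W, bias, geom, clamp, params.monitoring_activation, params, rng)
    return _trial_table(batch, responses, rts, condition, seed)


def _trial_table(batch: list[Stimulus], responses: np.ndarray,
                 rts: np.ndarray, condition: str, seed: int) -> pd.DataFrame:
    resp_objs = [Response.TIMEOUT if r < 0 else OUTPUT_RESPONSES[r]
                 for r in responses]
    classes = [classify_trial(s, r) for s, r in zip(batch, resp_objs)]
    return pd.DataFrame({
        "trial": np.arange(len(batch)),
        "condition": condition,
        "stimulus": [s.label for s in batch],
        "is_target": [s.is_target for s in batch],
        "response": [r.value for r in resp_objs],
        "rt_cycles": pd.array([int(rt) if r >= 0 else pd.NA
                               for r, rt in zip(responses, rts)],
                              dtype="Int64"),
        "trial_class": [c.value for c in classes],
        "seed": seed,
    })


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition behavioural statistics.

    RT statistics are computed over non-timeout trials only; rate
    denominators include timeouts (a timeout is an error).  Statistics
    of empty classes are ``None`` rather than zero.
    """

    condition: str
    n_trials: int
    class_stats: pd.DataFrame     # per trial_class: n, mean_rt, sd_rt, cv
    hit_rate: float | None
    ongoing_accuracy: float | None
    false_alarm_rate: float | None
    timeout_rate: float
    mean_ongoing_rt: float | None
    mean_pm_miss_rt: float | None
    mean_pm_hit_rt: float | None

    def class_cv(self, trial_class: TrialClass) -> float | None:
        row = self.class_stats.loc[self.class_stats.trial_class
                                   == trial_class.value]
        if row.empty:
            return None
        value = row.iloc[0]["cv"]
        return None if pd.isna(value) else float(value)


def _mean_rt(df: pd.DataFrame, classes: list[TrialClass]) -> float | None:
    values = df.loc[df.trial_class.isin([c.value for c in classes]),
                    "rt_cycles"].dropna()
    return float(values.mean()) if len(values) else None


def summarize(trials: pd.DataFrame) -> ConditionSummary:
    """Reduce a trial table to per-class RT statistics and rates."""
    if trials.empty:
        raise ValueError("cannot summarize an empty trial table")
    rows = []
    for cls, group in trials.groupby("trial_class"):
        rt = group["rt_cycles"].dropna().astype(float)
        n = len(group)
        mean = rt.mean() if len(rt) else np.nan
        sd = rt.std(ddof=1) if len(rt) >= 2 else np.nan
        rows.append({"trial_class": cls, "n": n, "mean_rt": mean,
                     "sd_rt": sd, "cv": sd / mean if len(rt) >= 2 else np.nan})
    class_stats = pd.DataFrame(rows)

    n_target = int(trials.is_target.sum())
    n_nontarget = int((~trials.is_target).sum())
    counts = trials.trial_class.value_counts()

    def _rate(cls: TrialClass, denom: int) -> float | None:
        return counts.get(cls.value, 0) / denom if denom else None

    miss_classes = [TrialClass.PM_MISS_CORRECT_ONGOING,
                    TrialClass.PM_MISS_WRONG_ONGOING]
    condition = trials.condition.iloc[0] if "condition" in trials else ""
    return ConditionSummary(
        condition=str(condition),
        n_trials=len(trials),
        class_stats=class_stats,
        hit_rate=_rate(TrialClass.PM_HIT, n_target),
        ongoing_accuracy=_rate(TrialClass.ONGOING_CORRECT, n_nontarget),
        false_alarm_rate=_rate(TrialClass.PM_FALSE_ALARM, n_nontarget),
        timeout_rate=counts.get(TrialClass.TIMEOUT.value, 0) / len(trials),
        mean_ongoing_rt=_mean_rt(trials, [TrialClass.ONGOING_CORRECT]),
        mean_pm_miss_rt=_mean_rt(trials, miss_classes),
        mean_pm_hit_rt=_mean_rt(trials, [TrialClass.PM_HIT]),
    )


@dataclass(frozen=True)
class EffectMeasures:
    """Derived contrasts between trial types and conditions.

    ``intention_superiority_cycles`` is mean ongoing RT minus mean
    PM-miss RT (positive when misses are faster, i.e. the intention
    superiority effect); the percentage is relative to mean ongoing RT.
    ``maintenance_cost_cycles`` is the ongoing-RT slowing of a condition
    relative to a zero-monitoring baseline.
    """

    intention_superiority_cycles: float
    intention_superiority_pct: float
    maintenance_cost_cycles: float | None = None


def intention_superiority(summary: ConditionSummary) -> tuple[float, float]:
    """(cycles, % of mean ongoing RT) for one condition's summary."""
    if summary.mean_ongoing_rt is None:
        raise ValueError("no ongoing_correct trials in summary")
    if summary.mean_pm_miss_rt is None:
        raise ValueError("no pm_miss trials in summary")
    cycles = summary.mean_ongoing_rt - summary.mean_pm_miss_rt
    return cycles, 100.0 * cycles / summary.mean_ongoing_rt


def effect_measures(summary: ConditionSummary,
                    baseline: ConditionSummary | None = None
                    ) -> EffectMeasures:
    """Intention superiority for ``summary``; if ``baseline`` (a
    no-monitoring condition) is given, also the maintenance cost."""
    cycles, pct = intention_superiority(summary)
    cost = None
    if baseline is not None:
        if baseline.mean_ongoing_rt is None:
            raise ValueError("no ongoing_correct trials in baseline")
        cost = summary.mean_ongoing_rt - baseline.mean_ongoing_rt
    return EffectMeasures(cycles, pct, cost)


def monitoring_sweep(
    params: ModelParameters,
    levels: dict[str, float] | None = None,
    n_per_nontarget: int = 10_000,
    n_per_target: int = 20_000,
    seed: int = 0,
) -> dict[str, tuple[pd.DataFrame, ConditionSummary]]:
    """Run the monitoring-level manipulation.

    By default runs ``no`` (0), ``standard`` (the calibrated level) and
    ``high`` (1.0) monitoring with matched trial counts, re-seeding each
    condition from ``seed``.
    """
    if levels is None:
        levels = {"no": 0.0,
                  "standard": params.monitoring_activation,
                  "high": 1.0}
    out = {}
    for i, (label, level) in enumerate(levels.items()):
        p = params.replace(monitoring_activation=level)
        table = run_condition(p, n_per_nontarget, n_per_target,
                              seed + i, condition=label)
        out[label] = (table, summarize(table))
    return out


def degradation_experiment(
    params: ModelParameters,
    degraded_input_activation: float = 0.9,
    n_per_nontarget: int = 10_000,
    n_per_target: int = 20_000,
    seed: int = 0,
) -> dict[str, dict]:
    """Contrast intact vs degraded stimulus input.

    For each input level the ongoing/PM-miss/PM-hit RTs, hit rate and
    accuracy are computed, together with the intention-maintenance cost
    (ongoing RT relative to a zero-monitoring run at the same input
    level).
    """
    if not 0.0 < degraded_input_activation <= params.input_activation:
        raise ValueError("degraded input level must be in (0, standard]")
    out = {}
    for i, (label, level) in enumerate(
            (("standard", params.input_activation),
             ("degraded", degraded_input_activation))):
        p = params.replace(input_activation=level)
        table = run_condition(p, n_per_nontarget, n_per_target,
                              seed + 2 * i, condition=label)
        summary = summarize(table)
        p0 = p.replace(monitoring_activation=0.0)
        base_table = run_condition(p0, n_per_nontarget, n_per_target,
                                   seed + 2 * i + 1,
                                   condition=f"{label}_no_monitoring")
        baseline = summarize(base_table)
        out[label] = {
            "summary": summary,
            "baseline": baseline,
            "effects": effect_measures(summary, baseline),
        }
    return out


#: Default absolute threshold for the PM unit in the dual-task variant.
DUAL_TASK_PM_THRESHOLD = 0.3
#: Default PM response window in cycles (respond before the next trial).
DUAL_TASK_PM_WINDOW = 150


def dual_task_variant(params: ModelParameters,
                      pm_response_threshold: float | None = None
                      ) -> tuple[np.ndarray, np.ndarray, NetworkGeometry, float]:
    """Configuration of the noncompetitive dual-task variant.

    The ongoing and PM pathways are made entirely separate: the lateral
    connections within the output layer are zeroed and the PM response
    gets its own threshold, tested on the PM unit's absolute activation
    (no competitor to compare against).  Returns
    ``(weights, bias, geometry, pm_response_threshold)``.
    """
    geom = standard_geometry()
    W = build_weight_matrix(params, geom)
    W[np.ix_(geom.output_idx, geom.output_idx)] = 0.0
    if pm_response_threshold is None:
        pm_response_threshold = DUAL_TASK_PM_THRESHOLD
    return W, build_bias_vector(params, geom), geom, pm_response_threshold


def run_dual_task_condition(
    params: ModelParameters,
    n_per_nontarget: int,
    n_per_target: int,
    seed: int,
    pm_response_threshold: float | None = None,
    pm_window: int = DUAL_TASK_PM_WINDOW,
) -> pd.DataFrame:
    """Simulate the dual-task variant; a trial may record both an
    ongoing and a PM response (within the first ``pm_window`` cycles,
    the analog of responding before the next trial begins), each with
    its own RT."""
    W, bias, geom, pm_thr = dual_task_variant(params, pm_response_threshold)
    batch, active = _build_stimulus_batch(n_per_nontarget, n_per_target)
    clamp = np.zeros((len(batch), 12))
    clamp[np.arange(len(batch))[:, None], active] = params.input_activation
    rng = np.random.default_rng(seed)
    ongoing, ongoing_rt, pm_made, pm_rt = simulate_batch_dual(
        W, bias, geom, clamp, params.monitoring_activation, params,
        pm_thr, rng, pm_window=pm_window)
    ongoing_resp = [Response.TIMEOUT if r < 0 else OUTPUT_RESPONSES[r]
                    for r in ongoing]
    return pd.DataFrame({
        "trial": np.arange(len(batch)),
        "condition": "dual_task",
        "stimulus": [s.label for s in batch],
        "is_target": [s.is_target for s in batch],
        "ongoing_response": [r.value for r in ongoing_resp],
        "ongoing_rt_cycles": pd.array(
            [int(rt) if r >= 0 else pd.NA
             for r, rt in zip(ongoing, ongoing_rt)], dtype="Int64"),
        "pm_response": pm_made,
        "pm_rt_cycles": pd.array(
            [int(rt) if made else pd.NA
             for made, rt in zip(pm_made, pm_rt)], dtype="Int64"),
        "seed": seed,
    })
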