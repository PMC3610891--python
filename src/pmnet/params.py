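"""Model parameters, named presets, and flat-file configuration.

All scalars governing the network dynamics live in a single immutable
:class:`ModelParameters` record.  The standard values shipped here are a
calibrated set: they were tuned (procedure in ``docs/methods.md``) so
that the model performs the letter-pair task adequately and reproduces
the canonical behavioural signatures — graded monitoring effects on hit
rate and ongoing RT, the intention-superiority effect and its reversal
without monitoring, the intention-maintenance cost, and the coefficient
of-variation ordering across trial types.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its structural constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Every scalar and connection weight governing the dynamics.

    Attributes
    ----------
    step_size:
        Dimensionless gain applied to the net input on every cycle; sets
        the speed of processing (and thereby the RT scale in cycles).
    noise_sd:
        Standard deviation of the zero-mean Gaussian noise added to the
        activation of every unit on every cycle.
    response_threshold:
        Minimum activation difference between the most active and the
        second most active output unit required to emit a response.
    act_max, act_min:
        Activation bounds; activations outside the bounds are reset to
        the relevant extreme after noise is added.
    input_activation:
        Clamp level for the two active stimulus input units (1.0 for
        intact stimuli, 0.9 for degraded stimuli).
    monitoring_activation:
        Clamp level for the top-down monitoring unit.  0 switches
        monitoring off entirely; 1.0 is the high-monitoring setting.
    detector_bias:
        Negative bias added to each target-detection unit's net input so
        that a single active letter unit cannot drive detection alone.
    w_input_ongoing:
        Weight of the direct pathway from an upper-case input unit to
        its ongoing (Left/Right) output unit.
    w_input_detector:
        Weight from each input unit to its letter's detection unit.
    w_detector_pm:
        Weight from each detection unit to the PM output unit.
    w_monitor_detector:
        Weight from the monitoring unit to each detection unit.
    w_lateral_output, w_lateral_detector:
        Negative lateral-inhibition weights within the output and the
        detector layer respectively.
    max_cycles:
        Trial cutoff; if no response has been selected the trial is
        recorded as a timeout error without an RT.
    """

    step_size: float = 0.0076
    noise_sd: float = 0.0085
    response_threshold: float = 0.14
    act_max: float = 1.0
    act_min: float = -0.16
    input_activation: float = 1.0
    monitoring_activation: float = 0.78
    detector_bias: float = -1.86
    w_input_ongoing: float = 0.51
    w_input_detector: float = 1.0
    w_detector_pm: float = 3.26
    w_monitor_detector: float = 0.85
    w_lateral_output: float = -1.23
    w_lateral_detector: float = -0.99
    max_cycles: int = 500

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.act_min < self.act_max:
            raise ConfigurationError("act_min must be < act_max")
        for name in ("w_input_ongoing", "w_input_detector",
                     "w_detector_pm", "w_monitor_detector"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"pathway weight {name} must be > 0")
        for name in ("w_lateral_output", "w_lateral_detector"):
            if getattr(self, name) >= 0:
                raise ConfigurationError(f"lateral weight {name} must be < 0")
        if self.detector_bias >= 0:
            raise ConfigurationError("detector_bias must be < 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.step_size <= 0:
            raise ConfigurationError("step_size must be > 0")
        if self.response_threshold <= 0:
            raise ConfigurationError("response_threshold must be > 0")
        if self.max_cycles < 1:
            raise ConfigurationError("max_cycles must be >= 1")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}")
        missing = known - set(data)
        if missing:
            raise ConfigurationError(
                f"missing parameter key(s): {', '.join(sorted(missing))}")
        return cls(**data)


#: Named presets differing from the standard settings in 1-2 scalars.
_PRESETS = {
    "standard": {},
    "no_monitoring": {"monitoring_activation": 0.0},
    "high_monitoring": {"monitoring_activation": 1.0},
    "degraded": {"input_activation": 0.9},
}


def preset(name: str = "standard") -> ModelParameters:
    """Return a named parameter preset.

    ``standard`` is the calibrated default; ``no_monitoring`` and
    ``high_monitoring`` set the monitoring clamp to 0 and 1;
    ``degraded`` lowers the stimulus input level from 1.0 to 0.9.
    """
    try:
        overrides = _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return ModelParameters(**overrides)


def load_config(path: str | Path) -> ModelParameters:
    """Load parameters from a flat key-value YAML file.

    Every :class:`ModelParameters` field must be present; unknown keys
    are rejected with an error naming the key.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a flat key-value mapping")
    return ModelParameters.from_dict(data)


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write parameters as a flat key-value YAML file (round-trips)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
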