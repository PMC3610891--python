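"""Run manifests and tabular trial-level output.

Every simulation artifact is reproducible from its manifest alone: the
full parameter set, the seed, the condition label and the trial counts
are written as a JSON sidecar (``<output>.manifest.json``) next to each
trial-level CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from pmnet import __version__ as _version
from pmnet.params import ModelParameters


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to regenerate an output file."""

    params: dict
    seed: int
    condition: str
    n_per_nontarget: int | None = None
    n_per_target: int | None = None
    software_version: str = field(default=_version)

    @classmethod
    def for_run(cls, params: ModelParameters, seed: int, condition: str,
                n_per_nontarget: int | None = None,
                n_per_target: int | None = None) -> "RunManifest":
        return cls(params.to_dict(), seed, condition,
                   n_per_nontarget, n_per_target)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    @property
    def model_parameters(self) -> ModelParameters:
        return ModelParameters.from_dict(self.params)


def manifest_path(path: str | Path) -> Path:
    return Path(str(path) + ".manifest.json")


def write_trials(table: pd.DataFrame, path: str | Path,
                 manifest: RunManifest | None = None) -> None:
    """Write a trial table as CSV (plus manifest sidecar).

    ``rt_cycles`` is left empty on timeout rows: a timeout is an error
    recorded without an RT.  Re-reading with :func:`read_trials`
    reproduces the table exactly.
    """
    table.to_csv(path, index=False)
    if manifest is not None:
        manifest_path(path).write_text(manifest.to_json())


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path)
    for col in ("rt_cycles", "ongoing_rt_cycles", "pm_rt_cycles"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def read_manifest(path: str | Path) -> RunManifest:
    """Read the manifest sidecar of a trial table."""
    return RunManifest.from_json(manifest_path(path).read_text())
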