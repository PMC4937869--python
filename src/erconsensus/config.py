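"""Run configuration: every numeric policy knob in one place, with defaults.

Several thresholds of the procedure are explicitly judgment calls (the
1000 g/mol weight cutoff, the 20% source-disagreement rule, the potency
class boundaries, the ambiguous AUC band, the three-model support rule),
so none of them is hard-coded in the stage implementations; they all live
here and can be overridden from a YAML file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _default_sweep() -> list[float]:
    return [round(0.05 * i, 2) for i in range(21)]  # 0, 0.05, ..., 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "run_output"

    # stage toggles / inputs
    simulate: bool = True
    n_chemicals: int = 1000
    n_models: int = 15
    predictions_dir: str | None = None  # used when simulate is False
    entries_file: str | None = None
    training_file: str | None = None

    # curation
    max_molweight: float = 1000.0

    # reference building
    disagreement_threshold: float = 0.20
    potency_strong_uM: float = 0.09
    potency_moderate_uM: float = 0.18
    potency_weak_uM: float = 20.0
    potency_very_weak_uM: float = 800.0

    # model evaluation
    auc_active_threshold: float = 0.01
    auc_ambiguous_low: float = 0.01
    auc_ambiguous_high: float = 0.1

    # consensus corrections
    min_active_models: int = 3

    # threshold sweep
    sweep_thresholds: list[float] = field(default_factory=_default_sweep)
    sweep_strata: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])

    #: fields that point at files/directories; excluded from the hash so that
    #: the same scientific configuration hashes identically wherever it runs
    _PATH_FIELDS = ("out_dir", "predictions_dir", "entries_file", "training_file")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()
                   if k not in self._PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
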