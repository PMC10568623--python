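"""Run configuration: defaults, YAML round-trip, strict key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # acquisition / preprocessing
    sfreq: float = 250.0
    bandpass_lo: float = 1.0
    bandpass_hi: float = 45.5
    notch: float | None = 60.0
    epoch_length: float = 4.0
    epoch_overlap: float = 0.5
    amp_thresh: float = 100.0
    var_ratio_thresh: float = 5.0
    # spectra / connectivity
    seg_length_s: float = 2.0
    density: float = 0.25
    network_mode: str = "weighted"
    # modeling
    r_min: float = 0.3
    top_k: int = 20
    models: list[str] = field(
        default_factory=lambda: ["ridge", "lasso", "elasticnet", "svr", "adaboost"]
    )
    selection_mode: str = "paper"  # or "strict"
    # simulation
    n_subjects: int = 20
    cohort_mode: str = "features"
    slow_wave_asymmetry: float = 2.0
    signal_fraction: float = 0.8
    duration: float = 60.0
    # run
    seed: int = 0
    input_dir: str = ""
    output_dir: str = "eegcog_run"

    def validate(self) -> "RunConfig":
        if not 0 < self.bandpass_lo < self.bandpass_hi < self.sfreq / 2:
            raise ValueError("need 0 < bandpass_lo < bandpass_hi < Nyquist")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.selection_mode not in ("paper", "strict"):
            raise ValueError("selection_mode must be 'paper' or 'strict'")
        if self.cohort_mode not in ("features", "eeg"):
            raise ValueError("cohort_mode must be 'features' or 'eeg'")
        if self.network_mode not in ("weighted", "binary"):
            raise ValueError("network_mode must be 'weighted' or 'binary'")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
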