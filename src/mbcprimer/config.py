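"""Run configuration shared by the CLI subcommands.

Defaults mirror the scanner's published defaults: 20 bp window, mismatch
threshold mm = 2, score floor 0.5, and a 20% column-trim threshold.
Values load from a YAML/JSON config file and are overridden by any CLI
flag given explicitly (standard precedence: defaults < file < flags).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError
from .scan import ScanConfig


@dataclass
class RunConfig:
    window_length: int = 20
    mm: int = 2
    min_score: float = 0.5
    max_gap_col_frac: float = 0.20
    max_gaps: int = 0
    max_ambiguous: int = 0
    max_mm: int = 2  # coverage evaluation horizon
    delta_tm_max: float = 5.0
    three_prime_run_max: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides: Any) -> "RunConfig":
        """New config with every non-None override applied."""
        values = dataclasses.asdict(self)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**values)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            window_length=self.window_length,
            mm=self.mm,
            min_score=self.min_score,
            max_gaps=self.max_gaps,
            max_ambiguous=self.max_ambiguous,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)
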