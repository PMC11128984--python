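"""Pipeline configuration: YAML file plus per-flag overrides.

Defaults are the standard operating point of the monitoring workflow — thin
one frame per 20 s, keep frames scoring at least 50 % fish, pad clips by
20 s on each side, and queue frames at or above 3 % for manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ArgumentError
from .media_io import DEFAULT_TIMESTAMP_PATTERN


@dataclass(frozen=True)
class PipelineConfig:
    interval_s: float = 20.0
    threshold: float = 0.5
    buffer_s: float = 20.0
    review_min_percent: int = 3
    timestamp_pattern: str = DEFAULT_TIMESTAMP_PATTERN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ArgumentError(f"interval_s must be positive: {self.interval_s}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ArgumentError(f"threshold must be in [0, 1]: {self.threshold}")
        if self.buffer_s < 0:
            raise ArgumentError(f"buffer_s must be >= 0: {self.buffer_s}")
        if not 0 <= self.review_min_percent <= 100:
            raise ArgumentError(
                f"review_min_percent must be in [0, 100]: {self.review_min_percent}"
            )


def load_config(path: Path | str | None, **overrides) -> PipelineConfig:
    """Config from an optional YAML file, with non-None keyword overrides
    (CLI flags) taking precedence over the file, which takes precedence over
    the defaults."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ArgumentError(f"config file {path} must hold a mapping")
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ArgumentError(f"unknown config keys in {path}: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)
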