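"""Pipeline configuration with defaults matching the published protocol.

Every numeric constant of the decoding pipeline lives here so that an empty
config file reproduces the protocol exactly: 0.1-50 Hz EEG band-pass,
theta/alpha/beta filter bank, -5..25 s epochs, 0-10 s task window,
0.01-0.09 Hz NIRS band-pass, 5-10/10-15 s NIRS feature windows with a
-1..0 s baseline, 3+3 CSP components, and 10x10-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["FilterSpec", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``zero_phase`` selects forward-backward application, which cancels group
    delay and doubles the effective magnitude order.
    """

    low_hz: float
    high_hz: float
    order: int = 6
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band: low={self.low_hz} must be >= 0 and < high={self.high_hz}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_for_rate(self, rate: float) -> None:
        if self.high_hz >= rate / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({rate / 2} Hz)"
            )


def _default_bank() -> list[FilterSpec]:
    # theta, alpha, beta
    return [FilterSpec(4, 8), FilterSpec(8, 13), FilterSpec(13, 30)]


@dataclass
class PipelineConfig:
    """All tunable parameters of the decoding pipeline."""

    # preprocessing
    eeg_rate: float = 200.0
    eeg_band: FilterSpec = field(default_factory=lambda: FilterSpec(0.1, 50.0))
    nirs_band: FilterSpec = field(default_factory=lambda: FilterSpec(0.01, 0.09))
    remove_eog: bool = True
    # epoching and features
    epoch_window: tuple[float, float] = (-5.0, 25.0)
    task_window: tuple[float, float] = (0.0, 10.0)
    filter_bank: list[FilterSpec] = field(default_factory=_default_bank)
    n_csp_first: int = 3
    n_csp_last: int = 3
    nirs_windows: tuple[tuple[float, float], ...] = ((5.0, 10.0), (10.0, 15.0))
    nirs_baseline: tuple[float, float] = (-1.0, 0.0)
    # classification
    folds: int = 10
    repetitions: int = 10
    inner_folds: int = 5
    shrinkage_identity_literal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epoch_window", "task_window", "nirs_baseline"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name}: start {lo} must be < end {hi}")
        for lo, hi in self.nirs_windows:
            if lo >= hi:
                raise ValueError(f"nirs window: start {lo} must be < end {hi}")
        if not self.filter_bank:
            raise ValueError("filter bank must contain at least one band")
        if self.folds < 2 or self.repetitions < 1 or self.inner_folds < 2:
            raise ValueError("folds/inner_folds must be >= 2, repetitions >= 1")
        if self.n_csp_first + self.n_csp_last < 1:
            raise ValueError("must keep at least one CSP component")

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return convert(self)

    def config_hash(self) -> str:
        """Stable hash stamping derived artifacts with their provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _parse_filterspec(value, name: str) -> FilterSpec:
    if isinstance(value, FilterSpec):
        return value
    if not isinstance(value, dict):
        raise ValueError(f"{name} must be a mapping with low_hz/high_hz")
    allowed = {f.name for f in dataclasses.fields(FilterSpec)}
    unknown = set(value) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")
    return FilterSpec(**value)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; an empty/missing file yields all defaults.

    Unknown keys are rejected rather than silently ignored.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            raw = loaded

    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    for key, value in raw.items():
        if key in ("eeg_band", "nirs_band"):
            kwargs[key] = _parse_filterspec(value, key)
        elif key == "filter_bank":
            kwargs[key] = [_parse_filterspec(v, "filter_bank entry") for v in value]
        elif key in ("epoch_window", "task_window", "nirs_baseline"):
            kwargs[key] = tuple(float(v) for v in value)
        elif key == "nirs_windows":
            kwargs[key] = tuple(tuple(float(x) for x in w) for w in value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
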