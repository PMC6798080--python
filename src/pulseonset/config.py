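"""Detector configuration.

The detector has ten free parameters (each with a recommended operating
range) plus a handful of fixed constants.  Defaults reproduce the published
operating point.  All durations are expressed in milliseconds and converted
to samples through the single rule in :func:`ms_to_samples`, which keeps
every stage sampling-rate independent.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = [
    "DetectionConfig",
    "FREE_PARAMETER_RANGES",
    "ParameterRangeWarning",
    "load_config",
    "ms_to_samples",
]


def ms_to_samples(ms: float, sampling_rate: float) -> int:
    """Convert a duration in milliseconds to a sample count.

    Centralized so every module converts identically:
    ``n = max(1, round(ms * fs / 1000))``.
    """
    return max(1, int(round(ms * sampling_rate / 1000.0)))


class ParameterRangeWarning(UserWarning):
    """A free parameter lies outside its recommended operating range."""


#: Recommended operating range for each free parameter.
FREE_PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "threshold_normalization": (0.5, 0.65),
    "refractory_period_ms": (150.0, 300.0),
    "mdf_window_ms": (125.0, 200.0),
    "peaks_number": (3, 30),
    "distance_threshold_1": (0.05, 0.6),
    "distance_threshold_2": (0.6, 0.8),
    "minimum_threshold_norm": (0.3, 0.4),
    "short_outlier": (2.5, 3.5),
    "long_outlier": (2.5, 3.5),
    "onset_threshold": (0.5, 0.9),
}


@dataclass(frozen=True)
class DetectionConfig:
    """Free parameters and fixed constants of the onset detector.

    Free parameters (defaults are the published operating point):

    threshold_normalization
        Fraction of the mean of recent MDF peaks used as the adaptive
        threshold on the moving-difference signal.
    refractory_period_ms
        Lockout τ after a threshold crossing during which no new crossing
        is registered; also the peak-search and alignment window span.
    mdf_window_ms
        Backward-difference window w of the moving difference filter;
        roughly the duration of a typical systolic upslope.
    peaks_number
        FIFO depth of recent MDF peaks feeding the adaptive threshold.
    distance_threshold_1
        Correlation-distance gate for merging a short beat into a neighbor.
    distance_threshold_2
        Correlation-distance cutoff for deleting an extremely atypical
        short beat outright.
    minimum_threshold_norm
        Floor of the relaxation ladder used when re-scanning long beats.
    short_outlier / long_outlier
        MAD multipliers flagging short / long inter-onset intervals.
    onset_threshold
        Required valley depth as a fraction of the MDF peak when picking
        the onset valley within a search window.
    """

    # --- free parameters (recommended-range checked) ---
    threshold_normalization: float = 0.6
    refractory_period_ms: float = 200.0
    mdf_window_ms: float = 150.0
    peaks_number: int = 20
    distance_threshold_1: float = 0.2
    distance_threshold_2: float = 0.7
    minimum_threshold_norm: float = 0.35
    short_outlier: float = 3.5
    long_outlier: float = 3.0
    onset_threshold: float = 0.75

    # --- fixed constants ---
    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 10.0
    filter_order: int = 4
    init_window_s: float = 10.0
    init_peak_factor: float = 2.5
    init_threshold_norm: float = 0.6
    threshold_decrement: float = 0.05
    max_iterations: int = 10
    alignment_shift_ms: float = 30.0
    mad_scale: float = 1.4826

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self
        checks = [
            (c.refractory_period_ms > 0, "refractory_period_ms must be > 0"),
            (c.mdf_window_ms > 0, "mdf_window_ms must be > 0"),
            (c.init_window_s > 0, "init_window_s must be > 0"),
            (c.alignment_shift_ms > 0, "alignment_shift_ms must be > 0"),
            (0 < c.threshold_normalization <= 1,
             "threshold_normalization must lie in (0, 1]"),
            (0 < c.onset_threshold <= 1, "onset_threshold must lie in (0, 1]"),
            (c.minimum_threshold_norm <= c.init_threshold_norm,
             "minimum_threshold_norm must not exceed init_threshold_norm"),
            (c.minimum_threshold_norm > 0, "minimum_threshold_norm must be > 0"),
            (c.threshold_decrement > 0, "threshold_decrement must be > 0"),
            (c.peaks_number >= 1, "peaks_number must be >= 1"),
            (c.max_iterations >= 1, "max_iterations must be >= 1"),
            (c.distance_threshold_1 >= 0, "distance_threshold_1 must be >= 0"),
            (c.distance_threshold_2 >= 0, "distance_threshold_2 must be >= 0"),
            (c.short_outlier > 0, "short_outlier must be > 0"),
            (c.long_outlier > 0, "long_outlier must be > 0"),
            (0 < c.bandpass_low_hz < c.bandpass_high_hz,
             "band edges must satisfy 0 < low < high"),
            (c.filter_order >= 1, "filter_order must be >= 1"),
            (c.init_peak_factor > 0, "init_peak_factor must be > 0"),
            (c.mad_scale > 0, "mad_scale must be > 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)

    def replace(self, **changes: Any) -> "DetectionConfig":
        """Return a copy with the given fields changed (validated)."""
        known = {f.name for f in dataclasses.fields(self)}
        for name in changes:
            if name not in known:
                raise ConfigError(f"unknown configuration field: {name!r}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def free_parameters(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FREE_PARAMETER_RANGES}


def _warn_out_of_range(config: DetectionConfig) -> None:
    for name, (lo, hi) in FREE_PARAMETER_RANGES.items():
        value = getattr(config, name)
        if not lo <= value <= hi:
            warnings.warn(
                f"{name}={value} outside recommended range [{lo}, {hi}]",
                ParameterRangeWarning,
                stacklevel=3,
            )


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> DetectionConfig:
    """Build a :class:`DetectionConfig` from an optional JSON/YAML file.

    Fields absent from the file keep their defaults; ``overrides`` are
    applied last.  A :class:`ParameterRangeWarning` is emitted for every
    free parameter outside its recommended range; hard invariant
    violations raise :class:`~pulseonset.errors.ConfigError`.
    """
    fields: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = (json.loads(text) if str(path).endswith(".json")
                  else yaml.safe_load(text))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        fields.update(loaded)
    if overrides:
        fields.update(overrides)

    known = {f.name for f in dataclasses.fields(DetectionConfig)}
    unknown = set(fields) - known
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
    config = DetectionConfig(**fields)
    _warn_out_of_range(config)
    return config
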