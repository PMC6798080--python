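"""Waveform and annotation I/O.

Conventions owned here: onset indices are 0-based sample positions,
intervals are half-open ``[start, end)``, annotation files carry both a
``sample`` and a ``seconds`` column, and a delimited waveform file either
provides a time column (from which a uniform sampling rate is inferred) or
a bare velocity column accompanied by an explicit sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SamplingError

__all__ = [
    "SignalRecord",
    "AnnotationSet",
    "read_signal",
    "read_annotations",
    "write_onsets",
]

#: Allowed relative deviation of successive time steps from the median step.
_UNIFORMITY_TOL = 0.01

_TIME_NAMES = {"time", "time_s", "t", "t_s", "seconds", "sec"}


@dataclass
class SignalRecord:
    """A uniformly sampled single-channel velocity trace.

    Parameters
    ----------
    samples : array of velocity values (cm/s)
    sampling_rate : sampling frequency in Hz, strictly positive
    label : free-text identifier
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParseError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParseError("signal contains non-finite samples")
        if not (self.sampling_rate > 0 and np.isfinite(self.sampling_rate)):
            raise ParseError("sampling_rate must be finite and positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class AnnotationSet:
    """A strictly increasing sequence of onset sample indices (0-based)."""

    onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    source: str = ""

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.onsets.ndim != 1:
            raise ParseError("onsets must be 1-D")
        if self.onsets.size and self.onsets[0] < 0:
            raise ParseError("onset indices must be non-negative")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ParseError("onset indices must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size

    def seconds(self, sampling_rate: float) -> np.ndarray:
        return self.onsets / float(sampling_rate)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if frame.empty:
        raise ParseError(f"empty file: {path}")
    return frame


def read_signal(
    path: str | Path,
    format: str = "delimited",
    sampling_rate: float | None = None,
    label: str | None = None,
) -> SignalRecord:
    """Read a velocity trace from delimited text.

    ``format="delimited"`` expects a header naming a time column (e.g.
    ``time_s``) and a velocity column; the sampling rate is inferred from
    the median time step after verifying uniformity (max step deviation
    < 1% of the median step).  ``format="raw"`` expects a single velocity
    column and requires ``sampling_rate``.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    frame = _read_table(path)

    if format == "raw":
        if sampling_rate is None:
            raise ParseError("raw format requires an explicit sampling_rate")
        column = frame.columns[0]
        values = pd.to_numeric(frame[column], errors="coerce").to_numpy()
        if np.isnan(values).any():
            raise ParseError(f"non-numeric or missing samples in {path}")
        return SignalRecord(values, float(sampling_rate), label)

    if format != "delimited":
        raise ParseError(f"unknown signal format: {format!r}")

    time_col = next(
        (c for c in frame.columns if str(c).strip().lower() in _TIME_NAMES), None
    )
    if time_col is None:
        raise ParseError(
            f"{path}: no time column found (expected one of {sorted(_TIME_NAMES)}); "
            "use format='raw' with an explicit sampling_rate for bare traces"
        )
    value_cols = [c for c in frame.columns if c != time_col]
    if not value_cols:
        raise ParseError(f"{path}: no velocity column found")
    velocity_col = next(
        (c for c in value_cols if "velo" in str(c).lower()), value_cols[0]
    )

    times = pd.to_numeric(frame[time_col], errors="coerce").to_numpy()
    values = pd.to_numeric(frame[velocity_col], errors="coerce").to_numpy()
    if np.isnan(times).any() or np.isnan(values).any():
        raise ParseError(f"non-numeric or missing entries in {path}")
    if times.size < 2:
        raise SamplingError(f"{path}: need at least two samples to infer a rate")

    steps = np.diff(times)
    median_step = float(np.median(steps))
    if median_step <= 0:
        raise SamplingError(f"{path}: time axis is not increasing")
    if np.max(np.abs(steps - median_step)) >= _UNIFORMITY_TOL * median_step:
        raise SamplingError(f"{path}: time axis is not uniformly sampled")
    return SignalRecord(values, 1.0 / median_step, label)


def read_annotations(
    path: str | Path,
    sampling_rate: float,
    units: str = "samples",
    source: str | None = None,
) -> AnnotationSet:
    """Read onset annotations, one onset per line.

    Accepts either the two-column ``sample,seconds`` files written by
    :func:`write_onsets` or a bare single column.  ``units`` selects which
    column (or how a bare column) is interpreted; seconds are converted to
    the nearest sample index.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if source is None:
        source = path.stem
    text = path.read_text().strip()
    if not text:
        return AnnotationSet(np.empty(0, dtype=np.int64), source)

    lines = [line.strip() for line in text.splitlines() if line.strip()]
    header: list[str] | None = None
    if any(ch.isalpha() for ch in lines[0]):
        header = [tok.strip().lower() for tok in re.split(r"[,\t; ]+", lines[0])]
        lines = lines[1:]
    rows = [re.split(r"[,\t; ]+", line) for line in lines]
    width = min(len(row) for row in rows) if rows else 0

    if units == "samples":
        column = header.index("sample") if header and "sample" in header else 0
    elif units == "seconds":
        column = (header.index("seconds") if header and "seconds" in header
                  else width - 1)
    else:
        raise ParseError(f"unknown annotation units: {units!r}")
    try:
        values = np.array([float(row[column]) for row in rows])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed onset entries in {path}: {exc}") from exc
    if units == "seconds":
        values = values * sampling_rate
    return AnnotationSet(np.round(values).astype(np.int64), source)


def write_onsets(
    annotations: AnnotationSet, sampling_rate: float, path: str | Path
) -> None:
    """Write onsets as ``sample,seconds`` rows (lossless on sample indices)."""
    frame = pd.DataFrame(
        {
            "sample": annotations.onsets,
            "seconds": annotations.onsets / float(sampling_rate),
        }
    )
    frame.to_csv(path, index=False)
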