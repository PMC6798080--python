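"""Filtering front end: band-pass and moving difference filter.

The detector operates on two signals derived from the raw trace: the
band-pass filtered velocity y (0.5–10 Hz, 4th-order Butterworth) and the
moving difference filter (MDF) signal z, a backward difference over a
window w that enhances each beat's initial systolic upslope:

    z[i] = y[i] - y[i - w]          (z[i] = 0 for i < w)

Filtering is applied zero-phase (forward-backward, second-order sections)
so onset timing carries no systematic phase delay; the doubled effective
order is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import DetectionConfig, ms_to_samples
from .errors import ConfigError, ProcessingError
from .io import SignalRecord

__all__ = ["FilteredSignal", "MDFSignal", "bandpass_filter", "moving_difference"]


@dataclass
class FilteredSignal:
    """Band-pass filtered velocity trace (same length and rate as source)."""

    samples: np.ndarray
    sampling_rate: float
    band: tuple[float, float] = (0.5, 10.0)
    order: int = 4

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class MDFSignal:
    """Moving-difference signal z with its window length in samples."""

    samples: np.ndarray
    window_samples: int
    sampling_rate: float

    def __len__(self) -> int:
        return self.samples.size


def design_bandpass(
    low_hz: float, high_hz: float, order: int, sampling_rate: float
) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass."""
    nyquist = sampling_rate / 2.0
    if not 0 < low_hz < high_hz:
        raise ConfigError("band edges must satisfy 0 < low < high")
    if high_hz >= nyquist:
        raise ConfigError(
            f"high band edge {high_hz} Hz must be below Nyquist ({nyquist} Hz)"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass",
                      fs=sampling_rate, output="sos")


def bandpass_filter(
    signal: SignalRecord,
    low_hz: float = 0.5,
    high_hz: float = 10.0,
    order: int = 4,
) -> FilteredSignal:
    """Zero-phase band-pass the velocity trace (DC removed)."""
    sos = design_bandpass(low_hz, high_hz, order, signal.sampling_rate)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(signal) <= padlen:
        raise ProcessingError(
            f"signal of {len(signal)} samples is too short for the "
            f"filter warm-up ({padlen} samples)"
        )
    filtered = sps.sosfiltfilt(sos, signal.samples)
    return FilteredSignal(filtered, signal.sampling_rate, (low_hz, high_hz), order)


def moving_difference(
    signal: FilteredSignal,
    window_ms: float = 150.0,
    sampling_rate: float | None = None,
) -> MDFSignal:
    """Apply the moving difference filter z[i] = y[i] - y[i-w].

    The head convention sets z[i] = 0 for i < w: zeros can never produce a
    spurious threshold crossing, and the 10 s initialization window dwarfs w.
    """
    if sampling_rate is None:
        sampling_rate = signal.sampling_rate
    w = ms_to_samples(window_ms, sampling_rate)
    y = signal.samples
    if w >= y.size:
        raise ProcessingError(
            f"MDF window of {w} samples must be shorter than the signal "
            f"({y.size} samples)"
        )
    z = np.zeros_like(y)
    z[w:] = y[w:] - y[:-w]
    return MDFSignal(z, w, sampling_rate)


def preprocess(
    signal: SignalRecord, config: DetectionConfig
) -> tuple[FilteredSignal, MDFSignal]:
    """Convenience: band-pass then MDF with the configured constants."""
    filtered = bandpass_filter(
        signal, config.bandpass_low_hz, config.bandpass_high_hz, config.filter_order
    )
    mdf = moving_difference(filtered, config.mdf_window_ms)
    return filtered, mdf
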