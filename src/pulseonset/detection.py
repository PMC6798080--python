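"""Sequential first-pass onset detection.

The detector walks the MDF signal left to right.  An adaptive threshold —
a fraction of the mean of the most recent MDF peaks — is propagated until
it crosses the MDF signal; a refractory period τ after each crossing
suppresses re-triggering on the same upslope.  The systolic peak of the
new beat is the maximum of the filtered signal within τ of the crossing,
and the onset is the latest valley inside the search window (previous
beat's peak → crossing) whose depth relative to the new peak is at least
a fraction of the MDF peak:

    CBFV_peak - CBFV_valley >= onset_threshold * MDF_peak

Local extrema are defined strictly (greater/less than both neighbors);
plateaus take their first sample, so quantized signals behave
deterministically.  The whole pass is deterministic: identical inputs and
configuration give byte-identical output.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import DetectionConfig, ms_to_samples
from .errors import DetectionError, ProcessingError
from .preprocessing import FilteredSignal, MDFSignal

__all__ = [
    "BeatRecord",
    "ThresholdState",
    "SearchWindow",
    "local_maxima",
    "local_minima",
    "initialize_threshold",
    "next_crossing",
    "locate_peaks",
    "identify_onset",
    "detect_onsets",
]


@dataclass
class BeatRecord:
    """One detected beat: its onset, systolic peak, and MDF evidence."""

    onset_index: int
    peak_index: int
    mdf_peak: float
    crossing_index: int
    fallback: bool = False  # onset taken as window argmin (no valley qualified)

    def __post_init__(self) -> None:
        if not self.onset_index < self.peak_index:
            raise ProcessingError("beat onset must precede its peak")


@dataclass
class ThresholdState:
    """Adaptive threshold: a fraction of the mean of recent MDF peaks."""

    recent_mdf_peaks: deque
    current_threshold: float
    normalization: float

    @classmethod
    def create(cls, initial_threshold: float, normalization: float,
               capacity: int) -> "ThresholdState":
        return cls(deque(maxlen=capacity), float(initial_threshold),
                   float(normalization))

    def push(self, mdf_peak: float) -> None:
        """Record a detected MDF peak and recompute the threshold."""
        self.recent_mdf_peaks.append(float(mdf_peak))
        self.current_threshold = self.normalization * float(
            np.mean(self.recent_mdf_peaks)
        )


@dataclass
class SearchWindow:
    """Half-open interval [start, end) in which the onset valley is sought."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not self.start_index < self.end_index:
            raise ProcessingError("search window must be non-empty")


def _runs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and values of constant runs in x."""
    if x.size == 0:
        return np.empty(0, dtype=np.int64), x
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate(([0], change))
    return starts, x[starts]


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus contribute their first sample."""
    starts, values = _runs(np.asarray(x, dtype=float))
    if starts.size < 3:
        return np.empty(0, dtype=np.int64)
    inner = (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    return starts[1:-1][inner]


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima; plateaus contribute their first sample."""
    return local_maxima(-np.asarray(x, dtype=float))


def initialize_threshold(
    mdf: MDFSignal,
    sampling_rate: float,
    config: DetectionConfig,
) -> ThresholdState:
    """Seed the adaptive threshold from the start of the scan.

    All MDF local maxima above ``init_peak_factor`` times the mean of the
    positive part of the MDF over the first ``init_window_s`` seconds are
    gathered; the initial threshold is ``init_threshold_norm`` times
    their median.  The positive-part mean is used because the raw MDF of
    a pulsatile signal telescopes to near-zero mean (a degenerate gate),
    while the rectified mean grows with heart rate until the gate can
    exceed every upslope peak; the positive part tracks upslope energy
    only and stays well below the peaks at any physiological rate.
    """
    z = mdf.samples
    n_init = int(round(config.init_window_s * sampling_rate))
    if n_init > z.size:
        warnings.warn(
            "signal shorter than the threshold initialization window; "
            "using the entire signal",
            stacklevel=2,
        )
        n_init = z.size
    head = z[:n_init]
    gate = config.init_peak_factor * float(np.mean(np.maximum(head, 0.0)))
    peak_indices = local_maxima(head)
    peak_values = head[peak_indices]
    peak_values = peak_values[peak_values > gate]
    if peak_values.size == 0:
        raise DetectionError(
            "no pulsatile activity: no MDF peaks above the initialization gate"
        )
    threshold = config.init_threshold_norm * float(np.median(peak_values))
    return ThresholdState.create(
        threshold, config.threshold_normalization, config.peaks_number
    )


def next_crossing(
    mdf: np.ndarray | MDFSignal,
    from_index: int,
    threshold: float,
    refractory_samples: int,
) -> int | None:
    """Smallest i >= from_index + refractory with an upward threshold crossing.

    A crossing at i requires ``mdf[i-1] < threshold <= mdf[i]``.  Returns
    None when the end of the signal is reached without a crossing.
    """
    z = mdf.samples if isinstance(mdf, MDFSignal) else np.asarray(mdf)
    start = max(from_index + refractory_samples, 1)
    if start >= z.size:
        return None
    segment = z[start - 1:]
    hits = np.flatnonzero((segment[:-1] < threshold) & (segment[1:] >= threshold))
    if hits.size == 0:
        return None
    return int(start + hits[0])


def locate_peaks(
    filtered: np.ndarray | FilteredSignal,
    mdf: np.ndarray | MDFSignal,
    crossing: int,
    refractory_samples: int,
) -> tuple[int, float]:
    """Systolic peak and MDF peak amplitude for a threshold crossing.

    The beat's peak is the maximum of the filtered signal within the
    refractory interval [crossing, crossing + τ); the MDF peak is the
    first local maximum of the MDF at or after the crossing, falling back
    to the interval maximum when the segment is monotone.  Ties take the
    earliest index.
    """
    y = filtered.samples if isinstance(filtered, FilteredSignal) else np.asarray(filtered)
    z = mdf.samples if isinstance(mdf, MDFSignal) else np.asarray(mdf)
    end = min(crossing + refractory_samples, y.size)
    if crossing >= end:
        raise ProcessingError("crossing lies beyond the end of the signal")
    peak_index = crossing + int(np.argmax(y[crossing:end]))

    lo = max(crossing - 1, 0)
    hi = min(end + 1, z.size)
    candidates = lo + local_maxima(z[lo:hi])
    candidates = candidates[candidates >= crossing]
    if candidates.size:
        mdf_peak = float(z[candidates[0]])
    else:
        mdf_peak = float(np.max(z[crossing:end]))
    return peak_index, mdf_peak


def identify_onset(
    filtered: np.ndarray | FilteredSignal,
    window: SearchWindow,
    cbfv_peak_value: float,
    mdf_peak: float,
    onset_threshold: float,
) -> tuple[int, bool]:
    """Pick the onset valley within a search window.

    Among local minima of the filtered signal inside the window, the
    latest (closest to the threshold crossing) whose depth satisfies
    ``cbfv_peak_value - valley >= onset_threshold * mdf_peak`` is the
    onset.  When no valley qualifies the window argmin is returned with a
    fallback flag — a missed onset costs more than a misplaced one, and
    the beat-length analysis can still repair the neighborhood.
    """
    y = filtered.samples if isinstance(filtered, FilteredSignal) else np.asarray(filtered)
    start, end = window.start_index, window.end_index
    if not 0 <= start < end <= y.size:
        raise ProcessingError("search window out of bounds")
    lo = max(start - 1, 0)
    hi = min(end + 1, y.size)
    valleys = lo + local_minima(y[lo:hi])
    valleys = valleys[(valleys >= start) & (valleys < end)]
    depth_ok = (cbfv_peak_value - y[valleys]) >= onset_threshold * mdf_peak
    qualified = valleys[depth_ok]
    if qualified.size:
        return int(qualified[-1]), False
    return start + int(np.argmin(y[start:end])), True


def detect_onsets(
    filtered: FilteredSignal,
    mdf: MDFSignal,
    sampling_rate: float,
    config: DetectionConfig,
) -> tuple[list[BeatRecord], ThresholdState]:
    """First-pass sequential detection over the whole scan.

    Composes threshold initialization, crossing propagation, peak
    location, and valley selection.  After each accepted crossing the MDF
    peak enters the FIFO and the threshold is recomputed; before the FIFO
    holds ``peaks_number`` entries the mean runs over what has been seen.
    The first beat's search window extends to the very beginning of the
    signal.
    """
    if len(filtered) != len(mdf):
        raise ProcessingError("filtered and MDF signals must have equal length")
    tau = ms_to_samples(config.refractory_period_ms, sampling_rate)
    state = initialize_threshold(mdf, sampling_rate, config)

    beats: list[BeatRecord] = []
    prev_peak: int | None = None
    from_index = -tau  # first search may trigger from the start of the scan
    while True:
        crossing = next_crossing(mdf, from_index, state.current_threshold, tau)
        if crossing is None:
            break
        peak_index, mdf_peak = locate_peaks(filtered, mdf, crossing, tau)
        window_start = 0 if prev_peak is None else prev_peak
        onset, fallback = identify_onset(
            filtered,
            SearchWindow(window_start, crossing),
            float(filtered.samples[peak_index]),
            mdf_peak,
            config.onset_threshold,
        )
        if (not beats or onset > beats[-1].onset_index) and onset < peak_index:
            beats.append(
                BeatRecord(onset, peak_index, mdf_peak, crossing, fallback)
            )
        state.push(mdf_peak)
        prev_peak = peak_index
        from_index = crossing
    return beats, state
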