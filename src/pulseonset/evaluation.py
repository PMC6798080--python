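"""Detector evaluation by one-to-one onset matching.

Rather than imposing an arbitrary tolerance Δt_max up front, annotated
and detected onsets are paired one-to-one by temporal proximity; every
pair is a true positive whose signed offset Δt = detected − true is
reported separately.  Unpaired annotated onsets are false negatives,
unpaired detections false positives.  This yields three error classes —
missing, extra, and misaligned onsets — plus TPR = TP/(TP+FN) and
PPV = TP/(TP+FP).  For comparison with tolerance-based conventions, the
report also recomputes counts under each Δt_max, where a pair with
|Δt| > Δt_max counts as both one FP and one FN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DetectionConfig
from .errors import ConfigError
from .io import AnnotationSet, SignalRecord

__all__ = [
    "MatchResult",
    "MetricsReport",
    "DEFAULT_OFFSET_THRESHOLDS_MS",
    "match_onsets",
    "compute_metrics",
    "evaluate",
    "run_parameter_sweep",
]

#: Offset thresholds (ms) reported by default.
DEFAULT_OFFSET_THRESHOLDS_MS = (5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 150.0)


@dataclass
class MatchResult:
    """One-to-one pairing of annotated vs detected onsets.

    ``pairs`` holds (true onset sample, detected onset sample, Δt ms,
    signed detected − true); ``fn_onsets`` / ``fp_onsets`` the unmatched
    annotated / detected onsets.
    """

    pairs: list[tuple[int, int, float]]
    fn_onsets: np.ndarray
    fp_onsets: np.ndarray

    @property
    def offsets_ms(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)


def match_onsets(true_onsets, detected_onsets, sampling_rate: float) -> MatchResult:
    """Greedily pair each annotated onset with its closest detection.

    Candidate (true, detected) pairs are taken in ascending |Δt| (ties:
    earlier true onset, then earlier detected onset); a pair is accepted
    only if neither member is already matched, so no onset is double
    counted.  No Δt cutoff is imposed.
    """
    t = np.asarray(true_onsets, dtype=np.int64)
    d = np.asarray(detected_onsets, dtype=np.int64)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ConfigError("true onsets must be strictly increasing")
    if d.size > 1 and not np.all(np.diff(d) > 0):
        raise ConfigError("detected onsets must be strictly increasing")

    if t.size == 0 or d.size == 0:
        return MatchResult([], t.copy(), d.copy())

    abs_dt = np.abs(d[None, :] - t[:, None])
    order = np.lexsort(
        (np.tile(np.arange(d.size), t.size),
         np.repeat(np.arange(t.size), d.size),
         abs_dt.ravel())
    )
    matched_t = np.zeros(t.size, dtype=bool)
    matched_d = np.zeros(d.size, dtype=bool)
    ms_per_sample = 1000.0 / sampling_rate
    pairs: list[tuple[int, int, float]] = []
    pair_keys: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), d.size)
        if matched_t[i] or matched_d[j]:
            continue
        matched_t[i] = matched_d[j] = True
        pair_keys.append((i, j))
        if len(pair_keys) == min(t.size, d.size):
            break
    pair_keys.sort()
    pairs = [
        (int(t[i]), int(d[j]), float((d[j] - t[i]) * ms_per_sample))
        for i, j in pair_keys
    ]
    return MatchResult(pairs, t[~matched_t], d[~matched_d])


@dataclass
class MetricsReport:
    tp: int
    fn: int
    fp: int
    tpr: float | None
    ppv: float | None
    mean_abs_offset_ms: float | None
    sd_offset_ms: float | None
    proportion_within: dict[float, float]
    conventional: dict[float, dict[str, float | int | None]]
    offsets_ms: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tpr": self.tpr,
            "ppv": self.ppv,
            "mean_abs_offset_ms": self.mean_abs_offset_ms,
            "sd_offset_ms": self.sd_offset_ms,
            "proportion_within": {str(k): v for k, v in self.proportion_within.items()},
            "conventional": {str(k): v for k, v in self.conventional.items()},
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(
    match: MatchResult,
    thresholds_ms=DEFAULT_OFFSET_THRESHOLDS_MS,
) -> MetricsReport:
    """Summarize a match: counts, rates, offset statistics, and the
    tolerance-based (Δt_max) reinterpretation.

    Under the conventional scheme a pair with |Δt| > Δt_max counts as one
    FP plus one FN.  ``proportion_within[thr]`` is the fraction of pairs
    with |Δt| <= thr and is non-decreasing in thr; it doubles as the
    conventional-scheme TPR numerator.
    """
    tp = len(match.pairs)
    fn = int(match.fn_onsets.size)
    fp = int(match.fp_onsets.size)
    abs_dt = np.abs(match.offsets_ms)

    proportion_within: dict[float, float] = {}
    conventional: dict[float, dict] = {}
    for thr in thresholds_ms:
        within = int(np.sum(abs_dt <= thr))
        proportion_within[float(thr)] = _ratio(within, tp) if tp else float("nan")
        misaligned = tp - within
        tp_c, fn_c, fp_c = within, fn + misaligned, fp + misaligned
        conventional[float(thr)] = {
            "tp": tp_c,
            "fn": fn_c,
            "fp": fp_c,
            "tpr": _ratio(tp_c, tp_c + fn_c),
            "ppv": _ratio(tp_c, tp_c + fp_c),
        }

    return MetricsReport(
        tp=tp,
        fn=fn,
        fp=fp,
        tpr=_ratio(tp, tp + fn),
        ppv=_ratio(tp, tp + fp),
        mean_abs_offset_ms=float(abs_dt.mean()) if tp else None,
        sd_offset_ms=float(abs_dt.std(ddof=1)) if tp > 1 else None,
        proportion_within=proportion_within,
        conventional=conventional,
        offsets_ms=match.offsets_ms,
    )


def evaluate(
    true_onsets, detected_onsets, sampling_rate: float,
    thresholds_ms=DEFAULT_OFFSET_THRESHOLDS_MS,
) -> MetricsReport:
    """Match then summarize in one call."""
    return compute_metrics(
        match_onsets(true_onsets, detected_onsets, sampling_rate), thresholds_ms
    )


def run_parameter_sweep(
    signal: SignalRecord,
    annotations: AnnotationSet,
    config: DetectionConfig,
    parameter: str,
    values,
) -> pd.DataFrame:
    """Re-run the full pipeline varying one parameter, others fixed.

    Returns a DataFrame with columns ``value``, ``fn``, ``fp``.
    """
    from .pipeline import detect_pulses  # deferred: pipeline imports this module's peers

    rows = []
    for value in values:
        cfg = config.replace(**{parameter: value})
        result = detect_pulses(signal, cfg)
        match = match_onsets(annotations.onsets, result.onsets, signal.sampling_rate)
        rows.append(
            {"value": value, "fn": int(match.fn_onsets.size),
             "fp": int(match.fp_onsets.size)}
        )
    return pd.DataFrame(rows, columns=["value", "fn", "fp"])
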