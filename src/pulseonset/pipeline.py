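"""Full detection pipeline: filter → MDF → sequential detection →
beat-length repair → template alignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentResult, align_onsets
from .beat_analysis import BeatAnalysisResult, analyze_beat_lengths, compute_mean_beat
from .config import DetectionConfig, ms_to_samples
from .detection import BeatRecord, detect_onsets
from .io import SignalRecord
from .preprocessing import preprocess

__all__ = ["PipelineResult", "detect_pulses"]


@dataclass
class PipelineResult:
    """Final onsets plus per-stage diagnostics."""

    onsets: np.ndarray
    config: DetectionConfig
    first_pass_beats: list[BeatRecord] = field(default_factory=list, repr=False)
    beat_analysis: BeatAnalysisResult | None = None
    alignment: AlignmentResult | None = None

    @property
    def stage_counts(self) -> dict[str, int]:
        counts = {
            "first_pass_beats": len(self.first_pass_beats),
            "fallback_onsets": sum(b.fallback for b in self.first_pass_beats),
            "final_onsets": int(self.onsets.size),
        }
        if self.beat_analysis is not None:
            counts.update(
                iterations=self.beat_analysis.iterations,
                onsets_added=self.beat_analysis.onsets_added,
                onsets_removed=self.beat_analysis.onsets_removed,
                long_flagged=self.beat_analysis.long_flagged,
                short_flagged=self.beat_analysis.short_flagged,
            )
        if self.alignment is not None:
            counts["shifts_applied"] = self.alignment.n_applied
        return counts


def detect_pulses(
    signal: SignalRecord,
    config: DetectionConfig | None = None,
    run_beat_analysis: bool = True,
    run_alignment: bool = True,
) -> PipelineResult:
    """Detect all pulse onsets in a velocity trace.

    The two repair stages can be disabled individually for ablation
    studies.  The whole pipeline is deterministic.
    """
    if config is None:
        config = DetectionConfig()
    fs = signal.sampling_rate
    filtered, mdf = preprocess(signal, config)
    beats, _ = detect_onsets(filtered, mdf, fs, config)
    onsets = np.array([b.onset_index for b in beats], dtype=np.int64)
    result = PipelineResult(onsets=onsets, config=config, first_pass_beats=beats)

    if run_beat_analysis and len(beats) >= 2:
        result.beat_analysis = analyze_beat_lengths(filtered, beats, fs, config)
        result.onsets = result.beat_analysis.onsets

    if run_alignment and result.onsets.size >= 2:
        tau = ms_to_samples(config.refractory_period_ms, fs)
        mean_beat = compute_mean_beat(filtered, result.onsets, tau)
        result.onsets, result.alignment = align_onsets(
            filtered, result.onsets, mean_beat, fs, config
        )
    return result
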