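"""Annotated synthetic CBFV-like scans.

Real transcranial-Doppler velocity envelopes vary widely in morphology
and quality; this module generates morphologically plausible pulse trains
with exact ground-truth onsets so the detector and its repair stages can
be exercised end to end without clinical data.

A pulse is modeled as smooth parameterized components on an exponentially
decaying envelope rather than as a hemodynamic flow model: the detector
only cares about a sharp systolic upslope, peaks P1/P2, and a dicrotic
notch, and analytic components give exact control of the ground truth.
The systolic rise is a quarter-sine from the diastolic level reaching P1,
so the first sample of every beat is its strict minimum — the ground
truth onset is, by construction, the diastolic valley at the start of the
upslope.  P2 and the dicrotic wave are Gaussian bumps whose centers and
widths scale with the beat length.

Noise archetypes (all optional, applied after concatenation): additive
Gaussian noise at a prescribed SNR, amplitude quantization (digitized
appearance), sharp half-sine noise spikes, and sinusoidal baseline drift.
All randomness flows from a single seed; regeneration is bit-exact.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import ms_to_samples
from .errors import ConfigError
from .io import AnnotationSet, SignalRecord

__all__ = [
    "MorphologySpec",
    "NoiseSpec",
    "SyntheticScan",
    "MORPHOLOGY_PRESETS",
    "generate_pulse",
    "generate_scan",
    "corrupt_scan",
]

#: Physiological floor on a beat length.
MIN_BEAT_MS = 300.0


@dataclass(frozen=True)
class MorphologySpec:
    """Shape parameters of one pulse archetype.

    Component times are fractions of the beat length; amplitudes are
    excursions above the diastolic level in cm/s.  ``upslope_time_ms``
    floors the time-to-P1 so the systolic rise stays physiological at
    high heart rates.
    """

    p1_amplitude: float = 30.0
    p2_amplitude: float = 22.0
    dicrotic_amplitude: float = 8.0
    p1_time: float = 0.13
    p2_time: float = 0.30
    notch_time: float = 0.42
    upslope_time_ms: float = 100.0
    diastolic_level: float = 30.0
    decay_rate: float = 1.2

    def __post_init__(self) -> None:
        if not 0.0 < self.p1_time < self.p2_time < self.notch_time < 1.0:
            raise ConfigError(
                "component times must satisfy 0 < p1 < p2 < notch < 1"
            )
        for name in ("p1_amplitude", "p2_amplitude", "dicrotic_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.upslope_time_ms <= 0:
            raise ConfigError("upslope_time_ms must be positive")
        if self.decay_rate < 0:
            raise ConfigError("decay_rate must be non-negative")


#: Named archetypes spanning the morphological range of clinical scans:
#: a healthy waveform, a blunted waveform without separable P1/P2, an
#: elevated second peak, a stenotic-like deep-notch shape, and a
#: low-pulsatility trace.
MORPHOLOGY_PRESETS: dict[str, MorphologySpec] = {
    "normal": MorphologySpec(),
    "blunted": MorphologySpec(
        p1_amplitude=20.0, p2_amplitude=0.0, dicrotic_amplitude=0.0,
        p1_time=0.18, p2_time=0.35, notch_time=0.5,
        upslope_time_ms=120.0, diastolic_level=25.0, decay_rate=0.8,
    ),
    "elevated_p2": MorphologySpec(
        p1_amplitude=22.0, p2_amplitude=28.0, dicrotic_amplitude=6.0,
        p1_time=0.12, p2_time=0.32, notch_time=0.46,
        upslope_time_ms=100.0, diastolic_level=28.0, decay_rate=0.2,
    ),
    "stenotic": MorphologySpec(
        p1_amplitude=25.0, p2_amplitude=12.0, dicrotic_amplitude=5.0,
        p1_time=0.12, p2_time=0.34, notch_time=0.55,
        upslope_time_ms=90.0, diastolic_level=26.0, decay_rate=0.5,
    ),
    "low_amplitude": MorphologySpec(
        p1_amplitude=12.0, p2_amplitude=8.0, dicrotic_amplitude=3.0,
        p1_time=0.14, p2_time=0.30, notch_time=0.44,
        upslope_time_ms=110.0, diastolic_level=35.0, decay_rate=1.0,
    ),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Optional corruption modes; all off by default."""

    gaussian_snr_db: float | None = None
    quantization_step: float | None = None
    spike_rate_per_min: float | None = None
    spike_amplitude: float = 30.0
    spike_width_ms: float = 60.0
    baseline_drift_hz: float | None = None
    baseline_drift_amplitude: float | None = None

    def __post_init__(self) -> None:
        for name in ("gaussian_snr_db", "quantization_step",
                     "spike_rate_per_min", "baseline_drift_hz",
                     "baseline_drift_amplitude"):
            value = getattr(self, name)
            if value is not None and value <= 0 and name != "gaussian_snr_db":
                raise ConfigError(f"{name} must be positive when set")
        if self.spike_amplitude <= 0 or self.spike_width_ms <= 0:
            raise ConfigError("spike amplitude and width must be positive")

    @property
    def is_clean(self) -> bool:
        return all(
            getattr(self, name) is None
            for name in ("gaussian_snr_db", "quantization_step",
                         "spike_rate_per_min", "baseline_drift_hz")
        )


@dataclass
class SyntheticScan:
    """A generated scan: signal, ground-truth onsets, and the full
    generation parameters (sufficient to regenerate it bit-exactly)."""

    signal: SignalRecord
    truth: AnnotationSet
    params: dict = field(default_factory=dict)


def _eased_segment(t: np.ndarray, t_a: float, t_b: float,
                   v_a: float, v_b: float) -> np.ndarray:
    """Cosine-eased interpolation from (t_a, v_a) to (t_b, v_b).

    Zero slope at both ends, so anchor points are genuine local extrema
    and segment steepness is bounded by (pi/2) * dv/dt.
    """
    u = (t - t_a) / (t_b - t_a)
    return v_a + (v_b - v_a) * 0.5 * (1.0 - np.cos(np.pi * u))


def generate_pulse(
    morphology: MorphologySpec, beat_length_ms: float, sampling_rate: float
) -> np.ndarray:
    """Render one beat; its first sample is the strict beat minimum.

    The beat is a single smooth curve through morphological anchor
    points — onset, P1, P2, dicrotic notch, dicrotic wave — joined by
    cosine-eased segments, so only the initial systolic upslope is steep;
    P2 and the dicrotic wave rise gently out of the preceding feature the
    way they do in measured envelopes.  Anchor amplitudes after P1 are
    attenuated by the exponential decay envelope.  After the last anchor
    the signal decays exponentially toward (but not onto) the diastolic
    level, leaving a small downward step at the next beat's onset; real
    envelope traces show the same abrupt foot.
    """
    if beat_length_ms <= morphology.upslope_time_ms:
        raise ConfigError("beat length must exceed the upslope time")
    n = ms_to_samples(beat_length_ms, sampling_rate)
    t = np.arange(n) / sampling_rate
    big_t = n / sampling_rate
    m = morphology

    # systolic timing does not stretch with long beats: cap the time to P1
    # in absolute terms while flooring it at the configured upslope time
    t1 = min(max(m.p1_time * big_t, m.upslope_time_ms / 1000.0),
             1.6 * m.upslope_time_ms / 1000.0, 0.45 * big_t)
    t2 = max(m.p2_time * big_t, t1 + 0.08 * big_t)
    t_notch = max(m.notch_time * big_t, t2 + 0.05 * big_t)
    t_dicrotic = min(t_notch + 0.6 * (t_notch - t2), 0.95 * big_t)

    decay = np.exp(-m.decay_rate * np.array([t2, t_notch, t_dicrotic]) + m.decay_rate * t1)
    anchors: list[tuple[float, float]] = [(0.0, 0.0), (t1, m.p1_amplitude)]
    if m.p2_amplitude > 0:
        anchors.append((t2, m.p2_amplitude * decay[0]))
    if m.dicrotic_amplitude > 0:
        anchors.append((t_notch, 0.8 * m.dicrotic_amplitude * decay[1]))
        anchors.append((t_dicrotic, m.dicrotic_amplitude * decay[2]))

    v = np.zeros(n)
    for (t_a, v_a), (t_b, v_b) in zip(anchors[:-1], anchors[1:]):
        mask = (t >= t_a) & (t < t_b)
        v[mask] = _eased_segment(t[mask], t_a, t_b, v_a, v_b)

    # diastolic runoff: exponential decay from the last anchor, then a
    # short linear descent onto the diastolic level whose slope mirrors
    # the next beat's early rise.  The onset valley is then a roughly
    # symmetric V, so band-pass filtering does not displace it (a flat or
    # one-sided approach lets the filtered minimum drift off the foot).
    t_last, v_last = anchors[-1]
    delta = min(0.04, 0.3 * (big_t - t_last))  # descent duration (s)
    # match the descent slope to the mean slope of the first ~16 ms of the
    # next beat's rise, whatever t1 is
    rise_slope = m.p1_amplitude * (1.0 - np.cos(np.pi * 0.016 / t1)) / (2 * 0.016)
    v_knee = min(rise_slope * delta, 0.8 * v_last)
    t_knee = big_t - delta
    tail = (t >= t_last) & (t < t_knee)
    if v_last > v_knee and t_knee > t_last:
        tau = (t_knee - t_last) / np.log(v_last / v_knee)
        v[tail] = v_last * np.exp(-(t[tail] - t_last) / tau)
    else:
        v[tail] = v_last
    descent = t >= t_knee
    v[descent] = v_knee * (big_t - t[descent]) / delta
    return m.diastolic_level + v


def _draw_beat_lengths(
    rng: np.random.Generator,
    total_ms: float,
    hr_mean_bpm: float,
    hr_sd_bpm: float,
) -> np.ndarray:
    """Beat lengths (ms) from a truncated normal (±3 sd, 300 ms floor)."""
    mean_ms = 60000.0 / hr_mean_bpm
    sd_ms = 60000.0 * hr_sd_bpm / hr_mean_bpm**2
    lengths = []
    elapsed = 0.0
    while elapsed < total_ms:
        if sd_ms > 0:
            draw = rng.normal(mean_ms, sd_ms)
            draw = float(np.clip(draw, mean_ms - 3 * sd_ms, mean_ms + 3 * sd_ms))
        else:
            draw = mean_ms
        draw = max(draw, MIN_BEAT_MS)
        lengths.append(draw)
        elapsed += draw
    return np.asarray(lengths)


def _render(params: dict) -> SyntheticScan:
    """Deterministically render a scan from its parameter dictionary."""
    morphology = MorphologySpec(**params["morphology"])
    noise = NoiseSpec(**params["noise"])
    fs = params["sampling_rate"]
    rng = np.random.default_rng(params["seed"])

    lengths_ms = _draw_beat_lengths(
        rng, params["duration_s"] * 1000.0,
        params["hr_mean_bpm"], params["hr_sd_bpm"],
    )
    suppress: dict[int, float] = {
        int(k): float(v) for k, v in params.get("suppress", {}).items()
    }

    # A short diastolic lead-in precedes the first beat (scans almost never
    # begin exactly at an onset, and a beat starting inside the MDF's
    # zero-padded head would be invisible to any detector).  It is shaped
    # like the tail of a typical beat so the first onset sits in the same
    # valley geometry as every other onset.  Record length is
    # lead_in_s + duration_s; the pulse train itself spans duration_s.
    lead = int(round(params.get("lead_in_s", 0.4) * fs))
    total = int(round(params["duration_s"] * fs)) + lead
    pieces = []
    onsets = []
    position = 0
    if lead > 0:
        proto = generate_pulse(
            morphology, 60000.0 / params["hr_mean_bpm"] + lead * 1000.0 / fs, fs
        )
        pieces.append(proto[-lead:])
        position = lead
    for k, length_ms in enumerate(lengths_ms):
        pulse = generate_pulse(morphology, length_ms, fs)
        if position + pulse.size > total:
            break  # a truncated pulse is not a beat; fill with diastole below
        scale = suppress.get(k, 1.0)
        if scale != 1.0:
            pulse = morphology.diastolic_level + scale * (
                pulse - morphology.diastolic_level
            )
        onsets.append(position)
        pieces.append(pulse)
        position += pulse.size
    if position < total:  # quiescent diastolic tail, no truth onset
        pieces.append(np.full(total - position, morphology.diastolic_level))
    x = np.concatenate(pieces)[:total]
    onsets = np.asarray(onsets, dtype=np.int64)

    t = np.arange(x.size) / fs
    if noise.baseline_drift_hz is not None:
        amplitude = noise.baseline_drift_amplitude or 5.0
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amplitude * np.sin(2 * np.pi * noise.baseline_drift_hz * t + phase)
    if noise.gaussian_snr_db is not None:
        sigma = float(np.std(x)) / 10.0 ** (noise.gaussian_snr_db / 20.0)
        x = x + rng.normal(0.0, sigma, x.size)
    spike_times = list(params.get("extra_spikes_s", []))
    if noise.spike_rate_per_min is not None:
        count = rng.poisson(noise.spike_rate_per_min * params["duration_s"] / 60.0)
        spike_times.extend(rng.uniform(0.0, params["duration_s"], count))
    width = ms_to_samples(noise.spike_width_ms, fs)
    for time_s in spike_times:
        start = int(round(time_s * fs))
        stop = min(start + width, x.size)
        if start >= x.size:
            continue
        x = x.copy()
        x[start:stop] += noise.spike_amplitude * np.sin(
            np.pi * np.arange(stop - start) / width
        )
    if noise.quantization_step is not None:
        x = np.round(x / noise.quantization_step) * noise.quantization_step

    truth = np.asarray(params.get("truth_override", onsets), dtype=np.int64)
    signal = SignalRecord(x, fs, label=params.get("label", "synthetic"))
    return SyntheticScan(signal, AnnotationSet(truth, source="synthetic"),
                         copy.deepcopy(params))


def generate_scan(
    duration_s: float,
    hr_mean_bpm: float = 70.0,
    hr_sd_bpm: float = 0.0,
    morphology: MorphologySpec | str = "normal",
    noise: NoiseSpec | None = None,
    sampling_rate: float = 125.0,
    seed: int = 0,
    lead_in_s: float = 0.4,
    label: str = "synthetic",
) -> SyntheticScan:
    """Generate an annotated scan.

    Beat lengths are drawn from a normal distribution (mean 60000/HR ms)
    truncated at ±3 sd with a 300 ms floor; pulses are concatenated and
    noise is applied afterwards.  Ground-truth onsets mark the first
    sample of every pulse.  Deterministic given ``seed``.
    """
    if hr_mean_bpm <= 0:
        raise ConfigError("hr_mean_bpm must be positive")
    if hr_sd_bpm < 0:
        raise ConfigError("hr_sd_bpm must be non-negative")
    if duration_s * 1000.0 <= 60000.0 / hr_mean_bpm:
        raise ConfigError("duration must exceed one beat")
    if isinstance(morphology, str):
        try:
            morphology = MORPHOLOGY_PRESETS[morphology]
        except KeyError:
            raise ConfigError(
                f"unknown morphology preset {morphology!r}; "
                f"choose from {sorted(MORPHOLOGY_PRESETS)}"
            ) from None
    if noise is None:
        noise = NoiseSpec()
    params = {
        "duration_s": float(duration_s),
        "lead_in_s": float(lead_in_s),
        "hr_mean_bpm": float(hr_mean_bpm),
        "hr_sd_bpm": float(hr_sd_bpm),
        "morphology": dataclasses.asdict(morphology),
        "noise": dataclasses.asdict(noise),
        "sampling_rate": float(sampling_rate),
        "seed": int(seed),
        "label": label,
    }
    return _render(params)


def corrupt_scan(
    scan: SyntheticScan,
    suppress_pulses: dict[int, float] | None = None,
    displace_truth_ms: dict[int, float] | None = None,
    insert_spikes_s: list[float] | None = None,
) -> SyntheticScan:
    """Deterministically edited copy of a scan.

    ``suppress_pulses`` scales the excursion of chosen pulses (truth
    unchanged — the detector must now miss and later recover them);
    ``displace_truth_ms`` shifts ground-truth onsets (annotation
    misalignment); ``insert_spikes_s`` adds sharp artifacts with no truth
    onset (spurious-onset bait).  An empty edit set reproduces the scan.
    """
    params = copy.deepcopy(scan.params)
    n_pulses = len(scan.truth)
    if suppress_pulses:
        merged = {int(k): float(v) for k, v in params.get("suppress", {}).items()}
        for k, v in suppress_pulses.items():
            if not 0 <= k < n_pulses:
                raise ConfigError(f"pulse index {k} out of range")
            merged[int(k)] = float(v)
        params["suppress"] = merged
    if insert_spikes_s:
        for time_s in insert_spikes_s:
            if not 0 <= time_s < params["duration_s"]:
                raise ConfigError(f"spike time {time_s}s out of range")
        params["extra_spikes_s"] = (
            list(params.get("extra_spikes_s", [])) + list(insert_spikes_s)
        )
    rendered = _render(params)
    if displace_truth_ms:
        fs = params["sampling_rate"]
        truth = rendered.truth.onsets.copy()
        for k, shift_ms in displace_truth_ms.items():
            if not 0 <= k < truth.size:
                raise ConfigError(f"truth onset index {k} out of range")
            truth[k] += int(round(shift_ms * fs / 1000.0))
        rendered.truth = AnnotationSet(truth, source="synthetic-displaced")
        rendered.params["truth_override"] = truth.tolist()
    return rendered
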