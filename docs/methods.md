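# Methods

This note documents the detection pipeline, its parameters, the synthetic
data model used to validate it, and the design decisions taken where the
procedure admitted more than one reasonable reading.

## Signal model and preprocessing

The input is a single-channel, uniformly sampled CBFV envelope (cm/s).
All durations in the package are specified in milliseconds and converted
to samples through one rule, `n = max(1, round(ms · fs / 1000))`, so the
pipeline is sampling-rate independent; 125 Hz is used throughout the
tests as a typical TCD envelope rate.

The trace is band-pass filtered at 0.5–10 Hz with a 4th-order Butterworth
filter, designed in second-order sections for numerical stability and
applied **zero-phase** (forward–backward). Zero-phase application is a
deliberate choice: a causal filter delays the upslope by a
morphology-dependent amount and would bias every onset late. The price is
a doubled effective order (the stopband attenuation is the squared
magnitude response), which is accepted and tested against the designed
transfer function directly.

The moving difference filter is zᵢ = yᵢ − yᵢ₋w with w = 150 ms,
approximately the duration of a systolic upslope, so z peaks once per
beat at roughly the beat's pulse height. The head convention is
zᵢ = 0 for i < w: zeros can never produce a spurious threshold crossing,
and the 10 s initialization window dwarfs w.

## Detection

**Threshold initialization.** Candidate peaks are MDF local maxima in the
first 10 s exceeding a gate of 2.5× the mean of the **positive part** of
the MDF; the initial threshold is 60% of their median. The positive part
is used deliberately: the raw MDF of a pulsatile signal telescopes to
near-zero mean (a degenerate gate), while the rectified mean |z| grows
with heart rate until, above ~90 bpm, the gate can exceed every upslope
peak and initialization reports no pulsatile activity. The positive-part
mean tracks upslope energy only and keeps the gate a stable fraction
(~½ of the rectified-mean gate) of the peak height at any physiological
rate.

**Sequential pass.** The current threshold is propagated until it crosses
the MDF from below; a refractory period τ = 200 ms after each crossing
suppresses re-triggering. The beat's systolic peak is the maximum of the
filtered signal within τ of the crossing (ties: earliest sample). The MDF
peak is the first local maximum of z at or after the crossing, falling
back to the interval maximum for monotone segments. After each accepted
crossing the MDF peak enters a FIFO of depth 20 and the threshold is
recomputed as 60% of the FIFO mean (over however many peaks exist early
in the scan).

**Onset selection.** Within the window from the previous beat's peak to
the crossing (the first window extends to the record start), the onset is
the latest valley of the filtered signal whose depth relative to the new
peak is at least 0.75·MDF_peak. When no valley qualifies — noisy shelf,
heavily quantized plateau — the window argmin is taken and the beat is
flagged, rather than dropped: a missed onset costs downstream analyses
more than a misplaced one, and the beat-length analysis can still repair
the neighborhood.

Local extrema are defined strictly (greater/less than both neighboring
*distinct* values) with plateaus represented by their first sample, so
quantized signals behave deterministically. All argmax/argmin ties take
the earliest index. The entire pass is deterministic; repeated runs are
byte-identical.

## Beat-length repair

Inter-onset intervals are screened with MAD statistics
(σ̂ = 1.4826·MAD; the constant is the reciprocal of the standard normal
0.75-quantile, which makes σ̂ a consistent estimator of the standard
deviation under normality). Bounds are asymmetric — short below
l_med − 3.5σ̂, long above l_med + 3.0σ̂ — because long beats usually hide
a missed onset, the costlier error. With fewer than three intervals the
statistics are degenerate and screening is skipped.

**Long beats** are re-scanned locally: the MDF is recomputed on the
segment from the long beat's peak to the next onset, the refractory
period is enforced from the segment start, and a threshold at
norm × (median of all first-pass MDF peaks) is walked down the ladder
0.60, 0.55, …, 0.35 until a crossing appears. The reference median is
frozen from the first pass and never updated. One onset at most is added
per long beat per iteration; nested misses surface on later iterations.
"No onset found at this norm" means "no threshold crossing in the
segment": once a crossing exists, the window/valley machinery always
produces an onset (the fallback rule), so crossing existence is the only
failure mode.

**Short beats** are compared, after the long-beat phase, against the mean
beat: all beats truncated or end-padded (repeating the final value) to
the rounded median length and averaged elementwise. A merge with the
following beat removes the boundary onset between them; a merge with the
preceding beat, or an outright deletion, removes the short beat's own
onset — the interval algebra forces these choices, and removing the
starting onset is the conservative option that preserves the following
beat. A merge requires both that the merged length approaches the median
better than the neighbor alone and that the fragment is dissimilar from
the mean beat (correlation distance > 0.2); deletion requires extreme
dissimilarity (> 0.7). Correlation distance is 1 minus the normalized
inner product of the centered, tail-truncated-to-equal-length vectors;
a constant vector is defined to be at distance 1 (uncorrelated), a
degenerate case real beats do not hit. A premature but normally shaped
beat therefore survives both gates untouched.

The analysis iterates — statistics and flags frozen per iteration, long
beats first, then short — until an iteration makes no edit, capped at 10
iterations as a guard against oscillating edits.

## Alignment

The mean beat's first τ of samples (the upslope template) is centered and
scaled to unit norm; candidate windows slide one sample at a time from
τ before to τ after each onset and are scored by dot product after the
same normalization, making the score amplitude-invariant (Pearson-style,
consistent with the correlation distance used elsewhere). The
best-scoring shift is applied only when |shift| > 30 ms: for near-correct
onsets, micro-adjustment is empirically counterproductive, so the gate is
two-sided and deliberately leaves small estimated shifts alone. Onsets
too close to a record edge for a full window are never shifted.
Alignment cannot change the onset count; a shift collision (never
observed, and precluded by |shift| ≤ τ < beat length) raises rather than
silently re-sorting.

## Evaluation

Annotated and detected onsets are paired greedily in ascending |Δt|
(ties: earlier annotated onset, then earlier detection), each onset used
at most once, with **no** offset cutoff. Pairs are TPs carrying a signed
offset Δt = detected − true; leftovers are FN (annotated side) and FP
(detected side). This cleanly separates three error types — missing,
extra, and misaligned onsets — instead of conflating large offsets into
an FP+FN pair. For cross-detector comparisons the report also recomputes
counts under a conventional tolerance Δt_max, where a pair with
|Δt| > Δt_max counts as one FP plus one FN; the offset-threshold
proportions use |Δt| ≤ thr and therefore double as the conventional TPR
numerators. Default thresholds: 5, 10, 20, 30, 50, 100, 150 ms.

On conflict-free instances — where unmatched annotations and unmatched
detections do not coexist — greedy pairing coincides with the exhaustive
minimum-total-|Δt| assignment, and the test suite verifies this against a
brute-force oracle on instances of up to 8 onsets per side. When both
kinds of leftover coexist, a cutoff-free maximal matching necessarily
drags one distant pair, and a total-offset-minimizing assignment may
reshuffle neighbors around it; such distant pairs are exactly the cases
the framework flags for manual review rather than silent optimization,
so the equivalence is stated (and tested) on the conflict-free class.

The single-parameter sweep harness re-runs the full pipeline varying one
configuration field at a time, everything else fixed, and tabulates
absolute FN/FP per value.

## Free parameters

| Parameter | Default | Range | Meaning |
|---|---|---|---|
| threshold_normalization | 0.6 | 0.5–0.65 | fraction of recent-MDF-peak mean used as threshold |
| refractory_period_ms (τ) | 200 | 150–300 | lockout after a crossing; also peak/alignment window |
| mdf_window_ms (w) | 150 | 125–200 | MDF backward-difference window |
| peaks_number | 20 | 3–30 | FIFO depth for the adaptive threshold |
| distance_threshold_1 | 0.2 | 0.05–0.6 | dissimilarity gate for merging a short beat |
| distance_threshold_2 | 0.7 | 0.6–0.8 | dissimilarity cutoff for deleting a short beat |
| minimum_threshold_norm | 0.35 | 0.3–0.4 | floor of the long-beat relaxation ladder |
| short_outlier | 3.5 | 2.5–3.5 | MAD multiplier flagging short beats |
| long_outlier | 3.0 | 2.5–3.5 | MAD multiplier flagging long beats |
| onset_threshold | 0.75 | 0.5–0.9 | valley depth as a fraction of MDF_peak |

Loading a configuration warns when a free parameter leaves its range and
rejects hard invariant violations. Fixed constants (band edges, filter
order, 10 s init window, 2.5 init gate factor, 0.05 ladder decrement,
10-iteration cap, 30 ms alignment gate, 1.4826 MAD scale) are exposed on
the same object for reproducibility but are not meant to be tuned.

## Synthetic data model

The generator emulates the archetypes seen in clinical TCD envelopes with
five morphology presets — normal (P1 dominant, dicrotic notch), blunted
(single broad hump, no separable P1/P2), elevated P2, stenotic-like
(deep notch, two distinct peaks), and low-amplitude/low-pulsatility —
with amplitudes in physiologically plausible ranges (diastolic 25–35
cm/s, systolic excursions 12–30 cm/s).

A beat is a single smooth curve through morphological anchor points
(onset → P1 → P2 → notch → dicrotic wave) joined by cosine-eased
segments, followed by an exponential diastolic runoff ending in a short
linear descent onto the diastolic level. Three geometric properties are
engineered deliberately:

- only the initial systolic upslope is steep; P2 and the dicrotic wave
  rise gently out of the preceding feature, as in measured envelopes
  (a P2 as steep as the primary upslope would rightly double-trigger any
  slope-based detector and corresponds to no real archetype);
- the first sample of each beat is its strict minimum, so the ground
  truth onset is exactly the diastolic valley at the upslope's foot;
- the descent slope into each onset mirrors the early rise slope out of
  it, making the foot a roughly symmetric V — a flat or one-sided foot
  lets zero-phase band-pass filtering displace the valley by several
  samples, which would measure the generator, not the detector.

Time-to-P1 is floored at the configured upslope time and capped at 1.6×
that value, since systolic timing does not stretch with long diastoles.
Beat lengths are drawn from a normal distribution (mean 60000/HR ms)
truncated at ±3 sd with a 300 ms floor. A 0.4 s diastolic lead-in,
shaped like a beat tail, precedes the first pulse: scans essentially
never begin exactly at an onset, and a beat starting inside the MDF's
zero-padded head would be invisible to any detector of this family. A
truncated final pulse is replaced by quiescent diastole with no truth
onset — a partial pulse is not a beat. Record length is therefore
lead-in + duration, and a duration of n beats yields exactly n truth
onsets at zero heart-rate variability.

Noise modes (all optional, applied after concatenation, all driven by
the single scan seed): additive Gaussian noise at a prescribed SNR,
amplitude quantization (digitized appearance), half-sine spikes
(probe-knock artifacts), and sinusoidal baseline drift. Scan corruption
utilities create the two canonical failure modes on demand: pulse
suppression (excursion scaled, truth unchanged — a beat the detector
must miss and later recover) and spike insertion (artifact with no truth
onset). The suppression factor 0.45 is chosen to land in the band the
missed-beat failure mode occupies: below ~0.55 the beat's MDF peak misses
the 60% running threshold, above ~0.40 it still clears the 0.35 relaxed
floor — both thresholds scale with the same global MDF peak median, so
the band is archetype-independent.

**What passing on synthetic data does and does not show.** The generator
provides exact, unambiguous onsets, noise-free feet, and stationary
morphology; real annotated data has annotator uncertainty, composite
noise, and drift, under which offsets grow from ~1 sample to the order of
5–10 ms and occasional FN/FP at morphological edge cases are expected.
Synthetic validation demonstrates the algorithm's mechanics — every stage
does what it is specified to do, with exact bookkeeping — not clinical
performance.

## Problem sizes and numerical choices

The test suite and the acceptance script run, as the package's standard
validation battery: 20 five-minute scans at 125 Hz spanning 40–120 bpm
and all five archetypes (~8,000 beats) for clean recovery; three to four
scans each for the repair and alignment checks; 1,000 random instances
(≤ 8 onsets/side) for the matching oracle; and a 10-parameter ×
4-value × 2-scan sweep grid. Seconds-to-sample conversion rounds half to
even (numpy convention). Medians of even-length sets use the midpoint.
Degenerate inputs are defined explicitly: empty MAD input raises;
constant vectors have correlation distance 1; zero-norm alignment
candidates score −∞; fewer than three beats skip outlier screening.

## Known limitations

- Offline only: beat-length repair and alignment use future samples; a
  streaming variant would need causal reformulations of both.
- Systolic peak locations are a byproduct of window construction and are
  not accuracy-validated outputs.
- The beat-length screen assumes a roughly stationary rhythm per scan;
  sustained arrhythmia inflates σ̂ and weakens outlier detection (by
  design — the conservative failure mode is to leave beats alone).
- Initialization requires pulsatile activity in the first 10 s; a
  pulseless head segment longer than that fails loudly rather than
  guessing.
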