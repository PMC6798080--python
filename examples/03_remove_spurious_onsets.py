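"""Remove false onsets triggered by sharp noise spikes.

Spikes injected mid-beat mimic probe-motion artifacts: their steep rise
crosses the MDF threshold and splits one beat into two short ones.  The
short-beat logic merges a split beat back only when the merged length is
closer to the median AND the fragment looks unlike the mean beat
(correlation distance > 0.2) - so genuinely short but normal-shaped
beats are left alone.
"""

from pulseonset import corrupt_scan, detect_pulses, generate_scan, match_onsets

scan = generate_scan(300.0, hr_mean_bpm=70.0, hr_sd_bpm=3.0,
                     morphology="normal", seed=21)
spike_times = [scan.truth.onsets[k] / 125.0 + 0.55 for k in (30, 90, 150)]
bad = corrupt_scan(scan, insert_spikes_s=spike_times)

first_pass = detect_pulses(bad.signal, run_beat_analysis=False, run_alignment=False)
full = detect_pulses(bad.signal)

fs = scan.signal.sampling_rate
m_first = match_onsets(bad.truth.onsets, first_pass.onsets, fs)
m_full = match_onsets(bad.truth.onsets, full.onsets, fs)

print(f"spikes injected:            {len(spike_times)}")
print(f"first pass: extra onsets    {m_first.fp_onsets.size}")
print(f"after short-beat analysis:  {m_full.fp_onsets.size} extra, "
      f"{m_full.fn_onsets.size} missed")
print(f"onsets removed:             {full.beat_analysis.onsets_removed}")

# Every spike-triggered onset is merged away; no true beat is lost.
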