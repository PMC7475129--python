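"""Heart-rate variability from a simulated arterial pressure waveform.

Plants a respiratory-frequency (1.5 Hz, HF band) and a Mayer-wave-like
(0.4 Hz, LF band) modulation on the beat intervals, detects beats from the
pressure waveform, and computes the full time/frequency HRV metric suite.
"""

import cihpheno as cp

spec = cp.RRSimSpec(
    duration_s=300.0,
    mean_rr_ms=153.0,
    band_components=((0.4, 4.0), (1.5, 8.0)),  # (Hz, ms amplitude)
    jitter_sd_ms=1.5,
    seed=2,
)
trace, planted_rr = cp.simulate_pressure_trace(spec)

beats = cp.detect_beats(trace)
res = cp.hrv_metrics(beats["rr_ms"].to_numpy(), beat_times_s=beats["onset_s"].to_numpy())

print(f"beats detected:   {len(beats)}")
print(f"SBP/DBP/MAP:      {beats.sbp_mmHg.mean():.0f}/{beats.dbp_mmHg.mean():.0f}/"
      f"{beats.map_mmHg.mean():.0f} mmHg")
print(f"mean RR:          {res.mean_rr_ms:.1f} ms  (HR {60000 / res.mean_rr_ms:.0f} bpm)")
print(f"SDRR / RMSSD:     {res.sdrr_ms:.2f} / {res.rmssd_ms:.2f} ms")
print(f"SD1 / SD2:        {res.sd1_ms:.2f} / {res.sd2_ms:.2f} ms")
print(f"LF / HF power:    {res.lf_ms2:.1f} / {res.hf_ms2:.1f} ms^2")
print(f"LF / HF (nu):     {res.lf_nu:.1f} / {res.hf_nu:.1f}")
print(f"LF:HF ratio:      {res.lf_hf_ratio:.2f}")
print()
print("The planted 8 ms HF modulation carries a^2/2 = 32 ms^2 and the 4 ms LF")
print("modulation 8 ms^2, so LF:HF should sit near 0.25 - vagal dominance, as")
print("in a healthy anaesthetised rat; sympathetic excess drives it upward.")
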