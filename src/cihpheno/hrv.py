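"""Arterial-pressure beat detection and heart-rate-variability metrics.

Beats are delimited by systolic peaks of the pressure waveform; per-beat
SBP/DBP/MAP and RR intervals feed a time-domain metric suite (SDRR, CVRR,
SD of rate, RMSSD, SDSD, Poincaré SD1/SD2) and a Welch-spectrum frequency
suite over rodent bands (VLF < 0.2 Hz, LF 0.2-0.75 Hz, HF 0.75-3 Hz; rat
HF tracks respiration at ~1-2 Hz).  All variability statistics use
population (1/n) variances, matching the Poincaré ellipse-fit convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .breath import poincare_sd

__all__ = [
    "PressureTrace",
    "BEAT_COLUMNS",
    "RAT_BANDS",
    "HRVTimeDomain",
    "HRVSpectral",
    "HRVResult",
    "detect_beats",
    "time_domain_hrv",
    "spectral_hrv",
    "hrv_metrics",
]

#: Rodent HRV band edges in Hz.
RAT_BANDS: dict[str, tuple[float, float]] = {
    "VLF": (0.0, 0.2),
    "LF": (0.2, 0.75),
    "HF": (0.75, 3.0),
}

BEAT_COLUMNS = ("onset_s", "sbp_mmHg", "dbp_mmHg", "map_mmHg", "rr_ms", "hr_bpm")


@dataclass
class PressureTrace:
    """Uniformly sampled arterial pressure in mmHg."""

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("pressure trace must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class HRVTimeDomain:
    mean_rr_ms: float
    median_rr_ms: float
    sdrr_ms: float
    cvrr: float
    sd_rate_bpm: float
    rmssd_ms: float
    sdsd_ms: float
    sd1_ms: float
    sd2_ms: float


@dataclass(frozen=True)
class HRVSpectral:
    total_power_ms2: float
    vlf_ms2: float
    lf_ms2: float
    hf_ms2: float
    vlf_pct: float
    lf_pct: float
    hf_pct: float
    lf_nu: float
    hf_nu: float
    lf_hf_ratio: float


@dataclass(frozen=True)
class HRVResult(HRVTimeDomain, HRVSpectral):
    """Combined time- and frequency-domain HRV metric bundle."""


def detect_beats(trace: PressureTrace) -> pd.DataFrame:
    """Detect beats from systolic peaks.

    Per cycle (systolic peak to next systolic peak): SBP is the peak value,
    DBP the cycle minimum, MAP the time average of the waveform over the
    cycle, RR the inter-peak interval.
    """
    x = trace.samples
    if trace.duration_s < 5.0:
        raise ValueError("need at least 5 s of pressure signal")
    ptp = float(np.ptp(x))
    if ptp < 1e-6:
        raise ValueError("no beats detected: flatline pressure signal")
    peaks, _ = signal.find_peaks(x, prominence=0.25 * ptp)
    if peaks.size < 2:
        raise ValueError("no beats detected: fewer than two systolic peaks")
    fs = trace.sample_rate_hz
    rows = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        cyc = x[a:b]
        rr_ms = (b - a) / fs * 1000.0
        rows.append(
            (
                a / fs,
                float(x[a]),
                float(cyc.min()),
                float(cyc.mean()),
                rr_ms,
                60000.0 / rr_ms,
            )
        )
    return pd.DataFrame(rows, columns=list(BEAT_COLUMNS))


def map_from_pressures(sbp: float, dbp: float) -> float:
    """Formula fallback when only beat pressures are available: DBP + PP/3."""
    return dbp + (sbp - dbp) / 3.0


def time_domain_hrv(rr_ms: np.ndarray) -> HRVTimeDomain:
    """Time-domain HRV of an RR series (ms).

    SDRR is the population SD of RR; CVRR = SDRR/mean; SD of rate is the SD
    of instantaneous heart rate 60000/RR; RMSSD the root-mean-square and
    SDSD the SD of successive differences; SD1/SD2 the lag-1 Poincaré axes.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 10:
        raise ValueError("need at least 10 RR intervals")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    d = np.diff(rr)
    sdrr = float(np.std(rr))
    mean_rr = float(np.mean(rr))
    sd1, sd2 = poincare_sd(rr)
    return HRVTimeDomain(
        mean_rr_ms=mean_rr,
        median_rr_ms=float(np.median(rr)),
        sdrr_ms=sdrr,
        cvrr=sdrr / mean_rr,
        sd_rate_bpm=float(np.std(60000.0 / rr)),
        rmssd_ms=float(np.sqrt(np.mean(d**2))),
        sdsd_ms=float(np.std(d)),
        sd1_ms=sd1,
        sd2_ms=sd2,
    )


def spectral_hrv(
    rr_ms: np.ndarray,
    beat_times_s: np.ndarray | None = None,
    bands: dict[str, tuple[float, float]] = RAT_BANDS,
    resample_hz: float = 20.0,
    segment_s: float = 30.0,
) -> HRVSpectral:
    """Frequency-domain HRV via Welch PSD of the resampled RR tachogram.

    The (unevenly sampled) RR series is cubic-spline interpolated onto a
    uniform ``resample_hz`` grid, linearly detrended, and its PSD estimated
    with Welch's method (Hann window, ~``segment_s`` segments, 50% overlap).
    Band powers are trapezoid integrals of the PSD; normalised units are
    relative to LF+HF.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if beat_times_s is None:
        beat_times_s = np.concatenate([[0.0], np.cumsum(rr[:-1])]) / 1000.0
    t = np.asarray(beat_times_s, dtype=float)
    if t.size != rr.size:
        raise ValueError("beat_times_s must match rr_ms in length")
    span = t[-1] - t[0]
    lf_low = bands["LF"][0]
    if span < 3.0 / lf_low:
        raise ValueError(
            f"record of {span:.1f} s is shorter than 3 cycles of the {lf_low} Hz LF edge"
        )

    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    x = CubicSpline(t, rr)(grid)
    x = signal.detrend(x, type="linear")
    nperseg = min(len(x), int(round(segment_s * resample_hz)))
    freqs, psd = signal.welch(
        x, fs=resample_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    vlf = band_power(*bands["VLF"])
    lf = band_power(*bands["LF"])
    hf = band_power(*bands["HF"])
    total = float(np.trapezoid(psd, freqs))
    lf_plus_hf = lf + hf
    return HRVSpectral(
        total_power_ms2=total,
        vlf_ms2=vlf,
        lf_ms2=lf,
        hf_ms2=hf,
        vlf_pct=100.0 * vlf / total if total > 0 else 0.0,
        lf_pct=100.0 * lf / total if total > 0 else 0.0,
        hf_pct=100.0 * hf / total if total > 0 else 0.0,
        lf_nu=100.0 * lf / lf_plus_hf if lf_plus_hf > 0 else float("nan"),
        hf_nu=100.0 * hf / lf_plus_hf if lf_plus_hf > 0 else float("nan"),
        lf_hf_ratio=lf / hf if hf > 0 else float("nan"),
    )


def hrv_metrics(
    rr_ms: np.ndarray,
    beat_times_s: np.ndarray | None = None,
    **spectral_kwargs,
) -> HRVResult:
    """Full HRV metric suite (time + frequency domains) from an RR series."""
    td = time_domain_hrv(np.asarray(rr_ms, dtype=float))
    sp = spectral_hrv(rr_ms, beat_times_s=beat_times_s, **spectral_kwargs)
    return HRVResult(**vars(td) | vars(sp))
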