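"""Chemoreflex, drug-challenge and metabolic quantification.

Two windowing conventions coexist in plethysmography/anaesthetised-rat
protocols and both are implemented here:

* plethysmography ("pleth") mode — the response to a gas challenge
  (hypoxia, hypercapnia, hypoxic hypercapnia) is the mean over the final
  5 min of the challenge epoch, compared with the unweighted mean of the
  three baseline epochs; reported as absolute change.
* anaesthetised ("anaesth") mode — the response is the mean over the last
  1 min of the challenge, compared with the 1 min immediately preceding it;
  reported as percent change.

Drug challenges (NaCN, PBG, phenylephrine, nitroprusside, atenolol,
propranolol, hexamethonium) are binned into 3 or 5 s bins and the peak
deviation from the 1 min pre-injection baseline is reported as percent
change.  The PBG pulmonary chemoreflex is summarised as apnoea and
tachypnoea durations normalised to the mean breath-cycle duration of the
30 s pre-injection baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GasTraces",
    "EpochDefinition",
    "ChallengeResponse",
    "MetabolicResult",
    "PBGResponse",
    "compute_metabolism",
    "baseline_from_epochs",
    "challenge_response",
    "drug_response",
    "pbg_apnoea_tachypnoea",
    "oedema_index",
    "ratio_quantify",
]

BASELINE_LABELS = ("baseline_1", "baseline_2", "baseline_3")


@dataclass
class GasTraces:
    """Inflow/outflow gas fractions over time (dimensionless fractions)."""

    time_s: np.ndarray
    fio2_in: np.ndarray
    fio2_out: np.ndarray
    fico2_in: np.ndarray
    fico2_out: np.ndarray
    flow_ml_min: float | None = None

    def __post_init__(self) -> None:
        arrays = [self.time_s, self.fio2_in, self.fio2_out, self.fico2_in, self.fico2_out]
        lengths = {len(np.asarray(a)) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("gas trace arrays must share a length")
        self.time_s = np.asarray(self.time_s, dtype=float)
        for name in ("fio2_in", "fio2_out", "fico2_in", "fico2_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class EpochDefinition:
    label: str  # baseline_1..3 | hypoxia | hypercapnia | hypoxic_hypercapnia | drug:<name>
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch {self.label}: end must follow start")


def validate_epochs(epochs: list[EpochDefinition]) -> None:
    """Epochs must be ordered and non-overlapping."""
    ordered = sorted(epochs, key=lambda e: e.start_s)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.start_s < a.end_s:
            raise ValueError(f"epochs {a.label} and {b.label} overlap")


@dataclass(frozen=True)
class ChallengeResponse:
    metric: str
    baseline_value: float
    response_value: float
    delta: float
    pct_change: float  # NaN with pct_undefined=True when baseline == 0
    pct_undefined: bool = False


@dataclass(frozen=True)
class MetabolicResult:
    vo2_ml_min_100g: float
    vco2_ml_min_100g: float
    ve_eq: float  # V_I / VCO2, dimensionless (both per 100 g)


@dataclass(frozen=True)
class PBGResponse:
    apnoea_cycles: float
    tachypnoea_cycles: float
    apnoea_found: bool


def _window_mean(series: pd.Series, lo: float, hi: float) -> float:
    sel = series[(series.index >= lo) & (series.index < hi)]
    if sel.empty:
        raise ValueError(f"no samples in window [{lo}, {hi})")
    return float(sel.mean())


def compute_metabolism(
    gas: GasTraces,
    flow_ml_min: float,
    window: tuple[float, float],
    body_mass_g: float,
    v_i_ml_min_100g: float | None = None,
) -> MetabolicResult:
    """Open-flow respirometry: VO2/VCO2 from inlet-outlet fraction differences.

    VO2 = flow x (mean FiO2_in - mean FiO2_out) and
    VCO2 = flow x (mean FiCO2_out - mean FiCO2_in) over the window, both
    normalised per 100 g.  The ventilatory equivalent V_I/VCO2 is computed
    when minute ventilation (already per 100 g) is supplied; mass cancels.
    """
    if flow_ml_min <= 0:
        raise ValueError("flow_ml_min must be positive")
    if body_mass_g <= 0:
        raise ValueError("body_mass_g must be positive")
    lo, hi = window
    m = (gas.time_s >= lo) & (gas.time_s < hi)
    if not np.any(m):
        raise ValueError(f"window {window} outside gas traces")
    vo2 = flow_ml_min * (gas.fio2_in[m].mean() - gas.fio2_out[m].mean())
    vco2 = flow_ml_min * (gas.fico2_out[m].mean() - gas.fico2_in[m].mean())
    tol = 1e-9 * flow_ml_min
    if vo2 < -tol or vco2 < -tol:
        raise ValueError(
            "negative computed gas exchange; inlet/outlet sensor order suspected"
        )
    scale = 100.0 / body_mass_g
    vo2_n, vco2_n = vo2 * scale, vco2 * scale
    ve_eq = v_i_ml_min_100g / vco2_n if (v_i_ml_min_100g is not None and vco2_n > 0) else math.nan
    return MetabolicResult(vo2_ml_min_100g=vo2_n, vco2_ml_min_100g=vco2_n, ve_eq=ve_eq)


def baseline_from_epochs(series: pd.Series, epochs: list[EpochDefinition]) -> float:
    """Unweighted mean of per-epoch means over the baseline epochs.

    Deliberately *not* a pooled mean: unequal epoch lengths contribute
    equally, matching the convention of averaging the (typically three)
    baseline recording epochs.
    """
    vals = [
        _window_mean(series, e.start_s, e.end_s)
        for e in epochs
        if e.label.startswith("baseline")
    ]
    if not vals:
        raise ValueError("no baseline epoch present")
    return float(np.mean(vals))


def _make_response(metric: str, baseline: float, response: float) -> ChallengeResponse:
    delta = response - baseline
    if baseline == 0:
        return ChallengeResponse(metric, baseline, response, delta, math.nan, True)
    return ChallengeResponse(metric, baseline, response, delta, 100.0 * delta / baseline)


def challenge_response(
    series: pd.Series,
    epochs: list[EpochDefinition],
    challenge_label: str,
    mode: str = "pleth",
    metric: str = "",
) -> ChallengeResponse:
    """Quantify the response of a metric series to a challenge epoch.

    ``series`` is indexed by time in seconds.  In ``pleth`` mode the
    response is the mean over the final 5 min of the challenge and the
    baseline the unweighted mean of the baseline epochs; in ``anaesth``
    mode the response is the mean over the final 1 min and the baseline the
    1 min immediately preceding the challenge.
    """
    validate_epochs(epochs)
    matches = [e for e in epochs if e.label == challenge_label]
    if not matches:
        raise ValueError(f"no epoch labelled {challenge_label!r}")
    ch = matches[0]
    if mode == "pleth":
        win = 300.0
        if ch.end_s - ch.start_s < win:
            raise ValueError(f"epoch {ch.label} shorter than the {win:.0f} s response window")
        response = _window_mean(series, ch.end_s - win, ch.end_s)
        baseline = baseline_from_epochs(series, epochs)
    elif mode == "anaesth":
        win = 60.0
        if ch.end_s - ch.start_s < win:
            raise ValueError(f"epoch {ch.label} shorter than the {win:.0f} s response window")
        response = _window_mean(series, ch.end_s - win, ch.end_s)
        baseline = _window_mean(series, ch.start_s - win, ch.start_s)
    else:
        raise ValueError("mode must be 'pleth' or 'anaesth'")
    return _make_response(metric or challenge_label, baseline, response)


def drug_response(
    series: pd.Series,
    injection_time_s: float,
    bin_s: float = 3.0,
    baseline_s: float = 60.0,
    search_s: float = 60.0,
    metric: str = "",
) -> ChallengeResponse:
    """Peak response to a bolus drug injection.

    The post-injection record is averaged into ``bin_s`` bins over a
    ``search_s`` window; the peak is the bin with maximum absolute deviation
    from the 1 min pre-injection baseline, its sign preserved (pressor
    responses positive, depressor negative).
    """
    t0, t1 = float(series.index[0]), float(series.index[-1])
    if not (t0 + baseline_s <= injection_time_s <= t1 - bin_s):
        raise ValueError("injection time outside the usable record")
    baseline = _window_mean(series, injection_time_s - baseline_s, injection_time_s)
    n_bins = int(search_s // bin_s)
    best_val, best_dev = baseline, -1.0
    for k in range(n_bins):
        lo = injection_time_s + k * bin_s
        hi = lo + bin_s
        sel = series[(series.index >= lo) & (series.index < hi)]
        if sel.empty:
            continue
        val = float(sel.mean())
        dev = abs(val - baseline)
        if dev > best_dev:
            best_dev, best_val = dev, val
    return _make_response(metric, baseline, best_val)


def pbg_apnoea_tachypnoea(
    breaths: pd.DataFrame,
    injection_time_s: float,
    search_s: float = 60.0,
    apnoea_gap_mult: float = 2.0,
    tachypnoea_sd_mult: float = 2.0,
    tachypnoea_min_run: int = 3,
) -> PBGResponse:
    """PBG pulmonary-chemoreflex apnoea and tachypnoea in baseline cycles.

    The 30 s pre-injection baseline defines the mean and SD of the breath
    cycle duration.  The apnoea is the first post-injection inter-onset
    interval exceeding ``apnoea_gap_mult`` x baseline mean; its duration
    (net of one expected cycle) is divided by the baseline mean cycle.  The
    tachypnoea is the contiguous run (>= ``tachypnoea_min_run`` breaths)
    following the apnoea with T_tot below mean - ``tachypnoea_sd_mult`` x SD,
    its total duration likewise normalised.  Returns zeros with
    ``apnoea_found=False`` when no qualifying pause exists.
    """
    kept = breaths[~breaths["artifact_flag"]]
    base = kept[
        (kept["onset_s"] >= injection_time_s - 30.0) & (kept["onset_s"] < injection_time_s)
    ]
    if len(base) < 5 or base["onset_s"].iloc[0] > injection_time_s - 25.0:
        raise ValueError("need >= 30 s of breaths before the injection")
    mean_tt_s = float(base["t_tot_ms"].mean()) / 1000.0
    sd_tt_ms = float(base["t_tot_ms"].std(ddof=1))

    post = kept[
        (kept["onset_s"] >= injection_time_s)
        & (kept["onset_s"] < injection_time_s + search_s)
    ]
    onsets = post["onset_s"].to_numpy()
    t_tot_ms = post["t_tot_ms"].to_numpy()
    gaps = np.diff(onsets)
    hits = np.nonzero(gaps > apnoea_gap_mult * mean_tt_s)[0]
    if hits.size == 0:
        return PBGResponse(0.0, 0.0, False)
    i = int(hits[0])
    apnoea_s = float(gaps[i]) - mean_tt_s
    apnoea_cycles = apnoea_s / mean_tt_s

    thresh_ms = mean_tt_s * 1000.0 - tachypnoea_sd_mult * sd_tt_ms
    run_ms = 0.0
    run_len = 0
    best_ms = 0.0
    for tt in t_tot_ms[i + 1 :]:
        if tt < thresh_ms:
            run_ms += tt
            run_len += 1
            if run_len >= tachypnoea_min_run:
                best_ms = run_ms
        else:
            if best_ms:
                break
            run_ms, run_len = 0.0, 0
    tachypnoea_cycles = (best_ms / 1000.0) / mean_tt_s
    return PBGResponse(apnoea_cycles, tachypnoea_cycles, True)


def oedema_index(wet_mg: float, dry_mg: float) -> float:
    """Pulmonary oedema index: water content as % of wet tissue weight."""
    if dry_mg <= 0 or wet_mg <= 0:
        raise ValueError("weights must be positive")
    if dry_mg > wet_mg:
        raise ValueError("dry weight exceeds wet weight")
    return 100.0 * (wet_mg - dry_mg) / wet_mg


def ratio_quantify(
    analyte_peak: float,
    internal_standard_peak: float,
    is_amount: float,
    calibration_factor: float = 1.0,
) -> float:
    """Chromatographic quantification via analyte:internal-standard ratio."""
    if internal_standard_peak <= 0:
        raise ValueError("internal standard peak must be positive")
    return (analyte_peak / internal_standard_peak) * is_amount * calibration_factor
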