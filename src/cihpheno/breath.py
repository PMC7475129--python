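"""Breath-by-breath analysis of whole-body plethysmography flow signals.

Respiratory flow is recorded with inspiration as a *negative* deflection
(the usual rodent plethysmography plotting convention).  Breaths are
segmented at inspiratory onsets found by hysteresis-gated zero crossings of
a lightly smoothed copy of the signal; per-breath timing (T_i, T_e, T_tot),
tidal volume (V_T, the integrated inspiratory flow excursion), mean
inspiratory flow (V_T/T_i) and instantaneous respiratory frequency are
tabulated.  Epoch summaries normalise volumes per 100 g body mass, the
convention in which rodent ventilation is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowTrace",
    "ArtifactRules",
    "VentilationSummary",
    "BREATH_COLUMNS",
    "segment_breaths",
    "reject_artifacts",
    "summarize_epoch",
    "poincare_sd",
]

#: Column order of a breath table (one row per detected breath).
BREATH_COLUMNS = (
    "onset_s",
    "t_i_ms",
    "t_e_ms",
    "t_tot_ms",
    "v_t_ml",
    "vt_over_ti_ml_s",
    "inst_f_r_brpm",
    "artifact_flag",
)


@dataclass
class FlowTrace:
    """Uniformly sampled respiratory flow in ml/s, inspiration negative."""

    samples: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""
    body_mass_g: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("flow trace must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("flow trace contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class ArtifactRules:
    """Breath-rejection rules.

    ``windows``: declared artifact intervals (start_s, end_s) — movement or
    sniffing episodes marked on the raw record.  ``t_tot_ms_bounds``: breaths
    with implausible total duration are rejected.  ``v_t_median_mult``:
    breaths whose V_T exceeds this multiple of the epoch median V_T are
    rejected (amplitude artifacts; genuine sighs sit well below 5x).
    """

    windows: tuple[tuple[float, float], ...] = ()
    t_tot_ms_bounds: tuple[float, float] = (100.0, 3000.0)
    v_t_median_mult: float = 5.0


@dataclass(frozen=True)
class VentilationSummary:
    """Epoch-mean ventilation, volumes normalised per 100 g body mass."""

    f_r_brpm: float
    v_t_ml_100g: float
    v_i_ml_min_100g: float
    vt_over_ti_ml_s_100g: float
    t_i_ms: float
    t_e_ms: float
    n_breaths: int
    window: tuple[float, float]


def _smooth(x: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    w = max(1, int(round(smooth_ms * fs / 1000.0)))
    if w == 1:
        return x
    kernel = np.full(w, 1.0 / w)
    return np.convolve(x, kernel, mode="same")


def _hysteresis_states(s: np.ndarray, thr: float) -> np.ndarray:
    """-1 while inspiring, +1 while expiring; gaps hold the previous state."""
    raw = np.zeros(len(s), dtype=np.int8)
    raw[s < -thr] = -1
    raw[s > thr] = 1
    nz = raw != 0
    last = np.where(nz, np.arange(len(s)), -1)
    last = np.maximum.accumulate(last)
    state = np.where(last >= 0, raw[np.clip(last, 0, None)], np.int8(1))
    return state.astype(np.int8)


def _start_of_negative_run(x: np.ndarray, i: int, max_steps: int) -> int:
    """First index of the negative run containing (or nearest after) ``i``."""
    if x[i] >= 0:
        steps = 0
        while i < len(x) - 1 and x[i] >= 0 and steps < max_steps:
            i += 1
            steps += 1
    steps = 0
    while i > 0 and x[i - 1] < 0 and steps < max_steps:
        i -= 1
        steps += 1
    return i


def _end_of_negative_run(x: np.ndarray, i: int, max_steps: int) -> int:
    """First non-negative index after the negative run containing ``i``."""
    if x[i] >= 0:
        steps = 0
        while i > 0 and x[i] >= 0 and steps < max_steps:
            i -= 1
            steps += 1
    steps = 0
    while i < len(x) - 1 and x[i] < 0 and steps < max_steps:
        i += 1
        steps += 1
    return i


def segment_breaths(
    trace: FlowTrace,
    min_ti_ms: float = 40.0,
    min_vt_ml: float = 0.0,
    max_ti_ms: float = 1000.0,
    smooth_ms: float = 10.0,
    hysteresis_frac: float = 0.02,
    invert: bool = False,
) -> pd.DataFrame:
    """Segment a flow trace into breaths.

    Inspiratory onsets are hysteresis-gated crossings of the smoothed flow
    below ``-hysteresis_frac * peak``; inspiration ends when the smoothed
    flow rises above the positive threshold.  Each detected phase boundary
    is then refined to the nearest raw-signal zero crossing, which removes
    the smoothing/threshold delay (timing is accurate to about one sample
    on clean signals).  T_e runs from the end of inspiration to the next
    inspiratory onset, so expiratory pauses are charged to T_e (the apnoea
    criterion operates on these intervals downstream).  Cycles with T_i
    below ``min_ti_ms`` or V_T below ``min_vt_ml`` are dropped as
    sub-threshold efforts, their time folded into the neighbouring breath's
    T_e.

    Set ``invert=True`` for recordings with inspiration positive.
    """
    if min_ti_ms < 0 or min_vt_ml < 0:
        raise ValueError("thresholds must be non-negative")
    x = -trace.samples if invert else trace.samples
    fs = trace.sample_rate_hz
    s = _smooth(x, fs, smooth_ms)
    peak = float(np.max(np.abs(s)))
    if peak <= 0:
        raise ValueError("no breaths detected: flow trace is empty or constant")
    thr = hysteresis_frac * peak

    state = _hysteresis_states(s, thr)
    flips = np.diff(state)
    onsets = np.nonzero(flips < 0)[0] + 1  # expiration -> inspiration
    ends = np.nonzero(flips > 0)[0] + 1  # inspiration -> expiration
    if onsets.size == 0:
        raise ValueError("no breaths detected: no inspiratory onsets found")

    dt = 1.0 / fs
    max_steps = int(0.25 * fs)  # refinement search bound, a quarter second
    cycles: list[tuple[int, int]] = []  # (onset_idx, insp_end_idx)
    for on in onsets:
        after = ends[ends > on]
        if after.size == 0:
            break
        on_r = _start_of_negative_run(x, int(on), max_steps)
        end_r = _end_of_negative_run(x, int(after[0]), max_steps)
        if end_r <= on_r:
            continue
        # A quiet stretch (e.g. an apnoea) can latch the inspiratory state on
        # a noise dip well before the actual breath.  The genuine inspiration
        # is the final contiguous negative run before the phase flip; if that
        # sits more than a noise-blip (~50 ms) past the hysteresis onset,
        # re-anchor to it.
        on_final = _start_of_negative_run(x, end_r - 1, max_steps)
        if (on_final - on_r) * dt * 1000.0 > 50.0:
            on_r = on_final
        if (end_r - on_r) * dt * 1000.0 > max_ti_ms:
            continue  # not a plausible single inspiration
        if cycles and on_r < cycles[-1][1]:
            continue  # refinement collapsed into the previous cycle
        cycles.append((on_r, end_r))

    # sub-threshold filter
    kept: list[tuple[int, int, float]] = []
    for on, end in cycles:
        ti_ms = (end - on) * dt * 1000.0
        v_t = -float(np.sum(x[on:end])) * dt
        if ti_ms < min_ti_ms or v_t < min_vt_ml:
            continue
        kept.append((on, end, v_t))
    if not kept:
        raise ValueError("no breaths detected after threshold filtering")

    n_samp = len(x)
    rows = []
    for j, (on, end, v_t) in enumerate(kept):
        nxt = kept[j + 1][0] if j + 1 < len(kept) else n_samp
        t_i = (end - on) * dt * 1000.0
        t_e = (nxt - end) * dt * 1000.0
        if t_e <= 0:
            continue  # truncated final expiration
        t_tot = t_i + t_e
        rows.append(
            (
                on * dt,
                t_i,
                t_e,
                t_tot,
                v_t,
                v_t / (t_i / 1000.0),
                60000.0 / t_tot,
                False,
            )
        )
    if not rows:
        raise ValueError("no complete breaths detected")
    return pd.DataFrame(rows, columns=list(BREATH_COLUMNS))


def reject_artifacts(breaths: pd.DataFrame, rules: ArtifactRules = ArtifactRules()) -> pd.DataFrame:
    """Flag artifact breaths; flagged rows are retained but excluded downstream.

    A breath is flagged when it overlaps a declared artifact window, its
    T_tot falls outside ``t_tot_ms_bounds``, or its V_T exceeds
    ``v_t_median_mult`` times the epoch median V_T.  The median is taken
    over all breaths (flagged included), which makes the operation
    idempotent.
    """
    if breaths.empty:
        raise ValueError("breath table is empty")
    out = breaths.copy()
    flag = out["artifact_flag"].to_numpy(copy=True).astype(bool)

    start = out["onset_s"].to_numpy()
    stop = start + out["t_tot_ms"].to_numpy() / 1000.0
    for w0, w1 in rules.windows:
        flag |= (start < w1) & (stop > w0)

    lo, hi = rules.t_tot_ms_bounds
    t_tot = out["t_tot_ms"].to_numpy()
    flag |= (t_tot < lo) | (t_tot > hi)

    med = float(np.median(out["v_t_ml"].to_numpy()))
    if med > 0:
        flag |= out["v_t_ml"].to_numpy() > rules.v_t_median_mult * med

    out["artifact_flag"] = flag
    return out


def summarize_epoch(
    breaths: pd.DataFrame,
    window: tuple[float, float],
    body_mass_g: float,
) -> VentilationSummary:
    """Mean ventilation over unflagged breaths whose onset lies in ``window``.

    V_T, V_I and V_T/T_i are normalised per 100 g body mass; minute
    ventilation is computed as f_R x V_T so the identity V_I = f_R.V_T holds
    exactly in the summary.
    """
    if body_mass_g <= 0:
        raise ValueError("body_mass_g must be positive")
    lo, hi = window
    sel = breaths[
        (~breaths["artifact_flag"])
        & (breaths["onset_s"] >= lo)
        & (breaths["onset_s"] < hi)
    ]
    if sel.empty:
        raise ValueError(f"no unflagged breaths in window {window}")
    scale = 100.0 / body_mass_g
    f_r = float(sel["inst_f_r_brpm"].mean())
    v_t = float(sel["v_t_ml"].mean()) * scale
    return VentilationSummary(
        f_r_brpm=f_r,
        v_t_ml_100g=v_t,
        v_i_ml_min_100g=f_r * v_t,
        vt_over_ti_ml_s_100g=float(sel["vt_over_ti_ml_s"].mean()) * scale,
        t_i_ms=float(sel["t_i_ms"].mean()),
        t_e_ms=float(sel["t_e_ms"].mean()),
        n_breaths=int(len(sel)),
        window=(float(lo), float(hi)),
    )


def poincare_sd(series: Sequence[float], lag: int = 1) -> tuple[float, float]:
    """Poincaré SD1/SD2 of an interval series (ms in, ms out).

    Plotting each interval against its ``lag``-th successor, SD1 is the
    dispersion perpendicular to the identity line (short-term variability)
    and SD2 the dispersion along it (long-term variability):

        SD1 = sqrt(Var(x_n - x_{n+lag}) / 2)
        SD2 = sqrt(Var(x_n + x_{n+lag}) / 2)

    with population (1/n) variances over the lagged pairs.
    """
    x = np.asarray(series, dtype=float)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if x.size < 3 or x.size - lag < 2:
        raise ValueError("need at least 3 intervals for Poincaré analysis")
    a, b = x[:-lag], x[lag:]
    sd1 = float(np.sqrt(np.var(a - b) / 2.0))
    sd2 = float(np.sqrt(np.var(a + b) / 2.0))
    return sd1, sd2
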