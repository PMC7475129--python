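"""Scoring of respiratory events (sighs and apnoeas) from a breath table.

A sigh is an augmented breath whose tidal volume reaches at least twice the
prevailing average V_T.  An apnoea is a pause in breathing longer than two
consecutive missed breaths, i.e. an inter-onset interval exceeding
(1 + miss_multiple) times the local mean cycle duration.  Apnoeas are
classified as post-sigh when they begin within a configurable number of
breaths after a sigh, otherwise spontaneous; the apnoea index (events per
hour of analysed breathing) combines both classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RespEvent",
    "EventSummary",
    "detect_sighs",
    "detect_apnoeas",
    "classify_apnoeas",
    "event_summary",
]

SIGH = "sigh"
SPONTANEOUS_APNOEA = "spontaneous_apnoea"
POST_SIGH_APNOEA = "post_sigh_apnoea"
APNOEA_KINDS = (SPONTANEOUS_APNOEA, POST_SIGH_APNOEA, "apnoea")


@dataclass(frozen=True)
class RespEvent:
    """A scored respiratory event.

    Apnoeas carry ``duration_s`` (the pause net of one expected breath);
    sighs carry ``amplitude_ml`` and, when body mass is known,
    ``amplitude_ml_100g``.
    """

    kind: str
    onset_s: float
    duration_s: float = math.nan
    amplitude_ml: float = math.nan
    amplitude_ml_100g: float = math.nan


@dataclass(frozen=True)
class EventSummary:
    apnoea_index_per_hr: float
    post_sigh_rate_per_hr: float
    spontaneous_rate_per_hr: float
    sigh_frequency_per_hr: float
    mean_sigh_amplitude_ml_100g: float
    analysed_duration_hr: float


def detect_sighs(
    breaths: pd.DataFrame,
    gain_threshold: float = 2.0,
    baseline_window_breaths: int = 50,
    body_mass_g: float | None = None,
) -> list[RespEvent]:
    """Detect sighs as breaths with V_T >= gain_threshold x local mean V_T.

    The local mean is a centred rolling mean of V_T over
    ``baseline_window_breaths`` unflagged breaths, computed in two passes:
    breaths crossing the threshold on the first pass are excluded from the
    baseline of the second, so large sighs do not inflate their own
    threshold.  The comparison is inclusive (exactly double counts; 1.9x
    does not).
    """
    kept = breaths[~breaths["artifact_flag"]]
    if len(kept) < baseline_window_breaths:
        raise ValueError(
            f"need at least {baseline_window_breaths} unflagged breaths, got {len(kept)}"
        )
    v_t = kept["v_t_ml"].reset_index(drop=True)
    roll = dict(window=baseline_window_breaths, center=True, min_periods=5)
    base1 = v_t.rolling(**roll).mean()
    cand = v_t >= gain_threshold * base1
    masked = v_t.where(~cand)
    base2 = masked.rolling(**roll).mean().fillna(base1)
    is_sigh = (v_t >= gain_threshold * base2).to_numpy()

    onsets = kept["onset_s"].to_numpy()
    t_tot = kept["t_tot_ms"].to_numpy() / 1000.0
    events = []
    for i in np.nonzero(is_sigh)[0]:
        amp = float(v_t.iloc[i])
        events.append(
            RespEvent(
                kind=SIGH,
                onset_s=float(onsets[i]),
                duration_s=float(t_tot[i]),
                amplitude_ml=amp,
                amplitude_ml_100g=(amp * 100.0 / body_mass_g) if body_mass_g else math.nan,
            )
        )
    return events


def detect_apnoeas(
    breaths: pd.DataFrame,
    miss_multiple: float = 2.0,
    local_window_breaths: int = 10,
    sighs: list[RespEvent] | None = None,
) -> list[RespEvent]:
    """Detect apnoeas as inter-onset gaps exceeding (1+miss_multiple) x local T_tot.

    The local mean T_tot is taken over the preceding ``local_window_breaths``
    unflagged breaths that are neither sighs nor carriers of an earlier
    apnoea, so slow rate drift is tracked without the events distorting
    their own criterion.  With the default ``miss_multiple=2`` an interval
    must exceed three local cycle durations (one expected breath plus two
    missed ones), the strict reading of "a pause greater than two
    consecutive missed breaths".  Gaps before the first full window are not
    scored.  Recorded onset is the end of the expected breath and duration
    the remaining pause, so a planted gap of k x T_tot rounds-trips to
    duration k x T_tot.
    """
    kept = breaths[~breaths["artifact_flag"]]
    if len(kept) < local_window_breaths + 1:
        raise ValueError(
            f"need at least {local_window_breaths + 1} unflagged breaths, got {len(kept)}"
        )
    onsets = kept["onset_s"].to_numpy()
    flagged_onsets = breaths.loc[breaths["artifact_flag"], "onset_s"].to_numpy()
    sigh_onsets = {round(e.onset_s, 9) for e in (sighs or []) if e.kind == SIGH}

    events: list[RespEvent] = []
    history: list[float] = []  # usable T_tot values, seconds
    for i in range(len(onsets) - 1):
        gap = onsets[i + 1] - onsets[i]
        if np.any((flagged_onsets > onsets[i]) & (flagged_onsets < onsets[i + 1])):
            continue  # artifact time: neither scored nor added to history
        is_sigh = round(float(onsets[i]), 9) in sigh_onsets
        if len(history) >= local_window_breaths:
            local_mean = float(np.mean(history[-local_window_breaths:]))
            if gap > (1.0 + miss_multiple) * local_mean:
                events.append(
                    RespEvent(
                        kind="apnoea",
                        onset_s=float(onsets[i] + local_mean),
                        duration_s=float(gap - local_mean),
                    )
                )
                continue  # carrier breath: exclude its gap from history
        if not is_sigh:
            history.append(float(gap))
    return events


def classify_apnoeas(
    apnoeas: list[RespEvent],
    sighs: list[RespEvent],
    breaths: pd.DataFrame,
    post_sigh_lag_breaths: int = 1,
) -> list[RespEvent]:
    """Split apnoeas into post-sigh and spontaneous.

    An apnoea is post-sigh when fewer than ``post_sigh_lag_breaths`` breath
    onsets separate the most recent sigh from the apnoea: with the default
    lag of 1 the sigh must be the breath immediately preceding the pause.
    """
    onsets = np.sort(breaths.loc[~breaths["artifact_flag"], "onset_s"].to_numpy())
    sigh_onsets = np.sort([e.onset_s for e in sighs])
    out = []
    for ap in sorted(apnoeas, key=lambda e: e.onset_s):
        kind = SPONTANEOUS_APNOEA
        prior = sigh_onsets[sigh_onsets < ap.onset_s]
        if prior.size:
            last_sigh = prior[-1]
            between = np.count_nonzero((onsets > last_sigh) & (onsets < ap.onset_s))
            if between < post_sigh_lag_breaths:
                kind = POST_SIGH_APNOEA
        out.append(
            RespEvent(
                kind=kind,
                onset_s=ap.onset_s,
                duration_s=ap.duration_s,
            )
        )
    return out


def event_summary(events: list[RespEvent], analysed_duration_hr: float) -> EventSummary:
    """Event rates per hour of analysed (artifact-free) recording time."""
    if analysed_duration_hr <= 0:
        raise ValueError("analysed_duration_hr must be positive")
    n_post = sum(1 for e in events if e.kind == POST_SIGH_APNOEA)
    n_spont = sum(1 for e in events if e.kind in (SPONTANEOUS_APNOEA, "apnoea"))
    sigh_amps = [e.amplitude_ml_100g for e in events if e.kind == SIGH]
    n_sigh = len(sigh_amps)
    return EventSummary(
        apnoea_index_per_hr=(n_post + n_spont) / analysed_duration_hr,
        post_sigh_rate_per_hr=n_post / analysed_duration_hr,
        spontaneous_rate_per_hr=n_spont / analysed_duration_hr,
        sigh_frequency_per_hr=n_sigh / analysed_duration_hr,
        mean_sigh_amplitude_ml_100g=float(np.mean(sigh_amps)) if n_sigh else math.nan,
        analysed_duration_hr=analysed_duration_hr,
    )
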