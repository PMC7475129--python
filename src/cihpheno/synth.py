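"""Synthetic physiological and count data with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
planted truth returned alongside, emulating a 2x2 chronic-intermittent-
hypoxia (CIH) x prebiotic (PREB) rat study:

* respiratory flow traces — half-sine inspiration (negative deflection),
  exponential-decay expiration, with sighs (amplitude-scaled breaths),
  apnoeas (zero-flow gaps of known cycle multiples) and movement-artifact
  bursts injected at known times;
* arterial pressure waveforms — stylised pulses whose beat-to-beat
  intervals carry controlled sinusoidal power in chosen VLF/LF/HF bands;
* steady-state gas fraction traces consistent with set VO2/VCO2;
* Dirichlet-multinomial count tables with planted group fold changes;
* a bundled study dataset over the four design groups.

Defaults sit at the scale of a ~300 g adult rat at rest: f_R ~82 brpm,
V_T ~0.7 ml/100 g, mean RR ~153 ms (HR ~390 bpm), VO2 ~2.7 and VCO2
~1.9 ml/min/100 g.  All randomness flows from explicit integer seeds;
identical seed and spec give bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .breath import FlowTrace
from .challenges import GasTraces
from .hrv import PressureTrace

__all__ = [
    "SimProtocol",
    "ApnoeaSpec",
    "PlantedEvent",
    "PlantedEventLog",
    "RRSimSpec",
    "CountSimSpec",
    "StudyDesign",
    "StudyDataset",
    "simulate_flow_trace",
    "simulate_pressure_trace",
    "simulate_gas_traces",
    "simulate_count_table",
    "simulate_study",
]

STUDY_GROUPS = ("Sham+VEH", "CIH+VEH", "Sham+PREB", "CIH+PREB")

#: Group mean body masses (g) at study end; SDs ~16-27 g.
BODY_MASS_MEANS = {
    "Sham+VEH": 368.0,
    "CIH+VEH": 346.0,
    "Sham+PREB": 308.0,
    "CIH+PREB": 263.0,
}
BODY_MASS_SD = 20.0


@dataclass(frozen=True)
class ApnoeaSpec:
    onset_s: float
    duration_ttot: float  # pause length in multiples of T_tot
    post_sigh: bool = False


@dataclass(frozen=True)
class PlantedEvent:
    kind: str  # sigh | spontaneous_apnoea | post_sigh_apnoea | artifact
    onset_s: float
    duration_s: float
    amplitude: float = 0.0


@dataclass(frozen=True)
class PlantedEventLog:
    events: tuple[PlantedEvent, ...]

    def of_kind(self, *kinds: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.kind in kinds]


@dataclass(frozen=True)
class SimProtocol:
    """Flow-trace generation protocol (resting adult rat defaults)."""

    duration_s: float = 600.0
    sample_rate_hz: float = 200.0
    f_r_brpm: float = 82.0
    v_t_ml: float = 2.1
    ti_fraction: float = 0.33  # T_i / T_tot
    noise_sd: float = 0.02  # fraction of peak inspiratory flow
    sigh_times_s: tuple[float, ...] = ()
    sigh_gain: float = 2.5
    apnoea_specs: tuple[ApnoeaSpec, ...] = ()
    artifact_specs: tuple[tuple[float, float], ...] = ()  # (onset_s, duration_s)
    seed: int = 0
    body_mass_g: float = 300.0
    subject_id: str = "sim"

    @property
    def t_tot_s(self) -> float:
        return 60.0 / self.f_r_brpm

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz < 50:
            raise ValueError("sample_rate_hz must be >= 50")
        if not 0 < self.ti_fraction < 1:
            raise ValueError("ti_fraction must lie in (0, 1)")
        if self.sigh_gain < 1:
            raise ValueError("sigh_gain must be >= 1 (>= 2 recommended)")
        for t in self.sigh_times_s:
            if not 0 <= t < self.duration_s:
                raise ValueError(f"sigh at {t} s outside the record")
        for ap in self.apnoea_specs:
            if not 0 <= ap.onset_s < self.duration_s:
                raise ValueError(f"apnoea at {ap.onset_s} s outside the record")
        for on, dur in self.artifact_specs:
            if not 0 <= on and on + dur <= self.duration_s:
                raise ValueError(f"artifact at {on} s outside the record")


def _check_overlaps(intervals: list[tuple[str, float, float]]) -> None:
    ordered = sorted(intervals, key=lambda iv: iv[1])
    for (na, a0, a1), (nb, b0, b1) in zip(ordered[:-1], ordered[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError(f"planted events overlap: {na} and {nb}")


def simulate_flow_trace(spec: SimProtocol) -> tuple[FlowTrace, PlantedEventLog]:
    """Generate a respiratory flow trace with a ground-truth event log.

    Breaths are half-sine inspirations (negative) followed by
    exponential-decay expirations, both integrating to V_T so each cycle is
    volume-balanced.  Sighs scale the whole cycle by ``sigh_gain``; apnoeas
    replace breathing with zero flow (plus baseline noise) for the stated
    T_tot multiple, starting at the end of the breath containing the
    requested onset; artifacts are broadband high-amplitude noise bursts.
    An apnoea with ``post_sigh=True`` additionally turns its preceding
    breath into a sigh, and both events are logged.  Overlapping planted
    events are rejected with an error naming the pair.
    """
    spec.validate()
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t_tot = spec.t_tot_s
    t_i = spec.ti_fraction * t_tot
    t_e = t_tot - t_i
    amp_i = spec.v_t_ml * np.pi / (2.0 * t_i)  # peak inspiratory flow, ml/s
    tau_e = t_e / 4.0
    amp_e = spec.v_t_ml / (tau_e * (1.0 - np.exp(-t_e / tau_e)))

    # one template cycle at unit gain
    n_i = int(round(t_i * fs))
    n_cyc = int(round(t_tot * fs))
    tt = np.arange(n_cyc) / fs
    template = np.empty(n_cyc)
    template[:n_i] = -amp_i * np.sin(np.pi * tt[:n_i] / t_i)
    template[n_i:] = amp_e * np.exp(-(tt[n_i:] - t_i) / tau_e)

    apnoeas = sorted(spec.apnoea_specs, key=lambda a: a.onset_s)
    sigh_times = sorted(spec.sigh_times_s)

    rng = np.random.default_rng(spec.seed)
    x = rng.normal(0.0, spec.noise_sd * amp_i, n) if spec.noise_sd > 0 else np.zeros(n)

    events: list[PlantedEvent] = []
    intervals: list[tuple[str, float, float]] = []
    cursor = 0.0
    ap_idx = 0
    while cursor + t_tot <= spec.duration_s + 1e-9:
        cyc_start, cyc_end = cursor, cursor + t_tot
        gain = 1.0
        is_sigh = any(cyc_start <= s < cyc_end for s in sigh_times)
        pending_ap = None
        if ap_idx < len(apnoeas) and cyc_start <= apnoeas[ap_idx].onset_s < cyc_end:
            pending_ap = apnoeas[ap_idx]
            ap_idx += 1
            if pending_ap.post_sigh:
                is_sigh = True
        if is_sigh:
            gain = spec.sigh_gain
            events.append(
                PlantedEvent("sigh", cyc_start, t_tot, amplitude=gain * spec.v_t_ml)
            )
            intervals.append((f"sigh@{cyc_start:.2f}", cyc_start, cyc_end))
        i0 = int(round(cyc_start * fs))
        seg = template[: max(0, min(n_cyc, n - i0))]
        x[i0 : i0 + len(seg)] += gain * seg
        cursor = cyc_end
        if pending_ap is not None:
            gap = pending_ap.duration_ttot * t_tot
            kind = "post_sigh_apnoea" if pending_ap.post_sigh else "spontaneous_apnoea"
            events.append(PlantedEvent(kind, cursor, gap))
            intervals.append((f"{kind}@{cursor:.2f}", cursor, cursor + gap))
            cursor += gap  # zero flow (noise only)

    for on, dur in spec.artifact_specs:
        i0, i1 = int(round(on * fs)), int(round((on + dur) * fs))
        x[i0:i1] += rng.normal(0.0, 3.0 * amp_i, i1 - i0)
        events.append(PlantedEvent("artifact", on, dur))
        intervals.append((f"artifact@{on:.2f}", on, on + dur))

    _check_overlaps(intervals)
    events.sort(key=lambda e: e.onset_s)
    trace = FlowTrace(
        samples=x,
        sample_rate_hz=fs,
        subject_id=spec.subject_id,
        body_mass_g=spec.body_mass_g,
    )
    return trace, PlantedEventLog(tuple(events))


@dataclass(frozen=True)
class RRSimSpec:
    """Pressure-waveform generation spec (anaesthetised rat defaults)."""

    duration_s: float = 300.0
    sample_rate_hz: float = 1000.0
    mean_rr_ms: float = 153.0
    band_components: tuple[tuple[float, float], ...] = ()  # (freq_hz, amplitude_ms)
    sbp_mmHg: float = 120.0
    dbp_mmHg: float = 80.0
    jitter_sd_ms: float = 2.0
    seed: int = 0
    subject_id: str = "sim"

    def validate(self) -> None:
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be positive")
        if self.dbp_mmHg >= self.sbp_mmHg:
            raise ValueError("dbp must be below sbp")
        nyquist = 0.5 / (self.mean_rr_ms / 1000.0)
        for f, a in self.band_components:
            if f >= nyquist:
                raise ValueError(
                    f"component at {f} Hz is at/above the beat-rate Nyquist {nyquist:.2f} Hz"
                )
            if a >= self.mean_rr_ms / 2:
                raise ValueError("component amplitude must be < mean_rr_ms / 2")


def simulate_pressure_trace(spec: RRSimSpec) -> tuple[PressureTrace, np.ndarray]:
    """Generate an arterial pressure waveform with planted RR modulation.

    Beat k starting at time t_k has interval
    RR_k = mean + sum_i a_i sin(2 pi f_i t_k) + jitter.  Each beat is a
    stylised pulse rising from DBP to SBP over the first 30% of the cycle
    (half-sine) and relaxing back to DBP (raised-cosine), so per-cycle
    max/min are exactly SBP/DBP.  Returns the trace and the planted RR
    series (ms), whose spectrum is the recovery target for HRV analysis.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rr_list: list[float] = []
    times: list[float] = []
    t = 0.0
    mean_rr_s = spec.mean_rr_ms / 1000.0
    while t < spec.duration_s:
        rr_ms = spec.mean_rr_ms + sum(
            a * np.sin(2 * np.pi * f * t) for f, a in spec.band_components
        )
        if spec.jitter_sd_ms > 0:
            rr_ms += rng.normal(0.0, spec.jitter_sd_ms)
        rr_ms = max(rr_ms, spec.mean_rr_ms * 0.2)
        times.append(t)
        rr_list.append(rr_ms)
        t += rr_ms / 1000.0

    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    pp = spec.sbp_mmHg - spec.dbp_mmHg
    rise_frac = 0.3
    k = 3.0  # diastolic decay constant
    starts = np.asarray(times)
    rr_s = np.asarray(rr_list) / 1000.0
    t = np.arange(n) / fs
    beat = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    tau = t - starts[beat]
    this_rr = rr_s[beat]
    t_rise = rise_frac * this_rr
    u = np.clip((tau - t_rise) / (this_rr - t_rise), 0.0, 1.0)
    decay = (np.exp(-k * u) - np.exp(-k)) / (1.0 - np.exp(-k))
    # linear upstroke + exponential run-off: the slope breaks at the systolic
    # peak on both sides, so the peak sample is unambiguous
    w = np.where(tau < t_rise, tau / t_rise, decay)
    x = spec.dbp_mmHg + pp * w
    trace = PressureTrace(samples=x, sample_rate_hz=fs, subject_id=spec.subject_id)
    return trace, np.asarray(rr_list)


def simulate_gas_traces(
    vo2_ml_min: float,
    vco2_ml_min: float,
    flow_ml_min: float,
    inlet_fractions: tuple[float, float] = (0.2093, 0.0004),
    duration_s: float = 60.0,
    sample_rate_hz: float = 1.0,
) -> GasTraces:
    """Steady-state open-flow gas traces consistent with set VO2/VCO2.

    Outlet fractions follow from mass balance:
    FiO2_out = FiO2_in - VO2/flow and FiCO2_out = FiCO2_in + VCO2/flow, so
    metabolic analysis of the traces recovers the planted rates exactly.
    """
    if flow_ml_min <= 0:
        raise ValueError("flow_ml_min must be positive")
    fio2_in, fico2_in = inlet_fractions
    for f in inlet_fractions:
        if not 0 <= f < 1:  # a CO2-free inlet is legitimate
            raise ValueError("inlet fractions must lie in [0, 1)")
    fio2_out = fio2_in - vo2_ml_min / flow_ml_min
    fico2_out = fico2_in + vco2_ml_min / flow_ml_min
    for name, f in (("FiO2_out", fio2_out), ("FiCO2_out", fico2_out)):
        if not 0 <= f < 1:
            raise ValueError(f"implied {name}={f:.4f} outside [0, 1)")
    n = int(round(duration_s * sample_rate_hz))
    ones = np.ones(n)
    return GasTraces(
        time_s=np.arange(n) / sample_rate_hz,
        fio2_in=fio2_in * ones,
        fio2_out=fio2_out * ones,
        fico2_in=fico2_in * ones,
        fico2_out=fico2_out * ones,
        flow_ml_min=flow_ml_min,
    )


@dataclass(frozen=True)
class CountSimSpec:
    """Dirichlet-multinomial count-table spec with planted fold changes."""

    n_taxa: int = 100
    n_samples_per_group: int = 12
    groups: tuple[str, ...] = STUDY_GROUPS
    base_proportions: tuple[float, ...] | None = None  # default: power-law 1/(i+1)
    dispersion: float = 0.02  # Dirichlet concentration = 1/dispersion
    planted_effects: tuple[tuple[int, str, float], ...] = ()  # (taxon, factor, log2fc)
    library_size_range: tuple[int, int] = (20_000, 50_000)
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.base_proportions is not None:
            p = np.asarray(self.base_proportions, dtype=float)
            if abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("base_proportions must sum to 1")
            if len(p) != self.n_taxa:
                raise ValueError("base_proportions length must equal n_taxa")
            return p
        p = 1.0 / (np.arange(self.n_taxa) + 1.0)
        return p / p.sum()

    def validate(self) -> None:
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        for idx, factor, _ in self.planted_effects:
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"planted taxon index {idx} out of range")
            if not any(factor in g for g in self.groups):
                raise ValueError(f"planted factor {factor!r} matches no group")


def simulate_count_table(spec: CountSimSpec):
    """Generate an overdispersed count table plus the planted-truth table.

    Per sample, a composition is drawn from Dirichlet(p_g / dispersion)
    and counts from a multinomial at a uniform random library size.  A
    planted effect (taxon, factor, log2fc) multiplies the taxon's base
    proportion by 2^log2fc in every group whose label contains ``factor``
    (renormalised).  ``dispersion -> 0`` recovers near-identical
    compositions across samples.
    """
    from .microbiome import CountTable

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = spec.proportions()
    group_props = {}
    for g in spec.groups:
        p = base.copy()
        for idx, factor, lfc in spec.planted_effects:
            if factor in g:
                p[idx] *= 2.0**lfc
        group_props[g] = p / p.sum()

    features = [f"taxon_{i:04d}" for i in range(spec.n_taxa)]
    columns, labels, data = [], [], []
    lo, hi = spec.library_size_range
    for g in spec.groups:
        for j in range(spec.n_samples_per_group):
            sid = f"{g}_s{j:02d}"
            lib = int(rng.integers(lo, hi + 1))
            if spec.dispersion > 0:
                comp = rng.dirichlet(group_props[g] / spec.dispersion)
            else:
                comp = group_props[g]
            data.append(rng.multinomial(lib, comp))
            columns.append(sid)
            labels.append(g)
    counts = pd.DataFrame(np.array(data).T, index=features, columns=columns)
    groups = pd.Series(labels, index=columns, name="group")
    truth = pd.DataFrame(
        [
            {"feature": features[idx], "factor": factor, "log2_fold_change": lfc}
            for idx, factor, lfc in spec.planted_effects
        ],
        columns=["feature", "factor", "log2_fold_change"],
    )
    return CountTable(counts, groups), truth


@dataclass(frozen=True)
class StudyDesign:
    """A 2x2 Sham/CIH x VEH/PREB study with configurable planted effects."""

    n_per_group: int = 12
    trace_duration_s: float = 120.0
    pressure_duration_s: float = 120.0
    body_mass_means: dict = field(default_factory=lambda: dict(BODY_MASS_MEANS))
    body_mass_sd: float = BODY_MASS_SD
    map_offset_cih_mmHg: float = 12.0  # planted diastolic/MAP elevation in CIH
    apnoea_rate_cih_per_hr: float = 24.0
    apnoea_rate_sham_per_hr: float = 12.0
    count_spec: CountSimSpec = CountSimSpec()
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")


@dataclass
class StudyDataset:
    subjects: pd.DataFrame  # subject_id, factor_exposure, factor_diet, group, body_mass_g
    flow: dict
    flow_truth: dict
    pressure: dict
    pressure_rr: dict
    gas: dict
    counts: "object"
    count_truth: pd.DataFrame

    def content_hash(self) -> str:
        """Stable digest of all numeric content (reproducibility check)."""
        h = hashlib.sha256()
        h.update(self.subjects.to_csv().encode())
        for sid in self.subjects["subject_id"]:
            h.update(np.ascontiguousarray(self.flow[sid].samples).tobytes())
            h.update(np.ascontiguousarray(self.pressure[sid].samples).tobytes())
        h.update(np.ascontiguousarray(self.counts.counts.to_numpy()).tobytes())
        return h.hexdigest()


def _child_seed(master: int, index: int) -> int:
    # fixed-offset derivation keeps subjects independent yet reproducible
    return (master * 100_003 + 7_919 * index + 1) % (2**31)


def simulate_study(design: StudyDesign) -> StudyDataset:
    """Bundle per-subject flow/pressure/gas traces and a count table.

    CIH groups receive the planted blood-pressure offset and a higher
    apnoea rate; body masses are drawn around the per-group means.  All
    per-subject streams derive from the master seed by fixed offsets.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    flow, flow_truth, pressure, pressure_rr, gas = {}, {}, {}, {}, {}
    idx = 0
    for g in STUDY_GROUPS:
        exposure, diet = g.split("+")
        for j in range(design.n_per_group):
            sid = f"{g}_r{j:02d}"
            mass = float(rng.normal(design.body_mass_means[g], design.body_mass_sd))
            rate = (
                design.apnoea_rate_cih_per_hr
                if exposure == "CIH"
                else design.apnoea_rate_sham_per_hr
            )
            n_ap = int(round(rate * design.trace_duration_s / 3600.0))
            seed = _child_seed(design.seed, idx)
            srng = np.random.default_rng(seed)
            dur = design.trace_duration_s
            slots = np.linspace(0.15 * dur, 0.85 * dur, max(n_ap, 1))
            apnoeas = tuple(
                ApnoeaSpec(onset_s=float(s + srng.uniform(-2, 2)), duration_ttot=2.5)
                for s in slots[:n_ap]
            )
            fspec = SimProtocol(
                duration_s=dur,
                apnoea_specs=apnoeas,
                sigh_times_s=(0.05 * dur,),
                seed=seed,
                body_mass_g=mass,
                subject_id=sid,
            )
            flow[sid], flow_truth[sid] = simulate_flow_trace(fspec)

            bp_off = design.map_offset_cih_mmHg if exposure == "CIH" else 0.0
            pspec = RRSimSpec(
                duration_s=design.pressure_duration_s,
                band_components=((0.4, 3.0), (1.5, 6.0)),
                sbp_mmHg=120.0 + bp_off,
                dbp_mmHg=80.0 + bp_off,
                seed=_child_seed(design.seed, 10_000 + idx),
                subject_id=sid,
            )
            pressure[sid], pressure_rr[sid] = simulate_pressure_trace(pspec)

            vo2 = float(srng.normal(2.7, 0.3)) * mass / 100.0
            vco2 = float(srng.normal(1.9, 0.2)) * mass / 100.0
            gas[sid] = simulate_gas_traces(vo2, vco2, flow_ml_min=3000.0)
            rows.append(
                {
                    "subject_id": sid,
                    "factor_exposure": exposure,
                    "factor_diet": diet,
                    "group": g,
                    "body_mass_g": mass,
                }
            )
            idx += 1
    cspec = replace(design.count_spec, n_samples_per_group=design.n_per_group,
                    seed=_child_seed(design.seed, 999_983))
    counts, count_truth = simulate_count_table(cspec)
    return StudyDataset(
        subjects=pd.DataFrame(rows),
        flow=flow,
        flow_truth=flow_truth,
        pressure=pressure,
        pressure_rr=pressure_rr,
        gas=gas,
        counts=counts,
        count_truth=count_truth,
    )
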