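# Methods

This note documents the models, conventions and numerical choices behind
`cihpheno`, and what the synthetic-data generator does and does not
emulate.

## Respiratory flow model and breath segmentation

The generator builds each breath from a half-sine inspiration (negative
deflection, the plethysmography plotting convention) and an
exponential-decay expiration (time constant T_e/4), both integrating to
V_T, so every cycle is volume-balanced and the planted V_T is an exact
integral of the waveform. Defaults describe a resting ~300 g adult rat:
f_R 82 brpm, V_T 2.1 ml (0.7 ml/100 g), T_i/T_tot 0.33, flow sampled at
200 Hz, additive white noise at 2% of peak inspiratory flow. Sighs scale a
whole cycle by `sigh_gain` (default 2.5); apnoeas replace breathing with
zero flow (plus noise) for a stated multiple of T_tot, with no amplitude
taper, so ground truth is unambiguous; artifacts are broadband noise bursts
at 3× peak flow. An apnoea marked post-sigh also converts its preceding
breath into a sigh and logs both events. One master seed drives everything;
per-subject streams in the study bundle derive from it by fixed integer
offsets, keeping subjects independent but the dataset bit-reproducible.

Segmentation smooths the flow with a 10 ms moving average and applies a
±2%-of-peak hysteresis: the inspiratory state begins when the smoothed flow
falls below −threshold and ends when it rises above +threshold. Each phase
boundary is then refined to the nearest raw-signal zero crossing, which
removes the smoothing/threshold delay; timing is accurate to about one
sample on clean signals, so sub-percent recovery of T_i/T_e needs sampling
≳500 Hz (f_R and V_T are insensitive to this). A quiet stretch such as an
apnoea can latch the inspiratory state on a noise dip well before the next
real breath; when the final contiguous negative run sits more than 50 ms
past the hysteresis onset, the onset is re-anchored to that run, and
candidate inspirations longer than 1 s are discarded. Cycles with
T_i < 40 ms (or V_T below an optional floor; the event-scoring examples use
0.2 ml ≈ 10% of resting V_T) are treated as sub-threshold efforts and
folded into the neighbouring expiration. T_e runs to the next inspiratory
onset, so expiratory pauses live in T_e until the apnoea criterion takes
over.

## Event scoring

Sigh detection compares each V_T with a centred 50-breath rolling mean
computed in two passes, the second excluding first-pass sighs so large
sighs cannot inflate their own threshold; the comparison is inclusive
("double the average" counts). The apnoea criterion reads "a pause greater
than two consecutive missed breaths" literally: an inter-onset interval
must exceed (1 + miss_multiple) × the local mean cycle with
miss_multiple = 2 — one expected breath plus two missed ones. The local
mean is taken over the preceding 10 unflagged, non-sigh, non-carrier
breaths, tracking slow rate drift without letting events distort their own
criterion; whether the original analyses used >2 or ≥2 missed breaths, and
the exact averaging window for "average V_T", are not published, so both
are parameters. Gaps spanning artifact-flagged breaths are never scored.
Recorded apnoea onset is the end of the expected cycle and duration the
remaining pause, so a planted gap of k×T_tot round-trips to k×T_tot.
Classification is post-sigh when fewer than `post_sigh_lag_breaths`
(default 1) breath onsets separate the last sigh from the pause.

## Pressure waveform and HRV

Beat k has RR_k = mean + Σ aᵢ sin(2π fᵢ t_k) + jitter, evaluated at the
(uneven) beat times, so a planted component of amplitude a carries power
a²/2 in the tachogram. The pulse is a linear systolic upstroke over the
first 30% of the cycle and an exponential diastolic run-off (k = 3)
normalised to end at DBP; the slope breaks at the peak, making the peak
sample unambiguous, and per-cycle max/min equal SBP/DBP by construction.
Defaults: RR 153 ms (HR ≈ 390 bpm), 120/80 mmHg, jitter 2 ms, 1 kHz
sampling — about 50× the highest rodent HF edge and comfortably enough for
beat detection.

Spectral HRV cubic-spline-interpolates the tachogram to 20 Hz, detrends
linearly (slow drift otherwise leaks into VLF), and uses Welch with a Hann
window, ~30 s segments and 50% overlap, giving ≥6 cycles of the 0.2 Hz LF
edge per segment. Band powers are trapezoid integrals of the PSD. Band
edges follow the prevailing rodent conventions (VLF < 0.2, LF 0.2–0.75,
HF 0.75–3 Hz) and are configurable; published rat studies rarely print
their estimator settings, so spectral values are validated by planted-power
recovery (within 15% at these settings), not by matching any specific
printed table. All variability statistics use population (1/n) variances —
the Poincaré ellipse convention; the difference from sample variance is
negligible for n ≥ 100. MAP is the waveform time-average over the cycle,
with DBP + PP/3 available when only beat pressures exist.

## Challenge and metabolic conventions

Two windowing modes reflect two recording preparations: plethysmography
responses are means over the final 5 min of a challenge against the
unweighted mean of the (typically three) baseline epoch means — unweighted
deliberately, so unequal epoch lengths contribute equally — reported as
absolute change; anaesthetised responses are last-1-min means against the
1-min pre-challenge baseline, reported as percent change. Drug responses
bin the post-injection record (3 or 5 s, per drug) and take the bin with
maximum absolute deviation from baseline within a 60 s search window,
keeping the sign, so pressor and depressor peaks fall out of the same rule.
The PBG chemoreflex apnoea is the first post-injection interval exceeding
2× the 30 s-baseline mean cycle; the tachypnoea is the following contiguous
run (≥3 breaths) with T_tot below mean − 2 SD. The tachypnoea boundary is
not defined in the physiology literature we follow, so it is a documented
parameter. Gas exchange assumes steady state with no STPD/BTPS correction:
VO₂ = flow·ΔFiO₂, VCO₂ = flow·ΔFiCO₂, per 100 g; V_I/VCO₂ uses both terms
per 100 g so body mass cancels.

## Compositional analyses

Counts are compositions; all between-sample geometry uses the centred
log-ratio transform with an additive pseudocount of 0.5 (the common
convention; configurable — the upstream tools delegate zero handling
without printing it). Features present in ≤5% of samples are removed
before any analysis; differential testing additionally requires ≥0.5%
relative abundance in at least one sample. PERMANOVA runs on Euclidean
distances between CLR vectors (Aitchison distance) with
pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)) computed from the
squared-distance matrix; the Monte-Carlo p includes the observed statistic,
p = (1+b)/(1+m), which keeps p > 0 and exact under exchangeability, and
small problems are enumerated exhaustively. The differential-abundance
test is a single per-feature test on CLR values — Welch's t when both
groups pass Shapiro–Wilk at 0.05, Mann–Whitney U otherwise — with BH at
FDR 10%; it deliberately omits any Dirichlet Monte-Carlo averaging layer,
and the simplification is backed by simulation: observed FDR stays at or
below the nominal level under the generator's Dirichlet-multinomial model.
Effect size is the difference of group medians over the pooled median
absolute deviation. Simpson is reported as 1 − Σp² (Gini–Simpson); Chao1
is the bias-corrected form S + f₁(f₁−1)/(2(f₂+1)). Module aggregation sums
each step's alternative KOs, takes the median over steps when ≥66% of
steps are non-zero, else 0 — the documented default of the standard
module-aggregation tooling; both rule and threshold are configurable.

## Group statistics

The decision tree is a pure function of the data: parametric (two-way
ANOVA, factors exposure × diet, type-II sums of squares, with unadjusted
pairwise t-tests in the Fisher-LSD style) only when every group passes
Shapiro–Wilk and Levene at 0.05, otherwise Kruskal–Wallis with pairwise
Mann–Whitney U. The four planned comparisons are judged at
α = 0.05/4 = 0.0125. Omnibus gating of the pairwise tests is available
behind `require_omnibus` but off by default, since the Bonferroni
correction already controls the family. Box-plot outlier assessment is
reported as 1.5×IQR flags and never removes data automatically. The
correlation screen is a flat all-against-all Spearman with BH q < 0.1 — a
deliberate non-hierarchical stand-in for hierarchical association testing,
recorded as such in the output metadata.

## What the generator does and does not emulate

It reproduces the *structure* of the study's data — breath trains with
sighs/apnoeas/artifacts, beat series with band-limited oscillatory power,
steady-state gas gradients, overdispersed compositional counts with planted
fold changes, and the 2×2 design with group body masses (368/346/308/263 g)
and a planted CIH pressure offset. It does not model chamber gas-mixing
dynamics, temperature/humidity corrections or barometric V_T calibration
(volumes are taken as instrument-calibrated ml), breath-shape variability
beyond amplitude/timing noise, baroreflex coupling between pressure and RR,
or phylogenetic correlation among taxa. Passing tests therefore demonstrate
that the estimators are correct and calibrated under controlled conditions,
not that they are robust to every artefact of real recordings.

## Problem sizes and determinism

The verification harness uses 10 min traces at 200 Hz (100 seeds) for event
recovery, 300 s pressure records for spectral recovery, 200 replicates ×
999 permutations for PERMANOVA calibration, and 100 simulations of a
100-feature, 12-per-group table for FDR measurement — sizes at which the
Monte-Carlo error of each rate is well below its acceptance band. Every
stochastic step takes an explicit integer seed; identical seeds give
bit-identical outputs.
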