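# cihpheno

Quantitative phenotyping tools for rodent models of sleep-disordered
breathing: breath-by-breath scoring of whole-body plethysmography flow
signals, heart-rate-variability analysis of arterial pressure recordings,
chemoreflex and drug-challenge quantification, metabolic normalisation, and
compositional summary statistics for gut-metagenome count tables — together
with a synthetic-data generator that produces every input with known ground
truth, so the whole pipeline is verifiable at desk scale.

The package is aimed at physiologists analysing chronic-intermittent-hypoxia
(CIH) studies with a 2×2 exposure × diet design (Sham/CIH × vehicle/
prebiotic), but each module stands alone.

## What it computes

**Breathing.** Flow traces (inspiration negative) are segmented at
hysteresis-gated zero crossings into breaths with T_i, T_e, T_tot,
V_T = |∫ flow dt| over inspiration, V_T/T_i and instantaneous f_R.
Epoch summaries normalise volumes per 100 g body mass with
V_I = f_R · V_T. A sigh is an augmented breath with
V_T ≥ 2× the prevailing average; an apnoea is a pause exceeding two
consecutive missed breaths (inter-onset interval > 3× local mean T_tot),
classified post-sigh or spontaneous; the apnoea index is events per hour.
Breath-to-breath variability uses Poincaré axes
SD1 = √(Var(BBₙ − BBₙ₊₁)/2), SD2 = √(Var(BBₙ + BBₙ₊₁)/2).

**Cardiovascular.** Systolic-peak beat detection gives per-beat SBP, DBP,
MAP (waveform time-average) and RR; the HRV suite covers SDRR, CVRR, SD of
rate, RMSSD, SDSD, SD1/SD2, and Welch-spectrum band powers over rodent
bands (VLF < 0.2 Hz, LF 0.2–0.75 Hz, HF 0.75–3 Hz) in ms², %, normalised
units and the LF:HF ratio.

**Challenges & metabolism.** Gas-challenge responses use the final-5-min
mean against the averaged baseline epochs (plethysmography convention) or
the last-1-min mean against the 1-min pre-challenge baseline (anaesthetised
convention); drug responses are peak 3/5-s bins as percent change from the
1-min baseline; the phenylbiguanide chemoreflex is apnoea/tachypnoea
duration in baseline-cycle units. VO₂/VCO₂ come from open-flow inlet-outlet
fraction differences; V_I/VCO₂ is the ventilatory equivalent.

**Microbiome.** Count tables are prevalence-filtered (>5% of samples),
CLR-transformed (pseudocount 0.5), ordinated by PCA in Aitchison geometry,
compared by pairwise PERMANOVA (permutation p with the +1 correction, exact
enumeration on small problems), tested feature-wise in CLR space with
Benjamini–Hochberg FDR at 10%, and aggregated from KEGG orthologues into
functional modules by the median-of-steps rule at 2/3 step coverage.
Alpha diversity: bias-corrected Chao1, Shannon (nats), Gini–Simpson.

**Statistics harness.** Shapiro–Wilk/Levene-gated choice between two-way
ANOVA + pairwise t-tests and Kruskal–Wallis + Mann–Whitney U; four planned
comparisons at the Bonferroni-adjusted α = 0.05/4 = 0.0125; a flat
all-against-all Spearman screen with BH q < 0.1.

## Worked example

`examples/01_breath_scoring.py` simulates a 10 min resting recording with
three planted sighs and three apnoeas, then scores it:

```
breaths scored:       812
f_R:                  81.8 breaths/min
V_T:                  0.70 ml/100 g
V_I:                  57.6 ml/min/100 g
T_i / T_e:            238 / 501 ms
apnoea index:         18 events/hr (post-sigh 6, spontaneous 12)
sigh frequency:       24 events/hr, mean amplitude 1.75 ml/100 g
T_tot Poincare SD1/SD2: 6.7 / 3.9 ms
```

All three planted apnoeas (3 events / (1/6 hr) = 18/hr) and sighs
(18 + the post-sigh companion = 24/hr) are recovered, at the resting scale
of an adult rat (f_R ≈ 82 brpm, V_T ≈ 0.7 ml/100 g). The other examples
(`02_hrv.py` … `05_group_stats.py`) walk through the HRV suite, challenge
windowing, the compositional chain and the group-statistics harness in the
same style.

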