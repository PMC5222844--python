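# Methods

This note documents the models and procedures implemented in `atonia`, the
defaults that matter, the numerical choices, and what the synthetic cohort
can and cannot establish.

## Signals and epoching

A recording is ≥1 EEG channel plus exactly one neck-EMG channel in µV at a
nominal 250 Hz (hardware band limits in the motivating acquisition setup:
EEG 0.1–100 Hz, EMG 50–90 Hz). Sessions nominally run 23 h starting at
lights-on, with the light→dark transition (`lights_off_at`, seconds) given
per recording; epochs before it belong to the inactive (rest) period of the
nocturnal animal. Analysis operates on non-overlapping 4-s epochs
(half-open `[t, t+4)`, 0-based indices); a 23-h session yields exactly
20 700 epochs, trailing remainder samples are discarded.

EEG is downsampled 250→125 Hz for analysis: a 129-tap Hamming-window FIR
low-pass (cutoff 55 Hz) applied forward-backward (zero phase, so epoch
boundaries do not shift), then every 2nd sample. Content above the new
Nyquist (62.5 Hz) is suppressed by >40 dB; band power in 0.5–30 Hz is
preserved within 2%. Odd-length inputs drop the final sample.

Signals are stored as EDF (the polysomnography standard; a plain CSV
fallback exists for testing). Reading goes through `mne`; writing uses a
minimal 16-bit EDF writer with 1-s records and per-channel symmetric
physical ranges, so samples round-trip within one quantization step of the
digital range. Which physical EEG electrode is analyzed is a config key
(`staging.eeg_channel`, default 0): multi-electrode montages differ between
labs and the analysis uses a single frontal derivation.

## Welch spectra and bands

Each 500-sample epoch gives a one-sided Welch PSD with 2-s Hamming
segments at 50% overlap (three segments), forcing exactly 0.5 Hz bins over
0–62.5 Hz — the resolution at which murine sleep spectra are conventionally
reported. Segment detrending is per-segment constant removal, so the
integral of the PSD approximates the epoch variance (Parseval within 5% for
smooth signals; verified on sinusoids).

Band powers are trapezoidal integrals of the density; because the grid is
shared, integrals over adjacent bands are exactly additive. Default murine
band edges: δ 0.5–5, θ 5–9, α 9–12, μ 12–16, β 16–30 Hz; SWA is fixed at
0.5–5 Hz during NREMS. Murine and human band conventions differ; all edges
are config keys. The edges were chosen so that the 8–10 Hz range of
interest for REMS spans the upper θ and lower α band.

Group spectra average per-epoch PSDs within animal first, then across
animals (SEM across animals); pooling epochs across animals would let
long-sleeping animals dominate. Artifact-flagged epochs are excluded from
every spectral average.

## Staging

Two-step epoch classifier:

1. **EMG step.** Per-epoch EMG activity = RMS of the mean-subtracted raw
   epoch. Epochs with activity above `emg_wake_threshold` are WAKE per se.
2. **EEG step.** Remaining epochs are REMS when the θ/δ power ratio of the
   125 Hz EEG epoch exceeds `theta_delta_threshold` (default 1.5), else
   NREMS.

Thresholds are calibrated per recording to absorb inter-animal gain
differences: `emg_wake_threshold = factor × percentile(emg_rms)` with
factor 2.5 and reference percentile 25. The reference quantile must sit in
the low-tone (sleep) EMG cluster for every animal; sleep occupies well over
a quarter of any session, so the 25th percentile is safe, whereas a median
reference fails for animals that are awake more than half the time (the
threshold then exceeds every epoch and WAKE is never scored). Band powers
may optionally be normalized by total power (`relative_power`, default
off).

Epochs whose peak-to-peak amplitude exceeds `artifact_amplitude_uV`
(default 750 µV) or that contain NaN samples are flagged ARTIFACT and their
state imputed from the nearest preceding scored epoch; artifacts are
excluded from proportions and spectra.

**Minimum-bout rule.** A vigilance change must last at least 3 epochs
(12 s) to count as a state change. Shorter runs are relabeled to the
preceding accepted state — left-attachment keeps the rule causal and
order-independent — and annotated MICRO_AROUSAL when the short run was WAKE
inside sleep, TRANSIENT otherwise. The session's first run is exempt (no
preceding state). The operation is idempotent and matches an independent
run-merging oracle in the tests. Manual epoch-level rescoring by a human
scorer is replaced by an optional override CSV applied after staging.

## REM-A detection

REM-A: REMS epochs with concurrent neck-EMG activity. Two routes:

- **Direct.** REMS epochs with EMG RMS above the atonia threshold are
  flagged REM_A (state stays REMS).
- **Flanked-WAKE rescoring.** EMG-first staging necessarily labels
  strong-burst REM-A as WAKE. A WAKE run of ≤3 epochs is rescored to
  REMS+REM_A iff the 3 epochs on each side are REMS with EMG at or below
  the atonia threshold and every epoch in the run has a θ/δ ratio above the
  REMS threshold — the automated operationalization of "EEG unmistakably
  different from WAKE EEG" (a stricter mode additionally requires total
  power within the session's REMS range). Longer WAKE runs are genuine
  awakenings. The two routes commute.

The atonia threshold is `factor × percentile(REMS EMG RMS) + margin`, never
below a floor, with defaults factor 2.5 and percentile 5. Anchoring on a
*low* percentile estimates the atonic floor and stays valid however much of
REMS carries muscle activity; a high-percentile anchor (e.g. the 95th)
breaks down as soon as REM-A is prevalent, because that quantile then lies
inside the REM-A cluster itself. With fewer than 10 REMS epochs the
threshold cannot be calibrated and the configured floor is used.

Epochs recovered by rescoring count toward both the REM-A numerator and
the REMS denominator (they are REMS by final label); the summary reports
percent of total REMS, and a hypnogram with no REMS at all has an
*undefined* proportion (an error), not 0%.

## Sleep architecture

Bouts are maximal runs of equal state; a bout (or transition) belongs to
the period containing its first epoch, and bouts spanning the light/dark
boundary are not split. State proportions are percentages of scored
(non-artifact) epochs per time bin (default 2 h); partial final bins use
the epochs they have. Transitions count the five behaviorally possible
changes (W→N, N→W, N→R, R→W, R→N); W→R is tallied separately as an anomaly
and excluded from the five-way normalization — both counts and normalized
probabilities are reported since conventions differ. REMS latency is the
number of epochs from a reference time (typically lights-off) to the first
*coherent* REMS bout, where coherent reuses the staging persistence
constant (≥3 epochs); no separate constant is introduced.

## Statistics

**AUC.** `A = P(y > x) + ½P(y = x)` over all between-group pairs, computed
by exact pair counting and folded to (0.5–1) so only magnitude is reported;
folding operates on the pair counts so the result is the exactly rounded
rational. Effect classes: none ≤ 0.64 < medium ≤ 0.71 < strong (strict
inequalities at the cuts). The 95% CI is a percentile bootstrap (default
10 000 replicates, seedable) resampling animals within each group — the
animal, not the epoch, is the exchangeable unit — with each replicate
folded; the interval is widened if needed to contain the point estimate.
Folding makes the interval conservative near A = 0.5.

**Youden.** Candidates are midpoints of consecutive sorted unique values;
J = sensitivity + specificity − 1 is maximized with ties broken toward
higher specificity, then the lower threshold. Positives are the class
expected to take higher values.

**Kolmogorov–Smirnov.** Sup-norm ECDF distance via scipy, asymptotic
p-value by default ('exact'/'auto' selectable — advisable below n ≈ 10),
Bonferroni-corrected by the family size `m` passed explicitly by the
caller; which comparisons form a family is a reporting decision, so it is
never inferred. At n = 30 per group the asymptotic test holds its nominal
5% size (measured rejection ≈ 0.035–0.045 under the null).

**Mixed ANOVA.** Classical univariate partition for a balanced design with
one between-subject factor (group) and one within-subject factor (time
bin): group is tested against the between-subject error, time and
group×time against the within-subject error. Implemented directly from the
partitioned sums of squares (exposed in the result for auditability) and
cross-checked against pingouin in the tests. No sphericity correction by
default, matching common practice in this literature; Greenhouse–Geisser
is a toggle and is noted in the result object. Missing cells are an error —
no imputation. Post-hoc per-bin two-sample t-tests are Bonferroni-corrected
across bins (× pairs when more than two groups).

## Synthetic cohort

The generator exists so every pipeline stage is testable with known ground
truth; its defaults encode the study conditions.

**States.** A discrete-time Markov chain on {W, N, R} at epoch resolution,
separate matrices per period, W→R structurally zero. Stay probabilities
were set from typical C57BL/6 sleep structure (WAKE bouts of minutes in
the dark phase, NREMS bouts ~1–2 min, REMS bouts ~40–80 s, sleep-dominated
light phase): inactive-period dwell means ≈ 12/20/10 epochs for W/N/R,
active ≈ 25/12/8, giving occupancies of roughly 30/55/15% (inactive) and
60/33/7% (active). Bout lengths are geometric by construction — adequate
for exercising the CDF/KS machinery, not a claim about real bout-length
tails (a heavy-tailed variant would need a semi-Markov chain; see
limitations). Chains start from the inactive-period stationary
distribution, and long-run occupancy matches the analytic stationary
distribution of the matrix.

**Phenotypes.** Four groups, default sizes 8 (control young), 6 (control
adult), 8 (MSA young), 10 (MSA adult) — the analyzed study design.
Configurable effects, defaults chosen once to mirror the reported
phenotype directions at clearly recoverable size:
young MSA — NREMS→REMS entry in the inactive period ×1.8, broadband EEG
gain ×1.3, REMS θ peak shifted +1.5 Hz (to ~8–9 Hz), SWA fast-δ mixture
weight 0.65 vs 0.35; adult control — slightly more active-period NREMS;
REM-A per-epoch probability 0.03 / 0.02 / 0.10 / 0.45 for control-young /
control-adult / MSA-young / MSA-adult (age-dependent, highest in adult
MSA).

**Signals.** Per epoch, EEG = 1/f-shaped noise (state-specific exponent
and RMS) plus a state oscillation: δ waves in NREMS (frequency drawn from
a 1–2 Hz / 3–5 Hz mixture — the mixture weight implements the SWA
redistribution), ~7 Hz θ in REMS, low-amplitude mixed activity in WAKE.
EMG = white noise band-passed 50–90 Hz (8th-order Butterworth, zero-phase,
gain-corrected) at per-state RMS tones 30/8/2 µV for W/N/R. REM-A is
injected as contiguous 1–3-epoch bursts with start probability
`p/(2−p)` per REMS epoch so the expected flagged fraction is `p_rema`;
burst EMG is 15 µV — phasic twitching between the NREM and WAKE tones —
with a 5% fraction of bursts at the full WAKE tone (30 µV) that staging
initially scores WAKE, exercising the flanked-rescoring route. Determinism:
per-animal RNG streams are spawned from the master seed by counter.

**What passing tests show — and don't.** The cohort demonstrates that the
pipeline recovers states, REM-A rates and injected group effects under
controlled conditions (staging agreement ≈ 98–99%, REM-A rates within a
few points across p = 0.05–0.6). It does not establish performance on real
recordings: real EEG has non-stationary 1/f structure, spindles, movement
and electrode artifacts, state transitions that are gradual rather than
epoch-aligned, and heavy-tailed bout lengths. WAKE-level REM-A bursts at
the very start or end of a REMS bout lack the required atonic flank and
stay WAKE — a small systematic undercount that mirrors the conservatism of
the manual rescoring rule; such epochs can also leave isolated W→R
boundaries in staged (never in ground-truth) hypnograms.

## Defaults for testing scale

Test and example cohorts use 2-h sessions (1800 epochs, lights-off at
mid-session) with 15-min proportion bins — the same geometry as the full
23-h/2-h-bin analysis at ~¹⁄₁₂ the data volume; full-length sessions are a
config change (`session_length: 82800`, `lights_off_at: 43200`).

## Known limitations

- The staging classifier is a faithful two-step implementation, not a
  reimplementation of any published semi-automatic scorer's internals;
  agreement figures refer to the synthetic cohort.
- Geometric bout lengths; no spindle/sub-stage structure in NREMS (murine
  NREMS substaging is not established practice).
- The AUC bootstrap resamples animals only; hierarchical (animal + epoch)
  uncertainty is not propagated.
- EDF writing quantizes to 16 bits over the per-channel observed range;
  recordings with extreme outliers lose amplitude resolution.
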