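# Methods

This note documents the generative model behind the synthetic cohorts,
the analysis conventions, the numerical choices made where the design
was genuinely open, and the limits of what the synthetic validation can
show about real recordings.

## Generative model of a trial

A trial lasts 14 s (2 s pre-roll + 12 s of pacing movie) at a default
250 Hz sampling rate, on a 30-channel 10–10 montage.  With t = 0 at the
first beat onset, channel c of a subject with gain g records

x_c(t) = g · A_im · w_im,c · Σ_h h^(−γ) sin(2π h f₀ t + φ_im)
       + g · A_vis · w_vis,c · sin(2π f_beat t + φ_vis)
       + n_c(t)

* **Imagery SSEP.**  f₀ is the condition's meter fundamental
  (f_beat / meter period: 2.4, 1.2 or 0.8 Hz), with harmonics h f₀ up to
  a 5 Hz cutoff and amplitudes decaying as h^(−γ), γ = 1 by default —
  the textbook SSEP behaviour of harmonic amplitude falling with
  harmonic number.  Marker viewing has no imagery term.
* **Imagery topography** w_im is 1 on all channels plus a
  `frontal_emphasis` (default 1.0) on the prefrontal/frontal row
  (Fp1…Fz).  A perfectly uniform topography would be annihilated exactly
  by the common-average reference, so some spatial contrast is a
  structural necessity; the frontal choice mirrors the widespread,
  frontally accented topography reported for imagery SSEPs.  Setting
  `frontal_emphasis = 0` recovers the uniform reading.
* **Visual response.**  A sinusoid at the beat rate (2.4 Hz exactly;
  the movie's "416 ms" inter-onset interval is a display rounding of
  416.67 ms, and the exact rate keeps every component bin-centred on the
  0.1 Hz grid).  Channel weights are chosen so that the occipital share
  of visual energy equals `occipital_concentration` (default 0.6) with
  mean-square weight 1.
* **Background.**  Independent per-channel 1/f^β noise (β = 1) made by
  spectral shaping of white Gaussian noise, scaled to
  `noise_amplitude` = 10 µV RMS per channel.
* **Variability.**  Per-subject log-normal gain (sd of log = 0.3,
  median 1) applied to both signal components; per-trial phase offsets
  φ_im, φ_vis ~ N(0, 0.2² rad) drawn independently — imagery cannot be
  perfectly phase-locked, and 0.2 rad preserves most of the
  time-domain averaging gain (cos-factor e^(−σ²/2) ≈ 0.98).

Amplitude defaults (imagery fundamental 3.5 µV, visual 1.5 µV) are a
calibration, not a measurement: no established µV scale exists for
imagery SSEPs, so the defaults were chosen once to place
single-trial classification between chance and ceiling (per-subject
three-class accuracies ≈ 0.5–0.9) and then frozen.  Only the
signal-to-noise ratios matter; the absolute scale is conventional.

Reproducibility: every trial has an RNG stream keyed by
(seed, subject, condition, trial), so a cohort is bit-identical across
runs and a partial simulation (e.g. a single condition) reproduces
exactly the trials it shares with the full one.

## Preprocessing

Re-reference to the common average, zero-phase (forward–backward)
third-order Butterworth band-pass 0.5–15 Hz, epoch of 10 s from beat
onset, four 2.5 s subepochs averaged.  Filtering is applied to the full
14 s recording *before* epoching so the pre-roll absorbs edge
transients; a causal-filter mode exists for latency-faithful uses.
Whether the original pipeline filtered before or after epoching is not
documented; the difference is confined to edge effects.  Every target
frequency completes an integer number of cycles in 2.5 s, so subepoch
averaging preserves the phase-locked components while attenuating
non-locked background by ≈ √4 in RMS (slightly less for 1/f noise,
whose low-frequency content is partly coherent across subepochs).
Artifact screening is an automated peak-to-peak threshold standing in
for visual inspection; it is disabled for synthetic cohorts (the
generator is bounded) and ~200 µV is suggested for imported data.

## Spectral analysis

Amplitudes are normalised as 2|X_k|/N with N the pre-padding sample
count, so a bin-centred unit sinusoid reads 1 µV.  The noise-subtracted
amplitude Φ subtracts the mean of the four neighbours at ±Δf and ±2Δf
(the symmetric reading of the subtraction formula; the offsets are
configurable, so an asymmetric neighbour set is a one-line change).
Edge bins where a neighbour leaves the grid are NaN, not errors.

**Spectrum source.**  A 2.5 s waveform has a native 0.4 Hz resolution;
a 0.1 Hz analysis grid admits two readings, both implemented:

* `spectral.source = "averaged"` zero-pads the subepoch-averaged
  waveform to 10 s.  Padding widens each tone's mainlobe to 0.8 Hz, so
  the ±0.1/±0.2 Hz neighbours sit *inside* the mainlobe: the
  subtraction then cancels ~77 % of a true peak and deterministic
  sidelobe interference can displace the local maximum (measured on
  noiseless trials: ternary maximum at 0.7 Hz, binary at 0.6 Hz).
* `spectral.source = "full_epoch"` (the default) transforms the
  trial-averaged 10 s epoch on its native 0.1 Hz grid.  Rhythm
  components are bin-centred with no leakage into the neighbour bins,
  Φ at a component keeps its full amplitude, and the group-mean peak
  falls on the condition's fundamental.  This is the only reading under
  which the 0.1 Hz grid and clean narrow-band peaks coexist,
  and it is what the downstream statistics assume.

Target lookups use the nearest bin with a Δf/10 alignment tolerance;
with the exact-2.4 Hz design all targets are bin-centred.  No window or
taper is applied: averaging already enforces periodicity at the target
frequencies, and a taper would reintroduce leakage into the neighbour
bins.

**Known floor bias.**  Near the 0.5 Hz high-pass edge the noise floor
curves upward with frequency, so Φ at 0.8 Hz carries a small positive
bias (~0.02 µV at default noise) that is *identical in sign across
synthetic subjects*; the scale-free sign-rank test can therefore flag
noise-only 0.8 Hz bins as significant in conditions with no 0.8 Hz
component.  In real cohorts, between-subject floor heterogeneity masks
this.  Paired contrasts (imagery vs marker viewing) cancel the bias,
and the type-I behaviour of those contrasts is verified by Monte-Carlo.

## Group statistics

Wilcoxon signed-rank: zeros dropped before ranking, midranks for ties,
exact p for n ≤ 25 tie-free samples (the study size n = 9 demands the
exact floor of 1/512), normal approximation otherwise.  The reported
statistic is always the tie-corrected normal-approximation z alongside
the exact p, because conventional software reports that pair.  Friedman:
midrank chi-square with tie correction, referred to χ²(k−1) by default
(matching conventionally reported chi-square/p pairs); an exact
enumeration mode over within-row rank permutations exists for small
instances and for k = 2, where the test reduces to a sign-test
analogue.  Holm adjustment is applied within each frequency's three
pairwise comparisons.  Pairwise tests run only where the Friedman gate
(p < 0.10) opens, with a config override.  The significance ladder
0.10 / 0.05 / 0.01 is reported as marks (+ / * / **).

## Single-trial classification

CCA is solved in the sample space: orthonormal bases of the centred
signal and reference subspaces via economy SVD with a relative
singular-value cutoff of 1e-10, then ρ = cosine of the smallest
principal angle.  Rank truncation (rather than ridge regularisation)
keeps ρ exact for rank-deficient inputs — common-average-referenced
data span 29 of 30 dimensions — makes the single-channel case agree
with the √R² regression identity to machine precision, and leaves ρ
invariant under invertible channel mixing.

Features default to the 2.5 s subepoch-averaged waveform
(`classifier.representation = "averaged"`; the 10 s epoch is a switch).
Within each leave-one-out training fold the four features are
standardised before a linear SVM (C = 1), pairwise machines voting
one-against-one with the lowest class label winning ties.
Standardisation is necessary, not cosmetic: against 1/f EEG the
canonical correlations of a 30-channel trial cluster tightly (≈ 0.9 ±
0.02), and an unscaled fixed-C margin at that scale is
regularisation-dominated — it degenerates to majority voting, which
leave-one-out turns into systematic *anti*-learning (0 % accuracy even
with clearly separated class means).  Classification is always within
subject; accuracies are never pooled across subjects before reporting.

A related caveat: under the null (no class information), cross-validated
accuracy is biased at or *below* chance, because each left-out trial
opposes its own class's training majority.  Chance-level controls are
therefore checked one-sided against the upper edge of the binomial
band; a null accuracy below chance indicates estimator pessimism, not
information.

## What the synthetic validation does and does not show

The generator reproduces the *spectral logic* of the paradigm —
frequencies, harmonics, topographic contrasts, trial/subject
variability structure — so passing tests demonstrate that the pipeline
recovers designed rhythm structure at realistic SNR, honours its exact
statistical contracts, and is deterministic end to end.  It does not
emulate non-sinusoidal SSEP waveshape, spatially correlated background
(volume conduction) — the independent-channel noise here is the *worst*
case for CCA — ocular or movement artifacts, non-stationary drift, or
attentional lapses.  Absolute accuracies and amplitudes on real data
will differ; the synthetic results validate machinery, not physiology.

## Problem sizes and budgets

Default analyses use the full design (9 × 4 × 20 trials, 250 Hz).  The
seed-sweep recovery check uses 20 independent cohorts of the three
imagery conditions; Monte-Carlo checks (noise slope, type-I rates,
variance ratios) use a handful of seeds each — sizes chosen to keep the
whole suite in the minutes range on a single core while leaving the
statistical margins comfortable.

## Out of scope

EDF export (no writer dependency; import is available via mne as an
optional extra), movie rendering, ICA/ocular regression, bad-channel
interpolation, scalp-map graphics, hyperparameter search, cross-subject
transfer.
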