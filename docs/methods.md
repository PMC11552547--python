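# Methods

This note documents the models, estimators, and design decisions behind
`lfpdisc`: what is computed, under what assumptions, and what the synthetic
validation does and does not establish.

## Task structure and data model

The package analyzes a cued orientation-change detection task.  Two
counterphasing Gabor stimuli (10 Hz counterphase, hence a 20 Hz steady-state
visually evoked potential, SSVEP) are shown, one per hemifield; at an
exponentially distributed latency (mean 3000 ms, truncated to 500–5500 ms)
one stimulus changes orientation and the subject must saccade to it.  LFP
(2 kHz) and spike times are recorded from arrays in both hemispheres;
each electrode's receptive field (RF) lies in the contralateral hemifield,
so every trial is attend-in for one array and attend-out for the other.

Analysis conditions are the cross of cue type (valid / neutral; invalid-cue,
instruction, and catch trials are excluded), side relative to the RF, and
outcome: AIVH, AOVH, AIVM, AOVM, TINH, TONH, TINM, TONM.  Only trials with
the second or third smallest orientation-change magnitude are analyzed
(performance near 50%, balancing hits and misses), and a cue type of a
session is used only when all four of its conditions have **more than 10**
trials (strict `> 10`).  All measures use the half-open pretarget window
[−500, 0) ms, exactly 1000 samples; spike times are stored relative to
target onset so windowing and peristimulus histograms share one origin.

## Spectral estimators

* **Multitaper.**  K = 2·TW − 1 orthonormal discrete prolate spheroidal
  (Slepian) tapers; per-taper FFT of the 500 ms window gives power (squared
  magnitude) and phase on a 0–200 Hz grid with exactly 2 Hz resolution (no
  zero padding).  TW = 3 (5 tapers) is the default for mean power spectra;
  TW = 5 (9 tapers) supplies the nine single-trial estimates.
* **Binned.**  Ten nonoverlapping 50 ms segments, untapered FFT each:
  10 estimates on a 20 Hz grid (the reciprocal of the segment length).
  Spike counts per 50 ms bin give rates in Hz.
* **Hilbert filterbank.**  4th-order Butterworth band-pass, center ± 5 Hz,
  centers 6–200 Hz in 2 Hz steps; the analytic signal gives instantaneous
  power (squared amplitude) and phase at all 1000 samples.  Filtering is
  zero-phase (forward–backward), so instantaneous phase carries no filter
  delay; this is the package's choice where a phase convention had to be
  fixed.

Power is scaled so that the one-sided spectrum sums to the signal variance
over the full grid, for any window — this puts the binned and multitaper
estimators on a common scale (they agree within ~10% for stationary
signals).  Every downstream quantity is a ratio, dB difference, correlation,
or d′, so the absolute scale is immaterial.  DC and Nyquist bins never enter
band averages (phase is undefined at DC).  Line noise is not notch-filtered;
60 Hz is handled by band exclusion (below).

## Measures

**Trial-averaged:** PSTH (10 ms bins), ERP (pointwise trial mean), firing
rate; Pearson correlation of rates or band powers across trials per
electrode pair; across-trial LFP–LFP PPC of the taper-averaged phase
difference; and a single-electrode PPC that applies the same estimator to
one electrode's absolute phase (high only where phase is stimulus-locked,
i.e. at the SSVEP).

The PPC primitive is the unbiased estimator of the squared phase-locking
value, `(R² − N)/(N(N−1))`, identical to the mean cosine of all pairwise
phase differences; its null expectation is 0 and its range `[−1/(N−1), 1]`.
Both algebraic forms are implemented and cross-checked.  Per-taper phase
differences are reduced by the *circular* mean (argument of the mean unit
vector): an arithmetic mean of angles is wrong under wrap-around.

**Single-trial:** per trial and frequency, the correlation or PPC across the
estimator's within-trial units — 10 bins, 9 tapers, or 1000 timepoints.
Shuffle correction (subtracting each trial's mean correlation with all
nonsimultaneous trials *of the same condition*) applies to binned and
Hilbert **correlations only**: the taper estimates coexist within one
window, so no nonsimultaneous analog exists, and PPC is never shuffle
corrected.  Correcting within condition is deliberate — cross-condition
shuffling would inject condition mean differences into the correction term.
For spikes only the binned method is defined.  The Hilbert method's 1000
timepoints are heavily autocorrelated (the filter's impulse response spans
many samples), which inflates its absolute PPC level; only condition
*differences* of Hilbert-based measures are meaningful, and tests treat them
that way.

Electrode pairs are restricted to the same array (same hemisphere): pairs
spanning hemispheres have opposite attention labels and no shared RF.

## Onset matching

Because early targets are missed disproportionately and the pretarget
window of an early-target trial overlaps the stimulus-onset transient,
unmatched hit-vs-miss comparisons confound outcome with onset time,
inflating low-frequency (≲ 8 Hz) differences.  Matching sorts hit and miss
trials into 250 ms onset bins (edges 500:250:5500, left-closed, onset
5500 ms in the last bin) and subsamples the larger group per bin without
replacement; the matched per-bin histograms are exactly equal.  The whole
measure computation is repeated over 50 independent matchings (a master
seed spawns per-iteration generators) and averaged per electrode/pair
*before* any population summary.

## Discriminability and statistics

Band definitions: alpha 8–12, SSVEP 18–22, gamma 40–80, high-gamma
120–200 Hz.  On 2 Hz grids the gamma and high-gamma supports exclude
multiples of 20 Hz (SSVEP harmonics), leaving 42–78 Hz (18 frequencies) and
122–198 Hz (36 frequencies); on the 20 Hz binned grid only 60 Hz is
excluded (gamma support {40, 80}), since excluding all multiples of 20
would empty the bands, and alpha has no binned support at all.  Band
averaging of linear power **precedes** d′ — averaging suppresses the
across-frequency-independent variability of the spectral estimator, which
is why band d′ exceeds the average of per-frequency d′.  PPC is averaged
over the band's per-frequency values; correlations are computed on
band-averaged power.  Phase enters d′ through its sine (cosine available
as an option) to linearize the circular variable.

d′ uses the pooled unbiased standard deviation (robust to unequal group
sizes); groups with fewer than two finite values or zero pooled variance
yield a missing value that is excluded (and logged).  d′ is computed per
electrode or pair, averaged across matching iterations, then summarized
(mean ± SEM) across units — never on trials pooled across electrodes.
Contrast orientation is fixed (group 1 = attend-in/target-in or hit).  The
Gaussian-classes mapping AUC = 0.5 + erf(d′/2)/2 gives 0.528, 0.556, 0.584
at d′ = 0.1, 0.2, 0.3; note 0.52/0.55 sometimes quoted for the first two
are truncations, and the implementation follows the formula.

Significance: Wilcoxon signed-rank against zero (paired per-unit values)
and rank-sum between unit sets, exact p-values for n ≤ 25 and the normal
approximation above; |d′| comparisons sign-flip negative values first.
Families are corrected per summary-panel analog (one family per cue type ×
contrast) with Bonferroni, Benjamini–Hochberg, or Benjamini–Yekutieli
(default, valid under unknown dependency).  The exact grouping of
comparisons into families is configurable since it is a reporting choice.

## Synthetic sessions and ground truth

Each trial's LFP per electrode is a sum of: 1/f ("pink") noise (spectral
shaping with random phases; private per electrode); an SSVEP sinusoid at
20 Hz with von Mises phase jitter (κ = 20, so across-trial phase locking is
high but below 1); and band-limited Gaussian noise ("bursty", not
sinusoidal) in alpha, gamma, and high-gamma.  Each oscillatory band is a
mix `sf·common + (1−sf)·private` of array-wide and electrode-private
sources, renormalized to unit variance, so `shared_fraction` (sf) controls
pairwise correlation and PPC monotonically: the expected correlation is
sf²/(sf² + (1−sf)²), i.e. 0 at sf = 0 and 1 at sf = 1.  The SSVEP is
generated target-locked: in the task, changes occur at stimulus contrast
zero-crossings, i.e. on the 50 ms SSVEP cycle grid, so the target-locked
window preserves SSVEP phase; the generator encodes that invariance
directly.

Condition effects are multiplicative amplitude gains, so ground-truth power
effects are squared gains, available in closed form.  Defaults (chosen once
as plausible cortical effect magnitudes: attention raises gamma/high-gamma
power by ~70% (1.3² − 1) and rates by 20%, misses carry ~2× alpha power,
hits ~1.6× SSVEP power):

| parameter | default | role |
|---|---|---|
| `base_rate_hz` | 50 | Poisson rate; 20 Hz modulation depth 0.5 |
| `rate_gain_attend_in` | 1.2 | attention effect on rate |
| `gamma/high_gamma_gain_attend_in` | 1.3 | attention effect on 40–80 / 120–200 Hz |
| `alpha_gain_attend_in` | 0.85 | attentional alpha suppression |
| `alpha_gain_miss` | 1.4 | behavioral effect (more alpha on misses) |
| `ssvep_gain_hit` | 1.25 | behavioral effect (stronger SSVEP on hits) |
| `shared_fraction` | 0.5 | across-electrode coupling per band |
| `early_miss_bias` | 0.3 | extra P(miss) for onsets < 750 ms |
| `transient_amp_uv`, `transient_decay_ms` | 50, 200 | stimulus-onset transient |

The onset confound is built in: targets draw from the truncated exponential
(inverse-CDF sampling, distributionally identical to rejection but with
bounded cost), outcomes are re-drawn with the early-miss bias
(P(miss) = 1 − base_hit_p + bias·1[onset < 750 ms], clamped), and the
transient `A·exp(−t/τ)` is added wherever the pretarget window overlaps the
first few hundred ms after stimulus onset.  The bias value 0.3 is a free
demonstration choice; the miss-rate dependence on onset is qualitative in
the source data.  Spikes are inhomogeneous Poisson (thinning) with a
20 Hz-modulated rate and a per-trial rate fluctuation shared across
electrodes in proportion to `shared_fraction`, inducing spike-count
correlations.

What the generator does **not** emulate: biophysical dynamics, eye
movements/microsaccades, gamma bursts with realistic duration statistics,
cross-frequency coupling, nonstationarity within the window beyond the
onset transient, electrode-distance-dependent coupling, and invalid-cue
trials.  Passing tests therefore establish that the *estimators and
pipeline* recover known effects of this statistical form — not that real
V4 data has those effects.  Synthetic effect gains also produce d′ values
around 1–2.5, far above the ~0.3 typical of cortical recordings, because
the generator lacks most real noise sources.

## Validation design and problem sizes

The test suite validates each operation against independent oracles (brute
force pairwise sums, closed forms, Monte-Carlo nulls, hand-enumerated
examples) and the pipeline against the generator's ground truth.  The
end-to-end checks use deliberately small sessions (2–3 electrodes per side,
16–25 trials per condition, 8–10 matching iterations, 8–20 seeds) so the
whole suite runs in a few minutes on one core; the recovered patterns are
insensitive to these sizes.  Three full-pipeline properties are checked:

1. **Null calibration** — with all gains at 1 and no confound, no
   comparison survives BY FDR in ≥ 95% of seeds.
2. **Dissociation recovery** — with the default gains, attention |d′| is
   maximal in gamma/high-gamma power and behavioral |d′| in alpha/SSVEP
   power, on 20-seed averages, and grows monotonically along a 3-point
   gain grid with the sign the contrast orientation dictates.
3. **Confound removal** — with the onset confound present but no true
   behavioral LFP effect, the population-mean hit-vs-miss d′ of ≤ 8 Hz
   power after matching is well under half its unmatched value.  The
   matched-vs-unmatched comparison uses the signed d′ averaged across
   electrodes, condition pairs, and seeds: the confound has a consistent
   sign, and population averaging separates it from small-sample |d′|
   noise, mirroring how the analysis averages across electrodes.

## Known limitations

* The Hilbert estimator is excluded from the default d′ summary (its
  bin/taper counterparts cover the same contrasts; the filter-induced
  autocorrelation makes its absolute levels hard to interpret).  It remains
  available through the single-trial API.
* Whether the original analyses used zero-phase filtering for the Hilbert
  method, or padding for 50 ms bins, is not documented; this implementation
  fixes zero-phase and no padding, and records both as conventions.
* Matching is performed per session and cue type; with very disjoint
  hit/miss onset distributions the matched sets can become small, and units
  whose d′ is undefined in an iteration are excluded and logged rather than
  imputed.
* RF side is taken from electrode hemisphere metadata; electrodes with
  ambiguous RF lateralization are not modeled (the generator avoids them by
  construction).
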