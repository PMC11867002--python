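# Methods

`cycdbs` analyzes cortical beta-band after-effects of *cyclic* deep brain
stimulation (DBS): stimulation delivered in repeated trains (5 s ON, 3 s
OFF) at beta-range frequencies (10–30 Hz) through a unilateral (left)
electrode, while cortical activity is recorded with a bilateral sensor
array.  The analysis asks three questions:

1. Does cortical beta power over the stimulated hemisphere remain elevated
   after each train ends, and for how long?
2. Is the after-effect an *induced* response (a power increase with random
   phase) or *entrainment* (phase-locked to the pulse train, and therefore
   tied to the stimulation frequency)?
3. Does the hemispheric imbalance of beta power couple to motor output
   (finger-tap rate)?

Because no public recordings accompany this problem, every stage is
validated against a synthetic cohort generator with known ground truth.

## Analysis chain

**Epoching.**  Trials are cut ±3.5 s around the end of each stimulation
train (t = 0 at the final pulse).  The DBS-OFF baseline recording has no
train offsets, so it is cut into consecutive 7 s epochs instead (the same
total duration as the offset-aligned epochs).  Automated amplitude
rejection replaces visual inspection: per channel, each trial's peak
absolute amplitude is z-scored across trials with robust statistics
(median, scaled MAD), and trials whose maximum z over channels exceeds 6
are dropped.  Rejecting more than half the trials is treated as an error
rather than silently proceeding.

**Time–frequency decomposition.**  Complex Morlet wavelets on a 5–60 Hz
grid (1 Hz steps).  "Wavelet length" is the *fixed total temporal support*
L at every frequency, with Gaussian σ_t = L/6 (support ≈ ±3σ): a fixed
duration bounds how far ON-period energy can leak past the train offset,
which is the reason the after-effect statistics start at 0.155 s when
L = 0.3 s.  Wavelets are zero-mean corrected and unit-energy normalized;
convolution is scaled by 1/fs so coefficients approximate the continuous
transform at any sample rate.  Power is |W|²; intertrial coherence (ITC)
is the resultant length of the per-trial unit phase vectors.  Output
samples within L/2 of an epoch edge are flagged invalid and excluded from
all statistics.  Baseline correction subtracts the frequency-specific mean
power over a reference window (default: the stimulation pause,
0.155–2.845 s).

**After-effect spectra.**  The immediate post-train window is 5–160 ms
(the 5 ms margin avoids the final pulse artifact).  The demeaned,
Hann-tapered 155 ms segment is Fourier transformed on its natural DFT
grid, k/0.155 s = k·6.45 Hz for k = 1..9; power is averaged over trials.
This grid is why the reportable effect bounds are 12.9 and 25.8 Hz
(bins k = 2 and 4).

**ROI selection.**  Visual selection of sensors with a clear pulse-evoked
field is replaced by a deterministic criterion: the data are re-averaged
across the pre-offset stimulation pulses; a left-hemisphere channel enters
the ROI when the across-trials t-statistic of its evoked deflection
(peak within 5–30 ms after a pulse, relative to the pre-pulse mean)
exceeds 4.  The across-trials formulation is robust to autocorrelated
background oscillations, which inflate naive pre-pulse noise estimates.
The right-hemisphere ROI is obtained by mirroring the left ROI across the
posteroanterior midline (nearest right channel to each x-negated left
position; the pairing is a bijection and is validated as an involution).

**Lateralization index.**  LI = (Left − Right)/(Left + Right) of
band-limited power averaged over the mirrored ROIs; positive = left
(stimulated) hemisphere dominance.  The after-effect LI is computed per
6.45 Hz bin, the baseline LI identically on the consecutive baseline
epochs, and the *normalized LI* is their difference.  LI is scale
invariant and antisymmetric under hemisphere exchange; both are property
tested.

**Statistics.**
* *Cluster-level paired t-tests*: sensor maps of mean power in windows
  T1–T3 (0.155–0.31, 0.31–0.465, 0.465–0.62 s) against the pause mean,
  10–23 Hz.  Channels above the two-sided paired-t critical value at
  α = 0.05 form spatial clusters under the layout adjacency graph; cluster
  mass is the sum of member t-values; the null is the maximum cluster mass
  over sign-flip permutations.  BH-FDR is applied across the
  window × condition family of cluster p-values.
* *tmax one-sample test*: per-frequency-bin t of the normalized LI across
  subjects; family-wise correction by the permutation distribution of
  max |t| across bins.
* Sign-flip permutations are enumerated exhaustively when 2ⁿ ≤ 16 384
  (p-values are then exact multiples of 1/2ⁿ and never zero, because the
  identity assignment counts itself); otherwise Monte-Carlo with the
  (b+1)/(m+1) estimate.  Both tests are verified against brute-force
  enumeration at n = 5.
* *Mixed models*: normalized LI ~ DBS frequency with a participant random
  intercept (REML; the F-test for the factor uses the within-subject
  containment denominator df, which equals the Satterthwaite value for
  balanced data — the design here is balanced; singular fits fall back to
  fixed-effects ANOVA).  Tap counts are modeled as Poisson with a
  log-exposure offset, DBS coded ON = +0.5 / OFF = −0.5, sum-coded
  frequency, their interaction, and a participant random intercept,
  fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
  (9 nodes); terms are tested by Type III likelihood-ratio χ².  Both
  models are checked against independent reference implementations on
  frozen datasets (see tests), and the Poisson GLMM is hand-implemented
  because no installed Python library provides likelihood-ratio-testable
  Poisson mixed models.
* *After-effect persistence*: on the group-average ROI band-power time
  course (10–23 Hz, 300 ms wavelets), an exponential a·e^(−t/τ) is fitted
  to the post-offset excess over the late-pause mean, and persistence is
  the time its value falls below 2 × the late-pause SD.  The noise floor
  deliberately uses the *late* pause (≥ 1 s post-offset) so the decaying
  effect does not inflate its own detection threshold.

## Synthetic cohort generator

Each simulated subject/condition is a channels × samples recording
containing, per channel: 1/f^1.5 background noise plus a flat
instrument-noise floor (SD 0.3 of the 1/f component); a bilateral,
non-lateralized alpha rhythm (10 ± 2 Hz, SD 2); and a narrowband beta
source per hemisphere (15 ± 2 Hz band-pass filtered Gaussian noise,
4th-order zero-phase filter, SD 1) projected strongly onto a
"sensorimotor" ROI group (weight 1) and weakly elsewhere (0.25).  Beta is
filtered noise rather than a sinusoid precisely so that ITC-based
entrainment discrimination is non-trivial.  Amplitudes are in units of the
background-noise SD.

During stimulation, biphasic single-sample pulses at the stimulation
frequency are projected onto a disjoint right-posterior "wire path"
channel group (so the artifact topography is dissociable from the neural
effect), and each pulse evokes a brief field on the left ROI channels
(unit-peak Gaussian bump, peak ≈ 8 ms, gone by 16 ms, gain 0.75) — the
basis of ROI selection.  The last pulse of every train falls exactly on
the train offset.

The post-train response has two modes.  *Induced* (default): the left
beta source's envelope is multiplied by 1 + A during ON and
1 + A·e^(−t/τ) during the pause (A = 0.6, τ = 0.15 s, so the power boost
decays below a 2-SD group noise floor by roughly 400 ms).  *Entrainment*:
a decaying sinusoid at the stimulation frequency, phase-continuous with
the final pulse, amplitude A (noise-SD units) with the same τ.  Across a
cohort, per-subject gains are drawn as Normal(A, 0.5·A) truncated at 0 —
a substantial between-subject heterogeneity, chosen so that the
across-subject correlation between the lateralization shift and the
tap-rate change is detectable above tap-count sampling noise, as it was
in the motivating experiments — and each subject gets a baseline LI drawn
as Normal(0, 0.12) (implemented as a left/right beta-amplitude ratio).

Tapping behavior follows the task structure (7 blocks of 10 s red +
15 s green fixation): taps occur only in green windows, as an equilibrium
gamma-renewal process (shape 4 — more regular than Poisson, as real
tapping is) with rate `base − coupling·LI(t)` in taps/min, where LI(t) is
the subject's baseline LI plus the injected shift while stimulation is
ON.  Subjects get individual base rates (SD 6 taps/min); with default
coupling 20 this produces an ON–OFF slowing of a few taps/min, a paired
effect size near d ≈ 0.6, and a negative across-subject correlation
between baseline LI and tap rate — the magnitudes the analysis is meant
to detect.  The equilibrium (forward-recurrence) first arrival makes the
expected count exactly rate × exposure regardless of how ON/OFF segments
cut the green windows.

### Generator realism calibration

Three background parameters were set by matching the *selectivity* of the
after-effect analysis, not its sensitivity: with a pure 1/f background the
6.45 Hz bin (via window mainlobe leakage of beta) and the 32.3 Hz bin
(via Hann sidelobe leakage of the boosted beta) showed spurious
lateralization shifts that real sensor data do not produce, because real
recordings have a strong low-frequency background and a flat instrument
noise floor that dominate those bins.  The alpha rhythm, the 1/f exponent
of 1.5, and the noise floor of 0.3 encode exactly that; with them, the
recovered effect is confined to the 12.9–25.8 Hz bins.

### What the generator does not emulate

Volume conduction and realistic field spread; head movement;
physiological artifacts (cardiac, ocular, muscle) beyond generic amplitude
outliers; environmental interference (the real pipeline's tSSS step is
out of scope); tremor; basal-ganglia dynamics.  Passing tests therefore
show that the *analysis chain* recovers the statistical structure it
assumes — they are not evidence about any particular patient dataset.

## Problem sizes

Test and validation runs use a 200 Hz sample rate (all windows are in
seconds, so results are rate-independent; 200 Hz keeps the 155 ms window
at exactly 31 samples), 8 channels per hemisphere (5 ROI, 3 wire), 14
subjects, and 60 trains per condition (480 s blocks).  Cohort-level
recovery checks use 8 effect cohorts and 6 null cohorts; behavioral
recovery uses 60 simulated model fits per scenario and 15 cohort draws
per coupling setting.  The persistence estimate pools all four analyzed
stimulation conditions, mirroring a grand-average time–frequency map.

## Numerical choices and degenerate inputs

* Exhaustive permutation counts use a relative comparison slack (1e-9) so
  the identity assignment always counts itself despite round-off.
* LI with zero total power is NaN and flagged, never silently zero.
* Mirror pairing processes left channels in order of best-match residual,
  so jitter cannot let one channel steal another's partner; unequal
  left/right counts raise an error listing the unmatched channels.
* Epochs touching a record edge are dropped (never zero-padded), to avoid
  wavelet edge artifacts; wavelet outputs within L/2 of an epoch edge are
  masked invalid.
* The 16 Hz condition is excluded from the 14–18 Hz tapping-band analysis
  because its artifact falls inside the band; the exclusion is logged.
* The GLMM optimizer accepts a "precision loss" stop as converged when
  the gradient norm is below 1e-2 (a flat log-σ direction at σ → 0).

## Known limitations

* The Satterthwaite denominator df is replaced by the containment formula;
  they agree exactly for balanced designs (the only designs produced
  here), but would differ for unbalanced real data.
* Artifact-channel offset detection assumes pulse artifacts dominate the
  named channel by ≥ 8 MADs; very weak artifacts would need the
  event-table path.
* The after-effect window (5–160 ms) and the 6.45 Hz grid are coupled by
  construction; changing one without the other breaks the bin ↔ frequency
  correspondence.
* Whether the pause reference is 0.155–2.845 s or 0.275–2.725 s is
  configurable (`RunConfig.pause_window`); the default is the former.
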