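# cycdbs

Sensor-space analysis of cortical beta-band **after-effects of cyclic deep
brain stimulation (DBS)**, with a synthetic cohort generator for end-to-end
validation.

## The problem

In Parkinson's disease, beta oscillations (13–35 Hz) are pathologically
enhanced and are suspected of causing motor slowing.  One way to probe
causality is to *drive* the system: stimulate the subthalamic nucleus at
beta frequencies (10–30 Hz) through one electrode in a cyclic pattern
(5 s ON, 3 s OFF) while recording cortical activity over both hemispheres,
and ask what persists in the pauses.  Key analysis targets:

* **After-effect**: does cortical beta power over the stimulated
  hemisphere stay elevated for a few hundred ms after each train ends?
* **Induced response vs entrainment**: is the effect a power increase with
  random phase (induced), or phase-locked to the pulse train and dependent
  on the stimulation frequency (entrainment)?  Diagnosed via intertrial
  coherence (ITC) and frequency-invariance of the effect.
* **Behavioral coupling**: does the hemispheric beta imbalance predict
  slowed finger tapping?

The central statistic is the **lateralization index** of band-limited
power over mirrored sensor regions of interest,

    LI = (Left − Right) / (Left + Right),

positive when the left (stimulated) hemisphere dominates.  The
**normalized LI** is the post-train LI (5–160 ms after the final pulse, on
a 6.45 Hz spectral grid) minus the same quantity from a DBS-OFF baseline.
Group inference uses sign-flip permutation tests (spatial cluster-mass
tests for sensor maps, tmax correction across frequency bins), BH-FDR, a
linear mixed model for frequency-specificity of the LI shift, and a
Poisson mixed model with exposure offset for tap counts.

Because no public recordings exist for this design, the package ships a
first-class synthetic generator (`cycdbs.synth`): bilateral sensor arrays,
1/f + instrument-noise background, alpha and beta band-limited sources,
pulse-train artifacts on a "wire path" channel group, pulse-evoked fields
for ROI selection, induced/entrainment response modes with known gain and
decay constant, and tap streams whose rate is negatively coupled to the
instantaneous LI.  Every analysis stage is validated by parameter recovery
against this ground truth.

## Worked example

```python
from cycdbs import SimulationConfig, RunConfig, run_all

sim = SimulationConfig(n_subjects=10, duration=320.0, sample_rate=200.0,
                       n_channels_per_hemisphere=8, seed=7)
res = run_all(sim, RunConfig(seed=7), out_dir="demo_out")
print(res.summary())
```

prints

```
cycdbs pipeline v0.1.0
subjects: 10, conditions: [10.0, 16.0, 20.0, 26.0, 30.0]

Normalized LI (tmax-corrected): significant bins at 19.35 Hz, 25.81 Hz
normalized LI ~ DBS frequency + (1 | participant)
method: REML mixed model
F(4, 36.00) = 1.474, p = 0.2305
tap_count ~ DBS * frequency + (1 | participant), Poisson, offset log(exposure)
method: ML, adaptive Gauss-Hermite (9 nodes)
chi2(1) = 19.232, p = 0.0000
  dbs: chi2(1) = 19.232, p = 0.0000
  frequency: chi2(4) = 0.529, p = 0.9706
  interaction: chi2(4) = 0.275, p = 0.9913
tap-rate ON-OFF difference: -10.44 taps/min (d = -1.13)
corr(delta LI, delta tap rate): r = -0.716, p = 0.0198
baseline corr(LI, tap rate): r = -0.644, p = 0.0443
```

Reading this: the post-train lateralization shift is confined to beta
bins of the 6.45 Hz grid (here 19.35 and 25.81 Hz survive tmax
correction); the mixed model finds **no** main effect of stimulation
frequency on the shift (the frequency-invariance signature of an induced
response rather than entrainment); stimulation slows tapping by ~10.4
taps/min; and subjects whose lateralization shifted more slowed more
(negative ΔLI–Δrate correlation), with the same negative LI–rate coupling
already present at baseline.  `demo_out/` contains the per-subject LI
table, cluster and tmax results, tap statistics, correlations, a markdown
report, and a manifest with the seeds and configuration hash.

The same stages are scriptable from the shell:

```bash
cycdbs simulate --config cohort.yaml --out data/
cycdbs epoch --raw data/sub00_stim20 --mode offset --out ep.h5
cycdbs tfr --epochs ep.h5 --wavelet-length 0.3 --out tfr.h5
cycdbs li --raw data/sub00_stim20 --baseline data/sub00_baseline --out li.csv
cycdbs run-all --out results/
```

## Library map

| module | contents |
|---|---|
| `cycdbs.core` | domain types (layout, schedule, recordings, epochs), raw container I/O, mirror-map construction, run configuration |
| `cycdbs.synth` | stimulation schedules, subject/cohort simulation, tapping behavior, ground truth |
| `cycdbs.epochs` | train-offset detection, offset/consecutive epoching, robust amplitude rejection |
| `cycdbs.spectral` | fixed-duration Morlet TFR, ITC, frequency-specific baseline correction, 155 ms segment spectra |
| `cycdbs.lateralization` | evoked-field ROI selection, LI / after-effect / normalized / tapping LI, persistence estimation |
| `cycdbs.stats` | cluster-mass and tmax sign-flip permutation tests, BH-FDR, Pearson, LME for LI, Poisson GLMM for tap counts |
| `cycdbs.pipeline` | `run_all` orchestration, caching, report |

See `docs/methods.md` for the model, parameter meanings, defaults, and
validation scope.

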