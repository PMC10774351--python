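# mindseye

Analysis pipeline linking the power of oscillatory EEG activity to the
subjective intensity (vividness) of imagined audio and visual experiences —
with a synthetic-cohort generator so that every stage is testable against a
known ground truth, end to end, without any recorded data.

## Who this is for

People studying mental imagery and its extremes (aphantasia /
hyper-phantasia) with eyes-closed EEG paradigms: participants imagine sounds
or images, or rest, and rate the vividness of each imagined experience on a
5-point VVIQ-style scale.  The package answers two questions about such
sessions:

1. *Compliance*: can the cognitive task a participant performed on a single
   trial (audio imagery, visual imagery, rest) be decoded from the power
   spectrum of that trial's EEG?
2. *Vividness*: do condition-specific changes in band power predict how
   intense different people's imagined experiences feel?

## The methods at the core

- **Features.** Each trial's sensor-wise voltage trace is band-pass filtered
  (1–100 Hz, 6th-order Butterworth, two-pass) with a 45–55 Hz notch,
  re-referenced to the instantaneous average over all sensors, cut to the
  centred 9/10 of the trial, and converted to a single-FFT periodogram
  averaged into integer 1 Hz bins, 1–40 Hz.  Sensor-trials whose
  peak-to-peak range exceeds a threshold (default 250 µV) become NaN.
- **Decoding.** A leave-one-trial-out nearest-signature classifier: a trial
  is assigned to the condition whose mean training-set PSD minimises
  `Σ |trial − signature|` over sensor × frequency cells (no rescaling, no
  Euclidean metric).  Significance per participant comes from re-running the
  full decode under random label reassignment (add-one-corrected shuffle
  p-value).
- **Group contrasts.** Paired t-tests at every (sensor, frequency) cell;
  cells with p < 0.05 are clustered by spatio-frequency adjacency
  (Delaunay-triangulated montage neighbours, ±1 Hz); the summed-t cluster
  mass is tested against the permutation distribution of the maximum
  |mass| under within-participant condition exchange.
- **Vividness prediction.** Per frequency, the sensor-averaged
  imagery-minus-rest PSD difference predicts mean ratings via linear ε-SVR
  in 125 iterations of 4-fold cross-validation (500 fold-wise Pearson
  R-values), against a matched shuffled-ratings null; a JZS (Cauchy-prior)
  Bayes-factor t-test per frequency compares actual and chance R-values,
  and runs of ≥ 2 consecutive frequencies with BF₁₀ ≥ 100 are reported as
  predictive bands.

## Worked example

```python
from mindseye import (AdjacencySpec, ClusterPermutationTest, ConditionDecoder,
                      SyntheticConfig, VividnessSVR)
from mindseye.montage import standard_montage
from mindseye.pipeline import simulate_psd

cfg = SyntheticConfig(n_participants=16, n_trials_per_condition=9,
                      n_sensors=16, sfreq=256.0, trial_duration=5.0, seed=7)
psd, truth = simulate_psd(cfg)          # simulate -> preprocess -> binned PSD

print(ConditionDecoder(psd).fit(n_shuffles=199, rng=1).summary())

adj = AdjacencySpec.from_montage(standard_montage(16))
print(ClusterPermutationTest(psd, "rest", "visual", adj)
      .fit(n_permutations=199, rng=2).summary())

print(VividnessSVR.from_psd(psd, "visual").fit(n_iter=25, k=4, rng=3).summary())
```

prints

```
Leave-one-trial-out condition decoding
==============================================
participants               16
mean success rate          0.500   (chance 0.333)
decodable at p < 0.05     62% of participants
group test vs chance       t(15) = 4.88, p = 0.0002, BF10 = 155

Cluster-based permutation test
==============================================
permutations     199
clusters found   3 (3 with p < 0.05)
  + mass      842.2   208 points  1-23 Hz  p = 0.005
  + mass      538.3   132 points  27-40 Hz  p = 0.005
  - mass     -163.9    39 points  24-26 Hz  p = 0.025

Per-frequency SVR prediction of vividness
==============================================
frequencies tested   40 (1-40 Hz)
R-values per freq    100 actual + 100 shuffled
predictive bands (BF10 >= 100, >= 2 consecutive Hz):
  6-7 Hz   minimum BF10 = 1.49e+03
  24-26 Hz   minimum BF10 = 1.73e+07
```

Reading the output: decoding is well above the 1/3 chance rate, so the three
simulated cognitive states are distinguishable trial by trial.  The
rest-vs-visual cluster test finds the planted broad-band power reduction
during imagery (positive mass: more power at rest), and a negative cluster
at 24–26 Hz — exactly where this cohort's visual vividness coupling *adds*
power during imagery.  The SVR stage recovers that same 24–26 Hz band as
predictive of the vividness ratings (the generator's configured coupling),
with extreme Bayes-factor evidence.

The same stages are available from the shell:

```bash
mindseye synth --out cohort.h5 --participants 8 --sensors 16 --sfreq 256
mindseye decode psd.h5 --n-shuffles 199
mindseye cluster psd.h5 --contrast rest-visual --n-perm 199
mindseye svr psd.h5 --modality visual
mindseye run config.yaml        # full pipeline from a YAML config
```

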