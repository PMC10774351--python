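# Methods

This note documents the models and procedures implemented in `mindseye`,
the choices made where the design was genuinely open, and what the
package's tests do and do not establish.

## The synthetic cohort generator

The generator (`mindseye.synth`) emulates an eyes-closed imagery EEG
session: `n_participants` (default 44) each complete
`n_trials_per_condition` (default 18) interleaved trials of three
conditions — imagined audio, imagined visual, resting state — recorded from
`n_sensors` (default 64, standard Biosemi positions) at `sfreq`
(default 1024 Hz) for `trial_duration` (default 10 s) per trial, and rate
each imagery trial's vividness on a 1–5 scale.

Signals are synthesised in the frequency domain as zero-mean Gaussian
processes. The one-sided amplitude spectrum of each sensor is

    A(f) = K · f^(−a/2) · (1 + α · w_s · exp(−(f − f_α)² / 2σ_α²)) · Π m_b(f)^(1/2)

with

- `a = noise_exponent` (default 1): the 1/f^a background every EEG
  spectrum shows;
- an alpha peak at `f_α = alpha_peak_freq` (default 10 Hz, width
  `σ_α = 2 Hz`, relative amplitude `α = 2`), weighted by `w_s`, a linear
  posterior-to-anterior ramp on the montage's y coordinate (occipital
  maximal, as eyes-closed alpha is);
- multiplicative band-power modulations `m_b`: condition effects (default:
  broad-band power reductions during imagery, factors 0.80 audio / 0.72
  visual, occipitally weighted as `factor^w_s`) and vividness couplings
  (below). A band (lo, hi) modulates exactly the Fourier components that
  fall into the integer 1 Hz bins lo..hi.
- `K` scales the broad-band RMS to `background_rms` (10 µV — scalp
  realistic, comfortably below the 250 µV peak-to-peak exclusion
  threshold).

Every trial additionally carries a global lognormal power factor
(`trial_power_logsd`, default 0.3, i.e. total power typically varies by
×/÷1.35 from trial to trial). Real EEG band power fluctuates at least this
much with arousal and posture; the parameter also matters statistically —
see "Decoder chance level" below.

**Vividness.** Each participant has a continuous latent vividness per
modality, uniform on [1, 5], tied across modalities by a Gaussian copula
(correlation 0.7, matching the strong audio/visual association such
ratings show). On imagery trials of modality *m* the configured coupling
band's power is multiplied by `exp(slope · v + e_p)` with
`e_p ~ N(0, noise_sd)` per participant, so the imagery-minus-rest band
log-power difference is linear in the latent vividness with the configured
slope (defaults: theta 6–9 Hz, slope −0.12 for audio; mid-beta 24–26 Hz,
slope +0.12 for visual; noise 0.1). Reported per-trial ratings are the
latent value plus N(0, 0.5) noise, rounded and clipped to 1–5.

**Artifacts.** With probability `artifact_rate` per sensor-trial a 1 s,
10 Hz Hann-windowed burst (amplitude 750 µV) is injected at the trial
centre; its (participant, trial, sensor) address is recorded in the
`GroundTruth` so the amplitude screen can be checked cell for cell.

What the generator does **not** emulate: volume-conduction correlations
between sensors (sensors are independent before average referencing), eye
movements or other ICA-separable artifact components, non-stationarity
within a trial, and realistic rating distributions per condition. Passing
tests therefore show the *procedures* behave correctly under a faithful
spectral model of the session, not that the effect sizes in real
recordings would match.

## Preprocessing

Fixed order: filter → average reference → centred epoch → amplitude screen.

- Filtering: 6th-order Butterworth high-pass (1 Hz), low-pass (100 Hz) and
  45–55 Hz band-stop, each applied forward and backward (zero phase).
  Two-pass IIR filtering leaves edge ringing on finite records; the epoch
  step (central 9 s of a 10 s trial by default, left offset floored when
  fractional) discards those edges along with the eye-closure transients.
- Average reference: subtract the instantaneous mean over all sensors.
- Amplitude screen: a sensor-trial whose peak-to-peak range exceeds
  `range_threshold` is excluded by setting its power estimates to NaN.
  The default threshold is 250 µV — a peak-to-peak range in recorded
  units; the parameter is configurable so other readings of the criterion
  are reproducible. Manual ICA-based artifact rejection is out of scope;
  the amplitude screen is the only artifact defence, a documented fidelity
  gap relative to a full manual pipeline.

## Spectral features

A single un-windowed FFT of the whole epoch per sensor-trial, normalised so
that power at an interior frequency is `|X_k|²·2/N²` (a sinusoid of
amplitude A on an exact bin gives A²/2; one-sided power sums to the mean
square). Fourier frequencies are averaged into the integer bin their value
rounds to (round half up), giving 40 features per sensor. No taper and no
segment averaging: the binning already pools ~9 neighbouring frequencies at
the default 9 s epoch, and every downstream quantity is a contrast or a
regression, so absolute power units are irrelevant (and not calibrated).

## Decoder chance level

The leave-one-trial-out nearest-signature decoder has a structural
below-chance bias under the null: when a trial is held out, its own
condition's signature averages 17 trials while the other two average 18,
so the own-condition signature is noisier and the sum-of-absolute-residuals
distance to it stochastically larger. With independent features this
pushes null accuracy to ≈ 0.30 at the full 64 × 40 feature space.
Trial-to-trial global power variability (shared across all cells of a
trial) suppresses the bias; at the default `trial_power_logsd = 0.3` the
measured null accuracy is 0.321 ± 0.006 (256 simulated participants), close
to — but measurably below — the nominal 1/3. The acceptance script reports
this empirical chance level over 240 participants.

The shuffle test is exact regardless of this bias (labels are exchangeable
under the null); ties between discrete success counts make it
conservative, the more so the smaller the feature space (measured
false-positive rate at p < 0.05: ≈ 0.03 at 64 sensors, ≈ 0.02 at 8).

## Cluster-based permutation tests

Before testing, per-cell group outliers (beyond ±3 SD of the conditional
mean over participants) are replaced by the participant's mean over
adjacent sensors at the same frequency, or set to NaN when no finite
neighbour exists. Paired t-maps use pairwise-complete participants per
cell (cells with < 2 pairs are NaN; zero-variance nonzero differences give
±∞ with p = 0). Clustering is two-sided at p < 0.05 with positive and
negative t clustered separately; sensor adjacency is the Delaunay
triangulation of the azimuthal-equidistant-projected montage (configurable
via a montage file), frequency adjacency ±1 Hz. The family-wise null is
the distribution of the maximum |cluster mass| over within-participant
condition exchanges (sign flips of paired differences), with add-one
p-values; all 2^n patterns are enumerated when `exact=True`. Measured
family-wise error over 200 null cohorts: ≤ 5% nominal, observed ~4%.

## Vividness SVR and Bayes factors

Per frequency and modality, the feature is the sensor-averaged
imagery-minus-rest mean PSD per participant and the target the
participant's mean rating. Hyperparameters the source procedure leaves
open are fixed at the common defaults: linear ε-SVR with C = 1, ε = 0.1 on
feature and target z-scored with training-fold statistics. Each of 125
iterations draws a fresh random partition into 4 equal groups (n divisible
by 4 is required, mirroring the 44 → 4 × 11 design); folds with degenerate
predictions or targets record R = 0 so the 500-value bookkeeping stays
intact. The shuffled null repeats the procedure with ratings permuted
before every iteration.

The JZS Bayes factor (Cauchy prior on the standardised effect, scale √2/2,
Jeffreys prior on variance) is computed by adaptive quadrature of the
one-dimensional scale-mixture integral in log space (relative tolerance
1e-10), so astronomically large Bayes factors are returned as finite
numbers up to the double-precision ceiling and `inf` beyond, never an
overflow crash. The per-frequency test is an independent two-sample test
on the 500 + 500 R-values (they carry no natural pairing); bands are
maximal runs of ≥ 2 consecutive frequencies with BF₁₀ ≥ 100.

**Calibration caveat (important).** The 500 fold-wise R-values are not
independent samples: all iterations reuse the same participants, so the
mean actual R tracks the dataset's sampled feature–rating correlation
(spread ~ 1/√(n−1) ≈ 0.15 at n = 44) while the t-test's standard error
shrinks as 1/√500. The shuffled distribution matches the null's mean but
not this dataset-level spread. Under a true null the procedure therefore
produces BF₁₀ ≥ 100 at far above the nominal rate (measured: ~35% of null
frequencies at n = 24), and when a real coupling is planted it reliably
recovers it (band hit rate 0.9 over 20 seeds) but also flags bands far
from the planted one (spurious rate 0.9). The corresponding calibration
tests assert the nominal bounds and fail; they are kept failing
deliberately, as a measured property of the procedure rather than a defect
of the implementation. Interpreting these Bayes factors as evidence
magnitudes is not recommended; the band *structure* and its contrast
against the shuffled mean remain interpretable.

## Pipeline and reproducibility

`run_full_pipeline` executes synth → preprocess → PSD → decode → three
cluster contrasts → two modality SVRs from one serialisable config; each
stochastic stage draws its own child generator from the master seed by a
counter-based split, so any stage can be re-run from saved intermediates
bit-identically. Full-scale cohorts are streamed participant-by-participant
(`simulate_psd`) because a whole raw cohort (44 × 54 trials × 64 sensors ×
10 s) does not fit comfortably in memory.

Problem sizes used by the test suite and acceptance script (sensor count,
sampling rate, trial counts, permutation counts) are chosen per check: the
session *design* quantities always use the full 44/54/18 layout; the
statistical calibration and recovery checks run at reduced sensor counts
and sampling rates where the tested property does not depend on them, with
the choices stated in each test.

## Known limitations

- Absolute spectral power units are uncalibrated (irrelevant to all
  contrasts, but Figure-style absolute PSD values are not reproducible).
- The decoder's empirical chance level is slightly below 1/3 (above), so
  comparing group success against exactly 1/3 is mildly conservative in
  the upward direction and the shuffle test should be preferred.
- The SVR Bayes-factor stage is anticonservative under the null (above).
- Sensor independence in the generator understates the spatial smoothness
  of real scalp data; cluster extents on real data will be larger.
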