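"""Synthetic eyes-closed EEG cohorts with known ground truth.

The generator emulates the structure of a sensory-imagination EEG session:
each participant completes interleaved trials of three conditions (imagined
audio, imagined visual, resting state), eyes closed, and rates the vividness
of imagery trials on a 1-5 scale.  Signals are built in the frequency domain
as Gaussian processes with a 1/f^a background, a Gaussian-enveloped alpha
peak that is maximal over posterior sensors, and a per-trial lognormal global
power factor capturing the large trial-to-trial fluctuations of real EEG band
power.  Experimental-condition effects multiply band-limited component power
with a sensor-weight topography, and per-participant imagery vividness is
linearly coupled to the imagery-minus-rest band log-power, so every
downstream analysis can be validated against a known latent truth.

Amplitudes are in volts at a scalp-realistic scale (tens of microvolts
peak-to-peak), so the amplitude-range artifact exclusion operates on the same
footing as it would on recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import posterior_weights, standard_montage

CONDITIONS = ("audio", "visual", "rest")
MODALITIES = ("audio", "visual")
RATING_SCALE = (1, 5)


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative band-power modulation attached to one condition.

    ``power_factor`` multiplies the power of band-limited signal components
    on trials of ``condition``; a per-sensor weight profile (``"occipital"``,
    ``"uniform"``, or an explicit array) sets the topography, with the factor
    applied as ``power_factor ** weight`` per sensor.
    """

    condition: str
    band: tuple[float, float]
    power_factor: float
    sensor_weights: str | np.ndarray = "occipital"


@dataclass(frozen=True)
class VividnessCoupling:
    """Linear link between latent vividness and imagery band power.

    On imagery trials of ``modality`` the band-limited power is multiplied by
    ``exp(slope * vividness + e_p)`` with ``e_p ~ N(0, noise_sd)`` drawn once
    per participant, so that the participant's imagery-minus-rest band
    log-power difference equals ``slope * vividness + e_p`` in expectation.
    """

    modality: str
    band: tuple[float, float]
    slope: float
    noise_sd: float = 0.1


def default_condition_effects() -> list[ConditionEffect]:
    # Broad-band power reduction during imagery relative to rest, maximal
    # occipitally.  Because the baseline spectrum is alpha-peaked, a flat
    # multiplicative reduction yields condition differences with the
    # characteristic alpha-band peak.
    return [
        ConditionEffect("audio", (1.0, 40.0), 0.80),
        ConditionEffect("visual", (1.0, 40.0), 0.72),
    ]


def default_vividness_couplings() -> list[VividnessCoupling]:
    # One predictive band per modality: theta-band reductions scale with
    # imagined-audio vividness, mid-beta increases with imagined-visual
    # vividness (signs mirror the kind of band-specific couplings the
    # analyses are designed to detect).
    return [
        VividnessCoupling("audio", (6.0, 9.0), -0.12),
        VividnessCoupling("visual", (24.0, 26.0), 0.12),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a simulated cohort.

    Defaults reproduce the session design the analyses target: 44
    participants, 18 trials per condition, 64 sensors at 1024 Hz, 10 s
    trials.
    """

    n_participants: int = 44
    n_trials_per_condition: int = 18
    n_sensors: int = 64
    sfreq: float = 1024.0
    trial_duration: float = 10.0
    noise_exponent: float = 1.0
    background_rms: float = 1.0e-5  # volts
    alpha_peak_freq: float = 10.0
    alpha_peak_amplitude: float = 2.0  # relative bump height on amplitude
    alpha_peak_width: float = 2.0  # Hz (Gaussian sigma)
    trial_power_logsd: float = 0.3  # lognormal sd of per-trial power factor
    condition_effects: list[ConditionEffect] = field(
        default_factory=default_condition_effects
    )
    vividness_couplings: list[VividnessCoupling] = field(
        default_factory=default_vividness_couplings
    )
    vividness_correlation: float = 0.7  # audio/visual latent correlation
    rating_noise_sd: float = 0.5  # per-trial rating noise before rounding
    artifact_rate: float = 0.0  # P(sensor-trial gets an injected excursion)
    artifact_amplitude: float = 7.5e-4  # volts, burst amplitude
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_participants, self.n_trials_per_condition, self.n_sensors) < 1:
            raise ValueError("participant, trial and sensor counts must be >= 1")
        if self.sfreq <= 0 or self.trial_duration <= 0:
            raise ValueError("sfreq and trial_duration must be positive")
        n = self.trial_duration * self.sfreq
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration * sfreq must be an integer")
        for eff in self.condition_effects:
            if eff.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {eff.condition!r}")
            _check_band(eff.band)
            if eff.power_factor <= 0:
                raise ValueError("power_factor must be positive")
        for coup in self.vividness_couplings:
            if coup.modality not in MODALITIES:
                raise ValueError(f"unknown modality {coup.modality!r}")
            _check_band(coup.band)
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sfreq))

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * len(CONDITIONS)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _check_band(band: tuple[float, float]) -> None:
    lo, hi = band
    if not (1.0 <= lo <= hi <= 40.0):
        raise ValueError(f"band {band} outside [1, 40] Hz")


@dataclass
class GroundTruth:
    """Latent quantities stored alongside a generated cohort.

    ``vividness`` is the continuous latent per participant and modality
    (columns ``audio``, ``visual``); ``coupling_noise`` the per-participant
    draw added to each modality's band log-power offset; ``artifacts`` the
    exact (participant, trial, sensor) cells carrying an injected
    out-of-range excursion.
    """

    vividness: pd.DataFrame
    coupling_noise: pd.DataFrame
    condition_effects: list[ConditionEffect]
    vividness_couplings: list[VividnessCoupling]
    artifacts: list[tuple[int, int, int]]


@dataclass
class SyntheticCohort:
    """Generated trial store: one (n_trials, n_sensors, n_samples) array per
    participant, a tidy metadata table and the montage used."""

    data: dict[int, np.ndarray]
    metadata: pd.DataFrame  # participant, trial_index, condition, rating
    montage: pd.DataFrame
    sfreq: float
    trial_duration: float

    @property
    def participants(self) -> list[int]:
        return sorted(self.data)


def _sensor_weights(spec: str | np.ndarray, montage: pd.DataFrame) -> np.ndarray:
    if isinstance(spec, str):
        if spec == "occipital":
            return posterior_weights(montage)
        if spec == "uniform":
            return np.ones(len(montage))
        raise ValueError(f"unknown sensor-weight profile {spec!r}")
    w = np.asarray(spec, float)
    if w.shape != (len(montage),):
        raise ValueError("sensor weight vector length does not match montage")
    return w


def _amplitude_profile(
    config: SyntheticConfig,
    montage: pd.DataFrame,
    condition: str,
    band_log_offsets: list[tuple[tuple[float, float], float]],
) -> np.ndarray:
    """Per-(sensor, rfft-frequency) target amplitude A such that the expected
    one-sided periodogram power of the generated component at that frequency
    is A**2."""
    n = config.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / config.sfreq)
    nf = len(freqs)
    ns = len(montage)

    with np.errstate(divide="ignore"):
        base = np.where(
            freqs >= 0.5, freqs ** (-config.noise_exponent / 2.0), 0.0
        )
    base[0] = 0.0  # zero DC -> zero-mean signals

    occ = posterior_weights(montage)
    bump = np.exp(
        -((freqs - config.alpha_peak_freq) ** 2) / (2 * config.alpha_peak_width**2)
    )
    amp = base[None, :] * (
        1.0 + config.alpha_peak_amplitude * occ[:, None] * bump[None, :]
    )

    # normalise so the broad-band RMS of the *median-weighted* sensor matches
    # background_rms before condition effects
    rms = np.sqrt(np.mean(np.sum(amp**2, axis=1)))
    if rms > 0:
        amp *= config.background_rms / rms

    # a band (lo, hi) modulates exactly the components that fall into the
    # integer 1 Hz bins lo..hi, i.e. frequencies in [lo - 0.5, hi + 0.5)
    for eff in config.condition_effects:
        if eff.condition != condition:
            continue
        w = _sensor_weights(eff.sensor_weights, montage)
        in_band = (freqs >= eff.band[0] - 0.5) & (freqs < eff.band[1] + 0.5)
        factor = eff.power_factor ** (w[:, None] / 2.0)
        amp = np.where(in_band[None, :], amp * factor, amp)

    for band, log_offset in band_log_offsets:
        in_band = (freqs >= band[0] - 0.5) & (freqs < band[1] + 0.5)
        amp = np.where(in_band[None, :], amp * np.exp(log_offset / 2.0), amp)

    assert amp.shape == (ns, nf)
    return amp


def generate_trial_timeseries(
    config: SyntheticConfig,
    participant: int,
    condition: str,
    rng: np.random.Generator,
    band_log_offsets: list[tuple[tuple[float, float], float]] | None = None,
    montage: pd.DataFrame | None = None,
    _amp: np.ndarray | None = None,
) -> np.ndarray:
    """One trial as a (n_sensors, n_samples) voltage array.

    Spectral synthesis: independent complex-Gaussian rfft coefficients with
    amplitude profile from the config (background + alpha peak + condition
    and vividness band modulations), scaled by a per-trial lognormal global
    power factor, then inverse-transformed.  Sensors are zero-mean by
    construction (DC coefficient is zero).
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r} for participant {participant}; "
            f"expected one of {CONDITIONS}"
        )
    config.validate()
    if _amp is not None:
        amp = _amp
    else:
        if montage is None:
            montage = standard_montage(config.n_sensors)
        amp = _amplitude_profile(config, montage, condition, band_log_offsets or [])
    n = config.n_samples
    ns, nf = amp.shape

    trial_gain = np.exp(rng.normal(0.0, config.trial_power_logsd) / 2.0)
    # E|X_k|^2 = N^2 A^2 / 2  ->  expected one-sided periodogram power = A^2
    z = rng.standard_normal((ns, nf)) + 1j * rng.standard_normal((ns, nf))
    coeffs = (n / 2.0) * amp * trial_gain * z
    coeffs[:, 0] = 0.0
    if n % 2 == 0:
        coeffs[:, -1] = coeffs[:, -1].real  # Nyquist bin must be real
    return np.fft.irfft(coeffs, n=n, axis=1)


def _inject_artifact(x: np.ndarray, sfreq: float, amplitude: float) -> None:
    """Add a 1 s, 10 Hz windowed burst at the trial centre (in place).

    The burst sits inside the central analysis epoch and within the 1-100 Hz
    pass band, so it survives filtering and is caught by the amplitude-range
    screen.
    """
    n = x.shape[-1]
    dur = min(int(round(sfreq)), n)
    start = (n - dur) // 2
    t = np.arange(dur) / sfreq
    window = np.hanning(dur)
    x[start : start + dur] += amplitude * window * np.sin(2 * np.pi * 10.0 * t)


def _latent_vividness(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Continuous latent vividness per participant and modality.

    Marginals are uniform on [1, 5]; the audio/visual pair is tied through a
    Gaussian copula with correlation ``vividness_correlation``.
    """
    from scipy.stats import norm

    rho = config.vividness_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_participants)
    u = norm.cdf(z)
    v = RATING_SCALE[0] + (RATING_SCALE[1] - RATING_SCALE[0]) * u
    return pd.DataFrame(v, columns=list(MODALITIES))


def _cohort_latents(config: SyntheticConfig):
    """Montage, latent vividness, coupling noise and per-participant seed
    sequences, all determined by ``config.seed`` alone."""
    montage = standard_montage(config.n_sensors)
    master = np.random.SeedSequence(config.seed)
    cohort_ss, *participant_ss = master.spawn(1 + config.n_participants)
    cohort_rng = np.random.default_rng(cohort_ss)
    vividness = _latent_vividness(config, cohort_rng)
    coupling_noise = pd.DataFrame(
        {
            m: cohort_rng.normal(
                0.0,
                next(
                    (c.noise_sd for c in config.vividness_couplings if c.modality == m),
                    0.0,
                ),
                size=config.n_participants,
            )
            for m in MODALITIES
        }
    )
    return montage, vividness, coupling_noise, participant_ss


def iter_participants(config: SyntheticConfig):
    """Stream the cohort one participant at a time.

    Yields ``(participant, trials, conditions, rows, artifacts)`` where
    ``trials`` is (n_trials, n_sensors, n_samples), ``rows`` the metadata
    records and ``artifacts`` the injected (trial, sensor) cells.  Memory
    stays bounded by a single participant, which matters at the full session
    scale (a whole cohort of raw trials is tens of gigabytes).
    """
    config.validate()
    montage, vividness, coupling_noise, participant_ss = _cohort_latents(config)
    for p in range(config.n_participants):
        rng = np.random.default_rng(participant_ss[p])
        conditions = np.repeat(CONDITIONS, config.n_trials_per_condition)
        rng.shuffle(conditions)
        trials = np.empty(
            (config.n_trials, config.n_sensors, config.n_samples), dtype=np.float64
        )
        rows = []
        artifacts: list[tuple[int, int]] = []
        # per-participant amplitude profiles are condition-constant: cache
        amp_cache: dict[str, np.ndarray] = {}
        for t, cond in enumerate(conditions):
            if cond not in amp_cache:
                offsets = []
                if cond in MODALITIES:
                    for coup in config.vividness_couplings:
                        if coup.modality == cond:
                            offsets.append(
                                (
                                    coup.band,
                                    coup.slope * vividness.loc[p, cond]
                                    + coupling_noise.loc[p, cond],
                                )
                            )
                amp_cache[cond] = _amplitude_profile(config, montage, cond, offsets)
            trials[t] = generate_trial_timeseries(
                config, p, cond, rng, montage=montage, _amp=amp_cache[cond]
            )
            if config.artifact_rate > 0:
                hit = rng.random(config.n_sensors) < config.artifact_rate
                for s in np.nonzero(hit)[0]:
                    _inject_artifact(
                        trials[t, s], config.sfreq, config.artifact_amplitude
                    )
                    artifacts.append((t, int(s)))
            rating = np.nan
            if cond in MODALITIES:
                noisy = vividness.loc[p, cond] + rng.normal(
                    0.0, config.rating_noise_sd
                )
                rating = float(np.clip(np.round(noisy), *RATING_SCALE))
            rows.append(
                {
                    "participant": p,
                    "trial_index": t,
                    "condition": cond,
                    "rating": rating,
                }
            )
        yield p, trials, conditions, rows, artifacts


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[SyntheticCohort, GroundTruth]:
    """Simulate a full in-memory cohort; deterministic given ``config.seed``."""
    montage, vividness, coupling_noise, _ = _cohort_latents(config)
    data: dict[int, np.ndarray] = {}
    rows = []
    artifacts: list[tuple[int, int, int]] = []
    for p, trials, _conds, prows, part_artifacts in iter_participants(config):
        data[p] = trials
        rows.extend(prows)
        artifacts.extend((p, t, s) for t, s in part_artifacts)

    cohort = SyntheticCohort(
        data=data,
        metadata=pd.DataFrame(rows),
        montage=montage,
        sfreq=config.sfreq,
        trial_duration=config.trial_duration,
    )
    truth = GroundTruth(
        vividness=vividness,
        coupling_noise=coupling_noise,
        condition_effects=list(config.condition_effects),
        vividness_couplings=list(config.vividness_couplings),
        artifacts=artifacts,
    )
    return cohort, truth


def expected_binned_power(
    config: SyntheticConfig,
    condition: str,
    band_log_offsets: list[tuple[tuple[float, float], float]] | None = None,
    montage: pd.DataFrame | None = None,
) -> np.ndarray:
    """Analytic expected 1 Hz-binned periodogram power per sensor (no trial
    gain, no filtering): the mean over each integer bin of the squared
    amplitude profile.  Exposed so tests can compare generated spectra with
    the composed generative components."""
    if montage is None:
        montage = standard_montage(config.n_sensors)
    amp = _amplitude_profile(config, montage, condition, band_log_offsets or [])
    freqs = np.fft.rfftfreq(config.n_samples, 1.0 / config.sfreq)
    bins = np.floor(freqs + 0.5).astype(int)
    gain = np.exp(config.trial_power_logsd**2 / 4.0)  # E[lognormal amp gain]^2
    out = np.full((len(montage), 40), np.nan)
    for f in range(1, 41):
        sel = bins == f
        if sel.any():
            out[:, f - 1] = (amp[:, sel] ** 2).mean(axis=1) * gain**2
    return out
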