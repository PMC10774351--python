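"""Time-series preprocessing: filter, re-reference, epoch, artifact-screen.

Pipeline order is fixed: zero-phase filtering of the full trial, average
re-referencing, extraction of the centred analysis epoch (which discards the
trial edges and any filter transients with them), then an amplitude-range
screen that flags sensor-trials whose peak-to-peak voltage exceeds a
threshold.  Flagged cells are carried as an exclusion mask and become NaN
power estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: default peak-to-peak exclusion threshold, volts (250 microvolts)
DEFAULT_RANGE_THRESHOLD = 250e-6


@dataclass
class EpochTensor:
    """Epoched voltage data for one participant.

    ``data`` is (n_trials, n_sensors, n_samples) in volts; ``conditions``
    holds one label per trial; ``exclusion_mask`` is True for (trial, sensor)
    cells rejected by the amplitude screen.
    """

    data: np.ndarray
    sfreq: float
    conditions: np.ndarray
    participant: int
    exclusion_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("EpochTensor data must be (trials, sensors, samples)")
        self.conditions = np.asarray(self.conditions)
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]


def _filter_sos(sfreq: float) -> np.ndarray:
    """Cascaded second-order sections: 6th-order Butterworth high-pass at
    1 Hz, low-pass at 100 Hz and 45-55 Hz band-stop."""
    nyq = sfreq / 2.0
    hp = signal.butter(6, 1.0, btype="highpass", fs=sfreq, output="sos")
    lp = signal.butter(6, min(100.0, 0.95 * nyq), btype="lowpass", fs=sfreq, output="sos")
    notch = signal.butter(6, [45.0, 55.0], btype="bandstop", fs=sfreq, output="sos")
    return np.vstack([hp, lp, notch])


def min_filter_length(sfreq: float) -> int:
    """Minimum number of samples `filter_timeseries` accepts (the two-pass
    filter's edge padding requirement)."""
    sos = _filter_sos(sfreq)
    return 3 * (2 * sos.shape[0] + 1) + 1


def filter_timeseries(x: np.ndarray, sfreq: float) -> np.ndarray:
    """Zero-phase (forward-backward) 1-100 Hz band-pass plus 45-55 Hz
    band-stop, applied per sensor.

    The band-pass is realised as cascaded 6th-order Butterworth high- and
    low-pass sections; applying every section forward and backward gives a
    two-pass, zero-phase response.
    """
    if sfreq <= 200.0:
        raise ValueError("sampling rate must exceed 200 Hz")
    x = np.asarray(x, float)
    need = min_filter_length(sfreq)
    if x.shape[-1] < need:
        raise ValueError(
            f"input too short for two-pass filtering: {x.shape[-1]} samples, "
            f"minimum {need}"
        )
    return signal.sosfiltfilt(_filter_sos(sfreq), x, axis=-1)


def average_reference(x: np.ndarray) -> np.ndarray:
    """Re-reference to the instantaneous mean over all sensors.

    After referencing the mean across sensors is zero at every sample.
    """
    x = np.asarray(x, float)
    if x.shape[-2] < 2:
        raise ValueError("average reference requires at least 2 sensors")
    return x - x.mean(axis=-2, keepdims=True)


def epoch_trial(
    x: np.ndarray, sfreq: float, trial_duration: float, epoch_duration: float
) -> np.ndarray:
    """Extract the centred analysis window from a full trial.

    Drops (trial - epoch)/2 seconds from each end; when the offset is a
    fractional number of samples the left offset is floored.
    """
    if epoch_duration > trial_duration:
        raise ValueError("epoch_duration must not exceed trial_duration")
    x = np.asarray(x)
    n_epoch = int(round(epoch_duration * sfreq))
    offset = int(np.floor((trial_duration - epoch_duration) / 2.0 * sfreq))
    if offset + n_epoch > x.shape[-1]:
        raise ValueError("trial shorter than trial_duration * sfreq samples")
    return x[..., offset : offset + n_epoch]


def amplitude_exclusion_mask(
    epochs: EpochTensor | np.ndarray,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> np.ndarray:
    """Boolean (trial, sensor) mask: True where the within-epoch peak-to-peak
    amplitude exceeds ``range_threshold`` volts."""
    if range_threshold <= 0:
        raise ValueError("range_threshold must be positive")
    data = epochs.data if isinstance(epochs, EpochTensor) else np.asarray(epochs)
    span = data.max(axis=-1) - data.min(axis=-1)
    return span > range_threshold


def preprocess_trials(
    trials: np.ndarray,
    sfreq: float,
    conditions: np.ndarray,
    participant: int,
    trial_duration: float | None = None,
    epoch_duration: float = 9.0,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> EpochTensor:
    """Filter -> average reference -> centred epoch -> amplitude screen for
    one participant's (n_trials, n_sensors, n_samples) raw array."""
    trials = np.asarray(trials, float)
    if trial_duration is None:
        trial_duration = trials.shape[-1] / sfreq
    filtered = filter_timeseries(trials, sfreq)
    referenced = average_reference(filtered)
    epoched = epoch_trial(referenced, sfreq, trial_duration, epoch_duration)
    out = EpochTensor(
        data=epoched, sfreq=sfreq, conditions=conditions, participant=participant
    )
    out.exclusion_mask = amplitude_exclusion_mask(out, range_threshold)
    return out


def preprocess_cohort(
    cohort,
    epoch_duration: float | None = None,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> dict[int, EpochTensor]:
    """Apply `preprocess_trials` to every participant of a
    :class:`~mindseye.synth.SyntheticCohort`-like object.

    ``epoch_duration`` defaults to 9/10 of the trial duration, the centred
    window that excises eye-closure/opening transients at the trial edges.
    """
    if epoch_duration is None:
        epoch_duration = 0.9 * cohort.trial_duration
    out = {}
    for p in cohort.participants:
        meta = cohort.metadata[cohort.metadata["participant"] == p].sort_values(
            "trial_index"
        )
        out[p] = preprocess_trials(
            cohort.data[p],
            cohort.sfreq,
            meta["condition"].to_numpy(),
            participant=p,
            trial_duration=cohort.trial_duration,
            epoch_duration=epoch_duration,
            range_threshold=range_threshold,
        )
    return out
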