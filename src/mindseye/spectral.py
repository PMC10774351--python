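"""Power spectral density features: bare periodogram, 1 Hz binning, tensors.

The feature of record for every downstream analysis is the per-trial,
per-sensor power spectrum of the full analysis epoch, averaged into integer
1 Hz bins from 1 to 40 Hz.  No taper and no segment averaging are applied:
the epoch is long (seconds), the binning already smooths across neighbouring
Fourier frequencies, and absolute power units cancel in all downstream
contrasts and regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochTensor

FREQS = np.arange(1, 41)


def periodogram(x: np.ndarray, sfreq: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of the un-windowed signal.

    Power at the k-th Fourier frequency (0 < k < Nyquist) is
    ``|X_k|**2 * 2 / N**2``; the DC and Nyquist terms carry no factor 2.
    With this normalisation a sinusoid of amplitude A on an exact bin has
    power A**2/2 in that bin, and the one-sided power sums to the signal's
    mean square (Parseval).  Works on any (..., time) array.
    """
    x = np.asarray(x, float)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    coeffs = np.fft.rfft(x, axis=-1)
    power = (np.abs(coeffs) ** 2) * (2.0 / n**2)
    power[..., 0] /= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    return freqs, power


def bin_power_1hz(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Average spectral power into integer 1 Hz bins, 1..40 Hz.

    A Fourier frequency belongs to the bin its value rounds to (round half
    up), i.e. bin f collects frequencies in [f - 0.5, f + 0.5).  Returns a
    (..., 40) array; a bin containing no Fourier frequency is NaN.
    """
    freqs = np.asarray(freqs, float)
    if len(freqs) > 1 and np.min(np.diff(freqs)) > 1.0 + 1e-12:
        raise ValueError("frequency resolution coarser than 1 Hz")
    power = np.asarray(power, float)
    bins = np.floor(freqs + 0.5).astype(int)
    out = np.full(power.shape[:-1] + (len(FREQS),), np.nan)
    for i, f in enumerate(FREQS):
        sel = bins == f
        if sel.any():
            out[..., i] = power[..., sel].mean(axis=-1)
    return out


@dataclass
class PSDTensor:
    """Binned power for a cohort.

    ``power`` is (participants, trials, sensors, 40) with NaN for excluded
    sensor-trials; ``conditions`` is (participants, trials) of labels;
    ``participants`` maps the first axis to participant ids.  ``ratings``
    (optional) is the tidy trial metadata with vividness ratings.
    """

    power: np.ndarray
    conditions: np.ndarray
    participants: list[int]
    freqs: np.ndarray = None  # type: ignore[assignment]
    ratings: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.freqs is None:
            self.freqs = FREQS.copy()
        self.power = np.asarray(self.power, float)
        if self.power.ndim != 4:
            raise ValueError(
                "power must be (participants, trials, sensors, freq_bins)"
            )
        with np.errstate(invalid="ignore"):
            if bool(np.any(self.power < 0)):
                raise ValueError("power must be non-negative (or NaN)")

    @property
    def n_participants(self) -> int:
        return self.power.shape[0]

    def participant_slice(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        """(trials, sensors, 40) power and trial labels for participant p."""
        i = self.participants.index(p)
        return self.power[i], self.conditions[i]

    def mean_rating(self, modality: str) -> pd.Series:
        """Per-participant mean vividness rating for one imagery modality."""
        if self.ratings is None:
            raise ValueError("no trial ratings attached to this PSDTensor")
        sel = self.ratings[self.ratings["condition"] == modality]
        return sel.groupby("participant")["rating"].mean()


def compute_trial_psd(epochs: EpochTensor) -> np.ndarray:
    """(trials, sensors, 40) binned power for one participant; sensor-trials
    flagged in the exclusion mask are NaN across all 40 bins."""
    freqs, power = periodogram(epochs.data, epochs.sfreq)
    binned = bin_power_1hz(freqs, power)
    binned[epochs.exclusion_mask] = np.nan
    return binned


def compute_psd_tensor(epochs: dict[int, EpochTensor] | EpochTensor,
                       ratings: pd.DataFrame | None = None) -> PSDTensor:
    """Binned-PSD tensor for a cohort (or a single participant's epochs)."""
    if isinstance(epochs, EpochTensor):
        epochs = {epochs.participant: epochs}
    participants = sorted(epochs)
    power = np.stack([compute_trial_psd(epochs[p]) for p in participants])
    conditions = np.stack([epochs[p].conditions for p in participants])
    return PSDTensor(
        power=power,
        conditions=conditions,
        participants=participants,
        ratings=ratings,
    )


def psd_long_table(psd: PSDTensor) -> pd.DataFrame:
    """Long-form (participant, trial, condition, sensor, freq, power) table."""
    P, T, S, F = psd.power.shape
    part = np.repeat(psd.participants, T * S * F)
    trial = np.tile(np.repeat(np.arange(T), S * F), P)
    cond = np.repeat(psd.conditions.reshape(-1), S * F)
    sensor = np.tile(np.repeat(np.arange(S), F), P * T)
    freq = np.tile(psd.freqs, P * T * S)
    return pd.DataFrame(
        {
            "participant": part,
            "trial": trial,
            "condition": cond,
            "sensor": sensor,
            "freq": freq,
            "power": psd.power.reshape(-1),
        }
    )
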