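"""Per-participant condition decoding from binned PSD features.

A deliberately simple nearest-signature classifier: each held-out trial is
assigned to the condition whose mean training-set PSD (the "conditional
signature") it matches most closely under a sum of unsigned differences —
no rescaling, no Euclidean metric.  Leave-one-trial-out cross-validation
gives a per-participant success rate, whose significance is assessed with a
within-participant label-shuffle test.  Trials are never compared across
participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes
from .spectral import PSDTensor
from .synth import CONDITIONS

CHANCE_RATE = 1.0 / len(CONDITIONS)


@dataclass
class DecodingResult:
    """Leave-one-out decoding outcome for a single participant."""

    participant: int
    success_rate: float
    n_trials: int  # decodable trials (denominator)
    confusion: np.ndarray  # (decoded, actual) proportions, columns sum to 1
    shuffle_p: float | None = None


def condition_signatures(
    train_psds: np.ndarray, train_labels: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-condition mean (sensor, freq) PSD over training trials, NaN-aware."""
    out = {}
    for cond in CONDITIONS:
        sel = train_labels == cond
        if not sel.any():
            raise ValueError(f"no training trials for condition {cond!r}")
        with np.errstate(invalid="ignore"):
            out[cond] = np.nanmean(train_psds[sel], axis=0)
    return out


def decode_trial(
    trial_psd: np.ndarray, signatures: dict[str, np.ndarray]
) -> str | None:
    """Label of the signature with the smallest sum of absolute residuals.

    Only cells finite in both the trial and the signature contribute.  Exact
    ties go to the first condition in the fixed (audio, visual, rest) order.
    Returns None when no finite cell is shared with some signature (the
    trial is undecodable).
    """
    best, best_d = None, np.inf
    for cond in CONDITIONS:
        sig = signatures[cond]
        valid = np.isfinite(trial_psd) & np.isfinite(sig)
        if not valid.any():
            return None
        d = np.abs(trial_psd[valid] - sig[valid]).sum()
        if d < best_d:
            best, best_d = cond, d
    return best


def _loo_distances(psds: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(trials, conditions) sums of absolute residuals against
    leave-one-out signatures, vectorised over trials.

    NaN cells are excluded per-cell from both signature means and distances.
    """
    T = psds.shape[0]
    X = psds.reshape(T, -1)
    finite = np.isfinite(X)
    Xz = np.where(finite, X, 0.0)

    onehot = np.stack([labels == c for c in CONDITIONS]).astype(float)  # (C, T)
    sums = onehot @ Xz  # (C, cells)
    counts = onehot @ finite  # (C, cells)

    dists = np.empty((T, len(CONDITIONS)))
    for ci in range(len(CONDITIONS)):
        # remove the held-out trial from its own condition's signature
        drop = onehot[ci][:, None] * Xz * finite  # (T, cells)
        cnt = counts[ci][None, :] - onehot[ci][:, None] * finite
        with np.errstate(invalid="ignore", divide="ignore"):
            sig = (sums[ci][None, :] - drop) / cnt  # NaN where cnt == 0
        resid = np.abs(X - sig)
        valid = finite & np.isfinite(sig)
        dists[:, ci] = np.where(valid, resid, 0.0).sum(axis=1)
        dists[np.all(~valid, axis=1), ci] = np.nan
    return dists


def leave_one_out_decode(
    psds: np.ndarray, labels: np.ndarray, participant: int = 0
) -> DecodingResult:
    """Leave-one-trial-out decoding for one participant.

    ``psds`` is (trials, sensors, freqs); every trial is decoded against
    signatures built from all remaining trials.  Trials with no usable
    features are excluded from the success-rate denominator.
    """
    labels = np.asarray(labels)
    for cond in CONDITIONS:
        if (labels == cond).sum() < 2:
            raise ValueError(
                f"need >= 2 trials per condition, got "
                f"{(labels == cond).sum()} for {cond!r}"
            )
    dists = _loo_distances(np.asarray(psds, float), labels)
    # a trial must share finite cells with *every* signature to be decodable
    decodable = ~np.any(np.isnan(dists), axis=1)
    decoded_idx = np.nanargmin(np.where(np.isnan(dists), np.inf, dists), axis=1)

    actual_idx = np.array([CONDITIONS.index(c) for c in labels])
    confusion = np.zeros((len(CONDITIONS), len(CONDITIONS)))
    correct = 0
    for t in np.nonzero(decodable)[0]:
        confusion[decoded_idx[t], actual_idx[t]] += 1
        correct += decoded_idx[t] == actual_idx[t]
    col = confusion.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(col > 0, confusion / col, np.nan)
    n = int(decodable.sum())
    return DecodingResult(
        participant=participant,
        success_rate=correct / n if n else np.nan,
        n_trials=n,
        confusion=confusion,
    )


def decoding_shuffle_test(
    psds: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    participant: int = 0,
) -> DecodingResult:
    """Leave-one-out decoding plus a label-shuffle significance test.

    Condition labels are randomly reassigned across the participant's trials
    ``n_shuffles`` times and the full leave-one-out decode re-run each time;
    the reported p-value is the add-one-corrected proportion of shuffles
    whose success rate is at least the actual one.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    result = leave_one_out_decode(psds, labels, participant)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(len(labels))
        shuf = leave_one_out_decode(psds, labels[perm], participant)
        if shuf.success_rate >= result.success_rate:
            exceed += 1
    result.shuffle_p = (1.0 + exceed) / (n_shuffles + 1.0)
    return result


class ConditionDecoder:
    """Cohort-level nearest-signature decoding model.

    Parameters
    ----------
    psd : PSDTensor
        Binned PSD features with per-trial condition labels.

    ``fit`` runs the leave-one-out decode (optionally with the shuffle test)
    for each participant and returns a :class:`DecodingResults`.
    """

    def __init__(self, psd: PSDTensor):
        self.psd = psd

    def fit(
        self,
        n_shuffles: int | None = 1000,
        rng: np.random.Generator | int | None = None,
        alpha: float = 0.05,
    ) -> "DecodingResults":
        rng = np.random.default_rng(rng)
        results = []
        for p in self.psd.participants:
            power, labels = self.psd.participant_slice(p)
            if n_shuffles:
                res = decoding_shuffle_test(
                    power, labels, n_shuffles=n_shuffles, rng=rng, participant=p
                )
            else:
                res = leave_one_out_decode(power, labels, participant=p)
            results.append(res)
        return DecodingResults(results, alpha=alpha, psd=self.psd)


class DecodingResults:
    """Per-participant decoding outcomes plus cohort-level inference."""

    def __init__(self, results: list[DecodingResult], alpha: float = 0.05,
                 psd: PSDTensor | None = None):
        self.results = results
        self.alpha = alpha
        self.psd = psd

    @property
    def success_rates(self) -> np.ndarray:
        return np.array([r.success_rate for r in self.results])

    @property
    def shuffle_ps(self) -> np.ndarray:
        return np.array(
            [np.nan if r.shuffle_p is None else r.shuffle_p for r in self.results]
        )

    @property
    def mean_success(self) -> float:
        return float(np.nanmean(self.success_rates))

    @property
    def proportion_significant(self) -> float:
        """Proportion of participants whose shuffle p is below alpha."""
        ps = self.shuffle_ps
        return float(np.mean(ps[~np.isnan(ps)] < self.alpha))

    @property
    def mean_confusion(self) -> np.ndarray:
        """(decoded, actual) confusion proportions averaged over participants."""
        return np.nanmean(np.stack([r.confusion for r in self.results]), axis=0)

    def group_test(self) -> tuple[float, float, bayes.BFResult]:
        """One-sample t and JZS BF of participant success rates against the
        1/3 chance rate.  Returns (t, two-sided p, BFResult)."""
        from scipy import stats

        rates = self.success_rates[~np.isnan(self.success_rates)]
        t, p = stats.ttest_1samp(rates, CHANCE_RATE)
        bf = bayes.jzs_bf_one_sample(rates, CHANCE_RATE)
        return float(t), float(p), bf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [r.participant for r in self.results],
                "success_rate": self.success_rates,
                "p": self.shuffle_ps,
                "n_trials": [r.n_trials for r in self.results],
            }
        )

    def rating_correlation(self, modality: str) -> tuple[float, float]:
        """Pearson correlation between decoding success and mean vividness
        ratings for one modality (a check that task compliance does not
        covary with reported imagery intensity)."""
        from .cluster import rating_correlation

        if self.psd is None or self.psd.ratings is None:
            raise ValueError("results carry no rating metadata")
        ratings = self.psd.mean_rating(modality)
        rates = pd.Series(
            self.success_rates, index=[r.participant for r in self.results]
        )
        common = ratings.index.intersection(rates.index)
        return rating_correlation(
            rates.loc[common].to_numpy(), ratings.loc[common].to_numpy()
        )

    def summary(self) -> str:
        n = len(self.results)
        lines = [
            "Leave-one-trial-out condition decoding",
            "=" * 46,
            f"participants               {n}",
            f"mean success rate          {self.mean_success:.3f}"
            f"   (chance {CHANCE_RATE:.3f})",
        ]
        if not np.all(np.isnan(self.shuffle_ps)):
            lines.append(
                f"decodable at p < {self.alpha:.2f}     "
                f"{100 * self.proportion_significant:.0f}% of participants"
            )
        if n >= 2 and np.isfinite(self.success_rates).sum() >= 2:
            t, p, bf = self.group_test()
            lines.append(
                f"group test vs chance       t({n - 1}) = {t:.2f}, "
                f"p = {p:.2g}, BF10 = {bf.bf10:.3g}"
            )
        return "\n".join(lines)
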