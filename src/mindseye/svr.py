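"""Per-frequency vividness prediction by cross-validated linear SVR.

For each oscillation frequency, a single global feature per participant —
the imagery-minus-rest PSD difference averaged over all sensors — is used to
predict the participant's mean vividness rating with linear epsilon-
insensitive support-vector regression.  The procedure repeats a four-fold
cross validation 125 times with fresh random partitions, recording the
Pearson correlation between predicted and actual ratings of each held-out
fold (500 R-values), alongside a matched run in which ratings are randomly
reassigned before each partition (500 shuffled chance R-values).  A JZS
Bayes-factor t-test per frequency quantifies the evidence that actual and
chance R-values differ; runs of consecutive frequencies with extreme
evidence (BF10 >= 100) are reported as predictive bands.

Note the 500 fold-wise R-values are not independent samples (folds share
participants across iterations); the Bayes-factor t-test treats them as if
they were, which makes the evidence scale anticonservative.  This is a
property of the procedure itself and is preserved as such; see the methods
note for its calibration behaviour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from . import bayes
from .cluster import condition_mean_psd
from .spectral import PSDTensor
from .synth import MODALITIES

logger = logging.getLogger(__name__)

BF_EXTREME = 100.0


def compute_difference_psd(psd: PSDTensor, modality: str) -> np.ndarray:
    """(participants, sensors, freqs) imagery-minus-rest mean PSD.

    NaN wherever either condition mean is missing.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return condition_mean_psd(psd, modality) - condition_mean_psd(psd, "rest")


def compute_global_difference(
    psd: PSDTensor | np.ndarray, modality: str | None = None
) -> np.ndarray:
    """(participants, freqs) sensor-averaged difference PSD (NaN-aware mean).

    Accepts either a PSDTensor plus modality, or a precomputed
    (participants, sensors, freqs) difference array.  Participants with no
    finite value at any frequency (a missing condition) are dropped with a
    warning by the caller that owns the participant index.
    """
    if isinstance(psd, PSDTensor):
        diff = compute_difference_psd(psd, modality)
    else:
        diff = np.asarray(psd, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(diff, axis=1)


def _fold_r(pred: np.ndarray, actual: np.ndarray) -> float:
    """Pearson R between predictions and held-out ratings; degenerate folds
    (no variance on either side) are recorded as 0."""
    if np.std(pred) < 1e-12 or np.std(actual) < 1e-12:
        logger.debug("degenerate fold (zero variance); recording R = 0")
        return 0.0
    return float(np.corrcoef(pred, actual)[0, 1])


def _cv_rvalues(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int,
    k: int,
    rng: np.random.Generator,
    shuffle: bool,
    C: float,
    epsilon: float,
) -> np.ndarray:
    n = len(x)
    group = n // k
    out = np.empty(n_iter * k)
    for it in range(n_iter):
        yy = rng.permutation(y) if shuffle else y
        order = rng.permutation(n)
        for f in range(k):
            test = order[f * group : (f + 1) * group]
            train = np.concatenate([order[: f * group], order[(f + 1) * group :]])
            xm, xs = x[train].mean(), x[train].std()
            ym, ys = yy[train].mean(), yy[train].std()
            xs = xs if xs > 0 else 1.0
            ys_ = ys if ys > 0 else 1.0
            model = SVR(kernel="linear", C=C, epsilon=epsilon)
            model.fit(((x[train] - xm) / xs)[:, None], (yy[train] - ym) / ys_)
            pred = model.predict(((x[test] - xm) / xs)[:, None])
            out[it * k + f] = _fold_r(pred, yy[test])
    return out


def svr_cv_rvalues(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = 125,
    k: int = 4,
    rng: np.random.Generator | int | None = None,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> np.ndarray:
    """n_iter x k fold-wise R-values for predicting ``y`` from the single
    feature ``x``.

    Each iteration draws a fresh random partition of the participants into
    ``k`` equal groups; each fold trains a linear epsilon-SVR (feature and
    target z-scored with training-fold statistics) on k-1 groups and scores
    the held-out group by the Pearson correlation between predicted and
    actual ratings.
    """
    x, y = _check_xy(x, y, k)
    rng = np.random.default_rng(rng)
    return _cv_rvalues(x, y, n_iter, k, rng, False, C, epsilon)


def shuffled_null_rvalues(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = 125,
    k: int = 4,
    rng: np.random.Generator | int | None = None,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> np.ndarray:
    """Matched chance distribution: identical procedure with the ratings
    randomly reassigned across participants before every iteration."""
    x, y = _check_xy(x, y, k)
    rng = np.random.default_rng(rng)
    return _cv_rvalues(x, y, n_iter, k, rng, True, C, epsilon)


def _check_xy(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("feature and rating vectors must have equal length")
    if len(x) % k != 0:
        raise ValueError(
            f"number of participants ({len(x)}) must be divisible by the fold "
            f"count ({k}); drop participants to a multiple of {k}"
        )
    if len(x) < 2 * k:
        raise ValueError("need at least two participants per fold")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("features and ratings must be finite")
    return x, y


@dataclass
class FrequencyBand:
    """Contiguous run of frequencies with extreme predictive evidence."""

    lo: int  # Hz, inclusive
    hi: int  # Hz, inclusive
    min_bf10: float

    def overlaps(self, band: tuple[float, float]) -> bool:
        return self.lo <= band[1] and self.hi >= band[0]


def frequency_band_clusters(
    bf10: np.ndarray, threshold: float = BF_EXTREME, min_len: int = 2,
    freqs: np.ndarray | None = None,
) -> list[FrequencyBand]:
    """Maximal runs of >= ``min_len`` consecutive frequencies whose BF10
    meets ``threshold``, annotated with the minimum BF within the run."""
    bf10 = np.asarray(bf10, float)
    if freqs is None:
        freqs = np.arange(1, len(bf10) + 1)
    above = bf10 >= threshold
    bands: list[FrequencyBand] = []
    start = None
    for i in range(len(bf10) + 1):
        if i < len(bf10) and above[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                bands.append(
                    FrequencyBand(
                        lo=int(freqs[start]),
                        hi=int(freqs[i - 1]),
                        min_bf10=float(np.min(bf10[start:i])),
                    )
                )
            start = None
    return bands


@dataclass
class SVRFrequencyResult:
    """Per-frequency actual and shuffled R-values with the BF10 comparing
    them."""

    freq: int
    actual_r: np.ndarray
    shuffled_r: np.ndarray
    bf: bayes.BFResult

    @property
    def bf10(self) -> float:
        return self.bf.bf10


class VividnessSVR:
    """Per-frequency SVR prediction of vividness ratings (one modality).

    Parameters
    ----------
    global_difference : (participants, freqs) array
        Sensor-averaged imagery-minus-rest PSD differences.
    ratings : (participants,) array
        Mean vividness rating per participant.
    """

    def __init__(
        self,
        global_difference: np.ndarray,
        ratings: np.ndarray,
        C: float = 1.0,
        epsilon: float = 0.1,
        freqs: np.ndarray | None = None,
    ):
        self.x = np.asarray(global_difference, float)
        self.y = np.asarray(ratings, float).ravel()
        if self.x.ndim != 2 or self.x.shape[0] != len(self.y):
            raise ValueError(
                "global_difference must be (participants, freqs) matching ratings"
            )
        self.C = C
        self.epsilon = epsilon
        self.freqs = np.arange(1, self.x.shape[1] + 1) if freqs is None else freqs

    @classmethod
    def from_psd(cls, psd: PSDTensor, modality: str, **kw) -> "VividnessSVR":
        """Build from a PSDTensor with rating metadata; participants missing
        a condition or a rating are dropped with a warning."""
        gd = compute_global_difference(psd, modality)
        ratings = psd.mean_rating(modality)
        keep = []
        for i, p in enumerate(psd.participants):
            if np.all(np.isfinite(gd[i])) and p in ratings.index and np.isfinite(
                ratings[p]
            ):
                keep.append(i)
            else:
                warnings.warn(
                    f"participant {p} dropped from {modality} SVR "
                    "(missing condition data or ratings)"
                )
        y = np.array([ratings[psd.participants[i]] for i in keep])
        return cls(gd[keep], y, freqs=psd.freqs, **kw)

    def fit(
        self,
        n_iter: int = 125,
        k: int = 4,
        rng: np.random.Generator | int | None = None,
        bf_threshold: float = BF_EXTREME,
    ) -> "SVRResults":
        rng = np.random.default_rng(rng)
        results = []
        for j, f in enumerate(self.freqs):
            x = self.x[:, j]
            actual = svr_cv_rvalues(
                x, self.y, n_iter, k, rng, C=self.C, epsilon=self.epsilon
            )
            shuffled = shuffled_null_rvalues(
                x, self.y, n_iter, k, rng, C=self.C, epsilon=self.epsilon
            )
            bf = bayes.jzs_bf_two_sample(actual, shuffled)
            results.append(
                SVRFrequencyResult(
                    freq=int(f), actual_r=actual, shuffled_r=shuffled, bf=bf
                )
            )
        return SVRResults(results, bf_threshold=bf_threshold)


class SVRResults:
    """Per-frequency SVR outcomes and the derived predictive bands."""

    def __init__(self, results: list[SVRFrequencyResult],
                 bf_threshold: float = BF_EXTREME):
        self.results = results
        self.bf_threshold = bf_threshold

    @property
    def freqs(self) -> np.ndarray:
        return np.array([r.freq for r in self.results])

    @property
    def bf10(self) -> np.ndarray:
        return np.array([r.bf10 for r in self.results])

    @property
    def mean_actual_r(self) -> np.ndarray:
        return np.array([r.actual_r.mean() for r in self.results])

    @property
    def mean_shuffled_r(self) -> np.ndarray:
        return np.array([r.shuffled_r.mean() for r in self.results])

    def predictive_bands(self, threshold: float | None = None) -> list[FrequencyBand]:
        thr = self.bf_threshold if threshold is None else threshold
        return frequency_band_clusters(self.bf10, thr, freqs=self.freqs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq": self.freqs,
                "mean_actual_R": self.mean_actual_r,
                "mean_shuffled_R": self.mean_shuffled_r,
                "bf10": self.bf10,
            }
        )

    def summary(self) -> str:
        bands = self.predictive_bands()
        lines = [
            "Per-frequency SVR prediction of vividness",
            "=" * 46,
            f"frequencies tested   {len(self.results)}"
            f" ({self.results[0].freq}-{self.results[-1].freq} Hz)",
            f"R-values per freq    {len(self.results[0].actual_r)} actual"
            f" + {len(self.results[0].shuffled_r)} shuffled",
            f"predictive bands (BF10 >= {self.bf_threshold:g}, >= 2 consecutive Hz):",
        ]
        if not bands:
            lines.append("  none")
        for b in bands:
            lines.append(
                f"  {b.lo}-{b.hi} Hz   minimum BF10 = {b.min_bf10:.3g}"
            )
        return "\n".join(lines)
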