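"""Group-level cluster-based permutation tests over sensor x frequency space.

Per-participant condition-mean PSDs are compared between two conditions with
paired t-tests at every (sensor, frequency) cell.  Cells with uncorrected
p < alpha are clustered by spatio-frequency proximity (sensor adjacency from
the montage, frequency adjacency |df| <= 1 Hz), positive and negative t
separately; each cluster's mass is the sum of its t values.  Family-wise
significance comes from the permutation distribution of the maximum
|cluster mass| under random within-participant condition exchanges
(equivalently, sign flips of the paired differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import sparse, stats

from .montage import delaunay_adjacency


@dataclass
class AdjacencySpec:
    """Neighbourhood structure over (sensor, frequency) points.

    ``sensor``: symmetric boolean sensor x sensor matrix, False diagonal.
    Frequencies are adjacent when they differ by at most ``freq_step`` bins.
    """

    sensor: np.ndarray
    freq_step: int = 1

    def __post_init__(self) -> None:
        self.sensor = np.asarray(self.sensor, bool)
        if self.sensor.ndim != 2 or self.sensor.shape[0] != self.sensor.shape[1]:
            raise ValueError("sensor adjacency must be square")
        if not (self.sensor == self.sensor.T).all():
            raise ValueError("sensor adjacency must be symmetric")
        if self.sensor.diagonal().any():
            raise ValueError("sensor adjacency must have an empty diagonal")

    @classmethod
    def from_montage(cls, montage) -> "AdjacencySpec":
        return cls(sensor=delaunay_adjacency(montage))

    def point_graph(self, n_freqs: int) -> sparse.csr_matrix:
        """Sparse adjacency over the flattened (sensor, freq) grid: points
        are neighbours when the sensors are identical-or-adjacent and the
        frequencies within ``freq_step``, excluding self-pairs."""
        S = self.sensor.shape[0]
        sensor_or_self = self.sensor | np.eye(S, dtype=bool)
        rows, cols = [], []
        si, sj = np.nonzero(sensor_or_self)
        for df in range(-self.freq_step, self.freq_step + 1):
            f = np.arange(n_freqs)
            g = f + df
            ok = (g >= 0) & (g < n_freqs)
            f, g = f[ok], g[ok]
            # all sensor pairs x all frequency pairs
            r = (si[:, None] * n_freqs + f[None, :]).ravel()
            c = (sj[:, None] * n_freqs + g[None, :]).ravel()
            rows.append(r)
            cols.append(c)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        keep = rows != cols
        n = S * n_freqs
        return sparse.csr_matrix(
            (np.ones(keep.sum(), bool), (rows[keep], cols[keep])), shape=(n, n)
        )


def condition_mean_psd(psd, condition: str) -> np.ndarray:
    """(participants, sensors, freqs) trial-mean power for one condition,
    NaN-aware per cell (mean over the unmasked trials)."""
    P, T, S, F = psd.power.shape
    out = np.full((P, S, F), np.nan)
    for i in range(P):
        sel = psd.conditions[i] == condition
        if sel.any():
            with np.errstate(invalid="ignore"):
                out[i] = np.nanmean(psd.power[i, sel], axis=0)
    return out


def outlier_interpolate(
    means: np.ndarray, adjacency: AdjacencySpec, sd_limit: float = 3.0
) -> np.ndarray:
    """Replace per-cell group outliers by spatial interpolation.

    For every (sensor, freq) cell, participants whose value lies more than
    ``sd_limit`` standard deviations from the group mean are replaced by the
    mean of that participant's value at adjacent sensors (same frequency);
    with no finite neighbour the cell becomes NaN.  Neighbour values are the
    original (pre-replacement) ones.
    """
    x = np.asarray(means, float)
    if np.isfinite(x).sum(axis=0).min() < 3:
        raise ValueError("need >= 3 participants with data per cell")
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
        outlier = np.abs(x - mu) > sd_limit * sd
    outlier &= np.isfinite(x)
    out = x.copy()
    adj = adjacency.sensor
    for p, s, f in zip(*np.nonzero(outlier)):
        neigh = x[p, adj[s], f]
        neigh = neigh[np.isfinite(neigh)]
        out[p, s, f] = neigh.mean() if len(neigh) else np.nan
    return out


def paired_t_map(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise paired t and two-sided p over the participant axis.

    NaN pairs are dropped per cell; cells with fewer than 2 complete pairs
    are NaN.  A zero-variance nonzero mean difference yields t = +-inf,
    p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shapes")
    d = a - b
    finite = np.isfinite(d)
    n = finite.sum(axis=0)
    dz = np.where(finite, d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = dz.sum(axis=0) / n
        var = np.where(finite, (dz - mean) ** 2, 0.0).sum(axis=0) / np.maximum(
            n - 1, 1
        )
        t = mean / np.sqrt(var / n)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 1, 1))
    with np.errstate(invalid="ignore"):
        zero_var = (var == 0) & (n >= 2)
        t = np.where(zero_var & (mean != 0), np.sign(mean) * np.inf, t)
        t = np.where(zero_var & (mean == 0), 0.0, t)
        p = np.where(zero_var, np.where(mean != 0, 0.0, 1.0), p)
    t = np.where(n < 2, np.nan, t)
    p = np.where(n < 2, np.nan, p)
    return t, p


@dataclass
class Cluster:
    """One supra-threshold connected component."""

    points: list[tuple[int, int]]  # (sensor, freq-index) members
    sign: int
    mass: float
    p: float | None = None

    @property
    def freq_range(self) -> tuple[int, int]:
        fs = [f for _, f in self.points]
        return min(fs) + 1, max(fs) + 1  # integer Hz (freq index 0 is 1 Hz)


def form_clusters(
    threshold_map: np.ndarray,
    t_map: np.ndarray,
    adjacency: AdjacencySpec,
    _graph: sparse.csr_matrix | None = None,
) -> list[Cluster]:
    """Connected components of supra-threshold points, split by t sign.

    Components are connected under the sensor x frequency point graph; the
    mass of a component is the sum of its member t values.
    """
    threshold_map = np.asarray(threshold_map, bool)
    t_map = np.asarray(t_map, float)
    S, F = t_map.shape
    graph = adjacency.point_graph(F) if _graph is None else _graph
    clusters: list[Cluster] = []
    for sign in (1, -1):
        with np.errstate(invalid="ignore"):
            mask = threshold_map & ((t_map > 0) if sign > 0 else (t_map < 0))
        idx = np.nonzero(mask.ravel())[0]
        if len(idx) == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            pts = [(int(i // F), int(i % F)) for i in members]
            mass = float(np.sum(t_map.ravel()[members]))
            clusters.append(Cluster(points=pts, sign=sign, mass=mass))
    clusters.sort(key=lambda cl: -abs(cl.mass))
    return clusters


@dataclass
class ClusterResult:
    """Observed clusters with permutation p-values and the underlying maps."""

    clusters: list[Cluster]
    t_map: np.ndarray
    threshold_map: np.ndarray
    null_max_mass: np.ndarray
    n_permutations: int
    alpha: float = 0.05

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p < self.alpha]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sign": [c.sign for c in self.clusters],
                "mass": [c.mass for c in self.clusters],
                "p": [c.p for c in self.clusters],
                "n_points": [len(c.points) for c in self.clusters],
                "freq_lo": [c.freq_range[0] for c in self.clusters],
                "freq_hi": [c.freq_range[1] for c in self.clusters],
            }
        )

    def summary(self) -> str:
        lines = [
            "Cluster-based permutation test",
            "=" * 46,
            f"permutations     {self.n_permutations}",
            f"clusters found   {len(self.clusters)}"
            f" ({len(self.significant)} with p < {self.alpha})",
        ]
        for c in self.clusters[:10]:
            lo, hi = c.freq_range
            lines.append(
                f"  {'+' if c.sign > 0 else '-'} mass {c.mass:10.1f}  "
                f"{len(c.points):4d} points  {lo}-{hi} Hz  p = {c.p:.4g}"
            )
        return "\n".join(lines)


def _max_cluster_mass(
    diffs: np.ndarray,
    adjacency: AdjacencySpec,
    alpha: float,
    graph: sparse.csr_matrix | None = None,
) -> float:
    """Maximum |cluster mass| of the paired-difference array (participants,
    sensors, freqs) against zero."""
    t, p = paired_t_map(diffs, np.zeros_like(diffs))
    with np.errstate(invalid="ignore"):
        thr = p < alpha
    clusters = form_clusters(thr, t, adjacency, _graph=graph)
    return max((abs(c.mass) for c in clusters), default=0.0)


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: AdjacencySpec,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    exact: bool = False,
) -> ClusterResult:
    """Paired cluster permutation test between condition means ``a`` and
    ``b`` (each (participants, sensors, freqs)).

    Each permutation exchanges the two condition labels within a random
    subset of participants (a sign flip of the paired differences); the
    family-wise null is the distribution of the maximum absolute cluster
    mass.  Observed cluster p-values use the add-one permutation estimator.
    With ``exact=True`` all 2^n sign patterns are enumerated instead (the
    identity included, as in the exact randomisation test).
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    n_part = d.shape[0]

    graph = adjacency.point_graph(d.shape[2])
    t_map, p_map = paired_t_map(a, b)
    with np.errstate(invalid="ignore"):
        threshold_map = p_map < alpha
    clusters = form_clusters(threshold_map, t_map, adjacency, _graph=graph)

    if exact:
        signs_iter = product([1.0, -1.0], repeat=n_part)
        n_perm = 2**n_part
    else:
        signs_iter = (
            rng.choice([1.0, -1.0], size=n_part) for _ in range(n_permutations)
        )
        n_perm = n_permutations
    null = np.empty(n_perm)
    for i, signs in enumerate(signs_iter):
        flipped = d * np.asarray(signs)[:, None, None]
        null[i] = _max_cluster_mass(flipped, adjacency, alpha, graph=graph)

    for c in clusters:
        if exact:
            c.p = float(np.mean(null >= abs(c.mass)))
        else:
            c.p = float((1 + np.sum(null >= abs(c.mass))) / (n_perm + 1))
    return ClusterResult(
        clusters=clusters,
        t_map=t_map,
        threshold_map=threshold_map,
        null_max_mass=null,
        n_permutations=n_perm,
        alpha=alpha,
    )


class ClusterPermutationTest:
    """Model-style wrapper: build from a PSDTensor and two condition labels.

    Applies the group-level outlier interpolation to each condition's
    participant means before testing, mirroring the full analysis path.
    """

    def __init__(self, psd, condition_a: str, condition_b: str,
                 adjacency: AdjacencySpec, sd_limit: float = 3.0):
        self.adjacency = adjacency
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.a = outlier_interpolate(
            condition_mean_psd(psd, condition_a), adjacency, sd_limit
        )
        self.b = outlier_interpolate(
            condition_mean_psd(psd, condition_b), adjacency, sd_limit
        )

    def fit(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        rng: np.random.Generator | int | None = None,
    ) -> ClusterResult:
        return cluster_permutation_test(
            self.a, self.b, self.adjacency,
            n_permutations=n_permutations, alpha=alpha, rng=rng,
        )


def rating_correlation(
    ratings_a: np.ndarray, ratings_b: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between two per-participant
    rating vectors."""
    a = np.asarray(ratings_a, float)
    b = np.asarray(ratings_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in ratings")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
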