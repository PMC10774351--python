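"""Optional figures: group PSD curves, Bayes-factor spectra, sensor maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectral import PSDTensor
from .synth import CONDITIONS


def group_psd(psd: PSDTensor):
    """Group-mean binned power per condition, averaged over sensors."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond in CONDITIONS:
        curves = []
        for i in range(psd.n_participants):
            sel = psd.conditions[i] == cond
            if sel.any():
                curves.append(np.nanmean(psd.power[i, sel], axis=(0, 1)))
        if curves:
            ax.plot(psd.freqs, np.nanmean(curves, axis=0), label=cond)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    return fig


def bf_spectrum(svr_results):
    """BF10 as a function of frequency with the extreme-evidence line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bf = np.clip(svr_results.bf10, 1e-3, 1e300)
    ax.plot(svr_results.freqs, bf, marker="o", ms=3)
    ax.axhline(svr_results.bf_threshold, color="k", lw=2)
    ax.set_yscale("log")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("BF$_{10}$")
    fig.tight_layout()
    return fig


def sensor_map(values: np.ndarray, montage, ax=None):
    """Scatter of per-sensor values on the 2-D projected montage."""
    from .montage import project_2d

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pos = project_2d(montage)
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, cmap="RdBu_r", s=60)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax.figure
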