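"""Sensor montages: electrode positions, 2-D projection and spatial adjacency.

EEG sensors live on (approximately) a sphere around the head.  Cluster-based
statistics over sensor x frequency space need a notion of which sensors are
spatial neighbours; we obtain one by projecting the 3-D electrode positions to
a 2-D plane (azimuthal equidistant projection, the standard "topomap" view)
and taking the Delaunay triangulation of the projected points.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay


def standard_montage(n_sensors: int = 64, name: str = "biosemi64") -> pd.DataFrame:
    """Standard electrode positions as a DataFrame (name, x, y, z) in metres.

    Positions come from the montage files bundled with :mod:`mne` (head
    coordinate frame: +x right, +y anterior, +z superior).  ``n_sensors``
    other than the montage's full complement selects an evenly spaced subset,
    which is useful for small simulated cohorts.
    """
    import mne

    mont = mne.channels.make_standard_montage(name)
    pos = mont.get_positions()["ch_pos"]
    names = list(pos)
    xyz = np.array([pos[ch] for ch in names], float)
    if n_sensors > len(names):
        raise ValueError(
            f"montage {name!r} has only {len(names)} electrodes, "
            f"{n_sensors} requested"
        )
    if n_sensors < len(names):
        idx = np.linspace(0, len(names) - 1, n_sensors).round().astype(int)
        names = [names[i] for i in idx]
        xyz = xyz[idx]
    return pd.DataFrame(
        {"name": names, "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]}
    )


def read_montage(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited ``name x y z`` electrode-position file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["name", "x", "y", "z"])
    if df[["x", "y", "z"]].isna().any().any():
        raise ValueError(f"malformed montage file: {path}")
    return df


def write_montage(montage: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in montage.itertuples(index=False):
            fh.write(f"{row.name} {row.x:.6f} {row.y:.6f} {row.z:.6f}\n")


def project_2d(montage: pd.DataFrame) -> np.ndarray:
    """Azimuthal equidistant projection of electrode positions to 2-D.

    The sphere is centred on the mean position; the vertex (Cz direction,
    +z) maps to the origin and arc length from the vertex is preserved.
    """
    xyz = montage[["x", "y", "z"]].to_numpy(float)
    xyz = xyz - xyz.mean(axis=0)
    r = np.linalg.norm(xyz, axis=1)
    r[r == 0] = 1.0
    unit = xyz / r[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def delaunay_adjacency(montage: pd.DataFrame) -> np.ndarray:
    """Symmetric boolean sensor adjacency from a Delaunay triangulation.

    Sensors sharing an edge of any Delaunay simplex of the 2-D projected
    positions are neighbours.  No sensor is its own neighbour.
    """
    pts = project_2d(montage)
    n = len(pts)
    adj = np.zeros((n, n), dtype=bool)
    tri = Delaunay(pts)
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    adj[i, j] = True
    np.fill_diagonal(adj, False)
    return adj


def posterior_weights(montage: pd.DataFrame) -> np.ndarray:
    """Per-sensor weights in [0, 1], largest at the most posterior sensors.

    Used to give simulated condition effects an occipital-maximal topography:
    the weight is a linear ramp on the anterior-posterior (y) coordinate,
    1 at the most posterior electrode and 0 at the most anterior.
    """
    y = montage["y"].to_numpy(float)
    span = y.max() - y.min()
    if span == 0:
        return np.ones(len(y))
    return (y.max() - y) / span
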