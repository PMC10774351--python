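"""On-disk containers: HDF5 trial stores, CSV metadata, PSD tensors.

Layout of the trial container (one HDF5 file per cohort): one group per
participant (``p000``, ``p001``, ...), one float32 dataset per trial
(``trial000``, ...) holding (sensors, samples) volts, with ``sfreq``,
``trial_duration`` and per-trial ``condition`` attributes.  Trial metadata
(participant, trial_index, condition, rating) travel in a sibling CSV and
electrode positions in a whitespace-delimited text montage.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import read_montage, write_montage
from .preprocess import EpochTensor
from .spectral import PSDTensor
from .synth import SyntheticCohort


def write_cohort(
    cohort: SyntheticCohort, h5_path: str | Path,
    metadata_path: str | Path | None = None,
    montage_path: str | Path | None = None,
) -> None:
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as fh:
        fh.attrs["sfreq"] = cohort.sfreq
        fh.attrs["trial_duration"] = cohort.trial_duration
        for p in cohort.participants:
            grp = fh.create_group(f"p{p:03d}")
            meta = cohort.metadata[
                cohort.metadata["participant"] == p
            ].sort_values("trial_index")
            for t, cond in zip(meta["trial_index"], meta["condition"]):
                ds = grp.create_dataset(
                    f"trial{t:03d}", data=cohort.data[p][t].astype(np.float32)
                )
                ds.attrs["condition"] = str(cond)
    if metadata_path is None:
        metadata_path = h5_path.with_suffix(".metadata.csv")
    cohort.metadata.to_csv(metadata_path, index=False)
    if montage_path is None:
        montage_path = h5_path.with_suffix(".montage.txt")
    write_montage(cohort.montage, montage_path)


def read_cohort(
    h5_path: str | Path,
    metadata_path: str | Path | None = None,
    montage_path: str | Path | None = None,
) -> SyntheticCohort:
    h5_path = Path(h5_path)
    if metadata_path is None:
        metadata_path = h5_path.with_suffix(".metadata.csv")
    if montage_path is None:
        montage_path = h5_path.with_suffix(".montage.txt")
    metadata = pd.read_csv(metadata_path)
    montage = read_montage(montage_path)
    data: dict[int, np.ndarray] = {}
    with h5py.File(h5_path, "r") as fh:
        sfreq = float(fh.attrs["sfreq"])
        trial_duration = float(fh.attrs["trial_duration"])
        for name in sorted(fh):
            p = int(name[1:])
            grp = fh[name]
            trials = [grp[t][...] for t in sorted(grp)]
            data[p] = np.stack(trials).astype(np.float64)
    return SyntheticCohort(
        data=data, metadata=metadata, montage=montage,
        sfreq=sfreq, trial_duration=trial_duration,
    )


def write_epochs(
    epochs: dict[int, EpochTensor], h5_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write preprocessed epochs in the cohort layout plus a JSON sidecar
    with per-participant exclusion counts."""
    h5_path = Path(h5_path)
    counts = {}
    with h5py.File(h5_path, "w") as fh:
        for p, ep in sorted(epochs.items()):
            grp = fh.create_group(f"p{p:03d}")
            grp.attrs["sfreq"] = ep.sfreq
            for t in range(ep.n_trials):
                ds = grp.create_dataset(
                    f"trial{t:03d}", data=ep.data[t].astype(np.float32)
                )
                ds.attrs["condition"] = str(ep.conditions[t])
                ds.attrs["excluded_sensors"] = np.nonzero(ep.exclusion_mask[t])[0]
            counts[p] = int(ep.exclusion_mask.sum())
    if sidecar_path is None:
        sidecar_path = h5_path.with_suffix(".exclusions.json")
    with open(sidecar_path, "w") as fh:
        json.dump({"excluded_sensor_trials": counts}, fh, indent=2)


def read_epochs(h5_path: str | Path) -> dict[int, EpochTensor]:
    out: dict[int, EpochTensor] = {}
    with h5py.File(h5_path, "r") as fh:
        for name in sorted(fh):
            p = int(name[1:])
            grp = fh[name]
            trials, conds, masks = [], [], []
            for t in sorted(grp):
                ds = grp[t]
                trials.append(ds[...])
                conds.append(ds.attrs["condition"])
                masks.append(ds.attrs["excluded_sensors"])
            data = np.stack(trials).astype(np.float64)
            mask = np.zeros(data.shape[:2], bool)
            for t, sensors in enumerate(masks):
                mask[t, np.asarray(sensors, int)] = True
            out[p] = EpochTensor(
                data=data,
                sfreq=float(grp.attrs["sfreq"]),
                conditions=np.array(conds),
                participant=p,
                exclusion_mask=mask,
            )
    return out


def write_psd(psd: PSDTensor, h5_path: str | Path) -> None:
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("power", data=psd.power.astype(np.float32))
        fh.create_dataset(
            "conditions", data=psd.conditions.astype("S")
        )
        fh.create_dataset("participants", data=np.asarray(psd.participants))
        fh.create_dataset("freqs", data=psd.freqs)
    if psd.ratings is not None:
        psd.ratings.to_csv(Path(h5_path).with_suffix(".ratings.csv"), index=False)


def read_psd(h5_path: str | Path) -> PSDTensor:
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "r") as fh:
        power = fh["power"][...].astype(np.float64)
        conditions = fh["conditions"][...].astype(str)
        participants = [int(p) for p in fh["participants"][...]]
        freqs = fh["freqs"][...]
    ratings_path = h5_path.with_suffix(".ratings.csv")
    ratings = pd.read_csv(ratings_path) if ratings_path.exists() else None
    return PSDTensor(
        power=power, conditions=conditions, participants=participants,
        freqs=freqs, ratings=ratings,
    )
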