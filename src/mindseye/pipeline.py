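"""End-to-end orchestration: simulate/load -> preprocess -> PSD ->
{decode, cluster tests, per-frequency SVR}.

A single :class:`PipelineConfig` drives the whole analysis.  Every
stochastic stage consumes its own child seed derived from the master seed by
a counter-based split, so each stage is individually reproducible and
re-entrant from saved intermediate outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .cluster import AdjacencySpec, ClusterPermutationTest
from .decode import ConditionDecoder
from .preprocess import DEFAULT_RANGE_THRESHOLD, preprocess_cohort
from .spectral import compute_psd_tensor
from .svr import VividnessSVR
from .synth import MODALITIES, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

CONTRASTS = (("audio", "visual"), ("rest", "visual"), ("rest", "audio"))

# fixed per-stage child-seed indices (counter-based split of the master seed)
_STAGE_KEYS = {"synth": 0, "decode": 1, "cluster": 2, "svr_audio": 3, "svr_visual": 4}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator derived from the master seed; independent of
    the order in which stages run."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_KEYS[stage],))
    )


@dataclass
class PipelineConfig:
    """Serialisable description of one full analysis run."""

    seed: int = 0
    output_dir: str = "mindseye-output"
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    cohort_path: str | None = None  # read instead of simulating
    epoch_duration: float | None = None  # default: 0.9 * trial duration
    range_threshold: float = DEFAULT_RANGE_THRESHOLD
    n_decode_shuffles: int = 1000
    n_cluster_permutations: int = 1000
    cluster_alpha: float = 0.05
    svr_iterations: int = 125
    svr_folds: int = 4
    bf_threshold: float = 100.0
    save_intermediates: bool = True
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if isinstance(syn, dict):
            from .synth import ConditionEffect, VividnessCoupling

            syn = dict(syn)
            syn["condition_effects"] = [
                ConditionEffect(**{**e, "band": tuple(e["band"])})
                for e in syn.get("condition_effects", [])
            ]
            syn["vividness_couplings"] = [
                VividnessCoupling(**{**c, "band": tuple(c["band"])})
                for c in syn.get("vividness_couplings", [])
            ]
            d["synthetic"] = SyntheticConfig(**syn)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_psd(
    config: SyntheticConfig,
    epoch_duration: float | None = None,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
):
    """Simulate -> preprocess -> binned PSD, one participant at a time.

    Streams the cohort so peak memory stays at a single participant's raw
    trials; returns ``(PSDTensor, GroundTruth)``.  This is the
    memory-appropriate route at the full session scale.
    """
    import pandas as pd

    from .preprocess import preprocess_trials
    from .spectral import PSDTensor, compute_trial_psd
    from .synth import GroundTruth, _cohort_latents, iter_participants

    if epoch_duration is None:
        epoch_duration = 0.9 * config.trial_duration
    montage, vividness, coupling_noise, _ = _cohort_latents(config)
    powers, conditions, rows, artifacts = [], [], [], []
    for p, trials, conds, prows, part_artifacts in iter_participants(config):
        epochs = preprocess_trials(
            trials, config.sfreq, conds, participant=p,
            trial_duration=config.trial_duration,
            epoch_duration=epoch_duration,
            range_threshold=range_threshold,
        )
        powers.append(compute_trial_psd(epochs))
        conditions.append(conds)
        rows.extend(prows)
        artifacts.extend((p, t, s) for t, s in part_artifacts)
    psd = PSDTensor(
        power=np.stack(powers),
        conditions=np.stack(conditions),
        participants=list(range(config.n_participants)),
        ratings=pd.DataFrame(rows),
    )
    truth = GroundTruth(
        vividness=vividness,
        coupling_noise=coupling_noise,
        condition_effects=list(config.condition_effects),
        vividness_couplings=list(config.vividness_couplings),
        artifacts=artifacts,
    )
    return psd, truth


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in fixed order and write a report bundle.

    Returns the machine-readable summary that is also written to
    ``summary.json`` in the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    # --- stage: data + preprocess + spectral ------------------------------
    try:
        if config.cohort_path is not None:
            logger.info("reading cohort from %s", config.cohort_path)
            cohort = io.read_cohort(config.cohort_path)
            montage = cohort.montage
            epochs = preprocess_cohort(
                cohort,
                epoch_duration=config.epoch_duration,
                range_threshold=config.range_threshold,
            )
            psd = compute_psd_tensor(epochs, ratings=cohort.metadata)
        else:
            if config.synthetic is None:
                raise ValueError(
                    "either cohort_path or a synthetic config is required"
                )
            syn = dataclasses.replace(
                config.synthetic,
                seed=int(stage_rng(config.seed, "synth").integers(2**31)),
            )
            logger.info("simulating cohort (%d participants)", syn.n_participants)
            from .montage import standard_montage

            montage = standard_montage(syn.n_sensors)
            if config.save_intermediates:
                cohort, _truth = generate_cohort(syn)
                io.write_cohort(cohort, out / "cohort.h5")
                epochs = preprocess_cohort(
                    cohort,
                    epoch_duration=config.epoch_duration,
                    range_threshold=config.range_threshold,
                )
                psd = compute_psd_tensor(epochs, ratings=cohort.metadata)
            else:
                # stream participant-by-participant: full-scale raw cohorts
                # do not fit in memory all at once
                psd, _truth = simulate_psd(
                    syn,
                    epoch_duration=config.epoch_duration,
                    range_threshold=config.range_threshold,
                )
    except Exception as err:
        raise RuntimeError(f"data/preprocessing stage failed: {err}") from err
    if config.save_intermediates:
        io.write_psd(psd, out / "psd.h5")

    summary: dict = {"seed": config.seed, "n_participants": psd.n_participants}

    # --- stage: decode -----------------------------------------------------
    logger.info("decoding conditions (leave-one-trial-out)")
    dec = ConditionDecoder(psd).fit(
        n_shuffles=config.n_decode_shuffles,
        rng=stage_rng(config.seed, "decode"),
    )
    dec.to_frame().to_csv(out / "decoding.csv", index=False)
    np.savetxt(out / "decoding_confusion.csv", dec.mean_confusion, delimiter=",")
    t, p, bf = dec.group_test()
    summary["decoding"] = {
        "mean_success": dec.mean_success,
        "proportion_significant": dec.proportion_significant,
        "group_t": t,
        "group_p": p,
        "group_bf10": bf.bf10,
    }

    # --- stage: cluster tests ---------------------------------------------
    adjacency = AdjacencySpec.from_montage(montage)
    summary["clusters"] = {}
    cluster_rng = stage_rng(config.seed, "cluster")
    for cond_a, cond_b in CONTRASTS:
        name = f"{cond_a}-{cond_b}"
        logger.info("cluster test %s", name)
        res = ClusterPermutationTest(psd, cond_a, cond_b, adjacency).fit(
            n_permutations=config.n_cluster_permutations,
            alpha=config.cluster_alpha,
            rng=cluster_rng,
        )
        res.to_frame().to_csv(out / f"clusters_{name}.csv", index=False)
        np.savetxt(out / f"tmap_{name}.csv", res.t_map, delimiter=",")
        summary["clusters"][name] = [
            {
                "sign": c.sign,
                "mass": c.mass,
                "p": c.p,
                "n_points": len(c.points),
                "freq_range": list(c.freq_range),
            }
            for c in res.significant
        ]

    # --- stage: SVR + Bayes ------------------------------------------------
    summary["svr"] = {}
    for modality in MODALITIES:
        logger.info("SVR analysis (%s imagery)", modality)
        model = VividnessSVR.from_psd(psd, modality)
        res = model.fit(
            n_iter=config.svr_iterations,
            k=config.svr_folds,
            rng=stage_rng(config.seed, f"svr_{modality}"),
            bf_threshold=config.bf_threshold,
        )
        res.to_frame().to_csv(out / f"svr_{modality}.csv", index=False)
        bands = res.predictive_bands()
        pd_bands = [
            {"lo": b.lo, "hi": b.hi, "min_bf10": b.min_bf10} for b in bands
        ]
        summary["svr"][modality] = {"predictive_bands": pd_bands}
        if config.make_plots:
            from . import plots

            plots.bf_spectrum(res).savefig(out / f"svr_{modality}_bf.png", dpi=150)

    if config.make_plots:
        from . import plots

        plots.group_psd(psd).savefig(out / "group_psd.png", dpi=150)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
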