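"""Generator behaviour: spectra, couplings, artifacts, determinism."""

import numpy as np
import pandas as pd
import pytest

from mindseye.preprocess import preprocess_cohort
from mindseye.spectral import bin_power_1hz, periodogram
from mindseye.synth import (
    ConditionEffect,
    SyntheticConfig,
    VividnessCoupling,
    expected_binned_power,
    generate_cohort,
    generate_trial_timeseries,
)

from conftest import null_config, small_config


def _trial_binned(config, condition, rng, n_trials=50):
    """Mean 1 Hz-binned raw-trial spectrum over sensors and trials."""
    acc = []
    for _ in range(n_trials):
        x = generate_trial_timeseries(config, 0, condition, rng)
        freqs, power = periodogram(x, config.sfreq)
        acc.append(bin_power_1hz(freqs, power).mean(axis=0))
    return np.mean(acc, axis=0)


def test_degenerate_config_gives_flat_spectrum(rng):
    cfg = null_config(
        noise_exponent=0.0, alpha_peak_amplitude=0.0, trial_power_logsd=0.0
    )
    mean_bins = _trial_binned(cfg, "rest", rng, n_trials=60)
    f = np.arange(1, 41, dtype=float)
    slope = np.polyfit(f, mean_bins / mean_bins.mean(), 1)[0]
    # flat to within Monte-Carlo error: relative tilt across 40 bins small
    assert abs(slope * 40) < 0.05


def test_alpha_peak_dominates_high_frequencies(rng):
    cfg = null_config()
    mean_bins = _trial_binned(cfg, "rest", rng, n_trials=50)
    assert mean_bins[9] > mean_bins[19:40].mean()  # bin 10 Hz vs 20-40 Hz


def test_condition_effect_matches_component_spectrum_oracle(rng):
    """Planted rest-vs-imagery alpha contrast reproduces the analytically
    composed component spectra (generation happens in the frequency domain,
    so the expected binned power is available in closed form)."""
    effect = ConditionEffect("audio", (8.0, 12.0), 1 / 1.5, "uniform")
    cfg = null_config(condition_effects=[effect], trial_power_logsd=0.0)
    rest = _trial_binned(cfg, "rest", rng, n_trials=80)
    audio = _trial_binned(cfg, "audio", rng, n_trials=80)

    exp_rest = expected_binned_power(cfg, "rest").mean(axis=0)
    exp_audio = expected_binned_power(cfg, "audio").mean(axis=0)
    assert (rest - audio)[9] > 0
    assert (exp_rest - exp_audio)[9] > 0
    # empirical difference tracks the analytic one in the alpha band
    np.testing.assert_allclose(
        (rest / exp_rest)[7:12], 1.0, rtol=0.15
    )
    np.testing.assert_allclose(
        (audio / exp_audio)[7:12], 1.0, rtol=0.15
    )


def test_cohort_layout_and_ratings():
    cohort, truth = generate_cohort(small_config())
    meta = cohort.metadata
    counts = meta.groupby(["participant", "condition"]).size()
    assert (counts == 4).all()
    # every imagery trial rated 1-5, no rest trial rated
    imagery = meta[meta["condition"] != "rest"]
    assert imagery["rating"].between(1, 5).all()
    assert meta[meta["condition"] == "rest"]["rating"].isna().all()
    assert truth.vividness.shape == (6, 2)
    assert ((truth.vividness >= 1) & (truth.vividness <= 5)).all().all()


def test_same_seed_reproduces_cohort_exactly():
    cfg = small_config(seed=77)
    c1, t1 = generate_cohort(cfg)
    c2, t2 = generate_cohort(cfg)
    for p in c1.participants:
        np.testing.assert_array_equal(c1.data[p], c2.data[p])
    pd.testing.assert_frame_equal(c1.metadata, c2.metadata)
    pd.testing.assert_frame_equal(t1.vividness, t2.vividness)


def test_zero_coupling_gives_uncorrelated_ratings_and_power():
    cfg = small_config(
        n_participants=24,
        vividness_couplings=[VividnessCoupling("audio", (6.0, 9.0), 0.0, 0.0)],
        rating_noise_sd=0.0,
        seed=5,
    )
    cohort, truth = generate_cohort(cfg)
    epochs = preprocess_cohort(cohort)
    diffs, ratings = [], []
    for p in cohort.participants:
        ep = epochs[p]
        freqs, power = periodogram(ep.data, ep.sfreq)
        binned = bin_power_1hz(freqs, power)  # (trials, sensors, 40)
        band = binned[..., 5:9].mean(axis=(1, 2))
        is_audio = ep.conditions == "audio"
        diffs.append(np.log(band[is_audio].mean()) - np.log(band[ep.conditions == "rest"].mean()))
        meta = cohort.metadata
        ratings.append(
            meta[(meta.participant == p) & (meta.condition == "audio")]["rating"].mean()
        )
    r = np.corrcoef(diffs, ratings)[0, 1]
    assert abs(r) < 3 / np.sqrt(len(diffs))


def test_coupling_slope_recovery_across_seeds():
    """Regressing imagery-minus-rest band log-power on the latent vividness
    recovers the configured slope, averaged over seeds at n = 44."""
    slope_cfg = -0.2
    est = []
    for seed in range(12):
        cfg = SyntheticConfig(
            n_participants=44,
            n_trials_per_condition=8,
            n_sensors=4,
            sfreq=256.0,
            trial_duration=4.0,
            condition_effects=[],
            vividness_couplings=[VividnessCoupling("audio", (6.0, 9.0), slope_cfg, 0.05)],
            seed=seed,
        )
        cohort, truth = generate_cohort(cfg)
        ys, vs = [], []
        for p in cohort.participants:
            trials = cohort.data[p]
            meta = cohort.metadata[cohort.metadata.participant == p]
            conds = meta.sort_values("trial_index")["condition"].to_numpy()
            freqs, power = periodogram(trials, cfg.sfreq)
            band = bin_power_1hz(freqs, power)[..., 5:9].mean(axis=(1, 2))
            ys.append(
                np.log(band[conds == "audio"].mean())
                - np.log(band[conds == "rest"].mean())
            )
            vs.append(truth.vividness.loc[p, "audio"])
        est.append(np.polyfit(vs, ys, 1)[0])
    est = np.asarray(est)
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - slope_cfg) < 2 * se + 1e-9


def test_artifact_bookkeeping_matches_mask_exactly():
    # 64 sensors: the average reference spreads each injected excursion
    # across sensors at 1/64 amplitude, far below the exclusion threshold,
    # so the screen flags exactly the injected cells
    cfg = small_config(n_sensors=64, artifact_rate=0.01, seed=21)
    cohort, truth = generate_cohort(cfg)
    epochs = preprocess_cohort(cohort)
    flagged = {
        (p, t, s)
        for p in cohort.participants
        for t, s in zip(*np.nonzero(epochs[p].exclusion_mask))
    }
    assert flagged == set(truth.artifacts)
    assert len(truth.artifacts) > 0


def test_no_artifacts_means_no_sample_beyond_threshold(small_cohort):
    cohort, truth = small_cohort
    assert truth.artifacts == []
    epochs = preprocess_cohort(cohort)
    for ep in epochs.values():
        assert not ep.exclusion_mask.any()


def test_unknown_condition_rejected(rng):
    with pytest.raises(ValueError, match="unknown condition"):
        generate_trial_timeseries(small_config(), 0, "sleep", rng)


@pytest.mark.parametrize(
    "overrides",
    [
        dict(n_participants=0),
        dict(trial_duration=3.0, sfreq=250.5),
        dict(condition_effects=[ConditionEffect("audio", (0.5, 10.0), 0.8)]),
        dict(vividness_couplings=[VividnessCoupling("smell", (6.0, 9.0), 0.1)]),
        dict(artifact_rate=1.5),
    ],
)
def test_invalid_configs_rejected(overrides):
    with pytest.raises(ValueError):
        small_config(**overrides).validate()


def test_latent_vividness_correlation_recovered():
    rs = []
    for seed in range(8):
        cfg = SyntheticConfig(
            n_participants=44, n_trials_per_condition=4, n_sensors=2,
            sfreq=256.0, trial_duration=1.0, condition_effects=[],
            vividness_couplings=[], seed=seed,
        )
        _, truth = generate_cohort(cfg)
        rs.append(np.corrcoef(truth.vividness["audio"], truth.vividness["visual"])[0, 1])
    se = np.std(rs, ddof=1) / np.sqrt(len(rs))
    # Gaussian-copula with uniform marginals slightly attenuates Pearson r
    assert abs(np.mean(rs) - 0.7) < 2 * se + 0.03
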