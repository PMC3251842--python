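"""Synthetic card generator: determinism, planted structure, dropout, IO."""

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    ConfigurationError,
    impute_undetected,
    normalize_delta_ct,
    read_fixture_bundle,
    simulate_card_experiment,
    write_fixture_bundle,
)
from mirsig.simulate import SimulationConfig


def test_same_config_and_seed_is_bit_identical():
    a = simulate_card_experiment(SimulationConfig(seed=42))
    b = simulate_card_experiment(SimulationConfig(seed=42))
    pd.testing.assert_frame_equal(a.ct.values, b.ct.values)
    pd.testing.assert_frame_equal(a.ct.detected, b.ct.detected)
    assert a.planted.probe_ids == b.planted.probe_ids
    c = simulate_card_experiment(SimulationConfig(seed=43))
    assert not a.ct.values.equals(c.ct.values)


@pytest.mark.parametrize(
    "overrides, fragment",
    [
        (dict(n_up_in_sensitive=10), "signature_size"),
        (dict(signature_size=400, n_up_in_sensitive=398), "assay probes"),
        (dict(noise_sd=0.0), "noise_sd"),
        (dict(baseline_ct_range=(10.0, 32.0)), "baseline_ct_range"),
        (dict(tumor_purity=0.0), "tumor_purity"),
        (dict(n_sensitive_train=-1), "n_sensitive_train"),
    ],
)
def test_invalid_config_names_violated_invariant(overrides, fragment):
    with pytest.raises(ConfigurationError, match=fragment):
        simulate_card_experiment(SimulationConfig(**overrides))


def test_dataset_dimensions_and_annotations():
    ds = simulate_card_experiment(SimulationConfig(seed=0))
    assert len(ds.ct.probe_ids) == 381
    assert len(ds.ct.control_probe_ids) == 3
    assert len(ds.ct.assay_probe_ids) == 378
    assert len(ds.training_samples) == 8
    assert len(ds.validation_samples) == 16
    ann = ds.annotations
    assert set(ann["label"]) <= {"sensitive", "resistant", "unknown"}
    assert set(ann["specimen"]) <= {"cell_line", "primary", "metastatic"}
    # metastatic tumours carry the resistant expression profile
    mets = ann[ann["specimen"] == "metastatic"]
    assert (mets["true_profile"] == "resistant").all()
    assert ds.planted.k == 13
    assert sum(d == "up_in_sensitive" for d in ds.planted.directions.values()) == 11


def test_planted_effect_recovered_within_three_standard_errors():
    """Mean ΔCt(sensitive) − ΔCt(resistant) on up-regulated planted probes
    should recover −effect_cycles from the generated matrix."""
    ds = simulate_card_experiment(SimulationConfig(seed=5))
    delta = normalize_delta_ct(impute_undetected(ds.ct))
    sens = [s for s in ds.training_samples if ds.labels[s] == "sensitive"]
    res = [s for s in ds.training_samples if ds.labels[s] == "resistant"]
    up = [p for p, d in ds.planted.directions.items() if d == "up_in_sensitive"]
    diffs = delta.values.loc[up, sens].mean(axis=1) - delta.values.loc[up, res].mean(axis=1)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - (-3.0)) < 3 * se + 1e-9


def test_null_t_rejection_rate_matches_alpha():
    """With effect_cycles=0 the per-probe two-sample t-test should reject at
    roughly the nominal rate (binomial tolerance over probes × seeds)."""
    from mirsig import probe_t_test

    alpha, n_seeds = 0.05, 20
    rates = []
    for seed in range(n_seeds):
        ds = simulate_card_experiment(SimulationConfig(seed=100 + seed, effect_cycles=0.0))
        delta = normalize_delta_ct(impute_undetected(ds.ct))
        stats = probe_t_test(delta, ds.training_labels())
        rates.append(float((stats["p_value"] < alpha).mean()))
    mean_rate = float(np.mean(rates))
    # seed-level CLT interval (probes within a seed share control noise)
    halfwidth = 3 * np.std(rates, ddof=1) / np.sqrt(n_seeds)
    assert abs(mean_rate - alpha) < max(halfwidth, 0.01)


def test_label_symmetry_of_effect_directions():
    """Swapping the up/down design (11 up + 2 down vs 2 up + 11 down) mirrors
    the planted ΔCt differences."""

    def mean_planted_diff(cfg, direction):
        est = []
        for seed in range(30):
            ds = simulate_card_experiment(cfg, seed=seed)
            delta = normalize_delta_ct(impute_undetected(ds.ct))
            sens = [s for s in ds.training_samples if ds.labels[s] == "sensitive"]
            res = [s for s in ds.training_samples if ds.labels[s] == "resistant"]
            probes = [p for p, d in ds.planted.directions.items() if d == direction]
            est.append(
                float(
                    (
                        delta.values.loc[probes, sens].mean(axis=1)
                        - delta.values.loc[probes, res].mean(axis=1)
                    ).mean()
                )
            )
        return float(np.mean(est))

    up_diff = mean_planted_diff(SimulationConfig(), "up_in_sensitive")
    down_diff = mean_planted_diff(
        SimulationConfig(n_up_in_sensitive=2, n_down_in_sensitive=11), "down_in_sensitive"
    )
    assert up_diff == pytest.approx(-3.0, abs=0.15)
    assert down_diff == pytest.approx(3.0, abs=0.15)


def test_dropout_fraction_increases_with_baseline_ct():
    """Probes nearer the ceiling drop out at least as often as abundant ones
    (non-strict, assessed over thousands of wells via baseline tertiles)."""
    cfg = SimulationConfig(
        seed=7,
        n_sensitive_train=30,
        n_resistant_train=30,
        n_validation={"cell_line": 0, "primary": 0, "metastatic": 0},
        baseline_ct_range=(25.0, 38.0),
        dropout_slope=0.15,
        effect_cycles=0.0,
    )
    ds = simulate_card_experiment(cfg)
    assay = ds.ct.assay_probe_ids
    # observed probe mean (imputed at ceiling) is a monotone proxy for baseline
    imputed = impute_undetected(ds.ct)
    mean_ct = imputed.values.loc[assay].mean(axis=1)
    frac_undet = (~ds.ct.detected.loc[assay]).mean(axis=1)
    order = mean_ct.sort_values().index
    n = len(order) // 3
    low = float(frac_undet.loc[order[:n]].mean())
    mid = float(frac_undet.loc[order[n : 2 * n]].mean())
    high = float(frac_undet.loc[order[2 * n :]].mean())
    assert low <= mid <= high
    assert high > low  # the ramp is actually exercised


def test_discordant_sample_follows_sensitive_profile():
    ds = simulate_card_experiment(SimulationConfig(seed=3, discordant_sample=True))
    ann = ds.annotations
    discordant = ann[(ann["label"] == "resistant") & (ann["true_profile"] == "sensitive")]
    assert len(discordant) == 1
    assert discordant.index[0] in ds.training_samples


def test_fixture_bundle_round_trip(tmp_path):
    ds = simulate_card_experiment(
        SimulationConfig(seed=21, baseline_ct_range=(24.0, 38.0), dropout_slope=0.1)
    )
    paths = write_fixture_bundle(ds, tmp_path)
    assert ds.ct.n_undetected() > 0
    text = paths["ct_table"].read_text()
    assert "Undetermined" in text
    back = read_fixture_bundle(tmp_path)
    pd.testing.assert_frame_equal(back.ct.values, ds.ct.values)
    pd.testing.assert_frame_equal(back.ct.detected, ds.ct.detected)
    assert back.ct.control_probe_ids == ds.ct.control_probe_ids
    assert back.planted.probe_ids == ds.planted.probe_ids
    assert len(back.planted.probe_ids) == 13
    pd.testing.assert_frame_equal(back.annotations, ds.annotations)
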