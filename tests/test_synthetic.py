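"""Synthetic study generator: determinism, noise model, presets, truth."""
import numpy as np
import pandas as pd
import pytest

import biodosim as bd
from biodosim.errors import ConfigError


def simple_config(nuclide, cv=0.0, seed=0, **kwargs):
    defaults = dict(
        nuclide=nuclide, injected_mbq=3.7,
        timepoints_h=(2.0, 24.0, 72.0, 168.0),
        organs={"Liver": bd.MonoExpKinetics(10.0, 0.01),
                "Tumor": bd.UptakeWashoutKinetics(20.0, 0.05, 0.002)},
        n_per_timepoint=4, cv=cv, seed=seed)
    defaults.update(kwargs)
    return bd.SyntheticConfig(**defaults)


def test_noiseless_animals_equal_mean_curve(lu177):
    study, truth = bd.generate_study(simple_config(lu177, cv=0.0))
    for organ in study.organs:
        sub = study.samples[study.samples["organ"] == organ]
        expected = truth.mean_curve(organ, sub["time_h"].to_numpy())
        assert np.allclose(sub["pidg"].to_numpy(), expected, rtol=1e-12)


def test_same_seed_identical_studies(lu177):
    s1, _ = bd.generate_study(simple_config(lu177, cv=0.2, seed=42))
    s2, _ = bd.generate_study(simple_config(lu177, cv=0.2, seed=42))
    pd.testing.assert_frame_equal(s1.samples, s2.samples)
    s3, _ = bd.generate_study(simple_config(lu177, cv=0.2, seed=43))
    assert not s3.samples["pidg"].equals(s1.samples["pidg"])


def test_noise_is_unbiased_multiplicative(lu177):
    """Log-normal deviates have mean 1: large-sample organ mean converges."""
    cfg = simple_config(lu177, cv=0.2, n_per_timepoint=4000,
                        organs={"Liver": bd.MonoExpKinetics(10.0, 0.0)})
    study, _ = bd.generate_study(cfg)
    sub = study.samples[study.samples["time_h"] == 2.0]
    assert sub["pidg"].mean() == pytest.approx(10.0, rel=0.02)


@pytest.mark.parametrize("preset_name,ref_key", [
    ("lu177-reference", "lu177"), ("cu64-reference", "cu64")])
def test_preset_means_within_2sd_of_published(preset_name, ref_key):
    """Preset mean curves stay within 2 SD of the published tumor, blood and
    muscle means at every tabulated timepoint."""
    cfg = bd.preset(preset_name)
    truth = bd.TruthRecord(config=cfg)
    ref, _ = bd.load_reference_summary(ref_key)
    for organ in ("Tumor", "Blood", "Muscle"):
        sub = ref[ref["organ"] == organ].sort_values("time_h")
        model = truth.mean_curve(organ, sub["time_h"].to_numpy())
        dev = np.abs(model - sub["mean_pidg"].to_numpy()) / sub["sd"].to_numpy()
        assert np.all(dev <= 2.0), f"{organ}: {dev}"


def test_preset_peaks_match_study_shape():
    lu_cfg = bd.preset("lu177-reference")
    peak_h = lu_cfg.organs["Tumor"].peak_time_h()
    assert 120 < peak_h < 220          # tumor peaks near 7 d
    cu_cfg = bd.preset("cu64-reference")
    assert 30 < cu_cfg.organs["Tumor"].peak_time_h() < 70  # near 48 h
    with pytest.raises(ConfigError):
        bd.preset("nope")


def test_blocking_arm_scales_target(lu177):
    cfg = simple_config(lu177, cv=0.0, blocking_multiplier=0.297)
    base, _ = bd.generate_study(cfg, arm="baseline")
    block, _ = bd.generate_study(cfg, arm="blocking")
    t = 72.0
    unb = base.samples[(base.samples.organ == "Tumor") & (base.samples.time_h == t)]
    blk = block.samples[(block.samples.organ == "Tumor") & (block.samples.time_h == t)]
    est = bd.blocking_fraction(unb["pidg"].mean(), blk["pidg"].mean())
    assert est == pytest.approx(29.7, abs=1e-9)
    # non-target organs untouched
    for organ in ("Liver",):
        a = base.samples[base.samples.organ == organ]["pidg"].to_numpy()
        b = block.samples[block.samples.organ == organ]["pidg"].to_numpy()
        assert np.allclose(a, b)


def test_blocking_estimate_converges_with_noise(lu177):
    """Estimated remaining-uptake fraction approaches the generating
    multiplier as animal noise shrinks."""
    for cv, tol in ((0.10, 15.0), (0.01, 1.5)):
        ests = []
        for seed in range(10):
            cfg = simple_config(lu177, cv=cv, seed=seed, blocking_multiplier=0.5)
            base, _ = bd.generate_study(cfg, arm="baseline")
            block, _ = bd.generate_study(cfg, arm="blocking")
            unb = base.samples[(base.samples.organ == "Tumor")
                               & (base.samples.time_h == 72.0)]["pidg"].mean()
            blk = block.samples[(block.samples.organ == "Tumor")
                                & (block.samples.time_h == 72.0)]["pidg"].mean()
            ests.append(bd.blocking_fraction(unb, blk))
        assert np.mean(ests) == pytest.approx(50.0, abs=tol)


def test_truth_record_closed_forms(lu177):
    cfg = simple_config(lu177)
    truth = bd.TruthRecord(config=cfg)
    lam_p = lu177.lambda_phys
    assert truth.residence_per_gram_h("Liver") == pytest.approx(
        10.0 / 100 / (0.01 + lam_p), rel=1e-12)
    assert truth.residence_per_gram_h("Tumor") == pytest.approx(
        20.0 / 100 * (1 / (0.002 + lam_p) - 1 / (0.05 + lam_p)), rel=1e-12)
    # tumor dose truth: cumulated x S(m) with phi == 1
    dose = truth.tumor_dose_gy(0.15, 12.95)
    expected = (truth.residence_per_gram_h("Tumor") * 12.95 * 0.15
                * bd.self_dose_factor(lu177, 0.15) * 1e-3)
    assert dose == pytest.approx(expected, rel=1e-12)


def test_cell_binding_noiseless_and_zero():
    df = bd.generate_cell_binding(1000.0, 0.746, 0.02, cv=0.0, seed=0)
    est = bd.cell_bound_percent(df["total_bound"].mean(), df["nonspecific"].mean(),
                                1000.0)
    assert est == pytest.approx(74.6, abs=1e-9)
    df0 = bd.generate_cell_binding(1000.0, 0.0, 0.05, cv=0.0, seed=0)
    assert bd.cell_bound_percent(df0["total_bound"].mean(),
                                 df0["nonspecific"].mean(), 1000.0) == pytest.approx(0.0)


def test_cell_binding_monte_carlo_recovery():
    """500 noisy replicate assays recover the specific fraction to < 1 %."""
    ests = []
    for seed in range(500):
        df = bd.generate_cell_binding(1000.0, 0.746, 0.02, cv=0.05, seed=seed)
        ests.append(bd.cell_bound_percent(df["total_bound"].mean(),
                                          df["nonspecific"].mean(), 1000.0))
    assert np.mean(ests) == pytest.approx(74.6, abs=0.746)


def test_config_validation(lu177):
    with pytest.raises(ConfigError):
        simple_config(lu177, cv=-0.1)
    with pytest.raises(ConfigError):
        simple_config(lu177, blocking_multiplier=1.5)
    with pytest.raises(ConfigError):
        bd.UptakeWashoutKinetics(10.0, 0.001, 0.05)  # in-rate must exceed out
    with pytest.raises(ConfigError):
        bd.MonoExpKinetics(10.0, -0.01)
    with pytest.raises(ConfigError):
        bd.generate_cell_binding(1000.0, 0.8, 0.5, cv=0.0, seed=0)
    with pytest.raises(ConfigError):
        bd.generate_study(simple_config(lu177), arm="sideways")
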