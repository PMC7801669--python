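"""Synthetic generators: determinism, closed forms, preset calibration, and
copula correlation convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from muscleqmri.signals import T1_SR_TR_MS, UTE_TE_MS
from muscleqmri.synth import (
    MarginalSpec,
    PRESETS,
    gen_asl_series,
    gen_cohort,
    gen_cpmg_signal,
    gen_t1_series,
    gen_texture_roi,
    gen_ute_signal,
    get_preset,
    spearman_to_latent,
)


# ------------------------------------------------------------- determinism


def test_generators_bit_identical_with_same_seed():
    for make in (
        lambda s: gen_t1_series(1650.0, noise_sd=0.01, seed=s).amplitudes,
        lambda s: gen_cpmg_signal([(1.0, 30.0)], noise_sd=0.01, seed=s).amplitudes,
        lambda s: gen_ute_signal(0.06, 0.94, 0.5, 13.0, noise_sd=0.01, seed=s).amplitudes,
        lambda s: gen_texture_roi(1000, outlier_fraction=0.05, seed=s),
    ):
        a, b = make(42), make(42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, make(43))


def test_cohort_regeneration_bit_identical():
    a = gen_cohort(n_animals=12, seed=5).table
    b = gen_cohort(n_animals=12, seed=5).table
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------------ closed forms


def test_t1_series_asymptote_and_closed_form():
    long_tr = gen_t1_series(1650.0, trs_ms=[1e7], scale=2.0)
    assert long_tr.amplitudes[0] == pytest.approx(2.0, rel=1e-6)
    one_t1 = gen_t1_series(1650.0, trs_ms=[1650.0])
    assert one_t1.amplitudes[0] == pytest.approx(1 - np.e**-1, rel=1e-12)


def test_t1_series_uses_13_protocol_trs_sorted():
    sig = gen_t1_series(1650.0)
    assert len(sig) == 13
    assert np.all(np.diff(sig.times_ms) > 0)
    assert set(sig.times_ms) == set(T1_SR_TR_MS)


def test_t1_series_rejects_bad_inputs():
    with pytest.raises(ValueError):
        gen_t1_series(-1.0)
    with pytest.raises(ValueError):
        gen_t1_series(1650.0, trs_ms=[])


def test_cpmg_hand_sum():
    sig = gen_cpmg_signal([(0.5, 10.0), (0.5, 100.0)], esp_ms=1.0, n_echoes=50)
    t = 20.0
    expected = 0.5 * np.exp(-t / 10) + 0.5 * np.exp(-t / 100)
    assert sig.amplitudes[19] == pytest.approx(expected, rel=1e-12)


def test_ute_signal_te_zero_is_amplitude_sum():
    sig = gen_ute_signal(0.3, 0.7, 0.5, 13.0, tes_ms=[0.0, 1.0])
    assert sig.amplitudes[0] == pytest.approx(1.0)


def test_ute_default_16_protocol_tes():
    sig = gen_ute_signal(0.06, 0.94, 0.5, 13.0)
    assert len(sig) == 16
    assert tuple(sig.times_ms) == UTE_TE_MS


def test_asl_zero_curve_tagged_equals_control():
    series = gen_asl_series(lambda t: np.zeros(np.asarray(t).shape))
    np.testing.assert_array_equal(series.tagged, series.control)


# --------------------------------------------------------------- texture


def test_texture_degenerate_sd_zero_single_level():
    x = gen_texture_roi(100, base_sd=0.0, outlier_fraction=0.0, seed=1)
    assert np.unique(x).size == 1


def test_texture_rejects_invalid_args():
    with pytest.raises(ValueError):
        gen_texture_roi(100, outlier_fraction=0.6)
    with pytest.raises(ValueError):
        gen_texture_roi(100, quant_levels=1)


# ----------------------------------------------------------------- presets


def test_presets_encode_reference_medians():
    inj = get_preset("pooled_injured")
    ctl = get_preset("pooled_control")
    assert inj.ecv_pct.median == 6.6 and ctl.ecv_pct.median == 5.9
    assert inj.t2_msme_ms.median == 21.4 and ctl.native_t1_ms.median == 1649.9
    assert inj.smi.median == 1.17 and ctl.smi.median == 0.67
    assert inj.collagen_total_pct.median == 17.0
    assert inj.perfusion_total.median == 252.6 and inj.perfusion_max.median == 91.5


def test_preset_invariants():
    for p in PRESETS.values():
        assert 0 < p.ecv_pct.median / 100 < 1
        assert p.t2_msme_ms.median > 0 and p.native_t1_ms.median > 0
        sm = p.sm_by_angle_kpa
        assert sm[0] <= sm[40] <= sm[60] <= sm[80]
        for _, (_, rho) in p.spearman_targets.items():
            assert -1 <= rho <= 1
        assert p.perfusion_baseline >= 0


def test_marginal_median_and_iqr_are_exact():
    m = MarginalSpec(17.0, 3.0)
    z = np.random.default_rng(0).standard_normal(400_000)
    x = m.from_latent(z)
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    assert q50 == pytest.approx(17.0, rel=0.01)
    assert q75 - q25 == pytest.approx(3.0, rel=0.03)


# ------------------------------------------------------------------ cohort


def test_cohort_paired_structure():
    c = gen_cohort(n_animals=10, seed=2)
    t = c.table
    assert len(t) == 20
    counts = t.groupby("animal_id")["group"].agg(lambda g: sorted(g))
    assert all(v == ["control", "injured"] for v in counts)
    for col in ("inflammation_score", "centronucleation_score", "calcification_score"):
        assert t[col].between(0, 3).all()
    # SMi identity holds per record
    np.testing.assert_allclose(
        t["sm80_kpa"], t["sm0_kpa"] * (1 + t["smi"]), rtol=1e-12
    )
    np.testing.assert_allclose(
        t[["cpmg_frac_s", "cpmg_frac_i", "cpmg_frac_l"]].sum(axis=1), 1.0, atol=1e-12
    )


def test_cohort_requires_three_animals():
    with pytest.raises(ValueError):
        gen_cohort(n_animals=2)


def test_cohort_rejects_out_of_range_target():
    with pytest.raises(ValueError, match="ecv_pct"):
        gen_cohort(
            n_animals=5,
            correlation_targets={"ecv_pct": ("collagen_total_pct", 1.2)},
        )


def test_injured_cohort_collagen_median_calibrated():
    t = gen_cohort(n_animals=200, seed=0).table
    med = t.loc[t.group == "injured", "collagen_total_pct"].median()
    assert med == pytest.approx(17.0, abs=0.5)


def test_cohort_medians_converge_to_presets():
    """Monte-Carlo cohort medians (n=4000, averaged over seeds to tame the
    sampling error of wide-spread metrics such as SMi) sit within 2% of the
    presets."""
    checks = [
        ("injured", "ecv_pct", 6.6),
        ("injured", "t2_msme_ms", 21.4),
        ("injured", "smi", 1.17),
        ("injured", "perfusion_total_ml_100g", 252.6),
        ("control", "ecv_pct", 5.9),
        ("control", "kurtosis", 3.6),
    ]
    seeds = (0, 1, 2, 3)
    sums = np.zeros(len(checks))
    for seed in seeds:
        t = gen_cohort(n_animals=4000, seed=seed).table
        for i, (grp, col, _) in enumerate(checks):
            sums[i] += t.loc[t.group == grp, col].median()
    for i, (grp, col, target) in enumerate(checks):
        assert sums[i] / len(seeds) == pytest.approx(target, rel=0.02), col


def test_copula_spearman_converges_to_targets():
    """Realized within-group rank correlations approach the reference targets.

    Averaged over a few seeds (n=500 per group) the Monte-Carlo error of the
    mean is well below the 0.05 acceptance band.
    """
    targets = {
        "ecv_pct": ("collagen_total_pct", 0.50),
        "t2_msme_ms": ("collagen_total_pct", -0.48),
        "smi": ("collagen_total_pct", 0.41),
        "kurtosis": ("collagen_endo_pct", 0.42),
    }
    sums = {k: 0.0 for k in targets}
    seeds = (0, 1, 2, 3, 4)
    for seed in seeds:
        inj = gen_cohort(n_animals=500, seed=seed).table.query("group=='injured'")
        for metric, (anchor, _) in targets.items():
            sums[metric] += spearmanr(inj[metric], inj[anchor]).statistic
    for metric, (anchor, rho) in targets.items():
        assert sums[metric] / len(seeds) == pytest.approx(rho, abs=0.05), metric


def test_zero_targets_give_independence():
    t = gen_cohort(
        n_animals=500,
        seed=3,
        correlation_targets={},
    ).table.query("group=='injured'")
    for col in ("ecv_pct", "t2_msme_ms", "smi"):
        r = spearmanr(t[col], t["collagen_total_pct"]).statistic
        assert abs(r) < 0.1, col


def test_collagen_cross_correlation():
    t = gen_cohort(n_animals=500, seed=8).table.query("group=='injured'")
    r = spearmanr(t["collagen_total_pct"], t["collagen_endo_pct"]).statistic
    assert r == pytest.approx(0.92, abs=0.05)


def test_latent_mapping_endpoints():
    assert spearman_to_latent(0.0) == 0.0
    assert spearman_to_latent(1.0) == pytest.approx(1.0)
    assert spearman_to_latent(-1.0) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        spearman_to_latent(1.5)
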