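"""Generator correctness: geometry, composition, intensities, survival."""

import numpy as np
import pandas as pd
import pytest

from mihcquant import (
    InvalidConfigError, SimConfig, cox_univariate, generate_core,
    generate_cohort, read_fixture, simulate_intensities, simulate_pooled_cells,
    simulate_survival, truth_positivity, write_fixture,
)


def test_invalid_tumor_area_fraction_rejected():
    with pytest.raises(InvalidConfigError):
        SimConfig(tumor_area_fraction=1.5).validate()
    with pytest.raises(InvalidConfigError):
        SimConfig(tumor_area_fraction=0.0).validate()


def test_composition_must_sum_to_one():
    cfg = SimConfig()
    cfg.composition = {k: v * 2 for k, v in cfg.composition.items()}
    with pytest.raises(InvalidConfigError):
        cfg.validate()


def test_inverted_intensity_components_rejected():
    cfg = SimConfig()
    cfg.intensity_model["CD3"] = {"neg": [3.0, 0.3], "pos": [0.0, 0.3]}
    with pytest.raises(InvalidConfigError):
        cfg.validate()


def test_negative_baseline_hazard_rejected():
    cfg = SimConfig()
    cfg.survival_model["baseline_hazard"] = -1.0
    with pytest.raises(InvalidConfigError):
        cfg.validate()


def test_mask_area_hits_target_fraction():
    cfg = SimConfig(seed=5, tumor_area_fraction=0.5)
    for i in range(10):
        mask, _ = generate_core(cfg, f"c{i}", core_index=i)
        frac = mask.tumor_area_mm2 / mask.core_area_mm2
        assert abs(frac - 0.5) <= 0.01 + 1e-12


def test_uniform_placement_inside_fraction():
    """With tumor_area_fraction=0.5 about half the (uniform) cells fall inside."""
    cfg = SimConfig(seed=7, tumor_area_fraction=0.5, cells_per_core_mean=10_000)
    mask, cells = generate_core(cfg, "c0", core_index=0)
    inside = (cells["truth_compartment"] == "tumoral").mean()
    # area is within 1% of 0.5; binomial noise at n~1e4 adds ~1.5%
    assert abs(inside - 0.5) < 0.03


def test_zero_nk_fraction_yields_no_nk_cells():
    cfg = SimConfig(seed=1, cells_per_core_mean=2000)
    nk = cfg.composition.pop("NK_cell")
    cfg.composition["NK_cell"] = 0.0
    cfg.composition["T_cell"] += nk
    _, cells = generate_core(cfg, "c0", core_index=0)
    assert (cells["truth_phenotype"] == "NK_cell").sum() == 0


def test_tumor_cells_only_inside_mask():
    cfg = SimConfig(seed=2, cells_per_core_mean=3000)
    mask, cells = generate_core(cfg, "c0", core_index=0)
    tumor = cells[cells["truth_phenotype"] == "tumor_cell"]
    assert (tumor["truth_compartment"] == "tumoral").all()


def test_generate_core_deterministic_under_seed():
    cfg = SimConfig(seed=42, cells_per_core_mean=500)
    m1, c1 = generate_core(cfg, "c0", core_index=0)
    m2, c2 = generate_core(cfg, "c0", core_index=0)
    pd.testing.assert_frame_equal(c1, c2)
    assert m1.tumor.equals_exact(m2.tumor, 0)


def test_composition_recovery_three_binomial_se():
    """Truth phenotype fractions over >=1e5 CD45+ cells match the config."""
    cfg = SimConfig(seed=9)
    cells = simulate_pooled_cells(cfg, 220_000)
    imm = cells[cells["truth_phenotype"].isin(
        ["T_cell", "B_cell", "NK_cell", "macrophage", "other_immune"])]
    n = len(imm)
    assert n >= 100_000
    immune_total = sum(v for k, v in cfg.composition.items() if k != "non_immune")
    for pheno in ["T_cell", "B_cell", "NK_cell", "macrophage"]:
        expected = cfg.composition[pheno] / immune_total
        got = (imm["truth_phenotype"] == pheno).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(got - expected) <= 3 * se


def test_intensities_follow_truth_component():
    cfg = SimConfig(seed=3)
    cells = simulate_pooled_cells(cfg, 20_000)
    pos = truth_positivity(cells)
    for ch in ["CD45", "CD3", "CD57"]:
        mu_n, mu_p = cfg.intensity_model[ch]["neg"][0], cfg.intensity_model[ch]["pos"][0]
        boundary = np.exp(0.5 * (mu_n + mu_p))
        neg_vals = cells.loc[~pos[ch], ch]
        pos_vals = cells.loc[pos[ch], ch]
        assert (neg_vals < boundary).mean() > 0.999
        if len(pos_vals):
            assert (pos_vals > boundary).mean() > 0.999


def test_zero_variance_components_give_exact_locations():
    cfg = SimConfig(seed=3)
    for ch in cfg.intensity_model:
        cfg.intensity_model[ch] = {"neg": [0.0, 0.0], "pos": [2.0, 0.0]}
    cells = simulate_pooled_cells(cfg, 500)
    pos = truth_positivity(cells)
    for ch in ["CD45", "CK"]:
        assert np.allclose(cells.loc[pos[ch], ch], np.exp(2.0))
        assert np.allclose(cells.loc[~pos[ch], ch], 1.0)


def test_channel_histogram_is_bimodal():
    """Well-separated components leave a valley between the two locations."""
    cfg = SimConfig(seed=4)
    cells = simulate_pooled_cells(cfg, 10_000)
    logv = np.log(cells["CD45"])
    mu_n, mu_p = 0.0, 3.0
    counts, edges = np.histogram(logv, bins=40)
    centers = 0.5 * (edges[:-1] + edges[1:])
    between = (centers > mu_n) & (centers < mu_p)
    peak_n = counts[centers <= mu_n + 0.5].max()
    peak_p = counts[centers >= mu_p - 0.5].max()
    valley = counts[between].min()
    assert valley < 0.2 * min(peak_n, peak_p)
    valley_pos = centers[between][np.argmin(counts[between])]
    assert mu_n < valley_pos < mu_p


# --- survival generator ----------------------------------------------------

def test_survival_null_coefficients_equal_groups():
    cov = pd.DataFrame({"g": np.repeat([0.0, 1.0], 300)})
    model = {"baseline_hazard": 0.01, "coefficients": {"g": 0.0},
             "censoring_rate": 0.0, "horizon_months": np.inf,
             "pfs_gap_mean_months": 0.0}
    out = simulate_survival(cov, model, seed=5)
    a = out.loc[cov["g"] == 0, "os_months"]
    b = out.loc[cov["g"] == 1, "os_months"]
    # same exponential distribution: medians agree within sampling noise
    assert abs(np.median(a) - np.median(b)) < 0.25 * np.median(a)


def test_survival_hazard_ratio_two_recovered_by_cox():
    cov = pd.DataFrame({"g": np.tile([0.0, 1.0], 1000)})
    model = {"baseline_hazard": 0.01, "coefficients": {"g": np.log(2)},
             "censoring_rate": 0.003, "horizon_months": 500.0,
             "pfs_gap_mean_months": 0.0}
    out = simulate_survival(cov, model, seed=8)
    res = cox_univariate(out["os_months"], out["os_event"], cov["g"])
    assert 1.8 < res.hazard_ratio < 2.2


def test_zero_horizon_censors_everything_at_zero():
    cov = pd.DataFrame({"g": np.zeros(20)})
    model = {"baseline_hazard": 0.01, "coefficients": {"g": 0.0},
             "censoring_rate": 0.0, "horizon_months": 0.0}
    out = simulate_survival(cov, model, seed=1)
    assert (out["os_months"] == 0).all() and (out["os_event"] == 0).all()
    assert (out["pfs_months"] == 0).all() and (out["pfs_event"] == 0).all()


def test_pfs_never_exceeds_os(small_cohort):
    clin = small_cohort.clinical
    assert (clin["pfs_months"] <= clin["os_months"] + 1e-12).all()


def test_cox_coverage_of_true_log_hazard():
    """95% Wald CI covers the true binary-covariate effect in >=90% of
    replicates at n=500, for effects 0, 0.5 and 1."""
    for beta in [0.0, 0.5, 1.0]:
        cover = 0
        reps = 67
        for rep in range(reps):
            cov = pd.DataFrame({"g": np.tile([0.0, 1.0], 250)})
            model = {"baseline_hazard": 0.01, "coefficients": {"g": beta},
                     "censoring_rate": 0.003, "horizon_months": 400.0,
                     "pfs_gap_mean_months": 0.0}
            out = simulate_survival(cov, model, seed=1000 + rep)
            r = cox_univariate(out["os_months"], out["os_event"], cov["g"])
            lo = r.log_hazard - 1.959963984540054 * r.standard_error
            hi = r.log_hazard + 1.959963984540054 * r.standard_error
            cover += lo <= beta <= hi
        assert cover / reps >= 0.90


# --- fixture round trip ----------------------------------------------------

def test_fixture_round_trip(tmp_path, small_cohort):
    write_fixture(small_cohort, tmp_path)
    back = read_fixture(tmp_path)
    pd.testing.assert_frame_equal(
        small_cohort.cells.reset_index(drop=True), back.cells, check_dtype=False)
    pd.testing.assert_frame_equal(small_cohort.clinical, back.clinical, check_dtype=False)
    pd.testing.assert_frame_equal(
        small_cohort.truth_cells.reset_index(drop=True), back.truth_cells,
        check_dtype=False)
    for cid, m in small_cohort.masks.items():
        assert m.tumor.equals(back.masks[cid].tumor)
        assert m.core.equals(back.masks[cid].core)
    assert back.config == small_cohort.config


def test_fixture_byte_identical_under_seed(tmp_path):
    cfg = SimConfig(n_patients=3, cells_per_core_mean=200, seed=21)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_fixture(generate_cohort(cfg), d1)
    write_fixture(generate_cohort(cfg), d2)
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_empty_cohort_writes_valid_headers(tmp_path):
    bundle = generate_cohort(SimConfig(n_patients=0))
    write_fixture(bundle, tmp_path)
    cells = pd.read_csv(tmp_path / "cells.csv")
    assert len(cells) == 0 and "CD45" in cells.columns
    clin = pd.read_csv(tmp_path / "clinical.csv")
    assert len(clin) == 0 and "os_months" in clin.columns


def test_default_cohort_has_55_clinical_rows(tmp_path):
    cfg = SimConfig(cells_per_core_mean=50, seed=2)  # tiny cells, full cohort
    bundle = generate_cohort(cfg)
    write_fixture(bundle, tmp_path)
    clin = pd.read_csv(tmp_path / "clinical.csv")
    assert len(clin) == 55
    import json
    features = json.load(open(tmp_path / "masks.geojson"))["features"]
    assert len(features) >= 55
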