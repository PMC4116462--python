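"""Synthetic-data generator: design layout, planted truth, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from flymet import synth
from flymet.containers import ConfigurationError


@pytest.mark.parametrize(
    "ages,expected",
    [((3, 10, 24, 36, 51, 66, 81), 420), ((3, 10, 24, 36, 51, 66), 360)],
)
def test_design_sample_count_is_factor_product(ages, expected):
    spec = synth.DesignSpec(ages=ages)
    meta = synth.generate_design(spec)
    assert len(meta) == expected
    assert meta.index.is_unique
    # one record per line x sex x age x replicate
    assert meta.groupby(["line", "sex", "age"]).size().eq(2).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_lines": 1},
        {"ages": (10, 3)},
        {"overlap": 1.5},
        {"replicates_per_cell": 0},
        {"columns": {}},
    ],
)
def test_invalid_design_specs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        synth.DesignSpec(**kwargs)


def test_invalid_effect_specs_rejected():
    with pytest.raises(ConfigurationError):
        synth.EffectSpec(sigma2_within=0.0)
    with pytest.raises(ConfigurationError):
        synth.EffectSpec(frac_age_up=0.7, frac_age_down=0.7)
    with pytest.raises(ConfigurationError):
        synth.MissingnessSpec(rate=0.0)


def _null_effects(**kw):
    base = dict(
        frac_age_up=0.0, frac_age_down=0.0, frac_sex=0.0, frac_genotype=0.0,
        frac_age_sex=0.0, frac_age_geno=0.0, frac_sex_geno=0.0,
    )
    base.update(kw)
    return synth.EffectSpec(**base)


def test_noise_only_variance_matches_sigma2_within():
    spec = synth.DesignSpec(columns={"AE": 200})
    eff = _null_effects(seed=11, sigma2_within=0.25, sigma2_between=0.0)
    table, truth = synth.generate_table(spec, eff)
    logged = np.log(table.intensities.to_numpy())
    per_feature_var = logged.var(axis=1, ddof=1)
    assert abs(per_feature_var.mean() - 0.25) / 0.25 < 0.05
    assert np.median(np.abs(per_feature_var - 0.25) / 0.25) < 0.10
    assert (truth.features["true_icc"] == 0).all()


def test_true_icc_recorded_from_variance_ratio():
    spec = synth.DesignSpec(columns={"AE": 50})
    eff = _null_effects(seed=3, frac_genotype=1.0, sigma2_between=1.0,
                        sigma2_within=3.0)
    _, truth = synth.generate_table(spec, eff)
    assert np.allclose(truth.features["true_icc"], 0.25)


def test_between_line_variance_unbiased():
    spec = synth.DesignSpec(columns={"AE": 500})
    eff = _null_effects(seed=9, frac_genotype=1.0, sigma2_between=1.0,
                        sigma2_within=3.0)
    _, truth = synth.generate_table(spec, eff)
    realized = truth.line_effects.to_numpy().var(axis=1, ddof=1)
    assert abs(realized.mean() - 1.0) < 0.05


def test_same_seed_gives_byte_identical_tables():
    spec = synth.DesignSpec(columns={"AE": 60, "C18": 70})
    t1, _ = synth.generate_table(spec, synth.EffectSpec(seed=5))
    t2, _ = synth.generate_table(spec, synth.EffectSpec(seed=5))
    assert t1.intensities.to_csv() == t2.intensities.to_csv()
    assert t1.feature_meta.to_csv() == t2.feature_meta.to_csv()
    t3, _ = synth.generate_table(spec, synth.EffectSpec(seed=6))
    assert t3.intensities.to_csv() != t1.intensities.to_csv()


def test_truth_flags_exactly_nonzero_magnitudes(small_table):
    _, truth = small_table
    tf = truth.features
    assert ((tf["age_sign"] != 0) == (tf["age_effect"] != 0)).all()
    assert ((tf["sex_effect"] != 0) == (tf["sex_effect"].abs() > 0)).all()
    assert (
        tf["genotype"]
        == (truth.line_effects.to_numpy() != 0).any(axis=1)
    ).all()
    assert (
        tf["age_geno"]
        == (truth.age_line_slopes.to_numpy() != 0).any(axis=1)
    ).all()


def test_overlap_features_share_truth_but_not_noise(small_table):
    table, truth = small_table
    tf = truth.features
    shared = tf.groupby("signal_id").filter(lambda g: g["column"].nunique() == 2)
    assert len(shared), "expected ~30% overlap between columns"
    n_shared = shared["signal_id"].nunique()
    assert n_shared == round(0.30 * 120)
    for _, grp in shared.groupby("signal_id"):
        assert grp["age_effect"].nunique() == 1
        assert grp["sex_effect"].nunique() == 1
        a, b = grp.index
        assert not np.allclose(
            table.intensities.loc[a], table.intensities.loc[b]
        )


def test_missingness_infinite_steepness_censors_lowest_quantile(small_table):
    table, _ = small_table
    eff = synth.EffectSpec(
        seed=1, missingness=synth.MissingnessSpec(rate=0.10, steepness=np.inf)
    )
    out = synth.inject_missingness(table, eff)
    x = table.intensities.to_numpy().ravel()
    miss = np.isnan(out.intensities.to_numpy().ravel())
    assert miss.sum() == round(0.10 * x.size)
    assert x[miss].max() <= x[~miss].min()


def test_missingness_zero_steepness_is_intensity_independent(small_table):
    table, _ = small_table
    eff = synth.EffectSpec(
        seed=8, missingness=synth.MissingnessSpec(rate=0.30, steepness=0.0)
    )
    out = synth.inject_missingness(table, eff)
    x = np.log(table.intensities.to_numpy().ravel())
    miss = np.isnan(out.intensities.to_numpy().ravel())
    assert abs(miss.mean() - 0.30) < 0.02
    # missing and observed cells have indistinguishable intensity profiles
    assert abs(x[miss].mean() - x[~miss].mean()) < 0.05


def test_missingness_default_rate_hits_target():
    spec = synth.DesignSpec(columns={"AE": 300})  # 300 x 420 > 1e5 cells
    eff = synth.EffectSpec(seed=13, missingness=synth.MissingnessSpec(rate=0.05))
    table, _ = synth.generate_table(spec, eff)
    out = synth.inject_missingness(table, eff)
    realized = out.intensities.isna().to_numpy().mean()
    assert abs(realized - 0.05) < 0.02
    # intensity dependence: missing cells are dimmer on average
    x = np.log(table.intensities.to_numpy().ravel())
    miss = np.isnan(out.intensities.to_numpy().ravel())
    assert x[miss].mean() < x[~miss].mean()


def test_plant_pathways_cases(small_table):
    _, truth = small_table
    empty = synth.plant_pathways(truth, 0)
    assert len(empty.pathways) == 0
    with pytest.raises(ConfigurationError):
        synth.plant_pathways(truth, 3, sizes=(10_000, 20_000))
    planted = synth.plant_pathways(truth, 5, sizes=(4, 6), n_enriched=1, seed=4)
    assert len(planted.pathways) == 5
    assert planted.pathways["enriched"].sum() == 1
    # enriched pathway prefers compounds from age-affected features
    tf = planted.features
    aged = set(tf.loc[tf["age_sign"] != 0, "compound_id"]) - {""}
    members = planted.pathways.loc[planted.pathways["enriched"], "members"].iloc[0]
    frac_aged = len(set(members) & aged) / len(members)
    overall = len(aged) / len(planted.compounds)
    assert frac_aged > overall


def test_truth_roundtrip_and_mz_range(tmp_path, small_table):
    table, truth = small_table
    assert table.feature_meta["mz"].between(85, 2000).all()
    truth2 = synth.plant_pathways(truth, 3, sizes=(4, 6), seed=2)
    paths = truth2.write(tmp_path)
    feats = pd.read_csv(paths["features"], sep="\t", index_col="feature_id")
    assert len(feats) == table.n_features
    pw = pd.read_csv(paths["pathways"], sep="\t", index_col="pathway_id")
    assert len(pw) == 3


def test_hump_mode_has_zero_linear_trend():
    spec = synth.DesignSpec(columns={"AE": 30})
    eff = dataclasses.replace(
        _null_effects(seed=21, frac_age_up=1.0), age_mode="hump",
    )
    table, truth = synth.generate_table(spec, eff)
    # mean log intensity per age has no linear component across age rank
    logged = np.log(table.intensities.to_numpy())
    ages = table.sample_meta["age"].to_numpy()
    ranks = np.unique(ages, return_inverse=True)[1].astype(float)
    ranks -= ranks.mean()
    profile = np.array(
        [logged[:, ages == a].mean() for a in np.unique(ages)]
    )
    slope = np.polyfit(np.unique(ranks), profile, 1)[0]
    assert abs(slope) < 0.02
    assert abs(profile.max() - profile.min()) > 0.2  # but it does vary
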