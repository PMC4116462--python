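"""Quality-control cascade: each filter's rule, order, and imputation."""

import numpy as np
import pandas as pd
import pytest

from flymet import qc
from flymet.containers import ConfigurationError, FeatureTable
from flymet.validation import imputation_benchmark, qc_toy_fixture


def _table(rows: dict, mz=None, sexes=None) -> FeatureTable:
    n = len(next(iter(rows.values())))
    samples = [f"S{j}" for j in range(n)]
    sexes = sexes or ["M"] * (n // 2) + ["F"] * (n - n // 2)
    intens = pd.DataFrame(rows, index=pd.Index(samples, name="sample_id")).T
    intens.index.name = "feature_id"
    fmeta = pd.DataFrame(
        {"mz": mz if mz is not None else [200.0] * len(rows),
         "rt": 60.0, "column": "AE"},
        index=intens.index.copy(),
    )
    smeta = pd.DataFrame(
        {"line": "L01", "sex": sexes, "age": 3, "replicate": 1},
        index=pd.Index(samples, name="sample_id"),
    )
    return FeatureTable(intens, fmeta, smeta)


def _with_moments(mean, sd, n=10):
    """Values with exactly the requested sample mean and SD (ddof=1)."""
    z = np.linspace(-1, 1, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestSNR:
    def test_threshold_is_inclusive(self):
        tab = _table({
            "at15": _with_moments(30.0, 2.0),     # SNR exactly 15 -> kept
            "at14": _with_moments(14.0, 1.0),     # SNR 14 -> removed
            "high": _with_moments(100.0, 1.0),
        })
        out, entry = qc.filter_snr(tab, qc.QCConfig())
        assert out.intensities.index.tolist() == ["at15", "high"]
        assert entry["removed"] == 1

    def test_constant_feature_kept_and_flagged(self):
        tab = _table({"const": np.full(10, 7.0), "high": _with_moments(90, 1)})
        out, entry = qc.filter_snr(tab, qc.QCConfig())
        assert "const" in out.intensities.index
        assert entry["constant_features"] == ["const"]

    def test_fewer_than_two_observations_removed(self):
        vals = np.full(10, np.nan)
        vals[0] = 5.0
        tab = _table({"one_obs": vals, "high": _with_moments(90, 1)})
        out, entry = qc.filter_snr(tab, qc.QCConfig())
        assert out.intensities.index.tolist() == ["high"]
        assert "1 with <2 observations" in entry["detail"]

    def test_missing_cells_ignored_in_moments(self):
        vals = _with_moments(100.0, 1.0).astype(float)
        vals[3] = np.nan
        tab = _table({"gap": vals})
        out, _ = qc.filter_snr(tab, qc.QCConfig())
        assert "gap" in out.intensities.index


class TestLogTransform:
    def test_bases(self):
        tab = _table({"a": np.full(10, np.e)})
        out = qc.log_transform(tab, qc.QCConfig())
        assert np.allclose(out.intensities.to_numpy(), 1.0)
        tab2 = _table({"a": np.full(10, 8.0)})
        out2 = qc.log_transform(tab2, qc.QCConfig(log_base="2"))
        assert np.allclose(out2.intensities.to_numpy(), 3.0)

    def test_nonpositive_intensity_names_cell(self):
        vals = np.full(10, 5.0)
        vals[4] = 0.0
        tab = _table({"bad": vals})
        with pytest.raises(ValueError, match="'bad'.*'S4'"):
            qc.log_transform(tab, qc.QCConfig())

    def test_missing_stays_missing(self):
        vals = np.full(10, 5.0)
        vals[2] = np.nan
        out = qc.log_transform(_table({"a": vals}), qc.QCConfig())
        assert np.isnan(out.intensities.iloc[0, 2])


class TestMissingBySex:
    def _sex_table(self, miss_m, miss_f, per_sex=20):
        vals = np.full(2 * per_sex, 100.0)
        vals[:miss_m] = np.nan
        vals[per_sex: per_sex + miss_f] = np.nan
        return _table({"f": vals}, sexes=["M"] * per_sex + ["F"] * per_sex)

    @pytest.mark.parametrize(
        "miss_m,miss_f,kept",
        [
            (0, 2, False),  # 10% of females missing -> removed
            (1, 1, True),   # exactly 5% in both -> kept ('more than 5%' strict)
            (0, 0, True),
        ],
    )
    def test_strict_threshold_per_sex(self, miss_m, miss_f, kept):
        tab = self._sex_table(miss_m, miss_f)
        out, _ = qc.filter_missing_by_sex(tab, qc.QCConfig())
        assert ("f" in out.intensities.index) is kept

    def test_sex_with_zero_samples_errors(self):
        tab = _table({"f": np.full(10, 1.0)}, sexes=["M"] * 10)
        tab.sample_meta["sex"] = pd.Categorical(
            ["M"] * 10, categories=["M", "F"]
        )
        with pytest.raises(ValueError):
            qc.filter_missing_by_sex(tab, qc.QCConfig())


class TestImpute:
    def test_perfect_neighbor_regression_is_exact(self):
        x = np.arange(10, dtype=float)
        y = x.copy()
        y[7] = np.nan
        tab = _table({"target": y, "neighbor": x})
        out, _ = qc.impute_ls(tab, qc.QCConfig(impute_neighbors=1))
        assert out.intensities.loc["target", "S7"] == pytest.approx(7.0)

    def test_no_usable_neighbor_falls_back_to_feature_mean(self):
        y = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, np.nan])
        # a constant neighbour has zero variance, hence undefined r
        tab = _table({"target": y, "flat": np.full(10, 3.0)})
        out, entry = qc.impute_ls(tab, qc.QCConfig())
        assert out.intensities.loc["target", "S9"] == pytest.approx(
            np.nanmean(y)
        )
        assert entry["fallback_cells"] == 1

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(1)
        vals = {f"f{i}": rng.normal(10, 1, 12) for i in range(6)}
        vals["f0"][3] = np.nan
        tab = _table(vals)
        out, _ = qc.impute_ls(tab, qc.QCConfig())
        obs = ~tab.intensities.isna()
        assert np.array_equal(
            tab.intensities.to_numpy()[obs.to_numpy()],
            out.intensities.to_numpy()[obs.to_numpy()],
        )
        assert not out.intensities.isna().any().any()

    def test_ls_beats_mean_imputation_on_correlated_data(self):
        res = imputation_benchmark(seed=7)
        assert res["rmse_ls"] < res["rmse_mean"]


class TestMzFilter:
    def test_strict_boundary(self):
        tab = _table(
            {"low": np.full(10, 1.0), "edge": np.full(10, 1.0),
             "glutamine_mh": np.full(10, 1.0)},
            mz=[899.9999, 900.0, 147.0764],
        )
        out, entry = qc.filter_mz(tab, qc.QCConfig())
        assert out.intensities.index.tolist() == ["low", "glutamine_mh"]
        assert entry["removed"] == 1

    def test_missing_mz_errors(self):
        tab = _table({"a": np.full(10, 1.0)})
        tab.feature_meta.loc["a", "mz"] = np.nan
        with pytest.raises(ValueError):
            qc.filter_mz(tab, qc.QCConfig())


class TestCenter:
    def test_sample_means_zero_and_idempotent(self, rng):
        vals = {f"f{i}": rng.normal(5, 2, 8) for i in range(4)}
        tab = _table(vals)
        out = qc.center_samples(tab)
        assert np.abs(out.intensities.mean(axis=0)).max() < 1e-10
        again = qc.center_samples(out)
        assert np.allclose(
            out.intensities.to_numpy(), again.intensities.to_numpy(), atol=1e-10
        )

    def test_single_feature_becomes_zero(self):
        tab = _table({"only": np.arange(10, dtype=float) + 1})
        out = qc.center_samples(tab)
        assert np.allclose(out.intensities.to_numpy(), 0.0)


class TestCascade:
    def test_toy_fixture_survivors_and_counts(self):
        table = qc_toy_fixture()
        cleaned, report = qc.run_qc(table, qc.QCConfig())
        assert sorted(cleaned.intensities.index) == ["OK1", "OK2", "OK3"]
        assert report.removed("snr") == 1
        assert report.removed("missing_by_sex") == 1
        assert report.removed("mz") == 1
        assert not cleaned.intensities.isna().any().any()
        assert (cleaned.feature_meta["mz"] < 900).all()
        assert np.abs(cleaned.intensities.mean(axis=0)).max() < 1e-10

    def test_step_order_matters(self):
        """Imputing before the missingness filter rescues a feature the
        canonical cascade order removes."""
        table = qc_toy_fixture()
        cfg = qc.QCConfig()
        t, _ = qc.filter_snr(table, cfg)
        t = qc.log_transform(t, cfg)
        t, _ = qc.impute_ls(t, cfg)            # swapped: impute first
        t, _ = qc.filter_missing_by_sex(t, cfg)
        t, _ = qc.filter_mz(t, cfg)
        permuted_survivors = set(t.intensities.index)
        cleaned, _ = qc.run_qc(table, cfg)
        assert permuted_survivors != set(cleaned.intensities.index)
        assert "BAD_MISS" in permuted_survivors

    def test_all_pass_fixture_removes_nothing(self, rng):
        vals = {f"f{i}": rng.normal(100, 1, 10) for i in range(5)}
        tab = _table(vals)
        cleaned, report = qc.run_qc(tab, qc.QCConfig())
        assert cleaned.n_features == 5
        assert report.to_frame()["removed"].sum() == 0

    def test_empty_table_passes_through(self):
        tab = _table({"a": np.full(10, 1.0)})
        empty = tab.subset_features([])
        cleaned, report = qc.run_qc(empty, qc.QCConfig())
        assert cleaned.n_features == 0
        assert report.n_features_out == 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            qc.QCConfig(snr_threshold=0)
        with pytest.raises(ConfigurationError):
            qc.QCConfig(max_missing_frac_per_sex=1.0)
        with pytest.raises(ConfigurationError):
            qc.QCConfig(log_base="7")
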