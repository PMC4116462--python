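"""Factorial model: encoding, OLS/LRT correctness, FDR, directions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from flymet import qc, synth, univariate as uv
from flymet.containers import ConfigurationError

from conftest import balanced_metadata


@pytest.fixture(scope="module")
def design():
    meta = balanced_metadata(n_lines=15, ages=(3, 10, 24, 36, 51, 66), reps=2)
    return uv.encode_design(meta), meta


class TestEncoding:
    def test_block_dimensions(self, design):
        d, _ = design
        assert len(d.term_cols["age"]) == 5          # levels - 1
        assert len(d.term_cols["genotype"]) == 14    # lines - 1
        assert len(d.term_cols["age:genotype"]) == 70
        assert len(d.term_cols["sex"]) == 1
        assert d.matrix.shape == (360, 1 + 5 + 1 + 14 + 5 + 70 + 14)

    def test_full_rank_and_orthogonal_age_contrasts(self, design):
        d, _ = design
        assert np.linalg.matrix_rank(d.matrix) == d.p
        pc = uv.poly_contrasts(6)
        assert np.allclose(pc.T @ pc, np.eye(5), atol=1e-12)
        assert np.allclose(pc.sum(axis=0), 0, atol=1e-12)
        # linear contrast increases with level order
        assert np.all(np.diff(pc[:, 0]) > 0)

    def test_rank_deficiency_reports_aliased_term(self):
        meta = balanced_metadata(n_lines=3, ages=(3, 10), reps=2)
        meta["line"] = np.where(meta["sex"] == "M", "L01", "L02")  # line == sex
        with pytest.raises(ConfigurationError, match="aliased"):
            uv.encode_design(meta)


class TestFit:
    def test_ols_matches_normal_equations(self, design, rng):
        d, _ = design
        y = rng.normal(size=d.n)
        fit = uv.fit_feature(y, d)
        X = d.matrix
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients.to_numpy(), beta, atol=1e-8)
        assert fit.df_resid == d.n - d.p

    def test_f_test_matches_statsmodels(self, design, rng):
        d, _ = design
        y = rng.normal(size=d.n)
        fit = uv.fit_feature(y, d)
        sm_fit = sm.OLS(y, d.matrix).fit()
        for term in ("age", "sex", "age:sex"):
            contrast = np.zeros((len(d.term_cols[term]), d.p))
            for i, j in enumerate(d.term_cols[term]):
                contrast[i, j] = 1.0
            sm_p = float(sm_fit.f_test(contrast).pvalue)
            assert fit.p_values[term] == pytest.approx(sm_p, rel=1e-6)

    def test_null_pvalues_uniform(self, design):
        d, _ = design
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(2000, d.n))
        res = uv.fit_features(Y, d)
        for term in uv.ModelSpec().terms:
            ks = kstest(res["p_values"][term].to_numpy(), "uniform")
            assert ks.pvalue > 0.01, term

    def test_planted_sex_shift_has_tiny_pvalue(self, design):
        d, meta = design
        rng = np.random.default_rng(8)
        y = rng.normal(size=d.n)
        y[(meta["sex"] == "M").to_numpy()] += 2.0  # 2 sigma shift
        fit = uv.fit_feature(y, d)
        assert fit.p_values["sex"] < 1e-6
        assert uv.classify_direction(fit)["sex"] == "M"

    def test_lrt_degenerate_nesting_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            uv.likelihood_ratio(1.0, 1.0, 0, 100, 90)

    def test_chi2_lrt_reference_available(self, design, rng):
        d, _ = design
        y = rng.normal(size=d.n)
        exact = uv.fit_feature(y, d, uv.ModelSpec(genotype_test="exact"))
        chi2 = uv.fit_feature(y, d, uv.ModelSpec(genotype_test="chi2"))
        # same statistic, different reference distribution
        assert chi2.statistics["genotype"] == pytest.approx(
            exact.statistics["genotype"]
        )
        assert chi2.p_values["genotype"] != exact.p_values["genotype"]

    def test_loglik_consistent_with_lr_statistic(self, design, rng):
        d, _ = design
        y = rng.normal(size=d.n)
        fit = uv.fit_feature(y, d)
        lr = 2 * (fit.loglik - fit.reduced_loglik["genotype"])
        assert lr == pytest.approx(fit.statistics["genotype"], abs=1e-8)


class TestDirections:
    def test_planted_trends_label_up_down(self, design, rng):
        d, meta = design
        ages = sorted(meta["age"].unique())
        rank = meta["age"].map({a: i for i, a in enumerate(ages)}).to_numpy()
        up = rank / rank.max() + 0.01 * rng.normal(size=d.n)
        fit_up = uv.fit_feature(up, d)
        assert uv.classify_direction(fit_up)["age"] == "up"
        fit_down = uv.fit_feature(-up, d)
        assert uv.classify_direction(fit_down)["age"] == "down"

    def test_symmetric_hump_is_flat(self, design):
        d, _ = design
        # response built purely from the quadratic age contrast: the
        # linear coefficient is exactly zero by orthogonality
        y = d.matrix[:, d.term_cols["age"][1]].copy()
        fit = uv.fit_feature(y, d)
        assert abs(fit.coefficients.iloc[d.idx_age_linear]) < 1e-12
        assert uv.classify_direction(fit)["age"] == "flat"


class TestBH:
    def test_hand_worked_stepup(self):
        reject, _ = uv.bh_adjust([0.001, 0.004, 0.02, 0.8], alpha=0.01)
        assert reject.tolist() == [True, True, False, False]

    def test_degenerate_inputs(self):
        reject, _ = uv.bh_adjust([0.005] * 7, alpha=0.01)
        assert reject.all()
        reject, _ = uv.bh_adjust([1.0] * 7, alpha=0.01)
        assert not reject.any()
        with pytest.raises(ValueError):
            uv.bh_adjust([0.5, 1.5], alpha=0.01)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_decisions_monotone_in_p(self, ps):
        reject, _ = uv.bh_adjust(ps, alpha=0.05)
        thresh = max((p for p, r in zip(ps, reject) if r), default=-1.0)
        assert all(r == (p <= thresh) for p, r in zip(ps, reject))


@pytest.fixture(scope="module")
def planted_run():
    spec = synth.DesignSpec(columns={"AE": 400})
    eff = synth.EffectSpec(seed=77)
    table, truth = synth.generate_table(spec, eff)
    table = qc.center_samples(qc.log_transform(table, qc.QCConfig()))
    return uv.run_univariate(table), truth, table


class TestPipeline:

    def test_age81_removed_from_fit(self, planted_run):
        _, _, table = planted_run
        keep = ~table.sample_meta["age"].isin([81])
        design = uv.encode_design(table.sample_meta[keep])
        assert design.n == 15 * 2 * 6 * 2
        with pytest.raises(ConfigurationError):
            uv.run_univariate(table, uv.ModelSpec(drop_age=(99,)))

    def test_direction_only_for_significant(self, planted_run):
        res, _, _ = planted_run
        frame = res.frame
        assert (frame.loc[frame["significant"] == 0, "direction"] == "").all()
        sig_dir = frame[
            (frame["significant"] == 1) & frame["factor"].isin(["age", "sex"])
        ]["direction"]
        assert sig_dir.isin(["up", "down", "M", "F", "flat"]).all()

    def test_summary_percentages_are_count_ratios(self, planted_run):
        res, _, _ = planted_run
        summary = uv.summarize_table1(res)
        total = res.frame.loc[res.frame["column"] == "AE", "feature_id"].nunique()
        expected = (summary["n_AE"] / total * 100).round(1)
        assert np.allclose(summary["pct_AE"], expected)

    def test_recovery_of_planted_fraction(self, planted_run):
        res, truth, _ = planted_run
        summary = uv.summarize_table1(res)
        total = truth.features.shape[0]
        planted_up = (truth.features["age_sign"] > 0).mean() * 100
        got_up = summary.loc["Increase with age", "pct_AE"]
        assert abs(got_up - planted_up) <= 3.0

    def test_three_way_term_optional(self, planted_run):
        _, _, table = planted_run
        spec3 = uv.ModelSpec(include_three_way=True)
        small = table.subset_features(table.intensities.index[:5])
        res = uv.run_univariate(small, spec3)
        assert "age:sex:genotype" in set(res.frame["factor"])

    def test_results_roundtrip(self, planted_run, tmp_path):
        res, _, _ = planted_run
        path = tmp_path / "factor_results.tsv"
        res.write(path)
        back = uv.FactorResults.read(path)
        pd.testing.assert_frame_equal(
            back.frame, res.frame, check_dtype=False, check_exact=False,
            rtol=1e-12,
        )
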