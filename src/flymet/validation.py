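"""End-to-end recovery and calibration checks on synthetic data.

Each function simulates data under known conditions, runs the relevant
pipeline stage(s), and returns the measured quantities. They are the
basis of the acceptance test suite and of ``scripts/acceptance.py``;
problem sizes are chosen so every check runs in seconds to a couple of
minutes on one CPU (the methods note states the sizes used).
"""

from __future__ import annotations

import dataclasses
import filecmp
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import enrichment as enr
from . import heritability as her
from . import multivariate as mv
from . import qc as qcmod
from . import synth, univariate
from .containers import FeatureTable

NULL_EFFECTS = dict(
    frac_age_up=0.0, frac_age_down=0.0, frac_sex=0.0, frac_genotype=0.0,
    frac_age_sex=0.0, frac_age_geno=0.0, frac_sex_geno=0.0,
)

SIX_AGES = (3, 10, 24, 36, 51, 66)  # day-81 cohort dropped, as in the analysis


def _sub(seed: int, key: int) -> int:
    return int(np.random.SeedSequence([seed, key]).generate_state(1)[0] % (2**31))


def heritability_recovery(
    seed: int = 0,
    icc_levels=(0.0, 0.10, 0.25, 0.40),
    n_features: int = 200,
    sigma2_within: float = 3.0,
) -> dict:
    """Mean estimated intraclass correlation per planted ICC level.

    15 lines x 2 sexes x 6 ages x 2 replicates; every feature carries a
    line effect at the level's between-line variance.
    """
    spec = synth.DesignSpec(ages=SIX_AGES, columns={"AE": n_features})
    means = {}
    for i, level in enumerate(icc_levels):
        s2b = level / (1.0 - level) * sigma2_within
        eff = synth.EffectSpec(
            seed=_sub(seed, 10 + i),
            **{**NULL_EFFECTS, "frac_genotype": 1.0 if level > 0 else 0.0},
            sigma2_between=s2b, sigma2_within=sigma2_within,
        )
        table, _ = synth.generate_table(spec, eff)
        table = qcmod.log_transform(table, qcmod.QCConfig())
        res = her.heritability_screen(table)
        means[level] = float(res.frame["t"].mean())
    ordered = all(
        means[a] < means[b] for a, b in zip(icc_levels, icc_levels[1:])
    )
    return {"mean_t": means, "strictly_ordered": ordered, "n_features": n_features}


def fdr_calibration(seed: int = 0, n_sims: int = 20, n_features: int = 500) -> dict:
    """Realized per-factor false-discovery proportion under the global null.

    With no planted effects every rejection is false, so the per-sim
    FDP is 1 when any feature is rejected for that factor and 0
    otherwise; the BH procedure at alpha = 0.01 should keep the average
    at or below alpha.
    """
    spec = synth.DesignSpec(columns={"AE": n_features})
    any_rejection: dict[str, list[float]] = {}
    frac_rejected: dict[str, list[float]] = {}
    for s in range(n_sims):
        eff = synth.EffectSpec(seed=_sub(seed, 100 + s), **NULL_EFFECTS)
        table, _ = synth.generate_table(spec, eff)
        table = qcmod.center_samples(qcmod.log_transform(table, qcmod.QCConfig()))
        res = univariate.run_univariate(table)
        counts = res.frame.groupby("factor")["significant"].sum()
        for factor, count in counts.items():
            any_rejection.setdefault(factor, []).append(1.0 if count > 0 else 0.0)
            frac_rejected.setdefault(factor, []).append(float(count) / n_features)
    mean_frac = {f: float(np.mean(v)) for f, v in frac_rejected.items()}
    mean_any = {f: float(np.mean(v)) for f, v in any_rejection.items()}
    return {
        # fraction of features falsely declared significant, per factor
        "mean_frac_rejected": mean_frac,
        "max_mean_frac_rejected": max(mean_frac.values()),
        # per-sim V/max(R,1) average; equals P(any rejection) under the
        # global null, a {0,1} quantity too noisy to bound tightly at
        # small n_sims but reported for completeness
        "mean_fdp_vr": mean_any,
        "mean_sig_fraction": float(np.mean(list(mean_frac.values()))),
        "n_sims": n_sims,
    }


def effect_recovery(seed: int = 0, n_features: int = 2000) -> dict:
    """Detection rate per factor and direction agreement at 2-sigma effects.

    Roughly 10% of features are planted per factor (age split evenly
    into increasing/decreasing); detection is the fraction of planted
    features declared significant at the per-factor 1% FDR, and
    direction agreement compares the up/down and male/female labels of
    significant planted features with the planted signs.
    """
    spec = synth.DesignSpec(columns={"AE": n_features})
    eff = synth.EffectSpec(seed=_sub(seed, 200))  # defaults: 10% per factor, 2 sigma
    table, truth = synth.generate_table(spec, eff)
    table = qcmod.center_samples(qcmod.log_transform(table, qcmod.QCConfig()))
    res = univariate.run_univariate(table)
    frame = res.frame.set_index(["feature_id", "factor"])
    tf = truth.features

    planted_masks = {
        "age": tf["age_sign"] != 0,
        "sex": tf["sex_effect"] != 0,
        "genotype": tf["genotype"],
        "age:sex": tf["age_sex"],
        "age:genotype": tf["age_geno"],
        "sex:genotype": tf["sex_geno"],
    }
    detection = {}
    for factor, mask in planted_masks.items():
        sig = frame.xs(factor, level="factor").loc[tf.index[mask], "significant"]
        detection[factor] = float(sig.mean())

    age = frame.xs("age", level="factor").join(tf, rsuffix="_t")
    sel = age[(age["significant"] == 1) & (age["age_sign"] != 0)]
    agree = list(((sel["direction"] == "up") == (sel["age_sign"] > 0)))
    sex = frame.xs("sex", level="factor").join(tf, rsuffix="_t")
    sels = sex[(sex["significant"] == 1) & (sex["sex_effect"] != 0)]
    agree += list(((sels["direction"] == "M") == (sels["sex_effect"] > 0)))
    return {
        "detection": detection,
        "min_detection": min(detection.values()),
        "direction_agreement": float(np.mean(agree)),
        "n_features": n_features,
    }


def pls_oracle_equivalence(seed: int = 0, n_instances: int = 50) -> dict:
    """Max |PLS - OLS| prediction gap at full-rank component count.

    On random (20 x 5) instances, PLS with 5 components must reproduce
    the normal-equations least-squares fit.
    """
    rng = np.random.default_rng(_sub(seed, 300))
    worst = 0.0
    for _ in range(n_instances):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = mv.pls_fit(X, y, 5)
        Z = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        worst = max(worst, float(np.max(np.abs(model.predict(X) - Z @ beta))))
    return {"max_abs_deviation": worst, "n_instances": n_instances}


def leakage_guard(
    seed: int = 0, n_samples: int = 100, n_features: int = 2000, n_perm: int = 10
) -> dict:
    """Permutation nulls on pure noise with many more features than samples.

    If selection, centring or scaling leaked test labels, the permuted
    CER would dip below chance and the permuted age R^2 would inflate;
    with the nested pipeline both sit at their chance levels.
    """
    rng = np.random.default_rng(_sub(seed, 400))
    X = rng.normal(size=(n_samples, n_features))
    labels = np.array(["F", "M"] * (n_samples // 2))
    null = mv.permutation_null(X, labels, n_perm=n_perm, metric="cer",
                               seed=_sub(seed, 401))
    dev_se = abs(null.mean - 0.5) / max(null.se, 1e-12)
    ages = np.tile(np.asarray(SIX_AGES + (81,), dtype=float),
                   n_samples // 7 + 1)[:n_samples]
    r2_null = mv.permutation_null(X, ages, n_perm=n_perm, metric="r2",
                                  seed=_sub(seed, 402), repeats=5)
    return {
        "perm_cer_mean": null.mean,
        "perm_cer_se": null.se,
        "perm_cer_dev_se": float(dev_se),
        "perm_age_r2": r2_null.mean,
        "n_samples": n_samples,
        "n_features": n_features,
    }


def classification_recovery(
    seed: int = 0, n_features: int = 500, shift: float = 3.0
) -> dict:
    """Sparse PLS-DA recovery of a small planted sex signal.

    A noise-only simulated table (one column) receives a ``shift``
    residual-SD male/female separation on exactly four features; the
    keep grid search should land on a sparse solution (keep <= 10) with
    near-zero cross-validated error.
    """
    spec = synth.DesignSpec(columns={"AE": n_features})
    eff = synth.EffectSpec(seed=_sub(seed, 500), **NULL_EFFECTS)
    table, _ = synth.generate_table(spec, eff)
    table = qcmod.center_samples(qcmod.log_transform(table, qcmod.QCConfig()))
    X = table.intensities.to_numpy().T.copy()
    sex = table.sample_meta["sex"].to_numpy()
    sw = np.sqrt(eff.sigma2_within)
    planted = [0, 1, 2, 3]
    X[np.ix_(sex == "M", planted)] += shift * sw
    keep, cer_min, curve = mv.select_keep_by_cv(X, sex, seed=_sub(seed, 501))
    model = mv.spls_fit(X, sex, keep=keep)
    return {
        "keep": int(keep),
        "cv_cer": float(cer_min),
        "selected_contains_planted": bool(
            set(planted) & set(model.selected_features.tolist())
        ),
        "n_features": n_features,
    }


# ---------------------------------------------------------------------------
# QC fixture: six hand-built features, one failing each filter


def qc_toy_fixture() -> FeatureTable:
    """Six features crafted so exactly one fails each of SNR /
    missingness-by-sex / m/z, and three survive the cascade."""
    samples = [f"S{i}" for i in range(1, 11)]
    sample_meta = pd.DataFrame(
        {
            "line": ["L01"] * 5 + ["L02"] * 5,
            "sex": ["M"] * 5 + ["F"] * 5,
            "age": [3, 3, 10, 10, 24] * 2,
            "replicate": [1, 2, 1, 2, 1] * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    base = np.linspace(99.0, 101.0, 10)  # SNR ~ 155, safely above 15
    rows = {
        "OK1": base,
        "BAD_SNR": np.array([10.0, 1000.0] * 5),  # mean ~505, SD ~521 -> SNR < 15
        "BAD_MISS": np.where(np.arange(10) < 2, np.nan, base),  # 40% of males missing
        "BAD_MZ": base + 1.0,
        "OK2": base + 2.0,
        "OK3": base + 3.0,
    }
    intensities = pd.DataFrame(
        rows, index=pd.Index(samples, name="sample_id")
    ).T
    intensities.index.name = "feature_id"
    feature_meta = pd.DataFrame(
        {
            "mz": [200.0, 300.0, 400.0, 950.0, 500.0, 600.0],
            "rt": [60.0] * 6,
            "column": ["AE"] * 6,
        },
        index=intensities.index.copy(),
    )
    return FeatureTable(intensities, feature_meta, sample_meta)


def qc_cascade_check() -> dict:
    """Run the cascade on the toy fixture and report per-step removals."""
    table = qc_toy_fixture()
    cleaned, report = qcmod.run_qc(table, qcmod.QCConfig())
    return {
        "survivors": cleaned.n_features,
        "survivor_ids": cleaned.intensities.index.tolist(),
        "removed_snr": report.removed("snr"),
        "removed_missing": report.removed("missing_by_sex"),
        "removed_mz": report.removed("mz"),
        "complete": not cleaned.intensities.isna().any().any(),
    }


def imputation_benchmark(
    seed: int = 0, n_features: int = 100, n_samples: int = 60,
    mask_frac: float = 0.20,
) -> dict:
    """Mask-and-recover RMSE of LS imputation vs feature-mean imputation.

    Features share latent structure (a two-factor model plus noise), so
    the correlation-weighted regressions should beat the mean fill.
    """
    rng = np.random.default_rng(_sub(seed, 600))
    factors = rng.normal(size=(2, n_samples))
    loadings = rng.normal(size=(n_features, 2))
    X = loadings @ factors + 0.3 * rng.normal(size=(n_features, n_samples)) + 10.0
    mask = rng.uniform(size=X.shape) < mask_frac
    masked = X.copy()
    masked[mask] = np.nan
    samples = [f"S{j}" for j in range(n_samples)]
    table = FeatureTable(
        intensities=pd.DataFrame(
            masked, index=pd.Index([f"F{i}" for i in range(n_features)],
                                   name="feature_id"),
            columns=samples,
        ),
        feature_meta=pd.DataFrame(
            {"mz": np.linspace(100, 800, n_features), "rt": 60.0, "column": "AE"},
            index=pd.Index([f"F{i}" for i in range(n_features)], name="feature_id"),
        ),
        sample_meta=pd.DataFrame(
            {"line": "L01", "sex": ["M", "F"] * (n_samples // 2),
             "age": 3, "replicate": 1},
            index=pd.Index(samples, name="sample_id"),
        ),
    )
    ls, _ = qcmod.impute_ls(table, qcmod.QCConfig())
    mean_filled = qcmod.impute_mean(table)
    rmse_ls = float(np.sqrt(np.mean((ls.intensities.to_numpy()[mask] - X[mask]) ** 2)))
    rmse_mean = float(
        np.sqrt(np.mean((mean_filled.intensities.to_numpy()[mask] - X[mask]) ** 2))
    )
    return {"rmse_ls": rmse_ls, "rmse_mean": rmse_mean,
            "ratio": rmse_ls / rmse_mean, "masked_cells": int(mask.sum())}


def enrichment_recovery(seed: int = 0, n_features: int = 400, n_perm: int = 999) -> dict:
    """Planted enriched pathway must rank first with small empirical p."""
    spec = synth.DesignSpec(columns={"AE": n_features})
    eff = synth.EffectSpec(
        seed=_sub(seed, 700), frac_annotated=0.5,
        frac_age_up=0.15, frac_age_down=0.15,
    )
    table, truth = synth.generate_table(spec, eff)
    truth = synth.plant_pathways(truth, 10, (8, 12), n_enriched=1,
                                 seed=_sub(seed, 701))
    db = synth.compound_db_from_truth(truth)
    clean = qcmod.center_samples(qcmod.log_transform(table, qcmod.QCConfig()))
    res = univariate.run_univariate(clean)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        up = enr.select_top(res, "age", 60, 1, "AE")
        down = enr.select_top(res, "age", 60, -1, "AE")
    universe = truth.features.index.tolist()
    result = enr.enrich(up + down, universe, db, n_perm=n_perm,
                        mz_lookup=table.feature_meta["mz"], seed=_sub(seed, 702))
    planted = truth.pathways.index[truth.pathways["enriched"]].tolist()[0]
    frame = result.frame
    return {
        "planted_pathway": planted,
        "planted_rank": int(frame.index.get_loc(planted)) + 1,
        "planted_p": float(frame.loc[planted, "p_emp"]),
        "n_perm": n_perm,
    }


def enrichment_calibration(seed: int = 0, n_seeds: int = 30, n_perm: int = 199) -> dict:
    """KS uniformity of randomised empirical p-values under uniform assignment.

    The add-one empirical p is conservative and discrete; the
    randomised tie-broken variant is exactly uniform under the null and
    is what the uniformity test evaluates.
    """
    ps: list[float] = []
    for s in range(n_seeds):
        spec = synth.DesignSpec(columns={"AE": 250}, ages=(3, 24, 51))
        eff = synth.EffectSpec(seed=_sub(seed, 800 + s), frac_annotated=0.4,
                               **NULL_EFFECTS)
        table, truth = synth.generate_table(spec, eff)
        truth = synth.plant_pathways(truth, 10, (5, 10), n_enriched=0,
                                     seed=_sub(seed, 850 + s))
        db = synth.compound_db_from_truth(truth)
        rng = np.random.default_rng(_sub(seed, 900 + s))
        universe = truth.features.index.tolist()
        selected = list(rng.choice(universe, 50, replace=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = enr.enrich(selected, universe, db, n_perm=n_perm,
                             mz_lookup=table.feature_meta["mz"],
                             seed=_sub(seed, 950 + s))
        ps += res.frame["p_rand"].tolist()
    ps_arr = np.asarray(ps)
    return {
        "ks_p": float(kstest(ps_arr, "uniform").pvalue),
        "type_i_at_05": float((ps_arr <= 0.05).mean()),
        "n_pvalues": len(ps_arr),
    }


DETERMINISM_CONFIG = """\
seed: {seed}
outdir: {outdir}
design:
  columns: {{AE: 150, C18: 150}}
qc:
  snr_threshold: 0.5
multivariate:
  n_perm: 2
  repeats: 3
enrichment:
  n_perm: 199
  n_top: 50
"""


def determinism_check(seed: int = 0) -> dict:
    """Run the full CLI pipeline twice with one seed; outputs must be
    byte-identical. Uses a reduced table so the double run stays fast;
    the SNR threshold is set for biological-sample variance (see the
    methods note)."""
    from click.testing import CliRunner

    from .cli import main as cli_main

    runner = CliRunner()
    mismatched: list[str] = []
    with tempfile.TemporaryDirectory() as tmp:
        outs = []
        for run in (1, 2):
            outdir = Path(tmp) / f"run{run}"
            cfg_path = Path(tmp) / f"cfg{run}.yaml"
            cfg_path.write_text(
                DETERMINISM_CONFIG.format(seed=seed % (2**31), outdir=outdir)
            )
            result = runner.invoke(cli_main, ["--config", str(cfg_path), "all"])
            if result.exit_code != 0:
                raise RuntimeError(f"pipeline run failed: {result.output}")
            outs.append(outdir)
        files1 = sorted(p.name for p in outs[0].iterdir())
        files2 = sorted(p.name for p in outs[1].iterdir())
        if files1 != files2:
            mismatched.append("file lists differ")
        for name in files1:
            if not filecmp.cmp(outs[0] / name, outs[1] / name, shallow=False):
                mismatched.append(name)
    return {"identical": not mismatched, "mismatched": mismatched,
            "n_files": len(files1)}
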