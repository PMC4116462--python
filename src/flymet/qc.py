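"""Six-step quality-control cascade for LC-MS feature tables.

The steps run in a fixed order: (1) signal-to-noise filter on raw
intensities, (2) log transform, (3) removal of features missing from
more than a set fraction of either sex's samples, (4) least-squares
imputation of remaining missing cells from correlated neighbour
features, (5) m/z < 900 filter, (6) per-sample mean centring. Each step
logs what it removed or filled so the cascade is auditable.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, FeatureTable

_LOG_FNS = {"natural": np.log, "2": np.log2, "10": np.log10}


@dataclasses.dataclass
class QCConfig:
    snr_threshold: float = 15.0
    max_missing_frac_per_sex: float = 0.05
    mz_max: float = 900.0
    impute_neighbors: int = 10
    log_base: str = "natural"
    min_neighbor_overlap: int = 3

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise ConfigurationError("snr_threshold must be > 0")
        if not 0.0 <= self.max_missing_frac_per_sex < 1.0:
            raise ConfigurationError("max_missing_frac_per_sex must lie in [0, 1)")
        if self.mz_max <= 85.0:
            raise ConfigurationError("mz_max must exceed the instrument minimum (85)")
        if self.impute_neighbors < 1:
            raise ConfigurationError("impute_neighbors must be >= 1")
        if str(self.log_base) not in _LOG_FNS:
            raise ConfigurationError("log_base must be one of natural, 2, 10")


@dataclasses.dataclass
class QCReport:
    """Ordered per-step log of the cascade."""

    steps: list[dict] = dataclasses.field(default_factory=list)
    constant_features: list[str] = dataclasses.field(default_factory=list)
    imputed_cells: int = 0
    mean_fallback_cells: int = 0
    n_features_in: int = 0
    n_features_out: int = 0
    n_samples: int = 0

    def add(self, step: str, removed: int, detail: str = "") -> None:
        if removed < 0:
            raise ValueError("removal counts must be nonnegative")
        self.steps.append({"step": step, "removed": removed, "detail": detail})

    def removed(self, step: str) -> int:
        for rec in self.steps:
            if rec["step"] == step:
                return rec["removed"]
        raise KeyError(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "detail"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def log_lines(self) -> list[str]:
        lines = [
            f"qc: input {self.n_features_in} features x {self.n_samples} samples"
        ]
        for rec in self.steps:
            lines.append(f"qc: step {rec['step']}: removed {rec['removed']} features")
        lines.append(
            f"qc: imputed {self.imputed_cells} cells "
            f"({self.mean_fallback_cells} mean fallbacks); "
            f"output {self.n_features_out} features"
        )
        return lines


def filter_snr(table: FeatureTable, cfg: QCConfig) -> tuple[FeatureTable, dict]:
    """Keep features whose raw-intensity mean/SD is at or above threshold.

    Missing cells are ignored; the SD is the sample SD (ddof=1) over
    observed cells. Constant features (SD exactly 0) carry no measurable
    noise, so they are kept and flagged rather than removed. Features
    with fewer than two observed cells have undefined SD and are
    removed.
    """
    x = table.intensities.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(x), axis=1)
    mean = np.where(n_obs > 0, np.nansum(x, axis=1) / np.maximum(n_obs, 1), np.nan)
    sd = np.full(len(mean), np.nan)
    ok = n_obs >= 2
    if ok.any():
        sd[ok] = np.nanstd(x[ok], axis=1, ddof=1)
    constant = ok & (sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean / sd
    keep = ok & (constant | (snr >= cfg.snr_threshold))
    kept_ids = table.intensities.index[keep]
    entry = {
        "step": "snr",
        "removed": int((~keep).sum()),
        "detail": f"threshold {cfg.snr_threshold}; "
        f"{int((n_obs < 2).sum())} with <2 observations; "
        f"{int(constant.sum())} constant features kept+flagged",
        "constant_features": table.intensities.index[constant].tolist(),
    }
    return table.subset_features(kept_ids), entry


def log_transform(table: FeatureTable, cfg: QCConfig) -> FeatureTable:
    """Elementwise log of observed intensities; missing stays missing."""
    x = table.intensities.to_numpy(dtype=float)
    bad = ~np.isnan(x) & (x <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "nonpositive intensity in feature "
            f"{table.intensities.index[i]!r}, sample {table.intensities.columns[j]!r}"
        )
    out = table.copy()
    out.intensities = pd.DataFrame(
        _LOG_FNS[str(cfg.log_base)](x),
        index=table.intensities.index,
        columns=table.intensities.columns,
    )
    return out


def filter_missing_by_sex(
    table: FeatureTable, cfg: QCConfig
) -> tuple[FeatureTable, dict]:
    """Remove features missing from more than the allowed fraction of
    either all male or all female samples (strict '>')."""
    sex = table.sample_meta["sex"]
    frac_max = np.zeros(table.n_features)
    counts = sex.value_counts()
    if (counts == 0).any() or len(counts) < sex.nunique():
        raise ValueError("each sex must have at least one sample")
    for label in counts.index:
        cols = table.sample_meta.index[sex == label]
        if len(cols) == 0:
            raise ValueError(f"sex {label!r} has zero samples")
        frac = table.intensities[cols].isna().mean(axis=1).to_numpy()
        frac_max = np.maximum(frac_max, frac)
    keep = frac_max <= cfg.max_missing_frac_per_sex
    entry = {
        "step": "missing_by_sex",
        "removed": int((~keep).sum()),
        "detail": f"max fraction {cfg.max_missing_frac_per_sex} per sex (strict >)",
    }
    return table.subset_features(table.intensities.index[keep]), entry


def _pairwise_stats(sub: np.ndarray, full: np.ndarray):
    """Joint-observation moments between each row of `sub` and of `full`.

    Rows are features, columns samples; NaN marks missing. Returns the
    per-pair observation count, means, variances, covariance and
    Pearson r, all computed over jointly observed samples only.
    """
    ms = (~np.isnan(sub)).astype(float)
    mf = (~np.isnan(full)).astype(float)
    xs = np.nan_to_num(sub)
    xf = np.nan_to_num(full)
    n = ms @ mf.T
    sx = xs @ mf.T
    sy = ms @ xf.T
    sxx = (xs * xs) @ mf.T
    syy = ms @ (xf * xf).T
    sxy = xs @ xf.T
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = sx / n
        my = sy / n
        cov = sxy / n - mx * my
        vx = sxx / n - mx * mx
        vy = syy / n - my * my
        r = cov / np.sqrt(vx * vy)
    return n, mx, my, vx, vy, cov, r


def impute_ls(table: FeatureTable, cfg: QCConfig) -> tuple[FeatureTable, dict]:
    """Least-squares imputation from correlated neighbour features.

    Each missing cell (i, j) is filled with an r^2-weighted combination
    of single-regressor least-squares predictions from the K features
    most correlated with feature i (|Pearson r| over jointly observed
    samples), restricted to neighbours observed at sample j. When no
    eligible neighbour exists the feature mean is used; observed cells
    are never altered.
    """
    x = table.intensities.to_numpy(dtype=float).copy()
    nan_rows = np.where(np.isnan(x).any(axis=1))[0]
    imputed = 0
    fallbacks = 0
    if len(nan_rows):
        n, mx, my, vx, vy, cov, r = _pairwise_stats(x[nan_rows], x)
        eligible = (n >= cfg.min_neighbor_overlap) & np.isfinite(r)
        # a feature is never its own neighbour
        for a, i in enumerate(nan_rows):
            eligible[a, i] = False
        feat_means = np.nanmean(x, axis=1)
        obs_mask = ~np.isnan(x)
        for a, i in enumerate(nan_rows):
            cand = np.where(eligible[a])[0]
            order = cand[np.argsort(-np.abs(r[a, cand]), kind="stable")]
            miss_js = np.where(np.isnan(x[i]))[0]
            for j in miss_js:
                picked = []
                for kf in order:
                    if obs_mask[kf, j]:
                        picked.append(kf)
                        if len(picked) == cfg.impute_neighbors:
                            break
                weights = []
                preds = []
                for kf in picked:
                    if vy[a, kf] <= 0 or r[a, kf] == 0:
                        continue
                    slope = cov[a, kf] / vy[a, kf]
                    pred = mx[a, kf] + slope * (x[kf, j] - my[a, kf])
                    weights.append(r[a, kf] ** 2)
                    preds.append(pred)
                if preds and sum(weights) > 0:
                    x[i, j] = float(np.average(preds, weights=weights))
                else:
                    x[i, j] = feat_means[i]
                    fallbacks += 1
                imputed += 1
    out = table.copy()
    out.intensities = pd.DataFrame(
        x, index=table.intensities.index, columns=table.intensities.columns
    )
    entry = {
        "step": "impute",
        "removed": 0,
        "detail": f"imputed {imputed} cells, {fallbacks} feature-mean fallbacks",
        "imputed_cells": imputed,
        "fallback_cells": fallbacks,
    }
    return out, entry


def impute_mean(table: FeatureTable) -> FeatureTable:
    """Feature-mean imputation (baseline comparator for impute_ls)."""
    x = table.intensities.to_numpy(dtype=float).copy()
    means = np.nanmean(x, axis=1)
    idx = np.where(np.isnan(x))
    x[idx] = means[idx[0]]
    out = table.copy()
    out.intensities = pd.DataFrame(
        x, index=table.intensities.index, columns=table.intensities.columns
    )
    return out


def filter_mz(table: FeatureTable, cfg: QCConfig) -> tuple[FeatureTable, dict]:
    """Keep features with m/z strictly below the configured maximum."""
    mz = table.feature_meta["mz"]
    if mz.isna().any():
        raise ValueError("m/z metadata missing for some features")
    keep = mz < cfg.mz_max
    entry = {
        "step": "mz",
        "removed": int((~keep).sum()),
        "detail": f"m/z < {cfg.mz_max} (strict)",
    }
    return table.subset_features(table.intensities.index[keep]), entry


def center_samples(table: FeatureTable) -> FeatureTable:
    """Subtract each sample's mean over features (post-imputation)."""
    x = table.intensities.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("center_samples requires a complete (imputed) table")
    out = table.copy()
    centered = x - x.mean(axis=0, keepdims=True) if x.size else x
    out.intensities = pd.DataFrame(
        centered, index=table.intensities.index, columns=table.intensities.columns
    )
    return out


def run_qc(table: FeatureTable, cfg: QCConfig | None = None) -> tuple[FeatureTable, QCReport]:
    """Run the full cascade in order: SNR -> log -> missingness filter ->
    impute -> m/z filter -> centre."""
    cfg = cfg or QCConfig()
    report = QCReport(
        n_features_in=table.n_features, n_samples=table.n_samples
    )
    if table.n_features == 0:
        for step in ("snr", "log", "missing_by_sex", "impute", "mz", "center"):
            report.add(step, 0, "empty table")
        report.n_features_out = 0
        return table.copy(), report

    table, entry = filter_snr(table, cfg)
    report.add(entry["step"], entry["removed"], entry["detail"])
    report.constant_features = entry["constant_features"]

    table = log_transform(table, cfg)
    report.add("log", 0, f"base {cfg.log_base}")

    table, entry = filter_missing_by_sex(table, cfg)
    report.add(entry["step"], entry["removed"], entry["detail"])

    table, entry = impute_ls(table, cfg)
    report.add(entry["step"], entry["removed"], entry["detail"])
    report.imputed_cells = entry["imputed_cells"]
    report.mean_fallback_cells = entry["fallback_cells"]

    table, entry = filter_mz(table, cfg)
    report.add(entry["step"], entry["removed"], entry["detail"])

    table = center_samples(table)
    report.add("center", 0, "per-sample mean 0")

    report.n_features_out = table.n_features
    return table, report
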