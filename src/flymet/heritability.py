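"""Per-feature variance components and intraclass correlation among lines.

The model is a linear mixed model with age and sex as fixed effects and
genotype line as a single random intercept:

    y = X beta + Z b + eps,   b ~ N(0, sigma2_B I),  eps ~ N(0, sigma2_W I).

The intraclass correlation t = sigma2_B / (sigma2_B + sigma2_W) is the
heritability proxy for fully inbred lines. REML is the default
estimator; because the model has one variance ratio, the restricted
likelihood is profiled down to a one-dimensional optimisation over
lambda = sigma2_B / sigma2_W after projecting out the fixed effects,
which makes screening thousands of features cheap. An ANOVA
method-of-moments estimator is kept as an independently verifiable
cross-check.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import ConfigurationError, FeatureTable

_LOG_LAMBDA_MAX = 30.0  # lambda up to ~1e13: effectively the t -> 1 boundary


@dataclasses.dataclass
class VarianceComponents:
    sigma2_between: float
    sigma2_within: float
    estimator: str
    truncated: bool = False   # MoM between-line estimate clipped at 0
    boundary: bool = False    # REML hit the lambda boundary (t ~ 0 or ~ 1)
    degenerate: bool = False  # zero total variance; t undefined


def icc(components: VarianceComponents, n_individuals: int | None = None) -> float:
    """Intraclass correlation t = s2_B / (s2_B + s2_W).

    With ``n_individuals`` given, returns the pooled-sample variant
    s2_B / (s2_B + s2_W / n) instead (each measured sample pools n
    individuals, so the residual reflects a mean of n flies).
    """
    sb, sw = components.sigma2_between, components.sigma2_within
    if sb == 0 and sw == 0:
        if components.degenerate:
            return 0.0
        raise ValueError("both variance components are zero; t undefined")
    denom = sb + (sw / n_individuals if n_individuals else sw)
    return sb / denom


@dataclasses.dataclass
class _ProjectedDesign:
    """Fixed-effect-projected quantities reusable across features."""

    K: np.ndarray      # (n - p) x n basis of the orthogonal complement of X
    d: np.ndarray      # eigenvalues of K Z Z' K'
    U: np.ndarray      # eigenvectors
    lines: np.ndarray
    line_codes: np.ndarray
    X: np.ndarray


def _project_design(metadata: pd.DataFrame) -> _ProjectedDesign:
    lines, line_codes = np.unique(metadata["line"].to_numpy(), return_inverse=True)
    if len(lines) < 2:
        raise ConfigurationError("variance-component estimation needs >= 2 lines")
    counts = np.bincount(line_codes)
    if (counts < 2).any():
        raise ConfigurationError("every line needs >= 2 samples")
    n = len(metadata)
    # fixed effects: intercept + age (categorical) + sex
    blocks = [np.ones((n, 1))]
    for col in ("age", "sex"):
        levels, codes = np.unique(metadata[col].to_numpy(), return_inverse=True)
        if len(levels) > 1:
            dummies = np.eye(len(levels))[codes][:, 1:]
            blocks.append(dummies)
    X = np.column_stack(blocks)
    q, _ = np.linalg.qr(np.linalg.qr(X)[0], mode="complete")
    p = np.linalg.matrix_rank(X)
    K = q[:, p:].T  # (n - p) x n, K X = 0, K K' = I
    Z = np.eye(len(lines))[line_codes]
    A = (K @ Z) @ (K @ Z).T
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    return _ProjectedDesign(K=K, d=d, U=U, lines=lines, line_codes=line_codes, X=X)


def _reml_from_projection(w: np.ndarray, d: np.ndarray) -> tuple[float, float, bool]:
    """Profiled REML for one variance ratio given w = U'K'y.

    Returns (sigma2_B, sigma2_W, hit_boundary)."""
    m = len(w)
    w2 = w * w

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = 1.0 + lam * d
        s2w = np.sum(w2 / denom) / m
        if s2w <= 0:
            return np.inf
        return float(np.sum(np.log(denom)) + m * np.log(s2w))

    res = minimize_scalar(
        neg_restricted_ll,
        bounds=(-_LOG_LAMBDA_MAX, _LOG_LAMBDA_MAX),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x)
    # compare against the lambda = 0 boundary (no between-line variance)
    at_zero = float(m * np.log(np.sum(w2) / m)) if np.sum(w2) > 0 else np.inf
    if at_zero <= res.fun + 1e-10:
        s2w = np.sum(w2) / m
        return 0.0, float(s2w), False
    lam = np.exp(log_lam)
    denom = 1.0 + lam * d
    s2w = float(np.sum(w2 / denom) / m)
    boundary = log_lam > _LOG_LAMBDA_MAX - 1e-3
    return lam * s2w, s2w, boundary


def _mom(y: np.ndarray, proj: _ProjectedDesign) -> tuple[float, float, bool]:
    """ANOVA method of moments on fixed-effect-adjusted residuals."""
    X = proj.X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    codes = proj.line_codes
    n = len(r)
    L = len(proj.lines)
    counts = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=r) / counts
    grand = r.mean()
    msb = float(np.sum(counts * (means - grand) ** 2) / (L - 1))
    msw = float(np.sum((r - means[codes]) ** 2) / (n - L))
    n0 = (n - np.sum(counts**2) / n) / (L - 1)
    sb = (msb - msw) / n0
    truncated = sb < 0
    return max(sb, 0.0), msw, truncated


def estimate_components(
    y: np.ndarray,
    metadata: pd.DataFrame,
    estimator: str = "reml",
    _proj: _ProjectedDesign | None = None,
) -> VarianceComponents:
    """Estimate (sigma2_B, sigma2_W) for one feature.

    ``estimator``: 'reml' (default) maximises the restricted likelihood
    of the one-random-effect model; 'mom' equates ANOVA mean squares on
    residuals after OLS adjustment for age and sex.
    """
    estimator = estimator.lower()
    if estimator not in ("reml", "mom"):
        raise ConfigurationError("estimator must be 'reml' or 'mom'")
    y = np.asarray(y, dtype=float)
    proj = _proj if _proj is not None else _project_design(metadata)
    if len(y) != proj.K.shape[1]:
        raise ValueError("y length does not match metadata")
    if np.allclose(y, y[0]):
        return VarianceComponents(0.0, 0.0, estimator, degenerate=True)
    if estimator == "mom":
        sb, sw, truncated = _mom(y, proj)
        return VarianceComponents(sb, sw, "mom", truncated=truncated)
    w = proj.U.T @ (proj.K @ y)
    sb, sw, boundary = _reml_from_projection(w, proj.d)
    return VarianceComponents(sb, sw, "reml", boundary=boundary)


@dataclasses.dataclass
class HeritabilityResult:
    """Per-feature variance components, t, ranks and screen flags."""

    frame: pd.DataFrame  # feature_id index: column, sigma2_B, sigma2_W, t, rank, ...
    threshold: float
    top_n: int

    def top_features(self, column: str | None = None) -> list[str]:
        sub = self.frame if column is None else self.frame[self.frame["column"] == column]
        return sub.index[sub["top"] == 1].tolist()

    def write(self, path: str | Path) -> None:
        out = self.frame.rename(columns={"top": f"top{self.top_n}"})
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read(cls, path: str | Path, threshold: float = 0.05, top_n: int = 150):
        frame = pd.read_csv(path, sep="\t", index_col="feature_id")
        top_col = [c for c in frame.columns if c.startswith("top")][0]
        frame = frame.rename(columns={top_col: "top"})
        return cls(frame=frame, threshold=threshold, top_n=top_n)


def heritability_screen(
    table: FeatureTable,
    estimator: str = "reml",
    threshold: float = 0.05,
    top_n: int = 150,
    n_individuals: int | None = None,
) -> HeritabilityResult:
    """Estimate t for every feature; rank and flag per column.

    Ranks are within-column, descending in t (ties broken by feature
    id); the top ``top_n`` features per column feed pathway-enrichment
    of heritable metabolites. t is clipped below 1 at the lambda
    boundary (flagged), and 0 when a feature has no variance at all.
    """
    frames = []
    for column in table.columns_present():
        ct = table.for_column(column)
        Y = ct.intensities.to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise ValueError("heritability screen requires a complete (QC'd) table")
        proj = _project_design(ct.sample_meta)
        recs = []
        for i, fid in enumerate(ct.intensities.index):
            comp = estimate_components(Y[i], ct.sample_meta, estimator, _proj=proj)
            if comp.degenerate:
                t = 0.0
            else:
                t = icc(comp, n_individuals)
                if comp.boundary and t >= 1.0:
                    t = np.nextafter(1.0, 0.0)
            recs.append(
                (
                    fid, column, comp.sigma2_between, comp.sigma2_within, t,
                    int(comp.truncated or comp.boundary or comp.degenerate),
                )
            )
        frame = pd.DataFrame(
            recs,
            columns=["feature_id", "column", "sigma2_B", "sigma2_W", "t", "flagged"],
        ).set_index("feature_id")
        order = frame.sort_values(
            ["t", "feature_id"], ascending=[False, True], kind="stable"
        ).index
        frame["rank"] = pd.Series(
            np.arange(1, len(order) + 1), index=order
        ).reindex(frame.index)
        frame["heritable"] = (frame["t"] >= threshold).astype(int)
        frame["top"] = (frame["rank"] <= top_n).astype(int)
        frames.append(frame)
    out = pd.concat(frames) if frames else pd.DataFrame(
        columns=["column", "sigma2_B", "sigma2_W", "t", "flagged", "rank",
                 "heritable", "top"]
    )
    return HeritabilityResult(frame=out, threshold=threshold, top_n=top_n)
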