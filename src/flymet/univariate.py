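"""Per-feature factorial linear models with per-factor FDR.

Each feature's log intensity is modelled as

    Y = mu + A + S + G + A:S + A:G + S:G (+ A:S:G) + eps

with age (A) an ordered factor encoded by orthogonal polynomial
contrasts, sex (S) a single +/-1 contrast (M = +1), and genotype (G)
deviation-coded line indicators; all predictors are fixed effects.
Age and sex terms are tested by partial F-tests; genotype-containing
terms by likelihood-ratio tests on nested OLS fits. Benjamini-Hochberg
FDR control is applied separately per factor across features, and
significant age/sex effects receive direction labels from the linear
age-trend and sex contrast coefficients.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, FeatureTable

MAIN_TERMS = ("age", "sex", "genotype")
TWO_WAY = ("age:sex", "age:genotype", "sex:genotype")
THREE_WAY = "age:sex:genotype"

# factors tested with a likelihood-ratio statistic rather than a partial F
GENOTYPE_TERMS = ("genotype", "age:genotype", "sex:genotype", THREE_WAY)

DIRECTIONAL_FACTORS = ("age", "sex")


@dataclasses.dataclass
class ModelSpec:
    drop_age: tuple[int, ...] = (81,)
    fdr_alpha: float = 0.01
    include_three_way: bool = False
    # "exact": finite-sample null of the LR statistic (equals the partial-F
    # p-value for nested Gaussian OLS); "chi2": classical asymptotic reference
    genotype_test: str = "exact"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ConfigurationError("fdr_alpha must lie in (0, 1)")
        if self.genotype_test not in ("exact", "chi2"):
            raise ConfigurationError("genotype_test must be 'exact' or 'chi2'")

    @property
    def terms(self) -> tuple[str, ...]:
        t = MAIN_TERMS + TWO_WAY
        return t + (THREE_WAY,) if self.include_three_way else t


def poly_contrasts(k: int) -> np.ndarray:
    """Orthogonal polynomial contrasts for k equally spaced ordered levels.

    Returns a (k, k-1) matrix whose columns are the linear, quadratic, ...
    degree contrasts, each orthogonal to the intercept and of unit norm.
    """
    if k < 2:
        raise ConfigurationError("ordered factor needs >= 2 levels")
    pos = np.arange(1, k + 1, dtype=float)
    v = np.vander(pos, k, increasing=True)
    q, _ = np.linalg.qr(v)
    c = q[:, 1:]
    # fix sign so the linear column increases with level order
    for j in range(c.shape[1]):
        lead = c[-1, j] - c[0, j] if j == 0 else c[-1, j]
        if lead < 0:
            c[:, j] = -c[:, j]
    return c


@dataclasses.dataclass
class Design:
    matrix: np.ndarray
    colnames: list[str]
    term_cols: dict[str, list[int]]
    sample_ids: list[str]
    age_levels: list[int]
    # column indices used for direction / sign labelling
    idx_age_linear: int = -1
    idx_sex: int = -1
    idx_age_sex_linear: int = -1

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def encode_design(sample_meta: pd.DataFrame, spec: ModelSpec | None = None) -> Design:
    """Build the fixed-effects design matrix for the factorial model.

    Expects metadata from which dropped ages have already been removed.
    Age: orthogonal polynomial contrasts over its ordered levels; sex:
    one +/-1 contrast (M = +1); genotype: deviation coding over lines;
    interactions: elementwise products of the component columns.
    """
    spec = spec or ModelSpec()
    ages = sorted(sample_meta["age"].unique().tolist())
    sexes = sorted(sample_meta["sex"].unique().tolist())
    lines = sorted(sample_meta["line"].unique().tolist())
    if len(sexes) != 2:
        raise ConfigurationError(f"expected exactly 2 sexes, got {sexes}")
    if len(lines) < 2:
        raise ConfigurationError("need >= 2 genotype lines")
    k = len(ages)
    n = len(sample_meta)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {"intercept": [0]}

    # age: orthogonal polynomial contrasts
    pc = poly_contrasts(k)
    age_rank = sample_meta["age"].map({a: i for i, a in enumerate(ages)}).to_numpy()
    age_block = pc[age_rank]  # n x (k-1)
    term_cols["age"] = list(range(len(cols), len(cols) + k - 1))
    for d in range(k - 1):
        cols.append(age_block[:, d])
        names.append(f"age^{d + 1}")

    # sex contrast: M = +1 when present, else the later label
    plus = "M" if "M" in sexes else sexes[-1]
    sex_col = np.where(sample_meta["sex"].to_numpy() == plus, 1.0, -1.0)
    term_cols["sex"] = [len(cols)]
    cols.append(sex_col)
    names.append("sex")

    # genotype: deviation (sum-to-zero) coding over lines
    gcols = []
    line_arr = sample_meta["line"].to_numpy()
    for line in lines[:-1]:
        col = np.where(line_arr == line, 1.0, np.where(line_arr == lines[-1], -1.0, 0.0))
        gcols.append(col)
    term_cols["genotype"] = list(range(len(cols), len(cols) + len(gcols)))
    for line, col in zip(lines[:-1], gcols):
        cols.append(col)
        names.append(f"geno[{line}]")

    def add_products(term: str, blocks: list[tuple[str, np.ndarray]]) -> None:
        term_cols[term] = []
        for bname, bcol in blocks:
            term_cols[term].append(len(cols))
            cols.append(bcol)
            names.append(bname)

    add_products(
        "age:sex",
        [(f"age^{d + 1}:sex", age_block[:, d] * sex_col) for d in range(k - 1)],
    )
    add_products(
        "age:genotype",
        [
            (f"age^{d + 1}:geno[{line}]", age_block[:, d] * g)
            for d in range(k - 1)
            for line, g in zip(lines[:-1], gcols)
        ],
    )
    add_products(
        "sex:genotype",
        [(f"sex:geno[{line}]", sex_col * g) for line, g in zip(lines[:-1], gcols)],
    )
    if spec.include_three_way:
        add_products(
            THREE_WAY,
            [
                (f"age^{d + 1}:sex:geno[{line}]", age_block[:, d] * sex_col * g)
                for d in range(k - 1)
                for line, g in zip(lines[:-1], gcols)
            ],
        )

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which terms lose rank when added cumulatively
        aliased = []
        seen: list[int] = []
        for term, idx in term_cols.items():
            prev = np.linalg.matrix_rank(X[:, seen]) if seen else 0
            seen += idx
            if np.linalg.matrix_rank(X[:, seen]) - prev < len(idx):
                aliased.append(term)
        raise ConfigurationError(f"design is rank deficient; aliased terms: {aliased}")

    d = Design(
        matrix=X,
        colnames=names,
        term_cols=term_cols,
        sample_ids=sample_meta.index.tolist(),
        age_levels=ages,
        idx_age_linear=term_cols["age"][0],
        idx_sex=term_cols["sex"][0],
        idx_age_sex_linear=term_cols["age:sex"][0],
    )
    return d


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of OLS fits of each row of Y on X."""
    q, _ = np.linalg.qr(X)
    fitted = (Y @ q) @ q.T
    resid = Y - fitted
    return np.einsum("ij,ij->i", resid, resid)


def likelihood_ratio(
    rss_reduced: float | np.ndarray,
    rss_full: float | np.ndarray,
    df_diff: int,
    n: int,
    df_resid_full: int,
    method: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """LR statistic 2*dlogL = n*log(RSS0/RSS1) for nested Gaussian OLS fits.

    ``method='chi2'`` uses the asymptotic chi-square reference;
    ``method='exact'`` evaluates the statistic against its exact
    finite-sample null (a monotone transform of the partial F), which
    stays calibrated when df_diff is large relative to n.
    """
    if df_diff == 0:
        raise ValueError("degenerate nesting: models have the same df")
    if df_diff < 0:
        raise ValueError("reduced model must have fewer parameters")
    rss0 = np.asarray(rss_reduced, dtype=float)
    rss1 = np.asarray(rss_full, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = n * np.log(rss0 / rss1)
        if method == "chi2":
            p = stats.chi2.sf(lr, df_diff)
        else:
            f = ((rss0 - rss1) / df_diff) / (rss1 / df_resid_full)
            p = stats.f.sf(f, df_diff, df_resid_full)
    return lr, p


@dataclasses.dataclass
class FeatureFit:
    coefficients: pd.Series
    residuals: np.ndarray
    df_resid: int
    rss: float
    loglik: float
    p_values: pd.Series          # per tested term
    statistics: pd.Series        # F or LR value per term
    reduced_loglik: pd.Series    # log-likelihood of each term-dropped fit
    design: Design


def _loglik(rss: np.ndarray | float, n: int) -> np.ndarray:
    rss = np.asarray(rss, dtype=float)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def fit_features(
    Y: np.ndarray, design: Design, spec: ModelSpec | None = None
) -> dict[str, pd.DataFrame | pd.Series]:
    """OLS fit of every feature (rows of Y) with per-term tests, vectorised.

    Returns per-term p-values and test statistics, the coefficients used
    for direction/sign labels, and fit summaries.
    """
    spec = spec or ModelSpec()
    X = design.matrix
    n, p = X.shape
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != n:
        raise ValueError("length of y must equal the number of design rows")
    df_resid = n - p
    if df_resid <= 0:
        raise ConfigurationError("no residual degrees of freedom")

    q, r = np.linalg.qr(X)
    beta = np.linalg.solve(r, (Y @ q).T).T  # features x p
    rss_full = _rss(X, Y)

    pvals = {}
    statistics = {}
    red_ll = {}
    for term in spec.terms:
        idx = design.term_cols[term]
        keep = [j for j in range(p) if j not in set(idx)]
        rss_red = _rss(X[:, keep], Y)
        df_diff = len(idx)
        if term in GENOTYPE_TERMS:
            stat, pv = likelihood_ratio(
                rss_red, rss_full, df_diff, n, df_resid, method=spec.genotype_test
            )
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = ((rss_red - rss_full) / df_diff) / (rss_full / df_resid)
            pv = stats.f.sf(stat, df_diff, df_resid)
        pvals[term] = pv
        statistics[term] = stat
        red_ll[term] = _loglik(rss_red, n)

    return {
        "p_values": pd.DataFrame(pvals),
        "statistics": pd.DataFrame(statistics),
        "coef": pd.DataFrame(
            {
                "age_linear": beta[:, design.idx_age_linear],
                "sex": beta[:, design.idx_sex],
                "age_sex_linear": beta[:, design.idx_age_sex_linear],
            }
        ),
        "beta": beta,
        "rss": rss_full,
        "df_resid": df_resid,
        "loglik": _loglik(rss_full, n),
        "reduced_loglik": pd.DataFrame(red_ll),
    }


def fit_feature(y: np.ndarray, design: Design, spec: ModelSpec | None = None) -> FeatureFit:
    """Fit a single feature and package the result."""
    spec = spec or ModelSpec()
    res = fit_features(np.asarray(y, dtype=float), design, spec)
    beta = res["beta"][0]
    fitted = design.matrix @ beta
    return FeatureFit(
        coefficients=pd.Series(beta, index=design.colnames),
        residuals=np.asarray(y, dtype=float) - fitted,
        df_resid=res["df_resid"],
        rss=float(res["rss"][0]),
        loglik=float(res["loglik"][0]),
        p_values=res["p_values"].iloc[0],
        statistics=res["statistics"].iloc[0],
        reduced_loglik=res["reduced_loglik"].iloc[0],
        design=design,
    )


#: coefficients below this magnitude are numerically zero ("flat")
FLAT_TOL = 1e-10


def classify_direction(fit: FeatureFit, flat_tol: float = FLAT_TOL) -> dict[str, str]:
    """Direction labels from the linear age contrast and sex contrast.

    Age: sign of the degree-1 orthogonal polynomial coefficient ('up' /
    'down'); sex: sign of the sex contrast ('M' = male-higher, 'F' =
    female-higher). A (numerically) zero coefficient is labelled
    'flat' and excluded from both direction counts.
    """
    age_c = fit.coefficients.iloc[fit.design.idx_age_linear]
    sex_c = fit.coefficients.iloc[fit.design.idx_sex]
    age = "flat" if abs(age_c) <= flat_tol else ("up" if age_c > 0 else "down")
    sex = "flat" if abs(sex_c) <= flat_tol else ("M" if sex_c > 0 else "F")
    return {"age": age, "sex": sex}


def bh_adjust(p, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up decisions and adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


@dataclasses.dataclass
class FactorResults:
    """Tidy per-feature, per-factor results (one row per feature x factor)."""

    frame: pd.DataFrame
    alpha: float

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, alpha: float = 0.01) -> "FactorResults":
        frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        frame["p_raw"] = frame["p_raw"].astype(float)
        frame["p_adj"] = frame["p_adj"].astype(float)
        frame["sign_coef"] = frame["sign_coef"].astype(float)
        frame["significant"] = frame["significant"].astype(int)
        return cls(frame=frame, alpha=alpha)


def run_univariate(table: FeatureTable, spec: ModelSpec | None = None) -> FactorResults:
    """Fit the factorial model per feature, column by column.

    Drops the configured ages (small/incomplete cells), fits every
    feature on each chromatography column separately, applies BH FDR
    per factor within each column, and attaches direction labels and
    the signed coefficients used for ranked selections.
    """
    spec = spec or ModelSpec()
    missing_drop = set(spec.drop_age) - set(table.sample_meta["age"].unique())
    if missing_drop:
        raise ConfigurationError(f"drop_age values not in design: {sorted(missing_drop)}")
    keep = ~table.sample_meta["age"].isin(spec.drop_age)
    sub = table.subset_samples(table.sample_meta.index[keep])

    rows = []
    for column in sub.columns_present():
        ct = sub.for_column(column)
        if ct.n_features == 0:
            continue
        design = encode_design(ct.sample_meta, spec)
        Y = ct.intensities.to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise ValueError("univariate stage requires a complete (QC'd) table")
        res = fit_features(Y, design, spec)
        fids = ct.intensities.index.to_numpy()
        # stable ordering for reproducible reporting of tied p-values
        order = np.argsort(fids, kind="stable")
        for term in spec.terms:
            p = res["p_values"][term].to_numpy()
            reject, p_adj = bh_adjust(p[order], spec.fdr_alpha)
            rej = np.empty_like(reject)
            padj = np.empty_like(p_adj)
            rej[order] = reject
            padj[order] = p_adj
            if term == "age":
                sign = res["coef"]["age_linear"].to_numpy()
            elif term == "sex":
                sign = res["coef"]["sex"].to_numpy()
            elif term == "age:sex":
                sign = res["coef"]["age_sex_linear"].to_numpy()
            else:
                sign = np.zeros(len(fids))
            direction = np.full(len(fids), "", dtype=object)
            if term in DIRECTIONAL_FACTORS:
                eff = np.where(np.abs(sign) <= FLAT_TOL, 0.0, sign)
                if term == "age":
                    lab = np.where(eff > 0, "up", np.where(eff < 0, "down", "flat"))
                else:
                    lab = np.where(eff > 0, "M", np.where(eff < 0, "F", "flat"))
                direction[rej] = lab[rej]
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": fids,
                        "column": column,
                        "factor": term,
                        "p_raw": p,
                        "p_adj": padj,
                        "significant": rej.astype(int),
                        "direction": direction,
                        "sign_coef": sign,
                    }
                )
            )
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "feature_id", "column", "factor", "p_raw", "p_adj",
                "significant", "direction", "sign_coef",
            ]
        )
    )
    return FactorResults(frame=frame, alpha=spec.fdr_alpha)


_SUMMARY_ROWS = [
    ("Increase with age", "age", "up"),
    ("Decrease with age", "age", "down"),
    ("Increase in males", "sex", "M"),
    ("Increase in females", "sex", "F"),
    ("Genotype", "genotype", None),
    ("Age x sex", "age:sex", None),
    ("Age x genotype", "age:genotype", None),
    ("Sex x genotype", "sex:genotype", None),
    ("Age x sex x genotype", THREE_WAY, None),
]


def summarize_table1(results: FactorResults) -> pd.DataFrame:
    """Counts and percentages of significant features per factor and column.

    Directional factors are split into up/down (age) and male-/female-
    higher (sex); percentages are relative to each column's feature
    total.
    """
    frame = results.frame
    columns = sorted(frame["column"].unique().tolist())
    factors_present = set(frame["factor"].unique())
    if not columns:
        return pd.DataFrame(index=pd.Index([], name="parameter"))
    labels: list[str] = []
    out = {}
    for column in columns:
        sub = frame[frame["column"] == column]
        total = sub["feature_id"].nunique()
        counts = []
        labels = []
        for label, factor, direction in _SUMMARY_ROWS:
            if factor not in factors_present:
                continue
            sel = sub[(sub["factor"] == factor) & (sub["significant"] == 1)]
            if direction is not None:
                sel = sel[sel["direction"] == direction]
            counts.append(len(sel))
            labels.append(label)
        out[f"n_{column}"] = counts
        out[f"pct_{column}"] = [
            round(100.0 * c / total, 1) if total else 0.0 for c in counts
        ]
    return pd.DataFrame(out, index=pd.Index(labels, name="parameter"))
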