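"""Putative m/z annotation and pathway enrichment with a selection-permutation null.

Features are annotated by matching observed m/z against theoretical
positive-mode adduct masses (M+H, M+Na, M+K, M+H-H2O) of database
compounds within a ppm tolerance. A single m/z commonly matches several
candidate compounds; rather than resolving that ambiguity, the
enrichment statistic (selected features with at least one candidate in
the pathway) is compared against a null built by re-drawing random
same-size feature selections from the full feature list and
re-annotating them with identical rules, so the ambiguity cancels
between observed and null. An add-one empirical p-value avoids zeros
at finite permutation counts; a randomised tie-broken variant (exactly
uniform under the null despite the discreteness of overlap counts) and
a compound-level hypergeometric p are reported alongside.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import ConfigurationError

PROTON = 1.00727646
_E = 0.00054858  # electron mass

#: Positive-mode electrospray adducts: (name, m/z shift in Da, charge +1)
DEFAULT_ADDUCTS = (
    ("M+H", PROTON),
    ("M+Na", 22.98976928 - _E),
    ("M+K", 38.96370649 - _E),
    ("M+H-H2O", PROTON - 18.01056468),
)

DEFAULT_TOL_PPM = 10.0


@dataclasses.dataclass
class CompoundDB:
    """Compound masses plus pathway membership.

    ``compounds``: indexed by compound_id with columns name, mass (Da,
    monoisotopic, > 0). ``pathways``: indexed by pathway_id with
    columns name and members (list of compound ids).
    """

    compounds: pd.DataFrame
    pathways: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.compounds) and (self.compounds["mass"] <= 0).any():
            raise ConfigurationError("compound masses must be positive")
        known = set(self.compounds.index)
        for pid, members in self.pathways.get("members", pd.Series(dtype=object)).items():
            missing = set(members) - known
            if missing:
                raise ConfigurationError(
                    f"pathway {pid} references unknown compounds: {sorted(missing)[:3]}"
                )

    def write(self, outdir: str | Path, prefix: str = "db") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": outdir / f"{prefix}_compounds.tsv",
            "pathways": outdir / f"{prefix}_pathways.tsv",
        }
        self.compounds.to_csv(paths["compounds"], sep="\t", index_label="compound_id")
        pw = self.pathways.copy()
        if len(pw):
            pw["members"] = [",".join(m) for m in pw["members"]]
        pw.to_csv(paths["pathways"], sep="\t", index_label="pathway_id")
        return paths

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "db") -> "CompoundDB":
        outdir = Path(outdir)
        compounds = pd.read_csv(
            outdir / f"{prefix}_compounds.tsv", sep="\t", index_col="compound_id"
        )
        pathways = pd.read_csv(
            outdir / f"{prefix}_pathways.tsv", sep="\t", index_col="pathway_id"
        )
        if len(pathways):
            pathways["members"] = [
                m.split(",") if isinstance(m, str) and m else []
                for m in pathways["members"]
            ]
            if "enriched" not in pathways.columns:
                pathways["enriched"] = False
        else:
            pathways = pd.DataFrame(
                {"name": pd.Series(dtype=str), "members": pd.Series(dtype=object),
                 "enriched": pd.Series(dtype=bool)},
                index=pd.Index([], name="pathway_id"),
            )
        return cls(compounds=compounds, pathways=pathways)


# A small synthetic fixture database: real monoisotopic masses for fly
# metabolites of interest, grouped into illustrative (not curated)
# pathway sets. Meant for examples and tests, not biological inference.
_FIXTURE_COMPOUNDS = [
    # id, name, monoisotopic mass
    ("FLY001", "glutamine", 146.069142),
    ("FLY002", "tryptophan", 204.089878),
    ("FLY003", "proline", 115.063329),
    ("FLY004", "gamma-aminobutyrate", 103.063329),
    ("FLY005", "dopamine", 153.078979),
    ("FLY006", "serotonin", 176.094963),
    ("FLY007", "kynurenine", 208.084792),
    ("FLY008", "glucose 6-phosphate", 260.029719),
    ("FLY009", "trehalose", 342.116212),
    ("FLY010", "carnitine", 161.105193),
    ("FLY011", "oleoylcarnitine", 425.350509),
    ("FLY012", "arginine", 174.111676),
    ("FLY013", "phenylalanine", 165.078979),
    ("FLY014", "methionine", 149.051050),
    ("FLY015", "threonine", 119.058243),
    ("FLY016", "aspartate", 133.037508),
    ("FLY017", "leucine", 131.094629),
    ("FLY018", "5-hydroxytryptophan", 220.084792),
    ("FLY019", "l-dopa", 197.068808),
    ("FLY020", "N-acetylserotonin", 218.105528),
    ("FLY021", "sphingosine", 299.282429),
    ("FLY022", "choline phosphate", 183.066045),
    ("FLY023", "pantothenate", 219.110673),
    ("FLY024", "pyruvate", 88.016044),
    ("FLY025", "tetrahydrobiopterin", 241.117489),
]

_FIXTURE_PATHWAYS = [
    ("FPW01", "tryptophan degradation (synthetic grouping)",
     ["FLY002", "FLY007", "FLY018"]),
    ("FPW02", "serotonin and melatonin biosynthesis (synthetic grouping)",
     ["FLY002", "FLY006", "FLY018", "FLY020"]),
    ("FPW03", "monoamine metabolism (synthetic grouping)",
     ["FLY005", "FLY019", "FLY025"]),
    ("FPW04", "glycolysis feeders (synthetic grouping)",
     ["FLY008", "FLY009", "FLY024"]),
    ("FPW05", "carnitine shuttle (synthetic grouping)",
     ["FLY010", "FLY011"]),
    ("FPW06", "amino acids (synthetic grouping)",
     ["FLY001", "FLY003", "FLY012", "FLY013", "FLY014", "FLY015", "FLY016",
      "FLY017"]),
]


def fixture_db() -> CompoundDB:
    """Bundled synthetic fixture database (real masses, synthetic pathways)."""
    compounds = pd.DataFrame(
        _FIXTURE_COMPOUNDS, columns=["compound_id", "name", "mass"]
    ).set_index("compound_id")
    pathways = pd.DataFrame(
        [(pid, name, members, False) for pid, name, members in _FIXTURE_PATHWAYS],
        columns=["pathway_id", "name", "members", "enriched"],
    ).set_index("pathway_id")
    return CompoundDB(compounds=compounds, pathways=pathways)


@dataclasses.dataclass
class MatchSet:
    """Per-feature candidate (compound, adduct) matches within tolerance."""

    matches: pd.DataFrame  # feature_id, compound_id, adduct, ppm_error
    tol_ppm: float

    def compounds_for(self, feature_ids) -> set[str]:
        sub = self.matches[self.matches["feature_id"].isin(set(feature_ids))]
        return set(sub["compound_id"])

    def feature_compounds(self) -> dict[str, set[str]]:
        return {
            fid: set(grp["compound_id"])
            for fid, grp in self.matches.groupby("feature_id")
        }

    def write(self, path: str | Path) -> None:
        self.matches.to_csv(path, sep="\t", index=False)


def annotate(
    mz_values,
    db: CompoundDB,
    rules=DEFAULT_ADDUCTS,
    tol_ppm: float = DEFAULT_TOL_PPM,
    feature_ids=None,
) -> MatchSet:
    """Match observed positive-mode m/z to adduct masses of db compounds.

    A feature matches (compound, adduct) when |observed - theoretical| /
    theoretical <= tol_ppm * 1e-6; features may match many compounds
    and compounds many features.
    """
    if len(db.compounds) == 0:
        raise ConfigurationError("empty compound database")
    if tol_ppm < 0:
        raise ConfigurationError("tolerance must be >= 0")
    mz = np.asarray(mz_values, dtype=float)
    fids = (
        np.asarray(feature_ids, dtype=object)
        if feature_ids is not None
        else np.arange(len(mz)).astype(object)
    )
    comp_ids = db.compounds.index.to_numpy()
    masses = db.compounds["mass"].to_numpy(dtype=float)

    rows = []
    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]
    for name, shift in rules:
        theo = masses + shift
        valid = theo > 0
        tol = theo * tol_ppm * 1e-6
        lo = np.searchsorted(mz_sorted, theo - tol, side="left")
        hi = np.searchsorted(mz_sorted, theo + tol, side="right")
        for ci in np.where(valid)[0]:
            for k in range(lo[ci], hi[ci]):
                fi = order[k]
                ppm = (mz[fi] - theo[ci]) / theo[ci] * 1e6
                rows.append((fids[fi], comp_ids[ci], name, ppm))
    matches = pd.DataFrame(
        rows, columns=["feature_id", "compound_id", "adduct", "ppm_error"]
    ).sort_values(["feature_id", "compound_id", "adduct"], kind="stable")
    return MatchSet(matches=matches.reset_index(drop=True), tol_ppm=tol_ppm)


def select_top(
    results,
    factor: str,
    n: int = 250,
    sign: int | None = None,
    column: str | None = None,
) -> list[str]:
    """The n smallest-p features for a factor, optionally among one sign.

    ``sign=+1``/``-1`` restricts to positively/negatively associated
    features (by the factor's signed coefficient), as used for age, sex
    and age x sex lists; ``sign=None`` ranks purely by p-value (age x
    genotype). Ties at the cutoff break by feature id.
    """
    frame = results.frame
    sub = frame[frame["factor"] == factor]
    if column is not None:
        sub = sub[sub["column"] == column]
    if sign is not None:
        if sign not in (1, -1):
            raise ConfigurationError("sign must be +1, -1 or None")
        sub = sub[np.sign(sub["sign_coef"]) == sign]
    sub = sub.sort_values(["p_raw", "feature_id"], kind="stable")
    if len(sub) < n:
        warnings.warn(
            f"only {len(sub)} features available for {factor} "
            f"(sign={sign}); requested {n}",
            stacklevel=2,
        )
    return sub["feature_id"].head(n).tolist()


@dataclasses.dataclass
class EnrichmentResult:
    """Per-pathway overlap counts and p-values."""

    frame: pd.DataFrame  # pathway_id index: observed, size, p_hyper, p_emp, p_rand
    n_perm: int

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="pathway_id")


def _pathway_indicator(
    feature_ids: np.ndarray, match: MatchSet, db: CompoundDB
) -> np.ndarray:
    """Boolean (features x pathways): feature has >= 1 candidate in pathway."""
    fc = match.feature_compounds()
    pw_sets = [set(m) for m in db.pathways["members"]]
    ind = np.zeros((len(feature_ids), len(pw_sets)), dtype=bool)
    for i, fid in enumerate(feature_ids):
        cands = fc.get(fid)
        if not cands:
            continue
        for j, pw in enumerate(pw_sets):
            if cands & pw:
                ind[i, j] = True
    return ind


def enrich(
    selected,
    universe,
    db: CompoundDB,
    rules=DEFAULT_ADDUCTS,
    n_perm: int = 999,
    tol_ppm: float = DEFAULT_TOL_PPM,
    mz_lookup: pd.Series | None = None,
    seed: int = 0,
) -> EnrichmentResult:
    """Pathway enrichment of a selected feature list versus random selections.

    The observed statistic per pathway counts selected features with at
    least one candidate compound in the pathway. The null re-draws
    ``n_perm`` random selections of the same size from the universe and
    recomputes the identical statistic (annotation ambiguity flows
    through both sides). Reported per pathway: the add-one empirical
    p, a randomised tie-broken empirical p (uniform under the null),
    and a hypergeometric p on resolved compound sets.
    """
    if mz_lookup is None:
        raise ConfigurationError("mz_lookup (feature_id -> m/z) is required")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse empirical p resolution", stacklevel=2
        )
    selected = list(selected)
    universe = list(universe)
    if not set(selected) <= set(universe):
        raise ConfigurationError("selected features must belong to the universe")
    if len(db.pathways) == 0:
        return EnrichmentResult(
            frame=pd.DataFrame(
                columns=["name", "size", "observed", "p_hyper", "p_emp", "p_rand"],
                index=pd.Index([], name="pathway_id"),
            ),
            n_perm=n_perm,
        )
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    match = annotate(
        mz_lookup.loc[uni].to_numpy(), db, rules, tol_ppm, feature_ids=uni
    )
    ind = _pathway_indicator(uni, match, db)  # |U| x n_pathways
    pos = {fid: i for i, fid in enumerate(uni)}
    sel_idx = np.array([pos[f] for f in selected], dtype=int)
    observed = ind[sel_idx].sum(axis=0)

    m = len(selected)
    null_counts = np.zeros((n_perm, ind.shape[1]), dtype=int)
    for b in range(n_perm):
        draw = rng.choice(len(uni), size=m, replace=False)
        null_counts[b] = ind[draw].sum(axis=0)

    ge = (null_counts >= observed[None, :]).sum(axis=0)
    gt = (null_counts > observed[None, :]).sum(axis=0)
    eq = ge - gt
    p_emp = (1.0 + ge) / (1.0 + n_perm)
    u = rng.uniform(size=ind.shape[1])
    p_rand = (gt + u * (eq + 1.0)) / (1.0 + n_perm)

    # compound-level hypergeometric on resolved candidate sets
    sel_compounds = match.compounds_for(selected)
    uni_compounds = match.compounds_for(universe)
    N, K = len(uni_compounds), len(sel_compounds)
    p_hyper = np.ones(ind.shape[1])
    sizes = np.array([len(mbs) for mbs in db.pathways["members"]])
    for j, members in enumerate(db.pathways["members"]):
        in_uni = len(set(members) & uni_compounds)
        k_obs = len(set(members) & sel_compounds)
        if in_uni and N and K:
            p_hyper[j] = float(hypergeom.sf(k_obs - 1, N, in_uni, K))
    frame = pd.DataFrame(
        {
            "name": db.pathways["name"].to_numpy(),
            "size": sizes,
            "observed": observed,
            "p_hyper": p_hyper,
            "p_emp": p_emp,
            "p_rand": p_rand,
        },
        index=db.pathways.index.copy(),
    ).sort_values(["p_emp", "p_hyper"], kind="stable")
    return EnrichmentResult(frame=frame, n_perm=n_perm)


def heritable_enrichment(
    herit_result,
    feature_meta: pd.DataFrame,
    db: CompoundDB,
    rules=DEFAULT_ADDUCTS,
    n_perm: int = 999,
    tol_ppm: float = DEFAULT_TOL_PPM,
    column: str | None = None,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of the most-heritable features (top list per column)."""
    frame = herit_result.frame
    if column is not None:
        frame = frame[frame["column"] == column]
    universe = frame.index.tolist()
    selected = frame.index[frame["top"] == 1].tolist()
    if len(universe) < herit_result.top_n:
        warnings.warn(
            f"fewer than {herit_result.top_n} features available; using all "
            f"{len(selected)} flagged features",
            stacklevel=2,
        )
    return enrich(
        selected, universe, db, rules, n_perm, tol_ppm,
        mz_lookup=feature_meta["mz"], seed=seed,
    )
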