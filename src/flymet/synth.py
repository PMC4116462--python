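"""Synthetic LC-MS feature tables with known planted structure.

Emulates a full-factorial inbred-line ageing study: ``n_lines``
genotypes x 2 sexes x 7 collection ages x 2 replicate pools per cell,
measured on two chromatography columns (anion exchange and reverse
phase) whose feature sets partially overlap. Effects are additive on
the log-intensity scale (intensities are log-normal); missingness is
intensity-dependent, mimicking detection limits. Every planted effect
is recorded in a :class:`GroundTruth` so downstream stages can be
tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import ConfigurationError, FeatureTable, fold_seed

PROTON_MASS = 1.00727646

# substream keys for per-stage reproducibility
_KEY_TABLE = 11
_KEY_MISSING = 12
_KEY_PATHWAYS = 13


@dataclasses.dataclass
class DesignSpec:
    """Layout of the factorial collection design.

    Defaults mirror the study design this simulator emulates: 15 inbred
    lines, both sexes, seven ages (days), two replicate pools of three
    flies per cell, and two columns with ~30% of chemicals detected on
    both.
    """

    n_lines: int = 15
    sexes: tuple[str, ...] = ("F", "M")
    ages: tuple[int, ...] = (3, 10, 24, 36, 51, 66, 81)
    replicates_per_cell: int = 2
    flies_per_sample: int = 3
    columns: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"AE": 3091, "C18": 3714}
    )
    overlap: float = 0.30

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ConfigurationError("need at least 2 genotype lines")
        if len(self.sexes) != len(set(self.sexes)) or not self.sexes:
            raise ConfigurationError("sexes must be distinct labels")
        ages = tuple(self.ages)
        if any(b <= a for a, b in zip(ages, ages[1:])) or not ages:
            raise ConfigurationError("ages must be strictly increasing")
        if self.replicates_per_cell < 1:
            raise ConfigurationError("replicates_per_cell must be >= 1")
        if self.flies_per_sample < 1:
            raise ConfigurationError("flies_per_sample must be >= 1")
        if not self.columns:
            raise ConfigurationError("need at least one column")
        if any(n < 1 for n in self.columns.values()):
            raise ConfigurationError("column feature counts must be positive")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigurationError("overlap fraction must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_lines * len(self.sexes) * len(self.ages) * self.replicates_per_cell

    @property
    def lines(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]


@dataclasses.dataclass
class MissingnessSpec:
    """Intensity-dependent (left-censoring-like) missingness.

    ``rate`` is the overall target fraction of missing cells; the
    per-cell missingness probability is logistic in log-intensity with
    the given ``steepness`` (per log-unit), centred so the mean equals
    ``rate``. ``steepness = inf`` censors exactly the lowest ``rate``
    fraction; ``steepness = 0`` yields intensity-independent dropout.
    """

    rate: float = 0.02
    steepness: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rate < 1.0:
            raise ConfigurationError("missingness rate must lie in (0, 1)")
        if self.steepness < 0:
            raise ConfigurationError("steepness must be nonnegative")


@dataclasses.dataclass
class EffectSpec:
    """Planted effect structure, on the log-intensity scale.

    Effect magnitudes are expressed in units of the residual standard
    deviation sqrt(sigma2_within); an "effect of 2" spans two residual
    SDs from youngest to oldest age (age effects), between sexes (sex
    effects), or as the SD of per-line deviations (genotype-containing
    terms). Assignment fractions may overlap: a feature can carry
    several effects at once.
    """

    frac_age_up: float = 0.05
    frac_age_down: float = 0.05
    frac_sex: float = 0.10
    frac_genotype: float = 0.10
    frac_age_sex: float = 0.10
    frac_age_geno: float = 0.10
    frac_sex_geno: float = 0.10
    effect_size_dist: tuple = ("fixed", 2.0)
    sigma2_between: float = 0.05
    sigma2_within: float = 0.25
    baseline_mean: float = 12.0
    baseline_sd: float = 1.0
    frac_annotated: float = 0.25
    mz_jitter_ppm: float = 3.0
    missingness: MissingnessSpec = dataclasses.field(default_factory=MissingnessSpec)
    age_mode: str = "monotone"  # or "hump" (non-monotone, exercises ordered-factor tests)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [
            self.frac_age_up, self.frac_age_down, self.frac_sex, self.frac_genotype,
            self.frac_age_sex, self.frac_age_geno, self.frac_sex_geno, self.frac_annotated,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("effect fractions must lie in [0, 1]")
        if self.frac_age_up + self.frac_age_down > 1.0:
            raise ConfigurationError("frac_age_up + frac_age_down must be <= 1")
        if self.sigma2_between < 0:
            raise ConfigurationError("sigma2_between must be >= 0")
        if self.sigma2_within <= 0:
            raise ConfigurationError("sigma2_within must be > 0")
        if self.age_mode not in ("monotone", "hump"):
            raise ConfigurationError("age_mode must be 'monotone' or 'hump'")


@dataclasses.dataclass
class GroundTruth:
    """Planted effects per feature plus compound/pathway assignments.

    ``features`` is indexed by feature_id; per-line effect matrices are
    (features x lines). Features shared across columns carry the same
    ``signal_id`` and identical planted values (independent noise).
    """

    features: pd.DataFrame
    line_effects: pd.DataFrame
    age_line_slopes: pd.DataFrame
    sex_line_effects: pd.DataFrame
    compounds: pd.DataFrame  # compound_id (index), mass
    pathways: pd.DataFrame  # pathway_id (index), name, members (list), enriched

    def write(self, outdir: str | Path, prefix: str = "truth") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": outdir / f"{prefix}_features.tsv",
            "compounds": outdir / f"{prefix}_compounds.tsv",
            "pathways": outdir / f"{prefix}_pathways.tsv",
        }
        self.features.to_csv(paths["features"], sep="\t", index_label="feature_id")
        self.compounds.to_csv(paths["compounds"], sep="\t", index_label="compound_id")
        pw = self.pathways.copy()
        if len(pw):
            pw["members"] = [",".join(m) for m in pw["members"]]
        pw.to_csv(paths["pathways"], sep="\t", index_label="pathway_id")
        return paths


def _empty_pathways() -> pd.DataFrame:
    return pd.DataFrame(
        {"name": pd.Series(dtype=str), "members": pd.Series(dtype=object),
         "enriched": pd.Series(dtype=bool)},
        index=pd.Index([], name="pathway_id"),
    )


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Sample metadata for the full factorial design.

    One record per line x sex x age x replicate; sample ids encode the
    cell so tables stay human-readable.
    """
    records = []
    for line in spec.lines:
        for sex in spec.sexes:
            for age in spec.ages:
                for rep in range(1, spec.replicates_per_cell + 1):
                    sid = f"{line}_{sex}_a{age:02d}_r{rep}"
                    records.append((sid, line, sex, age, rep))
    meta = pd.DataFrame.from_records(
        records, columns=["sample_id", "line", "sex", "age", "replicate"]
    ).set_index("sample_id")
    return meta


def _draw_magnitudes(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name, *params = dist
    if name == "fixed":
        return np.full(n, float(params[0]))
    if name == "lognormal":
        return rng.lognormal(mean=params[0], sigma=params[1], size=n)
    if name == "normal":
        return np.abs(rng.normal(loc=params[0], scale=params[1], size=n))
    if name == "uniform":
        return rng.uniform(params[0], params[1], size=n)
    raise ConfigurationError(f"unknown effect size distribution {name!r}")


def generate_table(
    spec: DesignSpec, effects: EffectSpec
) -> tuple[FeatureTable, GroundTruth]:
    """Simulate a raw-intensity feature table with planted effects.

    The log-scale signal for a sample (line l, sex s, age rank r) is

        baseline + age_effect * u + sex_effect * s/2 + line_effect[l]
        + age_sex_effect * u * s + age_line_slope[l] * u
        + sex_line_effect[l] * s/2 + noise,

    with u the centred age position in [-0.5, 0.5], s = +1 for males
    and -1 for females, and noise ~ N(0, sigma2_within). Raw
    intensities are the exponentiated signal. Identical (spec, effects)
    including the seed give byte-identical output.
    """
    rng = np.random.default_rng(fold_seed(effects.seed, _KEY_TABLE))
    sample_meta = generate_design(spec)

    col_names = list(spec.columns)
    col_sizes = [spec.columns[c] for c in col_names]
    n_shared = int(round(spec.overlap * min(col_sizes))) if len(col_names) > 1 else 0
    n_signals = sum(col_sizes) - n_shared * (len(col_names) - 1)

    sw = math.sqrt(effects.sigma2_within)
    sb = math.sqrt(effects.sigma2_between)

    baseline = rng.normal(effects.baseline_mean, effects.baseline_sd, n_signals)

    u_age = rng.uniform(size=n_signals)
    age_sign = np.where(
        u_age < effects.frac_age_up, 1, np.where(
            u_age < effects.frac_age_up + effects.frac_age_down, -1, 0)
    )
    age_mag = _draw_magnitudes(effects.effect_size_dist, n_signals, rng) * sw
    age_effect = age_sign * age_mag
    age_sign = np.sign(age_effect).astype(int)  # keep flag consistent if mag drawn 0

    sex_flag = rng.uniform(size=n_signals) < effects.frac_sex
    sex_mag = _draw_magnitudes(effects.effect_size_dist, n_signals, rng) * sw
    sex_effect = np.where(sex_flag, rng.choice([-1.0, 1.0], n_signals) * sex_mag, 0.0)
    sex_flag = sex_effect != 0

    geno_flag = rng.uniform(size=n_signals) < effects.frac_genotype
    line_eff = np.where(
        geno_flag[:, None], rng.normal(0.0, 1.0, (n_signals, spec.n_lines)) * sb, 0.0
    )
    if sb == 0:
        geno_flag = np.zeros(n_signals, dtype=bool)
        line_eff = np.zeros_like(line_eff)

    as_flag = rng.uniform(size=n_signals) < effects.frac_age_sex
    as_mag = _draw_magnitudes(effects.effect_size_dist, n_signals, rng) * sw
    age_sex_effect = np.where(
        as_flag, rng.choice([-1.0, 1.0], n_signals) * as_mag, 0.0
    )
    as_flag = age_sex_effect != 0

    ag_flag = rng.uniform(size=n_signals) < effects.frac_age_geno
    ag_mag = _draw_magnitudes(effects.effect_size_dist, n_signals, rng) * sw
    age_line_slopes = np.where(
        ag_flag[:, None],
        rng.normal(0.0, 1.0, (n_signals, spec.n_lines)) * ag_mag[:, None],
        0.0,
    )

    sg_flag = rng.uniform(size=n_signals) < effects.frac_sex_geno
    sg_mag = _draw_magnitudes(effects.effect_size_dist, n_signals, rng) * sw
    sex_line_effects = np.where(
        sg_flag[:, None],
        rng.normal(0.0, 1.0, (n_signals, spec.n_lines)) * sg_mag[:, None],
        0.0,
    )

    true_icc = np.where(
        geno_flag,
        effects.sigma2_between / (effects.sigma2_between + effects.sigma2_within),
        0.0,
    )

    # compound identities for a fraction of signals (enrichment oracle)
    annotated = rng.uniform(size=n_signals) < effects.frac_annotated
    compound_ids = np.array(
        [f"CPD{i + 1:05d}" if a else "" for i, a in enumerate(annotated)], dtype=object
    )
    masses = rng.uniform(100.0, 850.0, n_signals)

    # per-column feature lists; shared signals are the first n_shared
    feature_rows = []  # (feature_id, column, signal_index)
    offset = n_shared
    for ci, (cname, csize) in enumerate(zip(col_names, col_sizes)):
        own = csize - n_shared if len(col_names) > 1 else csize
        sig_idx = (list(range(n_shared)) if len(col_names) > 1 else []) + list(
            range(offset, offset + own)
        )
        offset += own
        for j, si in enumerate(sig_idx):
            feature_rows.append((f"{cname}_{j + 1:05d}", cname, si))

    fids = [r[0] for r in feature_rows]
    fcols = [r[1] for r in feature_rows]
    sidx = np.array([r[2] for r in feature_rows])
    n_features = len(fids)

    # observed m/z: planted compounds appear as M+H within a few ppm,
    # unannotated features get arbitrary masses over the acquisition range
    theo_mz = masses[sidx] + PROTON_MASS
    jitter = rng.uniform(-effects.mz_jitter_ppm, effects.mz_jitter_ppm, n_features) * 1e-6
    mz = np.where(
        annotated[sidx], theo_mz * (1.0 + jitter), rng.uniform(85.0, 2000.0, n_features)
    )
    rt = rng.uniform(10.0, 600.0, n_features)

    # design covariates
    ages = np.asarray(spec.ages, dtype=float)
    rank = {a: i for i, a in enumerate(spec.ages)}
    k = len(spec.ages)
    u = np.array([rank[a] for a in sample_meta["age"]], dtype=float)
    u = u / (k - 1) - 0.5 if k > 1 else np.zeros(len(sample_meta))
    if effects.age_mode == "hump":
        # symmetric non-monotone profile with zero linear-trend component
        u_prof = 0.25 - np.abs(u)
        u_prof = u_prof - u_prof.mean()
    else:
        u_prof = u
    # convention: "M" (or the last sex label if no "M") carries +1, so a
    # positive planted sex_effect means male-higher
    plus_sex = "M" if "M" in spec.sexes else spec.sexes[-1]
    s_sign = np.where(sample_meta["sex"].to_numpy() == plus_sex, 1.0, -1.0)
    line_idx = np.array([spec.lines.index(l) for l in sample_meta["line"]])

    sig = (
        baseline[sidx][:, None]
        + age_effect[sidx][:, None] * u_prof[None, :]
        + sex_effect[sidx][:, None] * s_sign[None, :] / 2.0
        + line_eff[sidx][:, line_idx]
        + age_sex_effect[sidx][:, None] * (u_prof * s_sign)[None, :]
        + age_line_slopes[sidx][:, line_idx] * u_prof[None, :]
        + sex_line_effects[sidx][:, line_idx] * s_sign[None, :] / 2.0
    )
    noise = rng.normal(0.0, sw, sig.shape)
    raw = np.exp(sig + noise)

    intensities = pd.DataFrame(raw, index=pd.Index(fids, name="feature_id"),
                               columns=sample_meta.index)
    feature_meta = pd.DataFrame(
        {"mz": mz, "rt": rt, "column": fcols},
        index=pd.Index(fids, name="feature_id"),
    )
    table = FeatureTable(intensities, feature_meta, sample_meta)

    feat_truth = pd.DataFrame(
        {
            "column": fcols,
            "signal_id": [f"S{si + 1:05d}" for si in sidx],
            "age_sign": age_sign[sidx],
            "age_effect": age_effect[sidx],
            "sex_effect": sex_effect[sidx],
            "genotype": geno_flag[sidx],
            "sigma2_between": np.where(geno_flag[sidx], effects.sigma2_between, 0.0),
            "true_icc": true_icc[sidx],
            "age_sex": as_flag[sidx],
            "age_sex_effect": age_sex_effect[sidx],
            "age_geno": ag_flag[sidx],
            "sex_geno": sg_flag[sidx],
            "compound_id": compound_ids[sidx],
        },
        index=pd.Index(fids, name="feature_id"),
    )
    lines = spec.lines
    truth = GroundTruth(
        features=feat_truth,
        line_effects=pd.DataFrame(line_eff[sidx], index=feat_truth.index, columns=lines),
        age_line_slopes=pd.DataFrame(
            age_line_slopes[sidx], index=feat_truth.index, columns=lines
        ),
        sex_line_effects=pd.DataFrame(
            sex_line_effects[sidx], index=feat_truth.index, columns=lines
        ),
        compounds=pd.DataFrame(
            {"mass": masses[annotated]},
            index=pd.Index(compound_ids[annotated], name="compound_id"),
        ),
        pathways=_empty_pathways(),
    )
    return table, truth


def inject_missingness(
    table: FeatureTable,
    effects: EffectSpec,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """Drop cells with probability decreasing in intensity.

    The per-cell dropout probability is expit(steepness * (c - log x)),
    with the centre c solved so the expected missing fraction equals
    the configured rate. Missing cells become NaN (absent on disk),
    never zero.
    """
    ms = effects.missingness
    if rng is None:
        rng = np.random.default_rng(fold_seed(effects.seed, _KEY_MISSING))
    x = table.intensities.to_numpy(dtype=float)
    if x.size == 0:
        return table.copy()
    z = np.log(x).ravel()
    if math.isinf(ms.steepness):
        order = np.argsort(z, kind="stable")
        n_miss = int(round(ms.rate * z.size))
        p = np.zeros(z.size)
        p[order[:n_miss]] = 1.0
    elif ms.steepness == 0.0:
        p = np.full(z.size, ms.rate)
    else:
        s = ms.steepness

        def mean_rate(c: float) -> float:
            return float(np.mean(expit(s * (c - z)))) - ms.rate

        lo, hi = z.min() - 50.0 / s, z.max() + 50.0 / s
        c = brentq(mean_rate, lo, hi)
        p = expit(s * (c - z))
    drop = rng.uniform(size=z.size) < p
    out = x.copy()
    out.ravel()[drop] = np.nan
    new = table.copy()
    new.intensities = pd.DataFrame(
        out, index=table.intensities.index, columns=table.intensities.columns
    )
    return new


def plant_pathways(
    truth: GroundTruth,
    n_pathways: int,
    sizes: tuple[int, int] = (6, 12),
    n_enriched: int = 1,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Group planted compounds into pathways; some enriched for age effects.

    Enriched pathways draw their members preferentially from compounds
    whose features carry planted age effects; the remaining pathways
    draw uniformly. Returns a new GroundTruth with the pathway table
    filled in (compounds may belong to several pathways).
    """
    if rng is None:
        rng = np.random.default_rng(fold_seed(seed, _KEY_PATHWAYS))
    if n_pathways < 0 or n_enriched < 0:
        raise ConfigurationError("invalid pathway counts")
    n_enriched = min(n_enriched, n_pathways)
    compounds = truth.compounds.index.to_numpy()
    if n_pathways == 0:
        return dataclasses.replace(truth, pathways=_empty_pathways())
    lo, hi = sizes
    if lo < 1 or hi < lo:
        raise ConfigurationError("invalid pathway size range")
    if hi > len(compounds):
        raise ConfigurationError(
            f"pathway size {hi} exceeds compound count {len(compounds)}"
        )
    feat = truth.features
    aged = feat.loc[feat["age_sign"] != 0, "compound_id"]
    aged_compounds = np.array(sorted(set(aged[aged != ""])), dtype=object)

    rows = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched
        if enriched and len(aged_compounds):
            n_from_aged = min(size, len(aged_compounds))
            members = list(rng.choice(aged_compounds, n_from_aged, replace=False))
            rest = np.setdiff1d(compounds, np.array(members, dtype=object))
            if size > n_from_aged:
                members += list(rng.choice(rest, size - n_from_aged, replace=False))
        else:
            members = list(rng.choice(compounds, size, replace=False))
        rows.append((f"PW{i + 1:03d}", f"pathway_{i + 1:03d}", sorted(members), enriched))
    pathways = pd.DataFrame(
        rows, columns=["pathway_id", "name", "members", "enriched"]
    ).set_index("pathway_id")
    return dataclasses.replace(truth, pathways=pathways)


def compound_db_from_truth(truth: GroundTruth):
    """Build an annotation database from planted compounds and pathways."""
    from .enrichment import CompoundDB

    compounds = pd.DataFrame(
        {
            "name": [f"compound {cid}" for cid in truth.compounds.index],
            "mass": truth.compounds["mass"].to_numpy(),
        },
        index=truth.compounds.index.copy(),
    )
    return CompoundDB(compounds=compounds, pathways=truth.pathways.copy())
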