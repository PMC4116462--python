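"""Core in-memory containers shared by every pipeline stage.

A :class:`FeatureTable` bundles the ion-intensity matrix (features x
samples) with feature metadata (m/z, retention time, chromatography
column) and sample metadata (genotype line, sex, age, replicate).
Missing intensities are ``NaN`` in memory and empty fields on disk;
zero is a legitimate observed value, never a missingness code.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MZ_MIN = 85.0
MZ_MAX = 2000.0

FEATURE_META_COLS = ("mz", "rt", "column")
SAMPLE_META_COLS = ("line", "sex", "age", "replicate")


class ConfigurationError(ValueError):
    """An invalid specification or configuration value."""


@dataclasses.dataclass
class FeatureTable:
    """Intensity matrix plus aligned feature and sample metadata.

    Parameters
    ----------
    intensities
        DataFrame of shape (n_features, n_samples); index holds feature
        identifiers, columns hold sample identifiers. NaN means the ion
        was not detected in that sample.
    feature_meta
        Per-feature metadata indexed like ``intensities``; requires
        columns ``mz`` (85-2000), ``rt`` and ``column``.
    sample_meta
        Per-sample metadata indexed by sample identifier; requires
        columns ``line``, ``sex``, ``age`` and ``replicate``.
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intensities.index.equals(self.feature_meta.index):
            raise ConfigurationError("feature_meta index must match intensity rows")
        if not self.intensities.columns.equals(self.sample_meta.index):
            raise ConfigurationError("sample_meta index must match intensity columns")
        if self.intensities.columns.duplicated().any():
            raise ConfigurationError("sample identifiers must be unique")
        if self.intensities.index.duplicated().any():
            raise ConfigurationError("feature identifiers must be unique")
        for col in FEATURE_META_COLS:
            if col not in self.feature_meta.columns:
                raise ConfigurationError(f"feature_meta missing column {col!r}")
        for col in SAMPLE_META_COLS:
            if col not in self.sample_meta.columns:
                raise ConfigurationError(f"sample_meta missing column {col!r}")
        mz = self.feature_meta["mz"]
        if len(mz) and ((mz < MZ_MIN) | (mz > MZ_MAX)).any():
            bad = self.feature_meta.index[(mz < MZ_MIN) | (mz > MZ_MAX)][:3].tolist()
            raise ConfigurationError(
                f"m/z outside instrument range [{MZ_MIN}, {MZ_MAX}]: {bad}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def subset_features(self, keep) -> "FeatureTable":
        """Return a new table restricted to the given feature ids (order kept)."""
        return FeatureTable(
            intensities=self.intensities.loc[keep],
            feature_meta=self.feature_meta.loc[keep],
            sample_meta=self.sample_meta,
        )

    def subset_samples(self, keep) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities.loc[:, keep],
            feature_meta=self.feature_meta,
            sample_meta=self.sample_meta.loc[keep],
        )

    def for_column(self, column: str) -> "FeatureTable":
        """Restrict to features measured on one chromatography column."""
        keep = self.feature_meta.index[self.feature_meta["column"] == column]
        return self.subset_features(keep)

    def columns_present(self) -> list[str]:
        return sorted(self.feature_meta["column"].unique().tolist())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.feature_meta.copy(), self.sample_meta.copy()
        )

    # -- disk round trip -------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "table") -> dict[str, Path]:
        """Write intensities + metadata as a TSV trio; missing cells are empty."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "intensities": outdir / f"{prefix}_intensities.tsv",
            "feature_meta": outdir / f"{prefix}_features.tsv",
            "sample_meta": outdir / f"{prefix}_samples.tsv",
        }
        self.intensities.to_csv(
            paths["intensities"], sep="\t", index_label="feature_id", na_rep=""
        )
        self.feature_meta.to_csv(paths["feature_meta"], sep="\t", index_label="feature_id")
        self.sample_meta.to_csv(paths["sample_meta"], sep="\t", index_label="sample_id")
        return paths

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "table") -> "FeatureTable":
        outdir = Path(outdir)
        intens = pd.read_csv(
            outdir / f"{prefix}_intensities.tsv", sep="\t", index_col="feature_id"
        )
        fmeta = pd.read_csv(
            outdir / f"{prefix}_features.tsv", sep="\t", index_col="feature_id"
        )
        smeta = pd.read_csv(
            outdir / f"{prefix}_samples.tsv", sep="\t", index_col="sample_id"
        )
        intens.columns.name = "sample_id"
        return cls(intens, fmeta.loc[intens.index], smeta.loc[intens.columns])


def missing_mask(table: FeatureTable) -> pd.DataFrame:
    """Boolean mask of missing (undetected) cells."""
    return table.intensities.isna()


def assert_complete(table: FeatureTable, context: str = "") -> None:
    if table.intensities.isna().any().any():
        raise ValueError(f"table contains missing cells {context}".strip())


def fold_seed(*parts: int) -> np.random.SeedSequence:
    """Deterministic per-stage seed stream derived from a global seed.

    Every source of randomness in the pipeline draws from a
    ``SeedSequence`` keyed by (global seed, stage key, ...), so stages
    can be re-run independently yet reproducibly.
    """
    return np.random.SeedSequence(list(parts))
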