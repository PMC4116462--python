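"""Pipeline configuration: one YAML file, strict keys, full defaults.

Every section mirrors a stage's spec/config dataclass; unknown keys are
rejected so typos fail loudly. An empty file (all defaults) is valid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .containers import ConfigurationError
from .enrichment import DEFAULT_TOL_PPM
from .multivariate import DEFAULT_KEEP_GRID
from .qc import QCConfig
from .synth import DesignSpec, EffectSpec, MissingnessSpec
from .univariate import ModelSpec


@dataclasses.dataclass
class HeritabilityConfig:
    estimator: str = "reml"
    threshold: float = 0.05
    top_n: int = 150
    pooled_n: int | None = None  # n flies per sample for the pooled-t variant

    def __post_init__(self) -> None:
        if self.estimator not in ("reml", "mom"):
            raise ConfigurationError("heritability estimator must be 'reml' or 'mom'")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")


@dataclasses.dataclass
class MultivariateConfig:
    keep_grid: tuple[int, ...] = DEFAULT_KEEP_GRID
    n_folds: int = 10
    n_perm: int = 10
    repeats: int = 20
    fraction: float = 2 / 3
    max_components: int = 10
    scale_da: bool = True
    scale_regression: bool = False

    def __post_init__(self) -> None:
        if not self.keep_grid:
            raise ConfigurationError("keep_grid must be nonempty")
        if not 0 < self.fraction < 1:
            raise ConfigurationError("train fraction must lie in (0, 1)")


@dataclasses.dataclass
class EnrichmentConfig:
    n_top: int = 250
    n_perm: int = 999
    tol_ppm: float = DEFAULT_TOL_PPM
    n_pathways: int = 10
    pathway_sizes: tuple[int, int] = (6, 12)
    n_enriched: int = 1

    def __post_init__(self) -> None:
        if self.n_top < 1 or self.n_perm < 1:
            raise ConfigurationError("n_top and n_perm must be >= 1")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "flymet_out"
    design: DesignSpec = dataclasses.field(default_factory=DesignSpec)
    effects: EffectSpec = dataclasses.field(default_factory=EffectSpec)
    qc: QCConfig = dataclasses.field(default_factory=QCConfig)
    model: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    heritability: HeritabilityConfig = dataclasses.field(
        default_factory=HeritabilityConfig
    )
    multivariate: MultivariateConfig = dataclasses.field(
        default_factory=MultivariateConfig
    )
    enrichment: EnrichmentConfig = dataclasses.field(default_factory=EnrichmentConfig)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = _as_jsonable(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    return obj


_TUPLE_FIELDS = {
    "ages", "sexes", "drop_age", "keep_grid", "pathway_sizes", "effect_size_dist",
}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"section {path!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(f"unknown keys in {path!r}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name == "missingness":
            value = _build(MissingnessSpec, value, f"{path}.missingness")
        elif name in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        elif name == "columns" and isinstance(value, dict):
            value = dict(value)
        kwargs[name] = value
    return cls(**kwargs)


_SECTIONS = {
    "design": DesignSpec,
    "effects": EffectSpec,
    "qc": QCConfig,
    "model": ModelSpec,
    "heritability": HeritabilityConfig,
    "multivariate": MultivariateConfig,
    "enrichment": EnrichmentConfig,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Parse a YAML config; None means all defaults. Unknown keys error."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config root must be a mapping")
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    unknown = set(raw) - set(_SECTIONS) - {"seed", "outdir"}
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "outdir" in raw:
        kwargs["outdir"] = str(raw["outdir"])
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    return PipelineConfig(**kwargs)
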