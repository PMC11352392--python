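"""YAML run configuration: strict parsing, defaults, freezing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._errors import ConfigError
from .community import ClusteringConfig, ModularityParams
from .evaluation import SVMConfig
from .hyperedges import ElasticNetConfig
from .synthetic import CohortConfig

__all__ = ["RunConfig", "load_config", "freeze_config"]

_KNOWN_TOP = {
    "seed",
    "log_level",
    "paths",
    "elastic_net",
    "hmll",
    "svm",
    "stats",
    "simulate",
    "deviation",
    "replication",
}


@dataclass
class StatsConfig:
    covariates: bool = True
    q_threshold: float = 0.05


@dataclass
class DeviationConfig:
    zscore_against_controls: bool = False
    correlation_distance: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    features: str | None = None
    phenotype: str | None = None
    output_dir: str = "results"
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    hmll: ClusteringConfig = field(default_factory=ClusteringConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    deviation: DeviationConfig = field(default_factory=DeviationConfig)
    simulate: CohortConfig = field(default_factory=CohortConfig)
    replication: dict = field(default_factory=dict)


def _build_block(cls, block: dict, name: str, **overrides):
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"config block '{name}' must be a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    merged = {**block, **overrides}
    for key in ("lambda1_grid", "lambda1_fractions", "lambda2_grid", "c_grid", "age_range", "edge_sizes"):
        if key in merged and merged[key] is not None:
            merged[key] = tuple(merged[key])
    try:
        return cls(**merged)
    except TypeError as exc:
        raise ConfigError(f"bad '{name}' block: {exc}") from exc


def _parse_hmll_params(raw):
    if raw is None or raw == "default":
        return None
    if raw == "estimate":
        return "estimate"
    if isinstance(raw, dict) and set(raw) <= {"beta", "gamma"}:
        return ModularityParams(
            beta={int(k): float(v) for k, v in raw.get("beta", {}).items()},
            gamma={int(k): float(v) for k, v in raw.get("gamma", {}).items()},
        )
    raise ConfigError(f"hmll params must be 'default', 'estimate', or beta/gamma maps, got {raw!r}")


def load_config(source) -> RunConfig:
    """Load and validate a YAML run configuration (path, str, or dict)."""
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    paths = raw.get("paths") or {}
    if not isinstance(paths, dict):
        raise ConfigError("'paths' must be a mapping")
    unknown_paths = set(paths) - {"features", "phenotype", "output_dir"}
    if unknown_paths:
        raise ConfigError(f"unknown keys in 'paths': {sorted(unknown_paths)}")

    hmll_block = dict(raw.get("hmll") or {})
    hmll_params = _parse_hmll_params(hmll_block.pop("params", None))

    cfg = RunConfig(
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        features=paths.get("features"),
        phenotype=paths.get("phenotype"),
        output_dir=str(paths.get("output_dir", "results")),
        elastic_net=_build_block(
            ElasticNetConfig, raw.get("elastic_net") or {}, "elastic_net", seed=seed
        ),
        hmll=_build_block(
            ClusteringConfig, hmll_block, "hmll", seed=seed, params=hmll_params
        ),
        svm=_build_block(SVMConfig, raw.get("svm") or {}, "svm", seed=seed),
        stats=_build_block(StatsConfig, raw.get("stats") or {}, "stats"),
        deviation=_build_block(DeviationConfig, raw.get("deviation") or {}, "deviation"),
        simulate=_build_block(CohortConfig, raw.get("simulate") or {}, "simulate", seed=seed),
        replication=dict(raw.get("replication") or {}),
    )
    return cfg


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialize(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, ModularityParams):
        return {"beta": obj.beta, "gamma": obj.gamma}
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def freeze_config(cfg: RunConfig) -> dict:
    """Fully-resolved, serializable snapshot of the effective configuration."""
    out = {
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "paths": {
            "features": cfg.features,
            "phenotype": cfg.phenotype,
            "output_dir": cfg.output_dir,
        },
        "elastic_net": _serialize(cfg.elastic_net),
        "hmll": _serialize(cfg.hmll),
        "svm": _serialize(cfg.svm),
        "stats": _serialize(cfg.stats),
        "deviation": _serialize(cfg.deviation),
        "simulate": _serialize(cfg.simulate),
        "replication": _serialize(cfg.replication),
    }
    # ClusteringConfig.params may hold a ModularityParams object
    params = cfg.hmll.params
    if isinstance(params, ModularityParams):
        out["hmll"]["params"] = {"beta": params.beta, "gamma": params.gamma}
    elif params is None:
        out["hmll"]["params"] = "default"
    return out


def config_hash(frozen: dict) -> str:
    """Hash of the methodological configuration only: file locations, logging
    and derived replication summaries do not change what is computed."""
    core = {
        k: v
        for k, v in frozen.items()
        if k not in ("paths", "log_level", "replication")
    }
    return hashlib.sha256(json.dumps(core, sort_keys=True).encode()).hexdigest()[:12]
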