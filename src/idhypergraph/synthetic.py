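"""Synthetic cohorts and planted-partition hypergraphs.

Two generators keep every pipeline stage testable without any real imaging
data: (a) case/control feature cohorts in which the case group carries K
planted subtypes, each shifting its own disjoint block of regional features;
(b) hypergraphs with planted vertex blocks and size-dependent within/between
edge probabilities. Plus the adjusted Rand index as the recovery metric.

All randomness flows from a single seed through named child streams so each
sub-stage (baselines, features, ages, sites, edges) is independently
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from ._errors import ConfigError, InvalidInputError
from .community import Partition
from .deviation import FeatureTable
from .hypergraph import Hypergraph, build_incidence

__all__ = [
    "CohortConfig",
    "PlantedHypergraphConfig",
    "simulate_cohort",
    "simulate_planted_hypergraph",
    "adjusted_rand_index",
]

_STREAMS = ("baselines", "features", "ages", "sites", "subtypes", "edges")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class CohortConfig:
    n_case: int = 147
    n_control: int = 125
    n_features: int = 116
    n_subtypes: int = 4
    effect_size: float = 2.0  # block shift in units of noise_sd
    regions_per_subtype: int = 15
    noise_sd: float = 0.1
    site_count: int = 3
    site_sd: float = 0.05  # SD of additive per-site offsets (shared by groups)
    age_range: tuple[float, float] = (8.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("need at least 2 subjects per group")
        if self.n_subtypes < 1 or self.n_subtypes > self.n_case:
            raise ConfigError("n_subtypes must lie in 1..n_case")
        if self.n_subtypes * self.regions_per_subtype > self.n_features:
            raise ConfigError(
                "disjoint subtype region blocks do not fit: "
                f"{self.n_subtypes} x {self.regions_per_subtype} > {self.n_features}"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")


def simulate_cohort(cfg: CohortConfig) -> tuple[FeatureTable, np.ndarray]:
    """Generate a two-group cohort with K planted case subtypes.

    Controls draw from per-region Gaussian baselines plus an additive site
    offset; each case additionally gets its subtype's region block shifted by
    ``effect_size * noise_sd``. Returns the combined feature table (cases
    first) and the true subtype labels of the cases (0-based), which are
    never stored in the table itself.
    """
    rngs = _child_rngs(cfg.seed)
    p = cfg.n_features
    baseline = rngs["baselines"].uniform(0.8, 1.2, size=p)
    site_offsets = rngs["sites"].normal(0.0, cfg.site_sd, size=cfg.site_count)

    n_total = cfg.n_case + cfg.n_control
    sites = rngs["sites"].integers(0, cfg.site_count, size=n_total)
    ages = rngs["ages"].uniform(*cfg.age_range, size=n_total)

    truth = rngs["subtypes"].integers(0, cfg.n_subtypes, size=cfg.n_case)
    values = baseline + rngs["features"].normal(0.0, cfg.noise_sd, size=(n_total, p))
    values += site_offsets[sites][:, None]
    shift = cfg.effect_size * cfg.noise_sd
    for i in range(cfg.n_case):
        s = int(truth[i])
        block = slice(s * cfg.regions_per_subtype, (s + 1) * cfg.regions_per_subtype)
        values[i, block] += shift

    ids = [f"case{i+1:03d}" for i in range(cfg.n_case)] + [
        f"ctrl{j+1:03d}" for j in range(cfg.n_control)
    ]
    group = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    covariates = pd.DataFrame(
        {"age": ages, "site": [f"site{s+1}" for s in sites]}
    )
    table = FeatureTable(
        values=values,
        subject_ids=ids,
        group=group,
        feature_names=[f"region{j+1:03d}" for j in range(p)],
        covariates=covariates,
    )
    return table, truth


@dataclass
class PlantedHypergraphConfig:
    n_vertices: int = 12
    n_blocks: int = 2
    edge_sizes: tuple[int, ...] = (2, 3)
    p_within: dict[int, float] | float = 0.8
    p_between: dict[int, float] | float = 0.05
    max_candidates: int = 20_000  # cross-block subsets are subsampled past this
    seed: int = 0

    def _prob(self, table, k: int) -> float:
        p = table[k] if isinstance(table, dict) else float(table)
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"probability {p} for size {k} outside [0, 1]")
        return p

    def prob_within(self, k: int) -> float:
        return self._prob(self.p_within, k)

    def prob_between(self, k: int) -> float:
        return self._prob(self.p_between, k)


def simulate_planted_hypergraph(
    cfg: PlantedHypergraphConfig,
) -> tuple[Hypergraph, Partition]:
    """Planted-block hypergraph with per-size edge probabilities.

    Within-block k-subsets are enumerated exhaustively; cross-block subsets
    are enumerated when feasible and otherwise Bernoulli-subsampled so the
    expected edge count is preserved. Deterministic per seed.
    """
    n = cfg.n_vertices
    if cfg.n_blocks < 1 or cfg.n_blocks > n:
        raise ConfigError("n_blocks must lie in 1..n_vertices")
    blocks = np.array_split(np.arange(n), cfg.n_blocks)
    labels = np.empty(n, dtype=int)
    for b, verts in enumerate(blocks):
        labels[verts] = b
    rng = _child_rngs(cfg.seed)["edges"]
    edges: list[tuple[int, ...]] = []
    for k in cfg.edge_sizes:
        if k < 2 or k > n:
            raise ConfigError(f"edge size {k} infeasible for {n} vertices")
        p_in = cfg.prob_within(k)
        p_out = cfg.prob_between(k)
        for verts in blocks:
            if len(verts) < k:
                continue
            for subset in itertools.combinations(verts.tolist(), k):
                if rng.random() < p_in:
                    edges.append(subset)
        n_total_subsets = comb(n, k)
        n_within = sum(comb(len(v), k) for v in blocks)
        n_cross = n_total_subsets - n_within
        if n_cross == 0 or p_out == 0.0:
            continue
        if n_total_subsets <= cfg.max_candidates:
            for subset in itertools.combinations(range(n), k):
                if len(set(labels[list(subset)])) > 1 and rng.random() < p_out:
                    edges.append(subset)
        else:
            # sample the number of cross edges, then distinct random subsets
            count = rng.binomial(n_cross, p_out)
            seen: set[tuple[int, ...]] = set()
            while len(seen) < count:
                subset = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
                if len(set(labels[list(subset)])) > 1:
                    seen.add(subset)
            edges.extend(sorted(seen))
    G = build_incidence(edges, n_vertices=n)
    return G, Partition(labels)


def adjusted_rand_index(z_true, z_hat) -> float:
    """Chance-corrected partition agreement (1 = identical up to relabeling)."""
    a = np.asarray(z_true.labels if isinstance(z_true, Partition) else z_true)
    b = np.asarray(z_hat.labels if isinstance(z_hat, Partition) else z_hat)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise InvalidInputError("partitions must be nonempty and of equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_cells = sum(comb(int(x), 2) for x in contingency.ravel())
    sum_rows = sum(comb(int(x), 2) for x in contingency.sum(axis=1))
    sum_cols = sum(comb(int(x), 2) for x in contingency.sum(axis=0))
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0 if sum_cells == max_index else 0.0
    return float((sum_cells - expected) / (max_index - expected))
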