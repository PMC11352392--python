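"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: set
partitions are enumerated directly, the penalized regression is solved by a
generic bound-constrained convex optimizer on the split-variable form, and
expected values in examples are hand-derived.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize


def iter_set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label lists."""

    def rec(prefix: list[int], m: int):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(m + 1):
            prefix.append(lab)
            yield from rec(prefix, max(m, lab + 1))
            prefix.pop()

    yield from rec([], 0)


def enet_objective(y: np.ndarray, Z: np.ndarray, w: np.ndarray, l1: float, l2: float) -> float:
    r = y - Z @ w
    return float(r @ r + l1 * np.abs(w).sum() + l2 * w @ w)


def enet_oracle(y: np.ndarray, Z: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Independent solver: split w = u - v with u, v >= 0 makes the L1 term
    smooth; minimize with L-BFGS-B."""
    p = Z.shape[1]

    def fun(x):
        u, v = x[:p], x[p:]
        w = u - v
        r = y - Z @ w
        f = r @ r + l1 * (u.sum() + v.sum()) + l2 * w @ w
        grad_w = -2.0 * Z.T @ r + 2.0 * l2 * w
        g = np.concatenate([grad_w + l1, -grad_w + l1])
        return f, g

    x0 = np.zeros(2 * p)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x[:p] - res.x[p:]


def random_hypergraph(rng: np.random.Generator, n_max: int = 8, m_max: int = 20):
    """Random planted-ish hypergraph for oracle comparisons."""
    from idhypergraph import build_incidence

    n = int(rng.integers(5, n_max + 1))
    n_blocks = int(rng.integers(2, 4))
    labels = rng.integers(0, n_blocks, size=n)
    edges = []
    m = int(rng.integers(4, m_max + 1))
    while len(edges) < m:
        k = int(rng.integers(2, 4))
        if rng.random() < 0.7:  # within-block edge
            b = int(rng.integers(0, n_blocks))
            pool = np.nonzero(labels == b)[0]
            if len(pool) < k:
                continue
            e = rng.choice(pool, size=k, replace=False)
        else:
            e = rng.choice(n, size=k, replace=False)
        edges.append(tuple(sorted(int(v) for v in e)))
    return build_incidence(edges, n_vertices=n), labels


# ---------------------------------------------------------------------------
# session-scoped cohort artifacts shared by the expensive acceptance tests
# ---------------------------------------------------------------------------

ACCEPT_COHORT = dict(n_case=150, n_control=125, n_features=116, n_subtypes=4)
# sparse sub-grid of the default lambda1 fractions: CV-min over denser grids
# picks supports too dense to carry community structure (and is far slower)
ACCEPT_ENET = dict(lambda1_fractions=(0.5, 0.7), lambda2_grid=(0.01,), n_folds=10)


def run_subtyping(seed: int, effect_size: float = 3.0, n_restarts: int = 10):
    """deviation -> hyperedges -> clustering on the acceptance cohort."""
    from idhypergraph import (
        ClusteringConfig,
        CohortConfig,
        ElasticNetConfig,
        deviation_matrix,
        build_id_hypergraph,
        hmll,
        merge_duplicates,
        simulate_cohort,
    )

    table, truth = simulate_cohort(
        CohortConfig(seed=seed, effect_size=effect_size, **ACCEPT_COHORT)
    )
    dev = deviation_matrix(table.cases(), table.controls())
    G = build_id_hypergraph(dev, ElasticNetConfig(seed=seed, **ACCEPT_ENET))
    G = merge_duplicates(G)
    part = hmll(G, ClusteringConfig(seed=seed, n_restarts=n_restarts))
    return table, truth, part


@pytest.fixture(scope="session")
def effect3_run():
    """One seed of the effect-size-3 cohort, reused by several tests."""
    return run_subtyping(seed=1)
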