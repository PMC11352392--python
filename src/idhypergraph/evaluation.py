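"""Subtype evaluation: pairwise RBF-SVM separability and covariate-adjusted
per-feature group differences with Benjamini-Hochberg FDR control.

Positive-class convention for each subtype pair: the lower-numbered subtype
is the positive class (this is recorded in all output headers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._errors import DesignError, InvalidInputError, UndefinedMetricError
from .community import Partition
from .deviation import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "PairMetrics",
    "SVMConfig",
    "confusion_metrics",
    "pairwise_svm_cv",
    "adjusted_group_difference",
    "fdr_bh",
    "subtype_profile",
]

DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 3))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidInputError("confusion counts must be nonnegative")
        if self.tp + self.fn + self.tn + self.fp < 1:
            raise InvalidInputError("confusion counts must total at least 1")


@dataclass
class PairMetrics:
    pair: tuple
    acc: float
    sen: float
    spe: float
    auc: float | None = None
    chosen_c: float | None = None


@dataclass
class SVMConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 10
    seed: int = 0
    gamma: object = "scale"  # 1 / (n_features * pooled variance)


def confusion_metrics(c: ConfusionCounts, pair: tuple = ()) -> PairMetrics:
    """ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP)."""
    total = c.tp + c.fn + c.tn + c.fp
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("SEN undefined: no positive examples (TP+FN=0)")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("SPE undefined: no negative examples (TN+FP=0)")
    return PairMetrics(
        pair=pair,
        acc=(c.tp + c.tn) / total,
        sen=c.tp / (c.tp + c.fn),
        spe=c.tn / (c.tn + c.fp),
    )


def _cv_accuracy(Xp, yp, C, gamma, folds) -> float:
    correct = 0
    for train, test in folds:
        clf = SVC(C=C, kernel="rbf", gamma=gamma)
        clf.fit(Xp[train], yp[train])
        correct += int((clf.predict(Xp[test]) == yp[test]).sum())
    return correct / len(yp)


def pairwise_svm_cv(
    F: FeatureTable | np.ndarray,
    Z: Partition | np.ndarray,
    cfg: SVMConfig | None = None,
) -> tuple[list[PairMetrics], PairMetrics]:
    """One-vs-one RBF-SVM separability of the subtypes.

    For each unordered subtype pair, a stratified k-fold split (shrunk with a
    warning when the smaller subtype has fewer members than ``n_folds``) is
    used both to select C from ``c_grid`` by cross-validated accuracy and to
    pool out-of-fold predictions into a single confusion table; AUC is the
    ROC area of the pooled decision scores. The averaged result is the
    unweighted mean over pairs. Deterministic under ``cfg.seed``.
    """
    cfg = cfg or SVMConfig()
    X = F.values if isinstance(F, FeatureTable) else np.asarray(F, dtype=float)
    labels = Z.labels if isinstance(Z, Partition) else np.asarray(Z)
    if len(labels) != X.shape[0]:
        raise InvalidInputError("partition length must match subject count")
    subtype_ids = sorted(int(s) for s in np.unique(labels))
    results: list[PairMetrics] = []
    for ai in range(len(subtype_ids)):
        for bi in range(ai + 1, len(subtype_ids)):
            a, b = subtype_ids[ai], subtype_ids[bi]
            mask = (labels == a) | (labels == b)
            na = int((labels == a).sum())
            nb = int((labels == b).sum())
            if min(na, nb) < 2:
                logger.warning("skipping pair (%s, %s): a subtype has < 2 members", a, b)
                continue
            Xp = X[mask]
            yp = (labels[mask] == a).astype(int)  # lower-numbered subtype = positive
            n_folds = min(cfg.n_folds, na, nb)
            if n_folds < cfg.n_folds:
                warnings.warn(
                    f"pair ({a}, {b}): shrinking folds to {n_folds} "
                    f"(smallest subtype has {min(na, nb)} members)",
                    stacklevel=2,
                )
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
            folds = list(skf.split(Xp, yp))
            accs = [_cv_accuracy(Xp, yp, C, cfg.gamma, folds) for C in cfg.c_grid]
            best_c = cfg.c_grid[int(np.argmax(accs))]
            pred = np.empty(len(yp), dtype=int)
            score = np.empty(len(yp))
            for train, test in folds:
                clf = SVC(C=best_c, kernel="rbf", gamma=cfg.gamma)
                clf.fit(Xp[train], yp[train])
                pred[test] = clf.predict(Xp[test])
                score[test] = clf.decision_function(Xp[test])
            counts = ConfusionCounts(
                tp=int(((pred == 1) & (yp == 1)).sum()),
                fn=int(((pred == 0) & (yp == 1)).sum()),
                tn=int(((pred == 0) & (yp == 0)).sum()),
                fp=int(((pred == 1) & (yp == 0)).sum()),
            )
            pm = confusion_metrics(counts, pair=(a, b))
            pm.auc = float(roc_auc_score(yp, score))
            pm.chosen_c = best_c
            results.append(pm)
    if not results:
        raise InvalidInputError("no subtype pair had enough members to evaluate")
    avg = PairMetrics(
        pair=("average",),
        acc=float(np.mean([r.acc for r in results])),
        sen=float(np.mean([r.sen for r in results])),
        spe=float(np.mean([r.spe for r in results])),
        auc=float(np.mean([r.auc for r in results])),
    )
    return results, avg


def metrics_table(results: list[PairMetrics], avg: PairMetrics) -> pd.DataFrame:
    rows = []
    for r in results + [avg]:
        name = "average" if r.pair == ("average",) else f"{r.pair[0]} vs {r.pair[1]}"
        rows.append(
            {"pair": name, "ACC": r.acc, "SPE": r.spe, "SEN": r.sen, "AUC": r.auc}
        )
    return pd.DataFrame(rows)


def _design_matrix(
    n: int, group: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(n), group.astype(float)]
    names = ["intercept", "group"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
                for dcol in dummies.columns:
                    cols.append(dummies[dcol].to_numpy(dtype=float))
                    names.append(str(dcol))
    Xd = np.column_stack(cols)
    return Xd, names


def adjusted_group_difference(
    values: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature group difference, adjusted for covariates.

    Fits ``value ~ group + covariates`` by OLS per feature (vectorized: the
    design is shared) and reports the group coefficient's t statistic and
    two-sided p. With no covariates this is algebraically identical to the
    classical equal-variance two-sample t-test. ``group`` is binary with 1 =
    case; categorical covariates are dummy-coded (first level dropped).
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    group = np.asarray(group)
    if group.dtype.kind in "UO":
        group = (group == "case").astype(int)
    n = Y.shape[0]
    if len(group) != n:
        raise InvalidInputError("group length must match subject count")
    for g in (0, 1):
        if (group == g).sum() < 3:
            raise InvalidInputError("need at least 3 subjects per group")
    Xd, names = _design_matrix(n, group, covariates)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        aliased = _aliased_columns(Xd, names)
        raise DesignError(
            f"rank-deficient design: aliased columns {aliased}", aliased=aliased
        )
    df_resid = n - Xd.shape[1]
    if df_resid < 1:
        raise InvalidInputError("not enough residual degrees of freedom")
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    beta = xtx_inv @ Xd.T @ Y
    resid = Y - Xd @ beta
    sigma2 = (resid**2).sum(axis=0) / df_resid
    g_idx = names.index("group")
    se = np.sqrt(sigma2 * xtx_inv[g_idx, g_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[g_idx] / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df_resid)
    if feature_names is None:
        feature_names = [f"f{j+1}" for j in range(Y.shape[1])]
    return pd.DataFrame(
        {
            "feature": feature_names,
            "t": t,
            "p": p,
            "direction": np.where(t > 0, "case>control", np.where(t < 0, "case<control", "none")),
        }
    )


def _aliased_columns(Xd: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    aliased = []
    kept: list[int] = []
    for j in range(Xd.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(Xd[:, cand]) < len(cand):
            aliased.append(names[j])
        else:
            kept.append(j)
    return aliased


def fdr_bh(pvals: np.ndarray, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q values and rejection flags.

    q_(i) = min over j >= i of p_(j) * n / j (tail cumulative minimum),
    clipped at 1; reject where q <= q_threshold.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("pvals must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q, q <= q_threshold


def subtype_profile(
    F: FeatureTable,
    Z: Partition | np.ndarray,
    controls: FeatureTable,
    covariates: bool = True,
    q_threshold: float = 0.05,
) -> dict[int, pd.DataFrame]:
    """Per-subtype feature difference maps against the control group.

    Runs the covariate-adjusted group test for every subtype-vs-control
    contrast across all features and applies BH-FDR at ``q_threshold``
    within each contrast. Empty subtypes are skipped with a log entry.
    """
    labels = Z.labels if isinstance(Z, Partition) else np.asarray(Z)
    if len(labels) != F.n_subjects:
        raise InvalidInputError("partition length must match case count")
    out: dict[int, pd.DataFrame] = {}
    for s in sorted(int(x) for x in np.unique(labels)):
        mask = labels == s
        if mask.sum() < 3:
            logger.info("subtype %s skipped: fewer than 3 members", s)
            continue
        sub = F.subset(mask)
        values = np.vstack([sub.values, controls.values])
        group = np.array([1] * sub.n_subjects + [0] * controls.n_subjects)
        cov = None
        if covariates and sub.covariates is not None and controls.covariates is not None:
            shared = [c for c in sub.covariates.columns if c in controls.covariates.columns]
            shared = [c for c in shared if c in ("age", "site")]
            if shared:
                cov = pd.concat(
                    [sub.covariates[shared], controls.covariates[shared]],
                    ignore_index=True,
                )
        table = adjusted_group_difference(
            values, group, covariates=cov, feature_names=F.feature_names
        )
        q, reject = fdr_bh(table["p"].to_numpy(), q_threshold)
        table["q"] = q
        table["significant"] = reject
        out[s] = table
    return out
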