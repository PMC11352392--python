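"""Inter-individual deviation: cosine distance of each case subject's
regional feature vector from every control subject's vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DegenerateInputError, InvalidInputError, SchemaError

__all__ = [
    "FeatureTable",
    "DeviationMatrix",
    "cosine_deviation",
    "deviation_matrix",
    "read_feature_table",
    "read_phenotype",
]

CASE = "case"
CONTROL = "control"


@dataclass
class FeatureTable:
    """Subjects x features matrix with IDs, group labels, and covariates.

    ``values`` has one row per subject; ``group`` entries are ``"case"`` or
    ``"control"``; ``covariates`` is an optional DataFrame indexed like
    ``subject_ids`` (typically columns ``age`` and ``site`` plus clinical
    scores).
    """

    values: np.ndarray
    subject_ids: list[str]
    group: list[str]
    feature_names: list[str] | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("feature values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            bad = [self.subject_ids[i] for i in np.unique(np.nonzero(~np.isfinite(self.values))[0])]
            raise InvalidInputError(f"non-finite feature values for subjects {bad}")
        n = self.values.shape[0]
        if len(self.subject_ids) != n or len(self.group) != n:
            raise InvalidInputError("subject_ids/group length must match row count")
        bad_groups = set(self.group) - {CASE, CONTROL}
        if bad_groups:
            raise SchemaError(f"unknown group labels {sorted(bad_groups)}; expected case/control")
        if self.feature_names is None:
            self.feature_names = [f"f{j+1}" for j in range(self.values.shape[1])]
        elif len(self.feature_names) != self.values.shape[1]:
            raise InvalidInputError("feature_names length must match column count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return FeatureTable(
            values=self.values[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            group=[self.group[i] for i in idx],
            feature_names=self.feature_names,
            covariates=cov,
        )

    def cases(self) -> "FeatureTable":
        return self.subset(np.array([g == CASE for g in self.group]))

    def controls(self) -> "FeatureTable":
        return self.subset(np.array([g == CONTROL for g in self.group]))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)


@dataclass
class DeviationMatrix:
    """n_case x n_control matrix of cosine deviations with subject IDs."""

    X: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not self.row_ids:
            self.row_ids = [f"case{i+1}" for i in range(self.X.shape[0])]
        if not self.col_ids:
            self.col_ids = [f"control{j+1}" for j in range(self.X.shape[1])]

    @property
    def n_cases(self) -> int:
        return self.X.shape[0]

    @property
    def n_controls(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.X, index=self.row_ids, columns=self.col_ids).to_csv(
            path, index_label="subject_id"
        )

    @classmethod
    def from_csv(cls, path) -> "DeviationMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(
            X=df.to_numpy(dtype=float),
            row_ids=[str(s) for s in df.index],
            col_ids=[str(c) for c in df.columns],
        )


def cosine_deviation(f: np.ndarray, g: np.ndarray) -> float:
    """Cosine distance ``1 - f.g / (|f| |g|)`` between two feature vectors.

    Raises :class:`DegenerateInputError` on a zero-norm vector rather than
    returning NaN. The result lies in [0, 2] and is 0 exactly when the
    vectors are positively collinear.
    """
    f = np.asarray(f, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if f.shape != g.shape or f.size == 0:
        raise InvalidInputError("vectors must share a positive length")
    nf = np.linalg.norm(f)
    ng = np.linalg.norm(g)
    if nf == 0.0 or ng == 0.0:
        raise DegenerateInputError("zero-norm vector in cosine deviation")
    return float(1.0 - np.dot(f, g) / (nf * ng))


def deviation_matrix(
    cases: FeatureTable,
    controls: FeatureTable,
    zscore_against_controls: bool = False,
    correlation_distance: bool = False,
) -> DeviationMatrix:
    """Deviation profiles of every case subject against every control.

    ``X[i, j]`` is the cosine deviation between case ``i`` and control ``j``;
    rows follow case order and columns control order. Optionally z-scores
    each feature column against the control mean/SD first, and/or centers
    each subject's own vector before the cosine (correlation distance);
    both are off by default.
    """
    A = cases.values
    B = controls.values
    if A.shape[1] != B.shape[1]:
        raise InvalidInputError("case and control tables must share feature columns")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise InvalidInputError("need at least 2 subjects per group")
    if zscore_against_controls:
        mu = B.mean(axis=0)
        sd = B.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        A = (A - mu) / sd
        B = (B - mu) / sd
    if correlation_distance:
        A = A - A.mean(axis=1, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    for ids, norms in ((cases.subject_ids, na), (controls.subject_ids, nb)):
        if np.any(norms == 0):
            bad = [ids[i] for i in np.nonzero(norms == 0)[0]]
            raise DegenerateInputError(f"zero-norm feature vector for subjects {bad}")
    X = 1.0 - (A @ B.T) / np.outer(na, nb)
    return DeviationMatrix(
        X=X, row_ids=list(cases.subject_ids), col_ids=list(controls.subject_ids)
    )


def read_feature_table(features_path, phenotype_path=None) -> FeatureTable:
    """Read a delimited feature table (first column subject ID, header row of
    region names) and optionally join a phenotype table carrying group/
    covariates."""
    sep = "\t" if str(features_path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(features_path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise SchemaError("feature table needs a subject ID column plus features")
    ids = [str(s) for s in df.iloc[:, 0]]
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    names = [str(c) for c in df.columns[1:]]
    group = ["case"] * len(ids)
    covariates = None
    if phenotype_path is not None:
        pheno = read_phenotype(phenotype_path)
        pheno = pheno.set_index("id")
        missing = [s for s in ids if s not in pheno.index]
        if missing:
            raise SchemaError(f"phenotype table missing subjects {missing[:5]}")
        pheno = pheno.loc[ids]
        group = [str(g) for g in pheno["group"]]
        covariates = pheno.drop(columns=["group"]).reset_index(drop=True)
    return FeatureTable(
        values=values,
        subject_ids=ids,
        group=group,
        feature_names=names,
        covariates=covariates,
    )


def read_phenotype(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, comment="#")
    pheno.columns = [str(c).strip() for c in pheno.columns]
    for col in ("id", "group"):
        if col not in pheno.columns:
            raise SchemaError(f"phenotype table missing required column '{col}'")
    pheno["id"] = pheno["id"].astype(str)
    return pheno
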