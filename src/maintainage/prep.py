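"""Feature preparation: confound residualization and standardization.

Structural and cognitive feature tables are regressed on nuisance
covariates (scanner, head motion, sex, ethnicity, intracranial volume)
with ordinary least squares, column by column, and the residuals are
carried forward. Features are then z-scored so that every column enters
the age models on the same scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ConfoundTable",
    "DEFAULT_CONFOUND_SETS",
    "residualize_features",
    "standardize_features",
]

#: Default nuisance sets per modality. Gray matter is additionally
#: adjusted for intracranial volume; an alternate GM set without the
#: ICV term is available for the cortical-thickness crosscheck.
DEFAULT_CONFOUND_SETS = {
    "gray-matter": ("scanner", "motion", "sex", "ethnicity", "icv"),
    "gray-matter-no-icv": ("scanner", "motion", "sex", "ethnicity"),
    "white-matter": ("scanner", "motion", "sex", "ethnicity"),
    "cognitive": (),
}


@dataclass
class FeatureMatrix:
    """Subjects x features table with a modality tag per feature.

    Parameters
    ----------
    values : DataFrame
        Numeric matrix indexed by subject id, one column per feature.
    modality : Series
        Feature name -> modality tag (``gray-matter`` | ``white-matter``
        | ``cognitive``). Broadcast from a single string if needed.
    """

    values: pd.DataFrame
    modality: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate feature names: {list(dupes[:5])}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate subject ids")
        if self.modality is None:
            self.modality = pd.Series("cognitive", index=self.values.columns)
        elif isinstance(self.modality, str):
            self.modality = pd.Series(self.modality, index=self.values.columns)
        else:
            self.modality = pd.Series(self.modality).reindex(self.values.columns)
            if self.modality.isna().any():
                missing = self.modality.index[self.modality.isna()]
                raise ValueError(f"features without modality tag: {list(missing[:5])}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[list(features)].copy(), self.modality[list(features)])

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        df = self.values.copy()
        df.insert(0, "subject_id", df.index)
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, modality: str | pd.Series = "cognitive", sep: str = "\t"
    ) -> "FeatureMatrix":
        df = pd.read_csv(path, sep=sep).set_index("subject_id")
        return cls(df, modality)


@dataclass
class ConfoundTable:
    """Named nuisance covariates, one row per subject."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()]
            raise ValueError(f"missing values in confound columns: {list(bad)}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    def design(self, columns: Sequence[str]) -> np.ndarray:
        """Intercept + selected columns as a float design matrix."""
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise KeyError(f"unknown confound columns: {missing}")
        X = self.values[list(columns)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X])


def _check_subjects(features: FeatureMatrix, confounds: ConfoundTable) -> None:
    if not features.subject_ids.equals(confounds.subject_ids):
        raise ValueError(
            "feature and confound tables must cover the same subjects in the same order"
        )


def residualize_features(
    features: FeatureMatrix,
    confounds: ConfoundTable,
    confound_set: Sequence[str],
    sidecar: str | Path | None = None,
) -> FeatureMatrix:
    """Replace each feature by its OLS residual on intercept + confounds.

    The returned columns are orthogonal to every confound column
    (|correlation| < 1e-10 up to floating point). Residualizing twice on
    the same confound set is idempotent.

    Raises
    ------
    ValueError
        If subjects mismatch or the design matrix is rank deficient
        (the error names the collinear columns).
    """
    _check_subjects(features, confounds)
    if not confound_set:
        return FeatureMatrix(features.values.copy(), features.modality.copy())
    X = confounds.design(confound_set)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j, name in enumerate(["intercept", *confound_set]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient confound design; collinear columns: {collinear}")
    Y = features.to_numpy()
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite feature values")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid, index=features.subject_ids, columns=features.feature_names)
    if sidecar is not None:
        Path(sidecar).write_text(
            json.dumps(
                {
                    "confound_set": list(confound_set),
                    "n_subjects": int(len(out)),
                    "features": list(map(str, features.feature_names)),
                },
                indent=2,
            )
        )
    return FeatureMatrix(out, features.modality.copy())


def standardize_features(features: FeatureMatrix, ddof: int = 1) -> FeatureMatrix:
    """Z-score every column (mean 0, sample SD 1, n-1 denominator).

    Raises
    ------
    ValueError
        If any column has zero variance; the error lists the columns.
    """
    Y = features.to_numpy()
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite feature values")
    sd = Y.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        raise ValueError(
            f"zero-variance feature columns: {list(features.feature_names[zero][:10])}"
        )
    Z = (Y - Y.mean(axis=0)) / sd
    return FeatureMatrix(
        pd.DataFrame(Z, index=features.subject_ids, columns=features.feature_names),
        features.modality.copy(),
    )
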