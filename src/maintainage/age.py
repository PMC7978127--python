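"""Cross-validated age prediction.

Chronological age is regressed on standardized brain or cognitive
features with a gradient-boosted tree ensemble (default) or a linear
fallback. Every subject receives an out-of-fold prediction: the model
that predicts subject i never saw subject i during training. Fold
assignment hashes sorted subject ids through a seeded permutation, so
folds are invariant to row order.

Performance (R², RMSE, MAE) is summarized over k folds x r repeats and
compared against permutation nulls in which age labels are shuffled and
the whole cross-validation is recomputed; empirical p-values use the
(k + 1) / (n + 1) estimator so that 0 exceedances in 1,000 permutations
yields p = 1.00e-3.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .prep import FeatureMatrix, standardize_features

__all__ = [
    "LearnerSpec",
    "BRAIN_SPEC",
    "COGNITIVE_SPEC",
    "DEFAULT_SEARCH_GRID",
    "PredictionResult",
    "ModelMetrics",
    "PermutationNull",
    "AgePrediction",
    "AgePredictionResults",
    "fit_predict_oof",
    "evaluate_cv",
    "hyperparameter_search",
    "nested_cv_evaluate",
    "permutation_test",
    "pca_reduce",
    "empirical_p",
]


@dataclass(frozen=True)
class LearnerSpec:
    """Learner contract: any regressor exposing fit/predict.

    ``kind="xgboost"`` is the default tree ensemble; ``kind="linear"``
    is a deterministic ordinary-least-squares fallback for bit-exact
    tests (depth/estimators/learning-rate are ignored there).
    """

    kind: str = "xgboost"
    max_depth: int = 2
    n_estimators: int = 180
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("xgboost", "linear"):
            raise ValueError(f"unknown learner kind: {self.kind!r}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")

    def make(self, seed: int = 0):
        if self.kind == "linear":
            from sklearn.linear_model import LinearRegression

            return LinearRegression()
        from xgboost import XGBRegressor

        return XGBRegressor(
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            random_state=int(seed) % (2**31 - 1),
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


#: Selected hyperparameters for the two default models.
BRAIN_SPEC = LearnerSpec("xgboost", max_depth=2, n_estimators=180, learning_rate=0.1)
COGNITIVE_SPEC = LearnerSpec("xgboost", max_depth=2, n_estimators=140, learning_rate=0.05)

#: Default randomized-search ranges: depth 1-5, estimators 60..220 by 40,
#: and the three candidate learning rates.
DEFAULT_SEARCH_GRID = {
    "max_depth": [1, 2, 3, 4, 5],
    "n_estimators": [60, 100, 140, 180, 220],
    "learning_rate": [0.1, 0.05, 0.01],
}


@dataclass
class PredictionResult:
    """Out-of-fold predicted ages with fold assignment."""

    predicted: pd.Series  # indexed by subject id, years
    folds: pd.Series  # subject id -> fold index
    model_tag: str = "brain"

    @property
    def subject_ids(self) -> pd.Index:
        return self.predicted.index


@dataclass
class ModelMetrics:
    """Fold-level accuracy summaries plus pooled prediction-age correlation."""

    r2_mean: float
    r2_sd: float
    rmse_mean: float
    rmse_sd: float
    mae_mean: float
    mae_sd: float
    r: float
    r_ci: tuple[float, float]
    r_p: float
    r_undefined: bool = False
    per_fold: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("r2_mean", "r2_sd", "rmse_mean", "rmse_sd", "mae_mean", "mae_sd",
                      "r", "r_p", "r_undefined")
        }
        d["r_ci"] = list(self.r_ci)
        return d


@dataclass
class PermutationNull:
    """Permutation null distributions with empirical p per metric."""

    observed: dict
    samples: pd.DataFrame  # one row per permutation: r2, rmse, mae
    exceedances: dict
    p_values: dict
    n_perm: int


def empirical_p(exceedances: int, n_perm: int) -> float:
    """(k + 1) / (n + 1) permutation p-value; never exactly zero."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 <= exceedances <= n_perm:
        raise ValueError("exceedances must lie in [0, n_perm]")
    return (exceedances + 1) / (n_perm + 1)


def subject_folds(subject_ids: Sequence, k: int, seed: int) -> pd.Series:
    """Seeded fold assignment keyed by subject id (row-order invariant)."""
    ids = sorted(map(str, subject_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = pd.Series(perm % k, index=pd.Index(ids, name="subject_id"))
    return folds.reindex([str(s) for s in subject_ids]).astype(int)


def _as_matrix(features: FeatureMatrix | pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    if isinstance(features, FeatureMatrix):
        return features.to_numpy(), features.subject_ids
    return features.to_numpy(dtype=float), features.index


def pooled_r(pred: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], float, bool]:
    """Pearson r with Fisher-z 95% CI between pooled predictions and age.

    A degenerate (constant) prediction or age vector leaves r undefined;
    it is reported as 0 with the ``undefined`` flag set.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0, (0.0, 0.0), 1.0, True
    r, r_p = stats.pearsonr(pred, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(len(y) - 3)
    return float(r), (float(np.tanh(z - half)), float(np.tanh(z + half))), float(r_p), False


def _metric_triplet(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    mae = float(np.mean(np.abs(y - yhat)))
    return r2, rmse, mae


def fit_predict_oof(
    features: FeatureMatrix | pd.DataFrame,
    age: Sequence[float],
    spec: LearnerSpec | None = None,
    k: int = 10,
    seed: int = 0,
    model_tag: str = "brain",
) -> PredictionResult:
    """One cross-validation pass of out-of-fold age predictions."""
    spec = spec or BRAIN_SPEC
    X, ids = _as_matrix(features)
    y = np.asarray(age, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) != len(X):
        raise ValueError("age vector length must match feature rows")
    if len(y) < 2 * k:
        raise ValueError(f"need n >= 2k subjects (n={len(y)}, k={k})")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in features or age")
    folds = subject_folds(ids, k, seed)
    fold_arr = folds.to_numpy()
    pred = np.empty(len(y))
    for f in range(k):
        test = fold_arr == f
        model = spec.make(seed=seed * 1000 + f)
        model.fit(X[~test], y[~test])
        pred[test] = model.predict(X[test])
    return PredictionResult(
        predicted=pd.Series(pred, index=ids, name="predicted_age"),
        folds=pd.Series(fold_arr, index=ids, name="fold"),
        model_tag=model_tag,
    )


def evaluate_cv(
    features: FeatureMatrix | pd.DataFrame,
    age: Sequence[float],
    spec: LearnerSpec | None = None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> ModelMetrics:
    """Fold-level R²/RMSE/MAE over k x repeats held-out folds.

    The pooled Pearson r between predicted and chronological age is
    computed on the out-of-fold predictions of the first repeat; for a
    degenerate (constant) prediction vector r is reported as 0 with
    ``r_undefined=True``.
    """
    y = np.asarray(age, dtype=float)
    rows = []
    first_pred = None
    child_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31 - 1)
    for rep in range(repeats):
        res = fit_predict_oof(features, y, spec, k=k, seed=int(child_seeds[rep]))
        if rep == 0:
            first_pred = res.predicted.to_numpy()
        fold_arr = res.folds.to_numpy()
        pred = res.predicted.to_numpy()
        for f in range(k):
            m = fold_arr == f
            r2, rmse, mae = _metric_triplet(y[m], pred[m])
            rows.append({"repeat": rep, "fold": f, "r2": r2, "rmse": rmse, "mae": mae})
    per_fold = pd.DataFrame(rows)
    assert first_pred is not None
    r, r_ci, r_p, undef = pooled_r(first_pred, y)
    return ModelMetrics(
        r2_mean=float(per_fold["r2"].mean()),
        r2_sd=float(per_fold["r2"].std(ddof=1)),
        rmse_mean=float(per_fold["rmse"].mean()),
        rmse_sd=float(per_fold["rmse"].std(ddof=1)),
        mae_mean=float(per_fold["mae"].mean()),
        mae_sd=float(per_fold["mae"].std(ddof=1)),
        r=float(r),
        r_ci=r_ci,
        r_p=float(r_p),
        r_undefined=undef,
        per_fold=per_fold,
    )


def hyperparameter_search(
    features: FeatureMatrix | pd.DataFrame,
    age: Sequence[float],
    grid: Mapping[str, Sequence],
    n_draws: int = 10,
    k: int = 10,
    seed: int = 0,
    kind: str = "xgboost",
) -> LearnerSpec:
    """Randomized search over a hyperparameter grid, scored by CV RMSE.

    Draws ``n_draws`` distinct grid points (all of them when the grid is
    no larger) and returns the spec minimizing mean cross-validated
    RMSE; ties break toward smaller depth, fewer estimators, then draw
    order.
    """
    keys = ("max_depth", "n_estimators", "learning_rate")
    if not grid or any(len(grid.get(kname, ())) == 0 for kname in grid):
        raise ValueError("empty hyperparameter grid")
    levels = [list(grid.get(kname, [getattr(LearnerSpec(), kname)])) for kname in keys]
    points = list(itertools.product(*levels))
    rng = np.random.default_rng(seed)
    if n_draws >= len(points):
        chosen = points
    else:
        idx = rng.choice(len(points), size=n_draws, replace=False)
        chosen = [points[i] for i in idx]
    scored = []
    for order, (depth, n_est, lr) in enumerate(chosen):
        spec = LearnerSpec(kind, max_depth=int(depth), n_estimators=int(n_est),
                           learning_rate=float(lr))
        m = evaluate_cv(features, age, spec, k=k, repeats=1, seed=seed)
        scored.append((m.rmse_mean, spec.max_depth, spec.n_estimators, order, spec))
    scored.sort(key=lambda t: t[:4])
    return scored[0][4]


def nested_cv_evaluate(
    features: FeatureMatrix | pd.DataFrame,
    age: Sequence[float],
    grid: Mapping[str, Sequence],
    k_outer: int = 10,
    k_inner: int = 5,
    n_draws: int = 10,
    seed: int = 0,
    kind: str = "xgboost",
) -> ModelMetrics:
    """Nested cross-validation crosscheck for the hyperparameter search.

    For each outer fold, hyperparameters are selected by randomized
    search on the training subjects only, and the refit model is scored
    on the held-out fold — an overfitting check for the single-level
    search, not the default path.
    """
    X, ids = _as_matrix(features)
    y = np.asarray(age, dtype=float)
    folds = subject_folds(ids, k_outer, seed).to_numpy()
    pred = np.empty(len(y))
    rows = []
    for f in range(k_outer):
        test = folds == f
        if isinstance(features, FeatureMatrix):
            train_feats = features.values.loc[~test]
        else:
            train_feats = pd.DataFrame(X[~test], index=np.asarray(ids)[~test])
        spec = hyperparameter_search(
            train_feats, y[~test], grid, n_draws=n_draws, k=k_inner,
            seed=seed * 100 + f, kind=kind,
        )
        model = spec.make(seed=seed * 100 + f)
        model.fit(X[~test], y[~test])
        pred[test] = model.predict(X[test])
        r2, rmse, mae = _metric_triplet(y[test], pred[test])
        rows.append({"fold": f, "r2": r2, "rmse": rmse, "mae": mae})
    per_fold = pd.DataFrame(rows)
    r, r_ci, r_p, undef = pooled_r(pred, y)
    return ModelMetrics(
        r2_mean=float(per_fold["r2"].mean()),
        r2_sd=float(per_fold["r2"].std(ddof=1)),
        rmse_mean=float(per_fold["rmse"].mean()),
        rmse_sd=float(per_fold["rmse"].std(ddof=1)),
        mae_mean=float(per_fold["mae"].mean()),
        mae_sd=float(per_fold["mae"].std(ddof=1)),
        r=r, r_ci=r_ci, r_p=r_p, r_undefined=undef, per_fold=per_fold,
    )


def permutation_test(
    features: FeatureMatrix | pd.DataFrame,
    age: Sequence[float],
    spec: LearnerSpec | None = None,
    k: int = 10,
    repeats: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Permutation null for the CV metrics.

    Each permutation shuffles the age labels and recomputes the full
    cross-validated metric set. An exceedance is a permuted metric at
    least as favorable as the observed one (higher R², lower RMSE/MAE);
    p = (exceedances + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(age, dtype=float)
    obs = evaluate_cv(features, y, spec, k=k, repeats=repeats, seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        m = evaluate_cv(features, y_perm, spec, k=k, repeats=repeats, seed=seed)
        rows.append({"r2": m.r2_mean, "rmse": m.rmse_mean, "mae": m.mae_mean})
    samples = pd.DataFrame(rows)
    exceed = {
        "r2": int((samples["r2"] >= obs.r2_mean).sum()),
        "rmse": int((samples["rmse"] <= obs.rmse_mean).sum()),
        "mae": int((samples["mae"] <= obs.mae_mean).sum()),
    }
    pvals = {m: empirical_p(c, n_perm) for m, c in exceed.items()}
    return PermutationNull(
        observed={"r2": obs.r2_mean, "rmse": obs.rmse_mean, "mae": obs.mae_mean},
        samples=samples,
        exceedances=exceed,
        p_values=pvals,
        n_perm=n_perm,
    )


def pca_reduce(
    features: FeatureMatrix, n_components: int = 20
) -> tuple[FeatureMatrix, float]:
    """Top principal-component scores of the standardized feature matrix.

    Returns the component-score matrix (columns ordered by decreasing
    explained variance) and the total explained-variance fraction.
    """
    n, p = features.shape
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_subjects, n_features)={min(n, p)}"
        )
    Z = standardize_features(features).to_numpy()
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    cols = [f"pc{j + 1:02d}" for j in range(n_components)]
    out = FeatureMatrix(
        pd.DataFrame(scores, index=features.subject_ids, columns=cols),
        pd.Series(features.modality.iloc[0], index=cols),
    )
    return out, float(pca.explained_variance_ratio_.sum())


class AgePrediction:
    """Age-prediction model over a prepared feature matrix.

    Parameters
    ----------
    features : FeatureMatrix
        Residualized, standardized subjects x features table.
    age : array-like
        Chronological age in years, aligned with the feature rows.
    spec : LearnerSpec, optional
        Learner and hyperparameters (default: the brain-model ensemble).
    tag : str
        Label for reports ("brain" or "cognitive").
    """

    def __init__(self, features: FeatureMatrix, age, spec: LearnerSpec | None = None,
                 tag: str = "brain"):
        self.features = features
        self.age = np.asarray(age, dtype=float)
        self.spec = spec or (COGNITIVE_SPEC if tag == "cognitive" else BRAIN_SPEC)
        self.tag = tag

    def fit(self, k: int = 10, repeats: int = 5, seed: int = 0) -> "AgePredictionResults":
        oof = fit_predict_oof(self.features, self.age, self.spec, k=k, seed=seed,
                              model_tag=self.tag)
        metrics = evaluate_cv(self.features, self.age, self.spec, k=k, repeats=repeats,
                              seed=seed)
        return AgePredictionResults(self, oof, metrics, k=k, repeats=repeats, seed=seed)


class AgePredictionResults:
    """Out-of-fold predictions plus cross-validated performance."""

    def __init__(self, model: AgePrediction, oof: PredictionResult,
                 metrics: ModelMetrics, k: int, repeats: int, seed: int):
        self.model = model
        self.oof = oof
        self.metrics = metrics
        self.k = k
        self.repeats = repeats
        self.seed = seed

    @property
    def predicted_age(self) -> pd.Series:
        return self.oof.predicted

    def permutation_null(self, n_perm: int = 1000) -> PermutationNull:
        return permutation_test(self.model.features, self.model.age, self.model.spec,
                                k=self.k, repeats=self.repeats, n_perm=n_perm,
                                seed=self.seed)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"{self.model.tag} age model ({self.model.spec.kind}), "
            f"{self.k}-fold CV x {self.repeats} repeats, n={len(self.model.age)}",
            f"  R^2  = {m.r2_mean:.2f} +/- {m.r2_sd:.2f}",
            f"  RMSE = {m.rmse_mean:.2f} +/- {m.rmse_sd:.2f} years",
            f"  MAE  = {m.mae_mean:.2f} +/- {m.mae_sd:.2f} years",
            f"  r(predicted, age) = {m.r:.2f} "
            f"[{m.r_ci[0]:.2f}, {m.r_ci[1]:.2f}], p = {m.r_p:.3g}",
        ]
        return "\n".join(lines)
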