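"""Latent class growth analysis (LCGA) for longitudinal lifestyle indices.

A finite mixture of polynomial growth curves with class-specific fixed
effects, no within-class random effects, and a residual variance shared
across classes and phases. Subject i in class k contributes a product of
independent normal densities over the phases i actually observed
(full-information maximum likelihood), so subjects missing a phase stay
in the likelihood::

    f(y_i) = sum_k  pi_k  prod_{j in obs(i)}  N(y_ij; X_j' beta_k, sigma^2)

where ``X_j = (1, t_j, t_j^2, ...)`` at the transformed time score
``t_j = (mean age at phase j - 53) / 10``.

Estimation is EM with a multi-start protocol: many short runs from
random responsibilities, the best few continued to convergence. The
within-start log-likelihood is non-decreasing at every iteration.
Class enumeration uses AIC/BIC/aBIC, entropy, a minimum class share, and
a parametric bootstrap likelihood-ratio test (BLRT) of K vs K-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeMetric",
    "GrowthSpec",
    "FitIndices",
    "LCGA",
    "LCGAResults",
    "transform_time",
    "fit_lcga",
    "fit_indices",
    "blrt",
    "BLRTResult",
    "select_model",
    "enumerate_classes",
    "SelectionReport",
]

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class TimeMetric:
    """Phase mean ages and their transformed time scores."""

    mean_ages: tuple[float, ...]
    center: float = 53.0
    scale: float = 10.0

    @property
    def scores(self) -> np.ndarray:
        return (np.asarray(self.mean_ages, dtype=float) - self.center) / self.scale


def transform_time(
    mean_ages: Sequence[float], center: float = 53.0, scale: float = 10.0
) -> TimeMetric:
    """Centered/scaled time metric: (mean age - center) / scale.

    The default centering (53, the mean baseline age) and scale (10)
    map phase mean ages [53, 56, 64, 68, 70] to [0, 0.3, 1.1, 1.5, 1.7].
    """
    ages = np.asarray(mean_ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("non-finite phase ages")
    if len(ages) > 1 and np.any(np.diff(ages) <= 0):
        raise ValueError("phase mean ages must be strictly increasing")
    return TimeMetric(tuple(float(a) for a in ages), center, scale)


@dataclass(frozen=True)
class GrowthSpec:
    """LCGA estimation settings.

    ``n_starts`` short EM runs (capped at ``max_iter_start`` iterations)
    seed the search; the best ``n_final`` by log-likelihood are run to a
    ``tol`` change in log-likelihood (up to ``max_iter_final``).
    """

    n_classes: int = 3
    order: int = 2
    n_starts: int = 500
    n_final: int = 20
    max_iter_start: int = 20
    max_iter_final: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.order not in (0, 1, 2):
            raise ValueError("polynomial order must be 0, 1 or 2")
        if self.n_starts < 1 or self.n_final < 1:
            raise ValueError("n_starts and n_final must be >= 1")

    @property
    def n_params(self) -> int:
        # K polynomial coefficient sets + (K-1) free weights + sigma^2
        return self.n_classes * (self.order + 1) + self.n_classes


@dataclass
class FitIndices:
    aic: float
    bic: float
    abic: float
    entropy: float
    smallest_class_share: float

    def to_dict(self) -> dict:
        return {
            "aic": self.aic,
            "bic": self.bic,
            "abic": self.abic,
            "entropy": self.entropy,
            "smallest_class_share": self.smallest_class_share,
        }


class _BoundaryCollapse(RuntimeError):
    """A class proportion or the residual variance collapsed to zero."""


class LCGA:
    """LCGA model over a subjects x phases outcome matrix.

    Parameters
    ----------
    endog : DataFrame or ndarray
        Standardized index values, one column per phase; NaN marks a
        missing (unobserved) phase.
    time : TimeMetric or array-like
        Transformed time scores per phase.
    n_classes, order : int
        Number of trajectory classes and polynomial order (<= 2).
    """

    def __init__(self, endog, time, n_classes: int = 3, order: int = 2):
        if isinstance(endog, pd.DataFrame):
            self.subject_ids = endog.index
            Y = endog.to_numpy(dtype=float)
        else:
            Y = np.asarray(endog, dtype=float)
            self.subject_ids = pd.RangeIndex(len(Y))
        t = time.scores if isinstance(time, TimeMetric) else np.asarray(time, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != len(t):
            raise ValueError("endog must be subjects x phases matching the time metric")
        self.Y = np.where(np.isnan(Y), 0.0, Y)
        self.mask = ~np.isnan(Y)
        self.n_obs_i = self.mask.sum(axis=1)
        if (self.n_obs_i == 0).any():
            raise ValueError("subjects with no observed phases")
        self.t = t
        self.spec = GrowthSpec(n_classes=n_classes, order=order)
        if self.spec.n_params > len(Y):
            raise ValueError("more parameters than subjects")
        self.X = np.vander(t, order + 1, increasing=True)  # phases x (order+1)

    # -- EM internals ------------------------------------------------------
    def _class_loglik(self, beta: np.ndarray, sigma2: float) -> np.ndarray:
        """n x K matrix of per-subject class log-densities over observed phases."""
        mu = self.X @ beta.T  # phases x K
        resid = self.Y[:, :, None] - mu[None, :, :]  # n x phases x K
        sq = np.einsum("npk,np->nk", resid**2, self.mask.astype(float))
        return -0.5 * (sq / sigma2 + self.n_obs_i[:, None] * (LOG_2PI + np.log(sigma2)))

    def _e_step(self, pi, beta, sigma2):
        logjoint = np.log(pi)[None, :] + self._class_loglik(beta, sigma2)
        m = logjoint.max(axis=1, keepdims=True)
        lse = m + np.log(np.exp(logjoint - m).sum(axis=1, keepdims=True))
        ll = float(lse.sum())
        r = np.exp(logjoint - lse)
        return r, ll

    def _m_step(self, r: np.ndarray):
        n, K = r.shape
        pi = r.mean(axis=0)
        if pi.min() < 1e-8:
            raise _BoundaryCollapse("class proportion collapsed to zero")
        beta = np.empty((K, self.X.shape[1]))
        Ym = self.Y * self.mask
        total_sq = 0.0
        for k in range(K):
            w = self.mask.T @ r[:, k]  # per-phase effective weight
            A = self.X.T @ (w[:, None] * self.X)
            b = self.X.T @ (Ym.T @ r[:, k])
            beta[k] = np.linalg.solve(A, b)
        mu = self.X @ beta.T
        resid2 = (self.Y[:, :, None] - mu[None, :, :]) ** 2
        total_sq = float(np.einsum("npk,np,nk->", resid2, self.mask.astype(float), r))
        sigma2 = total_sq / self.n_obs_i.sum()
        if sigma2 < 1e-12:
            if K == 1:
                # noiseless single-class data: clamp so the least-squares
                # limit (exact coefficient recovery) remains well-defined
                sigma2 = max(sigma2, 1e-15)
            else:
                raise _BoundaryCollapse("residual variance collapsed to zero")
        return pi, beta, sigma2

    def _run_em(self, r0: np.ndarray, max_iter: int, tol: float):
        r = r0
        ll_path: list[float] = []
        pi = beta = None
        sigma2 = None
        ll = -np.inf
        for _ in range(max_iter):
            pi, beta, sigma2 = self._m_step(r)
            r, ll_new = self._e_step(pi, beta, sigma2)
            ll_path.append(ll_new)
            if np.isfinite(ll) and ll_new - ll < tol:
                ll = ll_new
                break
            ll = ll_new
        return pi, beta, sigma2, r, ll, ll_path

    def fit(
        self,
        n_starts: int | None = None,
        n_final: int | None = None,
        max_iter_start: int | None = None,
        max_iter_final: int | None = None,
        tol: float | None = None,
        seed: int = 0,
    ) -> "LCGAResults":
        """Multi-start EM; returns the best converged solution."""
        spec = self.spec
        if n_starts is not None:
            spec = replace(spec, n_starts=n_starts)
        if n_final is not None:
            spec = replace(spec, n_final=n_final)
        if max_iter_start is not None:
            spec = replace(spec, max_iter_start=max_iter_start)
        if max_iter_final is not None:
            spec = replace(spec, max_iter_final=max_iter_final)
        if tol is not None:
            spec = replace(spec, tol=tol)
        self.spec = spec
        n, K = len(self.Y), spec.n_classes

        if K == 1:
            # degenerates to weighted least squares; no multi-start needed
            r0 = np.ones((n, 1))
            pi, beta, sigma2, r, ll, ll_path = self._run_em(
                r0, spec.max_iter_final, spec.tol
            )
            return LCGAResults(self, pi, beta, sigma2, r, ll, ll_path, spec, converged=True)

        ss = np.random.SeedSequence(seed)
        start_seeds = ss.generate_state(spec.n_starts) % (2**31 - 1)
        stage1 = []
        n_collapsed = 0
        for s in range(spec.n_starts):
            rng = np.random.default_rng(int(start_seeds[s]))
            r0 = rng.dirichlet(np.ones(K), size=n)
            try:
                out = self._run_em(r0, spec.max_iter_start, spec.tol)
            except _BoundaryCollapse:
                n_collapsed += 1
                logger.debug("start %d collapsed; skipped", s)
                continue
            stage1.append((out[4], s, out))
        if not stage1:
            raise RuntimeError("all EM starts collapsed; no solution found")
        stage1.sort(key=lambda x: (-x[0], x[1]))
        best = None
        best_path: list[float] = []
        for ll1, s, out in stage1[: spec.n_final]:
            pi, beta, sigma2, r, _, path1 = out
            try:
                pi, beta, sigma2, r, ll, path2 = self._run_em(
                    r, spec.max_iter_final, spec.tol
                )
            except _BoundaryCollapse:
                n_collapsed += 1
                continue
            if best is None or ll > best[4]:
                best = (pi, beta, sigma2, r, ll)
                best_path = path1 + path2
        if best is None:
            raise RuntimeError("all final optimizations collapsed; no solution found")
        pi, beta, sigma2, r, ll = best
        if n_collapsed:
            logger.info("%d/%d EM runs hit a boundary and were restarted/skipped",
                        n_collapsed, spec.n_starts)
        res = LCGAResults(self, pi, beta, sigma2, r, ll, best_path, spec, converged=True)
        return res._relabel()


class LCGAResults:
    """Fitted LCGA: weights, growth coefficients, posteriors, fit indices.

    Classes are relabelled in descending order of the fitted value at
    the first phase, so the least favorable (lowest-starting) class is
    last and serves as the dummy-coding reference downstream.
    """

    def __init__(self, model: LCGA, weights, coefficients, sigma2, posterior,
                 loglike, ll_path, spec: GrowthSpec, converged: bool):
        self.model = model
        self.weights = np.asarray(weights, dtype=float)
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.sigma2 = float(sigma2)
        self.posterior = np.asarray(posterior, dtype=float)
        self.loglike = float(loglike)
        self.ll_path = list(ll_path)
        self.spec = spec
        self.converged = converged

    def _relabel(self) -> "LCGAResults":
        baseline = self.model.X[0] @ self.coefficients.T
        order = np.argsort(-baseline, kind="stable")
        self.weights = self.weights[order]
        self.coefficients = self.coefficients[order]
        self.posterior = self.posterior[:, order]
        return self

    # -- derived quantities ------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def modal_assignment(self) -> pd.Series:
        return pd.Series(self.posterior.argmax(axis=1), index=self.model.subject_ids,
                         name="class")

    @property
    def class_shares(self) -> np.ndarray:
        counts = np.bincount(self.posterior.argmax(axis=1), minlength=self.n_classes)
        return counts / len(self.posterior)

    def class_curves(self) -> np.ndarray:
        """Fitted mean trajectory per class (K x phases)."""
        return (self.model.X @ self.coefficients.T).T

    def predict(self, t: Sequence[float] | None = None) -> np.ndarray:
        X = (self.model.X if t is None
             else np.vander(np.asarray(t, float), self.spec.order + 1, increasing=True))
        return (X @ self.coefficients.T).T

    def summary(self) -> str:
        fi = fit_indices(self)
        lines = [
            f"LCGA: K={self.n_classes}, order={self.spec.order}, "
            f"n={len(self.posterior)}, logL={self.loglike:.2f}, params={self.n_params}",
            f"  AIC={fi.aic:.2f}  BIC={fi.bic:.2f}  aBIC={fi.abic:.2f}  "
            f"entropy={fi.entropy:.3f}",
            f"  residual SD={np.sqrt(self.sigma2):.3f}",
        ]
        for k in range(self.n_classes):
            coef = ", ".join(f"{c:.3f}" for c in self.coefficients[k])
            lines.append(
                f"  class {k + 1}: pi={self.weights[k]:.3f} "
                f"share={self.class_shares[k]:.3f} coef=({coef})"
            )
        return "\n".join(lines)


def fit_lcga(
    endog,
    time,
    spec: GrowthSpec | None = None,
    seed: int = 0,
) -> LCGAResults:
    """Fit an LCGA under a :class:`GrowthSpec` multi-start protocol."""
    spec = spec or GrowthSpec()
    model = LCGA(endog, time, n_classes=spec.n_classes, order=spec.order)
    return model.fit(
        n_starts=spec.n_starts,
        n_final=spec.n_final,
        max_iter_start=spec.max_iter_start,
        max_iter_final=spec.max_iter_final,
        tol=spec.tol,
        seed=seed,
    )


def fit_indices(results: LCGAResults, n: int | None = None) -> FitIndices:
    """AIC / BIC / sample-size-adjusted BIC / entropy / smallest class share.

    aBIC replaces ln(n) with ln((n + 2) / 24). Entropy is
    ``1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K)``, defined as 1 for K=1
    and for perfectly sharp (0/1) posteriors.
    """
    n = n if n is not None else len(results.posterior)
    p = results.n_params
    ll = results.loglike
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * np.log(n)
    abic = -2.0 * ll + p * np.log((n + 2.0) / 24.0)
    K = results.n_classes
    if K == 1:
        entropy = 1.0
    else:
        post = np.clip(results.posterior, 1e-300, 1.0)
        h = float(-(post * np.log(post)).sum())
        entropy = 1.0 - h / (n * np.log(K))
    return FitIndices(float(aic), float(bic), float(abic), float(entropy),
                      float(results.class_shares.min()))


@dataclass
class BLRTResult:
    p: float
    observed_stat: float
    bootstrap_stats: np.ndarray
    n_bootstrap: int
    n_failures: int


def _simulate_from(results: LCGAResults, mask: np.ndarray, rng: np.random.Generator):
    """Parametric draw from a fitted LCGA, keeping the missingness pattern."""
    n = mask.shape[0]
    classes = rng.choice(results.n_classes, size=n, p=results.weights / results.weights.sum())
    mu = results.class_curves()[classes]  # n x phases
    y = mu + rng.normal(0.0, np.sqrt(results.sigma2), size=mu.shape)
    return np.where(mask, y, np.nan)


def blrt(
    endog,
    time,
    spec_k: GrowthSpec,
    spec_k_minus_1: GrowthSpec,
    n_bootstrap: int = 99,
    seed: int = 0,
    fitted_k: LCGAResults | None = None,
    fitted_km1: LCGAResults | None = None,
    max_failure_fraction: float = 0.2,
) -> BLRTResult:
    """Bootstrap likelihood-ratio test of K vs K-1 classes.

    Simulates ``n_bootstrap`` datasets from the fitted (K-1)-class model
    (preserving each subject's missingness pattern), refits both models
    on each, and compares the observed 2*(LL_K - LL_{K-1}) with the
    bootstrap distribution; p = (exceedances + 1) / (n_ok + 1). Bootstrap
    refits that fail are excluded and counted; more than
    ``max_failure_fraction`` failures is an error.
    """
    if spec_k.n_classes < 2 or spec_k.n_classes != spec_k_minus_1.n_classes + 1:
        raise ValueError("spec_k must have K >= 2 and spec_k_minus_1 exactly K-1 classes")
    Ydf = endog if isinstance(endog, pd.DataFrame) else pd.DataFrame(np.asarray(endog, float))
    mask = ~Ydf.isna().to_numpy()
    res_km1 = fitted_km1 or fit_lcga(Ydf, time, spec_k_minus_1, seed=seed)
    res_k = fitted_k or fit_lcga(Ydf, time, spec_k, seed=seed)
    observed = 2.0 * (res_k.loglike - res_km1.loglike)

    ss = np.random.SeedSequence(seed)
    boot_seeds = ss.generate_state(n_bootstrap + 1)[1:] % (2**31 - 1)
    stats_list = []
    failures = 0
    for b in range(n_bootstrap):
        rng = np.random.default_rng(int(boot_seeds[b]))
        Yb = _simulate_from(res_km1, mask, rng)
        try:
            b_km1 = fit_lcga(Yb, time, spec_k_minus_1, seed=int(boot_seeds[b]))
            b_k = fit_lcga(Yb, time, spec_k, seed=int(boot_seeds[b]))
        except RuntimeError:
            failures += 1
            continue
        stats_list.append(2.0 * (b_k.loglike - b_km1.loglike))
    if failures > max_failure_fraction * n_bootstrap:
        raise RuntimeError(
            f"{failures}/{n_bootstrap} bootstrap refits failed; BLRT unreliable"
        )
    boot = np.asarray(stats_list)
    exceed = int((boot >= observed).sum())
    p = (exceed + 1) / (len(boot) + 1)
    return BLRTResult(float(p), float(observed), boot, n_bootstrap, failures)


@dataclass
class SelectionReport:
    selected: LCGAResults
    selected_k: int
    met_criteria: bool
    audit: list[dict] = field(default_factory=list)


def select_model(
    candidates: Sequence[tuple[LCGAResults, FitIndices, float | None]],
    entropy_min: float = 0.8,
    min_class_share: float = 0.05,
    blrt_alpha: float = 0.05,
) -> SelectionReport:
    """Class-enumeration rule over fitted candidates.

    Survivors need entropy >= 0.8, every class >= 5% of subjects, and a
    significant BLRT (a one-class model has no BLRT and passes that
    criterion). Among survivors the lowest BIC wins; ties break by aBIC
    then AIC. With no survivor the best-BIC candidate is returned,
    flagged as not meeting criteria, and every exclusion is audited.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    audit = []
    survivors = []
    for res, fi, p in candidates:
        reasons = []
        if fi.entropy < entropy_min:
            reasons.append(f"entropy {fi.entropy:.3f} < {entropy_min}")
        if fi.smallest_class_share < min_class_share:
            reasons.append(
                f"class share {fi.smallest_class_share:.3f} < {min_class_share:.0%}"
            )
        if p is not None and not p < blrt_alpha:
            reasons.append(f"BLRT p {p:.3f} >= {blrt_alpha}")
        audit.append(
            {
                "k": res.n_classes,
                "loglike": res.loglike,
                "bic": fi.bic,
                "abic": fi.abic,
                "aic": fi.aic,
                "entropy": fi.entropy,
                "smallest_class_share": fi.smallest_class_share,
                "blrt_p": p,
                "excluded": bool(reasons),
                "reasons": reasons,
            }
        )
        if not reasons:
            survivors.append((fi.bic, fi.abic, fi.aic, res))
    if survivors:
        survivors.sort(key=lambda t: t[:3])
        chosen = survivors[0][3]
        return SelectionReport(chosen, chosen.n_classes, True, audit)
    by_bic = sorted(candidates, key=lambda c: (c[1].bic, c[1].abic, c[1].aic))
    chosen = by_bic[0][0]
    logger.warning("no candidate met the enumeration criteria; returning best BIC (K=%d)",
                   chosen.n_classes)
    return SelectionReport(chosen, chosen.n_classes, False, audit)


def enumerate_classes(
    endog,
    time,
    k_max: int = 4,
    order: int = 2,
    n_starts: int = 50,
    n_final: int = 5,
    n_bootstrap: int = 49,
    seed: int = 0,
    run_blrt: bool = True,
    blrt_spec_overrides: dict | None = None,
) -> tuple[SelectionReport, list[tuple[LCGAResults, FitIndices, float | None]]]:
    """Fit K = 1..k_max, compute fit indices and BLRT, apply the selection rule."""
    candidates = []
    fitted: dict[int, LCGAResults] = {}
    for K in range(1, k_max + 1):
        spec = GrowthSpec(n_classes=K, order=order, n_starts=n_starts, n_final=n_final)
        res = fit_lcga(endog, time, spec, seed=seed + K)
        fitted[K] = res
        p = None
        if run_blrt and K >= 2:
            overrides = blrt_spec_overrides or {}
            boot_spec_k = replace(spec, **overrides)
            boot_spec_km1 = replace(spec, n_classes=K - 1, **overrides)
            p = blrt(
                endog, time, boot_spec_k, boot_spec_km1,
                n_bootstrap=n_bootstrap, seed=seed + 100 * K,
                fitted_k=res, fitted_km1=fitted[K - 1],
            ).p
        candidates.append((res, fit_indices(res), p))
    return select_model(candidates), candidates
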