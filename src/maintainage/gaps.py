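"""Brain/cognitive age gaps, their associations, and coefficient comparisons.

The raw gap is predicted minus chronological age (positive = an
older-appearing brain or cognitive profile). Because predicted-age
residuals regress to the mean, the raw gap correlates negatively with
age; the age-bias-corrected gap is the OLS residual of the raw gap on
chronological age and is exactly uncorrelated with age.

Associations regress the (standardized) raw gap on a predictor plus
covariates: tier 1 adjusts for age only, tier 2 additionally for sex,
education, ethnicity, BMI and the other gap (mutually adjusting the two
reserve proxies — education and premorbid IQ — for each other, with BMI
dropped, when one of them is the predictor). Two association strengths
on correlated outcomes are compared with the correlated-samples Z::

    Z = (b1 - b2) / sqrt(se1^2 + se2^2 - 2*rho*se1*se2)

where rho is the age-adjusted correlation between the two gap measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GapEstimate",
    "AssociationResult",
    "ZComparison",
    "GapCorrelation",
    "compute_gap",
    "bias_correct_gap",
    "correlate_gaps",
    "GapAssociation",
    "associate",
    "z_correlated",
    "fdr_correct",
    "exclude_outliers",
    "se_from_ci",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class GapEstimate:
    """Per-subject predicted age, raw gap, and bias-corrected gap."""

    subject_ids: pd.Index
    predicted: np.ndarray  # years
    chronological: np.ndarray  # years
    raw: np.ndarray = field(init=False)  # predicted - chronological
    corrected: np.ndarray | None = None  # residual of raw on age
    tag: str = "brain"

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.chronological = np.asarray(self.chronological, dtype=float)
        if len(self.predicted) != len(self.chronological):
            raise ValueError("predicted and chronological age lengths differ")
        if not (np.all(np.isfinite(self.predicted)) and np.all(np.isfinite(self.chronological))):
            raise ValueError("non-finite ages")
        self.raw = self.predicted - self.chronological

    def as_frame(self) -> pd.DataFrame:
        d = {
            "predicted_age": self.predicted,
            "chronological_age": self.chronological,
            "raw_gap": self.raw,
        }
        if self.corrected is not None:
            d["corrected_gap"] = self.corrected
        return pd.DataFrame(d, index=self.subject_ids)


def compute_gap(
    predicted: Sequence[float],
    chronological: Sequence[float],
    subject_ids: Sequence | None = None,
    tag: str = "brain",
) -> GapEstimate:
    """Raw age gap: predicted minus chronological age (years).

    Positive values mean an older-appearing profile; negative values,
    maintenance relative to normative aging.
    """
    predicted = np.asarray(predicted, dtype=float)
    if subject_ids is None:
        subject_ids = pd.RangeIndex(len(predicted))
    return GapEstimate(pd.Index(subject_ids), predicted, np.asarray(chronological, float),
                       tag=tag)


def bias_correct_gap(gap: GapEstimate) -> GapEstimate:
    """Residualize the raw gap on chronological age (intercept + slope).

    The corrected gap has zero correlation with age by construction.
    """
    n = len(gap.raw)
    if n < 3:
        raise ValueError("need at least 3 subjects for bias correction")
    age = gap.chronological
    if np.var(age) == 0:
        raise ValueError("age variance is zero; bias correction undefined")
    X = np.column_stack([np.ones(n), age])
    beta, *_ = np.linalg.lstsq(X, gap.raw, rcond=None)
    out = GapEstimate(gap.subject_ids, gap.predicted, gap.chronological, tag=gap.tag)
    out.corrected = gap.raw - X @ beta
    return out


@dataclass
class GapCorrelation:
    r: float
    ci: tuple[float, float]
    p: float
    n: int


def correlate_gaps(bag: GapEstimate, cag: GapEstimate) -> GapCorrelation:
    """Pearson correlation between corrected gaps, with Fisher-z 95% CI."""
    if not bag.subject_ids.equals(cag.subject_ids):
        raise ValueError("gap estimates cover different subjects")
    if bag.corrected is None or cag.corrected is None:
        raise ValueError("bias-correct both gaps before correlating")
    n = len(bag.corrected)
    if n < 4:
        raise ValueError("need n >= 4 for a confidence interval")
    r, p = stats.pearsonr(bag.corrected, cag.corrected)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = Z95 / np.sqrt(n - 3)
    return GapCorrelation(float(r), (float(np.tanh(z - half)), float(np.tanh(z + half))),
                          float(p), n)


@dataclass
class AssociationResult:
    """One predictor -> gap regression coefficient."""

    predictor: str
    outcome: str
    tier: int
    beta: float
    se: float
    ci: tuple[float, float]
    p: float
    n: int
    p_corr: float | None = None

    @property
    def trend(self) -> bool:
        """Nominally significant but not after FDR correction."""
        return self.p < 0.05 and (self.p_corr is not None and self.p_corr >= 0.05)


def _maybe_standardize(s: pd.Series) -> pd.Series:
    """Z-score continuous columns; leave binary 0/1 codes untouched."""
    vals = s.dropna().unique()
    if len(vals) <= 2:
        return s.astype(float)
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero-variance column: {s.name}")
    return (s - s.mean()) / sd


TIER2_BASE = ("age", "sex", "education", "ethnicity", "bmi")
RESERVE_PROXIES = {"education": "premorbid_iq", "premorbid_iq": "education"}


class GapAssociation:
    """Linear association model between a predictor and an age gap.

    Parameters
    ----------
    gap : GapEstimate
        Outcome; the raw gap is used, with age always among the covariates.
    data : DataFrame
        Covariate table indexed by subject id; must contain ``age`` and,
        for tier 2, sex / education / ethnicity / bmi plus an
        ``other_gap`` column holding the complementary gap measure.
    predictor : str or Series
        Column name in ``data`` or an external (numeric or dummy-coded)
        series aligned on subject id.
    tier : int
        1 = age-adjusted only; 2 = full covariate adjustment.
    """

    def __init__(self, gap: GapEstimate, data: pd.DataFrame, predictor, tier: int = 1,
                 predictor_name: str | None = None):
        if tier not in (1, 2):
            raise ValueError(f"unknown model tier: {tier}")
        self.tier = tier
        self.gap = gap
        self.data = data.loc[gap.subject_ids]
        if isinstance(predictor, str):
            self.predictor = self.data[predictor]
            self.predictor_name = predictor
        else:
            self.predictor = pd.Series(predictor).reindex(gap.subject_ids)
            self.predictor_name = predictor_name or getattr(predictor, "name", "predictor")
        if self.predictor.isna().any():
            raise ValueError("missing predictor values")

    def covariate_columns(self) -> list[str]:
        if self.tier == 1:
            return ["age"]
        cols = list(TIER2_BASE)
        if self.predictor_name in RESERVE_PROXIES:
            cols.remove("bmi")
            other = RESERVE_PROXIES[self.predictor_name]
            if other not in cols:
                cols.append(other)
        cols = [c for c in cols if c != self.predictor_name]
        if "other_gap" in self.data.columns:
            cols.append("other_gap")
        return cols

    def fit(self) -> AssociationResult:
        y = _maybe_standardize(pd.Series(self.gap.raw, index=self.gap.subject_ids,
                                         name="gap"))
        cols = {self.predictor_name: _maybe_standardize(self.predictor)}
        for c in self.covariate_columns():
            cols[c] = _maybe_standardize(self.data[c])
        X = pd.DataFrame(cols, index=self.gap.subject_ids)
        X = sm.add_constant(X)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("rank-deficient association design matrix")
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        j = list(X.columns).index(self.predictor_name)
        ci = fit.conf_int()[j]
        return AssociationResult(
            predictor=self.predictor_name,
            outcome=self.gap.tag,
            tier=self.tier,
            beta=float(fit.params[j]),
            se=float(fit.bse[j]),
            ci=(float(ci[0]), float(ci[1])),
            p=float(fit.pvalues[j]),
            n=int(fit.nobs),
        )


def associate(
    gap: GapEstimate,
    predictor,
    data: pd.DataFrame,
    tier: int = 1,
    predictor_name: str | None = None,
) -> AssociationResult:
    """OLS of the (standardized) raw gap on predictor + tier covariates."""
    return GapAssociation(gap, data, predictor, tier=tier, predictor_name=predictor_name).fit()


@dataclass
class ZComparison:
    """Correlated-samples comparison of two regression coefficients."""

    z: float
    rho: float
    p: float
    beta1: float
    beta2: float


def z_correlated(beta1: float, se1: float, beta2: float, se2: float, rho: float) -> ZComparison:
    """Z-test for the difference of two correlated coefficients.

    ``rho`` is the correlation between the two outcome measures
    (age-adjusted when comparing gap associations). Two-sided p from the
    standard normal.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    var = se1**2 + se2**2 - 2.0 * rho * se1 * se2
    if var <= 0:
        raise ValueError(f"non-positive variance of the coefficient difference: {var}")
    z = (beta1 - beta2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ZComparison(float(z), float(rho), float(p), float(beta1), float(beta2))


def se_from_ci(lo: float, hi: float, level_z: float = Z95) -> float:
    """Standard error recovered from a printed 95% CI (half-width / 1.96)."""
    return (hi - lo) / 2.0 / level_z


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exclude_outliers(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Inclusion mask: keep values within [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (type-7).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values for quartile-based exclusion")
    q1, q3 = np.percentile(x, [25, 75])  # default linear interpolation = type 7
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)
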