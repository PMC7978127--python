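"""Healthy-lifestyle index scoring across repeated study phases.

Each subject-phase record carries three behaviors: weekly alcohol units,
smoker status (never / ex / current) and hours of moderate-to-vigorous
physical activity (MVPA, MET > 3). A phase index in {0,1,2,3} awards one
point per guideline-consistent behavior:

* alcohol point   — at most 7 units/week (abstinence and light drinking
  both count as healthy; anything above 7 does not),
* smoking point   — never-smoker only (ex- and current smokers score 0),
* activity point  — at least 2.5 h/week of MVPA.

Cumulative scores average the per-phase indices over observed phases
(subjects need at least four observed phases); a continuous variant
replaces the binary alcohol/activity points with within-phase z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LifestylePanel",
    "score_phase",
    "score_panel",
    "standardize_indices",
    "cumulative_score",
    "continuous_cumulative_score",
    "ALCOHOL_MAX_UNITS",
    "MVPA_MIN_HOURS",
]

logger = logging.getLogger(__name__)

ALCOHOL_MAX_UNITS = 7.0  # healthy iff units/week <= 7 (boundary inclusive)
MVPA_MIN_HOURS = 2.5  # healthy iff hours/week >= 2.5 (boundary inclusive)
SMOKER_LEVELS = ("never", "ex", "current")

REQUIRED_COLUMNS = ("subject_id", "phase", "alcohol_units", "smoker_status", "mvpa_hours")


@dataclass
class LifestylePanel:
    """Long-format subject x phase behavior records.

    ``records`` columns: subject_id, phase (integer, 0-based), alcohol_units,
    smoker_status, mvpa_hours. A missing behavior (NaN/None) marks the
    phase as unobserved rather than unhealthy.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"lifestyle panel missing columns: {missing}")
        bad = set(self.records["smoker_status"].dropna()) - set(SMOKER_LEVELS)
        if bad:
            raise ValueError(f"unknown smoker_status values: {sorted(bad)}")
        neg = self.records[["alcohol_units", "mvpa_hours"]].lt(0).any()
        if neg.any():
            raise ValueError(f"negative values in {list(neg.index[neg])}")
        dupes = self.records.duplicated(subset=["subject_id", "phase"])
        if dupes.any():
            raise ValueError("duplicate subject-phase records")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.records["subject_id"].unique()

    @property
    def phases(self) -> np.ndarray:
        return np.sort(self.records["phase"].unique())

    def to_tsv(self, path: str | Path, sep: str = "\t") -> None:
        self.records.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "LifestylePanel":
        return cls(pd.read_csv(path, sep=sep))


def score_phase(
    alcohol_units: float | None,
    smoker_status: str | None,
    mvpa_hours: float | None,
) -> int | None:
    """Score one subject-phase record on the 0-3 healthy-behavior index.

    Returns ``None`` when any behavior is missing — the phase is treated
    as unobserved, never zero-scored.
    """
    fields = (alcohol_units, smoker_status, mvpa_hours)
    if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in fields):
        return None
    if smoker_status not in SMOKER_LEVELS:
        raise ValueError(f"unknown smoker_status: {smoker_status!r}")
    if alcohol_units < 0 or mvpa_hours < 0:
        raise ValueError("alcohol_units and mvpa_hours must be non-negative")
    return int(
        (alcohol_units <= ALCOHOL_MAX_UNITS)
        + (smoker_status == "never")
        + (mvpa_hours >= MVPA_MIN_HOURS)
    )


def score_panel(panel: LifestylePanel) -> pd.DataFrame:
    """Per-phase index for every record; rows with a missing behavior get NaN.

    Returns a copy of ``panel.records`` with an ``index_score`` column.
    """
    rec = panel.records.copy()
    observed = (
        rec["alcohol_units"].notna() & rec["smoker_status"].notna() & rec["mvpa_hours"].notna()
    )
    score = np.full(len(rec), np.nan)
    obs = rec[observed]
    score[observed.to_numpy()] = (
        (obs["alcohol_units"] <= ALCOHOL_MAX_UNITS).astype(int)
        + (obs["smoker_status"] == "never").astype(int)
        + (obs["mvpa_hours"] >= MVPA_MIN_HOURS).astype(int)
    )
    rec["index_score"] = score
    return rec


def index_matrix(panel: LifestylePanel, phases: Iterable[int] | None = None) -> pd.DataFrame:
    """Wide subjects x phases matrix of indices, NaN where unobserved."""
    scored = score_panel(panel)
    wide = scored.pivot(index="subject_id", columns="phase", values="index_score")
    if phases is not None:
        wide = wide.reindex(columns=list(phases))
    return wide


def standardize_indices(wide: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each phase column across subjects with data for that phase.

    Within-phase standardization absorbs between-phase questionnaire
    differences before trajectory modelling.
    """
    sd = wide.std(axis=0, ddof=ddof)
    degenerate = sd[(sd == 0) | sd.isna()]
    if len(degenerate):
        raise ValueError(f"degenerate phases (zero variance): {list(degenerate.index)}")
    return (wide - wide.mean(axis=0)) / sd


def cumulative_score(
    wide: pd.DataFrame, min_phases: int = 4, how: str = "mean"
) -> pd.Series:
    """Per-subject cumulative lifestyle score over observed phases.

    The default is the arithmetic mean of the 0-3 indices, which is less
    biased than a sum when subjects miss a phase; ``how="sum"`` gives the
    summed variant. Subjects with fewer than ``min_phases`` observed
    phases are excluded (logged).
    """
    if how not in ("mean", "sum"):
        raise ValueError(f"how must be 'mean' or 'sum', got {how!r}")
    n_obs = wide.notna().sum(axis=1)
    excluded = wide.index[n_obs < min_phases]
    for sid in excluded:
        logger.info(
            "subject %s excluded from cumulative score: %d observed phases < %d",
            sid, n_obs[sid], min_phases,
        )
    kept = wide.loc[n_obs >= min_phases]
    agg = kept.mean(axis=1) if how == "mean" else kept.sum(axis=1, min_count=1)
    return agg.rename("cumulative_score")


def continuous_cumulative_score(
    panel: LifestylePanel, min_phases: int = 4, persistent_smoker_phases: int = 3
) -> pd.DataFrame:
    """Continuous cumulative lifestyle measures.

    Per phase, the composite sums a z-scored MVPA term, a z-scored
    negated alcohol term (so healthier is higher) and the binary
    never-smoker point, each weighted equally; the composite is then
    averaged over the subject's observed phases. Also returned:

    * ``persistent_smoker`` — 1 if the subject reported "current" smoker
      at ``persistent_smoker_phases`` or more phases,
    * ``mean_alcohol_units`` — mean weekly units over observed phases.

    Subjects with fewer than ``min_phases`` fully observed phases are
    dropped.
    """
    rec = score_panel(panel)
    obs = rec[rec["index_score"].notna()].copy()

    def _phase_z(col: pd.Series) -> pd.Series:
        g = obs.groupby("phase")[col.name]
        mu = g.transform("mean")
        sd = g.transform(lambda s: s.std(ddof=1))
        sd = sd.replace(0, np.nan)
        return ((col - mu) / sd).fillna(0.0)

    obs["z_mvpa"] = _phase_z(obs["mvpa_hours"])
    obs["z_alcohol_neg"] = -_phase_z(obs["alcohol_units"])
    obs["never_point"] = (obs["smoker_status"] == "never").astype(float)
    obs["composite"] = obs["z_mvpa"] + obs["z_alcohol_neg"] + obs["never_point"]

    g = obs.groupby("subject_id")
    n_obs = g.size()
    kept = n_obs.index[n_obs >= min_phases]
    out = pd.DataFrame(
        {
            "continuous_cumulative": g["composite"].mean(),
            "persistent_smoker": (
                g["smoker_status"].apply(lambda s: (s == "current").sum())
                >= persistent_smoker_phases
            ).astype(int),
            "mean_alcohol_units": g["alcohol_units"].mean(),
        }
    ).loc[kept]
    return out
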