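"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure of an aging-cohort MRI substudy:
brain-structural features that track chronological age strongly,
cognitive features that track it weakly, confound structure (scanner,
head motion, intracranial volume), a reserve covariate (premorbid IQ)
that shifts the cognitive age gap but not the brain age gap, and
longitudinal lifestyle panels drawn from planted polynomial trajectory
classes with missing phases.

The generative model for feature ``j`` of a modality with signal
fraction ``s`` and confound fraction ``c`` is::

    feature_ij = sqrt(s) * sign_j * z(latent_i) + sqrt(c) * z(conf_ij)
                 + sqrt(1 - s - c) * eps_ij

where ``latent_i = age_i + gap_i`` and the per-subject gap (years) is
the planted deviation from normative aging. The gap itself carries the
planted effects: the reserve covariate loads on the cognitive gap only,
and (optionally) the lifestyle trajectory latent loads on the brain gap.
The ``truth`` table records gaps and class memberships for oracle use in
tests; analysis stages never read it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .lifestyle import LifestylePanel
from .prep import FeatureMatrix

__all__ = [
    "ClassSpec",
    "CohortConfig",
    "SyntheticCohort",
    "ConfigError",
    "generate_cohort",
    "generate_lifestyle_panel",
    "PHASE_MEAN_AGES",
]

#: Mean age (years) at each of the five study phases; the trajectory
#: time metric is (age - 53) / 10 -> [0, 0.3, 1.1, 1.5, 1.7].
PHASE_MEAN_AGES = (53.0, 56.0, 64.0, 68.0, 70.0)


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the field."""


@dataclass(frozen=True)
class ClassSpec:
    """One lifestyle trajectory class.

    ``coefficients`` are (intercept, slope, quadratic) on the transformed
    time metric, on the standardized-index scale.
    """

    weight: float
    coefficients: tuple[float, float, float]

    def curve(self, t: np.ndarray) -> np.ndarray:
        b0, b1, b2 = self.coefficients
        return b0 + b1 * t + b2 * t**2


#: Default trajectory classes: low-but-improving, high-but-declining,
#: moderate-and-consistent, with mixing proportions mirroring the
#: observed three-class solution (41.2 / 24.2 / 34.6 %).
DEFAULT_CLASS_SPECS = (
    ClassSpec(0.412, (-1.3, 0.7, -0.10)),
    ClassSpec(0.242, (1.3, 0.1, -0.35)),
    ClassSpec(0.346, (0.0, 0.0, 0.0)),
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Signal fractions are the per-feature share of variance explained by
    the latent (age + gap) signal; gap SDs (years) set the ceiling on
    achievable age-prediction accuracy. Defaults emulate a cohort of 537
    subjects aged 60-83 whose brain features support out-of-fold R²
    around 0.4 and cognitive features around 0.1.
    """

    n_subjects: int = 537
    age_range: tuple[float, float] = (60.34, 82.76)
    age_mean: float = 69.75
    age_sd: float = 5.08
    n_brain_features: int = 100
    n_cognitive_features: int = 20
    brain_signal_fraction: float = 0.20
    cognitive_signal_fraction: float = 0.05
    confound_fraction: float = 0.10
    brain_gap_sd: float = 4.0
    cognitive_gap_sd: float = 8.0
    reserve_effect: float = -0.3
    lifestyle_effect_brain: float = 0.0
    n_phases: int = 5
    phase_mean_ages: tuple[float, ...] = PHASE_MEAN_AGES
    class_specs: tuple[ClassSpec, ...] = DEFAULT_CLASS_SPECS
    trajectory_noise_sd: float = 0.35
    phase_missing_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ConfigError("n_subjects must be >= 10")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range min must be < max")
        for name in ("brain_signal_fraction", "cognitive_signal_fraction", "confound_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.brain_signal_fraction + self.confound_fraction > 1.0:
            raise ConfigError("brain_signal_fraction + confound_fraction must be <= 1")
        if self.cognitive_signal_fraction + self.confound_fraction > 1.0:
            raise ConfigError("cognitive_signal_fraction + confound_fraction must be <= 1")
        for name in ("reserve_effect", "lifestyle_effect_brain"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [-1, 1]")
        if self.n_phases < 2:
            raise ConfigError("n_phases must be >= 2")
        if len(self.phase_mean_ages) < self.n_phases:
            raise ConfigError("phase_mean_ages must cover n_phases")
        if not self.class_specs:
            raise ConfigError("class_specs must be non-empty")
        w = sum(c.weight for c in self.class_specs)
        if abs(w - 1.0) > 1e-8:
            raise ConfigError(f"class_specs weights must sum to 1 (got {w})")
        if any(c.weight <= 0 for c in self.class_specs):
            raise ConfigError("class_specs weights must be positive")
        if not 0.0 <= self.phase_missing_rate <= 1.0:
            raise ConfigError("phase_missing_rate must lie in [0, 1]")
        if self.trajectory_noise_sd < 0:
            raise ConfigError("trajectory_noise_sd must be >= 0")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["phase_mean_ages"] = list(self.phase_mean_ages)
        d["class_specs"] = [
            {"weight": c.weight, "coefficients": list(c.coefficients)} for c in self.class_specs
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "phase_mean_ages" in d:
            d["phase_mean_ages"] = tuple(d["phase_mean_ages"])
        if "class_specs" in d:
            d["class_specs"] = tuple(
                ClassSpec(c["weight"], tuple(c["coefficients"])) for c in d["class_specs"]
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(d)


@dataclass
class SyntheticCohort:
    """Generated tables sharing one subject-id set, plus planted truth."""

    covariates: pd.DataFrame
    brain_features: FeatureMatrix
    cognitive_features: FeatureMatrix
    lifestyle_panel: LifestylePanel
    truth: pd.DataFrame
    config: CohortConfig

    @property
    def subject_ids(self) -> pd.Index:
        return self.covariates.index

    def write(self, directory: str | Path, sep: str = "\t") -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cov = self.covariates.copy()
        cov.insert(0, "subject_id", cov.index)
        cov.to_csv(d / "covariates.tsv", sep=sep, index=False)
        self.brain_features.to_tsv(d / "brain_features.tsv", sep=sep)
        self.cognitive_features.to_tsv(d / "cognitive_features.tsv", sep=sep)
        self.lifestyle_panel.to_tsv(d / "lifestyle.tsv", sep=sep)
        truth = self.truth.copy()
        truth.insert(0, "subject_id", truth.index)
        truth.to_csv(d / "cohort.truth.tsv", sep=sep, index=False)
        self.config.to_yaml(d / "config.yaml")


def _transformed_time(config: CohortConfig) -> np.ndarray:
    ages = np.asarray(config.phase_mean_ages[: config.n_phases], dtype=float)
    return (ages - 53.0) / 10.0


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_lifestyle_panel(
    config: CohortConfig,
    class_assignments: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[LifestylePanel, np.ndarray]:
    """Draw per-phase behaviors from the planted trajectory classes.

    Each subject's latent index level at phase ``j`` is the class
    polynomial at the transformed time score plus independent noise; the
    latent is quantized to the 0-3 index and raw behaviors (alcohol
    units/week, smoker status, MVPA hours/week) are constructed so the
    scoring rules recover exactly that index. With positive
    ``phase_missing_rate`` a matching share of subjects lacks exactly one
    pre-final phase.

    Returns the panel and the per-subject mean latent level (the
    lifestyle exposure used for planted brain-gap effects).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    class_assignments = np.asarray(class_assignments)
    K = len(config.class_specs)
    if class_assignments.min() < 0 or class_assignments.max() >= K:
        raise ValueError(f"class assignment outside 0..{K - 1}")
    n = len(class_assignments)
    t = _transformed_time(config)
    curves = np.stack([c.curve(t) for c in config.class_specs])  # K x phases
    latent = curves[class_assignments] + rng.normal(
        0.0, config.trajectory_noise_sd, size=(n, config.n_phases)
    )
    latent_mean = latent.mean(axis=1)
    # quantize the standardized-scale latent to the 0-3 index
    idx = np.clip(np.rint(1.5 + latent), 0, 3).astype(int)

    # per-subject behavior priority: which behaviors earn the points
    # (fixed across phases so smoker status is stable within subject)
    priorities = np.argsort(rng.random((n, 3)), axis=1)  # columns: alc, smoke, act ranks
    nonnever = rng.choice(["ex", "current"], size=n)

    rows = []
    missing_mask = rng.random(n) < config.phase_missing_rate
    drop_phase = rng.integers(0, config.n_phases - 1, size=n)
    for i in range(n):
        rank = priorities[i]  # rank[b] = priority position of behavior b
        for j in range(config.n_phases):
            if missing_mask[i] and j == drop_phase[i]:
                continue
            k = idx[i, j]
            pts = rank < k  # behaviors 0=alcohol, 1=smoking, 2=activity
            alcohol = rng.uniform(0.0, 7.0) if pts[0] else rng.uniform(8.0, 30.0)
            smoker = "never" if pts[1] else nonnever[i]
            mvpa = rng.uniform(2.5, 10.0) if pts[2] else rng.uniform(0.0, 2.4)
            rows.append((f"S{i:05d}", j, alcohol, smoker, mvpa))
    records = pd.DataFrame(
        rows, columns=["subject_id", "phase", "alcohol_units", "smoker_status", "mvpa_hours"]
    )
    return LifestylePanel(records), latent_mean


def _feature_block(
    rng: np.random.Generator,
    z_latent: np.ndarray,
    confounds: np.ndarray | None,
    n_features: int,
    signal_fraction: float,
    confound_fraction: float,
    prefix: str,
) -> pd.DataFrame:
    n = len(z_latent)
    signs = rng.choice([-1.0, 1.0], size=n_features)
    noise_frac = max(0.0, 1.0 - signal_fraction - confound_fraction)
    cols = np.sqrt(signal_fraction) * np.outer(z_latent, signs)
    if confounds is not None and confound_fraction > 0:
        w = rng.normal(size=(confounds.shape[1], n_features))
        conf = confounds @ w
        conf = (conf - conf.mean(0)) / conf.std(0, ddof=1)
        cols = cols + np.sqrt(confound_fraction) * conf
    cols = cols + np.sqrt(noise_frac) * rng.normal(size=(n, n_features))
    names = [f"{prefix}{j:04d}" for j in range(n_features)]
    return pd.DataFrame(cols, columns=names)


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic given ``seed``).

    All randomness flows from one ``numpy`` Generator seeded by
    ``config.seed``, so identical configs yield byte-identical tables.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")

    # chronological age: truncated normal within the configured range
    lo, hi = config.age_range
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    while True:
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(config.age_mean, config.age_sd, size=bad.sum())

    sex = rng.binomial(1, 0.175, size=n)  # 1 = female
    ethnicity = rng.binomial(1, 0.054, size=n)  # 1 = non-white
    education = np.clip(rng.normal(16.75, 4.44, size=n), 7, 44)
    bmi = np.clip(rng.normal(26.5, 4.0, size=n), 16, 45)
    premorbid_iq = rng.normal(100.0, 15.0, size=n)
    scanner = rng.binomial(1, 147 / 537, size=n)  # 1 = post-upgrade scanner
    motion = rng.gamma(4.0, 0.05, size=n)  # relative head motion, mm
    icv = rng.normal(1.5e6, 1.4e5, size=n)  # intracranial volume, mm^3

    # lifestyle trajectory classes and panel
    weights = np.array([c.weight for c in config.class_specs])
    classes = rng.choice(len(weights), size=n, p=weights)
    panel, lifestyle_latent = generate_lifestyle_panel(config, classes, rng)

    # planted gaps (years): reserve loads on the cognitive gap only,
    # lifestyle exposure (optionally) on the brain gap only
    iq_z = _zscore(premorbid_iq)
    ls_z = _zscore(lifestyle_latent)
    re, le = config.reserve_effect, config.lifestyle_effect_brain
    gap_brain = config.brain_gap_sd * (
        le * ls_z + np.sqrt(1.0 - le**2) * rng.normal(size=n)
    )
    gap_cog = config.cognitive_gap_sd * (
        re * iq_z + np.sqrt(1.0 - re**2) * rng.normal(size=n)
    )

    conf_mat = np.column_stack(
        [scanner, _zscore(motion), sex, ethnicity, _zscore(icv)]
    ).astype(float)
    brain = _feature_block(
        rng,
        _zscore(age + gap_brain),
        conf_mat,
        config.n_brain_features,
        config.brain_signal_fraction,
        config.confound_fraction,
        "gm",
    )
    cog = _feature_block(
        rng,
        _zscore(age + gap_cog),
        None,
        config.n_cognitive_features,
        config.cognitive_signal_fraction,
        0.0,
        "cog",
    )
    brain.index = ids
    cog.index = ids

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "education": education,
            "bmi": bmi,
            "premorbid_iq": premorbid_iq,
            "scanner": scanner,
            "motion": motion,
            "icv": icv,
        },
        index=ids,
    )
    truth = pd.DataFrame(
        {
            "brain_gap": gap_brain,
            "cognitive_gap": gap_cog,
            "lifestyle_class": classes,
            "lifestyle_latent": lifestyle_latent,
        },
        index=ids,
    )
    n_gm = config.n_brain_features // 2 + config.n_brain_features % 2
    modality = pd.Series(
        ["gray-matter"] * n_gm + ["white-matter"] * (config.n_brain_features - n_gm),
        index=brain.columns,
    )
    return SyntheticCohort(
        covariates=covariates,
        brain_features=FeatureMatrix(brain, modality),
        cognitive_features=FeatureMatrix(cog, "cognitive"),
        lifestyle_panel=panel,
        truth=truth,
        config=config,
    )


def load_cohort(directory: str | Path, sep: str = "\t") -> SyntheticCohort:
    """Read a cohort previously written with :meth:`SyntheticCohort.write`."""
    d = Path(directory)
    config = CohortConfig.from_yaml(d / "config.yaml")
    cov = pd.read_csv(d / "covariates.tsv", sep=sep).set_index("subject_id")
    truth = pd.read_csv(d / "cohort.truth.tsv", sep=sep).set_index("subject_id")
    brain = FeatureMatrix.from_tsv(d / "brain_features.tsv", sep=sep)
    n_gm = config.n_brain_features // 2 + config.n_brain_features % 2
    brain.modality = pd.Series(
        ["gray-matter"] * n_gm + ["white-matter"] * (config.n_brain_features - n_gm),
        index=brain.values.columns,
    )
    cog = FeatureMatrix.from_tsv(d / "cognitive_features.tsv", sep=sep, modality="cognitive")
    panel = LifestylePanel.from_tsv(d / "lifestyle.tsv", sep=sep)
    return SyntheticCohort(cov, brain, cog, panel, truth, config)
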