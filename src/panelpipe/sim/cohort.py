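"""Synthetic clinical cohort generator.

Each patient carries demographics (age, sex), tumor grade and location,
two immunostaining scores on the 0-3 scale, a proliferation group, and
survival/recurrence outcomes.  The probability of high staining (score
2-3) follows a logistic model in grade, cerebral location, and pediatric
age with configurable odds ratios; survival times follow an exponential
proportional-hazards model whose hazard depends on the staining group,
with administrative censoring at a fixed horizon.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ..errors import ConfigError

GRADES: Tuple[str, ...] = ("I", "II", "III")
LOCATIONS: Tuple[str, ...] = ("spinal", "cerebellar", "cerebral")

COHORT_COLUMNS = [
    "patient_id", "age_years", "pediatric", "sex", "grade", "location",
    "fgfr1_score", "fgfr3_score", "proliferation_group",
    "followup_months", "death", "recurrence", "primary_tumor",
]


@dataclass
class CohortConfig:
    n_patients: int = 108
    grade_probs: Tuple[float, float, float] = (0.17, 0.63, 0.20)
    location_probs: Tuple[float, float, float] = (0.40, 0.26, 0.34)
    age_mean: float = 35.0
    age_sd: float = 21.0
    age_min: float = 1.0
    age_max: float = 75.0
    male_prob: float = 0.55
    pediatric_cutoff: float = 16.0

    # logistic model for P(staining high); applied independently to the
    # two markers
    p_high_baseline: float = 0.15     # P(high) at grade I, non-cerebral, adult
    or_grade: float = 1.0             # odds ratio per grade step
    or_cerebral: float = 1.0          # cerebral vs other locations
    or_pediatric: float = 1.0         # pediatric vs adult

    # survival model: exponential baseline, multiplicative hazard for the
    # staining-high group, administrative censoring at the horizon
    baseline_hazard: float = 0.006    # events per month
    hazard_ratio: float = 1.82        # staining-high vs staining-low
    censor_horizon: float = 240.0     # months
    recurrence_hazard: float = 0.010
    recurrence_hazard_ratio: float = 1.82

    prolif_tertiles: Tuple[float, float] = (1 / 3, 2 / 3)
    missing_score_rate: float = 0.0

    def validate(self) -> None:
        for name, probs in (("grade_probs", self.grade_probs),
                            ("location_probs", self.location_probs)):
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"{name} must be 3 non-negative values summing to 1")
        for name, v in (("or_grade", self.or_grade), ("or_cerebral", self.or_cerebral),
                        ("or_pediatric", self.or_pediatric),
                        ("hazard_ratio", self.hazard_ratio),
                        ("recurrence_hazard_ratio", self.recurrence_hazard_ratio),
                        ("baseline_hazard", self.baseline_hazard),
                        ("recurrence_hazard", self.recurrence_hazard)):
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if not 0 < self.p_high_baseline < 1:
            raise ConfigError("p_high_baseline must be in (0,1)")
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if not 0 <= self.missing_score_rate < 1:
            raise ConfigError("missing_score_rate must be in [0,1)")


def _scores_from_high(high: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map a boolean high/low vector to 0-3 scores (low -> {0,1}, high -> {2,3})."""
    low_score = rng.integers(0, 2, size=high.size)
    high_score = rng.integers(2, 4, size=high.size)
    return np.where(high, high_score, low_score)


def simulate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Generate a cohort table; deterministic for fixed (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_patients

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n),
                  config.age_min, config.age_max)
    pediatric = age < config.pediatric_cutoff
    sex = np.where(rng.random(n) < config.male_prob, "M", "F")
    grade_idx = rng.choice(3, size=n, p=config.grade_probs)
    loc_idx = rng.choice(3, size=n, p=config.location_probs)
    cerebral = loc_idx == 2

    lin = (logit(config.p_high_baseline)
           + np.log(config.or_grade) * grade_idx
           + np.log(config.or_cerebral) * cerebral
           + np.log(config.or_pediatric) * pediatric)
    p_high = expit(lin)
    fgfr3_high = rng.random(n) < p_high
    fgfr1_high = rng.random(n) < p_high
    fgfr3_score = _scores_from_high(fgfr3_high, rng).astype(float)
    fgfr1_score = _scores_from_high(fgfr1_high, rng).astype(float)
    if config.missing_score_rate > 0:
        fgfr3_score[rng.random(n) < config.missing_score_rate] = np.nan
        fgfr1_score[rng.random(n) < config.missing_score_rate] = np.nan

    prolif_latent = rng.random(n)
    prolif_group = np.searchsorted(np.asarray(config.prolif_tertiles), prolif_latent) + 1

    hazard = config.baseline_hazard * np.where(fgfr3_high, config.hazard_ratio, 1.0)
    t_death = rng.exponential(1.0 / hazard)
    death = t_death <= config.censor_horizon
    followup = np.minimum(t_death, config.censor_horizon)

    rhaz = config.recurrence_hazard * np.where(fgfr3_high, config.recurrence_hazard_ratio, 1.0)
    t_rec = rng.exponential(1.0 / rhaz)
    recurrence = t_rec <= followup

    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "age_years": np.round(age, 1),
        "pediatric": pediatric,
        "sex": sex,
        "grade": [GRADES[i] for i in grade_idx],
        "location": [LOCATIONS[i] for i in loc_idx],
        "fgfr1_score": pd.array(
            [int(s) if np.isfinite(s) else None for s in fgfr1_score], dtype="Int64"),
        "fgfr3_score": pd.array(
            [int(s) if np.isfinite(s) else None for s in fgfr3_score], dtype="Int64"),
        "proliferation_group": prolif_group.astype(int),
        "followup_months": np.round(followup, 2),
        "death": death.astype(int),
        "recurrence": recurrence.astype(int),
        "primary_tumor": np.ones(n, dtype=int),
    })
    return df
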