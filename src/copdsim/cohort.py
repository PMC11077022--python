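"""Simulated population: initial cohort construction and incident COPD cases.

The cohort is stored struct-of-arrays (one numpy array per person attribute)
so the cycle engine can update a hundred thousand people with vectorized
operations.  A row-per-person pandas/CSV snapshot is provided for debugging
and regression fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .parameters import ParameterSet, age_band_index, annual_rate_to_cycle_prob
from . import natural_history as nh

__all__ = ["Cohort", "generate_cohort", "sample_incident_cases", "predicted_fev1",
           "truncated_normal_ppf", "SEX_CODES"]

SEX_CODES = {"male": 0, "female": 1}
SEX_NAMES = {v: k for k, v in SEX_CODES.items()}

#: person-attribute columns in snapshot order
COLUMNS = ("id", "sex", "age", "has_copd", "fev1_pct", "stage", "diagnosed",
           "treatment", "months_since_exac", "months_on_treatment", "care_stage",
           "ever_screened", "alive", "death_cause")

#: death_cause codes
CAUSE_NONE, CAUSE_BACKGROUND, CAUSE_COPD = 0, 1, 2


@dataclass
class Cohort:
    """A simulated closed population (struct-of-arrays).

    ``care_stage`` records the GOLD stage at which treatment uptake/choice was
    last evaluated (-1 if never); the engine uses it to re-evaluate care when
    a patient's stage changes.  ``months_since_exac`` is ``inf`` for persons
    with no exacerbation history.
    """

    id: np.ndarray
    sex: np.ndarray          # 0 male, 1 female
    age: np.ndarray          # years
    has_copd: np.ndarray     # bool
    fev1_pct: np.ndarray     # fraction of predicted FEV1
    stage: np.ndarray        # 0 = no COPD, 1-4 GOLD
    diagnosed: np.ndarray    # bool
    treatment: np.ndarray    # archetype index, -1 = none
    months_since_exac: np.ndarray
    months_on_treatment: np.ndarray
    care_stage: np.ndarray
    ever_screened: np.ndarray  # bool, drives one-time program setup cost
    alive: np.ndarray        # bool
    death_cause: np.ndarray  # 0 none, 1 background, 2 copd-attributed
    creation_seed: int = 0
    parameters_hash: str = ""

    def __len__(self) -> int:
        return self.id.size

    def copy(self) -> "Cohort":
        kw = {c: getattr(self, c).copy() for c in COLUMNS}
        return Cohort(**kw, creation_seed=self.creation_seed,
                      parameters_hash=self.parameters_hash)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in COLUMNS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, creation_seed: int = 0,
                   parameters_hash: str = "") -> "Cohort":
        kw = {}
        dtypes = dict(id=np.int64, sex=np.int8, age=float, has_copd=bool,
                      fev1_pct=float, stage=np.int8, diagnosed=bool,
                      treatment=np.int8, months_since_exac=float,
                      months_on_treatment=float, care_stage=np.int8,
                      ever_screened=bool, alive=bool, death_cause=np.int8)
        for c in COLUMNS:
            kw[c] = np.asarray(df[c], dtype=dtypes[c])
        return cls(**kw, creation_seed=creation_seed, parameters_hash=parameters_hash)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))


def truncated_normal_ppf(u, mean, sd, lo, hi):
    """Inverse CDF of a normal truncated to [lo, hi] (vectorized).

    Used instead of rejection sampling so that a common uniform draw maps to
    the same quantile across policy arms and parameter sets.
    """
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def predicted_fev1(sex, age, params: ParameterSet):
    """Reference (predicted) FEV1 in liters for a healthy person.

    Linear-in-age reference per sex: ``value_at_35 - slope * (age - 35)``.
    Only the *ratio* fev1/predicted drives disease dynamics; the reference
    fixture sets the liters scale.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any((age_arr < 35.0) | (age_arr > 110.0)):
        raise ValueError("age outside the supported range [35, 110]")
    if isinstance(sex, str):
        sex_idx = np.asarray(SEX_CODES[sex])
    else:
        sex_idx = np.asarray(sex)
    at35 = np.array([params.predicted_fev1_ref["male"][0],
                     params.predicted_fev1_ref["female"][0]])
    slope = np.array([params.predicted_fev1_ref["male"][1],
                      params.predicted_fev1_ref["female"][1]])
    out = at35[sex_idx] - slope[sex_idx] * (age_arr - 35.0)
    return float(out) if out.ndim == 0 else out


def _assign_initial_treatment(stage, diagnosed, params, u_uptake, u_choice):
    """Treatment uptake/choice for diagnosed prevalent cases (30% rule)."""
    n = stage.size
    treatment = np.full(n, -1, dtype=np.int8)
    care_stage = np.full(n, -1, dtype=np.int8)
    care_stage[diagnosed] = stage[diagnosed]
    takers = diagnosed & (u_uptake < params.p_treat_uptake)
    if np.any(takers):
        mix = np.asarray(params.treat_mix, dtype=float)  # [stage, archetype]
        cum = np.cumsum(mix, axis=1)
        rows = cum[stage[takers] - 1]
        treatment[takers] = (u_choice[takers, None] >= rows).sum(axis=1).astype(np.int8)
    return treatment, care_stage


def generate_cohort(n: int, params: ParameterSet, seed: int) -> Cohort:
    """Build the initial population of ``n`` individuals aged 35-80.

    Ages/sexes follow the configured band weights (uniform within band);
    COPD is assigned from age/sex prevalence; prevalent cases draw FEV1%
    predicted from the initial truncated normal, are staged by the GOLD map,
    and are diagnosed with the stage-specific initial awareness probability.
    Diagnosed prevalent cases receive a treatment-uptake draw.
    """
    if n < 0:
        raise ValueError("cohort size must be >= 0")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    lo_age, hi_age = params.age_range

    band = rng.choice(len(params.age_band_weights), size=n,
                      p=np.asarray(params.age_band_weights) / np.sum(params.age_band_weights))
    from .parameters import AGE_BANDS
    band_lo = np.array([b[0] for b in AGE_BANDS], dtype=float)
    band_hi = np.array([b[1] + 1 for b in AGE_BANDS], dtype=float)
    band_hi[-1] = hi_age + 1.0
    age = band_lo[band] + rng.random(n) * (band_hi[band] - band_lo[band])
    np.clip(age, lo_age, hi_age + 0.999, out=age)

    male_frac = np.asarray(params.male_fraction, dtype=float)
    sex = (rng.random(n) >= male_frac[band]).astype(np.int8)  # 0 male, 1 female

    prev = np.array([params.prevalence["male"], params.prevalence["female"]])
    has_copd = rng.random(n) < prev[sex, band]

    fev1_pct = np.full(n, 1.0)
    lo_b, hi_b = params.fev1pct_bounds
    for s in (0, 1):
        m = has_copd & (sex == s)
        if np.any(m):
            mean, sd = params.fev1pct_initial[SEX_NAMES[s]]
            fev1_pct[m] = truncated_normal_ppf(rng.random(m.sum()), mean, sd, lo_b, hi_b)

    stage = np.zeros(n, dtype=np.int8)
    stage[has_copd] = nh.gold_stage(fev1_pct[has_copd])

    diagnosed = np.zeros(n, dtype=bool)
    init_dx = np.asarray(params.initial_diagnosed, dtype=float)
    m = has_copd
    diagnosed[m] = rng.random(m.sum()) < init_dx[stage[m] - 1]

    treatment, care_stage = _assign_initial_treatment(
        stage, diagnosed, params, rng.random(n), rng.random(n))

    return Cohort(
        id=np.arange(n, dtype=np.int64),
        sex=sex,
        age=age,
        has_copd=has_copd,
        fev1_pct=fev1_pct,
        stage=stage,
        diagnosed=diagnosed,
        treatment=treatment,
        months_since_exac=np.full(n, np.inf),
        months_on_treatment=np.zeros(n),
        care_stage=care_stage,
        ever_screened=np.zeros(n, dtype=bool),
        alive=np.ones(n, dtype=bool),
        death_cause=np.zeros(n, dtype=np.int8),
        creation_seed=int(seed),
        parameters_hash=params.digest(),
    )


def incident_conversion_mask(sex, age, eligible, u, params: ParameterSet):
    """Which eligible non-COPD persons convert this cycle (common-uniform rule)."""
    inc = np.array([params.incidence["male"], params.incidence["female"]])
    band = age_band_index(age)
    p = annual_rate_to_cycle_prob(inc[sex, band], params.cycle_years)
    return eligible & (u < p)


def apply_incident_state(cohort: Cohort, converts: np.ndarray, u_fev1: np.ndarray,
                         params: ParameterSet) -> None:
    """Set disease state for persons converting to COPD (in place)."""
    if not np.any(converts):
        return
    lo_b, hi_b = params.fev1pct_bounds
    for s in (0, 1):
        m = converts & (cohort.sex == s)
        if np.any(m):
            mean, sd = params.fev1pct_incident[SEX_NAMES[s]]
            cohort.fev1_pct[m] = truncated_normal_ppf(u_fev1[m], mean, sd, lo_b, hi_b)
    cohort.has_copd[converts] = True
    cohort.stage[converts] = nh.gold_stage(cohort.fev1_pct[converts])
    cohort.diagnosed[converts] = False


def sample_incident_cases(cohort: Cohort, params: ParameterSet, rng) -> np.ndarray:
    """One cycle of COPD incidence among living non-COPD persons.

    Converts each eligible person with probability
    ``1 - exp(-incidence[sex, band] * cycle_years)``, assigns incident disease
    state in place, and returns the ids of the converts.
    """
    eligible = cohort.alive & ~cohort.has_copd
    u = rng.random(len(cohort))
    converts = incident_conversion_mask(cohort.sex, cohort.age, eligible, u, params)
    apply_incident_state(cohort, converts, rng.random(len(cohort)), params)
    return cohort.id[converts]
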