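"""Disease progression: GOLD staging, FEV1 decline, exacerbations, mortality.

All sampling functions come in two flavours sharing one computational core:
a deterministic kernel taking pre-drawn quantile inputs (used by the cycle
engine, where uniforms are drawn from named common-random-number streams),
and a convenience wrapper drawing from a numpy ``Generator``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import poisson

from .parameters import ParameterSet, annual_prob_to_hazard

__all__ = [
    "gold_stage", "sample_cycle_decline", "cycle_decline_ml",
    "sample_exacerbations", "exacerbation_counts",
    "sample_death", "death_event", "background_mortality_q",
]

_STAGE_EDGES = np.array([0.30, 0.50, 0.80])


def gold_stage(fev1_pct):
    """GOLD severity stage from FEV1 % predicted.

    >= 80% -> 1 (mild); 50-79% -> 2; 30-49% -> 3; < 30% -> 4 (very severe).
    Applies only to persons with COPD; negative input is rejected.
    """
    v = np.asarray(fev1_pct, dtype=float)
    if np.any(v < 0):
        raise ValueError("fev1_pct must be >= 0")
    stage = (4 - np.searchsorted(_STAGE_EDGES, v, side="right")).astype(np.int8)
    return int(stage) if stage.ndim == 0 else stage


def cycle_decline_ml(stage, recent_exac, treatment_reduction, z, params: ParameterSet):
    """FEV1 lost this cycle (ml), given standard-normal quantile(s) ``z``.

    The annual decline is drawn from the stage-specific normal (negative
    draws floored at zero), multiplied by the exacerbation factor if an
    exacerbation occurred within the effect window, reduced by the absolute
    treatment effect, floored at zero, and scaled to the cycle length.
    """
    stage = np.asarray(stage)
    mu = np.array([m for m, _ in params.decline])[stage - 1]
    sd = np.array([s for _, s in params.decline])[stage - 1]
    annual = np.maximum(mu + sd * np.asarray(z, dtype=float), 0.0)
    annual = np.where(recent_exac, annual * params.exac_decline_multiplier, annual)
    annual = np.maximum(annual - np.asarray(treatment_reduction, dtype=float), 0.0)
    out = annual * params.cycle_years
    return float(out) if out.ndim == 0 else out


def sample_cycle_decline(stage, recent_exac, treatment_reduction, params, rng):
    """Draw this cycle's FEV1 loss (ml) from a ``Generator``."""
    z = rng.standard_normal(np.shape(np.asarray(stage)) or None)
    return cycle_decline_ml(stage, recent_exac, treatment_reduction, z, params)


def exacerbation_counts(stage, rr_exac, u_nonsevere, u_severe, params: ParameterSet):
    """Per-cycle exacerbation counts via Poisson inverse-CDF on common uniforms.

    Counts for the two severities are independent Poisson with mean
    ``annual_rate[stage] * rr_exac * cycle_years``.  Using the inverse CDF on
    a per-person uniform keeps the draw coupled across policy arms that only
    differ in the treated relative risk.
    """
    stage = np.asarray(stage)
    rr = np.asarray(rr_exac, dtype=float)
    lam_ns = np.asarray(params.exac_rate_nonsevere)[stage - 1] * rr * params.cycle_years
    lam_sev = np.asarray(params.exac_rate_severe)[stage - 1] * rr * params.cycle_years
    n_ns = poisson.ppf(np.asarray(u_nonsevere, dtype=float), lam_ns)
    n_sev = poisson.ppf(np.asarray(u_severe, dtype=float), lam_sev)
    n_ns = np.maximum(np.nan_to_num(n_ns), 0.0).astype(np.int64)
    n_sev = np.maximum(np.nan_to_num(n_sev), 0.0).astype(np.int64)
    if n_ns.ndim == 0:
        return int(n_ns), int(n_sev)
    return n_ns, n_sev


def sample_exacerbations(stage, rr_exac, params, rng):
    """Draw (n_nonsevere, n_severe) for one cycle from a ``Generator``."""
    shape = np.shape(np.asarray(stage))
    u1 = rng.random(shape or None)
    u2 = rng.random(shape or None)
    return exacerbation_counts(stage, rr_exac, u1, u2, params)


def background_mortality_q(sex, age, params: ParameterSet):
    """Annual background death probability from the life table.

    Ages beyond the table use the terminal row (the packaged fixture drives
    the probability high by age 100 so the lifetime horizon terminates).
    """
    table = np.array([params.life_table["male"], params.life_table["female"]])
    idx = np.clip(np.asarray(age, dtype=np.int64) - params.life_table_start_age,
                  0, table.shape[1] - 1)
    out = table[np.asarray(sex), idx]
    return float(out) if out.ndim == 0 else out


def death_event(sex, age, stage, rr_mort, u_death, u_cause, params: ParameterSet):
    """Death outcome for one cycle given common uniforms.

    Background annual probability ``q`` gives hazard ``h = -ln(1-q)``; COPD
    persons (stage >= 1) face hazard ``h * HR[stage] * rr_mort``.  Deaths of
    COPD persons are labelled copd-attributed with the excess-hazard fraction
    ``(HR*rr - 1)/(HR*rr)``, else background.  Persons at or beyond the
    maximum age die with certainty (background).

    Returns ``(died, copd_attributed)`` boolean arrays (or scalars).
    """
    sex = np.asarray(sex)
    age_arr = np.asarray(age, dtype=float)
    stage = np.asarray(stage)
    q = background_mortality_q(sex, age_arr, params)
    h = annual_prob_to_hazard(q)
    hr = np.asarray(params.mortality_hr)[np.maximum(stage, 1) - 1]
    mult = np.where(stage >= 1, hr * np.asarray(rr_mort, dtype=float), 1.0)
    p_die = -np.expm1(-h * mult * params.cycle_years)
    p_die = np.where(age_arr >= params.max_age, 1.0, p_die)
    died = np.asarray(u_death, dtype=float) < p_die
    attr_frac = np.where(mult > 1.0, (mult - 1.0) / mult, 0.0)
    attr_frac = np.where(age_arr >= params.max_age, 0.0, attr_frac)
    copd_attr = died & (stage >= 1) & (np.asarray(u_cause, dtype=float) < attr_frac)
    if np.asarray(died).ndim == 0:
        return bool(died), bool(copd_attr)
    return died, copd_attr


def sample_death(sex, age, stage, rr_mort, params, rng):
    """Draw the death outcome for one cycle from a ``Generator``."""
    shape = np.shape(np.asarray(age))
    u1 = rng.random(shape or None)
    u2 = rng.random(shape or None)
    return death_event(sex, age, stage, rr_mort, u1, u2, params)
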