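"""Per-cycle utility weights, cost accrual, and discounting.

Utilities: the general population carries an age-band baseline weight; COPD
patients carry a stage-specific value, either as printed absolute utilities
or (default) as multipliers on the age baseline normalized so the reference
age band reproduces the printed absolute values.  Exacerbations subtract an
absolute per-event decrement from the cycle's weight.

Costs (payer perspective, 2022 USD) fall into six fixed categories:
screening, diagnosis, maintenance, treatment, exacerbation, complication.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet, utility_band_index, discount_factor

__all__ = ["COST_CATEGORIES", "stage_utility", "cycle_utility", "cycle_cost",
           "accumulate_discounted"]

COST_CATEGORIES = ("screening", "diagnosis", "maintenance", "treatment",
                   "exacerbation", "complication")

_MONTHS_PER_CYCLE_FACTOR = 12.0  # months per year; cycle months = cycle_years * 12


def stage_utility(stage, age, params: ParameterSet):
    """Utility weight for a COPD patient before event decrements.

    In multiplier mode the stage multiplier is the printed absolute value
    divided by the reference band's baseline, applied to the person's own
    age-band baseline; in absolute mode the printed value is used directly.
    """
    base = np.asarray(params.utility_baseline)[utility_band_index(age)]
    su = np.asarray(params.utility_stage)[np.maximum(np.asarray(stage), 1) - 1]
    if params.utility_stage_is_multiplier:
        ref = params.utility_baseline[params.utility_reference_band]
        return base * (su / ref)
    return su * np.ones_like(base)


def cycle_utility(stage, age, n_nonsevere, n_severe, params: ParameterSet):
    """QALY weight for one cycle (years of perfect health per year lived).

    Non-COPD persons (stage 0) carry the age-band baseline; COPD patients the
    stage-adjusted value; each exacerbation subtracts its per-event
    decrement.  Floored at zero.
    """
    stage = np.asarray(stage)
    base = np.asarray(params.utility_baseline)[utility_band_index(age)]
    w = np.where(stage >= 1, stage_utility(stage, age, params), base)
    w = w - (params.disutility_exac_nonsevere * np.asarray(n_nonsevere)
             + params.disutility_exac_severe * np.asarray(n_severe))
    out = np.maximum(w, 0.0)
    return float(out) if out.ndim == 0 else out


def cycle_cost(stage, diagnosed, has_copd, treatment, n_nonsevere, n_severe,
               screening_charge, diagnosis_charge, params: ParameterSet,
               occupancy=1.0) -> dict:
    """Per-person cost by category for one cycle (USD).

    ``occupancy`` scales time-based costs (maintenance, treatment,
    complication) for persons present only part of the cycle (0.5 for deaths
    within the cycle).  Event costs (exacerbations) and the screening /
    diagnosis charges passed through from the cascade are not scaled.
    Maintenance accrues for all prevalent cases, or only the diagnosed if
    ``params.maintenance_diagnosed_only``.
    """
    if np.any(np.asarray(screening_charge) < 0) or np.any(np.asarray(diagnosis_charge) < 0):
        raise ValueError("screening/diagnosis charges must be >= 0")
    stage = np.asarray(stage)
    months = params.cycle_years * _MONTHS_PER_CYCLE_FACTOR
    sidx = np.maximum(stage, 1) - 1
    copd = np.asarray(has_copd, dtype=bool)
    maint_pool = copd & np.asarray(diagnosed, dtype=bool) if params.maintenance_diagnosed_only else copd
    maint = np.where(maint_pool, np.asarray(params.cost_maint_monthly)[sidx] * months, 0.0)
    compl = np.where(copd, np.asarray(params.cost_complication_monthly)[sidx] * months, 0.0)
    t = np.asarray(treatment)
    tcost = np.asarray([a.monthly_cost for a in params.treatments] + [0.0])
    treat = np.where(t >= 0, tcost[t] * months, 0.0)
    exac = (params.cost_exac_nonsevere * np.asarray(n_nonsevere)
            + params.cost_exac_severe * np.asarray(n_severe))
    occ = np.asarray(occupancy, dtype=float)
    return {
        "screening": np.asarray(screening_charge, dtype=float),
        "diagnosis": np.asarray(diagnosis_charge, dtype=float),
        "maintenance": maint * occ,
        "treatment": treat * occ,
        "exacerbation": exac,
        "complication": compl * occ,
    }


def accumulate_discounted(stream, rate: float) -> float:
    """Present value of ``(time_years, amount)`` pairs at an annual rate."""
    total = 0.0
    for t, amount in stream:
        total += amount * discount_factor(t, rate)
    return float(total)
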