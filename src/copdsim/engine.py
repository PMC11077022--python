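"""Cycle engine: runs one screening policy over a cohort with named RNG streams.

Randomness contract
-------------------
Every stochastic process (screening tests, symptom diagnosis, treatment
uptake/choice, incidence, exacerbations, FEV1 decline, death, cause
attribution) draws from its own counter-based stream keyed by
``(master_seed, cycle, process)`` and indexed by person id.  Two runs with
the same master seed therefore give person *i* identical quantile draws in
every cycle regardless of policy, so policy arms are exactly coupled
(common random numbers) and differences between arms are attributable to the
policy alone.

Within-cycle event order (a documented convention): screening -> symptom
diagnosis -> treatment (re)assignment -> incidence -> exacerbations -> FEV1
decline & restaging -> death -> discounted accrual.  A cycle's exacerbations
affect that cycle's utility, cost, and decline.  Incident cases convert
mid-cycle and accrue at their pre-conversion state until the next cycle.
Persons dying within a cycle accrue half the cycle's utility and time-based
costs.  QALYs and costs are discounted at the cycle midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import economics, natural_history as nh
from .care_cascade import ScreeningPolicy, apply_screening, evaluate_care, \
    is_screening_cycle, sample_symptom_diagnosis
from .cohort import (CAUSE_BACKGROUND, CAUSE_COPD, Cohort, apply_incident_state,
                     incident_conversion_mask, predicted_fev1)
from .economics import COST_CATEGORIES
from .parameters import ParameterSet, utility_band_index

__all__ = ["PolicyResult", "run_policy", "run_policy_set", "ConsistencyError",
           "STREAMS"]

#: named random-number streams, one per stochastic process
STREAMS = {name: i for i, name in enumerate(
    ["sq", "spiro", "followup", "symptom", "uptake", "choice", "incidence",
     "incident_fev1", "exac_nonsevere", "exac_severe", "decline", "death", "cause"])}


class ConsistencyError(ValueError):
    """Cohort was generated under a different parameter set."""


def _stream(master, cycle: int, proc: int) -> np.random.Generator:
    bitgen = np.random.Philox(np.random.SeedSequence(master, spawn_key=(cycle, proc)))
    return np.random.Generator(bitgen)


@dataclass
class PolicyResult:
    """Aggregated outcomes of one policy run on one cohort."""

    policy: str
    cohort_size: int
    seed: object
    n_cycles: int = 0
    total_qaly_discounted: float = 0.0
    total_qaly_undiscounted: float = 0.0
    qaly_copd_patients_discounted: float = 0.0
    n_exac_nonsevere: int = 0
    n_exac_severe: int = 0
    n_copd_deaths: int = 0
    n_background_deaths: int = 0
    n_screens: int = 0
    n_spiro_tests: int = 0
    n_confirm_tests: int = 0
    n_new_dx_by_screen: int = 0
    n_new_dx_by_symptom: int = 0
    cost_breakdown: dict = field(default_factory=lambda: {c: 0.0 for c in COST_CATEGORIES})
    awareness: list = field(default_factory=list)
    #: final person-level state (a Cohort), populated when run_policy is
    #: called with return_state=True; not part of to_dict()
    final_state: object = None

    @property
    def total_cost_discounted(self) -> float:
        # total cost is by construction the exact sum of the category costs
        return float(sum(self.cost_breakdown.values()))

    @property
    def n_exacerbations(self) -> int:
        return self.n_exac_nonsevere + self.n_exac_severe

    def to_dict(self) -> dict:
        d = {
            "policy": self.policy, "cohort_size": self.cohort_size,
            "seed": self.seed, "n_cycles": self.n_cycles,
            "total_qaly_discounted": self.total_qaly_discounted,
            "total_qaly_undiscounted": self.total_qaly_undiscounted,
            "total_cost_discounted": self.total_cost_discounted,
            "qaly_copd_patients_discounted": self.qaly_copd_patients_discounted,
            "n_exac_nonsevere": self.n_exac_nonsevere,
            "n_exac_severe": self.n_exac_severe,
            "n_copd_deaths": self.n_copd_deaths,
            "n_background_deaths": self.n_background_deaths,
            "n_screens": self.n_screens, "n_spiro_tests": self.n_spiro_tests,
            "n_confirm_tests": self.n_confirm_tests,
            "n_new_dx_by_screen": self.n_new_dx_by_screen,
            "n_new_dx_by_symptom": self.n_new_dx_by_symptom,
        }
        for c in COST_CATEGORIES:
            d[f"cost_{c}"] = self.cost_breakdown[c]
        return d


def run_policy(cohort: Cohort, policy: ScreeningPolicy | str, params: ParameterSet,
               seed, *, max_cycles: int | None = None,
               track_awareness: bool = False, return_state: bool = False,
               check_hash: bool = True) -> PolicyResult:
    """Simulate one policy over the cohort's remaining lifetime.

    Deterministic and exactly reproducible given ``(cohort, policy, params,
    seed)``.  ``max_cycles`` truncates the horizon (used by calibration);
    the default runs until everyone has died or reached the maximum age.
    """
    if isinstance(policy, str):
        policy = ScreeningPolicy.parse(policy)
    if check_hash and cohort.parameters_hash and cohort.parameters_hash != params.digest():
        raise ConsistencyError(
            "cohort was generated under a different parameter set; regenerate "
            "the cohort or pass check_hash=False")

    st = cohort.copy()
    n = len(st)
    res = PolicyResult(policy=str(policy), cohort_size=n, seed=seed)
    if n == 0:
        return res

    cy = params.cycle_years
    rate = params.discount_rate
    two_step = policy.method == "two_step"
    screening_on = policy.method != "none"

    # precomputed lookups
    tr_red = np.array([a.decline_reduction for a in params.treatments] + [0.0])
    tr_rre = np.array([a.rr_exac for a in params.treatments] + [1.0])
    tr_rrm = np.array([a.rr_mort for a in params.treatments] + [1.0])

    cap = int(np.ceil((params.max_age - float(np.min(st.age))) / cy)) + 2 if n else 0
    if max_cycles is not None:
        cap = min(cap, max_cycles)

    zeros = np.zeros(n)
    cycle = 0
    while cycle < cap:
        present = st.alive.copy()
        if not present.any():
            break
        t_mid = cycle * cy + cy / 2.0
        df = (1.0 + rate) ** (-t_mid)

        # --- screening -----------------------------------------------------
        scr_charge = zeros
        dx_charge = np.zeros(n)
        if screening_on and is_screening_cycle(cycle, policy.frequency, cy):
            sres = apply_screening(
                st, params, two_step,
                _stream(seed, cycle, STREAMS["sq"]).random(n),
                _stream(seed, cycle, STREAMS["spiro"]).random(n) if two_step else zeros,
                _stream(seed, cycle, STREAMS["followup"]).random(n))
            scr_charge = sres["screening_charge"]
            dx_charge = sres["diagnosis_charge"]
            res.n_screens += sres["n_screens"]
            res.n_spiro_tests += sres["n_spiro_tests"]
            res.n_confirm_tests += sres["n_confirm_tests"]
            res.n_new_dx_by_screen += sres["n_new_dx"]

        # --- symptom-based diagnosis --------------------------------------
        if any(p > 0 for p in params.p_symptom_dx):
            new_sym = sample_symptom_diagnosis(
                st, params, _stream(seed, cycle, STREAMS["symptom"]).random(n))
            n_sym = int(np.count_nonzero(new_sym))
            if n_sym:
                dx_charge = dx_charge + np.where(new_sym, params.cost_dx_spirometry, 0.0)
                res.n_confirm_tests += n_sym
                res.n_new_dx_by_symptom += n_sym

        # --- treatment (re)assignment -------------------------------------
        if np.any(st.diagnosed & st.alive & (st.care_stage != st.stage)):
            evaluate_care(st, params,
                          _stream(seed, cycle, STREAMS["uptake"]).random(n),
                          _stream(seed, cycle, STREAMS["choice"]).random(n))

        # --- incidence ------------------------------------------------------
        eligible = st.alive & ~st.has_copd
        new_copd = np.zeros(n, dtype=bool)
        if eligible.any():
            u = _stream(seed, cycle, STREAMS["incidence"]).random(n)
            new_copd = incident_conversion_mask(st.sex, st.age, eligible, u, params)
            if new_copd.any():
                apply_incident_state(
                    st, new_copd,
                    _stream(seed, cycle, STREAMS["incident_fev1"]).random(n), params)

        # --- exacerbations ---------------------------------------------------
        n_ns = np.zeros(n, dtype=np.int64)
        n_sev = np.zeros(n, dtype=np.int64)
        sick = np.flatnonzero(st.alive & st.has_copd & ~new_copd)
        if sick.size:
            rr = tr_rre[st.treatment[sick]]
            u1 = _stream(seed, cycle, STREAMS["exac_nonsevere"]).random(n)
            u2 = _stream(seed, cycle, STREAMS["exac_severe"]).random(n)
            c_ns, c_sev = nh.exacerbation_counts(st.stage[sick], rr, u1[sick], u2[sick], params)
            n_ns[sick] = c_ns
            n_sev[sick] = c_sev
            had = sick[(c_ns + c_sev) > 0]
            st.months_since_exac[had] = 0.0
            res.n_exac_nonsevere += int(c_ns.sum())
            res.n_exac_severe += int(c_sev.sum())

            # --- FEV1 decline & restaging ---------------------------------
            z = _stream(seed, cycle, STREAMS["decline"]).standard_normal(n)
            recent = st.months_since_exac[sick] < params.exac_effect_months
            # the decline benefit holds only for the first treat_effect_months
            # on the current archetype (clinical evidence horizon)
            eff_red = tr_red[st.treatment[sick]] * (
                st.months_on_treatment[sick] < params.treat_effect_months)
            dml = nh.cycle_decline_ml(st.stage[sick], recent, eff_red, z[sick], params)
            age_now = np.minimum(st.age[sick], 110.0 - cy)
            pred_now = predicted_fev1(st.sex[sick], age_now, params)
            pred_next = predicted_fev1(st.sex[sick], age_now + cy, params)
            # FEV1 (liters) falls by the sampled decline while the age
            # reference falls along its own slope; % predicted never rises
            f_next = (st.fev1_pct[sick] * pred_now - dml / 1000.0) / pred_next
            st.fev1_pct[sick] = np.clip(f_next, 0.0, st.fev1_pct[sick])
            st.stage[sick] = nh.gold_stage(st.fev1_pct[sick])

        # --- death -----------------------------------------------------------
        idx = np.flatnonzero(st.alive)
        u_d = _stream(seed, cycle, STREAMS["death"]).random(n)
        u_c = _stream(seed, cycle, STREAMS["cause"]).random(n)
        stage_eff = np.where(new_copd, 0, st.stage)  # incident HR from next cycle
        rr_m = tr_rrm[st.treatment[idx]]
        died, copd_attr = nh.death_event(st.sex[idx], st.age[idx], stage_eff[idx],
                                         rr_m, u_d[idx], u_c[idx], params)
        dead_ids = idx[died]
        st.alive[dead_ids] = False
        st.death_cause[dead_ids] = np.where(copd_attr[died], CAUSE_COPD, CAUSE_BACKGROUND)
        res.n_copd_deaths += int(np.count_nonzero(copd_attr))
        res.n_background_deaths += int(np.count_nonzero(died) - np.count_nonzero(copd_attr))

        # --- accrual ----------------------------------------------------------
        occ = np.where(st.alive, 1.0, 0.5)  # died-this-cycle -> half occupancy
        copd_eff = st.has_copd & ~new_copd
        w = economics.cycle_utility(stage_eff, st.age, n_ns, n_sev, params)
        pyears = np.where(present, occ, 0.0) * cy
        q = w * pyears
        q_sum = float(q.sum())
        res.total_qaly_undiscounted += q_sum
        res.total_qaly_discounted += q_sum * df
        res.qaly_copd_patients_discounted += float(q[copd_eff].sum()) * df

        costs = economics.cycle_cost(
            stage_eff, st.diagnosed, copd_eff, st.treatment, n_ns, n_sev,
            scr_charge, dx_charge, params,
            occupancy=np.where(st.alive, 1.0, 0.5))
        for cat in COST_CATEGORIES:
            res.cost_breakdown[cat] += float(costs[cat][present].sum()) * df

        # --- clock ------------------------------------------------------------
        st.age[st.alive] += cy
        st.months_since_exac[st.alive] += cy * 12.0
        on_t = st.alive & (st.treatment >= 0)
        st.months_on_treatment[on_t] += cy * 12.0

        if track_awareness:
            rows = []
            for s in range(1, 5):
                m = st.alive & (st.stage == s)
                rows.append((int(np.count_nonzero(m)),
                             int(np.count_nonzero(m & st.diagnosed))))
            res.awareness.append(rows)

        cycle += 1

    res.n_cycles = cycle
    if return_state:
        res.final_state = st
    return res


def run_policy_set(cohort: Cohort, policies, params: ParameterSet, seed, *,
                   seed_mode: str = "common_random_numbers",
                   **kwargs) -> list[PolicyResult]:
    """Run several policies on the same cohort.

    ``seed_mode="common_random_numbers"`` couples all person-level streams
    across policies (paired comparison; differences are attributable to the
    policy).  ``"independent"`` derives a fresh master seed per policy.
    """
    policies = [ScreeningPolicy.parse(p) if isinstance(p, str) else p for p in policies]
    labels = [str(p) for p in policies]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate policies in {labels}")
    if seed_mode not in ("common_random_numbers", "independent"):
        raise ValueError(f"unknown seed_mode {seed_mode!r}")
    out = []
    for i, pol in enumerate(policies):
        master = seed if seed_mode == "common_random_numbers" else [seed, 7919 + i]
        out.append(run_policy(cohort, pol, params, master, **kwargs))
    return out
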