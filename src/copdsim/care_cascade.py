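"""Screening policies, symptom-based diagnosis, and treatment assignment.

Screening follows the two programme designs used in Chinese community
practice: a one-step questionnaire (COPD-SQ) pathway, and a two-step pathway
adding a portable spirometer test for questionnaire-positives.  Positive
screens proceed to confirmatory diagnostic spirometry (treated as a perfect
gold standard) with a follow-up probability reflecting incomplete linkage to
care.  Diagnosed patients take up one of five long-acting treatment
archetypes with a conservative 30% probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, TreatmentArchetype  # noqa: F401  (re-export)

__all__ = [
    "ScreeningPolicy", "ALL_POLICIES", "is_screening_cycle",
    "NOT_SCREENED", "NEGATIVE", "POSITIVE_NO_FOLLOWUP", "NEWLY_DIAGNOSED",
    "apply_screening", "screen_person", "sample_symptom_diagnosis",
    "evaluate_care", "assign_treatment",
    "two_step_sensitivity", "two_step_specificity",
    "calibrate_symptom_diagnosis", "CalibrationError",
]

_FREQ_INTERVALS = {"every_1y": 1, "every_2y": 2, "every_5y": 5, "every_10y": 10}
_FREQ_ALIASES = {"once": "one_time", "one_time": "one_time",
                 "1y": "every_1y", "2y": "every_2y", "5y": "every_5y", "10y": "every_10y"}


@dataclass(frozen=True)
class ScreeningPolicy:
    """A screening method x frequency combination.

    ``method`` is ``none`` (status quo), ``one_step`` or ``two_step``;
    ``frequency`` is ``one_time`` or ``every_{1,2,5,10}y`` (ignored when the
    method is ``none``).
    """

    method: str = "none"
    frequency: str = "one_time"

    def __post_init__(self):
        if self.method not in ("none", "one_step", "two_step"):
            raise ValueError(f"unknown screening method {self.method!r}")
        if self.frequency not in ("one_time", *_FREQ_INTERVALS):
            raise ValueError(f"unknown screening frequency {self.frequency!r}")

    @classmethod
    def parse(cls, text: str) -> "ScreeningPolicy":
        """Parse policy strings such as ``"none"``, ``"two_step:1y"``,
        ``"one_step:once"``."""
        text = text.strip()
        if text in ("none", "status_quo", "statusquo"):
            return cls("none")
        if ":" not in text:
            raise ValueError(
                f"bad policy string {text!r}; expected 'none' or "
                "'<one_step|two_step>:<once|1y|2y|5y|10y>'")
        method, freq = text.split(":", 1)
        if freq not in _FREQ_ALIASES:
            raise ValueError(f"bad screening frequency {freq!r}; "
                             f"expected one of {sorted(_FREQ_ALIASES)}")
        return cls(method, _FREQ_ALIASES[freq])

    def __str__(self) -> str:
        if self.method == "none":
            return "none"
        short = {v: k for k, v in _FREQ_ALIASES.items() if k != "one_time"}
        return f"{self.method}:{short[self.frequency]}"

    @property
    def label(self) -> str:
        return str(self)


#: the 11-policy evaluation set: status quo plus method x frequency grid
ALL_POLICIES: tuple[ScreeningPolicy, ...] = (ScreeningPolicy("none"),) + tuple(
    ScreeningPolicy(m, f)
    for f in ("one_time", "every_10y", "every_5y", "every_2y", "every_1y")
    for m in ("two_step", "one_step")
)


def is_screening_cycle(cycle_index: int, frequency: str, cycle_years: float = 0.25) -> bool:
    """Whether screening is offered in this cycle (year 0 counts)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if frequency == "one_time":
        return cycle_index == 0
    k = _FREQ_INTERVALS[frequency]
    per_year = round(1.0 / cycle_years)
    return cycle_index % (k * per_year) == 0


# screening outcome codes
NOT_SCREENED, NEGATIVE, POSITIVE_NO_FOLLOWUP, NEWLY_DIAGNOSED = 0, 1, 2, 3


def apply_screening(cohort, params: ParameterSet, two_step: bool,
                    u_sq, u_spiro, u_fu) -> dict:
    """Run one screening round on a cohort (in place).

    Everyone alive and not already diagnosed is screened.  Returns outcome
    codes per person plus per-person screening/diagnosis charges and test
    counts.  Confirmatory spirometry is a perfect gold standard: true cases
    become diagnosed, false positives are cleared back to the unlabelled
    pool.
    """
    n = len(cohort)
    screened = cohort.alive & ~cohort.diagnosed
    outcome = np.zeros(n, dtype=np.int8)

    sq_pos = screened & np.where(cohort.has_copd,
                                 u_sq < params.sq_sens,
                                 u_sq < 1.0 - params.sq_spec)
    if two_step:
        screen_pos = sq_pos & np.where(cohort.has_copd,
                                       u_spiro < params.spiro_sens,
                                       u_spiro < 1.0 - params.spiro_spec)
        n_spiro = int(np.count_nonzero(sq_pos))
    else:
        screen_pos = sq_pos
        n_spiro = 0

    followup = screen_pos & (u_fu < params.p_followup_dx)
    new_dx = followup & cohort.has_copd

    outcome[screened] = NEGATIVE
    outcome[screen_pos] = POSITIVE_NO_FOLLOWUP
    outcome[followup] = NEGATIVE      # false positives cleared by gold standard
    outcome[new_dx] = NEWLY_DIAGNOSED
    cohort.diagnosed[new_dx] = True

    screening_charge = np.zeros(n)
    screening_charge[screened] = params.cost_sq
    if params.setup_cost_once:
        screening_charge[screened & ~cohort.ever_screened] += params.cost_setup
    else:
        screening_charge[screened] += params.cost_setup
    cohort.ever_screened[screened] = True
    if two_step:
        screening_charge[sq_pos] += params.cost_spiro
    diagnosis_charge = np.zeros(n)
    diagnosis_charge[followup] = params.cost_dx_spirometry

    return {
        "outcome": outcome,
        "screening_charge": screening_charge,
        "diagnosis_charge": diagnosis_charge,
        "n_screens": int(np.count_nonzero(screened)),
        "n_spiro_tests": n_spiro,
        "n_confirm_tests": int(np.count_nonzero(followup)),
        "n_new_dx": int(np.count_nonzero(new_dx)),
        "new_dx": new_dx,
    }


def screen_person(person_cohort, policy: ScreeningPolicy, params: ParameterSet, rng):
    """Screen a single person (index 0 of a one-person cohort).

    Returns ``(outcome_code, total_charge)``; already-diagnosed persons are
    not screened and incur no cost.
    """
    if policy.method == "none":
        return NOT_SCREENED, 0.0
    n = len(person_cohort)
    res = apply_screening(person_cohort, params, policy.method == "two_step",
                          rng.random(n), rng.random(n), rng.random(n))
    charge = float(res["screening_charge"][0] + res["diagnosis_charge"][0])
    return int(res["outcome"][0]), charge


def two_step_sensitivity(params: ParameterSet) -> float:
    """Composite sensitivity of the two-step pathway (both tests positive)."""
    return params.sq_sens * params.spiro_sens


def two_step_specificity(params: ParameterSet) -> float:
    """Composite specificity of the two-step pathway."""
    return 1.0 - (1.0 - params.sq_spec) * (1.0 - params.spiro_spec)


def sample_symptom_diagnosis(cohort, params: ParameterSet, u) -> np.ndarray:
    """One cycle of symptom-driven diagnosis among undiagnosed COPD patients.

    Each undiagnosed living patient is diagnosed this cycle with the
    calibrated stage-specific per-cycle probability; returns the mask of new
    diagnoses (state updated in place).
    """
    eligible = cohort.alive & cohort.has_copd & ~cohort.diagnosed
    p = np.asarray(params.p_symptom_dx, dtype=float)
    new_dx = eligible & (np.asarray(u) < p[np.maximum(cohort.stage, 1) - 1])
    cohort.diagnosed[new_dx] = True
    return new_dx


def evaluate_care(cohort, params: ParameterSet, u_uptake, u_choice) -> np.ndarray:
    """(Re)assign treatment where care has not been evaluated at the current stage.

    Newly diagnosed patients (and previously untreated patients whose stage
    changed) receive a fresh uptake draw; already-treated patients whose
    stage changed switch archetype according to the stage's treatment mix,
    resetting time on the current treatment.  Returns the mask of persons
    starting or switching treatment this cycle.
    """
    due = cohort.alive & cohort.diagnosed & (cohort.care_stage != cohort.stage)
    if not np.any(due):
        return due
    untreated = due & (cohort.treatment < 0)
    starters = untreated & (np.asarray(u_uptake) < params.p_treat_uptake)
    switchers = due & (cohort.treatment >= 0)
    pick = starters | switchers
    if np.any(pick):
        mix = np.asarray(params.treat_mix, dtype=float)
        cum = np.cumsum(mix, axis=1)
        rows = cum[cohort.stage[pick] - 1]
        cohort.treatment[pick] = (
            np.asarray(u_choice)[pick, None] >= rows).sum(axis=1).astype(np.int8)
        cohort.months_on_treatment[pick] = 0.0
    cohort.care_stage[due] = cohort.stage[due]
    return pick


def assign_treatment(cohort, params: ParameterSet, rng) -> np.ndarray:
    """Convenience wrapper over :func:`evaluate_care` drawing its uniforms."""
    n = len(cohort)
    return evaluate_care(cohort, params, rng.random(n), rng.random(n))


# ---------------------------------------------------------------------------
# calibration of symptom-based diagnosis


class CalibrationError(RuntimeError):
    """Awareness target unattainable within the searched bracket."""


def _awareness_forward(p_vec, params, cohort_size, horizon_years, seed):
    """Simulated status-quo awareness by stage (window-averaged cross-sections)."""
    from .cohort import generate_cohort
    from .engine import run_policy

    trial = params.replace(p_symptom_dx=[float(p) for p in p_vec])
    cohort = generate_cohort(cohort_size, trial, seed)
    n_cycles = int(round(horizon_years / trial.cycle_years))
    res = run_policy(cohort, ScreeningPolicy("none"), trial, seed,
                     max_cycles=n_cycles, track_awareness=True)
    series = np.asarray(res.awareness)  # [cycle, stage, (n_copd, n_diag)]
    half = series.shape[0] // 2
    tail = series[half:]
    n_copd = tail[:, :, 0].sum(axis=0)
    n_diag = tail[:, :, 1].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        aw = np.where(n_copd > 0, n_diag / np.maximum(n_copd, 1), 0.0)
    return aw


def calibrate_symptom_diagnosis(targets, params: ParameterSet, *,
                                cohort_size: int = 20_000,
                                horizon_years: float = 10.0,
                                seed: int = 0,
                                tol_rel: float = 0.10,
                                max_iter: int = 9,
                                outer_passes: int = 2,
                                p_hi: float = 0.3) -> dict:
    """Calibrate per-cycle symptom-diagnosis probabilities to awareness targets.

    Uses the full status-quo simulator as the forward model and stage-wise
    bisection (repeated ``outer_passes`` times to absorb cross-stage
    interactions through disease progression).  Deterministic given ``seed``.

    Returns a dict with ``p_symptom_dx``, the achieved awareness, and the
    targets.  Raises :class:`CalibrationError` when a target exceeds the
    awareness achievable at the top of the bracket.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any((targets < 0) | (targets >= 1)):
        raise ValueError("awareness targets must lie in [0, 1)")
    p = np.where(targets > 0, np.minimum(targets / 4.0, p_hi), 0.0)

    def fwd(vec):
        return _awareness_forward(vec, params, cohort_size, horizon_years, seed)

    achieved = fwd(p)
    for _ in range(outer_passes):
        for s in range(4):
            if targets[s] == 0.0:
                p[s] = 0.0
                continue
            lo, hi = 0.0, p_hi
            trial = p.copy()
            trial[s] = hi
            a_hi = fwd(trial)[s]
            if a_hi + 1e-12 < targets[s]:
                raise CalibrationError(
                    f"stage {s + 1}: target awareness {targets[s]:.4f} exceeds "
                    f"achievable {a_hi:.4f} at per-cycle probability {hi}")
            for _ in range(max_iter):
                mid = 0.5 * (lo + hi)
                trial[s] = mid
                a = fwd(trial)[s]
                if abs(a - targets[s]) <= tol_rel * targets[s]:
                    break
                if a < targets[s]:
                    lo = mid
                else:
                    hi = mid
            p[s] = trial[s]
        achieved = fwd(p)
    return {"p_symptom_dx": [float(x) for x in p],
            "achieved": [float(a) for a in achieved],
            "targets": [float(t) for t in targets]}
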