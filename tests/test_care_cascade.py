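import math

import numpy as np
import pytest

from copdsim.care_cascade import (ALL_POLICIES, NEGATIVE, NEWLY_DIAGNOSED,
                                  NOT_SCREENED, POSITIVE_NO_FOLLOWUP,
                                  CalibrationError, ScreeningPolicy,
                                  apply_screening, assign_treatment,
                                  calibrate_symptom_diagnosis, evaluate_care,
                                  is_screening_cycle, sample_symptom_diagnosis,
                                  screen_person, two_step_sensitivity,
                                  two_step_specificity)

from conftest import make_cohort


# --- policies ---------------------------------------------------------------


def test_policy_parse_round_trip():
    for text in ("none", "one_step:1y", "two_step:10y", "two_step:once"):
        assert str(ScreeningPolicy.parse(text)) == text.replace(":one_time", ":once")


@pytest.mark.parametrize("bad", ["bogus", "two_step", "one_step:3y", "three_step:1y"])
def test_policy_parse_rejects_garbage(bad):
    with pytest.raises(ValueError):
        ScreeningPolicy.parse(bad)


def test_policy_set_is_the_eleven_policy_grid():
    labels = [str(p) for p in ALL_POLICIES]
    assert len(labels) == 11 and len(set(labels)) == 11
    assert labels[0] == "none"
    assert sum(p.method == "two_step" for p in ALL_POLICIES) == 5


def test_is_screening_cycle():
    assert is_screening_cycle(0, "one_time")
    assert not is_screening_cycle(4, "one_time")
    assert is_screening_cycle(8, "every_2y")       # year 2
    assert not is_screening_cycle(6, "every_2y")
    annual = [is_screening_cycle(c, "every_1y") for c in range(12)]
    assert annual == [c % 4 == 0 for c in range(12)]
    with pytest.raises(ValueError):
        is_screening_cycle(-1, "every_1y")


# --- screening ---------------------------------------------------------------


def test_two_step_composite_accuracy(params):
    assert two_step_sensitivity(params) == pytest.approx(0.57 * 0.85)       # 0.4845
    assert two_step_specificity(params) == pytest.approx(1 - 0.18 * 0.15)   # 0.973
    # the second test trades sensitivity for specificity vs one-step
    assert two_step_specificity(params) > params.sq_spec
    assert two_step_sensitivity(params) < params.sq_sens


def test_screening_chain_probabilities(params):
    """Empirical outcome rates of one two-step round match the product
    of the test accuracies and the follow-up probability within 3 SE."""
    n = 50_000
    rng = np.random.default_rng(0)

    sick = make_cohort(n, has_copd=True, fev1_pct=0.6, params=params)
    res = apply_screening(sick, params, True, rng.random(n), rng.random(n), rng.random(n))
    p_dx = 0.57 * 0.85 * 0.40
    se = math.sqrt(p_dx * (1 - p_dx) / n)
    assert abs(res["n_new_dx"] / n - p_dx) < 3 * se

    healthy = make_cohort(n, has_copd=False, params=params)
    res = apply_screening(healthy, params, True, rng.random(n), rng.random(n), rng.random(n))
    p_pos = 0.18 * 0.15
    n_pos = res["n_confirm_tests"] + np.count_nonzero(res["outcome"] == POSITIVE_NO_FOLLOWUP)
    se = math.sqrt(p_pos * (1 - p_pos) / n)
    assert abs(n_pos / n - p_pos) < 3 * se
    # confirmatory spirometry clears every false positive
    assert res["n_new_dx"] == 0
    assert not healthy.diagnosed.any()


def test_screening_counts_and_charges(params):
    n = 20_000
    rng = np.random.default_rng(1)
    c = make_cohort(n, has_copd=True, fev1_pct=0.6, params=params)
    res = apply_screening(c, params, True, rng.random(n), rng.random(n), rng.random(n))
    assert res["n_spiro_tests"] <= res["n_screens"]
    assert res["n_confirm_tests"] <= res["n_spiro_tests"]
    # every screened person pays the questionnaire + (first-time) setup cost
    assert res["screening_charge"].min() >= params.cost_sq
    assert c.ever_screened.all()
    # second round: setup is not charged again under the one-time rule
    res2 = apply_screening(c, params, True, rng.random(n), rng.random(n), rng.random(n))
    still = ~c.diagnosed
    assert res2["screening_charge"][still].min() == pytest.approx(params.cost_sq)


def test_already_diagnosed_not_screened(params):
    c = make_cohort(1, has_copd=True, fev1_pct=0.4, diagnosed=True, params=params)
    outcome, charge = screen_person(c, ScreeningPolicy("two_step", "every_1y"),
                                    params, np.random.default_rng(0))
    assert outcome == NOT_SCREENED and charge == 0.0


# --- symptom-based diagnosis -------------------------------------------------


def test_symptom_diagnosis_zero_probability(params):
    quiet = params.replace(p_symptom_dx=[0, 0, 0, 0])
    c = make_cohort(1000, has_copd=True, fev1_pct=0.6, params=quiet)
    for _ in range(10):
        sample_symptom_diagnosis(c, quiet, np.random.default_rng(0).random(1000))
    assert not c.diagnosed.any()


def test_symptom_diagnosis_geometric_oracle(params):
    """Per-cycle probability 0.01 over 40 cycles diagnoses 1 - 0.99^40 of
    patients within 3 binomial SE."""
    p = params.replace(p_symptom_dx=[0.01] * 4)
    n = 10_000
    c = make_cohort(n, has_copd=True, fev1_pct=0.6, params=p)
    rng = np.random.default_rng(7)
    for _ in range(40):
        sample_symptom_diagnosis(c, p, rng.random(n))
    expected = 1 - 0.99 ** 40
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(c.diagnosed.mean() - expected) < 3 * se


# --- treatment ---------------------------------------------------------------


def test_treatment_uptake_rate(params):
    n = 10_000
    c = make_cohort(n, has_copd=True, fev1_pct=0.6, diagnosed=True, params=params)
    c.care_stage[:] = -1  # newly diagnosed, uptake not yet evaluated
    assign_treatment(c, params, np.random.default_rng(2))
    frac = (c.treatment >= 0).mean()
    se = math.sqrt(0.3 * 0.7 / n)
    assert abs(frac - params.p_treat_uptake) < 3 * se
    assert (c.care_stage == c.stage).all()


def test_treatment_zero_uptake(params):
    none = params.replace(p_treat_uptake=0.0)
    c = make_cohort(500, has_copd=True, fev1_pct=0.6, diagnosed=True, params=none)
    c.care_stage[:] = -1
    assign_treatment(c, none, np.random.default_rng(0))
    assert (c.treatment == -1).all()


def test_degenerate_mix_assigns_single_archetype(params):
    mix = [[0, 0, 0, 1, 0]] * 4
    p = params.replace(treat_mix=mix, p_treat_uptake=1.0)
    c = make_cohort(2000, has_copd=True, fev1_pct=0.6, diagnosed=True, params=p)
    c.care_stage[:] = -1
    assign_treatment(c, p, np.random.default_rng(3))
    assert (c.treatment == 3).all()


def test_stage_change_triggers_switch_and_resets_clock(params):
    p = params.replace(p_treat_uptake=1.0)
    c = make_cohort(200, has_copd=True, fev1_pct=0.6, diagnosed=True, params=p)
    c.care_stage[:] = -1
    assign_treatment(c, p, np.random.default_rng(4))
    c.months_on_treatment[:] = 24.0
    c.stage[:] = 3  # progression
    switched = assign_treatment(c, p, np.random.default_rng(5))
    assert switched.all()
    assert (c.months_on_treatment == 0).all()
    assert (c.care_stage == 3).all()
    # declined-uptake patients are not re-drawn unless the stage changes
    d = make_cohort(200, has_copd=True, fev1_pct=0.6, diagnosed=True,
                    params=params)
    d.care_stage[:] = d.stage  # uptake already evaluated at this stage
    d.treatment[:] = -1
    assert not evaluate_care(d, params, np.zeros(200), np.zeros(200)).any()


# --- calibration -------------------------------------------------------------


def test_calibration_zero_targets(params):
    out = calibrate_symptom_diagnosis([0, 0, 0, 0], params, cohort_size=300,
                                      horizon_years=2, seed=0, max_iter=2,
                                      outer_passes=1)
    assert out["p_symptom_dx"] == [0.0] * 4


def test_calibration_unattainable_target_reports_failure(params):
    with pytest.raises(CalibrationError, match="stage 1"):
        calibrate_symptom_diagnosis([0.99, 0, 0, 0], params, cohort_size=400,
                                    horizon_years=2, seed=0, max_iter=2,
                                    outer_passes=1)


def test_default_probabilities_reproduce_awareness_profile(params):
    """The frozen calibrated defaults hold status-quo awareness near the
    observed by-stage profile, which increases with stage."""
    from copdsim.care_cascade import _awareness_forward

    aw = _awareness_forward(params.p_symptom_dx, params, 30_000, 10.0, 0)
    targets = np.array([0.0063, 0.0200, 0.1287, 0.2104])
    assert np.all(np.diff(aw) > 0)  # awareness increases with severity
    assert np.all(np.abs(aw - targets) <= 0.15 * targets + 0.002)
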