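import math

import numpy as np
import pytest
from scipy.stats import norm

from copdsim import (ceac, cea_table, frontier_indices, generate_cohort, icer,
                     linkage_scenario_grid, most_cost_effective, one_way_sweep,
                     run_policy_set, run_psa)
from copdsim.cea import DOMINATED, DOMINATES, UNDEFINED, PSASample, averted


# --- ICER arithmetic ---------------------------------------------------------


def test_icer_ratio_and_verdicts():
    assert icer((7000, 56e6), (0, 0)) == pytest.approx(8000.0)
    assert icer((10, 5.0), (8, 6.0)) == DOMINATES
    assert icer((8, 6.0), (10, 5.0)) == DOMINATED
    assert icer((5, 10.0), (5, 10.0)) == UNDEFINED
    assert icer((5, 12.0), (5, 10.0)) == DOMINATED  # equal QALYs, dearer


def test_averted_arithmetic_and_zero_denominator():
    sq = {"exacerbations": 100, "copd_deaths": 0, "qaly": 0, "cost": 0}
    pol = {"exacerbations": 90, "copd_deaths": 0, "qaly": 0, "cost": 0}
    out = averted(pol, sq)
    assert out["exac_averted"] == 10 and out["exac_averted_pct"] == pytest.approx(10.0)
    assert out["deaths_averted"] == 0 and out["deaths_averted_pct"] is None


# --- frontier ----------------------------------------------------------------


def _oracle_frontier(q, c):
    """Brute force: a policy is non-dominated iff no single policy nor convex
    blend of two policies weakly improves on it."""
    n = len(q)
    out = []
    for k in range(n):
        dominated = any(q[i] > q[k] and c[i] <= c[k] for i in range(n) if i != k)
        for i in range(n):
            for j in range(n):
                if dominated or k in (i, j) or q[i] == q[j]:
                    continue
                lam = (q[k] - q[j]) / (q[i] - q[j])
                if 0.0 <= lam <= 1.0 and lam * c[i] + (1 - lam) * c[j] < c[k]:
                    dominated = True
        if not dominated:
            out.append(k)
    return sorted(out, key=lambda k: q[k])


def test_simple_dominance():
    # A dominates B outright
    assert frontier_indices([10, 8], [5.0, 6.0]) == [0]


@pytest.mark.parametrize("seed", range(8))
def test_frontier_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    q = rng.random(n) * 10
    c = rng.random(n) * 100
    assert frontier_indices(q, c) == _oracle_frontier(q, c)


def test_frontier_invariant_to_order_and_cost_scale():
    rng = np.random.default_rng(99)
    q, c = rng.random(8) * 10, rng.random(8) * 100
    base = frontier_indices(q, c)
    perm = rng.permutation(8)
    permuted = frontier_indices(q[perm], c[perm])
    assert sorted(perm[permuted]) == sorted(base)
    assert frontier_indices(q, c * 1e6) == base


def test_frontier_icers_strictly_increase():
    rng = np.random.default_rng(5)
    q, c = rng.random(30) * 10, rng.random(30) * 100
    chain = frontier_indices(q, c)
    icers = [(c[b] - c[a]) / (q[b] - q[a]) for a, b in zip(chain[:-1], chain[1:])]
    assert all(x < y for x, y in zip(icers, icers[1:]))


def test_empty_frontier_rejected():
    with pytest.raises(ValueError):
        frontier_indices([], [])


# --- CEAC --------------------------------------------------------------------


def _synthetic_samples(n, rng, mu_dq=0.5, mu_dc=5000.0, sd_dq=0.2, sd_dc=2000.0):
    samples = []
    for rep in range(n):
        dq = rng.normal(mu_dq, sd_dq)
        dc = rng.normal(mu_dc, sd_dc)
        s = PSASample(replicate=rep, overrides={})
        s.results = {"none": (0.0, 0.0), "screen": (dq, dc)}
        samples.append(s)
    return samples


def test_ceac_single_replicate_and_partition():
    samples = _synthetic_samples(1, np.random.default_rng(0))
    curves = ceac(samples, [0, 20000])
    for lam in (0, 20000):
        probs = curves[curves.wtp == lam].probability
        assert probs.sum() == pytest.approx(1.0)
        assert set(np.round(probs, 12)) <= {0.0, 1.0}


def test_ceac_zero_wtp_prefers_cheapest():
    samples = _synthetic_samples(500, np.random.default_rng(1))
    curves = ceac(samples, [0.0])
    sq = curves[(curves.policy == "none")].probability.iloc[0]
    # at zero WTP the winner is the cheaper arm, replicate by replicate
    cheaper = np.mean([s.results["screen"][1] > 0 for s in samples])
    assert sq == pytest.approx(cheaper)


def test_ceac_matches_gaussian_closed_form():
    n = 4000
    samples = _synthetic_samples(n, np.random.default_rng(2))
    grid = [5000.0, 10000.0, 20000.0]
    curves = ceac(samples, grid)
    for lam in grid:
        p_true = norm.cdf((lam * 0.5 - 5000.0) / math.hypot(lam * 0.2, 2000.0))
        p_emp = curves[(curves.wtp == lam) & (curves.policy == "screen")].probability.iloc[0]
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_emp - p_true) < 3 * se


def test_ceac_tie_splitting():
    s = PSASample(replicate=0, overrides={})
    s.results = {"a": (1.0, 10.0), "b": (1.0, 10.0), "c": (0.0, 10.0)}
    curves = ceac([s], [100.0])
    probs = dict(zip(curves.policy, curves.probability))
    assert probs["a"] == probs["b"] == pytest.approx(0.5)
    assert probs["c"] == 0.0


def test_ceac_rejects_empty_inputs():
    with pytest.raises(ValueError):
        ceac([], [1.0])
    with pytest.raises(ValueError):
        ceac(_synthetic_samples(1, np.random.default_rng(0)), [])


# --- most cost-effective rule ------------------------------------------------


def test_most_cost_effective_wtp_rule(params):
    import pandas as pd
    table = pd.DataFrame([
        {"policy": "none", "total_qaly": 0.0, "total_cost": 0.0,
         "frontier_member": True, "icer_on_frontier": None},
        {"policy": "a", "total_qaly": 1.0, "total_cost": 8000.0,
         "frontier_member": True, "icer_on_frontier": 8000.0},
        {"policy": "b", "total_qaly": 2.0, "total_cost": 30000.0,
         "frontier_member": True, "icer_on_frontier": 22000.0},
        {"policy": "x", "total_qaly": 1.5, "total_cost": 40000.0,
         "frontier_member": False, "icer_on_frontier": None},
    ])
    assert most_cost_effective(table, 38441.0) == "b"
    assert most_cost_effective(table, 10000.0) == "a"
    assert most_cost_effective(table, 100.0) == "none"


# --- simulation-backed layers ------------------------------------------------


def test_psa_zero_variance_equals_base_case(params):
    dists = {"sq_sens": {"family": "beta", "mean": 0.57, "sd": 0.0},
             "cost_exac_severe": {"family": "gamma", "mean": 2987.06, "sd": 0.0}}
    pols = ["none", "two_step:1y"]
    samples = run_psa(600, 1, dists, pols, params, seed=11, max_cycles=40)
    cohort = generate_cohort(600, params, seed=11)
    base = run_policy_set(cohort, pols, params, [11, 0], max_cycles=40)
    for r in base:
        q, c = samples[0].results[r.policy]
        assert q == pytest.approx(r.total_qaly_discounted)
        assert c == pytest.approx(r.total_cost_discounted)


def test_psa_draws_respect_support(params):
    samples = run_psa(50, 15, None, ["none"], params, seed=3, max_cycles=2)
    for s in samples:
        for path, v in s.overrides.items():
            if path.split(".")[0] in ("sq_sens", "sq_spec", "spiro_sens",
                                      "spiro_spec", "p_followup_dx",
                                      "p_treat_uptake", "utility_stage",
                                      "disutility_exac_nonsevere",
                                      "disutility_exac_severe"):
                assert 0.0 <= v <= 1.0
            if path.startswith("cost") or path.startswith("exac_rate"):
                assert v >= 0.0
            if path.startswith("mortality_hr"):
                assert v >= 1.0


def test_psa_invalid_distribution_spec(params):
    with pytest.raises(ValueError, match="invalid distribution"):
        run_psa(10, 1, {"sq_sens": {"family": "cauchy", "mean": 0.5, "sd": 1}},
                ["none"], params, seed=0)


def test_linkage_grid_degenerate_cell_reproduces_base_case(params):
    pols = ["none", "two_step:1y", "two_step:2y"]
    grid = linkage_scenario_grid(params, [0.40], [0.30], pols, seed=29,
                                 cohort_size=1500, max_cycles=60)
    assert len(grid) == 1
    cohort = generate_cohort(1500, params, seed=29)
    base = cea_table(run_policy_set(cohort, pols, params, 29, max_cycles=60))
    assert grid.most_cost_effective.iloc[0] == most_cost_effective(base, params.wtp)


def test_one_way_sweep_degenerate_and_active(params):
    flat = one_way_sweep("p_followup_dx", 0.40, 0.40, params, "two_step:1y",
                         seed=31, cohort_size=1200, max_cycles=60)
    assert flat["icer_low"] == flat["icer_high"]
    assert flat["span"] == 0.0
    moved = one_way_sweep("mortality_hr.2", 2.7, 4.5, params, "two_step:1y",
                          seed=31, cohort_size=1200, max_cycles=60)
    assert moved["icer_low"] != moved["icer_high"]


def test_one_way_sweep_unknown_path(params):
    with pytest.raises(KeyError, match="valid top-level"):
        one_way_sweep("nonsense", 0, 1, params, "none", seed=0, cohort_size=10)
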