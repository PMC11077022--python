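"""Cost-effectiveness analysis: ICERs, dominance frontier, scenarios, PSA, CEAC.

The frontier uses the standard two-stage dominance rule: strictly dominated
policies (another policy gives strictly more QALYs at no greater cost) are
removed first, then extended dominance iteratively removes policies whose
incremental ICER exceeds that of the next step, leaving a chain with
strictly increasing ICERs — the lower-left convex hull of the (QALY, cost)
cloud.  "Most cost-effective at a willingness-to-pay" is the frontier policy
with the largest QALYs whose frontier ICER does not exceed the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .care_cascade import ScreeningPolicy
from .cohort import generate_cohort
from .engine import PolicyResult, run_policy_set
from .parameters import ParameterSet

__all__ = [
    "icer", "frontier_indices", "cea_table", "averted", "most_cost_effective",
    "linkage_scenario_grid", "one_way_sweep",
    "PSASample", "default_psa_distributions", "run_psa", "ceac",
]

DOMINATES, DOMINATED, UNDEFINED = "dominates", "dominated", "undefined"


def icer(result_a, result_b):
    """Incremental cost-effectiveness of A vs B (USD per QALY).

    Returns a dominance verdict string instead of a ratio when one policy
    dominates the other, and ``"undefined"`` when QALYs are equal (never a
    division by zero).
    """
    qa, ca = _qc(result_a)
    qb, cb = _qc(result_b)
    if ca <= cb and qa >= qb and (ca < cb or qa > qb):
        return DOMINATES
    if cb <= ca and qb >= qa and (cb < ca or qb > qa):
        return DOMINATED
    if qa == qb:
        return UNDEFINED
    return (ca - cb) / (qa - qb)


def _qc(r):
    if isinstance(r, PolicyResult):
        return r.total_qaly_discounted, r.total_cost_discounted
    if isinstance(r, dict):
        return r["qaly"], r["cost"]
    return tuple(r)  # (qaly, cost)


def frontier_indices(qalys, costs) -> list[int]:
    """Indices of non-dominated policies, ordered by increasing QALYs.

    Strict dominance first (strictly more QALYs at no greater cost), then
    iterative extended dominance (a policy whose incremental ICER is at least
    the next segment's is removed).  The highest-QALY survivor is never
    extended-dominated (no next segment).
    """
    q = np.asarray(qalys, dtype=float)
    c = np.asarray(costs, dtype=float)
    if q.size == 0:
        raise ValueError("frontier of an empty policy set")
    alive = []
    for j in range(q.size):
        if not np.any((q > q[j]) & (c <= c[j])):
            alive.append(j)
    chain = sorted(alive, key=lambda j: (q[j], c[j]))
    while len(chain) > 2:
        icers = []
        for a, b in zip(chain[:-1], chain[1:]):
            dq = q[b] - q[a]
            icers.append((c[b] - c[a]) / dq if dq > 0 else np.inf)
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                del chain[k + 1]
                break
        else:
            break
    return chain


def averted(result, statusquo) -> dict:
    """Events averted vs the status quo (counts and percentages).

    Percentages are ``None`` when the status-quo count is zero.
    """
    def pair(a, b):
        d = b - a
        return d, (100.0 * d / b) if b else None

    ex_d, ex_p = pair(_count(result, "exac"), _count(statusquo, "exac"))
    dth_d, dth_p = pair(_count(result, "deaths"), _count(statusquo, "deaths"))
    return {"exac_averted": ex_d, "exac_averted_pct": ex_p,
            "deaths_averted": dth_d, "deaths_averted_pct": dth_p}


def _count(r, what):
    if isinstance(r, PolicyResult):
        return r.n_exacerbations if what == "exac" else r.n_copd_deaths
    return r["exacerbations" if what == "exac" else "copd_deaths"]


def cea_table(results: list[PolicyResult], statusquo: str = "none") -> pd.DataFrame:
    """Build the per-policy incremental-outcome table with frontier annotations.

    One row per policy: QALYs, costs, events, events averted vs status quo,
    cost per event averted, ICER vs status quo, frontier membership, and the
    frontier (incremental) ICER vs the preceding non-dominated policy.
    """
    labels = [r.policy for r in results]
    if statusquo not in labels:
        raise ValueError(f"status quo policy {statusquo!r} missing from results")
    sq = results[labels.index(statusquo)]
    q = np.array([r.total_qaly_discounted for r in results])
    c = np.array([r.total_cost_discounted for r in results])
    front = frontier_indices(q, c)
    rows = []
    for i, r in enumerate(results):
        av = averted(r, sq)
        d_cost = c[i] - sq.total_cost_discounted
        v = icer(r, sq) if r is not sq else None
        rows.append({
            "policy": r.policy,
            "total_qaly": q[i],
            "total_cost": c[i],
            "qaly_copd_patients": r.qaly_copd_patients_discounted,
            "exacerbations": r.n_exacerbations,
            "copd_deaths": r.n_copd_deaths,
            **av,
            "cost_per_exac_averted": d_cost / av["exac_averted"] if av["exac_averted"] else None,
            "cost_per_death_averted": d_cost / av["deaths_averted"] if av["deaths_averted"] else None,
            "icer_vs_statusquo": v if isinstance(v, float) else None,
            "verdict_vs_statusquo": v if isinstance(v, str) else None,
            "frontier_member": i in front,
            "icer_on_frontier": None,
        })
    for a, b in zip(front[:-1], front[1:]):
        dq = q[b] - q[a]
        rows[b]["icer_on_frontier"] = (c[b] - c[a]) / dq if dq > 0 else np.inf
    return pd.DataFrame(rows)


def most_cost_effective(table: pd.DataFrame, wtp: float) -> str:
    """Frontier policy with the largest QALYs whose frontier ICER <= WTP."""
    ft = table[table.frontier_member].sort_values("total_qaly")
    best = ft.iloc[0]["policy"]  # anchor (status quo) is always affordable
    for _, row in ft.iterrows():
        v = row["icer_on_frontier"]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            best = row["policy"]
        elif v <= wtp:
            best = row["policy"]
    return best


# ---------------------------------------------------------------------------
# scenarios and sweeps


def linkage_scenario_grid(params: ParameterSet, dx_probs, treat_probs, policies,
                          seed: int, cohort_size: int = 100_000, **run_kwargs
                          ) -> pd.DataFrame:
    """Most cost-effective policy per (follow-up dx, treatment uptake) cell.

    For each cell the two linkage probabilities are overridden, the cohort is
    regenerated (treatment uptake affects initial care), all policies are run
    under common random numbers, and the standard WTP rule picks the winner.
    """
    records = []
    for p_dx in dx_probs:
        for p_tr in treat_probs:
            trial = params.replace(p_followup_dx=float(p_dx),
                                   p_treat_uptake=float(p_tr))
            cohort = generate_cohort(cohort_size, trial, seed)
            results = run_policy_set(cohort, policies, trial, seed, **run_kwargs)
            table = cea_table(results)
            records.append({"p_followup_dx": p_dx, "p_treat_uptake": p_tr,
                            "most_cost_effective": most_cost_effective(table, trial.wtp)})
    return pd.DataFrame(records)


def one_way_sweep(param_path: str, low, high, params: ParameterSet,
                  policy, seed: int, cohort_size: int = 100_000,
                  statusquo: str = "none", **run_kwargs) -> dict:
    """ICER of ``policy`` vs the status quo at the low/high ends of one parameter."""
    out = {"param": param_path, "low": low, "high": high}
    for key, value in (("icer_low", low), ("icer_high", high)):
        trial = params.set_path(param_path, value)
        cohort = generate_cohort(cohort_size, trial, seed)
        results = run_policy_set(cohort, [statusquo, policy], trial, seed, **run_kwargs)
        out[key] = icer(results[1], results[0])
    vals = [v for v in (out["icer_low"], out["icer_high"]) if isinstance(v, float)]
    out["span"] = (max(vals) - min(vals)) if len(vals) == 2 else None
    return out


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSASample:
    """One PSA replicate: the drawn parameter overrides and per-policy outcomes."""

    replicate: int
    overrides: dict
    results: dict = field(default_factory=dict)  # policy -> (qaly, cost)


def default_psa_distributions(params: ParameterSet, dispersion: float = 0.20) -> dict:
    """Default distribution spec: beta for probabilities/utilities, gamma for
    costs and rates, normal for effect sizes; sd = ``dispersion`` x mean."""
    spec = {}

    def add(path, family):
        m = float(params.get_path(path))
        spec[path] = {"family": family, "mean": m, "sd": dispersion * m}

    for p in ("sq_sens", "sq_spec", "spiro_sens", "spiro_spec",
              "p_followup_dx", "p_treat_uptake",
              "disutility_exac_nonsevere", "disutility_exac_severe"):
        add(p, "beta")
    for i in range(4):
        add(f"utility_stage.{i}", "beta")
        add(f"exac_rate_nonsevere.{i}", "gamma")
        add(f"exac_rate_severe.{i}", "gamma")
        add(f"cost_maint_monthly.{i}", "gamma")
        add(f"mortality_hr.{i}", "gamma")
    add("cost_exac_nonsevere", "gamma")
    add("cost_exac_severe", "gamma")
    for i in range(len(params.treatments)):
        add(f"treatments.{i}.decline_reduction", "normal")
    return spec


def _draw(family: str, mean: float, sd: float, rng) -> float:
    if sd == 0.0:
        return mean
    if family == "beta":
        v = sd * sd
        if mean <= 0.0 or mean >= 1.0 or v >= mean * (1 - mean):
            return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
        k = mean * (1 - mean) / v - 1.0
        return float(rng.beta(mean * k, (1 - mean) * k))
    if family == "gamma":
        if mean <= 0.0:
            return mean
        shape = (mean / sd) ** 2
        return float(rng.gamma(shape, sd * sd / mean))
    if family == "normal":
        return float(rng.normal(mean, sd))
    raise ValueError(f"unknown distribution family {family!r}")


def run_psa(cohort_size: int, n_reps: int, distributions: dict | None,
            policies, params: ParameterSet, seed: int, **run_kwargs
            ) -> list[PSASample]:
    """Probabilistic sensitivity analysis.

    Per replicate, draws every uncertain parameter from its distribution,
    regenerates the cohort under the drawn parameter set, simulates all
    policies under common random numbers, and records (QALY, cost) per
    policy.  Reproducible given ``seed``.
    """
    if distributions is None:
        distributions = default_psa_distributions(params)
    for path, d in distributions.items():
        if d.get("family") not in ("beta", "gamma", "normal"):
            raise ValueError(f"invalid distribution spec for {path}: {d}")
    samples = []
    for rep in range(n_reps):
        rng = np.random.Generator(np.random.Philox(
            np.random.SeedSequence(seed, spawn_key=(9000 + rep,))))
        overrides = {}
        trial = params.to_dict()
        ps = params
        for path in sorted(distributions):
            d = distributions[path]
            v = _draw(d["family"], d["mean"], d["sd"], rng)
            if path.startswith("mortality_hr"):
                v = max(v, 1.0)
            if path.startswith("treatments") or path.startswith("decline"):
                v = max(v, 0.0)
            overrides[path] = v
            ps = ps.set_path(path, v)
        cohort = generate_cohort(cohort_size, ps, seed)
        results = run_policy_set(cohort, policies, ps, [seed, rep], **run_kwargs)
        sample = PSASample(replicate=rep, overrides=overrides)
        for r in results:
            sample.results[r.policy] = (r.total_qaly_discounted, r.total_cost_discounted)
        samples.append(sample)
    return samples


def ceac(samples: list[PSASample], wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, each replicate's winner maximizes net
    monetary benefit ``wtp * qaly - cost``; ties split their probability
    equally.  Probabilities across policies sum to one at every grid point.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if not samples:
        raise ValueError("no PSA samples")
    policies = list(samples[0].results)
    q = np.array([[s.results[p][0] for p in policies] for s in samples])
    c = np.array([[s.results[p][1] for p in policies] for s in samples])
    rows = []
    for lam in wtp_grid:
        nmb = lam * q - c
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for p, pr in zip(policies, probs):
            rows.append({"wtp": lam, "policy": p, "probability": pr})
    return pd.DataFrame(rows)
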