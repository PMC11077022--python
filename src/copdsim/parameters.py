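"""Model parameter registry, configuration I/O, and rate/discount conversions.

The :class:`ParameterSet` holds every epidemiological, clinical, test-accuracy,
utility, and cost parameter of the COPD microsimulation, with defaults for the
Chinese adult population (35-80 years).  All fields can be overridden from a
YAML/JSON configuration document whose tree mirrors the dataclass fields.

Conventions used throughout the package:

* sexes are strings ``"male"``/``"female"`` (arrays: male=0, female=1);
* GOLD stages are 1-4, stage-indexed lists have length 4 (index = stage-1);
* epidemiology age bands are 35-39, 40-49, 50-59, 60-69, 70-80 (ages above 80
  reuse the last band);
* all rates are annual, all probabilities per the unit stated on the field;
* costs are 2022 US dollars.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import io
import json
import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Any

import numpy as np
import yaml

__all__ = [
    "AGE_BANDS",
    "UTILITY_BANDS",
    "STAGES",
    "ConfigurationError",
    "ValidationError",
    "TreatmentArchetype",
    "ParameterSet",
    "load_parameters",
    "load_life_table",
    "annual_rate_to_cycle_prob",
    "annual_prob_to_hazard",
    "discount_factor",
    "age_band_index",
    "utility_band_index",
]

#: Epidemiology age bands (inclusive bounds) for prevalence and incidence.
AGE_BANDS: tuple[tuple[int, int], ...] = ((35, 39), (40, 49), (50, 59), (60, 69), (70, 80))

#: Age bands for the general-population baseline utility.
UTILITY_BANDS: tuple[tuple[int, int], ...] = ((35, 44), (45, 54), (55, 64), (65, 74), (75, 200))

STAGES = (1, 2, 3, 4)


class ConfigurationError(ValueError):
    """A configuration document is malformed or names an unknown field."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass(frozen=True)
class TreatmentArchetype:
    """One long-acting maintenance therapy profile.

    ``decline_reduction`` is an absolute reduction of the annual FEV1 decline
    (ml/yr); ``rr_exac`` and ``rr_mort`` are relative risks applied to the
    exacerbation rates and the excess-mortality hazard while on therapy.
    """

    id: int
    decline_reduction: float  # ml/yr
    rr_exac: float
    rr_mort: float
    monthly_cost: float  # USD

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "decline_reduction": self.decline_reduction,
            "rr_exac": self.rr_exac,
            "rr_mort": self.rr_mort,
            "monthly_cost": self.monthly_cost,
        }


def _default_treatments() -> list[TreatmentArchetype]:
    # Five archetypes evenly spaced across the published effect/cost ranges,
    # paired rank-wise (stronger effect <-> higher cost).
    reductions = [73.0, 105.0, 137.0, 169.0, 201.0]
    rr_exacs = [0.92, 0.845, 0.77, 0.695, 0.62]
    rr_morts = [0.99, 0.92, 0.85, 0.78, 0.71]
    costs = [20.21, 41.30, 62.40, 83.49, 104.58]
    return [
        TreatmentArchetype(i, reductions[i], rr_exacs[i], rr_morts[i], costs[i])
        for i in range(5)
    ]


def load_life_table(source: str | None = None) -> dict[str, list[float]]:
    """Load annual background mortality probabilities for ages 35-100.

    The packaged default is a *synthetic* abridged life table: a Gompertz
    hazard per sex calibrated to China 2020 period life expectancy at age 35
    (about 42.3 remaining years for men, 47.5 for women).  ``source`` may name
    a CSV with columns ``sex, age, annual_mortality_probability``.
    """
    if source is None:
        ref = importlib.resources.files("copdsim.data") / "life_table_china_synthetic.csv"
        text = ref.read_text()
    else:
        with open(source) as f:
            text = f.read()
    import csv

    table: dict[str, dict[int, float]] = {"male": {}, "female": {}}
    for row in csv.DictReader(io.StringIO(text)):
        table[row["sex"]][int(row["age"])] = float(row["annual_mortality_probability"])
    out: dict[str, list[float]] = {}
    for sex, by_age in table.items():
        ages = sorted(by_age)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ConfigurationError(f"life table for {sex} has gaps in age coverage")
        out[sex] = [by_age[a] for a in ages]
    return out


@dataclass
class ParameterSet:
    """Full registry of model parameters (defaults: Chinese base case).

    Notes on individual defaults:

    * ``fev1pct_incident`` male sd: the source table prints 0.906, which would
      put most incident draws outside the physiologic range; the default uses
      0.0906 (presumed decimal slip), overridable like every field.
    * ``p_symptom_dx`` holds per-cycle symptom-driven diagnosis probabilities
      calibrated with :func:`copdsim.care_cascade.calibrate_symptom_diagnosis`
      so that status-quo awareness by stage tracks the observed 0.63 / 2.00 /
      12.87 / 21.04 % profile.
    * ``cost_complication_monthly`` is a per-cycle hook for non-exacerbation
      complication costs (e.g. pneumonia); it defaults to zero.
    """

    # --- epidemiology -----------------------------------------------------
    prevalence: dict = field(default_factory=lambda: {
        "male": [0.0186, 0.0745, 0.1557, 0.2708, 0.4296],
        "female": [0.0179, 0.0314, 0.0596, 0.1158, 0.2027],
    })
    # annual incidence per person-year (source prints per 100,000)
    incidence: dict = field(default_factory=lambda: {
        "male": [50.42e-5, 165.64e-5, 442.46e-5, 1053.21e-5, 5056.24e-5],
        "female": [48.50e-5, 69.84e-5, 169.44e-5, 450.33e-5, 2385.55e-5],
    })
    fev1pct_initial: dict = field(default_factory=lambda: {
        "male": (0.797, 0.206), "female": (0.835, 0.206)})
    fev1pct_incident: dict = field(default_factory=lambda: {
        "male": (1.014, 0.0906), "female": (1.034, 0.107)})
    fev1pct_bounds: tuple = (0.05, 1.3)
    initial_diagnosed: list = field(default_factory=lambda: [0.0063, 0.0200, 0.1287, 0.2104])

    # --- natural history --------------------------------------------------
    decline: list = field(default_factory=lambda: [(40.0, 5.0), (60.0, 5.0), (56.0, 5.0), (34.0, 5.0)])
    exac_rate_nonsevere: list = field(default_factory=lambda: [0.71, 1.01, 1.39, 1.82])
    exac_rate_severe: list = field(default_factory=lambda: [0.11, 0.16, 0.22, 0.28])
    exac_decline_multiplier: float = 1.957
    exac_effect_months: float = 12.0
    treat_effect_months: float = 12.0
    mortality_hr: list = field(default_factory=lambda: [1.2, 1.6, 2.7, 2.7])
    life_table: dict = field(default_factory=load_life_table)
    life_table_start_age: int = 35

    # predicted FEV1 reference (liters), linear in age per sex:
    # value_at_35 - slope_per_year * (age - 35)
    predicted_fev1_ref: dict = field(default_factory=lambda: {
        "male": (3.8, 0.028), "female": (2.8, 0.022)})

    # --- screening & care cascade -----------------------------------------
    sq_sens: float = 0.57
    sq_spec: float = 0.82
    spiro_sens: float = 0.85
    spiro_spec: float = 0.85
    p_followup_dx: float = 0.40
    p_treat_uptake: float = 0.30
    # per-cycle symptom-based diagnosis probability by stage, calibrated so
    # status-quo awareness tracks the observed by-stage profile; stage 4 needs
    # a smaller per-cycle probability than stage 3 because much of its
    # awareness is inherited from patients diagnosed at stage 3 who progress
    p_symptom_dx: list = field(default_factory=lambda: [
        0.00021972656249999998, 0.00029296875, 0.009375, 0.00234375])
    treatments: list = field(default_factory=_default_treatments)
    treat_mix: list = field(default_factory=lambda: [
        [0.35, 0.30, 0.20, 0.10, 0.05],
        [0.20, 0.25, 0.25, 0.20, 0.10],
        [0.10, 0.15, 0.25, 0.25, 0.25],
        [0.05, 0.10, 0.20, 0.30, 0.35],
    ])

    # --- utilities ---------------------------------------------------------
    utility_baseline: list = field(default_factory=lambda: [0.956, 0.946, 0.928, 0.910, 0.874])
    utility_stage: list = field(default_factory=lambda: [0.806, 0.767, 0.704, 0.616])
    #: if True, stage utilities act as multipliers on the age baseline,
    #: normalized so the reference band reproduces the absolute values above
    utility_stage_is_multiplier: bool = True
    utility_reference_band: int = 3  # 65-74 band
    disutility_exac_nonsevere: float = 0.010
    disutility_exac_severe: float = 0.040

    # --- costs (2022 USD) ---------------------------------------------------
    cost_sq: float = 0.72
    cost_spiro: float = 2.90
    cost_setup: float = 4.00
    cost_dx_spirometry: float = 26.93
    cost_maint_monthly: list = field(default_factory=lambda: [7.66, 24.25, 34.56, 54.04])
    cost_exac_nonsevere: float = 68.24
    cost_exac_severe: float = 2987.06
    cost_complication_monthly: list = field(default_factory=lambda: [0.0, 0.0, 0.0, 0.0])
    #: charge maintenance only to diagnosed patients (payer sees only
    #: COPD-coded claims) or to every prevalent case
    maintenance_diagnosed_only: bool = False
    #: charge the program setup cost once per person ever screened (True) or
    #: at every screening round (False)
    setup_cost_once: bool = True

    # --- economics / simulation controls ------------------------------------
    discount_rate: float = 0.03
    cycle_years: float = 0.25
    wtp: float = 38441.0
    cohort_size: int = 1_000_000
    age_range: tuple = (35, 80)
    max_age: float = 110.0
    seed_policy: str = "common_random_numbers"

    # --- cohort structure ----------------------------------------------------
    #: population weight of each epidemiology age band (China 2020 census)
    age_band_weights: list = field(default_factory=lambda: [0.130, 0.272, 0.293, 0.194, 0.111])
    #: fraction male within each band
    male_fraction: list = field(default_factory=lambda: [0.511, 0.509, 0.506, 0.497, 0.477])

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any violated invariant."""
        def chk_prob(name, v):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} = {v} must lie in [0, 1]")

        def chk_nonneg(name, v):
            if v < 0:
                raise ValidationError(f"{name} = {v} must be >= 0")

        for name in ("sq_sens", "sq_spec", "spiro_sens", "spiro_spec",
                     "p_followup_dx", "p_treat_uptake",
                     "disutility_exac_nonsevere", "disutility_exac_severe"):
            chk_prob(name, getattr(self, name))
        for sex in ("male", "female"):
            for i, v in enumerate(self.prevalence[sex]):
                chk_prob(f"prevalence[{sex}][{i}]", v)
            for i, v in enumerate(self.incidence[sex]):
                chk_nonneg(f"incidence[{sex}][{i}]", v)
            for i, v in enumerate(self.life_table[sex]):
                chk_prob(f"life_table[{sex}][{i}]", v)
            for arr, label in ((self.prevalence[sex], "prevalence"),
                               (self.incidence[sex], "incidence")):
                if any(b < a for a, b in zip(arr, arr[1:])):
                    warnings.warn(
                        f"{label}[{sex}] is not non-decreasing across age bands",
                        stacklevel=2)
        for i in range(4):
            chk_prob(f"initial_diagnosed[{i}]", self.initial_diagnosed[i])
            chk_prob(f"p_symptom_dx[{i}]", self.p_symptom_dx[i])
            chk_nonneg(f"exac_rate_nonsevere[{i}]", self.exac_rate_nonsevere[i])
            chk_nonneg(f"exac_rate_severe[{i}]", self.exac_rate_severe[i])
            chk_nonneg(f"cost_maint_monthly[{i}]", self.cost_maint_monthly[i])
            chk_nonneg(f"cost_complication_monthly[{i}]", self.cost_complication_monthly[i])
            chk_prob(f"utility_stage[{i}]", self.utility_stage[i])
            if self.mortality_hr[i] < 1.0:
                raise ValidationError(
                    f"mortality_hr[{i}] = {self.mortality_hr[i]} must be >= 1")
            s = sum(self.treat_mix[i])
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"treat_mix[stage {i + 1}] sums to {s}, expected 1")
        for name in ("cost_sq", "cost_spiro", "cost_setup", "cost_dx_spirometry",
                     "cost_exac_nonsevere", "cost_exac_severe", "discount_rate", "wtp"):
            chk_nonneg(name, getattr(self, name))
        for v in self.utility_baseline:
            chk_prob("utility_baseline", v)
        for t in self.treatments:
            chk_nonneg(f"treatment[{t.id}].decline_reduction", t.decline_reduction)
            chk_nonneg(f"treatment[{t.id}].monthly_cost", t.monthly_cost)
            if not (0.0 < t.rr_exac <= 1.0) or not (0.0 < t.rr_mort <= 1.0):
                raise ValidationError(
                    f"treatment[{t.id}] relative risks must lie in (0, 1]")
        if self.cycle_years <= 0:
            raise ValidationError("cycle_years must be > 0")
        if not self.utility_stage_is_multiplier:
            ref = self.utility_baseline[self.utility_reference_band]
            if any(u > ref for u in self.utility_stage):
                raise ValidationError(
                    "absolute stage utilities must not exceed the reference-band baseline")

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict[str, Any] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "treatments":
                v = [t.to_dict() for t in v]
            elif isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, dict):
                v = {k: list(x) if isinstance(x, tuple) else copy.deepcopy(x)
                     for k, x in v.items()}
            else:
                v = copy.deepcopy(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, doc: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(
                f"unknown parameter field(s): {sorted(unknown)}")
        defaults = cls()
        kwargs: dict[str, Any] = {}
        for f in fields(cls):
            if f.name not in doc:
                kwargs[f.name] = getattr(defaults, f.name)
                continue
            v = doc[f.name]
            if f.name == "treatments":
                v = [t if isinstance(t, TreatmentArchetype) else TreatmentArchetype(**t)
                     for t in v]
            elif f.name in ("fev1pct_initial", "fev1pct_incident", "predicted_fev1_ref"):
                v = {k: tuple(x) for k, x in v.items()}
            elif f.name in ("fev1pct_bounds", "age_range"):
                v = tuple(v)
            elif f.name == "decline":
                v = [tuple(x) for x in v]
            kwargs[f.name] = v
        return cls(**kwargs)

    def replace(self, **overrides) -> "ParameterSet":
        """Return a copy with ``overrides`` applied (re-validated)."""
        doc = self.to_dict()
        doc.update(overrides)
        return ParameterSet.from_dict(doc)

    def get_path(self, path: str):
        """Fetch a (possibly nested) parameter by dotted path.

        Examples: ``"p_treat_uptake"``, ``"mortality_hr.2"`` (stage 3),
        ``"prevalence.male.4"``.
        """
        obj: Any = self
        for i, part in enumerate(path.split(".")):
            if i == 0:
                if not hasattr(obj, part):
                    valid = sorted(f.name for f in fields(self))
                    raise KeyError(f"unknown parameter {part!r}; valid top-level "
                                   f"fields: {valid}")
                obj = getattr(obj, part)
            elif isinstance(obj, dict):
                obj = obj[part]
            elif part.lstrip("-").isdigit():
                obj = obj[int(part)]
            else:
                obj = getattr(obj, part)
        return obj

    def set_path(self, path: str, value) -> "ParameterSet":
        """Return a copy with the dotted-path parameter replaced."""
        self.get_path(path)  # raises on unknown path
        doc = self.to_dict()
        parts = path.split(".")
        obj: Any = doc
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) and part in obj else obj[int(part)]
        last = parts[-1]
        if isinstance(obj, dict) and last in obj:
            obj[last] = value
        elif isinstance(obj, dict):
            obj[last] = value
        else:
            obj[int(last)] = value
        return ParameterSet.from_dict(doc)

    def digest(self) -> str:
        """Stable hash of the full parameter tree."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def load_parameters(source: str | dict | None = "defaults") -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``source`` may be the token ``"defaults"`` (or ``None``), a mapping, or a
    path to a YAML/JSON document; unspecified fields take their defaults.
    """
    if source is None or source == "defaults":
        return ParameterSet()
    if isinstance(source, dict):
        return ParameterSet.from_dict(source)
    try:
        with open(source) as f:
            doc = yaml.safe_load(f)
    except FileNotFoundError:
        raise ConfigurationError(f"configuration file not found: {source}") from None
    except yaml.YAMLError as e:
        raise ConfigurationError(f"cannot parse configuration {source}: {e}") from None
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")
    return ParameterSet.from_dict(doc)


# ---------------------------------------------------------------------------
# conversions


def annual_rate_to_cycle_prob(rate, cycle_years):
    """Convert an annual event rate to a per-cycle probability.

    Constant-hazard transform ``1 - exp(-rate * cycle_years)``: monotone in
    the rate and always a valid probability in [0, 1).
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    if cycle_years <= 0:
        raise ValueError("cycle_years must be > 0")
    out = -np.expm1(-rate * cycle_years)
    return float(out) if out.ndim == 0 else out


def annual_prob_to_hazard(q):
    """Annual death probability -> constant hazard ``-ln(1 - q)``."""
    q = np.asarray(q, dtype=float)
    out = -np.log1p(-np.clip(q, 0.0, 1.0 - 1e-12))
    return float(out) if out.ndim == 0 else out


def discount_factor(t, rate):
    """Present-value factor ``(1 + rate)^(-t)`` for time ``t`` in years."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# band lookups (vectorized)

_BAND_EDGES = np.array([b[0] for b in AGE_BANDS[1:]], dtype=float)  # 40, 50, 60, 70
_UBAND_EDGES = np.array([b[0] for b in UTILITY_BANDS[1:]], dtype=float)  # 45, 55, 65, 75


def age_band_index(age):
    """Epidemiology band index (0-4) for an age; ages > 80 reuse band 4."""
    return np.searchsorted(_BAND_EDGES, np.asarray(age, dtype=float), side="right")


def utility_band_index(age):
    """Baseline-utility band index (0-4) for an age."""
    return np.searchsorted(_UBAND_EDGES, np.asarray(age, dtype=float), side="right")
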