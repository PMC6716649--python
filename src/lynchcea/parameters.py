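"""Typed model inputs, scenario overrides and PSA distribution specifications.

Every quantity used by the decision tree, the cohort model and the
cost-effectiveness engine enters through :class:`ParameterSet`, which is loaded
from a flat-namespaced YAML file (see ``data/base_case.yaml``).  Age-indexed
schedules are stored as anchor points and interpolated linearly with flat
extrapolation beyond the anchors.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Any, Iterable, Mapping

import numpy as np
import yaml
from scipy import stats

GENES: tuple[str, ...] = ("MLH1", "MSH2", "MSH6", "PMS2")
STAGES: tuple[str, ...] = ("stage_i", "stage_ii", "stage_iii", "stage_iv")


class ConfigurationError(ValueError):
    """Raised when a configuration file is missing keys or has unknown keys."""


class ValidationError(ValueError):
    """Raised when a parameter violates a domain invariant."""


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} = {value!r} is not a probability in [0, 1]")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValidationError(f"{name} = {value!r} must be nonnegative")


def _interp(age: float, table: Mapping[float, float]) -> float:
    xs = np.array(sorted(table), dtype=float)
    ys = np.array([table[x] for x in sorted(table)], dtype=float)
    return float(np.interp(age, xs, ys))


def _interp_vec(ages: np.ndarray, table: Mapping[float, float]) -> np.ndarray:
    xs = np.array(sorted(table), dtype=float)
    ys = np.array([table[x] for x in sorted(table)], dtype=float)
    return np.interp(ages, xs, ys)


def _take(d: dict, key: str, context: str) -> Any:
    try:
        return d.pop(key)
    except KeyError:
        raise ConfigurationError(f"missing required key {context}.{key}") from None


def _no_extras(d: dict, context: str) -> None:
    if d:
        raise ConfigurationError(f"unknown key(s) under {context}: {sorted(d)}")


def _age_table(raw: Any, context: str) -> dict[float, float]:
    if not isinstance(raw, Mapping) or not raw:
        raise ConfigurationError(f"{context} must be a non-empty age->value mapping")
    return {float(k): float(v) for k, v in raw.items()}


def set_by_path(tree: dict, path: str, value: Any) -> None:
    """Set ``value`` at a dotted ``path`` inside a nested dict ``tree``."""
    parts = path.split(".")
    node = tree
    for p in parts[:-1]:
        if p not in node:
            raise ConfigurationError(f"unknown parameter path {path!r}")
        node = node[p]
    if parts[-1] not in node:
        raise ConfigurationError(f"unknown parameter path {path!r}")
    node[parts[-1]] = value


def get_by_path(tree: Mapping, path: str) -> Any:
    node: Any = tree
    for p in path.split("."):
        node = node[p]
    return node


# ---------------------------------------------------------------------------
# component dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity/failure rate of a tumour triage test."""

    sensitivity: float
    specificity: float
    failure_rate: float

    def validate(self, name: str) -> None:
        for f in fields(self):
            _check_prob(f"{name}.{f.name}", getattr(self, f.name))


@dataclass(frozen=True)
class MethylationAfterDMLH1:
    # sensitivity: P(unmethylated | constitutional MLH1 variant)
    # specificity: P(methylated | no constitutional MLH1 variant)
    sensitivity: float
    specificity: float

    def validate(self, name: str) -> None:
        _check_prob(f"{name}.sensitivity", self.sensitivity)
        _check_prob(f"{name}.specificity", self.specificity)


@dataclass(frozen=True)
class MethylationAfterMSI:
    sensitivity: float
    p_methylated_ls_other: float
    p_methylated_sporadic: float

    def validate(self, name: str) -> None:
        for f in fields(self):
            _check_prob(f"{name}.{f.name}", getattr(self, f.name))


@dataclass
class Population:
    n_probands: int
    relatives_per_proband: int
    proband_age_years: float
    relative_age_years: float
    relative_age_weights: dict[float, float]
    relative_female_share: float
    horizon_age_years: float
    cycle_length_months: float


@dataclass
class Epidemiology:
    prevalence_ls: float
    prevalence_ls_by_age: dict[float, float]
    overall_gene_mix: dict[str, float]
    gene_mix_by_age: dict[float, dict[str, float]]
    ec_mortality_rate_ls_per_1000py: float
    ec_mortality_sporadic_per_1000py_by_age: dict[float, float]
    ec_mortality_window_years: float
    crc_incidence_ls_surveilled_per_1000py: dict[str, dict[float, float]]
    surveillance_incidence_hr: float
    crc_incidence_general_per_1000py_by_age: dict[float, float]
    crc_mortality_per_1000py_by_age: dict[str, dict[float, float]]
    crc_mortality_hr_ls_stage_i_iii: float
    stage_distribution: dict[str, list[float]]
    life_table_per_1000py: dict[str, dict[float, float]]


@dataclass
class Diagnostics:
    ihc: TestPerformance
    msi: TestPerformance
    p_mlh1_pattern_given_positive: dict[str, float]
    methylation_after_dmlh1: MethylationAfterDMLH1
    methylation_after_msi: MethylationAfterMSI
    germline_diagnostic_sensitivity: float
    germline_diagnostic_specificity: float
    predictive_test_accuracy: float
    p_attend_counselling: float
    p_decline_test_given_attend: float
    failure_policy: str
    relative_uptake: float
    relative_uptake_pls: float


@dataclass
class Utilities:
    baseline_by_age: dict[str, dict[float, float]]
    stage_iv_multiplier: float


@dataclass
class Costs:
    ihc: float
    msi: float
    methylation: float
    counselling_offer: float
    relative_referral: float
    pretest_counselling_proband: float
    pretest_counselling_relative: float
    posttest_counselling: float
    diagnostic_test: float
    predictive_test: float
    colonoscopy: float
    colonoscopy_interval_years: float
    crc_management_by_age: dict[str, dict[float, float]]


@dataclass
class Economics:
    discount_rate_annual: float
    wtp_per_qaly_gbp: float


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Validated container for every model input.

    Construct via :func:`load_parameters` (YAML) or :meth:`from_dict`.
    """

    population: Population
    epidemiology: Epidemiology
    diagnostics: Diagnostics
    utilities: Utilities
    costs_gbp: Costs
    economics: Economics

    # -- convenience accessors -------------------------------------------
    @property
    def prevalence_ls(self) -> float:
        return self.epidemiology.prevalence_ls

    @property
    def wtp(self) -> float:
        return self.economics.wtp_per_qaly_gbp

    def prevalence_at(self, age: float) -> float:
        """LS prevalence among EC probands of a given age.

        The by-age curve is rescaled so that its value at the base-case
        proband age equals ``prevalence_ls`` (so scenario overrides of the
        scalar prevalence move the whole curve).
        """
        curve = self.epidemiology.prevalence_ls_by_age
        anchor = _interp(self.population.proband_age_years, curve)
        return _interp(age, curve) * self.epidemiology.prevalence_ls / anchor

    def gene_mix_at(self, age: float) -> np.ndarray:
        table = self.epidemiology.gene_mix_by_age
        ages = sorted(table)
        rows = np.array([[table[a][g] for g in GENES] for a in ages])
        out = np.array([np.interp(age, ages, rows[:, j]) for j in range(4)])
        return out / out.sum()

    def sporadic_ec_mortality_rate(self, age: float) -> float:
        """Annual rate (per person-year) of EC death for sporadic probands."""
        return _interp(age, self.epidemiology.ec_mortality_sporadic_per_1000py_by_age) / 1000.0

    def ls_ec_mortality_rate(self) -> float:
        return self.epidemiology.ec_mortality_rate_ls_per_1000py / 1000.0

    def ls_crc_incidence(self, gene: str, ages: np.ndarray) -> np.ndarray:
        """Annual CRC incidence rate for LS carriers *under surveillance*."""
        return _interp_vec(ages, self.epidemiology.crc_incidence_ls_surveilled_per_1000py[gene]) / 1000.0

    def general_crc_incidence(self, ages: np.ndarray) -> np.ndarray:
        return _interp_vec(ages, self.epidemiology.crc_incidence_general_per_1000py_by_age) / 1000.0

    def crc_mortality_rate(self, ages: np.ndarray, late: bool) -> np.ndarray:
        key = "stage_iv" if late else "stage_i_iii"
        return _interp_vec(ages, self.epidemiology.crc_mortality_per_1000py_by_age[key]) / 1000.0

    def other_cause_mortality(self, ages: np.ndarray, sex: str) -> np.ndarray:
        return _interp_vec(ages, self.epidemiology.life_table_per_1000py[sex]) / 1000.0

    def utility(self, ages: np.ndarray, sex: str) -> np.ndarray:
        return _interp_vec(ages, self.utilities.baseline_by_age[sex])

    def stage_split(self, surveilled: bool) -> np.ndarray:
        key = "surveilled" if surveilled else "unsurveilled"
        return np.asarray(self.epidemiology.stage_distribution[key], dtype=float)

    def crc_cost(self, ages: np.ndarray, stage: str) -> np.ndarray:
        return _interp_vec(ages, self.costs_gbp.crc_management_by_age[stage])

    # -- (de)serialisation -----------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ParameterSet":
        d = copy.deepcopy(dict(raw))

        pop_raw = dict(_take(d, "population", "<root>"))
        pop = Population(
            n_probands=int(_take(pop_raw, "n_probands", "population")),
            relatives_per_proband=int(_take(pop_raw, "relatives_per_proband", "population")),
            proband_age_years=float(_take(pop_raw, "proband_age_years", "population")),
            relative_age_years=float(_take(pop_raw, "relative_age_years", "population")),
            relative_age_weights=_age_table(
                _take(pop_raw, "relative_age_weights", "population"), "population.relative_age_weights"
            ),
            relative_female_share=float(_take(pop_raw, "relative_female_share", "population")),
            horizon_age_years=float(_take(pop_raw, "horizon_age_years", "population")),
            cycle_length_months=float(_take(pop_raw, "cycle_length_months", "population")),
        )
        _no_extras(pop_raw, "population")

        epi_raw = dict(_take(d, "epidemiology", "<root>"))
        gene_mix_raw = _take(epi_raw, "gene_mix_by_age", "epidemiology")
        gene_mix = {
            float(a): {g: float(row[g]) for g in GENES} for a, row in gene_mix_raw.items()
        }
        ls_inc_raw = _take(epi_raw, "crc_incidence_ls_surveilled_per_1000py", "epidemiology")
        epi = Epidemiology(
            prevalence_ls=float(_take(epi_raw, "prevalence_ls", "epidemiology")),
            prevalence_ls_by_age=_age_table(
                _take(epi_raw, "prevalence_ls_by_age", "epidemiology"), "epidemiology.prevalence_ls_by_age"
            ),
            overall_gene_mix={g: float(v) for g, v in _take(epi_raw, "overall_gene_mix", "epidemiology").items()},
            gene_mix_by_age=gene_mix,
            ec_mortality_rate_ls_per_1000py=float(_take(epi_raw, "ec_mortality_rate_ls_per_1000py", "epidemiology")),
            ec_mortality_sporadic_per_1000py_by_age=_age_table(
                _take(epi_raw, "ec_mortality_sporadic_per_1000py_by_age", "epidemiology"),
                "epidemiology.ec_mortality_sporadic_per_1000py_by_age",
            ),
            ec_mortality_window_years=float(_take(epi_raw, "ec_mortality_window_years", "epidemiology")),
            crc_incidence_ls_surveilled_per_1000py={
                g: _age_table(ls_inc_raw[g], f"epidemiology.crc_incidence_ls_surveilled_per_1000py.{g}")
                for g in GENES
            },
            surveillance_incidence_hr=float(_take(epi_raw, "surveillance_incidence_hr", "epidemiology")),
            crc_incidence_general_per_1000py_by_age=_age_table(
                _take(epi_raw, "crc_incidence_general_per_1000py_by_age", "epidemiology"),
                "epidemiology.crc_incidence_general_per_1000py_by_age",
            ),
            crc_mortality_per_1000py_by_age={
                k: _age_table(v, f"epidemiology.crc_mortality_per_1000py_by_age.{k}")
                for k, v in _take(epi_raw, "crc_mortality_per_1000py_by_age", "epidemiology").items()
            },
            crc_mortality_hr_ls_stage_i_iii=float(_take(epi_raw, "crc_mortality_hr_ls_stage_i_iii", "epidemiology")),
            stage_distribution={
                k: [float(x) for x in v]
                for k, v in _take(epi_raw, "stage_distribution", "epidemiology").items()
            },
            life_table_per_1000py={
                k: _age_table(v, f"epidemiology.life_table_per_1000py.{k}")
                for k, v in _take(epi_raw, "life_table_per_1000py", "epidemiology").items()
            },
        )
        _no_extras(epi_raw, "epidemiology")

        diag_raw = dict(_take(d, "diagnostics", "<root>"))
        diag = Diagnostics(
            ihc=TestPerformance(**_take(diag_raw, "ihc", "diagnostics")),
            msi=TestPerformance(**_take(diag_raw, "msi", "diagnostics")),
            p_mlh1_pattern_given_positive={
                k: float(v) for k, v in _take(diag_raw, "p_mlh1_pattern_given_positive", "diagnostics").items()
            },
            methylation_after_dmlh1=MethylationAfterDMLH1(
                **_take(diag_raw, "methylation_after_dmlh1", "diagnostics")
            ),
            methylation_after_msi=MethylationAfterMSI(**_take(diag_raw, "methylation_after_msi", "diagnostics")),
            germline_diagnostic_sensitivity=float(_take(diag_raw, "germline_diagnostic_sensitivity", "diagnostics")),
            germline_diagnostic_specificity=float(_take(diag_raw, "germline_diagnostic_specificity", "diagnostics")),
            predictive_test_accuracy=float(_take(diag_raw, "predictive_test_accuracy", "diagnostics")),
            p_attend_counselling=float(_take(diag_raw, "p_attend_counselling", "diagnostics")),
            p_decline_test_given_attend=float(_take(diag_raw, "p_decline_test_given_attend", "diagnostics")),
            failure_policy=str(_take(diag_raw, "failure_policy", "diagnostics")),
            relative_uptake=float(_take(diag_raw, "relative_uptake", "diagnostics")),
            relative_uptake_pls=float(_take(diag_raw, "relative_uptake_pls", "diagnostics")),
        )
        _no_extras(diag_raw, "diagnostics")

        util_raw = dict(_take(d, "utilities", "<root>"))
        util = Utilities(
            baseline_by_age={
                k: _age_table(v, f"utilities.baseline_by_age.{k}")
                for k, v in _take(util_raw, "baseline_by_age", "utilities").items()
            },
            stage_iv_multiplier=float(_take(util_raw, "stage_iv_multiplier", "utilities")),
        )
        _no_extras(util_raw, "utilities")

        cost_raw = dict(_take(d, "costs_gbp", "<root>"))
        crc_costs_raw = _take(cost_raw, "crc_management_by_age", "costs_gbp")
        costs = Costs(
            crc_management_by_age={
                s: _age_table(crc_costs_raw[s], f"costs_gbp.crc_management_by_age.{s}") for s in STAGES
            },
            **{
                name: float(_take(cost_raw, name, "costs_gbp"))
                for name in (
                    "ihc", "msi", "methylation", "counselling_offer", "relative_referral",
                    "pretest_counselling_proband", "pretest_counselling_relative",
                    "posttest_counselling", "diagnostic_test", "predictive_test",
                    "colonoscopy", "colonoscopy_interval_years",
                )
            },
        )
        _no_extras(cost_raw, "costs_gbp")

        econ_raw = dict(_take(d, "economics", "<root>"))
        econ = Economics(
            discount_rate_annual=float(_take(econ_raw, "discount_rate_annual", "economics")),
            wtp_per_qaly_gbp=float(_take(econ_raw, "wtp_per_qaly_gbp", "economics")),
        )
        _no_extras(econ_raw, "economics")
        _no_extras(d, "<root>")

        ps = cls(
            population=pop, epidemiology=epi, diagnostics=diag,
            utilities=util, costs_gbp=costs, economics=econ,
        )
        ps.validate()
        return ps

    def to_dict(self) -> dict[str, Any]:
        def clean(x: Any) -> Any:
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            if isinstance(x, (TestPerformance, MethylationAfterDMLH1, MethylationAfterMSI)):
                return {f.name: getattr(x, f.name) for f in fields(x)}
            if isinstance(x, (Population, Epidemiology, Diagnostics, Utilities, Costs, Economics)):
                return {f.name: clean(getattr(x, f.name)) for f in fields(x)}
            if isinstance(x, float) and x == int(x) and abs(x) < 1e15:
                return x
            return x

        return {
            "population": clean(self.population),
            "epidemiology": clean(self.epidemiology),
            "diagnostics": clean(self.diagnostics),
            "utilities": clean(self.utilities),
            "costs_gbp": clean(self.costs_gbp),
            "economics": clean(self.economics),
        }

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ParameterSet":
        """Return a new, re-validated ParameterSet with dotted-path overrides."""
        tree = self.to_dict()
        for path, value in overrides.items():
            set_by_path(tree, path, value)
        return ParameterSet.from_dict(tree)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        pop, epi, diag, util, cost, econ = (
            self.population, self.epidemiology, self.diagnostics,
            self.utilities, self.costs_gbp, self.economics,
        )
        if pop.n_probands < 1 or pop.relatives_per_proband < 0:
            raise ValidationError("population sizes must be positive")
        if not (0 <= econ.discount_rate_annual <= 0.2):
            raise ValidationError("discount_rate_annual must lie in [0, 0.2]")
        _check_nonneg("wtp_per_qaly_gbp", econ.wtp_per_qaly_gbp)

        _check_prob("prevalence_ls", epi.prevalence_ls)
        for a, v in epi.prevalence_ls_by_age.items():
            _check_prob(f"prevalence_ls_by_age[{a}]", v)
        mix = np.array([epi.overall_gene_mix[g] for g in GENES])
        if abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
            raise ValidationError("overall_gene_mix must be a probability 4-vector summing to 1")
        ages = sorted(epi.gene_mix_by_age)
        if not ages or ages[0] > 40 or ages[-1] < 85:
            raise ValidationError("gene_mix_by_age must cover proband ages 40-85")
        for a in ages:
            row = np.array([epi.gene_mix_by_age[a][g] for g in GENES])
            if (row < 0).any():
                raise ValidationError(f"gene_mix_by_age[{a}] has negative entries")
            if abs(row.sum() - 1.0) > 5e-3:
                raise ValidationError(f"gene_mix_by_age[{a}] does not sum to 1")
            if abs(row.sum() - 1.0) > 1e-9:  # renormalise printed/rounded rows
                row = row / row.sum()
                epi.gene_mix_by_age[a] = dict(zip(GENES, row.tolist()))
        for key in ("surveilled", "unsurveilled"):
            v = np.asarray(epi.stage_distribution[key])
            if len(v) != 4 or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValidationError(f"stage_distribution.{key} must be a 4-vector summing to 1")
        for name, rate in (
            ("ec_mortality_rate_ls_per_1000py", epi.ec_mortality_rate_ls_per_1000py),
            ("surveillance_incidence_hr", epi.surveillance_incidence_hr),
            ("crc_mortality_hr_ls_stage_i_iii", epi.crc_mortality_hr_ls_stage_i_iii),
        ):
            _check_nonneg(name, rate)
        for tbl_name in (
            "ec_mortality_sporadic_per_1000py_by_age",
            "crc_incidence_general_per_1000py_by_age",
        ):
            for a, v in getattr(epi, tbl_name).items():
                _check_nonneg(f"{tbl_name}[{a}]", v)
        for g in GENES:
            for a, v in epi.crc_incidence_ls_surveilled_per_1000py[g].items():
                _check_nonneg(f"crc_incidence_ls_surveilled[{g}][{a}]", v)
        for k, tbl in epi.crc_mortality_per_1000py_by_age.items():
            for a, v in tbl.items():
                _check_nonneg(f"crc_mortality[{k}][{a}]", v)
        for sex in ("female", "male"):
            if sex not in epi.life_table_per_1000py:
                raise ConfigurationError(f"life_table_per_1000py missing sex {sex!r}")
            for a, v in epi.life_table_per_1000py[sex].items():
                _check_nonneg(f"life_table[{sex}][{a}]", v)

        diag.ihc.validate("ihc")
        diag.msi.validate("msi")
        diag.methylation_after_dmlh1.validate("methylation_after_dmlh1")
        diag.methylation_after_msi.validate("methylation_after_msi")
        for k in ("ls_mlh1", "ls_other", "sporadic"):
            _check_prob(f"p_mlh1_pattern_given_positive.{k}", diag.p_mlh1_pattern_given_positive[k])
        for name in (
            "germline_diagnostic_sensitivity", "germline_diagnostic_specificity",
            "predictive_test_accuracy", "p_attend_counselling",
            "p_decline_test_given_attend", "relative_uptake", "relative_uptake_pls",
        ):
            _check_prob(name, getattr(diag, name))
        if diag.failure_policy not in ("refer", "discharge"):
            raise ValidationError("failure_policy must be 'refer' or 'discharge'")

        _check_prob("stage_iv_multiplier", util.stage_iv_multiplier)
        for sex, tbl in util.baseline_by_age.items():
            for a, v in tbl.items():
                if not (0 <= v <= 1):
                    raise ValidationError(f"utility baseline[{sex}][{a}] outside [0, 1]")

        for f in fields(cost):
            v = getattr(cost, f.name)
            if isinstance(v, float):
                _check_nonneg(f"costs_gbp.{f.name}", v)
        for s in STAGES:
            for a, v in cost.crc_management_by_age[s].items():
                _check_nonneg(f"crc_management_by_age[{s}][{a}]", v)

        weights = np.array(list(pop.relative_age_weights.values()))
        if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-6:
            raise ValidationError("relative_age_weights must be nonnegative and sum to 1")


# ---------------------------------------------------------------------------
# loading / scenarios
# ---------------------------------------------------------------------------

SCENARIOS: dict[str, dict[str, Any]] = {
    # Prevalence restricted to low-dropout studies.
    "low_prevalence": {"epidemiology.prevalence_ls": 0.030},
    # Surveillance effect from the weaker observational estimate.
    "arrigoni_surveillance": {"epidemiology.surveillance_incidence_hr": 0.80},
    # Methylation-after-MSI parameters from the single direct study.
    "hampel_methylation_after_msi": {
        "diagnostics.methylation_after_msi.p_methylated_ls_other": 0.0,
        "diagnostics.methylation_after_msi.p_methylated_sporadic": 0.75,
    },
    # Two-protein IHC panel, 35% cheaper.
    "two_protein_ihc": {"costs_gbp.ihc": 136.5},
    # Only 9% of probands decline the counselling offer.
    "low_counselling_decline": {"diagnostics.p_attend_counselling": 0.91},
}


def packaged_base_case_path() -> str:
    return str(resources.files("lynchcea").joinpath("data/base_case.yaml"))


def load_parameters(config_path: str | None = None, scenario: str | None = None) -> ParameterSet:
    """Load a validated :class:`ParameterSet` from YAML, optionally applying a scenario.

    Parameters
    ----------
    config_path
        Path to a YAML configuration; defaults to the packaged base case.
    scenario
        Name of a scenario in :data:`SCENARIOS` applied on top of the file.
    """
    path = config_path or packaged_base_case_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration file {path!r} did not parse to a mapping")
    if scenario is not None:
        if scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}"
            )
        for p, v in SCENARIOS[scenario].items():
            set_by_path(raw, p, v)
    return ParameterSet.from_dict(raw)


def save_parameters(params: ParameterSet, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    ``family`` is one of ``beta | gamma | lognormal | dirichlet | fixed``;
    ``hyperparameters`` are family-specific (``alpha``/``beta``,
    ``shape``/``scale``, ``mu``/``sigma``, ``alpha`` list, ``value``).
    """

    family: str
    hyperparameters: dict[str, Any]
    correlation_group: str | None = None

    def __post_init__(self) -> None:
        known = {"beta", "gamma", "lognormal", "dirichlet", "fixed"}
        if self.family not in known:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        h = self.hyperparameters
        if self.family == "beta" and (h["alpha"] <= 0 or h["beta"] <= 0):
            raise ValidationError("beta hyperparameters must be positive")
        if self.family == "gamma" and (h["shape"] <= 0 or h["scale"] <= 0):
            raise ValidationError("gamma hyperparameters must be positive")
        if self.family == "lognormal" and h["sigma"] < 0:
            raise ValidationError("lognormal sigma must be nonnegative")
        if self.family == "dirichlet" and any(a <= 0 for a in h["alpha"]):
            raise ValidationError("dirichlet alphas must be positive")

    # -- moment-matching constructors ------------------------------------
    @staticmethod
    def beta_from_mean_se(mean: float, se: float) -> "DistributionSpec":
        if not (0 < mean < 1):
            raise ValidationError("beta mean must be in (0, 1)")
        se = min(se, 0.95 * math.sqrt(mean * (1 - mean)))
        nu = mean * (1 - mean) / se**2 - 1.0
        return DistributionSpec("beta", {"alpha": mean * nu, "beta": (1 - mean) * nu})

    @staticmethod
    def gamma_from_mean_se(mean: float, se: float) -> "DistributionSpec":
        if mean <= 0 or se <= 0:
            raise ValidationError("gamma mean and se must be positive")
        return DistributionSpec("gamma", {"shape": (mean / se) ** 2, "scale": se**2 / mean})

    @staticmethod
    def lognormal_from_mean_se(mean: float, se: float) -> "DistributionSpec":
        sigma2 = math.log1p((se / mean) ** 2)
        return DistributionSpec(
            "lognormal", {"mu": math.log(mean) - sigma2 / 2, "sigma": math.sqrt(sigma2)}
        )

    @staticmethod
    def fixed(value: Any) -> "DistributionSpec":
        return DistributionSpec("fixed", {"value": value})

    # -- sampling / quantiles --------------------------------------------
    def sample(self, rng: np.random.Generator) -> Any:
        h = self.hyperparameters
        if self.family == "fixed":
            return h["value"]
        if self.family == "beta":
            return float(rng.beta(h["alpha"], h["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(h["shape"], h["scale"]))
        if self.family == "lognormal":
            return float(np.exp(rng.normal(h["mu"], h["sigma"])))
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(h["alpha"], dtype=float)).tolist()
        raise AssertionError(self.family)

    def mean(self) -> Any:
        h = self.hyperparameters
        if self.family == "fixed":
            return h["value"]
        if self.family == "beta":
            return h["alpha"] / (h["alpha"] + h["beta"])
        if self.family == "gamma":
            return h["shape"] * h["scale"]
        if self.family == "lognormal":
            return math.exp(h["mu"] + h["sigma"] ** 2 / 2)
        if self.family == "dirichlet":
            a = np.asarray(h["alpha"], dtype=float)
            return (a / a.sum()).tolist()
        raise AssertionError(self.family)


def confidence_limits(spec: DistributionSpec) -> tuple[float, float]:
    """2.5th and 97.5th percentiles of a (scalar) distribution spec."""
    h = spec.hyperparameters
    if spec.family == "fixed":
        raise ValidationError("no uncertainty declared for a fixed parameter")
    if spec.family == "beta":
        dist = stats.beta(h["alpha"], h["beta"])
    elif spec.family == "gamma":
        dist = stats.gamma(h["shape"], scale=h["scale"])
    elif spec.family == "lognormal":
        dist = stats.lognorm(s=h["sigma"], scale=math.exp(h["mu"]))
    else:
        raise ValidationError(f"confidence limits undefined for family {spec.family!r}")
    return float(dist.ppf(0.025)), float(dist.ppf(0.975))


_PROB_PATHS = (
    "epidemiology.prevalence_ls",
    "diagnostics.ihc.sensitivity", "diagnostics.ihc.specificity", "diagnostics.ihc.failure_rate",
    "diagnostics.msi.sensitivity", "diagnostics.msi.specificity", "diagnostics.msi.failure_rate",
    "diagnostics.p_mlh1_pattern_given_positive.ls_mlh1",
    "diagnostics.p_mlh1_pattern_given_positive.ls_other",
    "diagnostics.p_mlh1_pattern_given_positive.sporadic",
    "diagnostics.methylation_after_dmlh1.sensitivity",
    "diagnostics.methylation_after_dmlh1.specificity",
    "diagnostics.methylation_after_msi.sensitivity",
    "diagnostics.methylation_after_msi.p_methylated_ls_other",
    "diagnostics.methylation_after_msi.p_methylated_sporadic",
    "diagnostics.germline_diagnostic_sensitivity",
    "diagnostics.germline_diagnostic_specificity",
    "diagnostics.predictive_test_accuracy",
    "diagnostics.p_attend_counselling",
    "diagnostics.p_decline_test_given_attend",
    "utilities.stage_iv_multiplier",
)
_HR_PATHS = (
    "epidemiology.surveillance_incidence_hr",
    "epidemiology.crc_mortality_hr_ls_stage_i_iii",
)
_COST_PATHS = tuple(
    f"costs_gbp.{n}" for n in (
        "ihc", "msi", "methylation", "counselling_offer", "relative_referral",
        "pretest_counselling_proband", "pretest_counselling_relative",
        "posttest_counselling", "diagnostic_test", "predictive_test", "colonoscopy",
    )
)
_DIRICHLET_PATHS = (
    "epidemiology.stage_distribution.surveilled",
    "epidemiology.stage_distribution.unsurveilled",
    "epidemiology.overall_gene_mix",
)


def default_distribution_specs(
    params: ParameterSet,
    prob_se_frac: float = 0.10,
    cost_se_frac: float = 0.20,
    hr_se_frac: float = 0.15,
    dirichlet_concentration: float = 100.0,
) -> dict[str, DistributionSpec]:
    """Default PSA distributions per parameter class (placeholder hyperparameters).

    Beta for probabilities (SE = 10% of the mean), gamma for costs (SE = 20%),
    lognormal for hazard ratios, dirichlet for the gene mixture and stage
    distributions.  The source model's exact distribution tables are not
    published; everything here is configurable so they can be substituted.
    """
    tree = params.to_dict()
    specs: dict[str, DistributionSpec] = {}
    for p in _PROB_PATHS:
        m = get_by_path(tree, p)
        if m <= 0.0 or m >= 1.0:
            specs[p] = DistributionSpec.fixed(m)
        else:
            specs[p] = DistributionSpec.beta_from_mean_se(m, prob_se_frac * m)
    for p in _HR_PATHS:
        m = get_by_path(tree, p)
        specs[p] = DistributionSpec.lognormal_from_mean_se(m, hr_se_frac * m)
    for p in _COST_PATHS:
        m = get_by_path(tree, p)
        specs[p] = DistributionSpec.gamma_from_mean_se(m, cost_se_frac * m)
    for p in _DIRICHLET_PATHS:
        v = get_by_path(tree, p)
        base = [v[g] for g in GENES] if isinstance(v, dict) else list(v)
        specs[p] = DistributionSpec(
            "dirichlet",
            {"alpha": [dirichlet_concentration * x for x in base]},
            correlation_group=p,
        )
    return specs


def sample_psa_draw(
    params: ParameterSet,
    specs: Mapping[str, DistributionSpec],
    seed: int | np.random.Generator,
) -> ParameterSet:
    """Draw one joint parameter sample; identical seeds give identical draws.

    Dirichlet specs resample probability vectors jointly.  A sampled overall
    gene mixture is propagated to the by-age mixture table by reweighting each
    row by the sampled/base ratio and renormalising.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = params.to_dict()
    base_overall = [params.epidemiology.overall_gene_mix[g] for g in GENES]
    for path in sorted(specs):
        value = specs[path].sample(rng)
        if path == "epidemiology.overall_gene_mix":
            set_by_path(tree, path, dict(zip(GENES, value)))
            ratio = np.asarray(value) / np.asarray(base_overall)
            for a, row in tree["epidemiology"]["gene_mix_by_age"].items():
                new = np.array([row[g] for g in GENES]) * ratio
                new /= new.sum()
                tree["epidemiology"]["gene_mix_by_age"][a] = dict(zip(GENES, new.tolist()))
        else:
            set_by_path(tree, path, value)
    return ParameterSet.from_dict(tree)
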