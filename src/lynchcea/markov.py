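"""Lifetime monthly-cycle cohort model of colorectal cancer outcomes.

States: alive without CRC, CRC stage I-III, CRC stage IV, dead (CRC),
dead (EC), dead (other causes).  Transitions occur midway through each
cycle, implemented with life-table (half-cycle) reward accrual and
mid-cycle discounting.  Competing cause-specific annual rates are converted
to a joint monthly probability and apportioned proportionally to rates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import ParameterSet, ValidationError


class HealthState(enum.IntEnum):
    ALIVE_NO_CRC = 0
    CRC_STAGE_I_III = 1
    CRC_STAGE_IV = 2
    DEAD_CRC = 3
    DEAD_EC = 4
    DEAD_OTHER = 5


N_STATES = len(HealthState)
_ALIVE_STATES = (HealthState.ALIVE_NO_CRC, HealthState.CRC_STAGE_I_III, HealthState.CRC_STAGE_IV)


def rate_to_prob(rate: float | np.ndarray, dt: float) -> float | np.ndarray:
    """Convert a constant event rate (per person-year) over ``dt`` years to a probability."""
    if np.any(np.asarray(rate) < 0):
        raise ValidationError("rates must be nonnegative")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    out = -np.expm1(-np.asarray(rate, dtype=float) * dt)
    return float(out) if np.isscalar(rate) else out


def discount_factor(annual_rate: float, t_months: float | np.ndarray) -> float | np.ndarray:
    """Discount factor at ``t_months`` for an annual discount rate."""
    if np.any(np.asarray(t_months) < 0):
        raise ValidationError("time must be nonnegative")
    out = (1.0 + annual_rate) ** (-np.asarray(t_months, dtype=float) / 12.0)
    return float(out) if np.isscalar(t_months) else out


@dataclass(frozen=True)
class Profile:
    """Who is being simulated: constitutional status, surveillance arm, role, sex."""

    carrier_gene: str | None     # None = no LS variant (general-population CRC risk)
    surveilled: bool
    is_proband: bool
    sex: str                     # "female" | "male"
    entry_age: float             # age at model entry (EC mortality window anchor)

    @property
    def is_ls(self) -> bool:
        return self.carrier_gene is not None


@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy with discounted cost and QALY increments."""

    start_age: float
    occupancy: np.ndarray        # (T+1, 6)
    disc_cost: np.ndarray        # (T,)
    disc_qaly: np.ndarray        # (T,)
    crc_inflow: np.ndarray       # (T, 2) incident flow into early/late CRC

    @property
    def n_cycles(self) -> int:
        return self.disc_cost.shape[0]

    @property
    def total_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def cumulative_crc_incidence(self) -> float:
        return float(self.crc_inflow.sum())

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValidationError("occupancy rows must sum to 1 (drift > 1e-9)")
        if self.occupancy.min() < -1e-12:
            raise ValidationError("negative occupancy")

    def to_frame(self):
        import pandas as pd

        t = np.arange(self.n_cycles + 1)
        df = pd.DataFrame(self.occupancy, columns=[s.name.lower() for s in HealthState])
        df.insert(0, "age", self.start_age + t / 12.0)
        df.insert(0, "cycle", t)
        df["disc_cost"] = np.concatenate([[0.0], self.disc_cost])
        df["disc_qaly"] = np.concatenate([[0.0], self.disc_qaly])
        return df


def _cycle_rates(profile: Profile, ages: np.ndarray, params: ParameterSet) -> dict[str, np.ndarray]:
    epi = params.epidemiology
    if profile.is_ls:
        inc = params.ls_crc_incidence(profile.carrier_gene, ages)
        if not profile.surveilled:
            inc = inc / epi.surveillance_incidence_hr
    else:
        inc = params.general_crc_incidence(ages)
        if profile.surveilled:
            inc = inc * epi.surveillance_incidence_hr

    split = params.stage_split(profile.surveilled)
    frac_late = split[3]

    mort_early = params.crc_mortality_rate(ages, late=False)
    if profile.is_ls:
        mort_early = mort_early * epi.crc_mortality_hr_ls_stage_i_iii
    mort_late = params.crc_mortality_rate(ages, late=True)

    other = params.other_cause_mortality(ages, profile.sex)

    ec = np.zeros_like(ages)
    if profile.is_proband:
        rate = (params.ls_ec_mortality_rate() if profile.is_ls
                else params.sporadic_ec_mortality_rate(profile.entry_age))
        ec[ages < profile.entry_age + epi.ec_mortality_window_years] = rate

    return {
        "inc_early": inc * (1.0 - frac_late),
        "inc_late": inc * frac_late,
        "mort_early": mort_early,
        "mort_late": mort_late,
        "other": other,
        "ec": ec,
    }


def _apportion(rates: list[np.ndarray], dt: float) -> list[np.ndarray]:
    """Joint competing-risk probabilities from cause-specific annual rates."""
    total = sum(rates)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_total = -np.expm1(-total * dt)
        out = [np.where(total > 0, p_total * r / np.where(total > 0, total, 1.0), 0.0)
               for r in rates]
    return out


def _transition_matrices(profile: Profile, ages: np.ndarray, params: ParameterSet) -> np.ndarray:
    dt = params.population.cycle_length_months / 12.0
    r = _cycle_rates(profile, ages, params)
    T = len(ages)
    P = np.zeros((T, N_STATES, N_STATES))

    p_ie, p_il, p_ec0, p_ot0 = _apportion(
        [r["inc_early"], r["inc_late"], r["ec"], r["other"]], dt)
    P[:, 0, 1] = p_ie
    P[:, 0, 2] = p_il
    P[:, 0, 4] = p_ec0
    P[:, 0, 5] = p_ot0
    P[:, 0, 0] = 1.0 - (p_ie + p_il + p_ec0 + p_ot0)

    p_me, p_ec1, p_ot1 = _apportion([r["mort_early"], r["ec"], r["other"]], dt)
    P[:, 1, 3] = p_me
    P[:, 1, 4] = p_ec1
    P[:, 1, 5] = p_ot1
    P[:, 1, 1] = 1.0 - (p_me + p_ec1 + p_ot1)

    p_ml, p_ec2, p_ot2 = _apportion([r["mort_late"], r["ec"], r["other"]], dt)
    P[:, 2, 3] = p_ml
    P[:, 2, 4] = p_ec2
    P[:, 2, 5] = p_ot2
    P[:, 2, 2] = 1.0 - (p_ml + p_ec2 + p_ot2)

    for s in (3, 4, 5):
        P[:, s, s] = 1.0
    return P


def build_transition_matrix(profile: Profile, age: float, params: ParameterSet) -> np.ndarray:
    """One-cycle transition matrix at a given age (row-stochastic)."""
    P = _transition_matrices(profile, np.array([float(age)]), params)[0]
    err = np.abs(P.sum(axis=1) - 1.0).max()
    if err > 1e-9:
        raise ValidationError(f"transition matrix rows fail stochasticity by {err}")
    return P


def run_cohort(profile: Profile, start_age: float, params: ParameterSet) -> CohortTrace:
    """Iterate the cohort monthly from ``start_age`` to the horizon age.

    Rewards use mid-cycle occupancy (mean of successive state vectors) and
    mid-cycle discounting.  One-off CRC management costs are charged on the
    incident flow into the CRC states; colonoscopy costs are charged to
    surveilled alive-without-CRC occupancy as a per-cycle equivalent of one
    colonoscopy per surveillance interval.
    """
    pop, econ, c = params.population, params.economics, params.costs_gbp
    if start_age >= pop.horizon_age_years:
        raise ValidationError("start_age must be below the horizon age")
    months = pop.cycle_length_months
    T = int(round((pop.horizon_age_years - start_age) * 12.0 / months))
    t = np.arange(T)
    ages = start_age + t * months / 12.0

    P = _transition_matrices(profile, ages, params)
    X = np.empty((T + 1, N_STATES))
    X[0] = 0.0
    X[0, HealthState.ALIVE_NO_CRC] = 1.0
    for i in range(T):
        X[i + 1] = X[i] @ P[i]

    occ_mid = 0.5 * (X[:-1] + X[1:])
    disc = discount_factor(econ.discount_rate_annual, (t + 0.5) * months)
    dt_years = months / 12.0

    u = params.utility(ages, profile.sex)
    q_weights = (occ_mid[:, 0] + occ_mid[:, 1]) * u \
        + occ_mid[:, 2] * u * params.utilities.stage_iv_multiplier
    disc_qaly = disc * q_weights * dt_years

    cost = np.zeros(T)
    if profile.surveilled:
        per_cycle = c.colonoscopy * dt_years / c.colonoscopy_interval_years
        cost += occ_mid[:, 0] * per_cycle

    inflow_early = X[:-1, 0] * P[:, 0, 1]
    inflow_late = X[:-1, 0] * P[:, 0, 2]
    split = params.stage_split(profile.surveilled)
    early_total = split[:3].sum()
    if early_total > 0:
        w = split[:3] / early_total
        cost_early = (w[0] * params.crc_cost(ages, "stage_i")
                      + w[1] * params.crc_cost(ages, "stage_ii")
                      + w[2] * params.crc_cost(ages, "stage_iii"))
    else:
        cost_early = np.zeros(T)
    cost += inflow_early * cost_early + inflow_late * params.crc_cost(ages, "stage_iv")

    trace = CohortTrace(
        start_age=start_age,
        occupancy=X,
        disc_cost=disc * cost,
        disc_qaly=disc_qaly,
        crc_inflow=np.stack([inflow_early, inflow_late], axis=1),
    )
    trace.validate()
    return trace


class CohortEngine:
    """Caches cohort traces per (profile, start age) for one ParameterSet."""

    def __init__(self, params: ParameterSet):
        self.params = params
        self._cache: dict[tuple, tuple[float, float]] = {}

    def totals(self, profile: Profile, start_age: float) -> tuple[float, float]:
        key = (profile, round(float(start_age), 6))
        if key not in self._cache:
            tr = run_cohort(profile, start_age, self.params)
            self._cache[key] = (tr.total_cost, tr.total_qalys)
        return self._cache[key]


def lifetime_outcomes(
    arm_mix: Mapping[tuple[Profile, float], float],
    params: ParameterSet,
    engine: CohortEngine | None = None,
) -> tuple[float, float]:
    """Probability-weighted (cost, QALY) totals over (profile, start_age) arms."""
    total_w = sum(arm_mix.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValidationError(f"arm mixture weights sum to {total_w}, not 1")
    engine = engine or CohortEngine(params)
    cost = qaly = 0.0
    for (profile, age), w in arm_mix.items():
        if w == 0.0:
            continue
        ci, qi = engine.totals(profile, age)
        cost += w * ci
        qaly += w * qi
    return cost, qaly
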