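"""Synthetic-data generators with the statistical structure the analysis assumes.

Stand-ins for unavailable source tables: study-level diagnostic-accuracy 2x2
tables with between-study heterogeneity on the logit scale, Gompertz-like
all-cause life tables, and a unimodal endometrial-cancer age-at-diagnosis
distribution for the age-threshold policy analysis.  All generators are pure
functions of their spec (and its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evidence import AccuracyStudy
from .parameters import ValidationError


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    # diagnostic-accuracy generator
    n_studies: int = 30
    mu_sens: float = _logit(0.944)
    mu_spec: float = _logit(0.748)
    tau_sens: float = 0.3
    tau_spec: float = 0.3
    rho: float = -0.2
    n_diseased: int = 150
    n_nondiseased: int = 150
    # life-table generator (Gompertz: rate = a0 * exp(b * age), per person-year)
    gompertz_a0: float = 2.0e-5
    gompertz_b: float = 0.1
    max_age: int = 100
    # EC age-at-diagnosis distribution (truncated normal on integer ages)
    ec_age_min: int = 40
    ec_age_max: int = 85
    ec_age_mode: float = 65.0
    ec_age_sd: float = 9.0

    def __post_init__(self) -> None:
        if self.tau_sens < 0 or self.tau_spec < 0:
            raise ValidationError("tau must be nonnegative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [-1, 1]")
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")


def gen_accuracy_studies(spec: SynthSpec) -> list[AccuracyStudy]:
    """Draw study-level 2x2 tables: logits bivariate-normal, counts binomial."""
    rng = np.random.default_rng(spec.seed)
    cov = np.array([
        [spec.tau_sens**2, spec.rho * spec.tau_sens * spec.tau_spec],
        [spec.rho * spec.tau_sens * spec.tau_spec, spec.tau_spec**2],
    ])
    logits = rng.multivariate_normal([spec.mu_sens, spec.mu_spec], cov, size=spec.n_studies)
    sens = 1.0 / (1.0 + np.exp(-logits[:, 0]))
    specif = 1.0 / (1.0 + np.exp(-logits[:, 1]))
    out = []
    for i in range(spec.n_studies):
        tp = int(rng.binomial(spec.n_diseased, sens[i]))
        tn = int(rng.binomial(spec.n_nondiseased, specif[i]))
        out.append(AccuracyStudy(tp=tp, fn=spec.n_diseased - tp,
                                 tn=tn, fp=spec.n_nondiseased - tn))
    return out


def gen_life_table(spec: SynthSpec) -> dict[float, float]:
    """Annual all-cause mortality rate by age, monotone increasing in adulthood.

    Deterministic given the spec (no sampling).  With the default shape the
    remaining life expectancy at 60 falls in a plausible 20-30 year band.
    """
    return {
        float(a): spec.gompertz_a0 * math.exp(spec.gompertz_b * a)
        for a in range(0, spec.max_age + 1)
    }


def life_expectancy(table: dict[float, float], from_age: float) -> float:
    """Remaining life expectancy implied by an annual-rate table (yearly steps)."""
    ages = sorted(a for a in table if a >= from_age)
    surv = 1.0
    total = 0.0
    for a in ages:
        p_die = 1.0 - math.exp(-table[a])
        total += surv * (1.0 - p_die / 2.0)
        surv *= 1.0 - p_die
    return total


def gen_ec_age_distribution(spec: SynthSpec) -> dict[float, float]:
    """Unimodal age-at-diagnosis weights over the modelled proband ages, summing to 1."""
    ages = np.arange(spec.ec_age_min, spec.ec_age_max + 1, dtype=float)
    w = np.exp(-0.5 * ((ages - spec.ec_age_mode) / spec.ec_age_sd) ** 2)
    w /= w.sum()
    return dict(zip(ages.tolist(), w.tolist()))
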