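"""Links the testing-phase decision tree to lifetime cohort outcomes.

Produces population-level totals (n_probands probands plus their modelled
relatives) per strategy, which feed the cost-effectiveness engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .markov import CohortEngine, Profile
from .parameters import GENES, ParameterSet
from .tree import (STRATEGIES, Strategy, TrueStatus, proband_pathway,
                   relative_cascade)


@dataclass(frozen=True)
class StrategyResult:
    """Population totals for one strategy (probands + relatives)."""

    name: str
    total_cost: float
    total_qalys: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.total_cost) and np.isfinite(self.total_qalys)):
            raise ValueError("strategy totals must be finite")


def _status_weights(params: ParameterSet, proband_age: float) -> list[tuple[TrueStatus, float]]:
    prev = params.prevalence_at(proband_age)
    mix = params.gene_mix_at(proband_age)
    out = [(TrueStatus[f"LS_{g}"], prev * mix[i]) for i, g in enumerate(GENES)]
    out.append((TrueStatus.SPORADIC, 1.0 - prev))
    return out


def _relative_arm_totals(
    gene: str | None,
    surveilled: bool,
    params: ParameterSet,
    engine: CohortEngine,
    relative_ages: Mapping[float, float],
) -> tuple[float, float]:
    """Expected (cost, qaly) for one relative arm, averaged over age and sex."""
    fshare = params.population.relative_female_share
    cost = qaly = 0.0
    for age, w in relative_ages.items():
        for sex, ws in (("female", fshare), ("male", 1.0 - fshare)):
            if w * ws == 0.0:
                continue
            prof = Profile(carrier_gene=gene, surveilled=surveilled,
                           is_proband=False, sex=sex, entry_age=age)
            ci, qi = engine.totals(prof, age)
            cost += w * ws * ci
            qaly += w * ws * qi
    return cost, qaly


def evaluate_strategy(
    strategy: Strategy,
    params: ParameterSet,
    engine: CohortEngine | None = None,
    proband_age: float | None = None,
    relative_ages: Mapping[float, float] | None = None,
) -> StrategyResult:
    """Full tree + Markov evaluation of one strategy.

    Parameters
    ----------
    engine
        Shared trace cache; pass one engine across strategies/ages to reuse
        cohort traces.
    proband_age, relative_ages
        Default to the configured base case (weighted relatives' ages).
    """
    engine = engine or CohortEngine(params)
    pop = params.population
    if proband_age is None:
        proband_age = pop.proband_age_years
    if relative_ages is None:
        relative_ages = pop.relative_age_weights

    cost_pp = 0.0   # per proband, including that proband's relatives
    qaly_pp = 0.0
    for status, w in _status_weights(params, proband_age):
        if w == 0.0:
            continue
        po = proband_pathway(strategy, status, params)

        # proband long-term arms: (P)LS diagnosis -> surveillance
        p_surv = po.p_ls_confirmed + po.p_pls
        cost_s = po.expected_test_cost
        qaly_s = 0.0
        for surveilled, p in ((True, p_surv), (False, po.p_discharged)):
            if p == 0.0:
                continue
            prof = Profile(carrier_gene=status.gene, surveilled=surveilled,
                           is_proband=True, sex="female", entry_age=proband_age)
            ci, qi = engine.totals(prof, proband_age)
            cost_s += p * ci
            qaly_s += p * qi

        casc = relative_cascade(po, status, params)
        rel_cost = casc.expected_cost
        rel_qaly = 0.0
        for (carrier, surveilled), p in casc.arm_probs.items():
            if p == 0.0:
                continue
            gene = status.gene if carrier else None
            ci, qi = _relative_arm_totals(gene, surveilled, params, engine, relative_ages)
            rel_cost += p * ci
            rel_qaly += p * qi

        cost_pp += w * (cost_s + pop.relatives_per_proband * rel_cost)
        qaly_pp += w * (qaly_s + pop.relatives_per_proband * rel_qaly)

    n = pop.n_probands
    return StrategyResult(strategy.name, n * cost_pp, n * qaly_pp)


def evaluate_all(
    params: ParameterSet,
    strategies: Sequence[Strategy] = STRATEGIES,
    engine: CohortEngine | None = None,
    proband_age: float | None = None,
    relative_ages: Mapping[float, float] | None = None,
) -> list[StrategyResult]:
    """Evaluate every strategy with a shared trace cache."""
    engine = engine or CohortEngine(params)
    return [
        evaluate_strategy(s, params, engine, proband_age, relative_ages)
        for s in strategies
    ]
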