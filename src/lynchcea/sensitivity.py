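"""PSA driver, one-way sensitivity analysis, and heterogeneity analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import CohortEngine
from .model import StrategyResult, evaluate_all, evaluate_strategy
from .parameters import (DistributionSpec, ParameterSet, ValidationError,
                         confidence_limits, sample_psa_draw)
from .tree import IHC_METH, NO_TESTING, STRATEGIES, Strategy


@dataclass
class PSAResult:
    """Per-iteration strategy totals from probabilistic sensitivity analysis."""

    names: list[str]
    costs: np.ndarray        # (iterations, strategies)
    qalys: np.ndarray
    seed: int
    n_iterations: int
    n_resampled: int = 0

    def mean_results(self) -> list[StrategyResult]:
        return [StrategyResult(n, float(self.costs[:, j].mean()), float(self.qalys[:, j].mean()))
                for j, n in enumerate(self.names)]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i in range(self.n_iterations):
            for j, n in enumerate(self.names):
                recs.append({"iteration": i, "strategy": n,
                             "total_cost": self.costs[i, j], "total_qalys": self.qalys[i, j]})
        return pd.DataFrame.from_records(recs)


def _psa_relative_ages(params: ParameterSet) -> dict[float, float]:
    # PSA/OWSA fix relatives at the single representative age.
    return {params.population.relative_age_years: 1.0}


def run_psa(
    params: ParameterSet,
    specs: Mapping[str, DistributionSpec],
    n_iter: int,
    seed: int,
    strategies: Sequence[Strategy] = STRATEGIES,
    max_resample_factor: int = 10,
) -> PSAResult:
    """Joint-sampling PSA: each iteration draws all uncertain parameters and
    runs the full tree + Markov evaluation of every strategy.

    Draws failing validation are recorded and resampled (hard cap at
    ``max_resample_factor`` times the requested iterations).
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    rel_ages = _psa_relative_ages(params)
    costs = np.empty((n_iter, len(strategies)))
    qalys = np.empty_like(costs)
    n_resampled = 0
    done = 0
    attempts = 0
    while done < n_iter:
        if attempts >= max_resample_factor * n_iter:
            raise ValidationError("too many invalid PSA draws; check distribution specs")
        attempts += 1
        try:
            draw = sample_psa_draw(params, specs, rng)
        except ValidationError:
            n_resampled += 1
            continue
        res = evaluate_all(draw, strategies, relative_ages=rel_ages)
        costs[done] = [r.total_cost for r in res]
        qalys[done] = [r.total_qalys for r in res]
        done += 1
    return PSAResult(
        names=[s.name for s in strategies], costs=costs, qalys=qalys,
        seed=seed, n_iterations=n_iter, n_resampled=n_resampled,
    )


@dataclass
class OWSAEntry:
    parameter: str
    low_value: float
    high_value: float
    inmb_low: float          # per proband
    inmb_high: float
    inmb_range: float = field(init=False)

    def __post_init__(self) -> None:
        self.inmb_range = abs(self.inmb_high - self.inmb_low)


def _inmb_per_proband(
    params: ParameterSet,
    pair: tuple[Strategy, Strategy],
    lam: float,
    relative_ages: Mapping[float, float],
) -> float:
    engine = CohortEngine(params)
    a = evaluate_strategy(pair[0], params, engine, relative_ages=relative_ages)
    b = evaluate_strategy(pair[1], params, engine, relative_ages=relative_ages)
    dq = a.total_qalys - b.total_qalys
    dc = a.total_cost - b.total_cost
    return (lam * dq - dc) / params.population.n_probands


def owsa(
    params: ParameterSet,
    specs: Mapping[str, DistributionSpec],
    strategy_pair: tuple[Strategy, Strategy] = (IHC_METH, NO_TESTING),
    lam: float | None = None,
    range_filter_frac: float = 0.01,
) -> list[OWSAEntry]:
    """One-way sensitivity analysis at the 95% confidence limits of each parameter.

    Each scalar uncertain parameter is set in turn to its 2.5th and 97.5th
    percentile (others at base case) and the incremental net monetary benefit
    per proband of ``strategy_pair[0]`` versus ``strategy_pair[1]`` is
    recomputed.  Entries are sorted by INMB range (descending) and entries
    below ``range_filter_frac`` of the maximum range are dropped.
    """
    if not specs:
        raise ValidationError("owsa requires a nonempty spec map")
    lam = params.wtp if lam is None else lam
    rel_ages = _psa_relative_ages(params)
    entries: list[OWSAEntry] = []
    for path in sorted(specs):
        spec = specs[path]
        if spec.family in ("fixed", "dirichlet"):
            continue
        lo, hi = confidence_limits(spec)
        inmbs = []
        for v in (lo, hi):
            p = params.with_overrides({path: float(v)})
            inmbs.append(_inmb_per_proband(p, strategy_pair, lam, rel_ages))
        entries.append(OWSAEntry(path, lo, hi, inmbs[0], inmbs[1]))
    entries.sort(key=lambda e: e.inmb_range, reverse=True)
    if entries:
        cutoff = range_filter_frac * entries[0].inmb_range
        entries = [e for e in entries if e.inmb_range >= cutoff]
    return entries


def age_heterogeneity(
    params: ParameterSet,
    ages: Sequence[float] = tuple(range(40, 86)),
    strategies: Sequence[Strategy] = STRATEGIES,
    lam: float | None = None,
) -> pd.DataFrame:
    """Re-evaluate every strategy across proband ages (relatives unchanged).

    Age-appropriate prevalence, gene mixture and EC mortality enter through
    the by-age parameter curves.  Returns long-format rows with incremental
    cost/QALYs and INMB per proband versus no testing.
    """
    lam = params.wtp if lam is None else lam
    engine = CohortEngine(params)   # relative traces shared across ages
    n = params.population.n_probands
    recs = []
    for age in ages:
        res = evaluate_all(params, strategies, engine, proband_age=float(age))
        base = next(r for r in res if r.name == NO_TESTING.name)
        for r in res:
            dc = r.total_cost - base.total_cost
            dq = r.total_qalys - base.total_qalys
            recs.append({
                "age": float(age), "strategy": r.name,
                "total_cost": r.total_cost, "total_qalys": r.total_qalys,
                "inc_cost_vs_none": dc, "inc_qalys_vs_none": dq,
                "inmb_per_proband": (lam * dq - dc) / n,
            })
    return pd.DataFrame.from_records(recs)


def age_threshold_policy(
    params: ParameterSet,
    ec_age_distribution: Mapping[float, float],
    thresholds: Sequence[float],
    strategy: Strategy = IHC_METH,
    lam: float | None = None,
    per_age_inmb: Mapping[float, float] | None = None,
) -> pd.DataFrame:
    """Population INMB of testing only probands at or below an age threshold.

    For each threshold T the population INMB is the EC-age-distribution
    weighted sum of per-age INMB over ages <= T (unweighted ages contribute
    nothing: those probands are simply not tested).  Weights must sum to 1
    over the modelled ages.
    """
    weights = {float(a): float(w) for a, w in ec_age_distribution.items()}
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9 or any(w < 0 for w in weights.values()):
        raise ValidationError("EC age distribution must be nonnegative and sum to 1")
    if per_age_inmb is None:
        het = age_heterogeneity(params, ages=sorted(weights), strategies=(NO_TESTING, strategy), lam=lam)
        sub = het[het.strategy == strategy.name]
        per_age_inmb = dict(zip(sub.age, sub.inmb_per_proband))
    recs = []
    for t in thresholds:
        val = sum(w * per_age_inmb[a] for a, w in weights.items() if a <= t)
        recs.append({"threshold": float(t), "population_inmb_per_proband": val})
    df = pd.DataFrame.from_records(recs)
    df["is_argmax"] = df.population_inmb_per_proband == df.population_inmb_per_proband.max()
    return df
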