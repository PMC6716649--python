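"""Cost-effectiveness engine: ICERs, dominance frontier, NMB, CEAC."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import StrategyResult

DOMINANT = "DOMINANT"
DOMINATED = "DOMINATED"
EXTENDEDLY_DOMINATED = "EXTENDEDLY_DOMINATED"
ON_FRONTIER = "ON_FRONTIER"
COMPARATOR = "COMPARATOR"
UNDEFINED = "UNDEFINED"


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance flag.

    Returns the ratio when the QALY difference is positive (or when both
    differences are negative, the south-west quadrant); ``DOMINANT`` when
    cheaper and more effective; ``DOMINATED`` when dearer and no more
    effective; ``UNDEFINED`` when both differences are zero.
    """
    if delta_qaly == 0.0 and delta_cost == 0.0:
        return UNDEFINED
    if delta_qaly > 0.0:
        return DOMINANT if delta_cost < 0.0 else delta_cost / delta_qaly
    if delta_qaly == 0.0:
        return DOMINANT if delta_cost < 0.0 else DOMINATED
    return DOMINATED if delta_cost >= 0.0 else delta_cost / delta_qaly


def round_3sf(x: float) -> float:
    """Round to 3 significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + 2)


def nmb(result: StrategyResult, comparator: StrategyResult, lam: float) -> float:
    """Net monetary benefit of ``result`` versus ``comparator`` at threshold ``lam``."""
    if lam < 0:
        raise ValueError("willingness-to-pay threshold must be nonnegative")
    return lam * (result.total_qalys - comparator.total_qalys) \
        - (result.total_cost - comparator.total_cost)


@dataclass
class CEARow:
    name: str
    total_cost: float
    total_qalys: float
    inc_cost_vs_comparator: float
    inc_qalys_vs_comparator: float
    icer_vs_comparator: float | str
    label: str
    frontier_icer: float | None = None
    note: str = ""


@dataclass
class CEATable:
    rows: list[CEARow]
    comparator: str

    def row(self, name: str) -> CEARow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def frontier(self) -> list[str]:
        return [r.name for r in self.rows if r.label in (ON_FRONTIER, COMPARATOR)]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            icer_num = r.icer_vs_comparator if isinstance(r.icer_vs_comparator, float) else np.nan
            recs.append({
                "strategy": r.name,
                "total_cost": r.total_cost,
                "total_qalys": r.total_qalys,
                "inc_cost_vs_none": r.inc_cost_vs_comparator,
                "inc_qalys_vs_none": r.inc_qalys_vs_comparator,
                "icer_vs_none": icer_num,
                "icer_vs_none_3sf": round_3sf(icer_num) if np.isfinite(icer_num) else np.nan,
                "frontier_label": r.label,
                "fully_incremental_icer": r.frontier_icer if r.frontier_icer is not None else np.nan,
                "fully_incremental_icer_3sf": (round_3sf(r.frontier_icer)
                                               if r.frontier_icer is not None else np.nan),
                "note": r.note,
            })
        return pd.DataFrame.from_records(recs)


def frontier(results: Sequence[StrategyResult]) -> CEATable:
    """Fully incremental analysis with strict and extended dominance.

    Strategies are sorted by cost; strictly dominated options (another option
    no dearer and no less effective, one strictly) are removed, then options
    whose ICER to the next frontier member exceeds that member's onward ICER
    are removed as extendedly dominated until frontier ICERs increase
    monotonically.  Exact cost/QALY ties keep the earlier-listed strategy.
    """
    if len(results) < 2:
        raise ValueError("frontier requires at least 2 strategies")
    names = [r.name for r in results]
    if len(set(names)) != len(names):
        raise ValueError("strategy names must be unique")

    labels: dict[str, str] = {}
    notes: dict[str, str] = {}

    for i, a in enumerate(results):
        for j, b in enumerate(results):
            if i == j or a.name in labels:
                continue
            tie = (b.total_cost == a.total_cost and b.total_qalys == a.total_qalys)
            if tie:
                if j < i:
                    labels[a.name] = DOMINATED
                    notes[a.name] = f"exact tie with {b.name}; earlier-listed kept"
            elif (b.total_cost <= a.total_cost and b.total_qalys >= a.total_qalys):
                labels[a.name] = DOMINATED

    order = sorted(range(len(results)), key=lambda i: (results[i].total_cost, i))
    candidates = [results[i] for i in order if results[i].name not in labels]

    while True:
        icers = [
            (candidates[k + 1].total_cost - candidates[k].total_cost)
            / (candidates[k + 1].total_qalys - candidates[k].total_qalys)
            for k in range(len(candidates) - 1)
        ]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] > icers[k + 1]:
                labels[candidates[k + 1].name] = EXTENDEDLY_DOMINATED
                del candidates[k + 1]
                removed = True
                break
        if not removed:
            break

    comparator = candidates[0]
    labels[comparator.name] = COMPARATOR
    frontier_icers: dict[str, float] = {}
    for k in range(1, len(candidates)):
        a, b = candidates[k - 1], candidates[k]
        frontier_icers[b.name] = (b.total_cost - a.total_cost) / (b.total_qalys - a.total_qalys)
        labels[b.name] = ON_FRONTIER

    rows = []
    for r in results:
        dc = r.total_cost - comparator.total_cost
        dq = r.total_qalys - comparator.total_qalys
        rows.append(CEARow(
            name=r.name, total_cost=r.total_cost, total_qalys=r.total_qalys,
            inc_cost_vs_comparator=dc, inc_qalys_vs_comparator=dq,
            icer_vs_comparator=icer(dc, dq),
            label=labels.get(r.name, ON_FRONTIER),
            frontier_icer=frontier_icers.get(r.name),
            note=notes.get(r.name, ""),
        ))
    return CEATable(rows=rows, comparator=comparator.name)


def ceac(
    costs: np.ndarray,
    qalys: np.ndarray,
    lambdas: Sequence[float],
    names: Sequence[str],
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA iterations.

    ``costs``/``qalys`` are (iterations x strategies).  For each threshold the
    fraction of iterations in which each strategy attains maximal NMB is
    returned (exact NMB ties split equally), long format with columns
    ``lambda``, ``strategy``, ``probability``.
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if costs.ndim != 2 or costs.shape != qalys.shape or costs.shape[0] < 1:
        raise ValueError("costs and qalys must be equal-shape (iterations x strategies)")
    if costs.shape[1] != len(names):
        raise ValueError("names must match the strategy axis")
    recs = []
    for lam in lambdas:
        if lam < 0:
            raise ValueError("lambda values must be nonnegative")
        net = lam * qalys - costs
        best = net.max(axis=1, keepdims=True)
        tie = net == best
        frac = (tie / tie.sum(axis=1, keepdims=True)).mean(axis=0)
        for j, name in enumerate(names):
            recs.append({"lambda": float(lam), "strategy": name, "probability": float(frac[j])})
    return pd.DataFrame.from_records(recs)
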