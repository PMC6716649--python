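"""Evidence-synthesis computations used to construct model inputs.

Implements the bivariate random-effects meta-analysis of diagnostic
sensitivity/specificity (Reitsma-style: study-level logits drawn from a
bivariate normal, within-study variability approximated by a normal on the
logit scale), random-effects pooling of proportions, and the age-specific
mismatch-repair gene mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .parameters import GENES, ValidationError


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class AccuracyStudy:
    """One study's 2x2 diagnostic-accuracy table."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("2x2 counts must be nonnegative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.tn + self.fp

    def logits(self) -> tuple[float, float, float, float]:
        """(logit sens, logit spec, var sens, var spec) with 0.5 correction on zero cells."""
        tp, fn = float(self.tp), float(self.fn)
        tn, fp = float(self.tn), float(self.fp)
        if tp == 0 or fn == 0:
            tp, fn = tp + 0.5, fn + 0.5
        if tn == 0 or fp == 0:
            tn, fp = tn + 0.5, fp + 0.5
        return (
            math.log(tp / fn),
            math.log(tn / fp),
            1.0 / tp + 1.0 / fn,
            1.0 / tn + 1.0 / fp,
        )


@dataclass(frozen=True)
class BivariateFit:
    pooled_sens: float
    pooled_spec: float
    mu: np.ndarray            # logit-scale means (2,)
    sigma: np.ndarray         # between-study covariance (2, 2)
    converged: bool
    n_studies: int
    log_likelihood: float
    message: str = ""


def fit_bivariate(
    studies: Sequence[AccuracyStudy], rho_zero: bool = False
) -> BivariateFit:
    """Maximum-likelihood fit of the bivariate logit-normal accuracy model.

    Parameters
    ----------
    studies
        At least three studies, each with >=1 diseased and >=1 non-diseased
        subject.
    rho_zero
        Constrain the between-study correlation to zero (two independent
        univariate logit-normal poolings share this likelihood when data are
        balanced; used for oracle comparisons).

    Returns
    -------
    BivariateFit
        Pooled estimates are the inverse-logits of the fitted means.  A
        failed optimisation is returned with ``converged=False`` rather than
        raising, so diagnostics are never silently discarded.
    """
    if len(studies) < 3:
        raise ValidationError("bivariate meta-analysis requires at least 3 studies")
    for s in studies:
        if s.n_diseased < 1 or s.n_nondiseased < 1:
            raise ValidationError("each study needs >=1 diseased and >=1 non-diseased subject")

    y = np.array([s.logits()[:2] for s in studies])          # (k, 2)
    s2 = np.array([s.logits()[2:] for s in studies])         # (k, 2) within-study vars

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = theta[:2]
        t1, t2 = np.exp(np.clip(theta[2:4], -10, 5))
        rho = 0.0 if rho_zero else math.tanh(theta[4])
        sigma = np.array([[t1**2, rho * t1 * t2], [rho * t1 * t2, t2**2]])
        return mu, sigma

    def nll(theta: np.ndarray) -> float:
        mu, sigma = unpack(theta)
        total = 0.0
        for i in range(len(studies)):
            v = sigma + np.diag(s2[i])
            det = v[0, 0] * v[1, 1] - v[0, 1] ** 2
            if det <= 0:
                return 1e12
            r = y[i] - mu
            quad = (v[1, 1] * r[0] ** 2 - 2 * v[0, 1] * r[0] * r[1] + v[0, 0] * r[1] ** 2) / det
            total += 0.5 * (math.log(det) + quad)
        return total

    start = np.array([y[:, 0].mean(), y[:, 1].mean(),
                      math.log(max(y[:, 0].std(), 0.05)),
                      math.log(max(y[:, 1].std(), 0.05)), 0.0])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    mu, sigma = unpack(res.x)
    return BivariateFit(
        pooled_sens=_expit(mu[0]),
        pooled_spec=_expit(mu[1]),
        mu=mu,
        sigma=sigma,
        converged=bool(res.success),
        n_studies=len(studies),
        log_likelihood=-float(res.fun),
        message=str(res.message),
    )


@dataclass(frozen=True)
class PooledProportion:
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    n_studies: int


def pool_proportion(events: Sequence[int], totals: Sequence[int]) -> PooledProportion:
    """Random-effects (DerSimonian-Laird) pooling of proportions on the logit scale.

    A single study reduces to the crude proportion.  The 0.5 continuity
    correction is applied only to studies with zero or all events.
    """
    if len(events) == 0:
        raise ValidationError("pool_proportion requires at least one study")
    if len(events) != len(totals):
        raise ValidationError("events and totals must have equal length")
    for e, n in zip(events, totals):
        if e < 0 or n <= 0 or e > n:
            raise ValidationError("each study needs 0 <= events <= total, total > 0")

    if len(events) == 1:
        p = events[0] / totals[0]
        lo, hi = stats.beta.ppf([0.025, 0.975], events[0] + 0.5, totals[0] - events[0] + 0.5)
        return PooledProportion(p, float(lo), float(hi), 0.0, 1)

    ys, vs = [], []
    for e, n in zip(events, totals):
        a, b = float(e), float(n - e)
        if a == 0 or b == 0:
            a, b = a + 0.5, b + 0.5
        ys.append(math.log(a / b))
        vs.append(1.0 / a + 1.0 / b)
    ys, vs = np.array(ys), np.array(vs)

    w = 1.0 / vs
    y_fixed = (w * ys).sum() / w.sum()
    q = (w * (ys - y_fixed) ** 2).sum()
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (len(ys) - 1)) / c)

    w_re = 1.0 / (vs + tau2)
    y_re = (w_re * ys).sum() / w_re.sum()
    se = math.sqrt(1.0 / w_re.sum())
    z = 1.959963984540054
    return PooledProportion(
        _expit(y_re), _expit(y_re - z * se), _expit(y_re + z * se), tau2, len(ys)
    )


def gene_mix_at_age(
    overall_mix: Mapping[str, float] | Sequence[float],
    gene_incidence_curves: Mapping[str, Mapping[float, float]],
) -> dict[float, np.ndarray]:
    """Age-specific gene mixture by Bayes' rule.

    At each tabulated age ``a`` the share of gene ``g`` is proportional to
    ``overall_mix[g] * incidence_g(a)`` and rows are normalised to sum to 1.
    """
    if isinstance(overall_mix, Mapping):
        mix = np.array([overall_mix[g] for g in GENES], dtype=float)
    else:
        mix = np.asarray(overall_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValidationError("overall_mix must be a probability vector summing to 1")
    ages = sorted(set().union(*(set(c) for c in gene_incidence_curves.values())))
    out: dict[float, np.ndarray] = {}
    for a in ages:
        inc = np.array([gene_incidence_curves[g].get(a, 0.0) for g in GENES])
        if (inc < 0).any():
            raise ValidationError(f"negative incidence at age {a}")
        raw = mix * inc
        total = raw.sum()
        if total <= 0:
            raise ValidationError(f"zero total incidence at age {a}")
        out[float(a)] = raw / total
    return out


def read_accuracy_studies(path: str) -> list[AccuracyStudy]:
    """Read study tables from CSV (columns study_id, tp, fn, tn, fp)."""
    df = pd.read_csv(path)
    return [AccuracyStudy(tp=int(r.tp), fn=int(r.fn), tn=int(r.tn), fp=int(r.fp))
            for r in df.itertuples()]


def load_packaged_gene_curves() -> dict[str, dict[float, float]]:
    """Relative EC incidence curves per gene (calibrated to the mixture table)."""
    path = resources.files("lynchcea").joinpath("data/gene_ec_incidence_curves.csv")
    df = pd.read_csv(str(path))
    out: dict[str, dict[float, float]] = {g: {} for g in GENES}
    for r in df.itertuples():
        out[r.gene][float(r.age)] = float(r.rate)
    return out
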