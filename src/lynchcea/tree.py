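"""Diagnostic decision tree for probands and the relatives' cascade.

For each testing strategy and true constitutional status the tree yields an
exact expected distribution over diagnostic categories (LS confirmed,
putative LS, discharged), expected testing-phase costs and test counts, by
exhaustive enumeration of branch products.

Putative LS (PLS) requires tumour-based evidence: a mutation-negative (or
untested-carrier-negative) woman is classed PLS only under a tumour-test
strategy whose triage she screened positive on.  Under direct referral a
negative diagnostic test discharges.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .parameters import ParameterSet, ValidationError


class TrueStatus(enum.Enum):
    LS_MLH1 = "LS_MLH1"
    LS_MSH2 = "LS_MSH2"
    LS_MSH6 = "LS_MSH6"
    LS_PMS2 = "LS_PMS2"
    SPORADIC = "SPORADIC"

    @property
    def is_ls(self) -> bool:
        return self is not TrueStatus.SPORADIC

    @property
    def gene(self) -> str | None:
        return None if self is TrueStatus.SPORADIC else self.value[3:]


LS_STATUSES = tuple(s for s in TrueStatus if s.is_ls)


@dataclass(frozen=True)
class Strategy:
    """One of the six testing policies, described by its topology switches."""

    name: str
    tumour_test: str          # "ihc" | "msi" | "none"
    methylation_triage: bool
    direct_referral: bool

    def __post_init__(self) -> None:
        if self.tumour_test not in ("ihc", "msi", "none"):
            raise ValidationError(f"unknown tumour test {self.tumour_test!r}")
        if self.direct_referral and (self.tumour_test != "none" or self.methylation_triage):
            raise ValidationError("direct referral excludes tumour and methylation testing")
        if self.methylation_triage and self.tumour_test == "none":
            raise ValidationError("methylation triage requires a tumour test")


NO_TESTING = Strategy("NO_TESTING", "none", False, False)
IHC = Strategy("IHC", "ihc", False, False)
IHC_METH = Strategy("IHC_METH", "ihc", True, False)
MSI = Strategy("MSI", "msi", False, False)
MSI_METH = Strategy("MSI_METH", "msi", True, False)
DIRECT = Strategy("DIRECT", "none", False, True)

STRATEGIES: tuple[Strategy, ...] = (NO_TESTING, IHC, IHC_METH, MSI, MSI_METH, DIRECT)
STRATEGY_BY_NAME = {s.name: s for s in STRATEGIES}


@dataclass
class PathwayOutcome:
    """Per-proband expected outcome of the testing phase."""

    p_ls_confirmed: float
    p_pls: float
    p_discharged: float
    expected_test_cost: float
    n_tumour_tests: float = 0.0
    n_methylation_tests: float = 0.0
    n_counselling_sessions: float = 0.0
    n_germline_tests: float = 0.0

    @property
    def p_diag(self) -> dict[str, float]:
        return {"LS_CONFIRMED": self.p_ls_confirmed, "PLS": self.p_pls,
                "DISCHARGED": self.p_discharged}

    def validate(self) -> None:
        total = self.p_ls_confirmed + self.p_pls + self.p_discharged
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"diagnostic categories sum to {total}, not 1")
        for v in (self.p_ls_confirmed, self.p_pls, self.p_discharged):
            if v < -1e-15:
                raise ValidationError("negative branch probability")
        if self.expected_test_cost < 0:
            raise ValidationError("negative expected cost")


def proband_pathway(strategy: Strategy, status: TrueStatus, params: ParameterSet) -> PathwayOutcome:
    """Expected diagnostic outcome of one proband under a strategy.

    Branch structure: tumour triage (with a failure branch handled per
    ``failure_policy``; failed tests carry no staining pattern so skip
    methylation) -> MLH1 staining-pattern split (IHC) -> methylation triage
    -> counselling offer/attendance -> test acceptance -> diagnostic
    germline test.
    """
    if not isinstance(strategy, Strategy) or not isinstance(status, TrueStatus):
        raise ValidationError("unknown strategy or status")
    d, c = params.diagnostics, params.costs_gbp
    is_ls = status.is_ls

    if strategy.name == "NO_TESTING":
        return PathwayOutcome(0.0, 0.0, 1.0, 0.0)

    cost = 0.0
    n_tumour = n_meth = 0.0

    if strategy.direct_referral:
        p_refer = 1.0
        tumour_evidence = False
    else:
        perf = d.ihc if strategy.tumour_test == "ihc" else d.msi
        f = perf.failure_rate
        p_pos_valid = (1.0 - f) * (perf.sensitivity if is_ls else 1.0 - perf.specificity)
        cost += c.ihc if strategy.tumour_test == "ihc" else c.msi
        n_tumour = 1.0

        if strategy.methylation_triage:
            if strategy.tumour_test == "ihc":
                key = ("ls_mlh1" if status is TrueStatus.LS_MLH1
                       else "ls_other" if is_ls else "sporadic")
                q = d.p_mlh1_pattern_given_positive[key]
                meth = d.methylation_after_dmlh1
                # unmethylated -> continue; methylated -> discharged as sporadic
                p_unmeth = (meth.sensitivity if status is TrueStatus.LS_MLH1
                            else 1.0 - meth.specificity)
                p_continue_valid = p_pos_valid * ((1.0 - q) + q * p_unmeth)
                p_meth_tested = p_pos_valid * q
            else:
                meth = d.methylation_after_msi
                if status is TrueStatus.LS_MLH1:
                    p_unmeth = meth.sensitivity
                elif is_ls:
                    p_unmeth = 1.0 - meth.p_methylated_ls_other
                else:
                    p_unmeth = 1.0 - meth.p_methylated_sporadic
                p_continue_valid = p_pos_valid * p_unmeth
                p_meth_tested = p_pos_valid
            cost += p_meth_tested * c.methylation
            n_meth = p_meth_tested
        else:
            p_continue_valid = p_pos_valid

        p_fail_continue = f if d.failure_policy == "refer" else 0.0
        p_refer = p_continue_valid + p_fail_continue
        tumour_evidence = True

    # referral stage (shared by all testing strategies)
    p_attend = p_refer * d.p_attend_counselling
    p_tested = p_attend * (1.0 - d.p_decline_test_given_attend)
    cost += p_refer * c.counselling_offer
    cost += p_attend * c.pretest_counselling_proband
    cost += p_tested * (c.diagnostic_test + c.posttest_counselling)

    if is_ls:
        p_conf = p_tested * d.germline_diagnostic_sensitivity
        p_neg = p_tested - p_conf
    else:
        p_conf = p_tested * (1.0 - d.germline_diagnostic_specificity)
        p_neg = p_tested - p_conf

    p_pls = p_neg if tumour_evidence else 0.0
    p_disch = 1.0 - p_conf - p_pls

    out = PathwayOutcome(
        p_ls_confirmed=p_conf, p_pls=p_pls, p_discharged=p_disch,
        expected_test_cost=cost, n_tumour_tests=n_tumour,
        n_methylation_tests=n_meth, n_counselling_sessions=p_attend,
        n_germline_tests=p_tested,
    )
    out.validate()
    return out


@dataclass
class CascadeOutcome:
    """Per-relative expected cost and long-term arm probabilities.

    ``arm_probs`` maps (carrier?, surveilled?) to probability; carrier arms
    refer to the proband's gene.  Probabilities sum to 1 (every relative is
    always modelled, reached or not).
    """

    expected_cost: float
    arm_probs: dict[tuple[bool, bool], float] = field(default_factory=dict)
    n_predictive_tests: float = 0.0

    def validate(self) -> None:
        total = sum(self.arm_probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"cascade arm probabilities sum to {total}")


def relative_cascade(
    proband_outcome: PathwayOutcome, status: TrueStatus, params: ParameterSet
) -> CascadeOutcome:
    """Expected cascade outcome for one first-degree relative.

    A confirmed-LS proband triggers referral, pre-test counselling and a
    predictive test (assumed perfectly accurate); carriers (Mendelian
    probability 1/2) enter surveillance.  A PLS proband triggers counselling
    plus surveillance without a germline test, thinned by the PLS cascade
    uptake.  A discharged proband triggers no contact.
    """
    d, c = params.diagnostics, params.costs_gbp
    p_carrier = 0.5 if status.is_ls else 0.0
    pc, pp, pd_ = proband_outcome.p_ls_confirmed, proband_outcome.p_pls, proband_outcome.p_discharged

    cost = 0.0
    arms = {(True, True): 0.0, (True, False): 0.0, (False, True): 0.0, (False, False): 0.0}

    u = d.relative_uptake
    cost += pc * u * (c.relative_referral + c.pretest_counselling_relative
                      + c.predictive_test + c.posttest_counselling)
    arms[(True, True)] += pc * u * p_carrier
    arms[(False, False)] += pc * u * (1.0 - p_carrier)
    arms[(True, False)] += pc * (1.0 - u) * p_carrier
    arms[(False, False)] += pc * (1.0 - u) * (1.0 - p_carrier)

    up = d.relative_uptake_pls
    cost += pp * up * (c.relative_referral + c.pretest_counselling_relative)
    arms[(True, True)] += pp * up * p_carrier
    arms[(False, True)] += pp * up * (1.0 - p_carrier)
    arms[(True, False)] += pp * (1.0 - up) * p_carrier
    arms[(False, False)] += pp * (1.0 - up) * (1.0 - p_carrier)

    arms[(True, False)] += pd_ * p_carrier
    arms[(False, False)] += pd_ * (1.0 - p_carrier)

    out = CascadeOutcome(expected_cost=cost, arm_probs=arms,
                         n_predictive_tests=pc * u)
    out.validate()
    return out
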