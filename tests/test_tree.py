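import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynchcea.parameters import ValidationError
from lynchcea.tree import (DIRECT, IHC, IHC_METH, MSI, MSI_METH, NO_TESTING,
                           STRATEGIES, LS_STATUSES, PathwayOutcome, Strategy,
                           TrueStatus, proband_pathway, relative_cascade)
from conftest import modify


# ---------------------------------------------------------------------------
# independent brute-force path walker (oracle)
# ---------------------------------------------------------------------------

def walk_paths(strategy, status, params):
    """Enumerate every terminal path as (probability, cost, label) tuples."""
    d, c = params.diagnostics, params.costs_gbp
    paths = []

    def referral(prob, cost, tumour_evidence):
        if prob == 0.0:
            return
        cost = cost + c.counselling_offer
        paths.append((prob * (1 - d.p_attend_counselling), cost, "DISCHARGED"))
        p_att = prob * d.p_attend_counselling
        cost_att = cost + c.pretest_counselling_proband
        paths.append((p_att * d.p_decline_test_given_attend, cost_att, "DISCHARGED"))
        p_test = p_att * (1 - d.p_decline_test_given_attend)
        cost_test = cost_att + c.diagnostic_test + c.posttest_counselling
        if status.is_ls:
            p_pos = d.germline_diagnostic_sensitivity
        else:
            p_pos = 1 - d.germline_diagnostic_specificity
        paths.append((p_test * p_pos, cost_test, "LS_CONFIRMED"))
        neg_label = "PLS" if tumour_evidence else "DISCHARGED"
        paths.append((p_test * (1 - p_pos), cost_test, neg_label))

    if strategy.name == "NO_TESTING":
        paths.append((1.0, 0.0, "DISCHARGED"))
    elif strategy.direct_referral:
        referral(1.0, 0.0, tumour_evidence=False)
    else:
        perf = d.ihc if strategy.tumour_test == "ihc" else d.msi
        test_cost = c.ihc if strategy.tumour_test == "ihc" else c.msi
        f = perf.failure_rate
        p_pos = perf.sensitivity if status.is_ls else 1 - perf.specificity

        # failed tumour test: no staining pattern, no methylation
        if d.failure_policy == "refer":
            referral(f, test_cost, tumour_evidence=True)
        else:
            paths.append((f, test_cost, "DISCHARGED"))
        # valid negative
        paths.append(((1 - f) * (1 - p_pos), test_cost, "DISCHARGED"))
        # valid positive
        p_vp = (1 - f) * p_pos
        if not strategy.methylation_triage:
            referral(p_vp, test_cost, tumour_evidence=True)
        elif strategy.tumour_test == "ihc":
            key = ("ls_mlh1" if status is TrueStatus.LS_MLH1
                   else "ls_other" if status.is_ls else "sporadic")
            q = d.p_mlh1_pattern_given_positive[key]
            referral(p_vp * (1 - q), test_cost, tumour_evidence=True)
            meth_cost = test_cost + c.methylation
            m = d.methylation_after_dmlh1
            p_unmeth = (m.sensitivity if status is TrueStatus.LS_MLH1
                        else 1 - m.specificity)
            referral(p_vp * q * p_unmeth, meth_cost, tumour_evidence=True)
            paths.append((p_vp * q * (1 - p_unmeth), meth_cost, "DISCHARGED"))
        else:
            meth_cost = test_cost + c.methylation
            m = d.methylation_after_msi
            if status is TrueStatus.LS_MLH1:
                p_unmeth = m.sensitivity
            elif status.is_ls:
                p_unmeth = 1 - m.p_methylated_ls_other
            else:
                p_unmeth = 1 - m.p_methylated_sporadic
            referral(p_vp * p_unmeth, meth_cost, tumour_evidence=True)
            paths.append((p_vp * (1 - p_unmeth), meth_cost, "DISCHARGED"))
    return paths


def oracle_outcome(strategy, status, params):
    paths = walk_paths(strategy, status, params)
    agg = {"LS_CONFIRMED": 0.0, "PLS": 0.0, "DISCHARGED": 0.0}
    cost = 0.0
    for p, k, label in paths:
        agg[label] += p
        cost += p * k
    return agg, cost


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestProbandPathway:
    def test_no_testing_comparator(self, params):
        for status in TrueStatus:
            po = proband_pathway(NO_TESTING, status, params)
            assert po.p_discharged == 1.0
            assert po.expected_test_cost == 0.0

    def test_ihc_meth_msh2_hand_enumeration(self, params):
        p0 = modify(params, lambda t: t["diagnostics"]["ihc"].__setitem__("failure_rate", 0.0))
        po = proband_pathway(IHC_METH, TrueStatus.LS_MSH2, p0)
        # tumour positive x (non-MLH1 pattern, or MLH1 pattern and unmethylated)
        # x attend x accept x germline sensitivity
        expected = 0.944 * (0.994 + 0.006 * (1 - 0.936)) * 0.55 * 0.9 * 0.9
        assert po.p_ls_confirmed == pytest.approx(expected, abs=1e-12)

    def test_ihc_meth_sporadic_hand_enumeration(self, params):
        p0 = modify(params, lambda t: t["diagnostics"]["ihc"].__setitem__("failure_rate", 0.0))
        po = proband_pathway(IHC_METH, TrueStatus.SPORADIC, p0)
        expected = 0.252 * (0.17 + 0.83 * 0.064) * 0.55 * 0.9
        assert po.p_pls == pytest.approx(expected, abs=1e-12)
        assert po.p_ls_confirmed == 0.0  # perfect germline specificity

    def test_direct_referral_negatives_discharged(self, params):
        po = proband_pathway(DIRECT, TrueStatus.SPORADIC, params)
        assert po.p_pls == 0.0
        assert po.p_ls_confirmed == 0.0
        po_ls = proband_pathway(DIRECT, TrueStatus.LS_MLH1, params)
        assert po_ls.p_ls_confirmed == pytest.approx(0.55 * 0.9 * 0.9, abs=1e-12)
        assert po_ls.p_pls == 0.0

    @pytest.mark.parametrize("strategy", STRATEGIES, ids=lambda s: s.name)
    @pytest.mark.parametrize("status", list(TrueStatus), ids=lambda s: s.name)
    def test_matches_brute_force_walker(self, params, strategy, status):
        po = proband_pathway(strategy, status, params)
        agg, cost = oracle_outcome(strategy, status, params)
        assert sum(agg.values()) == pytest.approx(1.0, abs=1e-12)
        assert po.p_ls_confirmed == pytest.approx(agg["LS_CONFIRMED"], abs=1e-12)
        assert po.p_pls == pytest.approx(agg["PLS"], abs=1e-12)
        assert po.p_discharged == pytest.approx(agg["DISCHARGED"], abs=1e-12)
        assert po.expected_test_cost == pytest.approx(cost, abs=1e-9)

    @pytest.mark.parametrize("policy", ["refer", "discharge"])
    def test_walker_agreement_under_failure_policies(self, params, policy):
        p2 = modify(params, lambda t: t["diagnostics"].__setitem__("failure_policy", policy))
        for strategy in (IHC, IHC_METH, MSI, MSI_METH):
            for status in TrueStatus:
                po = proband_pathway(strategy, status, p2)
                agg, cost = oracle_outcome(strategy, status, p2)
                assert po.p_diag == pytest.approx(agg, abs=1e-12)
                assert po.expected_test_cost == pytest.approx(cost, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        sens=st.floats(0.0, 1.0), spec=st.floats(0.0, 1.0),
        fail=st.floats(0.0, 0.3), attend=st.floats(0.0, 1.0),
    )
    def test_probability_conservation_randomised(self, params, sens, spec, fail, attend):
        def mut(t):
            t["diagnostics"]["ihc"].update(sensitivity=sens, specificity=spec,
                                           failure_rate=fail)
            t["diagnostics"]["p_attend_counselling"] = attend
        p2 = modify(params, mut)
        for strategy in STRATEGIES:
            for status in (TrueStatus.LS_MLH1, TrueStatus.LS_MSH6, TrueStatus.SPORADIC):
                po = proband_pathway(strategy, status, p2)
                agg, _ = oracle_outcome(strategy, status, p2)
                assert po.p_diag == pytest.approx(agg, abs=1e-12)

    def test_blind_tests_reduce_to_no_testing(self, params):
        def mut(t):
            for test in ("ihc", "msi"):
                t["diagnostics"][test].update(sensitivity=0.0, specificity=1.0,
                                              failure_rate=0.0)
            t["diagnostics"]["germline_diagnostic_sensitivity"] = 0.0
        p2 = modify(params, mut)
        for strategy in STRATEGIES:
            for status in TrueStatus:
                po = proband_pathway(strategy, status, p2)
                assert po.p_discharged == pytest.approx(1.0, abs=1e-12)

    def test_methylation_triage_cuts_sporadic_testing_cost(self, params):
        for with_m, without_m in ((IHC_METH, IHC), (MSI_METH, MSI)):
            a = proband_pathway(with_m, TrueStatus.SPORADIC, params)
            b = proband_pathway(without_m, TrueStatus.SPORADIC, params)
            assert a.expected_test_cost <= b.expected_test_cost

    def test_invalid_strategy_flags(self):
        with pytest.raises(ValidationError):
            Strategy("BAD", "none", True, False)
        with pytest.raises(ValidationError):
            Strategy("BAD", "ihc", False, True)


class TestRelativeCascade:
    def test_discharged_proband_zero_cascade(self, params):
        po = PathwayOutcome(0.0, 0.0, 1.0, 0.0)
        casc = relative_cascade(po, TrueStatus.LS_MLH1, params)
        assert casc.expected_cost == 0.0
        assert casc.arm_probs[(True, False)] == pytest.approx(0.5)
        assert casc.arm_probs[(False, False)] == pytest.approx(0.5)
        assert casc.arm_probs[(True, True)] == 0.0

    def test_confirmed_proband_unit_cost_sum(self, params):
        po = PathwayOutcome(1.0, 0.0, 0.0, 0.0)
        casc = relative_cascade(po, TrueStatus.LS_MSH2, params)
        assert casc.expected_cost == pytest.approx(36 + 172 + 166 + 133)
        assert casc.arm_probs[(True, True)] == pytest.approx(0.5)   # Mendelian
        assert casc.arm_probs[(False, False)] == pytest.approx(0.5)

    def test_pls_proband_surveillance_without_test(self, params):
        po = PathwayOutcome(0.0, 1.0, 0.0, 0.0)
        casc = relative_cascade(po, TrueStatus.SPORADIC, params)
        up = params.diagnostics.relative_uptake_pls
        assert casc.expected_cost == pytest.approx(up * (36 + 172))
        assert casc.n_predictive_tests == 0.0
        assert casc.arm_probs[(False, True)] == pytest.approx(up)

    def test_arm_probabilities_sum_to_one(self, params):
        for strategy in STRATEGIES:
            for status in TrueStatus:
                po = proband_pathway(strategy, status, params)
                casc = relative_cascade(po, status, params)
                assert sum(casc.arm_probs.values()) == pytest.approx(1.0, abs=1e-12)
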