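import numpy as np
import pandas as pd
import pytest

from lynchcea.model import evaluate_all
from lynchcea.parameters import (DistributionSpec, ValidationError,
                                 default_distribution_specs)
from lynchcea.sensitivity import (age_heterogeneity, age_threshold_policy,
                                  owsa, run_psa)
from lynchcea.synth import SynthSpec, gen_ec_age_distribution
from lynchcea.tree import IHC_METH, MSI_METH, NO_TESTING, STRATEGIES
from conftest import modify


@pytest.fixture(scope="module")
def fixed_specs(params):
    tree = params.to_dict()
    from lynchcea.parameters import get_by_path
    paths = ("epidemiology.prevalence_ls", "costs_gbp.ihc",
             "diagnostics.ihc.sensitivity")
    return {p: DistributionSpec.fixed(get_by_path(tree, p)) for p in paths}


class TestRunPsa:
    def test_degenerate_distributions_reproduce_deterministic_run(self, params, fixed_specs):
        psa = run_psa(params, fixed_specs, n_iter=3, seed=11)
        det = evaluate_all(params, STRATEGIES,
                           relative_ages={params.population.relative_age_years: 1.0})
        for i in range(3):
            assert psa.costs[i] == pytest.approx([r.total_cost for r in det], rel=1e-12)
            assert psa.qalys[i] == pytest.approx([r.total_qalys for r in det], rel=1e-12)

    def test_seed_determinism(self, params):
        specs = default_distribution_specs(params)
        a = run_psa(params, specs, n_iter=3, seed=5)
        b = run_psa(params, specs, n_iter=3, seed=5)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        c = run_psa(params, specs, n_iter=3, seed=6)
        assert not np.array_equal(a.costs, c.costs)

    def test_mean_qaly_ordering_matches_deterministic(self, params):
        specs = default_distribution_specs(params)
        psa = run_psa(params, specs, n_iter=30, seed=2)
        mean_q = dict(zip(psa.names, psa.qalys.mean(axis=0)))
        det = {r.name: r.total_qalys
               for r in evaluate_all(params, STRATEGIES,
                                     relative_ages={params.population.relative_age_years: 1.0})}
        order = sorted(mean_q, key=mean_q.get)
        det_order = sorted(det, key=det.get)
        assert order == det_order

    def test_invalid_n_iter(self, params, fixed_specs):
        with pytest.raises(ValidationError):
            run_psa(params, fixed_specs, n_iter=0, seed=1)


@pytest.fixture(scope="module")
def entries(params):
    return owsa(params, default_distribution_specs(params))


class TestOwsa:
    def test_fixed_specs_excluded(self, params, fixed_specs):
        # germline specificity is 1.0 -> fixed spec -> excluded from the tornado
        specs = default_distribution_specs(params)
        assert specs["diagnostics.germline_diagnostic_specificity"].family == "fixed"
        entries = owsa(params, {"diagnostics.germline_diagnostic_specificity":
                                specs["diagnostics.germline_diagnostic_specificity"],
                                "costs_gbp.colonoscopy": specs["costs_gbp.colonoscopy"]})
        assert [e.parameter for e in entries] == ["costs_gbp.colonoscopy"]

    def test_irrelevant_parameter_filtered(self, params):
        # MSI cost does not enter IHC_METH vs NO_TESTING
        specs = default_distribution_specs(params)
        sub = {p: specs[p] for p in ("costs_gbp.msi", "costs_gbp.colonoscopy")}
        entries = owsa(params, sub)
        names = [e.parameter for e in entries]
        assert "costs_gbp.msi" not in names

    def test_sorted_by_range_and_filtered(self, entries):
        ranges = [e.inmb_range for e in entries]
        assert ranges == sorted(ranges, reverse=True)
        assert all(r >= 0.01 * ranges[0] for r in ranges)

    def test_widening_interval_increases_range(self, params):
        path = "epidemiology.surveillance_incidence_hr"
        hr = params.epidemiology.surveillance_incidence_hr
        narrow = {path: DistributionSpec.lognormal_from_mean_se(hr, 0.05 * hr)}
        wide = {path: DistributionSpec.lognormal_from_mean_se(hr, 0.20 * hr)}
        e_narrow = owsa(params, narrow)[0]
        e_wide = owsa(params, wide)[0]
        assert e_wide.inmb_range >= e_narrow.inmb_range

    def test_range_definition(self, entries):
        for e in entries:
            assert e.inmb_range == pytest.approx(abs(e.inmb_high - e.inmb_low))


@pytest.fixture(scope="module")
def het_inmb(params):
    het = age_heterogeneity(params, ages=range(40, 86),
                            strategies=(NO_TESTING, IHC_METH))
    sub = het[het.strategy == "IHC_METH"]
    return dict(zip(sub.age, sub.inmb_per_proband))


class TestAgeHeterogeneity:
    def test_inmb_strictly_decreasing_in_age(self, het_inmb):
        vals = [het_inmb[a] for a in sorted(het_inmb)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_sign_change_within_60_70(self, het_inmb):
        crossings = [a for a in range(60, 70) if het_inmb[a] > 0 >= het_inmb[a + 1]]
        assert len(crossings) == 1
        assert het_inmb[40] > 0 and het_inmb[85] < 0

    def test_gene_mix_is_only_driver_when_other_curves_flattened(self, params):
        """Controlled comparison: flatten every age-varying proband input
        except the gene mixture; outcome differences across ages then stem
        from the mixture alone, and vanish when it is flattened too."""
        def flatten(t, also_mix):
            epi = t["epidemiology"]
            epi["prevalence_ls_by_age"] = {40.0: 0.039, 85.0: 0.039}
            epi["ec_mortality_sporadic_per_1000py_by_age"] = {40.0: 43.0, 85.0: 43.0}
            if also_mix:
                row = dict(epi["gene_mix_by_age"][60.0])
                epi["gene_mix_by_age"] = {40.0: dict(row), 85.0: dict(row)}
        p_mix = modify(params, lambda t: flatten(t, False))
        p_flat = modify(params, lambda t: flatten(t, True))

        def inmb_at(p, age):
            het = age_heterogeneity(p, ages=[age], strategies=(NO_TESTING, IHC_METH))
            return het[het.strategy == "IHC_METH"].inmb_per_proband.iloc[0]

        # proband Markov traces still differ with age (life table/horizon), so
        # compare the *gap* attributable to the gene mix at one age
        gap = inmb_at(p_mix, 50) - inmb_at(p_flat, 50)
        assert gap != pytest.approx(0.0, abs=1e-9)
        assert inmb_at(p_mix, 60) == pytest.approx(inmb_at(p_flat, 60), abs=1e-9)


@pytest.fixture(scope="module")
def dist():
    return gen_ec_age_distribution(SynthSpec(seed=0))


class TestAgeThresholdPolicy:
    def test_threshold_below_range_is_zero(self, params, dist, het_inmb):
        df = age_threshold_policy(params, dist, thresholds=[39.0],
                                  per_age_inmb=het_inmb)
        assert df.population_inmb_per_proband.iloc[0] == 0.0

    def test_cumulative_recurrence(self, params, dist, het_inmb):
        df = age_threshold_policy(params, dist, thresholds=range(40, 86),
                                  per_age_inmb=het_inmb)
        vals = dict(zip(df.threshold, df.population_inmb_per_proband))
        for t in range(41, 86):
            assert vals[t] == pytest.approx(vals[t - 1] + dist[float(t)] * het_inmb[t],
                                            abs=1e-9)

    def test_argmax_in_60_65_and_positive_at_80(self, params, dist, het_inmb):
        df = age_threshold_policy(params, dist, thresholds=range(40, 86),
                                  per_age_inmb=het_inmb)
        argmax = df[df.is_argmax].threshold.iloc[0]
        assert 60 <= argmax <= 65
        assert df[df.threshold == 80].population_inmb_per_proband.iloc[0] > 0

    def test_bad_distribution_rejected(self, params):
        with pytest.raises(ValidationError):
            age_threshold_policy(params, {60.0: 0.5}, thresholds=[60])


class TestScenarioSignAudit:
    def test_null_surveillance_scenario(self, params):
        """With no incidence effect, testing adds cost in every strategy and
        QALY gains come only from the stage shift (still positive)."""
        p2 = modify(params, lambda t: t["epidemiology"].__setitem__(
            "surveillance_incidence_hr", 1.0))
        res = evaluate_all(p2)
        base = next(r for r in res if r.name == "NO_TESTING")
        for r in res:
            if r.name == "NO_TESTING":
                continue
            assert r.total_cost > base.total_cost
            assert r.total_qalys > base.total_qalys

        # removing the stage shift as well eliminates the QALY gain channel
        def null_all(t):
            t["epidemiology"]["surveillance_incidence_hr"] = 1.0
            t["epidemiology"]["stage_distribution"]["surveilled"] = \
                list(t["epidemiology"]["stage_distribution"]["unsurveilled"])
        p3 = modify(params, null_all)
        res3 = evaluate_all(p3)
        base3 = next(r for r in res3 if r.name == "NO_TESTING")
        for r in res3:
            assert r.total_qalys == pytest.approx(base3.total_qalys, abs=1e-6)
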