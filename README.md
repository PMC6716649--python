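# lynchcea

Decision-analytic model of reflex testing for Lynch syndrome (LS) in women
newly diagnosed with endometrial cancer, with cascade predictive testing of
relatives and a lifetime monthly-cycle Markov model of colorectal-cancer
outcomes. The package provides a full cost-effectiveness engine —
incremental analysis with strict and extended dominance, ICERs, net monetary
benefit, cost-effectiveness acceptability curves — plus probabilistic and
one-way sensitivity analysis and proband-age heterogeneity / age-threshold
policy analysis.

Six strategies are compared: reflex tumour testing with MMR
immunohistochemistry or microsatellite instability testing (each with or
without *MLH1* methylation triage), direct referral for diagnostic mutation
testing, and no testing.

## Command line

```bash
lynchcea run --mode base --out results/            # deterministic base case
lynchcea run --mode psa --iterations 1000 --seed 1 --out results/
lynchcea run --mode owsa --out results/            # tornado (INMB per proband)
lynchcea run --mode ages --out results/            # proband-age sweep 40-85
lynchcea run --mode threshold --out results/       # age-threshold policy
lynchcea tree --strategy IHC_METH --status LS_MSH2 # pathway outcome as JSON
lynchcea meta --studies studies.csv                # bivariate meta-analysis
lynchcea synth accuracy --seed 1 --out studies.csv # synthetic fixtures
```

Every `run` writes fixed-name CSVs plus a `manifest.json` (parameter-file
hash, scenario, seed, iteration count, package version) sufficient to
reproduce the run. Scenario overrides (`--scenario low_prevalence`, etc.)
and custom parameter files (`--params my.yaml`) are applied on top of the
packaged base case `src/lynchcea/data/base_case.yaml`.

## Package layout

| Module | Role |
| --- | --- |
| `lynchcea.parameters` | Typed, validated model inputs; YAML loading; scenario overrides; PSA distribution specs |
| `lynchcea.evidence` | Bivariate sensitivity/specificity meta-analysis, random-effects proportion pooling, age-specific gene mixture |
| `lynchcea.tree` | Diagnostic decision tree per strategy × true status; relatives' cascade |
| `lynchcea.markov` | Monthly-cycle cohort model with half-cycle rewards and mid-cycle discounting |
| `lynchcea.model` | Links tree outputs to cohort arms; population strategy totals |
| `lynchcea.cea` | ICERs, dominance frontier, NMB, CEAC |
| `lynchcea.sensitivity` | PSA driver, OWSA/tornado, age heterogeneity, age-threshold policy |
| `lynchcea.synth` | Synthetic accuracy studies, life tables, age distributions |
| `lynchcea.cli` / `lynchcea.reporting` | CLI entry points, CSV writers, run manifests |

## Data caveats

Headline inputs (test accuracy, uptake, unit costs, discounting, thresholds)
are the published point estimates. Age-indexed schedules that were not
published — life tables, gene-specific colorectal-cancer incidence under
surveillance, stage splits, CRC management costs by age and stage, the LS
prevalence-by-age curve, and all PSA distribution hyperparameters — are
clearly-flagged synthetic fixtures with the right qualitative structure,
generated/calibrated by `scratch/make_fixtures.py`. They enter the model
only through the parameter file, so real tables can be substituted without
code changes. Quantitative results with the packaged fixtures are therefore
indicative; the engine, not the fixture values, is the deliverable.
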