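# frailbn

Bayesian-network risk analysis of categorical patient cohorts, built as a
reusable re-implementation of a published oral-frailty study in
maintenance-hemodialysis patients: univariate screening, multivariable
logistic regression, MMHC structure learning with expert constraints,
maximum-likelihood CPT estimation, exact probabilistic inference,
sensitivity analysis and model validation — exercised end to end on
synthetic cohorts sampled from the study's published network.

## What is in the box

| Module | Purpose |
| --- | --- |
| `frailbn.network` | Discrete-BN data model (variables, CPTs, `NetworkSpec`), JSON/DOT IO |
| `frailbn.fixtures` | The published aggregate tables as machine-readable constants |
| `frailbn.reference` | The 12-node / 15-edge reference network, calibrated to the published marginals and the published outcome CPT |
| `frailbn.synthetic` | Ancestral-sampling cohort simulator (seeded, byte-reproducible) |
| `frailbn.screening` | Pearson chi-square (no continuity correction), pooled/Welch t, tie-corrected Mann-Whitney, sample-size formula, alpha screening |
| `frailbn.logistic` | IRLS logistic regression, Wald inference, OR CIs, tolerance/VIF, Hosmer-Lemeshow |
| `frailbn.structure` | G² CI tests, MMPC skeleton discovery, BIC hill climbing with whitelist/blacklist |
| `frailbn.inference` | ML CPT fitting, variable elimination (min-fill), conditional tables, per-record prediction |
| `frailbn.validation` | ROC/AUC, Youden point, decile calibration, max-swing / mutual-information sensitivity |
| `frailbn.pipeline` | End-to-end orchestration with YAML config and a reproducibility manifest |

## CLI

```bash
# simulate a cohort from the packaged reference network
frailbn simulate --n 680 --seed 1 --out cohort.csv

# univariate screening and logistic regression
frailbn screen --cohort cohort.csv --outcome oral_frailty
frailbn regress --cohort cohort.csv --out regression.tsv

# structure learning, parameter fitting, inference
frailbn learn-structure --cohort cohort.csv --out structure.json --dot structure.dot
frailbn fit-params --cohort cohort.csv --structure structure.json --out fitted.json
frailbn infer -e polypharmacy=yes -e malnutrition=yes -e eating_alone=yes -e general_frailty=yes

# sensitivity, validation, published fixtures, sample size
frailbn sensitivity --out sensitivity.tsv
frailbn validate --cohort cohort.csv --out validation.json --plot roc.png
frailbn tables --fixture table3
frailbn sample-size --pi 0.412 --dropout 0.2
```

The whole study runs as one pipeline from a YAML config:

```bash
cat > config.yaml <<EOF
outdir: pipeline-out
seed: 1
n: 680
EOF
frailbn run --config config.yaml
```

Artifacts (cohort CSV, screening/regression/sensitivity TSVs, learned and
fitted network JSON, DOT graph, validation JSON, manifest) land in
`outdir`; two runs of the same config are byte-identical.

## Notes on fidelity

* The published outcome CPT is stored verbatim to four decimals; root
  priors equal the published marginal counts; internal-node CPTs use a
  documented logistic-link calibration (recorded in the network's
  `metadata`) whose baselines are solved so implied marginals match the
  published ones exactly.
* The published regression coefficients, AUC/sensitivity/specificity,
  Hosmer-Lemeshow statistic and sensitivity-index values depend on the
  unavailable patient-level data; the test suite replaces them with
  property-based checks (closed-form oracles, enumeration oracles,
  simulation-based recovery) at documented tolerances.
* One published contingency row (depression) is internally inconsistent:
  its printed chi-square (13.294) does not follow from its printed counts
  (which give 24.498). The package asserts the value recomputed from the
  counts.
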