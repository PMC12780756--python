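# hetforest

Honest causal forests and register-style cohort simulation for
heterogeneous-treatment-effect analysis of childhood-onset disease.

## The problem

Total-population register studies can ask not only *whether* a childhood
disease such as type 1 diabetes (T1D) leaves traces in adult life —
mortality, antidepressant use, partnership, education, unemployment, income —
but *for whom* the consequences are worst. The workflow for that question
is a matched register cohort (every case plus up to 26 controls matched on
region, sex and birth year) analyzed with honest causal forests: the target
is the conditional average treatment effect

    tau(x) = E[Y(1) - Y(0) | X = x]

given 38 childhood covariates x measured before diagnosis, and the
heterogeneity readout is a cross-fitted ranking of people into CATE
quartiles, whose covariate profiles reveal the vulnerable subgroups.

Register data of this kind are confidential, so `hetforest` ships a
synthetic cohort generator calibrated to the published descriptive margins
of such a design (3048 cases, ~79,000 matched controls; treated/control
mortality 2.3%/0.9%, antidepressant use 17.1%/13.1%, no partnership
35.8%/31.8%, basic education only 10.8%/10.3%, unemployment 1.18/1.02
months/year, income 25,697/27,453 €/yr), with configurable ground-truth
effect heterogeneity — by default a sex-modified antidepressant effect and
a family-SES-modified partnership effect. Estimation and simulation are
independent components: the estimator never sees the generator's truth
except in tests.

## What is inside

| module | role |
|---|---|
| `hetforest.synthetic` | calibrated register-style cohort generator, ground-truth CATEs |
| `hetforest.matching` | exclusion rules, stratified 1:26 control matching |
| `hetforest.nuisance` | honest out-of-bag regression forests, local centering |
| `hetforest.forest` | the honest causal forest (gradient splitting, forest weights, importance) |
| `hetforest.effects` | AIPW scores, doubly robust ATE/ATT and group effects |
| `hetforest.pipeline` | pilot→final screening, cross-fitted CATE quartiles, SMD profiles |
| `hetforest.cli` | `hetforest simulate / match / analyze / run-all` |

The forest is implemented from scratch (numba kernels; exhaustive split
search, property-tested against a brute-force oracle); scikit-learn appears
only as an independent cross-check in the test suite. See
`docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
import dataclasses
import hetforest as hf

# a 1/6-size version of the full design, recalibrated to the same margins
cfg = hf.calibrate(dataclasses.replace(hf.DGPConfig(),
                                       n_treated=500, n_control_pool=30_000))
cohort = hf.generate_cohort(cfg, seed=7)
kept, counts = hf.apply_exclusions(cohort)
matched = hf.match_controls(kept, cfg.max_controls_per_case, seed=7).data
print(hf.outcome_summary(matched))

res = hf.analyze_outcome(matched, "antidepressant_use",
                         params=hf.ForestParams(n_trees=80, min_node_size=50),
                         seed=7, K=5)
print(res.rank_effects[["target", "group", "estimate", "ci_low", "ci_high", "n"]])
```

prints (seed 7):

```
                       outcome  treated_mean  control_mean  n_treated  n_control
                    died_by_30      0.016000      0.006916        500      12146
            antidepressant_use      0.192857      0.137621        420      10449
                no_partnership      0.361789      0.309153        492      12062
          basic_education_only      0.101626      0.100564        492      12062
unemployment_months_annualized      1.091709      1.020754        492      12062
                 income_annual  25683.571429  27062.551440        420      10449

   target  group  estimate  ci_low  ci_high     n
group-ATE    1.0    0.0545 -0.0224   0.1314  2718
group-ATE    2.0    0.0231 -0.0420   0.0882  2717
group-ATE    3.0    0.0712 -0.0119   0.1542  2717
group-ATE    4.0    0.0394 -0.0389   0.1178  2717
      ATT    NaN    0.0509  0.0129   0.0890 10869
      ATE    NaN    0.0471  0.0090   0.0851 10869
```

Reading it: the matched groups reproduce the calibrated margins (first
table), and the doubly robust ATT says T1D raises the probability of
antidepressant purchase by 5.1 points (95% CI 1.3–8.9) in this synthetic
cohort — the generator's true average effect is ~4 points. At this reduced
size the four CATE-quartile estimates are statistically indistinguishable:
500 cases are too few to resolve the injected 6-point sex interaction. At
the full design size the same pipeline separates them cleanly — the
full-size acceptance test finds the high-effect quartile 71% female versus
24% in the low-effect quartile, with sex the largest-magnitude
standardized mean difference between the extreme quartiles.

The same analysis from a shell:

```bash
hetforest simulate --seed 7 --output cohort.csv
hetforest match --input cohort.csv --seed 7 --output matched.csv
hetforest analyze --input matched.csv --outcome antidepressant_use \
    --seed 7 --outdir out/
```

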