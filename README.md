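# crcscreen

Cost-effectiveness microsimulation of colorectal cancer (CRC) screening,
built for settings — like the Dominican Republic and the wider Caribbean —
where no organized screening exists, diagnoses skew late-stage, and the
question is which of the guideline strategies (10-yearly colonoscopy,
5-yearly sigmoidoscopy, biennial FIT or FOBT, ages 45–75) buys the most
health per dollar against no screening.

The package is aimed at health-economic modelers: it provides a calibrated
natural-history engine, a screening overlay, DALY/cost accounting, frontier
decision logic, and the full sensitivity-analysis toolkit, each usable as a
library or through a small CLI.

## The model

A monthly-cycle Markov microsimulation of the adenoma–carcinoma sequence:

    Healthy → adenoma (low-risk → high-risk) → preclinical CRC
            (local → regional → distant, symptomatic detection by stage)
            → clinical CRC → death (CRC within 10 y of diagnosis / other)

Monthly transition probabilities are age-banded; the natural-history
parameters are fitted by stepwise simulated annealing to CRC incidence,
adenoma prevalence, and stage-distribution targets through a deterministic
forward operator. Strategies are compared on mean discounted cost per
person and DALYs averted vs no screening,

    ICER = Δcost / ΔDALYs averted,

along the efficiency frontier (strict and extended dominance removed), with
the willingness-to-pay threshold defaulting to $11,692 per DALY averted.
Uncertainty is handled by one-way deterministic sensitivity analysis
(tornado), probabilistic sensitivity analysis (Gamma costs, Beta
probabilities/weights; CEAC by net monetary benefit), and scenario analyses
(start/stop ages, adherence grids, halved/doubled incidence, alternative
stage mix, FIT→colonoscopy switch). Everything runs from synthetic,
structurally realistic fixtures — no data downloads. See
`docs/methods.md` for assumptions and design choices.

## Worked example

```python
from crcscreen import CohortConfig, ModelInputs, cea_table, evaluate_strategies
from crcscreen.synthetic import make_fixture_bundle

b = make_fixture_bundle("dr", seed=0)        # DR-like late-stage fixture set
inputs = ModelInputs(
    params=b.truth_params, lifetable=b.lifetable, survival=b.survival,
    costs=b.costs, tests=b.tests, weights=b.weights,
    strategies=b.strategies, cohort=CohortConfig(n=20_000, seed=11),
)
table = cea_table(list(evaluate_strategies(inputs).values()), inputs.wtp)
print(table[["strategy", "cost", "dalys_averted_vs_ref", "icer",
             "incidence_reduction_pct", "colonoscopies_per_1000"]].round(3))
print("optimal:", table.attrs["optimal"])
```

Output (fixture inputs, 20,000 persons, seed 11):

```
  strategy     cost  dalys_averted_vs_ref       icer  incidence_reduction_pct  colonoscopies_per_1000
0       NH   56.287                 0.000          -                    0.000                   24.35
1      FIT   81.510                 0.014    1825.65                   45.585                  521.55
2     FOBT   89.095                 0.009  Dominated                   33.059                  595.30
3      Sig  195.359                 0.013  Dominated                   53.593                  327.80
4     Colo  200.791                 0.023   13201.59                   66.530                 2219.65
optimal: FIT
```

Read it as a cost-effectiveness table: each row is a strategy's mean
discounted per-person cost, DALYs averted vs no screening (NH), and its ICER
against the previous frontier strategy. On these fixtures FOBT and
sigmoidoscopy are dominated (costlier and less effective than alternatives),
FIT is on the frontier at ~$1,826 per DALY averted — well under the
threshold — and colonoscopy, though most effective (67 % incidence
reduction), exceeds it, while also demanding four times the colonoscopy
capacity (2,220 vs 522 per 1,000 screened). The fixture inputs are labeled
placeholders, so the absolute numbers characterize the fixtures, not any
real population; the decision structure is the meaningful output.

### CLI

```bash
crcscreen fixtures config.yaml    # generate the synthetic input bundle
crcscreen simulate config.yaml    # run all strategies, write traces
crcscreen cea config.yaml         # CEA table, frontier, decision
crcscreen dsa|psa|scenarios|report config.yaml
```

`tests/test_workbench.py::write_config` shows a minimal config.

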