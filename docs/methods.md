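# Methods

## Model

`crcscreen` simulates colorectal cancer (CRC) natural history as a
state-transition (Markov) microsimulation of the adenoma–carcinoma sequence.
Each person enters healthy at age 20 and is followed on 1-month cycles to age
100 or death through the states

    Healthy → low-risk adenoma (<10 mm) → high-risk adenoma (≥10 mm)
            → preclinical CRC (local → regional → distant)
            → clinical CRC (stage frozen at diagnosis) → death (CRC / other)

Each preclinical stage can surface clinically through symptomatic detection,
with detection probabilities rising by stage. Within a cycle, exactly one
outcome is drawn from the current state's exit-probability vector — disease
transitions, all-cause death, and (for diagnosed persons) cancer-specific
death compete in a single multinomial draw, so no ordering assumption is
needed. Key structural assumptions:

- **One lesion per person.** The state records the person's most advanced
  lesion; lesion multiplicity is not modeled (its effects are absorbed into
  the calibrated transition probabilities).
- **No excess mortality before diagnosis.** Undetected (preclinical) cancer
  carries only all-cause mortality; stage-specific cancer mortality applies
  from diagnosis for 120 months, after which survivors revert to all-cause
  rates only.
- **Stage is frozen at diagnosis.** Survival after diagnosis depends on the
  stage at diagnosis and years since diagnosis, not on further progression.
- **Complete polypectomy.** A detected adenoma is removed entirely; the
  person returns to Healthy (a high-risk finding additionally enrolls
  colonoscopy surveillance).
- **Monthly cycles, no half-cycle correction** — at a 1-month step the
  correction is far below Monte-Carlo noise.
- Ages are completed months on half-open cycles `[t, t+1)`; entry is exactly
  240 months; the all-cause probability at age 100 is treated as 1 (horizon).

Transition probabilities are *monthly*; annual inputs are converted with
`1 − (1 − p)^(1/12)`. Age dependence is piecewise-constant over configurable
age bands (5-year bands by default; the shipped fixtures use decade bands for
adenoma onset and a single band for the other parameters).

### Randomness and common random numbers

Randomness is counter-based: every (purpose, cycle) pair owns an independent
Philox stream of per-person uniforms derived from the master seed. The
disease process consumes one full vector per cycle in fixed order, while
screening draws (adherence, test results, complications) live on separate
purposes. Consequently two runs that share a seed experience identical
disease histories wherever screening has not intervened — a screening arm
with zero adherence reproduces the natural-history event log *bit for bit*,
and incremental comparisons (DSA arms, PSA iterations) are variance-reduced
by construction. The per-cycle inner loop is compiled with numba.

### Deterministic companions

Two deterministic forward models mirror the stochastic engine:

- `cohort_matrix_oracle` propagates exact expected state occupancy,
  tracking the diagnosed population by months-since-diagnosis so the
  10-year mortality window is applied exactly. Microsimulation occupancy
  converges to it as the cohort grows; the test suite verifies agreement
  with exact binomial tails at a family-wise 3-sigma level (raw pointwise
  z-scores are invalid in cells whose expected counts are far below 1).
- `nh_forward_summary` restricts the recursion to the undiagnosed
  population, which is sufficient for incidence (denominator:
  alive-and-undiagnosed person-time), adenoma prevalence, and the stage mix
  at diagnosis. It costs ~4 ms and is the forward operator calibration
  optimizes against, so the annealer sees a noise-free landscape.

## Calibration

Targets are CRC incidence by age band (per 100,000 undiagnosed
person-years), adenoma prevalence by age, and the stage distribution at
diagnosis. The objective is the weighted sum of squared relative deviations,
`Σ w·((model − target)/max(target, ε))²`, with ε guarding near-zero targets
(1 per 100k for incidence, 10⁻³ for fractions).

**What is calibrated.** These target classes cannot identify all eight
transition-probability groups: the adenoma dwell split (LR→HR vs
HR→preclinical) and the preclinical progression-vs-detection split trade off
almost exactly — the classic sojourn-time/test-sensitivity
non-identifiability. A quasi-Newton optimizer driven to objective ≈10⁻⁷
still leaves those parameters up to 140 % from a known truth. The package
therefore treats the three dwell-rate parameters (LR→HR, local→regional,
regional→distant) as fixed, literature-informed inputs and calibrates the
identifiable set: the adenoma-onset age bands, HR→preclinical progression,
and the three stage-specific detection rates. With that set, a local
optimizer recovers a known truth exactly on every seed tried.

**Optimizer.** Classic Metropolis simulated annealing (accept improvements;
accept a worsening Δ with probability `exp(−Δ/T)`; geometric cooling) on the
logit scale, run stepwise: onset vs prevalence, progression vs incidence,
detection vs stage mix, then a joint polish over the whole calibrated set.
Proposal mechanics are configurable per stage; the parameter-recovery
harness uses single-coordinate proposals with mixed step sizes and a long
zero-temperature polish, which descend the objective's curved,
ill-conditioned valley far more reliably than isotropic joint steps. The
recovery benchmark (targets generated from a known truth, start perturbed by
independent U(0.5, 2) factors per parameter) reaches objective ~10⁻⁵ with
every parameter within ~13 % of truth on all three benchmark seeds.

## Screening

Four base policies between ages 45 and 75 with 60.6 % first-line adherence
and 100 % follow-up adherence: colonoscopy every 10 years, sigmoidoscopy
every 5, FIT and FOBT every 2. Mechanics:

- Stool tests are positive with the lesion-class sensitivity, or
  `1 − specificity` with no lesion; positives are referred to a follow-up
  colonoscopy. Endoscopies detect a present lesion with
  `sensitivity × distal fraction` (the fraction is 1 for colonoscopy; the
  fixtures use 0.6 for sigmoidoscopy's reach) and produce no false-positive
  findings; a positive sigmoidoscopy is also referred to colonoscopy.
- A negative colonoscopy — whatever the person's true state — locks
  first-line screening out for 120 months. Offer schedules are
  person-relative: after an offer the next one falls one interval later,
  pushed past any lockout.
- A detected high-risk adenoma enrolls the person in surveillance
  colonoscopy (3 years after polypectomy, then every 5) until age 85;
  surveillance supersedes first-line screening.
- Adherence is an independent Bernoulli draw per offer (a persistent
  per-person mode is available for adherence scenarios). Complications are
  drawn per endoscopy, priced and disability-weighted, and never fatal.
- Symptomatic presentation triggers one diagnostic colonoscopy — the only
  colonoscopy source in the no-screening arm. Sigmoidoscopies are counted
  separately from colonoscopies in the per-1,000 demand figures.
- The FIT-to-colonoscopy switch policy is a two-phase schedule (biennial FIT
  to the switch age, 10-yearly colonoscopy after); at the boundary the later
  phase takes precedence.

## Economics

Costs (healthcare-payer perspective, 2024 USD; pesos convert at 0.017 with a
health-CPI factor) attach to tests, follow-up/surveillance/diagnostic
colonoscopies, complication episodes, and a one-off stage-specific treatment
bundle at diagnosis. Health outcomes are DALYs: discounted life years (DLY)
accrue 1/12 per alive month; years lived with disability (YLD) combine a
living-with-cancer weight (1 − stage utility, applied for 120 months after
diagnosis) with lump episode weights for endoscopy, complications, and the
initial treatment period. A strategy's effect against the no-screening
reference is

    DALYs averted = (DLY_S − DLY_ref) + (YLD_ref − YLD_S),

which is antisymmetric and equals the YLL+YLD difference for any common
reference age, so no external life-expectancy standard is needed. "Monthly
3 %" discounting is interpreted as 3 % *per annum* applied at monthly
resolution, `(1+0.03)^(−t/12)` — 3 % per month would compound to an
implausible 42.6 %/year — with the clock at model entry (age 20) for every
strategy; both choices are configuration knobs and any common epoch cancels
in increments. No age weighting is applied.

## Decision analysis

Strategies are compared on (mean cost, mean DALYs averted). The efficiency
frontier is found by cost-ordering, removing strictly dominated strategies,
then iteratively removing extended dominance until frontier ICERs increase
strictly; equal-cost-equal-effect duplicates are flagged, and ICER ties
resolve toward the more effective strategy. The decision rule selects the
most effective frontier strategy whose ICER against its predecessor is at or
below the willingness-to-pay threshold (default $11,692 per DALY averted —
the 2024 GDP per capita of the Dominican Republic).

## Sensitivity analyses

- **One-way DSA**: each parameter in turn to its low/high bound, ICER of a
  strategy pair recomputed under common random numbers; tornado ordering by
  bar width.
- **PSA**: costs ~ Gamma, probabilities and disability weights ~ Beta, both
  by method of moments around the base value (default SE = 20 % of the mean;
  a supplied low–high range maps to SE = (high − low)/3.92). Natural-history
  transition probabilities stay at their calibrated values. Each iteration
  draws one joint parameter set and evaluates every strategy on the *same*
  cohort stream, isolating parameter uncertainty; iterations whose test
  characteristics equal the base case reuse the base traces, which makes the
  zero-SE degenerate case exact. Optimality is by highest net monetary
  benefit over a WTP grid (the CEAC).
- **Scenarios**: start age 40/45/50, stop 75/85, surveillance stop 75/85,
  adherence grids, halved/doubled incidence (the onset multiplier re-solved
  by bisection on the deterministic forward model to 1 % tolerance), an
  alternative earlier-stage mix (detection parameters re-annealed against
  it), and the FIT-then-colonoscopy switch policy.

## Synthetic fixtures

Every input is generated, none downloaded. The lifetable is
Gompertz–Makeham (life expectancy at 20 between 50 and 65 years at the
"mid" level); stage survival declines with years since diagnosis and is
ordered distant ≥ regional ≥ local; natural-history truth parameters yield
lifetime CRC incidence between 1.5 % and 4 %, adenoma prevalence rising to
roughly 25–45 % by age 70, and either a late-stage-skewed mix ("dr" variant:
regional+distant ≥ 50 %, distant ≥ 30 %) or an earlier-stage mix ("seer8":
local+regional ≥ 55 %). Distant-stage detection is set low enough
(0.03/month) that its competition with mortality leaves a usable calibration
signal. Costs, test characteristics, and disability weights are *labeled
placeholders* carrying only the field's ordinal structure (colonoscopy ≥
sigmoidoscopy ≥ FIT ≥ FOBT sensitivity per lesion class; FIT specificity ≥
FOBT; stool < sigmoidoscopy < colonoscopy < treatment costs; distant ≥
regional ≥ local for treatment cost and cancer disability weight). Targets
are produced from the truth through the same forward operator calibration
uses, so the truth scores exactly zero.

Because the fixtures are structural stand-ins, passing tests demonstrate
that the *machinery* is correct — conservation, oracle agreement, CRN
equivalences, dominance logic, recovery of known parameters — not that the
fixture outputs numerically reproduce any particular population's burden or
any published cost figure. Absolute fixture outputs (e.g. lifetime cost per
person) have no external meaning.

## Problem sizes and numerics

Default cohort 100,000 persons (~3 s per strategy); the test suite uses
2,000–20,000 person cohorts, a 200-iteration × 5,000-person PSA, and
10-seed × 10,000-person averages for monotonicity checks — sizes chosen so
the full suite completes in minutes while keeping Monte-Carlo error well
inside the asserted tolerances. Probabilities are clipped to
(10⁻¹², 1 − 10⁻¹²) before logit transforms; bisection for incidence scaling
is capped at 60 iterations (1 % tolerance); annealing aborts on non-finite
objectives. Known limitations: no serrated pathway, no sex or birth-cohort
stratification, no lesion multiplicity, no colonoscopy capacity constraints,
no procedural mortality, and single-bundle treatment costs without
continuing/terminal phases.
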