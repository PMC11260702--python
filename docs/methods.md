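# Methods

This note documents the model implemented in `sbtox`: its structure,
assumptions, numerical conventions, the open design choices we made and
what the synthetic fixtures do and do not represent.

## Cohort and states

A closed cohort of rectal-cancer survivors enters the model immediately
after radiotherapy, either at a single age (homogeneous cohorts, used in
the hospitalization scenario) or as an age mix over 25–99 weighted by an
age-at-diagnosis distribution. The state space has 22 states:

- `post_treatment` — symptom-free; the only state at risk of a *first*
  toxicity event. Once any event occurs the patient never returns: the
  first-event probabilities are cumulative-incidence-style hazards for the
  first occurrence, and re-exposing event survivors to them every cycle
  would produce implausible event counts.
- `mgmt_{pathway}_r{level}` — symptom management after an event, indexed
  by the pathway of the most recent event (pharmaceutical, supportive,
  surgical) and the number of recurrences so far (0–4). The pathway
  carries the recurrence risk (operated patients recur less than
  non-operatively treated ones) and the level selects which recurrence
  probability applies next. Level 4 is a cap: further recurrences reuse
  the level-4 probabilities.
- `recurrent_event_{1..4}` — tunnel states occupied for exactly one
  cycle. A recurrence means obstruction or perforation, so every
  recurrence resolves through the hospitalization tree.
- `death_sb`, `death_other` — absorbing.

Cycle length is half a year; the horizon is age 100.

## Transition structure

Within a cycle, background mortality is applied first (annual life-table
probability converted by $q_{1/2} = 1-(1-q)^{1/2}$) and the toxicity
dynamics act on survivors. The alternative convention (toxicity first)
differs at order $q \cdot p$ per cycle, negligible at these magnitudes.

First events split into grades 1–4. Grades 1–2 route through the
pharmaceutical tree, grades 3–4 through the hospitalization tree, both
resolving within the cycle; recurrences enter the tunnel and resolve
through the hospitalization tree at the next cycle boundary. Event
*payloads* (costs, admission counts, sick leave, disutility) accrue in the
cycle the event occurs — for recurrences that is tunnel entry, while the
destination state (or toxicity death) materialises at tunnel exit.

### Hazard decay

Trial follow-up gives no long-term time course for late toxicity, so all
small-bowel event hazards are constant for the first five years after
treatment and then decline by 25% per whole elapsed year — a step
function on the *rate* scale ($r=-\ln(1-p)/t$, decayed, converted back).
The decay clock runs on time since treatment, not age.

We apply the decay to recurrence hazards as well as first-event hazards
(`decay_on_recurrence=True`). With decay on first events only, cumulative
admissions grow essentially without bound (about 5 per patient over a
70-year zero-mortality horizon), which contradicts the strong saturation
this model family is meant to reproduce; with decay on all event hazards
the lifetime admission count saturates at a realistic level. The flag is
configurable for sensitivity exploration.

### NTCP scaling

The IMRT/IGRT grade-probability vector is the measured reference; other
techniques scale it by the *unrounded* NTCP ratio (0.265/0.180,
0.395/0.180) directly on the probability scale. Rate-scale scaling would
be more orthodox but probability-scale scaling is what reproduces the
published per-technique probability table to three decimals; at these
magnitudes the difference is below 0.1 percentage points.

## Cycle trees

*Pharmaceutical tree* (grade 1–2): loperamide controls symptoms with
probability 92.80%; failures receive a second line (antibiotics 44.44% /
bile-acid sequestrants 55.56%, success 41.85% / 30.87%). All paths end in
pharmacologically managed symptom control within the cycle — recovery
from mild toxicity is taken as given, and escalation happens only through
later recurrence. A configurable flag (`pharma_failure_escalates`) routes
second-line failures into the hospitalization tree instead.

*Hospitalization tree* (grade 3–4 and recurrences): surgery 22.80%
(toxicity death 3.783%) or supportive treatment 77.20% (death 0.837%).

Branch pairs that must sum to one (surgery/supportive, death/survival per
arm, antibiotic/sequestrant mix) are stored as printed but the trees use
one canonical member plus its complement, so chance nodes remain
normalized under perturbation and sampling.

Drug resource use is one course per event at defined daily doses for 90
days (loperamide 2, antibiotics 3, sequestrants 4 units/day), all
configurable: unit prices are well sourced but per-event quantities are a
modelling choice, so they are explicit knobs rather than buried constants.
Sick leave attaches 14.55 days per event (multiplied by 1.5 after
hospitalization — the 0.5 factor is *additional* leave) plus 9.65 days on
entry into symptom management (once per event, not per cycle spent
managed: a recurring interpretation would implausibly dominate all other
costs).

Trees are collapsed exactly by path enumeration; a Monte-Carlo walk oracle
in the test suite confirms the expectations.

## Valuation

- **Discounting**: costs 3.0%/year, utilities 1.5%/year, factors
  $(1+r)^{-t}$ with $t$ at mid-cycle by default (start-of-cycle available
  via `half_cycle="start"`); life-years use the trapezoid of start- and
  end-of-cycle alive occupancy (half-cycle correction).
- **Direct costs**: event flows × collapsed-tree expected costs.
- **Morbidity productivity**: sick-leave days × daily wage (€250.118) ×
  activity rate (75.1%), for the working-age (< 65) portion of the cohort.
- **Mortality productivity**: human-capital approach — each toxicity death
  before 65 costs the remaining gross earnings to retirement (annual wage
  € 55,025.90 × activity rate), discounted within the working life at the
  cost rate; the undiscounted totals use the undiscounted earnings sum.
- **QALYs**: baseline age-dependent utility, multiplied for one cycle by
  $(1-|d|)$ during an event (relative disutility −24.7% pharmaceutical,
  −32.3% supportive, −38.7% surgical; the third printed disutility row is
  attributed to surgery, matching the three named pathways).

The hospitalization scenario reports *expected* cumulative admissions per
100 patients as (fractional) expectations, not rounded integers.

## Sensitivity analyses

*One-way DSA* multiplies one parameter at a time by 0.70/1.30, capping
probabilities at 100% (logged). *PSA* draws all parameters jointly and
independently. Two distribution modes exist:

- **calibrated** (default): beta parameters are re-derived by method of
  moments around the printed base-case mean with effective sample size 100
  (several printed beta parameters are inconsistent with their own base
  values — e.g. a 92.80% success probability carrying β(41,22), mean
  0.651); gamma keeps its printed shape with scale re-set to base/shape;
  lognormal uses σ=0.25 (none is printed) with μ set for mean = base.
  This keeps the PSA centred on the base case, which is what a PSA of this
  design intends.
- **verbatim**: distribution parameters exactly as printed.

Grade probabilities carry no individual distributions; their joint
uncertainty is a single multiplicative factor on the reference vector,
drawn as $2 \cdot \mathrm{Beta}(50, 50)$ (mean 1, SD ≈ 0.10, support
[0, 2] — a plain beta cannot be centred on 1). Because the factor moves
all techniques together, its first-order effect on *incremental* outcomes
largely cancels; the incremental cost responds non-monotonically
(saturation: higher toxicity depletes the 3D-CRT at-risk pool faster,
narrowing the between-technique gap), so this factor ranks mid-table in
the cost tornado while population and indirect-cost parameters
(activity rate, wages, early recurrence risk) rank high. A DSA that
perturbed each technique's probabilities independently would rank toxicity
risk first; with the correlated design that information sits in the PSA
factor instead.

## Synthetic fixtures

The three population inputs emulate national registry data:

- **Life table**: Gompertz–Makeham, $q(a)=1-e^{-(\lambda + A e^{Ba})}$,
  λ=5·10⁻⁴, A=2·10⁻⁵, B=0.095/yr, giving a remaining life expectancy of
  ≈ 15 years at age 70 — Western European order of magnitude.
- **Incidence mix**: discretized Gaussian over ages 25–99, mode 70,
  spread 12 years — a realistic breadth for rectal-cancer age at
  diagnosis.
- **Utility curve**: linear decline 0.90 (age 25) → 0.65 (age 100);
  a logistic variant is available.

These reproduce the *structure* the analyses assume (monotone adult
mortality, unimodal late-adult incidence, declining utility in [0,1]) but
not any specific country's values. Consequently, tests of absolute
economic totals only check direction and order of magnitude; exact-value
tests are confined to quantities that depend solely on the parameter
table (probability scaling, tree expectations, the zero-mortality
hospitalization scenario). Passing tests therefore demonstrate internal
correctness and the published technique ordering, not calibration to a
particular population.

## Numerical conventions and checks

- Transition-matrix rows sum to 1 within 1e-9 (property-tested over 1,000
  random parameter draws); occupancies conserve mass to 1e-9 per cycle.
- The vectorized engine is verified cycle-by-cycle against explicit
  transition-matrix propagation (1e-12) and against a 50,000-patient
  individual-level microsimulation (3 Monte-Carlo SEs at cycles 10/40/100).
- Rate/probability conversions round-trip to 1e-12.
- Age-100 truncation: cohorts whose horizon falls before the longest run
  are frozen (no transitions, no accrual) once they reach it.
- Problem sizes: the bundled analyses use the full 75-age mix, 1,000 PSA
  draws and 10⁶-walk / 5·10⁴-patient oracles in the test suite; these
  sizes give Monte-Carlo errors well below the decision-relevant margins.

## Known limitations

- The within-cycle treatment trees are reconstructed from the clinical
  pathway description; the original supplementary tree topology may
  differ in detail (the hospitalization-scenario validation band reflects
  this).
- Whether the loperamide success probability is per course or per cycle
  is not documented; it is treated as per event.
- Recurrence risks for pharmacologically managed patients are not
  published; the non-operative ("supportive") values are used as proxy
  (configurable to the surgical values).
- PSA draws are independent across parameters; no correlation structure
  is imposed beyond complement pairs and the shared toxicity factor.
- No currency conversion or inflation machinery: all prices enter as
  2022 euros.
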