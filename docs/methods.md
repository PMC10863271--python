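# Methods

## The decision problem

`ntgcua` models a closed cohort of Chinese patients with mild normal-tension
glaucoma (NTG), entering at age 64, followed for 10 annual cycles through
four health states: **mild → moderate → severe** disease, with **death**
reachable from every alive state. Two management strategies are compared:

* **Positive treatment** — intensive IOP lowering from the mild stage.
  Patients either stay on topical medication (a 3:1 mix of dual and triple
  therapy) or, for a configurable fraction (`surgery_rate`), receive
  trabeculectomy at entry. Annual progression probabilities are
  0.044 (mild→moderate) and 0.018 (moderate→severe).
* **Traditional treatment** — follow-up only while mild; surgery plus
  medication once the disease progresses, captured as stage-level first-year
  and consecutive-year cost aggregates. Annual progression probabilities are
  0.149 and 0.056.

Outcomes are per-person discounted costs (2023 USD, payer perspective,
direct costs only) and quality-adjusted life years (state utilities
0.80 / 0.75 / 0.71 / 0), both discounted at 3.5%/year. The decision
statistic is the incremental cost-utility ratio
ICUR = ΔCost/ΔQALY, judged against 1× and 3× China's 2023 per-capita GDP
($12,692.90): below 1× GDP the positive strategy is *worthwhile*, below 3×
GDP *acceptable*, otherwise *not acceptable*. When one strategy is both
cheaper and more effective the ratio is replaced by a dominance label;
a zero QALY increment raises an explicit undefined-ICUR condition.

## Rate arithmetic

Multi-year trial probabilities become annual transition probabilities under
a constant hazard: r = −ln(1 − p_t)/t and p_1 = 1 − e^(−r). The treated
arm's 5-year progression probability of 0.20 therefore corresponds to an
annual probability of 0.0436 ≈ 4%, consistent with the tabulated 0.044.
Note that the event form 1 − e^(−rt) is required; the survival shorthand
e^(−rt) gives the complementary probability.

## Cycle mechanics and conventions

Within a cycle, death competes with progression and is applied first:
an alive row of the transition matrix is ((1−q)(1−p), (1−q)p, 0, q).
This keeps rows stochastic without renormalisation; the alternative order
(progression first) changes 10-year QALYs by less than 0.01.

**Half-cycle correction.** The default accrual is the classic trapezoid
form: boundary-state occupancies are weighted ½ at the first and last cycle
boundaries and 1 in between, each multiplied by the per-boundary discount
factor (1+r)^−c. This treats transitions as occurring mid-cycle by
averaging the discounted accruals of adjacent boundaries, and it applies
uniformly to QALYs, recurring costs and one-time boundary charges — so the
entry-cycle trabeculectomy cost carries a discounted weight of ½, and a
first-year stage cost carries the weight of the boundary at which the
member arrives in the stage. A `midpoint` variant (mean occupancy times
(1+r)^−(c+½)) and an uncorrected variant are selectable via
`EconomicSettings`; all three reduce to per-boundary weight vectors.

**Mortality.** Natural annual mortality is age-banded (0.364% at 65–69,
0.518% at 70–74; entrants at 64 fall into the first band). Two switches
control how it enters the matrix:

* `band_mode` — `'entry'` (default) holds the entry band's rate over the
  whole horizon; `'attained'` switches bands with the age attained at each
  cycle start.
* `apply_odds_ratio` — when set, the glaucoma mortality odds ratio (1.8) is
  folded in on the odds scale, p′ = oR/(1+oR) with o = p/(1−p)
  (`adjust_mortality`).

The defaults (`'entry'`, odds ratio not applied) are the convention set
under which the model reproduces the published per-arm QALYs (6.58 / 6.43)
at their printed precision; the published one-way cost decomposition
likewise pins the trapezoid accrual (the implied discounted weight on the
one-time surgery cost is 0.4999 ≈ ½). Both switches are fully implemented
and tested, so the structurally "complete" variant — attained-age bands
with the odds-ratio uplift — is one configuration edit away; it lowers
10-year QALYs by ≈0.1 per arm and leaves every qualitative conclusion
unchanged.

## Costing rules

Annual medication cost is `dose × (¾·dual + ¼·triple)` = $348.04 at normal
dose; the dose multiplier (1.5) applies from the first cycle a member
occupies a progressed stage, and stays on (states never regress, so the
per-patient flag coincides with stage occupancy).

*Positive arm, medication path*: medication (normal or escalated dose) plus
follow-up ($79.55/year unprogressed, $119.32/year progressed — treated as
per-year visit-schedule totals).
*Positive arm, surgery path*: trabeculectomy ($530.97 × scenario
multiplier) plus follow-up at entry; thereafter follow-up for everyone,
with the 20% surgical-failure fraction resuming the normal-dose 3:1
medication mix from the cycle after surgery. The failure fraction is not
dose-escalated: the published totals identify post-surgical unstable-IOP
therapy with the plain mix, and the implied surgery-path cost (1519.78 from
the exact linearity of the published 0/25/50% totals) matches this rule to
0.8%. Path costs blend linearly in `surgery_rate`.
*Traditional arm*: follow-up in every alive state (the visit schedule
applies to both strategies), plus the stage aggregates — $381.84 in the
entry year of the moderate or severe stage (charged on the entrant fraction
at each boundary, hence at most once per member per stage entered, and
again on severe entry after moderate) and $254.56 in consecutive years.

Under these rules the model reproduces the published strategy costs to
within 2% (medication-only 3882.22 vs 3887.38; 25% surgery 3294.66 vs
3295.48; 50% surgery 2707.10 vs 2703.58; traditional 1936.76 vs 1975.79);
the residual in the traditional arm sits in its follow-up component, whose
exact published composition is not decomposable from the printed tables.
Full-precision ICURs differ from the printed ones by more: the published
table derives increments from 2-decimal-rounded averages (e.g.
1911.59/0.15 = 12,743.93), while this package reports the unrounded ratio
(13,499.66 for the same comparison). The `icur` operation applied to the
printed increments reproduces every printed ratio exactly.

`inflate_cost` carries historical prices forward at 3.5%/year; the
traditional arm's stage aggregates are 2019 source values (345 / 230 USD)
inflated three years.

## Sensitivity analyses

**One-way.** Each lever is moved alone: transition probabilities ±50%,
cost inputs ±20% (eye drops move dual and triple together; follow-up moves
both visit-schedule totals), and the surgery rate swung 25% ↔ 50%. Tornado
rows carry both the ICUR range and the incremental-cost range; the figure
sorts on incremental-cost spread (the published tornado's quantity) with
stable ties. The top three levers — surgery rate, mild→moderate
progression, eye-drop cost — match the published figure, and the eye-drop
incremental-cost spread (740.8) reproduces the published implied value
(739.1) to 0.2%.

**Probabilistic.** Because the source's distribution appendices are
unavailable, the PSA uses the field's standard families: Beta for
probabilities and utilities, Gamma for costs, each moment-matched to
mean = base value and SD = 10% of the mean (the stated SD rule). Mortality
and structural rules (mix ratio, dose multiplier, failure rate,
discounting) are not drawn. Utility margins are independent, so roughly a
third of draws invert the mild/moderate/severe ordering; these draws are
kept (re-ordering or rejecting would bias the moments) and the violation
fraction is reported. The headline statistic is the ICUR of mean
increments, matching how a PSA table prints a single ratio. Draws are
propagated through a vectorised replica of the cohort arithmetic
(~1 s for 100,000 draws on one CPU); a test pins the vectorised path to
the scalar engine draw by draw at 1e-8. Default sample size is 10,000;
the full-size run is used where the published analysis is reproduced.
Surgery-cost stress scenarios (5× and 10× the trabeculectomy price) enter
through the strategy's `surgery_cost_multiplier`.

## Synthetic data and what the tests show

`ntgcua.simulate` provides parameter presets (the base case, the
alternative slope-derived positive-arm rates 0.085/0.035, and two stress
sets) and a seeded individual-level microsimulation that samples each
patient's annual path from exactly the matrices the cohort engine uses,
with per-patient surgery assignment and failure. Its role is oracle, not
realism: agreement of the empirical state frequencies with the
deterministic trace (within 3 binomial standard errors at every cycle,
n = 200,000) validates the cohort propagation, and assignment/failure
frequencies validate the strategy sampling. The generator does not emulate
real-world features absent from the model — heterogeneous entry ages
(beyond an optional jitter used only in robustness tests), adherence,
bilateral disease, or measurement of visual-field trajectories — so
passing tests certify the model's internal arithmetic and its agreement
with the published tables, not calibration to an external cohort.

## Numerical choices and limitations

* Row-stochasticity is enforced at 1e−12, occupancy conservation tested at
  1e−9; probability↔rate round-trips hold to 1e−12.
* Tie-breaks: tornado bars with equal spread keep input order.
* Degenerate inputs: `sd_fraction = 0` makes the PSA collapse exactly onto
  the deterministic result; zero progression with (near-)zero mortality
  yields an identity transition matrix; a zero QALY increment raises
  rather than divides.
* The horizon is short enough (ages 64–74) that a single odds-ratio and
  two mortality bands suffice; extending the horizon requires extending
  the band table, which is validated for coverage.
* Utilities are state-constant (no time-in-state tunnels); costs carry no
  indirect or societal components; adherence is not modelled.
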