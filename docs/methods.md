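# Methods

This note records the modelling conventions, defaults, and numerical choices
behind `omppricer`, and what the test suite does and does not establish.

## Scope and perspective

The package prices one medicine for one market (the EU, 447 million people in
the bundled case) under four cost-based models. It deliberately excludes
list-price comparisons, QALY-monetized innovation premiums (the bundled
case's innovation premium is a fixed 5–15% surcharge instead), worldwide
GDP-tiered differential pricing, and any per-member-state, body-weight or
vial-count refinement. Prices are per "average" patient-years.

## Scenario construction

Each model has a minimum-price and a maximum-price input column. Column
orientation follows the source-table convention: a parameter inversely
proportional to the price (prevalence, treatment rate, patent years, …)
takes its highest value in the *minimum* column. The average scenario is
built by averaging inputs field-wise and re-pricing — never by averaging the
two prices. Averaging integer inputs can produce half-integers (patent years,
development years); all formulas accept real-valued years, and the DCF
horizon treats a fractional final year as a pro-rated patient-year weight.

Reported prices are rounded half-up to the reporting granularity (€1,000
default). Rounding happens only at reporting; orderings and sensitivity
analyses use full precision. Patient counts for the static models are
rounded half-up to whole patients (this reproduces the published 907 and
179); the DCF schedule stays real-valued because patients there act as a
rate in cash flows.

## Population

Static models: N = round_half_up(prevalence/1e6 × population × treatment
rate × market share). ROROR carries a treatment-rate input (its published
patient counts imply one) with market share fixed at 1; NCP fixes market
share at 1; AIM uses both.

DCF schedule: the prevalent pool is a steady-state stock — incident inflow
is assumed to offset attrition, so prevalence and incidence terms are both
applied every year rather than accumulating the incident cohort
(accumulation grossly overshoots the published patient averages; the
steady-state reading lands within 0.6% of the published minimum-scenario
average). Prescription restrictions apply separately to the prevalent and
incident pools; the four clinical rates (response, failure, adverse events,
contraindications) compose multiplicatively as independent filters — the
source does not state additive vs multiplicative, and the multiplicative
form keeps a probabilistic interpretation. Uptake ramps linearly to its cap
over `uptake_ramp_years` (default 0 = instant cap, since the real uptake
curve is not published; the ramp is a config knob).

## Pricing conventions

- NCP / AIM compositions are reconstructions validated against the published
  outputs they can reach: NCP reproduces €87k exactly and €224k/€126k within
  one rounding step from raw inputs (exactly when composed from the published
  intermediate rows); AIM reproduces €33k under both bonus conventions and
  €104k (average) under the additive default. The additive bonus convention
  is the default because it matches the published average; multiplicative is
  a switch.
- DCF: end-of-year discounting; the EU-attributed R&D lump sum is a sunk,
  undiscounted outflow at launch (t = 0). Forward-compounding of pre-launch
  R&D at the cost of capital is available (`compound_rd_years`) but off by
  default. Drug costs are a margin-style deduction, δ = 40% of revenue in
  the bundled case. The breakdown splits the price into the r = 0
  cost-recovery price ("rd_principal"), the discounting increment
  (P* − P*|r=0, "cost_of_capital") and the premium.
- ROROR: WACC compounding and GDP deflation are combined into the single
  real-terms factor ((1+w)/(1+d))^T_dev. The published ROROR prices are not
  reproducible from main-text inputs under any simple convention tried (the
  maximum scenario explodes under naive nominal compounding); this package's
  convention is therefore held to property-based checks, not to the
  published figures.

## Sensitivity and fixed-population analyses

OAT sensitivity substitutes one parameter (group) at a time into the average
scenario at its min-/max-column values. Parameters the tables only define
jointly — the DCF prescription restrictions on the prevalent and incident
pools — vary as one named group. Substituting a parameter's own average is
an exact identity (bitwise-equal price), which the suite asserts.

The fixed-population analysis pins the treated population (static count, or
a flat DCF schedule) and bypasses treatment rate, market share and uptake;
its output is provably invariant to those inputs.

## Synthetic scenarios

`sample_config`/`sample_inputs` draw admissible inputs for property tests:
prevalence 0.1–30 per million, incidence 0–2 per million, rates uniform on
[0, 1] (response ≥ 0.5), patent years 1–20, R&D lump sums log-uniform
€50M–€2.5B (the AIM cap), unit costs log-uniform €1k–€200k, cost of
capital/WACC 0–20%, GDP deflators 0–8% (clamped below WACC so price is
monotone in development time), margins/bonuses 0–50%, drug-cost share 0–60%.
Draws whose implied treated population falls below one patient are resampled
(bounded retries). One integer seed controls everything; each model reads a
fixed substream offset so adding a model does not shift other models' draws.

The generator emulates the *structure* of admissible cases, not the joint
distribution of real OMP portfolios: parameters are sampled independently,
costs are log-uniform rather than fitted, and no correlation between, e.g.,
prevalence and price exists by construction. Passing property tests
therefore establish algebraic behaviour (monotonicity, conservation,
determinism, oracle agreement), not calibration to real market data.

## Numerical choices

- Rounding: half-up everywhere a value is reported (`floor(x + 0.5)`), to
  avoid banker's-rounding surprises on .5 boundaries.
- Breakdown conservation is enforced at construction: components must sum to
  the unrounded price within 1e-9 relative.
- The DCF break-even price uses the closed form K / Σ nₜ(1−δ)/(1+r)ᵗ; the
  test suite checks it against an independent NPV root (scipy bisection) to
  1e-6 relative on 1000 seeded random instances.
- Degenerate inputs raise typed errors (zero patients, zero patent years,
  zero discounted revenue, empty schedules) rather than returning infinities.

## Known limitations

- The published DCF and ROROR scenario prices (€182k/€748k/€377k and
  €81k/€273k/€134k) are not reproducible from main-text inputs; they depend
  on supplementary conventions (notably the real uptake curve) that are not
  public. The package documents its own conventions and verifies them by
  properties instead. Two acceptance tests are intentionally kept failing to
  keep the discrepancies visible: the published DCF maximum/average patient
  schedules (186/253 vs reconstructed 179.8/273.5), and the claim that the
  cost-of-capital component leads the DCF breakdown (under the instant-uptake
  default the R&D principal leads; with the published break-even prices the
  claim would hold).
- The published AIM maximum is internally inconsistent at the source
  (€340k/€400k in different places; reconstruction gives ≈€405k) and is not
  asserted.
- Published counts 359/604/452 differ by <1% from any standard rounding of
  the printed inputs; the suite asserts them at ±1% and flags them as
  transcription-level discrepancies.
- Problem sizes: property suites run 1000 seeded draws per model and the
  full engine runs in well under a second per case, so no down-scaling is
  applied anywhere.
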