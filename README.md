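# omppricer

Cost-based pricing models for orphan medicinal products (OMPs).

When a rare-disease medicine reaches the market with thin effectiveness data,
value-based pricing and conventional cost-effectiveness analysis give payers
little to negotiate with. Cost-based pricing models offer an alternative
benchmark: a price that recovers documented development and production costs,
plus an explicit, arguable surcharge for profit, innovation, or the cost of
capital. `omppricer` implements four such models as a reusable scenario
engine and ships, as its bundled case, lumasiran — an RNAi therapy for
primary hyperoxaluria type 1 (PH1), a disease affecting roughly 1.6–2.9 per
million people. It is written for health-technology-assessment analysts,
payers, and pricing researchers who want reproducible, inspectable price
benchmarks rather than numbers from a spreadsheet.

## The models

All models report a price per patient per year (PPPPY) in EUR and expose an
additive component breakdown. Global R&D lump sums are attributed to the EU
by a population share φ (0.3585 for the bundled case), and amortized over the
eligible patients *N* and the remaining patent years *T*:

    rd_ppppy = C·φ / (N·T)

with *N* = round(prevalence × EU population × treatment rate × market share).

**NCP — Novel Cancer Pricing model.** Audited cost build-up with a
clinical-benefit profit margin π:

    P = (rd_ppppy + COGS·(1 + marketing)) · (1 + π)

**AIM — AIM model for innovative medicines.** Lump-sum R&D recovery (lump
sums capped at €2.5B), standardized production/overhead and sales
assumptions, an 8% basic profit and an innovation bonus β ∈ [0, 40%]:

    P = (rd_ppppy·(1 + sales) + production) · (1 + profit + β)

(a multiplicative convention `(1+profit)(1+β)` is a config switch).

**DCF — Discounted cash flow.** The break-even price P\* at which the net
present value of launch cash flows reaches zero at patent expiry — R&D lump
sum K = C·φ out at t = 0, net revenues discounted at the cost of capital r:

    P* = K / Σₜ nₜ·(1 − δ) / (1 + r)ᵗ ,   P = P*·(1 + premium)

where δ is the drug-cost share of revenue and nₜ a per-year treated-patient
schedule built from prevalence, incidence, prescription restrictions,
clinical attrition, population growth and a capped uptake curve.

**ROROR — Real-option rate of return.** R&D per patient-year compounded at
the weighted average cost of capital w, net of the GDP deflator d, over the
development time T_dev:

    P = (production + rd_ppppy·((1+w)/(1+d))^T_dev) · (1 + π)

The engine runs minimum/maximum input columns plus an average scenario
recomputed from averaged inputs, a one-at-a-time (tornado) sensitivity
analysis around the average scenario, and a supplementary analysis with the
treated population pinned (default 1000 patients).

## Worked example

```sh
omppricer run --config src/omppricer/data/lumasiran.yaml --model all --scenario all --out out/
```

logs one line per model/scenario:

```
INFO omppricer: ncp/min: reported price 87000 EUR ppppy
INFO omppricer: ncp/max: reported price 223000 EUR ppppy
INFO omppricer: ncp/avg: reported price 126000 EUR ppppy
INFO omppricer: aim/min: reported price 33000 EUR ppppy
...
```

and writes `scenario_table.csv/.json` (unrounded and reported prices plus all
intermediates), `breakdown_table.csv/.json` (component values and shares),
`tornado_table.csv/.json` (OAT sensitivity) and `overlap.json`. For the
bundled case the NCP range is €87,000–€223,000 (average €126,000) and the AIM
minimum is €33,000 per patient per year; the price interval shared by all
four model ranges is

```json
{"empty": false, "lower_eur": 133000, "upper_eur": 223000}
```

i.e. from the DCF minimum up to the NCP maximum. The tornado table shows
prevalence driving the widest NCP interval (±, width ≈ €39,000 around the
€126,373 base) — patient-number uncertainty dominates every model.

The same analyses are available as library calls (`run_scenarios`,
`oat_sensitivity`, `fixed_population_analysis`, `range_overlap`) on a
validated `CaseConfig`; `sample_config(ranges, seed)` generates random
admissible cases for property testing. Other medicines are priced by writing
a YAML/JSON file with the same keys as the bundled fixture (strict schema;
monetary entries may be written as `{value: ..., currency: USD}` and are
converted at load time — the bundled 2021 rate 0.8458 EUR/USD is this
package's default, not a value from the source tables).

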