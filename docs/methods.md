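# Methods

This note documents the model behind `magnetea`: what is simulated, which
numbers are published inputs versus calibrated fixture values, the numerical
choices, and what the model can and cannot say.

## Scope and design basis

The modelled plant produces 640 kg/yr of biological-origin magnetite
nanoparticles (BMNs, magnetosomes) with *M. gryphiswaldense* MSR-1, in three
sections: inoculum train, fermentation, downstream recovery. Two operating
modes share the same flowsheet: **single-stage** fed-batch (42 h, 250 mg/L
magnetite) and **semicontinuous** (stage 1 as above; 90 % of the broth
harvested and replaced; stage 2 run from the retained 10 % at 110 mg/L, then
fully harvested). All economics are reported in USD; Brazilian-market prices
are held in BRL and converted at the scenario exchange rate (5.20 BRL/USD)
*at evaluation time*, so the exchange rate is a live sensitivity parameter.

## Fermentation model

Growth is exponential at the specific rate μ (default 0.10 h⁻¹, the value
derived in the source study's running text; its parameter table prints 0.01,
which we treat as a typographical slip — both are selectable). The culture
starts at X₀ = 0.30 g/L dry cell weight after inoculation and grows to a
substrate-limited cap X_f = 3.5 g/L, both realistic for high-density MSR-1
cultivation. The fermentation duration is fixed (42 h) and splits into

* a growth phase t_g = ln(X_f/X₀)/μ  (≈ 24.6 h at μ = 0.10), and
* a production window t_p = 42 − t_g during which magnetite accumulates at a
  constant volumetric rate.

The nominal titer (250 mg/L) is defined at the reference μ = 0.10; at other
growth rates the titer scales with t_p. This is the mechanism behind the
growth-rate sensitivity: a 30 % slower strain spends most of the fixed
recipe in growth, the production window collapses from 17.4 h to 6.9 h, and
annual product falls to ~40 % — multiplying the unit cost by ≈ 2.5. (A pure
scheduling channel — longer batches, fewer per year — was examined first and
produces only a ≈ 1.3× response, far weaker than the sensitivity the model
is meant to reproduce, because the fermenter-bound cycle time dilutes any
batch-time growth.) The seed train still dilates the *batch* time at low μ
(ln 10/μ per stage), which the schedule accounts for, but the cycle time is
fermenter-bound and fixed, so the batch count barely moves.

pH-coupled feeding is represented as an aggregate feed mass balance — feed
volume equals final minus initial working volume, with the medium recipe's
composition — not as a closed-loop controller: only per-batch totals enter
the TEA. Oxygen transfer (kLa), dissolved-oxygen dynamics and shear effects
at m³ scale are out of scope; they are precisely the scale-up unknowns the
sensitivity analysis brackets via the titer and growth-rate sweeps.

### Stoichiometry

The global growth reaction is carried verbatim with molar coefficients
352 lactate : 33.6 NO₃⁻ : 133 NH₄⁺ : 6.46 O₂ : 1.25 Fe³⁺ →
718.4 biomass : 591.3 H₂O : 314 CO₂, biomass CH₂.₀₆O₀.₁₃N₀.₂₈Fe₀.₀₀₁₇₄.
The printed equation is typographically corrupted in its source; species are
reconstructed from context (lactic acid substrate, nitrate/ammonium
nitrogen). It does **not** balance element-by-element (e.g. nitrogen
residual −34.55 mol per formula unit); residuals are computed and surfaced
as data, never forced to zero, and regression-tested. The economics use only
coefficient ratios (the medium recipe, not the stoichiometry, drives
material costs; the stoichiometric demands are reported as metabolic floors
and checked to be covered by the recipe).

## Downstream recovery

Cascade: high-pressure homogenizer (4 passes; per-pass lysis 0.70, a
standard figure for high-pressure homogenization, giving 1 − 0.3⁴ = 99.19 %
lysis) → magnetic separation column (MSC, 85 % capture) → disk-stack
centrifuge (90 %) → second MSC (85 %). The published "binding capacity 85 %"
is read as per-column capture applied to both columns; this is the only
reading consistent with the published low-efficiency sensitivity point
(cost scales with (0.85/0.65)² ≈ 1.71). Overall recovery is
0.9919 × 0.85 × 0.90 × 0.85 = 0.645. Every stage conserves magnetite
exactly (captured + waste = input); magnetite in unlysed cells leaves with
the homogenizer waste. Urea (4 M wash), sucrose and wash water scale with
processed lysate volume; phosphate buffer with product mass; the product is
a 1 mg/mL colloid.

## Scheduling

Staggered-batch counting: N = ⌊(AOT − t_batch)/t_cycle⌋ + 1, with
AOT = 7,200 h/yr and the published batch/cycle times (161.7/46.67 h and
193.1/85.75 h). This convention reproduces both published batch counts (151,
82) exactly; plain ⌊AOT/t_cycle⌋ does not, which is how the convention was
identified. Labor is fixed operator-hours per batch per section.

## Costing and calibration

The intermediate cost model (equipment lists, installation factor, indirect
fractions, medium recipe, labor hours, utilities) is not published; it was
**calibrated once** against the published economic summary and then frozen
in `magnetea.fixtures`. The calibration is algebraic and auditable
(`magnetea.calibrate`, or `magnetea calibrate` on the CLI, re-derives every
constant and verifies the frozen values). Anchors and choices:

* **Throughput basis.** The 640 kg/yr annual throughput is interpreted as
  *recovered* product. Single-stage working volume then follows as
  640/(151 · 0.25 kg/m³ · 0.645) = 26.29 m³ — 91 % of the 29 m³ vessel,
  above the stated 80 % maximum working fraction, which the validator
  surfaces as a warning. (A produced-basis reading cannot be reconciled with
  the published batch counts and recovery efficiencies at all.) The
  semicontinuous volume is 33.61 m³ in a proportionally larger vessel.
* **Capital.** Equipment totals pinned at the published US$ 8.898 M /
  12.888 M with the main bioreactor at 30.6 % / 38.2 %; installation
  multipliers (4.836 / 5.123) are the published plant-cost over equipment
  ratios; working capital 15 % of direct fixed capital plus a startup
  fraction closing the published US$ 52.11 M / 79.86 M investments.
* **Indirect operating costs** are fractions of direct fixed capital:
  straight-line depreciation over 12 years with 5 % salvage, plus
  maintenance and taxes/overhead fractions closing the published operating
  totals (US$ 6.64 M / 7.15 M per year). A 10-year life was considered and
  rejected: on the semicontinuous plant it alone would exceed the entire
  indirect budget implied by the published 76–79 % indirect share; any life
  ≥ 11.6 yr is feasible and 12 yr is adopted for both modes.
* **Materials.** A medium recipe (per m³) with commodity BRL prices; the
  lactic-acid concentration (51.3 kg/m³) sets its 64 % share of
  fermentation-section material cost, and the urea wash ratio (0.80 m³/m³
  lysate) sets urea's 87 % share of downstream materials while closing the
  total at the published US$ 1,472 per kg product (single stage). With the
  same recipe, the semicontinuous mode computes to ≈ US$ 1,899/kg — higher
  than the published 1,477, an arithmetic consequence of "twice the medium
  per batch" at 1.84× the product per batch; the published figure is not
  reachable under the published medium statement and is reported as-is.
* **Labor** is calibrated so single-stage annual labor cost is 1.09× the
  semicontinuous (more inoculations and CIP cycles per year), at
  130 BRL/h; QC is 15 % of labor. Utilities are a per-batch aggregate.

Everything downstream of the frozen calibration — the sensitivity sweep
points (80 mg/L titer → ≈ US$ 32,400/kg operating cost; 65 % MSC capture →
≈ US$ 17,700/kg; capacity doubling → ≈ 22 % unit-cost drop) — is an
out-of-sample prediction of the calibrated model.

## Economics

Unit production cost = annual operating cost / annual recovered product.
Payback = total investment / after-tax net profit, with net profit
(revenue − operating cost)(1 − tax) and **no depreciation add-back**; the
income-tax rate (0.40) is the convention under which the model's capital and
operating costs reproduce the published minimum selling prices within a few
percent (the add-back convention undershoots by ~25 %). The MSP solves
payback(p) = 5 yr by bisection (`scipy.optimize.bisect`, relative tolerance
1e-6) on the 30–120 thousand USD/kg grid; payback(p) is strictly decreasing
above break-even, so the root is unique. If a rescaled or perturbed plant
has its MSP outside the grid, the bracket is widened geometrically first;
with expansion disabled an unbracketed grid raises an error advising
expansion. No NPV/IRR or discounting is performed — the model is simple
payback by design.

## Sensitivity and ensembles

One-at-a-time sweeps re-run the full pipeline per value, holding all else at
base; a row-level error is recorded (and the sweep continues) for values
violating scenario invariants. MSC-efficiency sweeps move both columns
together. Plant-capacity rescaling scales volumes linearly, equipment
through its 0.6 power-law exponents, labor with exponent 0.25 and utilities
linearly, keeping the batch schedule fixed.

The scenario-ensemble generator draws triangular perturbations (mode at the
base value) over the same ranges as the deterministic sweeps: lactic acid
4.55–13.65 BRL/kg, urea 0.26–3.90 BRL/kg (0.05–0.75 USD/kg; units of the
published urea sweep are unstated and read as USD/kg, matching commodity
pricing), exchange rate 4.0–6.5 BRL/USD, μ 0.07–0.13 h⁻¹, titer 80–350
mg/L, MSC capture 0.65–0.95, capacity ×0.5–×2. Draws use
`numpy.random.default_rng(seed)` (default seed 42) in sorted parameter
order; invalid draws are rejection-resampled with the count reported;
summaries are P5/P50/P95 by linear interpolation. Identical seeds give
bitwise-identical summaries.

What the ensemble emulates is parametric uncertainty around the base case.
It does **not** emulate structural uncertainty (a different flowsheet,
failure modes, correlated parameters — draws are independent), so a passing
Monte-Carlo suite says the *model* is robust to input noise, not that the
process is de-risked.

## Numerical choices and degenerate inputs

Tolerances: downstream conservation is exact to floating point and tested at
rel. 1e-9; MSP bisection at rel. 1e-6 (cross-checked against a 1-USD grid
scan). Prices below break-even return +∞ payback (a sentinel, not an
error). Zero downstream efficiencies are rejected as modelling mistakes;
μ ≤ 0, overfilled vessels, harvest fractions outside (0,1) and expansion
factors ≤ 1 are hard errors. μ low enough to consume the whole fermentation
time (t_g ≥ 42 h, i.e. μ ≤ 0.058 h⁻¹ at the default densities) gives a zero
production window and hence zero product — the unit cost is then undefined
and surfaces as an error row in sweeps. Scenario documents are strict:
unknown keys are errors (a typo in a price name must not silently drop a
cost), and hard invariant violations abort with the offending path.

## Known limitations

* The calibration absorbs every unpublished cost detail into a few
  fractions; section-level attributions (e.g. fermentation ≈ 55 % of
  operating cost) are therefore approximate even where totals are exact.
* No oxygen-transfer or pH-titration physics; titer and growth-rate sweeps
  are the proxy for all scale-up biology.
* The semicontinuous material cost per kg exceeds the published value (see
  calibration notes); its operating total and unit cost still close.
* Problem sizes are desk-scale throughout: a full base-case analysis is
  ~1 ms, a 1,000-draw ensemble ~2 s on one CPU; tests use 50–500 draws.
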