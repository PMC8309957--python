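# Methods

## The model

`ammokin` treats a dialyzed neonate as a single well-mixed compartment.
The ammonia distribution volume `V` (mL) is identified with total body
water, the dialyzer removes ammonia with a constant clearance `K`
(mL/min), and the patient produces ammonia — net of scavenger therapy — at
a constant rate `G` (µmol/min). The governing equation is

    dC/dt = 1000·G/V − (K/V)·C       on dialysis
    dC/dt = 1000·G/V                 off dialysis (K = 0)

with `C` in µmol/L; the factor 1000 converts the mL volume to litres.
Closed forms follow directly:

* on-dialysis decay: `C(t) = C∞ + (C0 − C∞)·exp(−K·t/V)` with the
  generation steady state `C∞ = 1000·G/K`;
* off-dialysis rise: `C(t) = C0 + 1000·G·t/V`;
* time to target: `T = (V/K)·ln((C_start − C∞)/(C_target − C∞))`,
  reducing to `T = (V/K)·ln(C_start/C_target)` when `G = 0`;
* clearance from one paired dialyzer sample:
  `K = Qb·(C_inlet − C_outlet)/C_inlet`, and `ER = K/Qb`.

Assumptions inherited from the model: single pool (no multicompartment
rebound — observed rebound is attributed to ongoing generation), constant
`K` and `G` within a phase, negligible ultrafiltration (constant `V`
during a session), and a flow-independent extraction ratio when converting
`ER` measured at one blood flow to a clearance at another. `G` defaults to
0 everywhere, which is the regime under which the reference tables were
generated; the generation-extended forms exist for rebound simulation and
for steady-state reasoning.

Units are fixed package-wide (min, mL, mL/min, µmol/L, µmol/min); all
conversions happen at I/O boundaries.

## Parameters that matter

| parameter | unit | default | notes |
|---|---|---|---|
| `V` | mL | — | resolved per patient; the reference infants use 72 % (3 kg) and 63 % (4 kg) of body weight |
| `K` | mL/min | — | `ER × Qb`; reference ERs 0.45 (4008/FXPaed), 0.15 (CarpeDiem 0.25 m²), 0.13 (0.15 m²) |
| `G` | µmol/min | 0 | measured values cluster near 0.5 µmol/min |
| table horizon | min | 1440 | cells beyond it print `>>` |
| per-kg blood-flow rules | mL/kg/min | 15 initial, 10 after | clamped to each machine's operating range before any kinetics |
| noise CV (synthetic) | — | 0.05 | multiplicative lognormal, median 1 |

Anthropometric total-body-water formulas are deliberately pluggable
(`TBWResolver`): their coefficients are institution choices, so the
package ships only explicit-volume, weight-fraction and a two-entry
reference lookup (the 3 kg/72 % and 4 kg/63 % infants) that refuses other
inputs rather than extrapolate.

## Estimation

Clearance is fit by OLS of `ln C` on `t` over systemic intradialytic
samples (`K̂ = −slope·V`), using all session points by default with an
optional time window. Non-positive concentrations are excluded (logged);
a positive slope clips `K̂` to 0 with a warning so batch processing
survives degenerate sessions. `V` is not estimable from a single decay
(only `K/V` is identified) and is never fit. Generation is the first-to-
last interdialytic rise, `G = ΔC·(V/1000)/Δt`; negative values are
returned with a warning rather than suppressed.

## Numerical choices

* Closed forms are exact per phase; multi-phase schedules chain each
  phase's end concentration into the next, so trajectories are continuous
  at boundaries by construction.
* The validation oracle integrates the ODE with a fixed-step explicit
  Heun (trapezoidal predictor–corrector) scheme. At dt = 0.1 min its
  relative discrepancy from the closed form is far below the 0.1 % test
  band; a first-order Euler step would sit at ~0.12 % for the reference
  scenario (K/V ≈ 0.00625 min⁻¹ over 600 min), which is why the
  second-order step was chosen.
* Reported times are rounded half-away-from-zero to integer minutes for
  tables; internal values stay float. Threshold-crossing times come from
  the closed-form solver, not grid interpolation, so tables are
  grid-independent.
* Protocol tie-breaks among equal-clearance setups prefer the smaller
  priming volume (smaller extracorporeal circuit), then the label
  lexicographically, making synthesis fully deterministic.
* Degenerate inputs: start ≤ target returns 0 min with a warning; targets
  at or below `C∞` raise an unreachable-target error; `K = 0` has no
  steady state and raises.

## Reference-table reproduction and its limits

The published 3 kg table is reproduced cell-by-cell within
max(±5 min, ±1 %) — its printed integers are only self-consistent to a few
minutes (e.g. the 3000→200 and 200→100 columns do not add up to the
3000→100 column exactly). Two published sentinel cells (`>>`, "more than
24 h") disagree with the formula the table was built from: CD025 3000→200
and 1500→100 both compute to ≈1300 min, under the 1440-min horizon. The
package keeps the horizon semantics exact (`>>` iff the computed time
exceeds the horizon, default 1440 min); the corresponding acceptance test
documents the discrepancy and fails on those cells by design.

The published 4 kg table is internally consistent only with a volume of
≈3.16 L (~79 % of body weight), not the stated 63 % (2.52 L). The package
follows the stated fraction; a non-normative test demonstrates both facts
(implied volume reproduces every numeric cell; the stated fraction misses
by >10 %).

## Synthetic data

The generator emulates the measurement structure the estimators consume:
closed-form trajectories sampled hourly (the clinical sampling target)
with multiplicative lognormal noise (median 1, CV 5 % by default — assay
error scales with concentration across the 100–3000 µmol/L range), plus
paired inlet/outlet samples built by inverting the clearance formula.
Everything is seed-deterministic. It does not emulate: assay detection
limits, irregular clinical sampling, drifting clearance within a session
(circuit clotting), scavenger pharmacokinetics, or patient-to-patient ER
variability. Passing recovery tests therefore show the estimators are
correct and noise-stable under the stated error model, not that the
one-compartment description itself holds in any particular patient.

Test and acceptance problem sizes — 200 seeds for recovery Monte-Carlo,
100 random schedules for the oracle comparison at dt = 0.1 min, 1000 draws
for the inversion property — were chosen so the whole suite completes in a
few seconds while keeping Monte-Carlo standard errors well inside the
asserted bands.

## Known limitations

* `V` enters every result linearly and is the least certain input:
  neonatal body water changes rapidly after birth and with fluid balance.
* Flow-independence of ER is an extrapolation consistent with the
  reference tables, not a measured fact; converting ER across large flow
  changes should be validated against paired samples at the new flow.
* Constant `G` ignores metabolic correction dynamics; interdialytic
  predictions are first-order only.
* Blood-water vs plasma-flow corrections to `Qb` and dialysate-side
  saturation are not modeled.
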