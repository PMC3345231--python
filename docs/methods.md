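# Methods

## Scope

`ethexpo` reconstructs systemic ethanol exposure from repeated
hand-sanitizer use indoors in two coupled stages: a pulsed-emission
well-mixed room-air model, and a six-compartment flow-limited PBPK model of
inhaled ethanol. It evaluates scenarios of the form "N people rub their
hands with ethanol gel k times a day for d days in one room" and compares
the predicted blood ethanol against endogenous levels in nondrinkers.
Dermal absorption (~1% of the applied dose on intact skin), oral intake and
acetaldehyde kinetics are out of scope.

## Stage 1: well-mixed room air

Assumptions:

- **Instantaneous emission.** All ethanol of a rub event enters the air at
  the event time. Measured evaporation half-lives of gel films are ~11 s,
  negligible against the hours between events, and the day-1 concentration
  arithmetic of the reference incident matches instantaneous pulses to the
  printed precision.
- **Single first-order loss.** Removal only by ventilation at the
  air-change rate `k = Q/V` (per minute internally; hours at the API);
  no deposition, sorption or re-emission. The reference incident's
  residuals (0.43 → 0.38 g/m³ over 3 h at Q = 0.08 m³/min, V = 116 m³)
  match `exp(−Q t/V)` to two decimals.
- **Spatial homogeneity.** One zone, no gradients.

The closed form is evaluated exactly; window means are computed by exact
integration of the piecewise exponential (with `expm1` so the k → 0
sealed-room limit is stable) and reported in mg/m³. The stored value *at* a
pulse time is the post-jump value, matching how peak concentrations are
conventionally reported.

Gel ethanol content is treated as a mass fraction (default 0.70) of a gel
of density 0.8 g/mL: a 30-person event with 3 mL/person releases
30 × 3 × 0.8 × 0.70 = 50.4 g.

### Agreement with the reference incident evaluation

The original incident assessment produced its air values with a commercial
well-mixed-room package. Our analytic model reproduces its day-1 peaks and
residuals to the printed 0.01 g/m³ once one accounts for the fact that the
printed sums are sums of *independently rounded* terms (e.g. printed
0.43 + 0.54 = 0.97 where the exact values are 0.4345 + 0.5495 = 0.9839);
the printed day-2 start value therefore carries up to two printed ulps of
rounding error, and the tests budget for exactly that. One printed value —
the day-2 residual of 0.8 g/m³ three hours in — is not consistent with the
same first-order decay that reproduces every other value (the closed form
gives 0.869 pre-jump); it is deliberately not a test target. The printed
stepwise window means
(408/768/1108; 924/1224/1518 mg/m³) agree with the analytic time-weighted
means (408.6/769.5/1110.6; 925.3/1225.9/1522.0) within 0.3%.

## Stage 2: flow-limited PBPK

Compartments: blood, fat, liver, rapidly perfused, slowly perfused, brain.
Venous-equilibration (perfusion-limited) tissue equations; hepatic
Michaelis–Menten clearance on the liver-exit (venous) concentration
`C_vL = C_L / P_L:b`, the standard flow-limited convention with Km
expressed in mg/L of liver-exit blood.

Parameters (packaged default, `ethanol_human_table1.yaml`):

| parameter | default | units | note |
|---|---|---|---|
| body weight BW | 70 | kg | allometric base |
| cardiac output QC | 18 · BW^0.75 | L/h | ≈ 436 L/h at 70 kg |
| alveolar ventilation QP | 18 · BW^0.75 | L/h | resting |
| net airway uptake F | 0.62 | — | measured net fractional uptake |
| flow fractions | fat .05, liver .25, rapid .39, slow .19, brain .12 | of QC | sum 1.00 |
| volume fractions | fat .213, liver .0257, rapid .0443, slow .607, brain .02 | of BW | sum 0.91; 1 kg ≈ 1 L |
| blood volume fraction | 0.079 | of BW | reference-man value, configurable |
| tissue:air partitions | blood 2280, fat 226, liver 1730, rapid 2030, slow 1710, brain 1870 | — | rat-derived, applied to the human simulation as tabulated |
| Vmax | 359.5 · BW^0.75 | mg/h | ≈ 8.7 g/h at 70 kg |
| Km | 82.1 | mg/L | far above the mg/L-scale predictions here, so kinetics are effectively first-order |

Tissue:blood partitions are derived as tissue:air / blood:air.

**Inhalation term.** The default is the fractional-uptake construction:
net input `F · QP · C_inh / 1000` mg/h added to blood, with no explicit
exhalation term (F is net of exhaled back-flux; the blood:air partition is
then inert). A conventional alveolar-equilibration switch
(`uptake_model: alveolar`, input `QP · (C_inh/1000 − C_b/P_b:air)`) is
provided for sensitivity analysis; with ethanol's blood:air coefficient of
2280 it retains nearly everything inhaled and predicts ~1.6× higher blood
levels (8.82 vs 5.44 mg/L at the day-1 endpoint).

**Blood volume.** The tabulated volume fractions total 0.91 of body volume
with no blood entry; blood is assigned the reference-man fraction 0.079
(configurable). The blood-concentration endpoints are insensitive to this
choice: over the whole admissible range (0.05–0.09, bounded by the
whole-body volume budget) the day-1 endpoint moves by < 0.5%
(5.453 → 5.431 mg/L), because the quasi-steady blood level is set by the
uptake/elimination balance, not by any volume.

**Initial condition** is zero in all compartments: endogenous ethanol is
handled as a reporting comparison, not simulated.

### Relation to the originally tabulated blood predictions

Driving this model with the reference stepwise air means gives 5.44 mg/L at
the end of day 1 and 7.61 mg/L at the end of day 2, where the original
evaluation tabulated 4.21 and 5.9 mg/L — a uniform ≈29% gap. The gap is
structural, not numerical: the quasi-steady blood concentration implied by
the tabulated uptake and metabolism parameters alone is
`C_b = C_vL + U/Q_L` with `U = F·QP·C_inh/1000` and
`C_vL = Km·U/(Vmax − U)`, which evaluates to 7.83 mg/L for the final
1518 mg/m³ window — above the tabulated 5.9 "plateau" regardless of any
volume, partition or blood-volume choice, and the two formulation switches
above only raise it. The original software run therefore must have used at
least one parameter value differing from its own published table (a
plausible candidate is a lower effective ventilation–uptake product). We
implement the published table faithfully and do not tune toward the
published endpoints; the corresponding acceptance test is expected to fail
and says so in its docstring. The qualitative conclusion is unaffected:
both 5.9 and 7.6 mg/L lie well inside the endogenous nondrinker range.

### Numerics

- `scipy.integrate.solve_ivp` with LSODA (stiff-capable), rtol 1e-8,
  atol 1e-10 mg; integration restarted at every exposure-segment boundary
  so discontinuities are never smoothed across.
- Cumulative uptake and metabolism are carried as auxiliary states, so mass
  balance (uptake = body burden + metabolized) is checked to 1e-6 relative
  at every reporting time.
- Solver failure raises with diagnostics; amounts are never clipped.
- Independent oracles in the test suite: 1 s trapezoid quadrature for the
  window means (0.1% agreement required) and a fixed-step explicit Euler
  integration at 0.36 s steps with the mass-balance equations restated
  longhand (0.1% agreement on the day-1 endpoint).

## Scenario pipeline

`run_evaluation` couples the stages. Averaging windows run event-to-event
within each day, the last window ending at the 8 h day end; the PBPK clock
runs continuously across nights with no state reset (clearance is complete
well before the next morning: 2×10⁻⁶ mg/L at 24 h, below the 0.01 mg/L
reporting precision). Two modes: `continuous` (self-consistent: window
means computed by stage 1) and `reference` (the tabulated means of the
original incident evaluation, verbatim). Their peak predictions differ by
< 0.3%.

## Synthetic scenarios

`ScenarioDistribution` samples uniformly within broad plausible ranges
(room 50–500 m³, ventilation 0–5 m³/min, 1–50 persons, 1–10 rub events/day
on a 0.25 h lattice, 0.5–5 mL gel, ethanol fraction 0.4–0.9, body weight
40–110 kg, 1–3 days). Uniform sampling is a deliberate choice: the
generator exists to give property tests structural coverage of the input
space, not to model a population. `perturb_parameters` applies
multiplicative log-normal noise (positivity-preserving) with flow fractions
renormalized to 1, volume fractions to their original total, and the blood
fraction capped by the remaining body-volume budget. What the generator
does *not* emulate: correlated physiology, activity-dependent ventilation,
non-instantaneous emission, or multi-zone buildings — passing property
tests demonstrate internal consistency of the model, not field accuracy.

## Problem sizes

The default evaluation integrates 8 ODE states over 32 h with ~650
reporting points and runs in under a second; the test suite's Monte-Carlo
and property sweeps use 12–30 seeded draws per property, which
characterizes the behaviour while keeping the full suite around a minute.

## Known limitations

- The rat-derived partition coefficients are applied to a human simulation
  as tabulated; human measurements would shift transients (not the
  quasi-steady levels).
- Human chamber data suggest real net uptake of ethanol vapor at these
  concentrations is lower than the fixed F = 0.62 (wash-in/wash-out in the
  airways), so both this model and the original evaluation are conservative
  (over-predicting) by design.
- The room model ignores sorption to surfaces and re-emission, which the
  reference incident's later-days observations (persistent smell) suggest
  were real but which only lower airborne exposure during the demonstration
  days.
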