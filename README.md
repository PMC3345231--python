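# ethexpo

Indoor-air reconstruction and physiologically based pharmacokinetic (PBPK)
simulation of inhaled ethanol from ethanol-based hand-sanitizer use.

## The problem

When ethanol gel is used repeatedly by a group of people in a poorly
ventilated room, the evaporated ethanol accumulates in the room air. The
question for an occupational-health assessor is whether breathing that air
can raise blood ethanol meaningfully — in particular, whether it can exceed
the *endogenous* blood-ethanol range of nondrinkers (0–35.2 mg/L, mean
1.1 mg/L, from gut-microbial fermentation).

`ethexpo` answers this with a two-stage forward model:

**Stage 1 — well-mixed room air.** Each group hand-rub event releases an
ethanol mass pulse `m = n · v · ρ · w` (n frictions of `v` mL gel, density
`ρ` g/mL, ethanol mass fraction `w`) instantaneously into a room of volume
`V` ventilated at `Q` m³/min. Under the spatially well-mixed assumption the
air concentration is a superposition of decaying exponentials,

```
C(t) = Σ_{t_j ≤ t}  (m_j / V) · exp(−(Q/V)·(t − t_j))
```

with exact (analytic) time-weighted window means for the stepwise exposure
profile a PBPK model consumes.

**Stage 2 — six-compartment flow-limited PBPK.** Blood plus fat, liver,
rapidly perfused, slowly perfused tissue and brain, connected by cardiac
output `QC = 18·BW^0.75` L/h. For each tissue `dA_i/dt = Q_i (C_b −
C_i/P_i)`; the liver also clears ethanol by saturable Michaelis–Menten
metabolism `Vmax·C_vL/(Km + C_vL)` (Vmax = 359.5·BW^0.75 mg/h, Km =
82.1 mg/L) acting on the liver-exit concentration. Inhaled input enters
blood as net fractional airway uptake `F·QP·C_inh` with F = 0.62 and
alveolar ventilation `QP = 18·BW^0.75` L/h; a conventional
alveolar-equilibration formulation is available as a switch.

## Worked example

The packaged default scenario is the worst case evaluated for a reported
occupational incident: 30 people rubbing hands 3×/day (at 0, 3 and 6 h of
each 8 h day) with 3 mL of 70% w/w gel on two successive days in a 116 m³
classroom with defective ventilation (0.08 m³/min):

```
$ ethexpo tsdd --mode continuous --out out/
Scenario evaluation (mode: continuous)

Air windows (mg/m3):
    0.0-  3.0 h :   408.60
    3.0-  6.0 h :   769.49
    6.0-  8.0 h :  1110.61
   24.0- 27.0 h :   925.32
   27.0- 30.0 h :  1225.89
   30.0- 32.0 h :  1522.01

Blood ethanol (mg/L):
  t =   0.0 h :     0.00
  t =   8.0 h :     5.45
  t =  24.0 h :     0.00
  t =  32.0 h :     7.63

Peak blood ethanol: 7.63 mg/L

Endogenous blood ethanol in nondrinkers (Al-Awadhi et al. (2004), n=1557 nondrinkers):
  mean 1.10 mg/L, median 0.40 mg/L, range 0.00-35.20 mg/L
  peak / endogenous mean : 6.94
  peak / endogenous upper: 0.22
```

Reading: each of the six rub events releases 50.4 g of ethanol; air
concentrations climb through each day (to ~1.5 g/m³ late on day 2, since
the overnight air change is far from complete) and the stepwise window
means drive the PBPK stage. Blood ethanol peaks at 7.6 mg/L at the end of
day 2 and clears to effectively zero overnight. The peak sits inside the
endogenous nondrinker range — about 7× the endogenous *mean* and a fifth
of its upper bound — which is the quantitative basis for judging such an
exposure incapable of producing pharmacologically meaningful blood ethanol
(an oral dose of ~12 g, one glass of wine, peaks at 150–250 mg/L).

Other entry points: `ethexpo air` (room model only, with `--windows`),
`ethexpo pbpk` (PBPK for an arbitrary exposure CSV), `ethexpo
simulate-random` (seeded random scenario files), and the Python API
(`ethexpo.run_evaluation`, `ethexpo.simulate`, ...).

`--mode reference` drives the PBPK stage with the stepwise air means
tabulated in the original incident evaluation instead of the internally
computed ones; the two differ by well under 1%. See `docs/methods.md` for
model assumptions, parameter provenance and a discussion of how these
predictions compare with the originally tabulated ones.

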