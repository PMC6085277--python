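# vvecmo

A steady-state mathematical model of O₂, CO₂ and N₂ exchange during
venovenous extracorporeal membrane oxygenation (vv-ECMO).

Clinicians managing severe ARDS on vv-ECMO juggle two gas-exchange
systems at once: a diseased lung (large pulmonary shunt, reduced
alveolar ventilation) and a membrane oxygenator ventilated by sweep gas.
`vvecmo` couples the two through the circulation so that questions such
as *"if I raise circuit blood flow, what happens to PaCO₂?"* or *"does
the choice of sweep-gas strategy change oxygenation?"* can be answered
quantitatively. It is aimed at intensivists, perfusionists and
physiologists studying extracorporeal gas exchange.

## The model

- **Lung** — a Riley three-compartment lung: shunt (perfused, not
  ventilated), dead space (ventilated, not perfused) and an ideal
  alveolar compartment in diffusion equilibrium. The *standard ARDS*
  parameterisation follows the baby-lung concept: V̇A/Q̇L is held at
  0.7183 and V̇D at 1.847 l/min while the shunt fraction Q̇S/Q̇T varies;
  a *constant-V̇A* variant holds V̇A = 4.310 l/min instead.
- **Oxygenator** — the same ideal-compartment mass balance with zero
  shunt and dead space, ventilated by sweep gas (ATPD) and subject to
  recirculation of returned blood.
- **Blood chemistry** — Kelman's subroutines: the virtual-PO₂
  transformation and rational polynomial for SO₂, whole-blood CO₂
  content with the Haldane correction, dissolved N₂, and a
  zero-base-excess buffer line for pH. Hct = 3·Hb/100.
- **Closure** — for each gas *g*, in each exchanger,
  `Q̇·10·(C_g(P) − C_g,in) = V̇in·F_g,in − V̇out·F_g,out` with outlet
  fractions `F_g,out = P_g/(PB − PH₂O)` summing to one; N₂ flux is *not*
  assumed zero. The steady state is the pulmonary-arterial tension
  triple (P_pa_O₂, P_pa_CO₂, P_pa_N₂) that reproduces itself around the
  loop lung → tissues → circuit → pulmonary artery, found by false
  position per gas to within 0.001 mmHg. Scenarios that would need
  negative mixed-venous O₂ content are reported as *untenable*, with no
  outputs.

## Worked example

Severe ARDS (shunt 0.7) on a 3 l/min circuit with 5 l/min sweep:

```sh
vvecmo solve --set shunt_fraction=0.7 --set va=1.293 --set qec=3 --set vsweep=5
```

prints

```
PaO2 79.9 mmHg  PaCO2 28.24 mmHg  SaO2 96.8%  SvO2 66.8%  CaO2 13.21 ml/dl
```

With 70 % of the cardiac output shunting past the ventilated lung,
arterial PO₂ is only 80 mmHg despite pure oxygen everywhere — venous
admixture, not membrane failure. Oxygenation is nonetheless adequate
(SaO₂ 96.8 %, Sv̄O₂ 66.8 %: 3 l/min of circuit flow covers the
250 ml/min oxygen consumption). On the CO₂ side, the 1.29 l/min of
alveolar ventilation clears only part of the 200 ml/min produced; the
oxygenator removes the rest, and 5 l/min of sweep is more than needed —
PaCO₂ sits at 28 mmHg. Finding the sweep flow that restores
normocapnia:

```sh
vvecmo calibrate-sweep --set shunt_fraction=0.7 --set va=1.293 --set qec=3
# Vsweep = 3.143 l/min ATPD  (PaCO2 40.01 mmHg, SaO2 96.4%)
```

The same operations are available as library functions
(`solve_steady_state`, `find_sweep_for_paco2`, `run_grid`,
`compare_sweep_strategies`), returning dataclasses and pandas
DataFrames. `grid` runs Cartesian scenario grids from a YAML config and
writes one CSV row per point, with untenable points flagged in a status
column rather than silently dropped.

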