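# Methods

## Model structure

The circulation is closed around five elements: a three-compartment
lung, systemic tissues, a membrane oxygenator with recirculation, and
two content-space mixing nodes (arterial and pulmonary-arterial). All
blood streams are described by their O₂/CO₂/N₂ contents (ml STPD/dl);
tensions are recovered where needed by inverting the content functions.
The model is strictly steady-state: one solution is one equilibrium of
the whole system, and time, compliance and intra-breath dynamics do not
appear.

Both gas exchangers are *ideal compartments*: outgoing blood is in
diffusion equilibrium with a single well-mixed gas phase. Per gas *g*
the mass balance is

    Q̇b · 10 · (C_g(P) − C_g,in) = V̇in·F_g,in − V̇out·F_g,out     [ml STPD/min]

with outlet dry fractions F_g,out = P_g/(PB − PH₂O) that sum to one, so
the compartment tensions lie on the simplex ΣP_g = PB − PH₂O and the
second gas flow is closed by summing the three balances. The lung
specifies the *expired* alveolar flow (V̇A, BTPS) and closes the
inspired flow; the oxygenator specifies the sweep inflow (ATPD) and
closes the exhaust. Net gas-volume exchange and non-zero N₂ flux are
therefore represented in both exchangers — important, because with an
oxygenator in the circuit the lung is generally not N₂-neutral.

Tissues apply fixed metabolic rates: Cv̄O₂ = CaO₂ − V̇O₂/(10·Q̇T) and
Cv̄CO₂ = CaCO₂ + RQ·V̇O₂/(10·Q̇T). If Cv̄O₂ (or any mixed content)
would be negative the scenario is *untenable* and is reported as a
status with no output values.

## Blood-gas chemistry

- **SO₂**: Kelman's virtual-PO₂ transformation
  x = PO₂·10^[0.024(37−T) + 0.40(pH−7.40) + 0.06(log₁₀40 − log₁₀PCO₂)]
  followed by the seven-coefficient rational polynomial (P50 26.86 mmHg
  at standard conditions); below x = 10 mmHg the quadratic low-tension
  approximation is used. A P50 shift DP50 (mmHg) is applied as
  x → x·26.86/(26.86 + DP50), i.e. an additive shift of P50, chosen as
  the simplest reading of "a factor that accounts for shifts of the
  dissociation curve"; DP50 = 0 is exactly a no-op.
- **O₂ content**: 1.34·Hb·SO₂ + 0.003·PO₂ (ml/dl).
- **pH**: zero base excess throughout. The buffer line solves
  HCO₃⁻(pH, PCO₂) − 24.02 + β·(pH − 7.40) = 0 with Henderson–
  Hasselbalch bicarbonate (pK′ 6.1, α 0.0301 mmol·l⁻¹·mmHg⁻¹) and a
  haemoglobin-dependent non-bicarbonate buffer value
  β = 7.7 + 2.3·cHb (mmol/l per pH unit, cHb in mmol/l), anchored so
  that pH(40 mmHg) = 7.40 exactly.
- **CO₂ content**: plasma content by Henderson–Hasselbalch with
  temperature-dependent solubility and apparent pK, scaled to whole
  blood by the red-cell partition term
  1 − 0.0289·Hb/((3.352 − 0.456·SO₂)(8.142 − pH)), which carries the
  Haldane effect; mmol/l → ml STPD/dl via 2.226.
- **N₂ content**: dissolved only, Bunsen coefficient 0.0140 ml·ml⁻¹·atm⁻¹
  (0.00184 ml·dl⁻¹·mmHg⁻¹), temperature-independent over 30–42 °C.

Gas volumes convert between ATPD (24 °C, 760 mmHg, dry), BTPS
(body temperature, saturated) and STPD by ideal-gas temperature and
dry-pressure ratios; water vapour pressure uses a Clausius–Clapeyron
form anchored to 47 mmHg at 37 °C. The oxygenator gas phase is treated
like alveolar gas — saturated at blood temperature, total pressure
760 mmHg; the alternative (dry sweep at 760) would shift exhaust
fractions by a few percent but cancels almost entirely in the
strategy-difference comparisons.

### Validity guards

The red-cell partition term is an empirical fit with a pole at
pH 8.142; its pH argument is clamped to [6.6, 7.9] (and the Bohr
correction arguments to pH [6.5, 8.0], PCO₂ [1, 300] mmHg) so that the
extreme hypocapnic states visited transiently by the root finders stay
finite, positive and monotone. The clamp only engages below roughly
PCO₂ 8 mmHg; between 10 and 150 mmHg the formulas are used as
published. This is the model's largest chemistry uncertainty: below
~10 mmHg PCO₂ the published fits are extrapolations however they are
guarded, and outputs that depend on deeply hypocapnic states (e.g.
very high sweep at high circuit flow) inherit that uncertainty.

## Numerical scheme

- Compartment equilibrium: damped Newton on log(PCO₂, PN₂) with PO₂
  closing the simplex, finite-difference Jacobian, tolerance 10⁻⁶
  ml STPD/min; hybrid-Powell fallback, failure threshold 10⁻³ ml/min.
  A compartment with sweep inflow too small to sustain a gas phase
  against sub-atmospheric venous tensions has no non-negative-outflow
  equilibrium and is reported as infeasible.
- Content inversion: damped Newton in log(PO₂, PCO₂) (N₂ is exactly
  linear), with nested Brent bracketing as fallback; residual tolerance
  10⁻¹⁰ ml/dl.
- Recirculation fixed point: hybrid-Powell root find on the returned
  contents (a relaxed direct substitution is kept as fallback); with
  recirculation 0 a single pass is exact. When the set circuit flow
  exceeds the available venous return (Q̇EC > Q̇T), the effective
  recirculated fraction is max(recirc, 1 − Q̇T/Q̇EC): the excess
  drainage can only come from the circuit's own return.
- Whole-body closure: per-gas false position (Illinois variant) on the
  residual calculated − trial, cycling over the three gases from a
  venous-like start (45, 45, 570) mmHg, to 0.001 mmHg per gas; outer
  cap 200 cycles. Solutions are start-independent to < 0.01 mmHg (this
  is a tested invariant), so any convergent scheme would do; brackets
  grow adaptively from the fixed-point image of the current trial.
- Calibrations (V̇E, V̇A, V̇sweep for a PaCO₂ target) are scalar Brent
  searches over an adaptively grown bracket; the solved target is
  always re-verified to within 0.05 mmHg. Untenable or infeasible
  states at small sweep flows are interpreted as "more sweep needed"
  during the search; points whose target is unreachable are flagged and
  excluded, never silently filled.

## Scenario conventions

Defaults (unless a scenario overrides them): FIO₂ 1.0, FoxyO₂ 1.0,
Q̇T 6 l/min, V̇O₂ 250 ml STPD/min, RQ 0.8, Hb 10 g/dl, temp 37 °C,
DP50 0, base excess 0, V̇D 1.847 l/min, no recirculation, no circuit
shunt, no extracorporeal exchange. The standard ARDS lung keeps
V̇A/Q̇L = 0.7183 and V̇D = 1.847 l/min as shunt varies; the constant-V̇A
lung keeps V̇A = 4.310 l/min. Both constants derive from the same
calibration: V̇E giving PaCO₂ = 40 mmHg at zero shunt with VD/VT = 0.3
and the circuit off (the classic alveolar-ventilation relation
PaCO₂ ≈ 863·V̇CO₂/V̇A makes the triplet V̇E 6.157, V̇D 1.847,
V̇A/Q̇L 0.7183 mutually consistent only without extracorporeal CO₂
removal, which fixes the otherwise open question of how the
calibration was run).

The sweep-strategy comparison uses shunt 0.5–1.0 (step 0.1) ×
Q̇EC 0.5–7 l/min (step 0.25), comparing fixed sweeps of 2.5/5/10/15
l/min and a fixed sweep:flow ratio (anchored at 5 l/min at Q̇EC 3
l/min, the stated strategy not fixing its constant) against sweep
titrated to PaCO₂ = 40 mmHg at matched points; points where any arm is
untenable or the target unreachable are excluded and counted. The test
suite samples the same ranges with a 0.5 l/min Q̇EC step to stay fast;
maxima on the coarser grid are conservative (they can only be smaller).

## Known limitations

- Oxygenator gas exchange is purely perfusion-limited: no membrane
  diffusion limitation, no oxygenator dead space, no performance decay
  — differences of strategy at very high sweep flows are therefore
  upper bounds on real-device behaviour.
- Inputs are independent: cardiac output does not react to hypoxia or
  hypercapnia, pulmonary shunt does not react to mixed-venous PO₂.
- Carbamino kinetics, 2,3-DPG metabolism, dyshaemoglobins and
  temperature-dependent N₂ solubility are out of scope.
- At FIO₂ = 1.0 the arterial PO₂ of a well-supported patient sits on
  the flat part of the dissociation curve, where PO₂ ≈ (PB − PH₂O) −
  PaCO₂ − PaN₂ at the exchanger outlets; PaO₂ differences between
  sweep strategies therefore track their PaCO₂ differences nearly
  one-for-one, and are sensitive to exactly how far a fixed high sweep
  drives PaCO₂ below target.
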