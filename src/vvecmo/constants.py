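"""Physical constants and default gas-exchange parameters.

All pressures are in mmHg, temperatures in degrees Celsius, blood-gas
contents in ml STPD per dl blood, flows in l/min at the stated condition.
The constants below are module-level so that they can be overridden (e.g.
in sensitivity analyses) by code that imports them, but they are treated
as fixed by the model itself.
"""

import math

#: Barometric pressure (mmHg). The model works at sea level throughout.
PB = 760.0

#: Standard temperature (K) for STPD gas volumes.
T_STPD = 273.15

#: Ambient temperature (degC) defining the ATPD condition for sweep gas.
T_AMBIENT = 24.0

#: Saturated water vapour pressure at 37 degC (mmHg).
PH2O_37 = 47.0

#: O2 binding capacity of haemoglobin (ml STPD per g Hb).
O2_HB_CAPACITY = 1.34

#: Plasma O2 solubility (ml STPD per dl blood per mmHg).
O2_SOLUBILITY = 0.003

#: CO2 solubility in plasma at 37 degC (mmol per l per mmHg).
ALPHA_CO2 = 0.0301

#: Apparent pK of the plasma bicarbonate system (zero-base-excess line).
PK_CO2 = 6.1

#: ml STPD of CO2 per mmol (22.26 l/mol at STPD, per dl blood).
ML_PER_MMOL_CO2 = 2.226

#: Whole-blood N2 Bunsen solubility, ml STPD per ml blood per atm.
#: Converted below to ml per dl per mmHg; treated as temperature
#: independent over the 30-42 degC range of the model.
BUNSEN_N2 = 0.0140
ALPHA_N2 = BUNSEN_N2 * 100.0 / PB  # ml STPD / dl / mmHg (~0.00184)

#: Standard P50 of adult haemoglobin at pH 7.40, PCO2 40, 37 degC (mmHg).
P50_STANDARD = 26.86

#: Non-bicarbonate buffer value of whole blood, mmol/l per pH unit:
#: 7.7 (plasma proteins) + 2.3 per mmol/l of haemoglobin monomer.
BUFFER_PLASMA = 7.7
BUFFER_PER_HB = 2.3

#: Haemoglobin monomer molar mass (g/mmol) for g/dl -> mmol/l conversion.
HB_MONOMER_G_PER_MMOL = 16.114


def hb_mmol_per_l(hb_g_dl: float) -> float:
    """Haemoglobin monomer concentration in mmol/l from g/dl."""
    return hb_g_dl * 10.0 / HB_MONOMER_G_PER_MMOL


def ph2o(temp: float) -> float:
    """Saturated water vapour pressure (mmHg) at ``temp`` degC.

    Clausius-Clapeyron form anchored to 47 mmHg at 37 degC.
    """
    return PH2O_37 * math.exp(5132.0 * (1.0 / 310.15 - 1.0 / (temp + T_STPD)))
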