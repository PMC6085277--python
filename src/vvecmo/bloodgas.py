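"""Blood-gas chemistry: tensions <-> saturations and contents.

Implements the classic digital-computer subroutines for whole-blood gas
transport: the Kelman virtual-PO2 transformation and rational polynomial
for the oxyhaemoglobin dissociation curve, the Kelman whole-blood CO2
content (plasma Henderson-Hasselbalch with a red-cell partition and
Haldane correction), physically dissolved N2, and an acid-base closure on
the zero-base-excess buffer line.  The inverse map (contents -> tensions)
is provided for reporting arterial tensions after content-space mixing.

Units: tensions mmHg, contents ml STPD per dl blood, Hb g/dl, temp degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import constants as c
from .errors import DomainError, InfeasibleContentError

__all__ = [
    "BloodSpec",
    "GasTensions",
    "BloodGasState",
    "ph_from_pco2",
    "o2_saturation",
    "o2_content",
    "co2_content",
    "n2_content",
    "blood_gas_state",
    "tensions_from_contents",
]

# Kelman (1966) rational-polynomial coefficients for SO2 as a function of
# the virtual (standard-condition) oxygen tension x:
#   SO2 = (a1 x + a2 x^2 + a3 x^3 + x^4) / (a4 + a5 x + a6 x^2 + a7 x^3 + x^4)
_A1 = -8.5322289e3
_A2 = 2.1214010e3
_A3 = -6.7073989e1
_A4 = 9.3596087e5
_A5 = -3.1346258e4
_A6 = 2.3961674e3
_A7 = -6.7104406e1


@dataclass(frozen=True)
class BloodSpec:
    """Patient blood context shared by all chemistry routines.

    Parameters
    ----------
    hb : haemoglobin concentration, g/dl (> 0).
    temp : blood temperature, degC (30-42).
    dp50 : additive shift of the oxyhaemoglobin P50, mmHg
        (0 = standard curve; positive = right shift, e.g. raised 2,3-DPG).
    be : base excess, mEq/l.  The model fixes it at zero.

    The haematocrit is derived as ``3 * hb / 100`` and exposed as
    :attr:`hct`.
    """

    hb: float
    temp: float = 37.0
    dp50: float = 0.0
    be: float = 0.0

    def __post_init__(self):
        if not self.hb > 0:
            raise DomainError(f"Hb must be positive, got {self.hb}")
        if not 30.0 <= self.temp <= 42.0:
            raise DomainError(f"temp must be in [30, 42] degC, got {self.temp}")
        if self.be != 0.0:
            raise DomainError("base excess is fixed at zero in this model")
        if self.dp50 <= -c.P50_STANDARD:
            raise DomainError("dp50 must exceed -P50 (P50 must stay positive)")

    @property
    def hct(self) -> float:
        """Haematocrit fraction, 3 x Hb / 100."""
        return 3.0 * self.hb / 100.0

    @property
    def o2_capacity(self) -> float:
        """Maximum Hb-bound O2, ml STPD/dl."""
        return c.O2_HB_CAPACITY * self.hb


@dataclass(frozen=True)
class GasTensions:
    """Partial pressures (mmHg) of the three exchanged gases."""

    po2: float
    pco2: float
    pn2: float

    def __post_init__(self):
        for name in ("po2", "pco2", "pn2"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.po2, self.pco2, self.pn2])

    @classmethod
    def from_array(cls, arr) -> "GasTensions":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class BloodGasState:
    """Fully evaluated state of one blood stream."""

    tensions: GasTensions
    ph: float
    so2: float
    o2_content: float
    co2_content: float
    n2_content: float

    @property
    def contents(self) -> np.ndarray:
        """(O2, CO2, N2) contents, ml STPD/dl."""
        return np.array([self.o2_content, self.co2_content, self.n2_content])


# ---------------------------------------------------------------------------
# acid-base closure
# ---------------------------------------------------------------------------

def _buffer_value(spec: BloodSpec) -> float:
    # whole-blood non-bicarbonate buffer value, mmol/l per pH unit
    return c.BUFFER_PLASMA + c.BUFFER_PER_HB * c.hb_mmol_per_l(spec.hb)


# bicarbonate at the anchor point pH 7.40 / PCO2 40 (mmol/l)
_HCO3_ANCHOR = c.ALPHA_CO2 * 40.0 * 10.0 ** (7.40 - c.PK_CO2)


def ph_from_pco2(pco2: float, spec: BloodSpec) -> float:
    """Plasma pH on the zero-base-excess buffer line.

    Solves ``HCO3(pH, PCO2) - HCO3(7.40, 40) + beta * (pH - 7.40) = 0``
    where HCO3 follows Henderson-Hasselbalch (pK' 6.1, alpha 0.0301) and
    ``beta`` is the Hb-dependent non-bicarbonate buffer value, so that
    pH(40 mmHg) = 7.40 exactly and pH is strictly decreasing in PCO2.
    """
    if not pco2 > 0:
        raise DomainError(f"PCO2 must be positive, got {pco2}")
    beta = _buffer_value(spec)
    ph = 7.40
    # Newton with analytic derivative; the residual is smooth and convex.
    for _ in range(50):
        hco3 = c.ALPHA_CO2 * pco2 * 10.0 ** (ph - c.PK_CO2)
        f = hco3 - _HCO3_ANCHOR + beta * (ph - 7.40)
        df = math.log(10.0) * hco3 + beta
        step = f / df
        ph -= step
        if abs(step) < 1e-12:
            break
    return ph


# ---------------------------------------------------------------------------
# oxygen
# ---------------------------------------------------------------------------

def _virtual_po2(po2: float, ph: float, pco2: float, spec: BloodSpec) -> float:
    # Bohr/temperature corrections map PO2 onto the standard curve.
    # clamp the Bohr arguments to the fitted range of the corrections so
    # degenerate tensions (PCO2 -> 0) cannot blow up the exponent
    ph_b = min(max(ph, 6.5), 8.0)
    pco2_b = min(max(pco2, 1.0), 300.0)
    expo = (
        0.024 * (37.0 - spec.temp)
        + 0.40 * (ph_b - 7.40)
        + 0.06 * (math.log10(40.0) - math.log10(pco2_b))
    )
    x = po2 * 10.0 ** expo
    if spec.dp50 != 0.0:
        x *= c.P50_STANDARD / (c.P50_STANDARD + spec.dp50)
    return x


def o2_saturation(tensions: GasTensions, ph: float, spec: BloodSpec) -> float:
    """Fractional haemoglobin O2 saturation via the Kelman curve.

    The measured PO2 is first mapped to a virtual tension on the standard
    curve (37 degC, pH 7.40, PCO2 40, P50 26.86 mmHg); below 10 mmHg the
    quadratic low-tension approximation replaces the rational polynomial.
    """
    if tensions.po2 < 0:
        raise DomainError("PO2 must be >= 0")
    x = _virtual_po2(tensions.po2, ph, tensions.pco2, spec)
    if x <= 0.0:
        return 0.0
    if x < 10.0:
        s = x * (0.003683 + 0.000584 * x)
    else:
        num = x * (_A1 + x * (_A2 + x * (_A3 + x)))
        den = _A4 + x * (_A5 + x * (_A6 + x * (_A7 + x)))
        s = num / den
    return min(max(s, 0.0), 1.0)


def o2_content(spec: BloodSpec, po2: float, so2: float) -> float:
    """Whole-blood O2 content: Hb-bound plus physically dissolved."""
    return c.O2_HB_CAPACITY * spec.hb * so2 + c.O2_SOLUBILITY * po2


# ---------------------------------------------------------------------------
# carbon dioxide
# ---------------------------------------------------------------------------

def co2_content(spec: BloodSpec, pco2: float, ph: float, so2: float) -> float:
    """Whole-blood CO2 content (ml STPD/dl), Kelman 1967 formulation.

    Plasma content by Henderson-Hasselbalch with temperature-dependent
    solubility and apparent pK; scaled to whole blood with the red-cell
    partition term, which carries the Haldane effect through SO2.
    """
    if pco2 < 0:
        raise DomainError("PCO2 must be >= 0")
    if pco2 == 0.0:
        return 0.0
    t = spec.temp
    sol = 0.0307 + 0.00057 * (37.0 - t) + 0.00002 * (37.0 - t) ** 2
    pk = 6.086 + 0.042 * (7.4 - ph) + (38.0 - t) * (0.00472 + 0.00139 * (7.4 - ph))
    cp = sol * pco2 * (1.0 + 10.0 ** (ph - pk))  # mmol/l plasma
    # The red-cell partition is an empirical fit valid over physiological
    # pH and is singular at pH 8.142; clamp its pH argument so extreme
    # hypocapnic states stay finite, positive and monotone in PCO2.
    ph_h = min(max(ph, 6.6), 7.9)
    haldane = 1.0 - (0.0289 * spec.hb) / ((3.352 - 0.456 * so2) * (8.142 - ph_h))
    return cp * haldane * c.ML_PER_MMOL_CO2


# ---------------------------------------------------------------------------
# nitrogen
# ---------------------------------------------------------------------------

def n2_content(spec: BloodSpec, pn2: float) -> float:
    """Dissolved N2, exactly linear in tension."""
    if pn2 < 0:
        raise DomainError("PN2 must be >= 0")
    return c.ALPHA_N2 * pn2


# ---------------------------------------------------------------------------
# composition and inversion
# ---------------------------------------------------------------------------

def blood_gas_state(spec: BloodSpec, tensions: GasTensions) -> BloodGasState:
    """Evaluate pH, SO2 and all three contents at the given tensions."""
    if tensions.pco2 > 0:
        ph = ph_from_pco2(tensions.pco2, spec)
    else:
        # CO2-free blood: the buffer line has no anchor; report the
        # alkaline limit but keep contents consistent (CO2 content 0).
        ph = ph_from_pco2(1e-6, spec)
    so2 = o2_saturation(tensions, ph, spec)
    return BloodGasState(
        tensions=tensions,
        ph=ph,
        so2=so2,
        o2_content=o2_content(spec, tensions.po2, so2),
        co2_content=co2_content(spec, tensions.pco2, ph, so2),
        n2_content=n2_content(spec, tensions.pn2),
    )


_PO2_MAX = 3000.0
_PCO2_MAX = 400.0


def _o2_content_at(spec: BloodSpec, po2: float, pco2: float, ph: float) -> float:
    so2 = o2_saturation(GasTensions(po2, max(pco2, 0.0), 0.0), ph, spec)
    return o2_content(spec, po2, so2)


def _invert_newton(spec: BloodSpec, o2c: float, co2c: float) -> tuple[float, float] | None:
    """Damped 2-D Newton for the (PO2, PCO2) inversion in log space.

    Returns None on failure (caller falls back to bracketed nesting).
    """
    pco2 = min(max(40.0 * co2c / 48.0, 1.0), 150.0)
    s0 = min(max(o2c / (spec.o2_capacity + 1e-12), 1e-3), 0.999)
    po2 = c.P50_STANDARD * (s0 / (1.0 - s0)) ** (1.0 / 2.7)
    v = np.log([max(po2, 1e-3), pco2])

    def F(vv):
        p_o2, p_co2 = math.exp(vv[0]), math.exp(vv[1])
        if p_o2 > _PO2_MAX or p_co2 > _PCO2_MAX:
            return None
        ph = ph_from_pco2(p_co2, spec)
        so2 = o2_saturation(GasTensions(p_o2, p_co2, 0.0), ph, spec)
        return np.array([
            o2_content(spec, p_o2, so2) - o2c,
            co2_content(spec, p_co2, ph, so2) - co2c,
        ])

    f = F(v)
    if f is None:
        return None
    for _ in range(60):
        fn = max(abs(f[0]), abs(f[1]))
        if fn < 1e-10:
            return math.exp(v[0]), math.exp(v[1])
        J = np.empty((2, 2))
        h = 1e-7
        for j in range(2):
            vj = v.copy()
            vj[j] += h
            fj = F(vj)
            if fj is None:
                return None
            J[:, j] = (fj - f) / h
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        step = np.clip(step, -2.0, 2.0)
        lam = 1.0
        while lam > 1e-3:
            f_new = F(v + lam * step)
            if f_new is not None and max(abs(f_new[0]), abs(f_new[1])) < fn:
                v = v + lam * step
                f = f_new
                break
            lam *= 0.5
        else:
            return None
    return None


def tensions_from_contents(
    spec: BloodSpec,
    o2c: float,
    co2c: float,
    n2c: float,
    tol: float = 1e-9,
) -> GasTensions:
    """Invert contents -> tensions.

    N2 is exactly linear.  The coupled (PO2, PCO2) subproblem is solved by
    a damped Newton iteration, falling back to two nested bracketed scalar
    root finds: for each trial PCO2 (which fixes pH on the buffer line)
    the PO2 matching the O2 content is found, then the CO2-content
    residual is driven to zero in PCO2.  Both maps are strictly monotone
    so the fallback brackets are certain.

    Raises
    ------
    InfeasibleContentError
        if any content is negative or the O2 content exceeds what fully
        saturated haemoglobin plus dissolved O2 can carry.
    """
    if min(o2c, co2c, n2c) < -1e-12:
        raise InfeasibleContentError("negative blood-gas content")
    pn2 = n2c / c.ALPHA_N2

    if o2c > spec.o2_capacity + c.O2_SOLUBILITY * _PO2_MAX:
        raise InfeasibleContentError(
            f"O2 content {o2c:.3f} ml/dl exceeds carrying capacity of "
            f"Hb {spec.hb} g/dl blood"
        )

    if o2c > 0.0 and co2c > 0.0:
        fast = _invert_newton(spec, o2c, co2c)
        if fast is not None:
            return GasTensions(fast[0], fast[1], pn2)

    def po2_for(pco2: float, ph: float) -> float:
        if o2c <= 0.0:
            return 0.0
        f = lambda p: _o2_content_at(spec, p, pco2, ph) - o2c
        if f(_PO2_MAX) < 0.0:
            raise InfeasibleContentError("O2 content not achievable")
        return brentq(f, 0.0, _PO2_MAX, xtol=1e-10, rtol=8.9e-16)

    if co2c <= 0.0:
        ph = ph_from_pco2(1e-6, spec)
        return GasTensions(po2_for(0.0, ph), 0.0, pn2)

    def co2_resid(pco2: float) -> float:
        ph = ph_from_pco2(pco2, spec)
        po2 = po2_for(pco2, ph)
        so2 = o2_saturation(GasTensions(po2, pco2, 0.0), ph, spec)
        return co2_content(spec, pco2, ph, so2) - co2c

    lo, hi = 1e-8, 200.0
    while co2_resid(hi) < 0.0:
        hi *= 2.0
        if hi > _PCO2_MAX * 4:
            raise InfeasibleContentError("CO2 content not achievable")
    pco2 = brentq(co2_resid, lo, hi, xtol=1e-10, rtol=8.9e-16)
    ph = ph_from_pco2(pco2, spec)
    return GasTensions(po2_for(pco2, ph), pco2, pn2)
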