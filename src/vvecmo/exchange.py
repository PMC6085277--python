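"""Physical gas-exchange building blocks.

An *ideal compartment* is a gas-exchange unit (alveolar compartment or
membrane oxygenator) in which outgoing blood is in diffusion equilibrium
with the compartment gas.  Steady-state mass balance per gas g:

    Qb * 10 * (Cg(P) - Cg_in)  =  Vin * Fg_in - Vout * Fg_out      [ml STPD/min]

with outlet dry fractions Fg_out = Pg / (PB - PH2O) summing to one, so
the compartment tensions live on the simplex sum(P) = PB - PH2O and the
total outlet (or inlet) gas flow is closed by summing the balances.  N2
flux is *not* assumed zero: with an oxygenator in the circulation the
lung can be a net N2 exporter or importer.

The same solve serves the lung (expired alveolar flow specified, BTPS)
and the oxygenator (sweep inflow specified, ATPD), wrapped by
:func:`lung_unit` and :func:`oxygenator_unit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import scipy.optimize

from . import constants as c
from .bloodgas import BloodGasState, BloodSpec, GasTensions, blood_gas_state
from .errors import (
    CompartmentInfeasibleError,
    ConvergenceError,
    DegenerateMixError,
    DomainError,
    UntenableStateError,
)

__all__ = [
    "GasCondition",
    "GasStream",
    "BloodStream",
    "TissueParams",
    "CompartmentEquilibrium",
    "convert_gas_flow",
    "mix_blood",
    "tissue_exchange",
    "ideal_compartment_equilibrium",
    "lung_unit",
    "oxygenator_unit",
]


class GasCondition(Enum):
    """Reference conditions for gas volumes (barometric pressure 760)."""

    ATPD = "atpd"  # ambient temperature (24 degC), dry
    BTPS = "btps"  # body temperature, saturated
    STPD = "stpd"  # 0 degC, dry


def _stpd_factor(condition: GasCondition, temp: float) -> float:
    """Multiplier converting a volume at ``condition`` to STPD."""
    if condition is GasCondition.STPD:
        return 1.0
    if condition is GasCondition.ATPD:
        return c.T_STPD / (c.T_STPD + c.T_AMBIENT)
    if condition is GasCondition.BTPS:
        return (c.T_STPD / (c.T_STPD + temp)) * ((c.PB - c.ph2o(temp)) / c.PB)
    raise DomainError(f"unknown gas condition {condition!r}")


def convert_gas_flow(
    flow: float,
    from_condition: GasCondition,
    to_condition: GasCondition,
    temp: float = 37.0,
) -> float:
    """Ideal-gas conversion of a flow between ATPD/BTPS/STPD conditions.

    ``temp`` is the body temperature used for the BTPS condition.
    """
    if from_condition is to_condition:
        return flow
    return flow * _stpd_factor(from_condition, temp) / _stpd_factor(to_condition, temp)


@dataclass(frozen=True)
class GasStream:
    """A gas flow with dry-gas composition at a stated condition."""

    flow: float
    condition: GasCondition
    fo2: float
    fco2: float
    fn2: float
    temp: float = 37.0

    def __post_init__(self):
        if self.flow < 0:
            raise DomainError("gas flow must be >= 0")
        fr = (self.fo2, self.fco2, self.fn2)
        if any(f < -1e-12 or f > 1 + 1e-12 for f in fr):
            raise DomainError("gas fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise DomainError(f"dry fractions must sum to 1, got {sum(fr)}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.fo2, self.fco2, self.fn2])

    @property
    def flow_stpd(self) -> float:
        return convert_gas_flow(self.flow, self.condition, GasCondition.STPD, self.temp)


@dataclass(frozen=True)
class BloodStream:
    """A blood flow (l/min) with its gas contents (ml STPD/dl)."""

    flow: float
    contents: np.ndarray  # (O2, CO2, N2)

    def __post_init__(self):
        if self.flow < 0:
            raise DomainError("blood flow must be >= 0")


@dataclass(frozen=True)
class TissueParams:
    """Whole-body metabolism: O2 consumed, CO2 produced."""

    vo2: float  # ml STPD/min
    rq: float  # respiratory quotient

    def __post_init__(self):
        if self.vo2 < 0:
            raise DomainError("VO2 must be >= 0")
        if not 0.0 < self.rq < 3.0:
            raise DomainError("RQ out of range")

    @property
    def vco2(self) -> float:
        return self.rq * self.vo2


@dataclass(frozen=True)
class CompartmentEquilibrium:
    """Solved state of an ideal gas-exchange compartment."""

    tensions: GasTensions
    blood_out: BloodGasState
    gas_out: GasStream  # STPD flow with outlet dry fractions
    fluxes: np.ndarray  # ml STPD/min per gas, positive into blood
    v_in_stpd: float
    v_out_stpd: float


def mix_blood(streams: Sequence[BloodStream]) -> tuple[np.ndarray, float]:
    """Flow-weighted mixing in content space.

    Returns the mixed (O2, CO2, N2) contents and the total flow.
    """
    total = sum(s.flow for s in streams)
    if total <= 0.0:
        raise DegenerateMixError("cannot mix streams with zero total flow")
    mixed = sum(s.flow * np.asarray(s.contents, dtype=float) for s in streams) / total
    return mixed, total


def tissue_exchange(
    arterial: np.ndarray, tissue: TissueParams, qt: float
) -> np.ndarray:
    """Arterial -> mixed-venous contents across the tissues.

    O2 is removed and CO2 added at the metabolic rates; N2 is inert.
    Raises :class:`UntenableStateError` if the implied mixed-venous O2
    content is negative (the scenario cannot supply VO2).
    """
    if qt <= 0:
        raise DomainError("cardiac output must be positive")
    arterial = np.asarray(arterial, dtype=float)
    dc = np.array([-tissue.vo2, tissue.vco2, 0.0]) / (10.0 * qt)
    venous = arterial + dc
    if venous[0] < 0.0:
        raise UntenableStateError(
            f"mixed-venous O2 content would be {venous[0]:.3f} ml/dl < 0",
            value=venous[0],
        )
    return venous


# ---------------------------------------------------------------------------
# ideal compartment
# ---------------------------------------------------------------------------


def _compartment_residuals(
    w: np.ndarray,
    spec: BloodSpec,
    qb: float,
    c_in: np.ndarray,
    f_in: np.ndarray,
    v_in: float | None,
    v_out: float | None,
    pbh: float,
):
    """Mass-balance residuals (CO2, N2) at log-tensions w = log(PCO2, PN2).

    Exactly one of ``v_in``/``v_out`` (ml STPD/min... here l/min STPD) is
    given; the other is closed by the summed balance.  Returns the
    residual pair plus the full flux vector and closed flows.
    """
    if w[0] > 8.0 or w[1] > 8.0:  # e^8 ~ 3000 mmHg, already off-simplex
        return None
    pco2, pn2 = math.exp(w[0]), math.exp(w[1])
    po2 = pbh - pco2 - pn2
    if po2 <= 0.0:
        return None  # outside the simplex
    tens = GasTensions(po2, pco2, pn2)
    state = blood_gas_state(spec, tens)
    flux = qb * 10.0 * (state.contents - c_in)  # ml/min into blood
    f_out = np.array([po2, pco2, pn2]) / pbh
    if v_in is None:
        v_in_l = v_out + flux.sum() / 1000.0
        v_out_l = v_out
    else:
        v_in_l = v_in
        v_out_l = v_in - flux.sum() / 1000.0
    resid = 1000.0 * (v_in_l * f_in - v_out_l * f_out) - flux  # ml/min, gas-side minus blood-side
    return resid, flux, state, v_in_l, v_out_l, f_out


def _initial_tensions(
    c_in: np.ndarray, f_in: np.ndarray, pbh: float, spec: BloodSpec
) -> tuple[float, float]:
    # heuristic start: CO2 near a venous-like tension, N2 between the
    # humidified inlet-gas value and the blood value
    pco2 = min(max(5.0, 40.0 * c_in[1] / 48.0 if c_in[1] > 0 else 5.0), 0.4 * pbh)
    pn2_blood = c_in[2] / c.ALPHA_N2
    pn2 = 0.5 * (min(pn2_blood, pbh) + f_in[2] * pbh)
    pn2 = min(max(pn2, 1e-3), 0.9 * pbh)
    if pco2 + pn2 > 0.95 * pbh:
        scale = 0.95 * pbh / (pco2 + pn2)
        pco2, pn2 = pco2 * scale, pn2 * scale
    return pco2, pn2


def ideal_compartment_equilibrium(
    spec: BloodSpec,
    blood_in: BloodStream,
    gas_fractions_in: np.ndarray,
    *,
    gas_in_stpd: float | None = None,
    gas_out_stpd: float | None = None,
    x0: tuple[float, float] | None = None,
    tol: float = 1e-6,
) -> CompartmentEquilibrium:
    """Solve one ideal compartment to diffusion equilibrium.

    Parameters
    ----------
    blood_in : inlet blood stream (flow l/min, contents ml/dl).
    gas_fractions_in : dry fractions (O2, CO2, N2) of the fresh gas.
    gas_in_stpd, gas_out_stpd : exactly one must be given — the fresh gas
        inflow (oxygenator sweep) or the expired alveolar outflow (lung),
        in l/min STPD.  The other is closed by total mass balance.
    x0 : optional warm-start (PCO2, PN2) tensions.
    tol : residual tolerance, ml STPD/min.

    The two free tensions (PCO2, PN2; PO2 closes the simplex) are found
    by damped Newton iteration in log space, with a hybrid-Powell
    fallback.  Degenerate limits (no blood, no gas) are handled exactly.
    """
    if (gas_in_stpd is None) == (gas_out_stpd is None):
        raise DomainError("specify exactly one of gas_in_stpd / gas_out_stpd")
    f_in = np.asarray(gas_fractions_in, dtype=float)
    pbh = c.PB - c.ph2o(spec.temp)
    qb = blood_in.flow
    c_in = np.asarray(blood_in.contents, dtype=float)

    gas_flow = gas_in_stpd if gas_in_stpd is not None else gas_out_stpd

    def make_result(tens, state, flux, v_in_l, v_out_l, f_out):
        gas_out = GasStream(
            max(v_out_l, 0.0), GasCondition.STPD,
            float(f_out[0]), float(f_out[1]), float(f_out[2]), spec.temp,
        )
        return CompartmentEquilibrium(tens, state, gas_out, flux, v_in_l, v_out_l)

    # --- degenerate limits -------------------------------------------------
    if gas_flow <= 0.0:
        # no fresh gas: no exchange; blood passes through unchanged
        state = _state_from_contents_passthrough(spec, c_in)
        gas_out = GasStream(0.0, GasCondition.STPD, *f_in, spec.temp)
        return CompartmentEquilibrium(state.tensions, state, gas_out,
                                      np.zeros(3), 0.0, 0.0)
    if qb <= 0.0:
        # gas-dominated limit: compartment gas = humidified inlet gas
        tens = GasTensions(*(f_in * pbh))
        state = blood_gas_state(spec, tens)
        gas_out = GasStream(gas_flow, GasCondition.STPD, *f_in, spec.temp)
        return CompartmentEquilibrium(tens, state, gas_out, np.zeros(3),
                                      gas_flow, gas_flow)

    args = (spec, qb, c_in, f_in, gas_in_stpd, gas_out_stpd, pbh)

    if x0 is not None:
        pco2_0, pn2_0 = x0
        pco2_0 = min(max(pco2_0, 1e-9), 0.98 * pbh)
        pn2_0 = min(max(pn2_0, 1e-12), 0.98 * pbh)
        if pco2_0 + pn2_0 >= 0.99 * pbh:
            pco2_0, pn2_0 = _initial_tensions(c_in, f_in, pbh, spec)
    else:
        pco2_0, pn2_0 = _initial_tensions(c_in, f_in, pbh, spec)
    w = np.log([pco2_0, pn2_0])

    best = None
    out = _compartment_residuals(w, *args)
    for _ in range(120):
        if out is None:
            break
        resid = out[0][1:3]  # CO2, N2 components
        rnorm = max(abs(resid[0]), abs(resid[1]))
        if best is None or rnorm < best[0]:
            best = (rnorm, w.copy(), out)
        if rnorm < tol:
            break
        # finite-difference Jacobian of (R_CO2, R_N2) wrt w
        J = np.empty((2, 2))
        h = 1e-7
        for j in range(2):
            wj = w.copy()
            wj[j] += h
            oj = _compartment_residuals(wj, *args)
            if oj is None:
                wj[j] -= 2 * h
                oj = _compartment_residuals(wj, *args)
                if oj is None:
                    break
                J[:, j] = (resid - oj[0][1:3]) / h
            else:
                J[:, j] = (oj[0][1:3] - resid) / h
        else:
            try:
                step = np.linalg.solve(J, -resid)
            except np.linalg.LinAlgError:
                break
            step = np.clip(step, -4.0, 4.0)
            # damped line search
            lam = 1.0
            for _ in range(12):
                w_new = w + lam * step
                out_new = _compartment_residuals(w_new, *args)
                if out_new is not None:
                    r_new = out_new[0][1:3]
                    if max(abs(r_new[0]), abs(r_new[1])) < rnorm or lam < 0.01:
                        w, out = w_new, out_new
                        break
                lam *= 0.5
            else:
                break
            continue
        break

    if best is None or best[0] >= tol:
        # fallback: hybrid Powell from the heuristic start
        def fun(wv):
            o = _compartment_residuals(np.asarray(wv), *args)
            if o is None:
                return np.array([1e6, 1e6])
            return o[0][1:3]

        for start in (np.log(_initial_tensions(c_in, f_in, pbh, spec)), w):
            sol = scipy.optimize.root(fun, start, method="hybr", tol=1e-12)
            o = _compartment_residuals(sol.x, *args)
            if o is not None:
                rn = max(abs(o[0][1]), abs(o[0][2]))
                if best is None or rn < best[0]:
                    best = (rn, np.asarray(sol.x), o)
            if best is not None and best[0] < tol:
                break

    if best is None or best[0] >= max(tol, 1e-3):
        raise CompartmentInfeasibleError(
            f"no compartment equilibrium found (best residual "
            f"{float('nan') if best is None else best[0]:.3g} ml/min)"
        )
    _, w, out = best
    resid, flux, state, v_in_l, v_out_l, f_out = out
    if v_out_l < -1e-9 or v_in_l < -1e-9:
        raise CompartmentInfeasibleError(
            f"negative closed gas flow (in {v_in_l:.4f}, out {v_out_l:.4f} l/min)"
        )
    return make_result(state.tensions, state, flux, v_in_l, max(v_out_l, 0.0), f_out)


def _state_from_contents_passthrough(spec: BloodSpec, contents: np.ndarray) -> BloodGasState:
    """Blood state for an unchanged pass-through, via content inversion."""
    from .bloodgas import tensions_from_contents

    tens = tensions_from_contents(spec, *np.maximum(contents, 0.0))
    return blood_gas_state(spec, tens)


# ---------------------------------------------------------------------------
# lung and oxygenator assemblies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LungOutcome:
    arterial_contents: np.ndarray
    expired: GasStream  # total expired flow (BTPS) incl. dead space
    fluxes: np.ndarray  # ml/min into blood
    compartment: CompartmentEquilibrium | None
    ql: float


def lung_unit(
    pa_contents: np.ndarray,
    qt: float,
    shunt_fraction: float,
    va_btps: float,
    fio2: float,
    spec: BloodSpec,
    vd_btps: float = 0.0,
    x0: tuple[float, float] | None = None,
) -> LungOutcome:
    """Three-compartment (Riley) lung: shunt, ideal alveolus, dead space.

    ``va_btps`` is the *expired* alveolar ventilation; the inspired flow
    is closed by the compartment mass balance, so net gas-volume uptake
    (RQ < 1, N2 exchange) is represented.  Dead-space ventilation adds to
    the expired stream without exchanging.
    """
    if not 0.0 <= shunt_fraction <= 1.0:
        raise DomainError("shunt fraction must be in [0, 1]")
    if va_btps < 0 or vd_btps < 0:
        raise DomainError("ventilations must be >= 0")
    pa_contents = np.asarray(pa_contents, dtype=float)
    ql = qt * (1.0 - shunt_fraction)
    f_in = np.array([fio2, 0.0, 1.0 - fio2])

    if ql <= 0.0 or va_btps <= 0.0:
        expired = GasStream(va_btps + vd_btps, GasCondition.BTPS,
                            *f_in, spec.temp)
        return LungOutcome(pa_contents.copy(), expired, np.zeros(3), None, ql)

    va_stpd = convert_gas_flow(va_btps, GasCondition.BTPS, GasCondition.STPD, spec.temp)
    eq = ideal_compartment_equilibrium(
        spec,
        BloodStream(ql, pa_contents),
        f_in,
        gas_out_stpd=va_stpd,
        x0=x0,
    )
    arterial, _ = mix_blood(
        [BloodStream(qt * shunt_fraction, pa_contents),
         BloodStream(ql, eq.blood_out.contents)]
    )
    expired = GasStream(va_btps + vd_btps, GasCondition.BTPS,
                        eq.gas_out.fo2, eq.gas_out.fco2, eq.gas_out.fn2, spec.temp)
    return LungOutcome(arterial, expired, eq.fluxes, eq, ql)


@dataclass(frozen=True)
class OxygenatorOutcome:
    returned_contents: np.ndarray  # blood returned to the body
    inlet_contents: np.ndarray  # post-recirculation oxygenator inlet
    exhaust: GasStream | None
    fluxes: np.ndarray  # ml/min into blood
    compartment: CompartmentEquilibrium | None


def oxygenator_unit(
    venous_contents: np.ndarray,
    qec: float,
    recirc_fraction: float,
    circuit_shunt_fraction: float,
    foxy_o2: float,
    vsweep_atpd: float,
    spec: BloodSpec,
    x0: tuple[float, float] | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> OxygenatorOutcome:
    """Membrane oxygenator with recirculation and circuit shunt.

    The oxygenator is an ideal compartment (no dead space, no diffusion
    limitation) ventilated by sweep gas {FO2 = foxy_o2, FCO2 = 0} at
    ``vsweep_atpd`` l/min ATPD.  Recirculation mixes a fraction of the
    returned blood back into the drained inflow, which makes the inlet
    contents a fixed point; it is solved with a hybrid-Powell root find
    (direct relaxed substitution as fallback).
    """
    if qec < 0 or vsweep_atpd < 0:
        raise DomainError("circuit flows must be >= 0")
    if not 0.0 <= recirc_fraction < 1.0:
        raise DomainError("recirculation fraction must be in [0, 1)")
    if not 0.0 <= circuit_shunt_fraction <= 1.0:
        raise DomainError("circuit shunt fraction must be in [0, 1]")
    cv = np.asarray(venous_contents, dtype=float)
    q_oxy = qec * (1.0 - circuit_shunt_fraction)

    if qec <= 0.0 or vsweep_atpd <= 0.0 or q_oxy <= 0.0:
        return OxygenatorOutcome(cv.copy(), cv.copy(), None, np.zeros(3), None)

    v_in_stpd = convert_gas_flow(vsweep_atpd, GasCondition.ATPD, GasCondition.STPD)
    f_in = np.array([foxy_o2, 0.0, 1.0 - foxy_o2])
    r = recirc_fraction
    s = circuit_shunt_fraction
    warm = {"x0": x0}

    def pass_through(c_in: np.ndarray):
        eq = ideal_compartment_equilibrium(
            spec, BloodStream(q_oxy, c_in), f_in,
            gas_in_stpd=v_in_stpd, x0=warm["x0"],
        )
        warm["x0"] = (eq.tensions.pco2, eq.tensions.pn2)
        return eq

    if r == 0.0:
        eq = pass_through(cv)
        c_ret = s * cv + (1.0 - s) * eq.blood_out.contents
        flux = q_oxy * 10.0 * (eq.blood_out.contents - cv)
        return OxygenatorOutcome(c_ret, cv.copy(), eq.gas_out, flux, eq)

    def step(c_ret: np.ndarray):
        c_in = r * c_ret + (1.0 - r) * cv
        eq = pass_through(c_in)
        return s * c_in + (1.0 - s) * eq.blood_out.contents, c_in, eq

    def resid(c_ret):
        new, _, _ = step(np.asarray(c_ret))
        return new - c_ret

    sol = scipy.optimize.root(resid, cv, method="hybr", tol=1e-12)
    c_ret = np.asarray(sol.x)
    if not sol.success or np.max(np.abs(resid(c_ret))) > 1e-7:
        c_ret = cv.copy()
        ok = False
        for _ in range(max_iter):
            new, _, _ = step(c_ret)
            if np.max(np.abs(new - c_ret)) < tol:
                c_ret = new
                ok = True
                break
            c_ret = 0.5 * c_ret + 0.5 * new  # relaxed substitution
        if not ok:
            raise ConvergenceError("oxygenator recirculation loop did not converge")
    _, c_in, eq = step(c_ret)
    c_ret_final = s * c_in + (1.0 - s) * eq.blood_out.contents
    flux = q_oxy * 10.0 * (eq.blood_out.contents - c_in)
    return OxygenatorOutcome(c_ret_final, c_in, eq.gas_out, flux, eq)
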