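"""Close the whole-body circulation at steady state.

One evaluation of the loop runs, from trial pulmonary-arterial tensions:
lung -> arterial mix -> tissue metabolism -> mixed venous -> extracorporeal
circuit -> pulmonary-arterial mix, yielding *calculated* pulmonary-arterial
tensions.  The steady state is the fixed point where calculated equals
trial to within 0.001 mmHg per gas, found by the false position (regula
falsi) method applied per gas inside an outer cycling loop.

Scenarios whose solution would require negative mixed-venous O2 content
are *untenable*: the solver reports the status and outputs no values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import constants as c
from .bloodgas import (
    BloodGasState,
    BloodSpec,
    GasTensions,
    blood_gas_state,
    tensions_from_contents,
)
from .errors import (
    CompartmentInfeasibleError,
    ConvergenceError,
    DomainError,
    InfeasibleContentError,
    UntenableStateError,
)
from .exchange import (
    BloodStream,
    LungOutcome,
    OxygenatorOutcome,
    TissueParams,
    lung_unit,
    mix_blood,
    oxygenator_unit,
    tissue_exchange,
)

__all__ = ["ModelInputs", "SteadyState", "evaluate_loop", "solve_steady_state"]

#: Default initial trial tensions (venous-like), mmHg.
DEFAULT_TRIAL = (45.0, 45.0, 570.0)

#: Convergence criterion on |calculated - trial| per gas, mmHg.
DEFAULT_TOL = 1e-3


@dataclass(frozen=True)
class ModelInputs:
    """Complete input-parameter set for one steady-state solve.

    Flows are l/min (BTPS for ventilation, ATPD for sweep gas), VO2 is
    ml STPD/min, Hb g/dl, temperatures degC.  Exactly one of ``ve``/``va``
    may be given; the other is derived through the dead-space ventilation
    ``vd`` (``ve = va + vd``).
    """

    qt: float = 6.0
    shunt_fraction: float = 0.0
    fio2: float = 1.0
    qec: float = 0.0
    recirc_fraction: float = 0.0
    circuit_shunt_fraction: float = 0.0
    foxy_o2: float = 1.0
    vsweep: float = 0.0
    hb: float = 10.0
    temp: float = 37.0
    dp50: float = 0.0
    vo2: float = 250.0
    rq: float = 0.8
    vd: float = 1.847
    ve: float | None = None
    # default alveolar ventilation: the calibrated zero-shunt value of the
    # standard ARDS lung (so the all-defaults instance is a healthy lung
    # with PaCO2 near 40 and no extracorporeal exchange)
    va: float | None = 4.310

    def __post_init__(self):
        if self.qt <= 0:
            raise DomainError("QT must be positive")
        for name in ("qec", "vsweep", "vd", "vo2"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        for name in ("shunt_fraction", "recirc_fraction",
                     "circuit_shunt_fraction", "fio2", "foxy_o2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.recirc_fraction >= 1.0:
            raise DomainError("recirculation fraction must be < 1")
        if self.ve is None and self.va is None:
            raise DomainError("one of ve / va must be given")
        if self.ve is not None and self.va is not None:
            if abs(self.ve - (self.va + self.vd)) > 1e-9:
                raise DomainError("ve, va and vd are inconsistent")

    @property
    def va_btps(self) -> float:
        va = self.va if self.va is not None else self.ve - self.vd
        if va < -1e-12:
            raise DomainError("VE < VD leaves negative alveolar ventilation")
        return max(va, 0.0)

    @property
    def ve_btps(self) -> float:
        return self.va_btps + self.vd

    @property
    def effective_recirc_fraction(self) -> float:
        """Recirculation actually experienced by the circuit.

        When the set circuit flow exceeds the venous return available
        (QEC > QT at the nominal recirculation), the excess drained blood
        can only come from the circuit's own return, so the effective
        recirculated fraction is at least 1 - QT/QEC.
        """
        if self.qec <= 0:
            return self.recirc_fraction
        return max(self.recirc_fraction, 1.0 - self.qt / self.qec)

    @property
    def blood_spec(self) -> BloodSpec:
        return BloodSpec(hb=self.hb, temp=self.temp, dp50=self.dp50)

    @property
    def tissue(self) -> TissueParams:
        return TissueParams(vo2=self.vo2, rq=self.rq)


@dataclass(frozen=True)
class SteadyState:
    """Solved circulation with convergence metadata.

    ``status`` is one of ``"converged"``, ``"untenable"``,
    ``"not_converged"``.  Output fields are ``None`` unless converged.
    """

    inputs: ModelInputs
    status: str
    pa_tensions: GasTensions | None = None
    pa_state: BloodGasState | None = None
    arterial: BloodGasState | None = None
    mixed_venous: BloodGasState | None = None
    lung: LungOutcome | None = None
    oxygenator: OxygenatorOutcome | None = None
    iterations: int = 0
    loop_evaluations: int = 0
    max_residual: float = float("nan")
    message: str = ""

    # -- convenience accessors (None-safe only when converged) ------------
    @property
    def pao2(self) -> float:
        return self.arterial.tensions.po2

    @property
    def paco2(self) -> float:
        return self.arterial.tensions.pco2

    @property
    def sao2(self) -> float:
        return self.arterial.so2

    @property
    def svo2(self) -> float:
        return self.mixed_venous.so2

    @property
    def cao2(self) -> float:
        return self.arterial.o2_content

    @property
    def cvo2(self) -> float:
        return self.mixed_venous.o2_content

    @property
    def ve(self) -> float:
        return self.inputs.ve_btps

    @property
    def va(self) -> float:
        return self.inputs.va_btps

    @property
    def vd_vt(self) -> float:
        ve = self.inputs.ve_btps
        return self.inputs.vd / ve if ve > 0 else 1.0

    def global_balance(self) -> np.ndarray:
        """Whole-body conservation residual per gas (ml STPD/min).

        At a converged steady state lung + oxygenator fluxes must equal
        (+VO2, -VCO2, 0).
        """
        total = self.lung.fluxes + self.oxygenator.fluxes
        expected = np.array([self.inputs.vo2, -self.inputs.tissue.vco2, 0.0])
        return total - expected


@dataclass
class _LoopResult:
    calculated: np.ndarray  # (PO2, PCO2, PN2) mmHg
    spec: BloodSpec
    arterial_contents: np.ndarray
    mixed_venous_contents: np.ndarray
    lung: LungOutcome
    oxygenator: OxygenatorOutcome
    pa_contents: np.ndarray
    _arterial: BloodGasState | None = None

    @property
    def arterial(self) -> BloodGasState:
        """Arterial blood state (computed lazily by content inversion)."""
        if self._arterial is None:
            tens = tensions_from_contents(
                self.spec, *np.maximum(self.arterial_contents, 0.0))
            object.__setattr__(self, "_arterial",
                               blood_gas_state(self.spec, tens))
        return self._arterial


def evaluate_loop(
    trial: GasTensions | tuple,
    inputs: ModelInputs,
    _cache: dict | None = None,
) -> _LoopResult:
    """One sequential pass of the circulation from trial PA tensions.

    Raises :class:`UntenableStateError` when the pass requires a negative
    O2 content or an out-of-range saturation anywhere.
    """
    if not isinstance(trial, GasTensions):
        trial = GasTensions(*trial)
    spec = inputs.blood_spec
    cache = _cache if _cache is not None else {}

    pa_state = blood_gas_state(spec, trial)

    lung = lung_unit(
        pa_state.contents,
        inputs.qt,
        inputs.shunt_fraction,
        inputs.va_btps,
        inputs.fio2,
        spec,
        vd_btps=inputs.vd,
        x0=cache.get("lung"),
    )
    if lung.compartment is not None:
        cache["lung"] = (lung.compartment.tensions.pco2,
                         lung.compartment.tensions.pn2)

    if lung.arterial_contents[0] < 0:
        raise UntenableStateError("negative arterial O2 content",
                                  value=lung.arterial_contents[0])

    venous = tissue_exchange(lung.arterial_contents, inputs.tissue, inputs.qt)

    recirc = inputs.effective_recirc_fraction
    oxy = oxygenator_unit(
        venous,
        inputs.qec,
        recirc,
        inputs.circuit_shunt_fraction,
        inputs.foxy_o2,
        inputs.vsweep,
        spec,
        x0=cache.get("oxy"),
    )
    if oxy.compartment is not None:
        cache["oxy"] = (oxy.compartment.tensions.pco2,
                        oxy.compartment.tensions.pn2)

    q_ret = inputs.qec * (1.0 - recirc)
    pa_contents, _ = mix_blood([
        BloodStream(inputs.qt - q_ret, venous),
        BloodStream(q_ret, oxy.returned_contents),
    ])
    if pa_contents[0] < 0:
        raise UntenableStateError("negative pulmonary-arterial O2 content",
                                  value=pa_contents[0])
    calc = tensions_from_contents(spec, *np.maximum(pa_contents, 0.0))
    return _LoopResult(
        calculated=calc.as_array(),
        spec=spec,
        arterial_contents=lung.arterial_contents,
        mixed_venous_contents=venous,
        lung=lung,
        oxygenator=oxy,
        pa_contents=pa_contents,
    )


def _regula_falsi(f: Callable[[float], float], a: float, fa: float,
                  b: float, fb: float, tol: float, max_iter: int = 60) -> float:
    """Illinois-variant false position on a bracketed root."""
    side = 0
    for _ in range(max_iter):
        if abs(fb - fa) < 1e-300:
            break
        x = (a * fb - b * fa) / (fb - fa)
        fx = f(x)
        if abs(fx) < tol or abs(b - a) < tol * 1e-3:
            return x
        if fx * fb < 0:
            a, fa = b, fb
            side = 0
        else:
            if side == 1:
                fa *= 0.5
            side = 1
        b, fb = x, fx
    return b


def solve_steady_state(
    inputs: ModelInputs,
    trial0: tuple[float, float, float] = DEFAULT_TRIAL,
    tol: float = DEFAULT_TOL,
    max_cycles: int = 200,
) -> SteadyState:
    """Find pulmonary-arterial tensions reproducing themselves round the loop.

    Per outer cycle, each gas tension in turn is updated by a bracketed
    false-position solve of its own residual ``calculated_g - trial_g``
    (the other two held fixed); cycles repeat until all three residuals
    are within ``tol`` (default 0.001 mmHg).  Untenable scenarios return a
    :class:`SteadyState` with ``status="untenable"`` and no outputs.
    """
    cache: dict = {}
    memo: dict = {}
    n_eval = 0
    trial = np.array(trial0, dtype=float)

    def residuals(p: np.ndarray) -> tuple[np.ndarray, _LoopResult]:
        nonlocal n_eval
        key = (p[0], p[1], p[2])
        hit = memo.get(key)
        if hit is not None:
            return hit
        n_eval += 1
        res = evaluate_loop(GasTensions(*np.maximum(p, 0.0)), inputs, cache)
        out = (res.calculated - np.maximum(p, 0.0), res)
        if len(memo) > 32:
            memo.clear()
        memo[key] = out
        return out

    try:
        r, last = residuals(trial)
        converged = bool(np.max(np.abs(r)) <= tol)
        cycles = 0
        while not converged and cycles < max_cycles:
            cycles += 1
            for g in range(3):
                def fg(x: float) -> float:
                    p = trial.copy()
                    p[g] = x
                    return residuals(p)[0][g]

                a = trial[g]
                fa = residuals(trial)[0][g]
                if abs(fa) <= tol / 2:
                    continue
                # bracket using the fixed-point image as the second point
                b = max(a + fa, 0.0)
                fb = fg(b)
                k = 0
                while fa * fb > 0 and k < 60:
                    step = fb if abs(fb) > tol else (b - a if b != a else 1.0)
                    b_new = max(b + step, 0.0)
                    if b_new == b:  # stuck at the zero bound
                        break
                    a, fa = b, fb
                    b = b_new
                    fb = fg(b)
                    k += 1
                if fa * fb > 0:
                    # no sign change: accept the best endpoint
                    trial[g] = b if abs(fb) < abs(fa) else a
                    continue
                trial[g] = _regula_falsi(fg, a, fa, b, fb, tol / 2)
            r, last = residuals(trial)
            converged = bool(np.max(np.abs(r)) <= tol)
    except UntenableStateError as exc:
        return SteadyState(inputs=inputs, status="untenable",
                           message=str(exc), loop_evaluations=n_eval)
    except (CompartmentInfeasibleError, InfeasibleContentError,
            ConvergenceError) as exc:
        # e.g. a sweep trickle too small to sustain a gas-filled
        # compartment against subatmospheric venous tensions
        return SteadyState(inputs=inputs, status="infeasible",
                           message=str(exc), loop_evaluations=n_eval)

    if not converged:
        return SteadyState(inputs=inputs, status="not_converged",
                           iterations=cycles, loop_evaluations=n_eval,
                           max_residual=float(np.max(np.abs(r))),
                           message="residuals above tolerance after cycle cap")

    spec = inputs.blood_spec
    pa_tensions = GasTensions(*trial)
    mv = blood_gas_state(
        spec, tensions_from_contents(spec, *np.maximum(last.mixed_venous_contents, 0.0))
    )
    return SteadyState(
        inputs=inputs,
        status="converged",
        pa_tensions=pa_tensions,
        pa_state=blood_gas_state(spec, pa_tensions),
        arterial=last.arterial,
        mixed_venous=mv,
        lung=last.lung,
        oxygenator=last.oxygenator,
        iterations=cycles,
        loop_evaluations=n_eval,
        max_residual=float(np.max(np.abs(r))),
    )
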