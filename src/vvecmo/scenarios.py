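"""Experiment designs: ARDS lung parameterisations, calibrations and grids.

The *standard ARDS lung* follows the baby-lung concept: the aerated lung
keeps a constant ventilation-perfusion ratio VA/QL while atelectasis
(the pulmonary shunt fraction) grows, with dead-space ventilation held
constant; the *constant-VA lung* keeps alveolar ventilation fixed
regardless of shunt.  The two parameterisations are calibrated so that a
zero-shunt lung with VD/VT = 0.3 and no extracorporeal exchange reaches
PaCO2 = 40 mmHg.

Sweep-gas management strategies: (a) sweep flow adjusted to hold PaCO2
at a target, (b) sweep flow fixed, (c) sweep flow proportional to
circuit blood flow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, DomainError
from .solver import DEFAULT_TRIAL, ModelInputs, SteadyState, solve_steady_state

__all__ = [
    "LungStrategy",
    "SweepStrategy",
    "ards_ventilation",
    "calibrate_ve_for_paco2",
    "calibrate_va_for_paco2",
    "find_sweep_for_paco2",
    "run_grid",
    "compare_sweep_strategies",
    "STANDARD_VA_QL_RATIO",
    "STANDARD_VD",
    "CONSTANT_VA",
]

#: Baby-lung ventilation-perfusion ratio of the standard ARDS lung.
STANDARD_VA_QL_RATIO = 0.7183
#: Constant dead-space ventilation, l/min BTPS.
STANDARD_VD = 1.847
#: Alveolar ventilation of the constant-VA lung, l/min BTPS.
CONSTANT_VA = 4.310


@dataclass(frozen=True)
class LungStrategy:
    """How lung ventilation responds to worsening shunt."""

    kind: str = "standard_ards"  # or "constant_va"
    va_ql_ratio: float = STANDARD_VA_QL_RATIO
    vd: float = STANDARD_VD
    va_fixed: float = CONSTANT_VA

    def __post_init__(self):
        if self.kind not in ("standard_ards", "constant_va"):
            raise DomainError(f"unknown lung strategy {self.kind!r}")


@dataclass(frozen=True)
class SweepStrategy:
    """How sweep-gas flow is managed as circuit flow varies."""

    kind: str = "target_paco2"  # or "fixed_sweep" / "fixed_ratio"
    target_paco2: float = 40.0
    fixed_sweep: float = 5.0
    #: l sweep per l blood flow; default anchored at 5 l/min at QEC 3.
    ratio: float = 5.0 / 3.0

    def __post_init__(self):
        if self.kind not in ("target_paco2", "fixed_sweep", "fixed_ratio"):
            raise DomainError(f"unknown sweep strategy {self.kind!r}")


def ards_ventilation(
    shunt_fraction: float, qt: float, strategy: LungStrategy = LungStrategy()
) -> tuple[float, float, float, float]:
    """Ventilation bookkeeping for a given shunt: (VE, VA, VD, VD/VT).

    Standard ARDS lung: VA = (VA/QL) * QT * (1 - shunt); constant-VA
    lung: VA fixed.  In both, VE = VA + VD and VD/VT = VD/VE.
    """
    if not 0.0 <= shunt_fraction <= 1.0:
        raise DomainError("shunt fraction must be in [0, 1]")
    if strategy.kind == "standard_ards":
        va = strategy.va_ql_ratio * qt * (1.0 - shunt_fraction)
    else:
        va = strategy.va_fixed
    ve = va + strategy.vd
    return ve, va, strategy.vd, strategy.vd / ve if ve > 0 else 1.0


def _inputs_for(base: ModelInputs, shunt: float, lung: LungStrategy) -> ModelInputs:
    ve, va, vd, _ = ards_ventilation(shunt, base.qt, lung)
    return replace(base, shunt_fraction=shunt, vd=vd, ve=None, va=va)


def calibrate_ve_for_paco2(
    target_paco2: float,
    shunt_fraction: float,
    vd_vt: float,
    inputs: ModelInputs,
    bracket: tuple[float, float] = (1.0, 30.0),
    tol: float = 0.02,
) -> float:
    """Minute ventilation (l/min BTPS) giving the target PaCO2.

    ``vd_vt`` fixes the dead-space fraction, so VD = vd_vt * VE.  The
    calibration is intended for a circuit-free lung (QEC = 0, sweep = 0),
    where the classic alveolar ventilation relation applies; the supplied
    ``inputs`` define everything except the ventilation pair.
    Solved PaCO2 is within 0.05 mmHg of target.
    """
    state = {"last": DEFAULT_TRIAL}

    def f(ve: float) -> float:
        inp = replace(inputs, shunt_fraction=shunt_fraction,
                      vd=vd_vt * ve, ve=ve, va=None)
        ss = solve_steady_state(inp, trial0=state["last"])
        if ss.status != "converged":
            raise CalibrationError(f"solve failed at VE={ve}: {ss.status}")
        state["last"] = tuple(ss.pa_tensions.as_array())
        return ss.paco2 - target_paco2

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"PaCO2 target {target_paco2} not bracketed by VE in {bracket}")
    ve = brentq(f, lo, hi, xtol=tol * 0.2)
    if abs(f(ve)) > 0.05:
        raise CalibrationError("VE calibration did not reach target")
    return ve


def calibrate_va_for_paco2(
    target_paco2: float,
    shunt_fraction: float,
    inputs: ModelInputs,
    bracket: tuple[float, float] = (0.5, 25.0),
    tol: float = 0.02,
) -> float:
    """Alveolar ventilation (l/min BTPS) giving the target PaCO2 at
    fixed dead-space ventilation ``inputs.vd``."""
    state = {"last": DEFAULT_TRIAL}

    def f(va: float) -> float:
        inp = replace(inputs, shunt_fraction=shunt_fraction, ve=None, va=va)
        ss = solve_steady_state(inp, trial0=state["last"])
        if ss.status != "converged":
            raise CalibrationError(f"solve failed at VA={va}: {ss.status}")
        state["last"] = tuple(ss.pa_tensions.as_array())
        return ss.paco2 - target_paco2

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise CalibrationError("PaCO2 target not bracketed by VA")
    va = brentq(f, lo, hi, xtol=tol * 0.2)
    if abs(f(va)) > 0.05:
        raise CalibrationError("VA calibration did not reach target")
    return va


def find_sweep_for_paco2(
    target_paco2: float,
    inputs: ModelInputs,
    bracket: tuple[float, float] = (0.02, 60.0),
    max_sweep: float = 500.0,
    trial0: tuple = DEFAULT_TRIAL,
) -> tuple[float, SteadyState]:
    """Sweep-gas flow (l/min ATPD) holding PaCO2 at the target.

    Returns the sweep flow and the solved steady state.  Raises
    :class:`CalibrationError` when the target cannot be reached (too
    little exchange capacity even at ``max_sweep``, or PaCO2 below the
    target even with the sweep shut off).
    """
    state = {"last": trial0, "ss": None}

    def solve_at(vs: float):
        ss = solve_steady_state(replace(inputs, vsweep=vs), trial0=state["last"])
        if ss.status == "converged":
            state["last"] = tuple(ss.pa_tensions.as_array())
            state["ss"] = ss
        return ss

    def f(vs: float) -> float:
        ss = solve_at(vs)
        if ss.status in ("infeasible", "untenable"):
            # below the minimum sweep that sustains a gas-filled
            # compartment, or too little O2 transfer to supply VO2;
            # both resolve with more sweep, so act as "PaCO2 far above
            # target" and let the root search move upward
            return 1e3
        if ss.status != "converged":
            raise CalibrationError(
                f"{ss.status} at sweep {vs:.3g} l/min: {ss.message}")
        return ss.paco2 - target_paco2

    lo, hi = bracket
    # a sweep trickle may be infeasible (no gas-filled compartment can be
    # sustained); grow the lower bracket until the model solves
    ss_lo = solve_at(lo)
    while ss_lo.status in ("infeasible", "untenable") and lo < hi / 2:
        lo *= 2.0
        ss_lo = solve_at(lo)
    if ss_lo.status != "converged":
        raise CalibrationError(f"{ss_lo.status} at sweep {lo:.3g} l/min")
    flo = ss_lo.paco2 - target_paco2
    if flo < 0.0:
        raise CalibrationError("PaCO2 already below target at minimal sweep")
    fhi = f(hi)
    while fhi > 0.0 and hi < max_sweep:
        hi = min(hi * 2.0, max_sweep)
        fhi = f(hi)
    if fhi > 0.0:
        raise CalibrationError(
            f"PaCO2 target {target_paco2} unreachable below {max_sweep} l/min sweep")
    vs = brentq(f, lo, hi, xtol=1e-3, rtol=1e-9)
    resid = f(vs)
    if abs(resid) > 0.05:
        raise CalibrationError("sweep calibration did not reach target")
    return vs, state["ss"]


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_INPUT_COLS = [
    "qt_lmin", "shunt_fraction", "fio2", "qec_lmin", "recirc_fraction",
    "circuit_shunt_fraction", "foxy_o2", "sweep_lmin_atpd", "hb_g_dl",
    "temp_c", "dp50_mmhg", "vo2_ml_min", "rq", "vd_lmin_btps",
    "ve_lmin_btps", "va_lmin_btps", "vd_vt",
]
_OUTPUT_COLS = [
    "pao2_mmhg", "paco2_mmhg", "ph_a", "sao2_pct", "svo2_pct",
    "cao2_ml_dl", "cvo2_ml_dl", "caco2_ml_dl", "cvco2_ml_dl",
    "ppao2_mmhg", "ppaco2_mmhg", "ppan2_mmhg",
    "lung_o2_flux_ml_min", "lung_co2_flux_ml_min", "lung_n2_flux_ml_min",
    "oxy_o2_flux_ml_min", "oxy_co2_flux_ml_min", "oxy_n2_flux_ml_min",
    "iterations", "max_residual_mmhg",
]


def _row_from_state(ss: SteadyState) -> dict:
    inp = ss.inputs
    row = {
        "qt_lmin": inp.qt,
        "shunt_fraction": inp.shunt_fraction,
        "fio2": inp.fio2,
        "qec_lmin": inp.qec,
        "recirc_fraction": inp.recirc_fraction,
        "circuit_shunt_fraction": inp.circuit_shunt_fraction,
        "foxy_o2": inp.foxy_o2,
        "sweep_lmin_atpd": inp.vsweep,
        "hb_g_dl": inp.hb,
        "temp_c": inp.temp,
        "dp50_mmhg": inp.dp50,
        "vo2_ml_min": inp.vo2,
        "rq": inp.rq,
        "vd_lmin_btps": inp.vd,
        "ve_lmin_btps": inp.ve_btps,
        "va_lmin_btps": inp.va_btps,
        "vd_vt": inp.vd / inp.ve_btps if inp.ve_btps > 0 else 1.0,
        "status": ss.status,
    }
    if ss.status == "converged":
        row.update({
            "pao2_mmhg": ss.pao2,
            "paco2_mmhg": ss.paco2,
            "ph_a": ss.arterial.ph,
            "sao2_pct": 100.0 * ss.sao2,
            "svo2_pct": 100.0 * ss.svo2,
            "cao2_ml_dl": ss.cao2,
            "cvo2_ml_dl": ss.cvo2,
            "caco2_ml_dl": ss.arterial.co2_content,
            "cvco2_ml_dl": ss.mixed_venous.co2_content,
            "ppao2_mmhg": ss.pa_tensions.po2,
            "ppaco2_mmhg": ss.pa_tensions.pco2,
            "ppan2_mmhg": ss.pa_tensions.pn2,
            "lung_o2_flux_ml_min": ss.lung.fluxes[0],
            "lung_co2_flux_ml_min": ss.lung.fluxes[1],
            "lung_n2_flux_ml_min": ss.lung.fluxes[2],
            "oxy_o2_flux_ml_min": ss.oxygenator.fluxes[0],
            "oxy_co2_flux_ml_min": ss.oxygenator.fluxes[1],
            "oxy_n2_flux_ml_min": ss.oxygenator.fluxes[2],
            "iterations": ss.iterations,
            "max_residual_mmhg": ss.max_residual,
        })
    else:
        # untenable / failed points carry no output values
        row.update({k: np.nan for k in _OUTPUT_COLS})
    return row


def run_grid(
    axes: dict[str, list],
    base: ModelInputs = ModelInputs(),
    lung: LungStrategy = LungStrategy(),
    sweep: SweepStrategy | None = None,
) -> pd.DataFrame:
    """Evaluate the Cartesian product of ``axes`` (ModelInputs field name
    -> values) and return one tidy row per point.

    Rows are in lexicographic axis order; per-point failures (untenable
    scenarios) are recorded in the ``status`` column with empty outputs.
    The lung strategy re-derives VE/VA/VD from the shunt fraction at each
    point; the sweep strategy, if given, sets (or solves for) the sweep
    flow.
    """
    if not axes:
        raise DomainError("axes must be non-empty")
    names = list(axes)
    rows = []
    warm = DEFAULT_TRIAL
    for values in itertools.product(*(axes[n] for n in names)):
        inp = replace(base, **dict(zip(names, values)))
        inp = _inputs_for(inp, inp.shunt_fraction, lung)
        try:
            if sweep is not None and sweep.kind == "target_paco2":
                _, ss = find_sweep_for_paco2(sweep.target_paco2, inp, trial0=warm)
            else:
                if sweep is not None:
                    vs = (sweep.fixed_sweep if sweep.kind == "fixed_sweep"
                          else sweep.ratio * inp.qec)
                    inp = replace(inp, vsweep=vs)
                ss = solve_steady_state(inp, trial0=warm)
        except CalibrationError as exc:
            ss = SteadyState(inputs=inp, status="unachievable", message=str(exc))
        if ss.status == "converged":
            warm = tuple(ss.pa_tensions.as_array())
        row = _row_from_state(ss)
        for n, v in zip(names, values):
            row[n] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=names + ["status"] +
                        [c for c in _INPUT_COLS if c not in names] + _OUTPUT_COLS)


def compare_sweep_strategies(
    shunts: list[float],
    qecs: list[float],
    base: ModelInputs = ModelInputs(),
    lung: LungStrategy = LungStrategy(),
    fixed_sweeps: tuple[float, ...] = (2.5, 5.0, 10.0, 15.0),
    ratio: float = 5.0 / 3.0,
    target_paco2: float = 40.0,
) -> dict:
    """Compare sweep-management strategies on oxygenation outputs.

    At every (shunt, QEC) grid point the reference strategy solves the
    sweep flow for PaCO2 = ``target_paco2``; each fixed-sweep and the
    fixed-ratio strategy is then compared at the matched point.  Points
    where the reference is untenable/unachievable, or where a compared
    strategy is untenable, are excluded and counted.

    Returns a dict with the per-point table (DataFrame) and the grid
    maxima of |dSaO2|, |dSvO2| (percentage points), |dCaO2| (ml/dl) and
    |dPaO2| (mmHg) versus the reference.
    """
    strategies = {f"fixed_{v:g}": v for v in fixed_sweeps}
    rows = []
    excluded = {"reference": 0, **{k: 0 for k in strategies}, "fixed_ratio": 0}
    warm_ref = DEFAULT_TRIAL
    for shunt in shunts:
        for qec in qecs:
            inp = _inputs_for(replace(base, qec=qec), shunt, lung)
            try:
                vs_ref, ss_ref = find_sweep_for_paco2(target_paco2, inp,
                                                      trial0=warm_ref)
            except CalibrationError:
                excluded["reference"] += 1
                continue
            warm_ref = tuple(ss_ref.pa_tensions.as_array())
            for name, vs in {**strategies, "fixed_ratio": ratio * qec}.items():
                ss = solve_steady_state(replace(inp, vsweep=vs),
                                        trial0=warm_ref)
                if ss.status != "converged":
                    excluded[name] += 1
                    continue
                rows.append({
                    "shunt_fraction": shunt,
                    "qec_lmin": qec,
                    "strategy": name,
                    "sweep_lmin_atpd": vs,
                    "sweep_ref_lmin_atpd": vs_ref,
                    "paco2_mmhg": ss.paco2,
                    "d_sao2_pct": 100.0 * (ss.sao2 - ss_ref.sao2),
                    "d_svo2_pct": 100.0 * (ss.svo2 - ss_ref.svo2),
                    "d_cao2_ml_dl": ss.cao2 - ss_ref.cao2,
                    "d_pao2_mmhg": ss.pao2 - ss_ref.pao2,
                })
    table = pd.DataFrame(rows)
    if table.empty:
        raise CalibrationError("no comparable grid points")
    return {
        "table": table,
        "excluded": excluded,
        "n_points": len(table),
        "max_abs_d_sao2_pct": float(table["d_sao2_pct"].abs().max()),
        "max_abs_d_svo2_pct": float(table["d_svo2_pct"].abs().max()),
        "max_abs_d_cao2_ml_dl": float(table["d_cao2_ml_dl"].abs().max()),
        "max_abs_d_pao2_mmhg": float(table["d_pao2_mmhg"].abs().max()),
    }
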