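"""Deterministic fixture generation for testing and demonstration.

Produces randomised-but-physiological model inputs plus the
known-answer cases (calibrated healthy lung, total-atelectasis identity,
degenerate limits) that anchor the test suite.  Same seed, same
fixtures.
"""

from __future__ import annotations

import numpy as np

from .solver import ModelInputs

__all__ = ["generate_fixtures", "KNOWN_CASES"]

#: Named deterministic cases with a known qualitative answer.
KNOWN_CASES = {
    # calibrated zero-shunt lung, no circuit: PaCO2 ~ 40 mmHg
    "calibrated_healthy": ModelInputs(shunt_fraction=0.0, ve=6.157, va=None,
                                      vd=0.3 * 6.157),
    # total atelectasis: lung inert, all exchange extracorporeal
    "total_atelectasis": ModelInputs(shunt_fraction=1.0, va=0.0,
                                     qec=4.0, vsweep=5.0),
    # shunt 1 with no sweep: no gas exchange anywhere -> untenable
    "untenable_no_exchange": ModelInputs(shunt_fraction=1.0, va=0.0,
                                         qec=0.0, vsweep=0.0),
    # circuit-free severe ARDS (pure Riley lung)
    "riley_only": ModelInputs(shunt_fraction=0.6, va=0.7183 * 6.0 * 0.4),
}


def generate_fixtures(seed: int, n: int = 10) -> list[ModelInputs]:
    """``n`` random valid input sets spanning the physiological ranges.

    Sampled within: QT 3-8 l/min, shunt 0-1, QEC 0-6 l/min, sweep 0-15
    l/min, recirculation 0-0.5, Hb 7-15 g/dl, temp 34-40 degC, VO2
    150-400 ml/min, RQ 0.7-1.0.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        qt = rng.uniform(3.0, 8.0)
        shunt = rng.uniform(0.0, 1.0)
        va = 0.7183 * qt * (1.0 - shunt)
        out.append(ModelInputs(
            qt=qt,
            shunt_fraction=shunt,
            fio2=rng.uniform(0.21, 1.0),
            qec=rng.uniform(0.0, min(6.0, qt)),
            recirc_fraction=rng.uniform(0.0, 0.5),
            circuit_shunt_fraction=rng.uniform(0.0, 0.3),
            foxy_o2=rng.uniform(0.6, 1.0),
            vsweep=rng.uniform(0.5, 15.0),
            hb=rng.uniform(7.0, 15.0),
            temp=rng.uniform(34.0, 40.0),
            vo2=rng.uniform(150.0, 400.0),
            rq=rng.uniform(0.7, 1.0),
            vd=1.847,
            va=va,
            ve=None,
        ))
    return out
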