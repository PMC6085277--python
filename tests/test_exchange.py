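"""Gas-condition conversions, mixing, tissue exchange and the ideal
compartment shared by lung and oxygenator."""

import itertools

import numpy as np
import pytest

from vvecmo import (
    BloodSpec,
    BloodStream,
    DegenerateMixError,
    GasCondition,
    GasStream,
    GasTensions,
    TissueParams,
    UntenableStateError,
    blood_gas_state,
    convert_gas_flow,
    ideal_compartment_equilibrium,
    lung_unit,
    mix_blood,
    oxygenator_unit,
    tissue_exchange,
)
from vvecmo import constants as c


class TestGasConditions:
    def test_identity(self):
        assert convert_gas_flow(2.5, GasCondition.ATPD, GasCondition.ATPD) == 2.5

    def test_atpd_to_stpd(self):
        # dry gas at 24 degC: pure temperature ratio
        assert convert_gas_flow(1.0, GasCondition.ATPD, GasCondition.STPD) == \
            pytest.approx(273.15 / 297.15, abs=1e-4)

    def test_btps_to_stpd(self):
        # saturated at 37 degC: temperature and dry-pressure ratios
        assert convert_gas_flow(1.0, GasCondition.BTPS, GasCondition.STPD) == \
            pytest.approx((273.15 / 310.15) * (713.0 / 760.0), abs=1e-4)

    def test_round_trips(self):
        for a, b in itertools.permutations(list(GasCondition), 2):
            f = convert_gas_flow(1.7, a, b)
            assert convert_gas_flow(f, b, a) == pytest.approx(1.7)

    def test_stream_validates_fractions(self):
        with pytest.raises(Exception):
            GasStream(1.0, GasCondition.ATPD, 0.5, 0.1, 0.1)


class TestMixing:
    def test_degenerate(self):
        with pytest.raises(DegenerateMixError):
            mix_blood([BloodStream(0.0, np.array([1.0, 2.0, 3.0]))])

    def test_zero_flow_stream_ignored(self):
        a = BloodStream(0.0, np.array([10.0, 40.0, 1.0]))
        b = BloodStream(2.0, np.array([15.0, 50.0, 0.5]))
        mixed, flow = mix_blood([a, b])
        assert mixed == pytest.approx(b.contents)
        assert flow == 2.0

    def test_arithmetic_mean(self):
        a = BloodStream(1.0, np.array([10.0, 40.0, 1.0]))
        b = BloodStream(1.0, np.array([20.0, 50.0, 1.0]))
        mixed, _ = mix_blood([a, b])
        assert mixed[0] == pytest.approx(15.0)

    def test_identical_streams_invariant_to_split(self):
        cont = np.array([12.0, 45.0, 0.8])
        m1, _ = mix_blood([BloodStream(1.0, cont), BloodStream(5.0, cont)])
        m2, _ = mix_blood([BloodStream(3.0, cont), BloodStream(3.0, cont)])
        assert m1 == pytest.approx(m2)


class TestTissue:
    def test_mass_balance_arithmetic(self):
        art = np.array([20.0, 48.0, 1.0])
        ven = tissue_exchange(art, TissueParams(vo2=250.0, rq=0.8), qt=6.0)
        assert ven[0] == pytest.approx(20.0 - 250.0 / 60.0)
        assert ven[1] == pytest.approx(48.0 + 200.0 / 60.0)
        assert ven[2] == pytest.approx(1.0)

    def test_zero_metabolism_identity(self):
        art = np.array([20.0, 48.0, 1.0])
        assert tissue_exchange(art, TissueParams(vo2=0.0, rq=0.8), 6.0) == \
            pytest.approx(art)

    def test_untenable(self):
        art = np.array([3.0, 48.0, 1.0])
        with pytest.raises(UntenableStateError):
            tissue_exchange(art, TissueParams(vo2=250.0, rq=0.8), qt=6.0)


def _oracle_compartment(spec, qb, c_in, f_in, v_in=None, v_out=None,
                        stages=40, grid=25):
    """Brute-force grid refinement over the tension simplex.

    Independent of the production Newton path: scans (PCO2, PN2) boxes,
    recomputing the residuals from the content functions directly, and
    shrinks the box around the best point.
    """
    pbh = c.PB - c.ph2o(spec.temp)

    def resid(pco2, pn2):
        po2 = pbh - pco2 - pn2
        if po2 <= 0:
            return None, np.inf
        st = blood_gas_state(spec, GasTensions(po2, pco2, pn2))
        flux = qb * 10.0 * (st.contents - c_in)
        if v_in is None:
            vi = v_out + flux.sum() / 1000.0
            vo = v_out
        else:
            vi = v_in
            vo = v_in - flux.sum() / 1000.0
        f_out = np.array([po2, pco2, pn2]) / pbh
        r = 1000.0 * (vi * f_in - vo * f_out) - flux
        return r, np.max(np.abs(r))

    lo = np.array([1e-6, 1e-6])
    hi = np.array([pbh - 1.0, pbh - 1.0])
    best = None
    for _ in range(stages):
        xs = np.linspace(lo[0], hi[0], grid)
        ys = np.linspace(lo[1], hi[1], grid)
        for x in xs:
            for y in ys:
                _, m = resid(x, y)
                if best is None or m < best[1]:
                    best = ((x, y), m)
        (bx, by), _ = best
        w = (hi - lo) / (grid - 1)
        lo = np.maximum([bx - 2 * w[0], by - 2 * w[1]], 1e-9)
        hi = np.array([bx + 2 * w[0], by + 2 * w[1]])
    return best


class TestIdealCompartment:
    def test_equilibrated_blood_is_fixed_point(self, spec10):
        pbh = c.PB - c.PH2O_37
        f_in = np.array([0.15, 0.056, 1 - 0.15 - 0.056])
        st = blood_gas_state(spec10, GasTensions(*(f_in * pbh)))
        eq = ideal_compartment_equilibrium(
            spec10, BloodStream(5.0, st.contents), f_in, gas_in_stpd=3.0)
        assert eq.fluxes == pytest.approx(np.zeros(3), abs=1e-6)
        assert eq.tensions.po2 == pytest.approx(f_in[0] * pbh, abs=1e-6)
        assert np.asarray(eq.blood_out.contents) == pytest.approx(st.contents, abs=1e-9)

    def test_gas_dominated_limit(self, spec10):
        f_in = np.array([0.21, 0.0, 0.79])
        ven = blood_gas_state(spec10, GasTensions(45.0, 46.0, 570.0))
        eq = ideal_compartment_equilibrium(
            spec10, BloodStream(0.0, ven.contents), f_in, gas_in_stpd=3.0)
        pbh = c.PB - c.PH2O_37
        assert eq.tensions.po2 == pytest.approx(0.21 * pbh, abs=1e-9)
        assert eq.tensions.pco2 == pytest.approx(0.0, abs=1e-9)

    def test_per_gas_conservation(self, spec10):
        ven = blood_gas_state(spec10, GasTensions(45.0, 46.0, 570.0))
        eq = ideal_compartment_equilibrium(
            spec10, BloodStream(4.0, ven.contents), np.array([1.0, 0.0, 0.0]),
            gas_in_stpd=4.0)
        f_out = eq.gas_out.fractions
        gas_side = 1000.0 * (eq.v_in_stpd * np.array([1.0, 0, 0])
                             - eq.v_out_stpd * f_out)
        assert gas_side - eq.fluxes == pytest.approx(np.zeros(3), abs=0.01)
        assert f_out.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed, spec10):
        rng = np.random.default_rng(seed)
        qb = rng.uniform(0.5, 3.0)
        fo2 = rng.uniform(0.21, 1.0)
        f_in = np.array([fo2, 0.0, 1.0 - fo2])
        ven = blood_gas_state(
            spec10, GasTensions(rng.uniform(30, 60), rng.uniform(35, 60),
                                rng.uniform(100, 600)))
        gas = rng.uniform(1.0, 4.0)
        eq = ideal_compartment_equilibrium(
            spec10, BloodStream(qb, ven.contents), f_in, gas_in_stpd=gas)
        (pco2, pn2), m = _oracle_compartment(
            spec10, qb, ven.contents, f_in, v_in=gas)
        assert eq.tensions.pco2 == pytest.approx(pco2, abs=0.1)
        assert eq.tensions.pn2 == pytest.approx(pn2, abs=0.1)

    def test_small_pure_o2_instance_against_oracle(self, spec10):
        ven = blood_gas_state(spec10, GasTensions(40.0, 46.0, 570.0))
        eq = ideal_compartment_equilibrium(
            spec10, BloodStream(1.0, ven.contents), np.array([1.0, 0.0, 0.0]),
            gas_in_stpd=1.0)
        (pco2, pn2), m = _oracle_compartment(
            spec10, 1.0, ven.contents, np.array([1.0, 0.0, 0.0]), v_in=1.0)
        assert m < 0.01 or eq.tensions.pco2 == pytest.approx(pco2, abs=0.1)
        assert eq.tensions.pco2 == pytest.approx(pco2, abs=0.1)
        assert eq.tensions.pn2 == pytest.approx(pn2, abs=0.1)


class TestLungUnit:
    def setup_method(self):
        self.spec = BloodSpec(hb=10.0)
        self.pa = blood_gas_state(self.spec, GasTensions(45.0, 46.0, 570.0))

    def test_total_shunt_passthrough(self):
        out = lung_unit(self.pa.contents, 6.0, 1.0, 0.0, 1.0, self.spec,
                        vd_btps=1.847)
        assert out.arterial_contents == pytest.approx(self.pa.contents)
        assert out.fluxes == pytest.approx(np.zeros(3))

    def test_zero_shunt_equals_end_capillary(self):
        out = lung_unit(self.pa.contents, 6.0, 0.0, 4.31, 1.0, self.spec)
        assert out.arterial_contents == pytest.approx(
            np.asarray(out.compartment.blood_out.contents))

    def test_arterial_linear_in_shunt(self):
        ends = {}
        for s in (0.0, 0.5, 1.0):
            ends[s] = lung_unit(self.pa.contents, 6.0, s, 4.31, 1.0,
                                self.spec).arterial_contents
        # mixing is content-linear between the shunt = 0 ideal-compartment
        # outcome and the shunt = 1 pass-through at fixed end-capillary blood
        cc = lung_unit(self.pa.contents, 6.0, 0.0, 4.31, 1.0,
                       self.spec).compartment.blood_out.contents
        expected_mid = 0.5 * np.asarray(cc) + 0.5 * self.pa.contents
        got_mid = 0.5 * ends[0.0] + 0.5 * ends[1.0]
        assert got_mid == pytest.approx(expected_mid, abs=1e-9)

    def test_pure_o2_washout_leaves_trace_alveolar_n2(self):
        out = lung_unit(self.pa.contents, 6.0, 0.0, 4.31, 1.0, self.spec)
        # inspired FN2 = 0 but venous blood delivers N2 to the alveolus
        assert 0.0 < out.compartment.tensions.pn2 < 570.0
        assert out.fluxes[2] < 0.0  # blood loses N2


class TestOxygenatorUnit:
    def setup_method(self):
        self.spec = BloodSpec(hb=10.0)
        self.ven = blood_gas_state(self.spec, GasTensions(45.0, 46.0, 570.0))

    def test_transparent_when_off(self):
        for kwargs in (dict(qec=0.0, vsweep_atpd=5.0),
                       dict(qec=3.0, vsweep_atpd=0.0)):
            out = oxygenator_unit(self.ven.contents, recirc_fraction=0.0,
                                  circuit_shunt_fraction=0.0, foxy_o2=1.0,
                                  spec=self.spec, **kwargs)
            assert out.returned_contents == pytest.approx(self.ven.contents)
            assert out.fluxes == pytest.approx(np.zeros(3))

    def test_full_circuit_shunt_is_bypass(self):
        out = oxygenator_unit(self.ven.contents, 3.0, 0.0, 1.0, 1.0, 5.0,
                              self.spec)
        assert out.returned_contents == pytest.approx(self.ven.contents)

    def test_recirculation_reduces_o2_uptake(self):
        base = oxygenator_unit(self.ven.contents, 3.0, 0.0, 0.0, 1.0, 5.0,
                               self.spec)
        rec = oxygenator_unit(self.ven.contents, 3.0, 0.3, 0.0, 1.0, 5.0,
                              self.spec)
        assert rec.fluxes[0] < base.fluxes[0]

    def test_matches_lung_with_no_shunt_no_dead_space(self):
        """An oxygenator without recirculation or shunt is the same ideal
        compartment as a lung without shunt or dead space, fed the same
        gas (matching the lung's expired flow to the oxygenator's)."""
        oxy = oxygenator_unit(self.ven.contents, 3.0, 0.0, 0.0, 1.0, 5.0,
                              self.spec)
        from vvecmo import GasCondition, convert_gas_flow
        va_btps = convert_gas_flow(oxy.compartment.v_out_stpd,
                                   GasCondition.STPD, GasCondition.BTPS)
        lung = lung_unit(self.ven.contents, 3.0, 0.0, va_btps, 1.0, self.spec)
        assert lung.compartment.tensions.po2 == pytest.approx(
            oxy.compartment.tensions.po2, abs=1e-3)
        assert lung.compartment.tensions.pco2 == pytest.approx(
            oxy.compartment.tensions.pco2, abs=1e-3)
        assert lung.arterial_contents == pytest.approx(
            oxy.returned_contents, abs=1e-5)
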