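"""Forward-model unit and property tests, checked against closed forms and
the brute-force discrete-time oracle."""

import numpy as np
import pytest

from mteasl import (
    AcquisitionScheme,
    HemodynamicState,
    ModelOptions,
    TissueConstants,
    apply_te_decay,
    arterial_input,
    exchange_fraction,
    forward_signal,
    longitudinal_components,
)


def scheme_with(bolus=1800.0, tis=(1900.0, 2600.0, 3600.0),
                tes=(13.84, 50.0, 200.0), **opts):
    return AcquisitionScheme(ti_list=tis, te_list=tes, bolus_duration=bolus,
                             model_options=ModelOptions(**opts))


class TestArterialInput:
    def test_zero_before_arrival(self, constants):
        state = HemodynamicState(f=60, att=500, texch=150)
        assert arterial_input(400.0, state, scheme_with(), constants) == 0.0

    def test_leading_edge_closed_form(self):
        const = TissueConstants(label_efficiency=1.0)
        state = HemodynamicState(f=60, att=500, texch=150)
        got = arterial_input(500.0, state, scheme_with(), const)
        assert got == pytest.approx(np.exp(-500.0 / 1650.0), rel=1e-12)

    def test_integral_matches_closed_form(self):
        # total delivered label over [0, 10 s] equals the boxcar integral
        const = TissueConstants(label_efficiency=1.0)
        state = HemodynamicState(f=60, att=500, texch=150)
        sch = scheme_with(bolus=1800.0)
        t = np.arange(0.0, 10000.0, 0.1) + 0.05
        quad = np.sum(arterial_input(t, state, sch, const)) * 0.1
        t1b = const.t1_blood
        closed = t1b * (np.exp(-500.0 / t1b) - np.exp(-2300.0 / t1b))
        assert quad == pytest.approx(closed, rel=1e-4)

    def test_negative_time_rejected(self, constants):
        state = HemodynamicState(f=60, att=500, texch=150)
        with pytest.raises(ValueError):
            arterial_input(-1.0, state, scheme_with(), constants)

    def test_bolus_extension_widens_input(self, constants):
        state = HemodynamicState(f=60, att=500, texch=150)
        t = 2350.0  # past the nominal trailing edge at 2300 ms
        assert arterial_input(t, state, scheme_with(), constants) == 0.0
        ext = scheme_with(bolus_extension_frac=0.15)
        assert arterial_input(t, state, ext, constants) > 0.0


class TestExchangeFraction:
    @pytest.mark.parametrize("t, texch, expected", [
        (0.0, 150.0, 1.0),
        (150.0, 150.0, np.exp(-1.0)),
        (450.0, 150.0, np.exp(-3.0)),
    ])
    def test_closed_form(self, t, texch, expected):
        assert exchange_fraction(t, texch) == pytest.approx(expected, rel=1e-12)

    def test_monotone_non_increasing(self):
        t = np.linspace(0, 5000, 200)
        r = exchange_fraction(t, 150.0)
        assert np.all(np.diff(r) <= 0)

    def test_invalid_texch(self):
        with pytest.raises(ValueError):
            exchange_fraction(10.0, 0.0)


class TestLongitudinalComponents:
    def test_zero_before_arrival(self, constants):
        state = HemodynamicState(f=60, att=500, itt=200, texch=150)
        comps = longitudinal_components(400.0, state, scheme_with(), constants)
        assert comps.total == pytest.approx(0.0, abs=1e-15)

    def test_itt_zero_collapses_to_two_compartment(self, constants):
        sch = scheme_with()
        state = HemodynamicState(f=60, att=500, itt=0, texch=150)
        comps = longitudinal_components(sch.ti, state, sch, constants)
        assert np.all(comps.s_bl1 == 0.0)
        two = forward_signal(state, sch, constants, "two_compartment")
        ext = forward_signal(state, sch, constants, "extended")
        np.testing.assert_allclose(ext, two, rtol=1e-12)

    def test_no_exchange_limit_matches_delivery_integral(self, constants, oracle):
        # Texch -> inf: label never leaves blood; bl1 + bl2 equals the
        # single-blood-compartment delivery integral (brute force, 1 ms)
        sch = scheme_with()
        state = HemodynamicState(f=60, att=500, itt=200, texch=1e9)
        comps = longitudinal_components(sch.ti, state, sch, constants)
        assert np.all(comps.s_ex < 1e-5 * comps.total)
        for i, ti in enumerate(sch.ti):
            bf = oracle(ti, 0.0, state, sch, constants, dt=0.25)
            total = comps.s_bl1[i] + comps.s_bl2[i]
            assert total == pytest.approx(bf, rel=2e-3)

    def test_negative_ti_rejected(self, constants):
        state = HemodynamicState(f=60, att=500, texch=150)
        with pytest.raises(ValueError):
            longitudinal_components(-5.0, state, scheme_with(), constants)


class TestTeDecay:
    def test_te_zero_identity(self, constants):
        sch = scheme_with()
        state = HemodynamicState(f=60, att=500, itt=200, texch=150)
        comps = longitudinal_components(sch.ti, state, sch, constants)
        total = apply_te_decay(comps, 0.0, state, constants, sch)
        np.testing.assert_allclose(total, comps.total, rtol=1e-12)

    @pytest.mark.parametrize("exchange_on", [False, True])
    def test_equal_t2s_factor_out(self, exchange_on):
        # with T2_blood = T2_tissue the compartment split is invisible at
        # readout: the total just decays by the common factor, whether or
        # not exchange during the echo is modelled
        const = TissueConstants(t2_blood=100.0, t2_tissue=100.0)
        sch = scheme_with(exchange_during_te=exchange_on)
        state = HemodynamicState(f=60, att=500, itt=200, texch=150)
        comps = longitudinal_components(sch.ti, state, sch, const)
        te = 120.0
        total = apply_te_decay(comps, te, state, const, sch)
        np.testing.assert_allclose(total, comps.total * np.exp(-te / 100.0),
                                   rtol=1e-12)

    def test_transfer_integral_against_quadrature(self, constants, oracle):
        # exchange during TE: closed-form two-exponential convolution vs
        # 0.1 ms Riemann quadrature inside the oracle
        sch = scheme_with(exchange_during_te=True)
        state = HemodynamicState(f=60, att=500, itt=200, texch=150)
        for te in (50.0, 200.0):
            comps = longitudinal_components(2600.0, state, sch, constants)
            total = apply_te_decay(comps, te, state, constants, sch)
            bf = oracle(2600.0, te, state, sch, constants, dt=0.25)
            assert float(total) == pytest.approx(bf, rel=2e-3)

    def test_negative_te_rejected(self, constants):
        sch = scheme_with()
        state = HemodynamicState(f=60, att=500, texch=150)
        comps = longitudinal_components(2600.0, state, sch, constants)
        with pytest.raises(ValueError):
            apply_te_decay(comps, -1.0, state, constants, sch)


class TestForwardSignal:
    def test_zero_perfusion_zero_surface(self, constants):
        state = HemodynamicState(f=0, att=500, texch=150)
        surf = forward_signal(state, scheme_with(), constants)
        assert np.all(surf == 0.0)

    def test_m0_linearity(self, constants):
        sch = scheme_with()
        s1 = forward_signal(HemodynamicState(f=60, att=500, itt=200,
                                             texch=150, m0=1.0),
                            sch, constants)
        s2 = forward_signal(HemodynamicState(f=60, att=500, itt=200,
                                             texch=150, m0=2.0),
                            sch, constants)
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)

    def test_monotone_decreasing_in_te(self, constants):
        sch = scheme_with(tes=tuple(np.linspace(0.0, 250.0, 11)[1:]))
        state = HemodynamicState(f=60, att=500, itt=200, texch=150)
        surf = forward_signal(state, sch, constants)
        assert np.all(np.diff(surf, axis=1) <= 1e-15)

    def test_models_diverge_at_long_te(self, constants):
        # the two models nearly coincide at TE = 50 ms but separate at 200 ms
        state = HemodynamicState(f=60, att=500, itt=200, texch=150)
        sch = scheme_with(tis=tuple(np.arange(600.0, 3601.0, 100.0)),
                          tes=(50.0, 200.0))
        ext = forward_signal(state, sch, constants, "extended")
        two = forward_signal(state, sch, constants, "two_compartment")
        ref = ext.max(axis=0)
        disc = np.max(np.abs(ext - two), axis=0) / ref
        assert disc[0] < disc[1]

    def test_empty_te_rejected(self, constants):
        with pytest.raises(ValueError):
            AcquisitionScheme(ti_list=(1900.0,), te_list=(),
                              bolus_duration=1800.0)

    def test_unknown_model_rejected(self, constants):
        state = HemodynamicState(f=60, att=500, texch=150)
        with pytest.raises(ValueError):
            forward_signal(state, scheme_with(), constants, "one_compartment")


class TestInvariants:
    def test_label_conservation_in_tissue(self):
        # negligible relaxation and instant exchange: after full delivery the
        # entire label sits in the extravascular pool
        const = TissueConstants(t1_blood=1e9, t1_tissue=1e9,
                                t2_blood=1e6, t2_tissue=1e6)
        sch = scheme_with(tis=(3000.0,), bolus=400.0)
        state = HemodynamicState(f=60, att=500, itt=200, texch=1e-3)
        comps = longitudinal_components(3000.0, state, sch, const)
        total = float(comps.total)
        assert float(comps.s_bl1) < 1e-9 * total
        assert float(comps.s_bl2) < 1e-9 * total

    @pytest.mark.parametrize("clock", ["voxel_arrival", "capillary_arrival"])
    @pytest.mark.parametrize("exchange_on", [False, True])
    def test_oracle_equivalence(self, constants, oracle, clock, exchange_on):
        # closed forms vs 1 ms discrete-time bookkeeping over a parameter grid
        sch = scheme_with(tis=(700.0, 1900.0, 3600.0), tes=(13.84, 124.56),
                          bolus=400.0, exchange_clock=clock,
                          exchange_during_te=exchange_on)
        worst = 0.0
        for att in (500.0, 1500.0, 2500.0):
            for texch in (10.0, 150.0, 1000.0):
                for itt in (0.0, 200.0, 500.0):
                    state = HemodynamicState(f=60, att=att, itt=itt,
                                             texch=texch, m0=1000.0)
                    surf = forward_signal(state, sch, constants)
                    ref = max(surf.max(), 1e-30)
                    for i, ti in enumerate(sch.ti):
                        for j, te in enumerate(sch.te):
                            bf = oracle(ti, te, state, sch, constants, dt=1.0)
                            err = abs(surf[i, j] - bf) / max(bf, 1e-3 * ref)
                            worst = max(worst, err)
        assert worst < 5e-3

    def test_s_ex_non_increasing_in_texch(self, constants):
        sch = scheme_with()
        prev = None
        for texch in (50.0, 150.0, 400.0, 1000.0):
            state = HemodynamicState(f=60, att=500, itt=200, texch=texch)
            s_ex = longitudinal_components(2600.0, state, sch, constants).s_ex
            if prev is not None:
                assert float(s_ex) <= prev + 1e-15
            prev = float(s_ex)
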