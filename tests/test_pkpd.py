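"""Drug kinetics and concentration-to-effect mappings."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from arthrosim.pkpd import (
    MTXEffectParameters,
    PKModel,
    TherapyEffects,
    TrialProtocol,
    ada_free_tnf,
    default_pk,
    default_protocol,
    mtx_effects,
    simulate_pk,
    tcz_il6_clearance_scaling,
)


def _mono_model(v=10.0, cl=5.0):
    # two-compartment structure with q=0 collapses to one compartment
    return PKModel(drug="MTX", structure="2c_bolus", v1=v, v2=1.0, cl=cl, q=0.0)


class TestPk:
    def test_iv_bolus_closed_form(self):
        m = _mono_model(v=10.0, cl=5.0)  # k = 0.5/day
        events = [(0.0, 100.0)]
        c0 = m.central_concentration([1e-9], events)[0]
        assert c0 == pytest.approx(10.0, rel=1e-6)
        thalf = np.log(2) / 0.5
        assert m.central_concentration([thalf], events)[0] == pytest.approx(5.0, rel=1e-6)

    def test_dose_proportionality(self):
        m = default_pk("TCZ")
        t = np.linspace(0.0, 60.0, 200)
        c1 = m.central_concentration(t, [(0.0, 100.0), (28.0, 100.0)])
        c2 = m.central_concentration(t, [(0.0, 200.0), (28.0, 200.0)])
        assert np.allclose(c2, 2.0 * c1, rtol=1e-8)

    def test_multidose_equals_shifted_single_doses(self):
        m = default_pk("ADA")
        t = np.linspace(0.0, 70.0, 300)
        multi = m.central_concentration(t, [(k * 14.0, 40.0) for k in range(5)])
        summed = sum(m.central_concentration(t - k * 14.0, [(0.0, 40.0)]) for k in range(5))
        assert np.allclose(multi, summed, rtol=1e-8, atol=1e-12)

    def test_sc_profile_matches_ode_oracle(self):
        m = default_pk("ADA")
        k = m.cl / m.v1
        events = [(k14 * 14.0, 40.0) for k14 in range(6)]

        def rhs(t, y):
            dose_rate = 0.0
            return [-m.ka * y[0], m.ka * y[0] / m.v1 - k * y[1]]

        # piecewise ODE integration with absorption-depot boluses
        y = np.array([0.0, 0.0])
        t0 = 0.0
        for td, amt in events:
            if td > t0:
                sol = solve_ivp(rhs, (t0, td), y, rtol=1e-10, atol=1e-12)
                y = sol.y[:, -1]
                t0 = td
            y[0] += amt * m.bioavailability
        sol = solve_ivp(rhs, (t0, 84.0), y, rtol=1e-10, atol=1e-12)
        ode_trough = sol.y[1, -1]
        closed = m.central_concentration([84.0], events)[0]
        assert closed == pytest.approx(ode_trough, rel=1e-6)

    def test_protocol_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate_pk(default_pk("ADA"), default_protocol("MTX"), [0.0, 1.0])

    def test_unsupported_route(self):
        with pytest.raises(ValueError):
            PKModel(drug="X", structure="inhaled", v1=1.0, cl=1.0)


class TestMtxEffects:
    def test_zero_concentration_neutral(self):
        eff = mtx_effects(0.0)
        assert eff.anti_cytsec_mtx == 0.0
        assert eff.pro_cytsec_mtx == 0.0
        assert eff.anti_cellinflux_mtx == 0.0

    def test_half_effect_at_km(self):
        p = MTXEffectParameters()
        eff = mtx_effects(p.km, p)
        assert eff.anti_cytsec_mtx == pytest.approx(0.25)  # vm/2 with vm=0.5
        assert eff.pro_cytsec_mtx == pytest.approx(0.25)
        assert eff.anti_cellinflux_mtx == pytest.approx(0.25)

    def test_saturation_at_printed_vm(self):
        eff = mtx_effects(1e3)
        assert eff.anti_cytsec_mtx == pytest.approx(0.5, rel=1e-6)
        # secretion multiplier at saturation
        assert 1.0 - eff.anti_cytsec_mtx == pytest.approx(0.5, rel=1e-6)

    def test_monotone_in_concentration(self):
        c = np.logspace(-8, 0, 60)
        e = [mtx_effects(x).anti_cytsec_mtx for x in c]
        assert np.all(np.diff(e) >= 0)


class TestAdaBinding:
    def test_no_drug_all_free(self):
        assert ada_free_tnf(2.5, 0.0, kd=1.0) == pytest.approx(2.5)

    def test_excess_drug_limit(self):
        total, ada, kd = 1.0, 1e6, 10.0
        assert ada_free_tnf(total, ada, kd) == pytest.approx(total * kd / ada, rel=1e-3)

    def test_golden_ratio_case_and_fixed_point_oracle(self):
        free = ada_free_tnf(1.0, 1.0, 1.0)
        assert free == pytest.approx((np.sqrt(5) - 1) / 2, abs=1e-12)
        # brute-force fixed point: free = total - ada*free/(kd+free)
        x = 0.5
        for _ in range(200):
            x = 1.0 - 1.0 * x / (1.0 + x)
        assert free == pytest.approx(x, abs=1e-10)

    def test_mass_balance(self, rng):
        total = rng.uniform(0.01, 100.0, 50)
        ada = rng.uniform(0.0, 500.0, 50)
        kd = 3.7
        free = ada_free_tnf(total, ada, kd)
        bound = ada * free / (kd + free)
        assert np.allclose(free + bound, total, rtol=1e-10)

    def test_monotone_decreasing_in_drug(self):
        ada = np.linspace(0.0, 100.0, 200)
        free = ada_free_tnf(5.0, ada, 2.0)
        assert np.all(np.diff(free) <= 1e-12)
        assert np.all((free >= 0) & (free <= 5.0))


class TestTczScaling:
    def test_no_drug_unchanged(self):
        assert tcz_il6_clearance_scaling(0.0, 0.4) == 1.0

    def test_at_kd_half(self):
        assert tcz_il6_clearance_scaling(0.4, 0.4) == pytest.approx(0.5)

    def test_limit_zero(self):
        assert tcz_il6_clearance_scaling(1e9, 0.4) < 1e-8

    def test_steady_il6_falls_by_divisor(self, bare_spec):
        # decoupled IL-6: steady = flux/clearance; divisor 0.5 doubles
        # the effective clearance so the steady level halves
        from arthrosim.engine import CompiledModel, N_CELLS
        from arthrosim.patient import VirtualPatient
        from arthrosim.tables import ODE_MEDIATORS

        p = VirtualPatient(
            id="t", baseline_prolif={}, baseline_influx={},
            baseline_deg={"FLS": 1e-12},
            baseline_secretion={("FLS", "IL6"): 1e-6},
            mediator_clearance={"IL6": 2.0},
        )
        model = CompiledModel(bare_spec, [p])

        class StubDriver:
            class protocol:
                dose_mg = 1.0

                @staticmethod
                def dose_events():
                    return []

            @staticmethod
            def effects(t):
                return TherapyEffects(il6_clearance_divisor=0.5)

        y0 = np.zeros((1, N_CELLS + len(ODE_MEDIATORS)))
        y0[0, 0] = 1e6  # FLS
        y_off = model.integrate(y0, 0.0, 50.0, 0.05)
        y_on = model.integrate(y0, 0.0, 50.0, 0.05, StubDriver())
        j = N_CELLS + ODE_MEDIATORS.index("IL6")
        # 1e6 cells * 1e-6 ng/cell/day / (2/day) = 0.5 ng/mL untreated
        assert y_off[0, j] == pytest.approx(0.5, rel=1e-4)
        assert y_on[0, j] == pytest.approx(0.25, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tcz_il6_clearance_scaling(1.0, 0.0)
        with pytest.raises(ValueError):
            tcz_il6_clearance_scaling(-1.0, 1.0)


class TestProtocol:
    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            TrialProtocol("MTX", -1.0, "oral_bolus", 7.0, 12, 12.0)
        with pytest.raises(ValueError):
            TrialProtocol("MTX", 15.0, "oral_bolus", 7.0, 12, 0.0)

    def test_mg_per_kg_resolution(self):
        p = default_protocol("TCZ")
        assert p.dose_per_kg and p.dose_mg == pytest.approx(8.0 * 70.0)

    def test_defaults_match_trial_arms(self):
        ada = default_protocol("ADA")
        assert (ada.dose, ada.interval_days) == (40.0, 14.0)
        mtx = default_protocol("MTX")
        assert mtx.interval_days == 7.0 and mtx.readout_week == 12.0
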