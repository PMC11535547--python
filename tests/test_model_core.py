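"""ODE assembly, steady states and time courses."""

import numpy as np
import pytest

from arthrosim import (
    build_rhs,
    default_protocol,
    sample_cohort,
    simulate_timecourse,
    solve_steady_state,
)
from arthrosim.cohort import ParameterBounds, baseline_steady_states
from arthrosim.engine import CompiledModel, N_CELLS
from arthrosim.model_core import compile_model
from arthrosim.network import EssentialEdge, NetworkSpec, ProcessRef
from arthrosim.patient import SynoviumState, VirtualPatient
from arthrosim.tables import CELLS, MEDIATORS, ODE_MEDIATORS


def _patient(prolif=None, influx=None, deg=None, secretion=None, clearance=None, **kw):
    return VirtualPatient(
        id="toy",
        baseline_prolif=prolif or {},
        baseline_influx=influx or {},
        baseline_deg=deg or {},
        baseline_secretion=secretion or {},
        mediator_clearance=clearance or {},
        **kw,
    )


def _state(cells=None, meds=None):
    return SynoviumState(
        {c: (cells or {}).get(c, 0.0) for c in CELLS},
        {m: (meds or {}).get(m, 0.0) for m in MEDIATORS},
    )


class TestBuildRhs:
    def test_decoupled_cell_derivative(self, bare_spec):
        # prolif 100, deg 0.1/day, density 500 -> d/dt = 100 - 50 = 50
        p = _patient(prolif={"FLS": 100.0}, deg={"FLS": 0.1})
        f = build_rhs(bare_spec, p)
        dy = f(0.0, _state({"FLS": 500.0}).vector())
        assert dy[CELLS.index("FLS")] == pytest.approx(50.0)
        assert np.all(dy[np.arange(len(dy)) != CELLS.index("FLS")] == 0.0)

    def test_decoupled_mediator_derivative(self, bare_spec):
        # 1e6 cells/mL secreting 1e-6 ng/cell/day, clearance 1/day,
        # conc 0.5 ng/mL -> d/dt = 1 - 0.5 = +0.5 ng/mL/day
        p = _patient(secretion={("FLS", "IL6"): 1e-6}, clearance={"IL6": 1.0})
        f = build_rhs(bare_spec, p)
        dy = f(0.0, _state({"FLS": 1e6}, {"IL6": 0.5}).vector())
        assert dy[N_CELLS + ODE_MEDIATORS.index("IL6")] == pytest.approx(0.5)

    def test_essential_gate_zeroes_ifng_secretion(self):
        spec = NetworkSpec(
            secretion_edges=[("Th1", "IFNg")],
            essential_edges=[EssentialEdge("IL12", ProcessRef("secretion", "Th1", "IFNg"),
                                           km_gate=0.01)],
            cam=None,
        )
        spec.validate()
        p = _patient(secretion={("Th1", "IFNg"): 1e-6}, clearance={"IFNg": 0.0})
        f = build_rhs(spec, p)
        dy = f(0.0, _state({"Th1": 1e6}, {"IL12": 0.0}).vector())
        assert dy[N_CELLS + ODE_MEDIATORS.index("IFNg")] == 0.0
        dy = f(0.0, _state({"Th1": 1e6}, {"IL12": 1e6}).vector())
        assert dy[N_CELLS + ODE_MEDIATORS.index("IFNg")] == pytest.approx(1.0, rel=1e-4)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            _patient(prolif={"FLS": -1.0})

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            _patient(prolif={"Fibroblast": 1.0})


class TestSteadyState:
    def test_decoupled_closed_forms(self, bare_spec):
        # cell: (prolif+influx)/deg; mediator: flux/clearance
        p = _patient(
            prolif={"FLS": 100.0}, deg={"FLS": 0.1, "Macrophage": 1.0},
            influx={"Macrophage": 30.0},
            secretion={("FLS", "IL6"): 1e-6}, clearance={"IL6": 2.0},
        )
        p.baseline_deg["Macrophage"] = 0.5
        res = solve_steady_state(bare_spec, p, _state({"FLS": 1.0, "Macrophage": 1.0}),
                                 t_max=600.0)
        assert res.converged
        assert res.state.cell_density["FLS"] == pytest.approx(1000.0, rel=1e-6)
        assert res.state.cell_density["Macrophage"] == pytest.approx(60.0, rel=1e-6)
        # FLS=1000 cells/mL * 1e-6 ng/cell/day / 2 per day = 5e-4 ng/mL
        assert res.state.mediator_conc["IL6"] == pytest.approx(5e-4, rel=1e-6)

    def test_doubling_degradation_halves_density(self, bare_spec):
        for deg, expect in ((0.1, 1000.0), (0.2, 500.0)):
            p = _patient(prolif={"FLS": 100.0}, deg={"FLS": deg})
            res = solve_steady_state(bare_spec, p, _state({"FLS": 1.0}), t_max=600.0)
            assert res.state.cell_density["FLS"] == pytest.approx(expect, rel=1e-6)

    def test_reference_patient_lands_in_published_ranges(self, spec, reference, ref_state):
        from arthrosim.tables import CELL_RANGES, MEDIATOR_RANGES

        res = solve_steady_state(spec, reference, ref_state, t_max=400.0)
        assert res.converged
        for c, (lo, hi) in CELL_RANGES.items():
            assert lo <= res.state.cell_density[c] <= hi
        for m, (lo, hi) in MEDIATOR_RANGES.items():
            assert lo <= res.state.mediator_conc[m] <= hi

    def test_invalid_t_max(self, bare_spec):
        with pytest.raises(ValueError):
            solve_steady_state(bare_spec, _patient(), _state(), t_max=-1.0)


class TestTimecourse:
    def test_fixed_point_invariance_no_therapy(self, spec, reference, ref_state):
        states = simulate_timecourse(spec, reference, ref_state, duration=180.0,
                                     sample_times=[90.0, 180.0])
        y0 = ref_state.vector()
        for s in states:
            drift = np.abs(s.vector() - y0) / (y0 + 1e-12)
            assert drift.max() < 1e-6

    def test_fixed_point_invariance_random_patients(self, spec, reference):
        pats, _ = sample_cohort(ParameterBounds(), 20, seed=11, reference=reference)
        from arthrosim.fixtures import reference_state

        Y, res, conv = baseline_steady_states(spec, pats, reference_state().vector(),
                                              t_max=600.0)
        model = CompiledModel(spec, pats)
        Y2 = model.integrate(Y, 0.0, 180.0, 0.25)
        ok = conv
        assert ok.sum() >= 15  # most random patients reach steady state
        drift = np.abs(Y2[ok] - Y[ok]) / (np.abs(Y[ok]) + 1e-9)
        assert drift.max() < 1e-3

    def test_zero_dose_identical_to_untreated(self, spec, reference, ref_state):
        proto = default_protocol("ADA")
        proto.dose = 0.0
        treated = simulate_timecourse(spec, reference, ref_state, therapy=proto,
                                      duration=170.0, sample_times=[170.0])
        untreated = simulate_timecourse(spec, reference, ref_state, duration=170.0,
                                        sample_times=[170.0])
        assert treated[0].vector() == pytest.approx(untreated[0].vector())

    def test_ada_lowers_free_synovial_tnf_at_trough(self, spec, reference, ref_state):
        from arthrosim.pkpd import TherapyDriver, ada_free_tnf

        proto = default_protocol("ADA")
        driver = TherapyDriver(proto)
        out = simulate_timecourse(spec, reference, ref_state, therapy=proto,
                                  therapy_driver=driver, duration=168.0,
                                  sample_times=[168.0])[0]
        eff = driver.effects(168.0)
        free = ada_free_tnf(out.mediator_conc["TNFa"], eff.ada_syn_ngml, eff.ada_kd_ngml)
        assert free < ref_state.mediator_conc["TNFa"]

    def test_sample_time_beyond_duration_rejected(self, spec, reference, ref_state):
        with pytest.raises(ValueError):
            simulate_timecourse(spec, reference, ref_state, duration=10.0,
                                sample_times=[20.0])


class TestEngineConsistency:
    def test_batch_matches_lsoda(self, spec, reference, ref_state, rng):
        y0 = ref_state.vector() * np.exp(rng.normal(0, 0.3, ref_state.vector().size))
        model = compile_model(spec, reference)
        batch = model.integrate(y0[None, :], 0.0, 60.0, 0.1)[0]
        init = SynoviumState.from_vector(y0, cam=0.0)
        lsoda = simulate_timecourse(spec, reference, init, duration=60.0,
                                    sample_times=[60.0])[0].vector()
        assert np.max(np.abs(batch - lsoda) / (np.abs(lsoda) + 1e-9)) < 5e-3

    def test_non_negativity_from_perturbed_states(self, spec, reference, ref_state, rng):
        model = compile_model(spec, reference)
        Y0 = ref_state.vector()[None, :] * np.exp(rng.normal(0, 1.0, (8, ref_state.vector().size)))
        Y = model.integrate(Y0, 0.0, 120.0, 0.1)
        assert np.all(Y >= 0.0)
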