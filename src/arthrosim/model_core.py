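"""Single-patient model assembly and solution.

Assembles the ODE right-hand side for one virtual patient, relaxes it
to dynamic steady state and simulates therapy time courses.  The
underlying compiled engine is shared with the cohort-scale batch path;
here the stiff implicit LSODA integrator is used with tight tolerances
(relative 1e-8; absolute 1e-3 cells/mL and 1e-9 ng/mL).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .engine import CompiledModel, N_CELLS, state_atol
from .network import NetworkSpec
from .patient import SteadyStateResult, SynoviumState, VirtualPatient
from .pkpd import TherapyDriver, TrialProtocol
from .regulation import CapPolicy

__all__ = ["build_rhs", "solve_steady_state", "simulate_timecourse", "compile_model", "state_from_vector"]

RTOL = 1e-8
STEADY_TOL = 1e-6


def compile_model(spec: NetworkSpec, patient: VirtualPatient,
                  policy: CapPolicy | None = None) -> CompiledModel:
    return CompiledModel(spec, [patient], policy)


def state_from_vector(model: CompiledModel, y: np.ndarray, time: float = 0.0) -> SynoviumState:
    cam = 0.0
    if model.spec.cam is not None:
        cam = float(model.f_cam[0] * model.spec.cam(max(y[model.endo_idx], 0.0)))
    return SynoviumState.from_vector(y, cam=cam, time=time)


def build_rhs(spec: NetworkSpec, patient: VirtualPatient,
              therapy_driver: TherapyDriver | None = None,
              policy: CapPolicy | None = None):
    """Derivative function f(t, y) for one patient.

    ``y`` is the flat state vector (9 cell densities then 16 dynamic
    mediator concentrations).  Cell dynamics are zeroth-order
    proliferation and influx scaled by capped regulation factors minus
    first-order death; mediators are per-cell secretion sums minus
    first-order clearance; the B-cell -> plasma-cell differentiation
    flux moves cells between the two pools; therapy effects, when a
    driver is given, multiply the designated rates.
    """
    model = compile_model(spec, patient, policy)

    def f(t, y):
        return model.rhs_single(t, np.asarray(y, dtype=float), therapy_driver)

    f.model = model
    return f


def _solve_segments(model: CompiledModel, y0: np.ndarray, t0: float, t1: float,
                    driver: TherapyDriver | None, t_eval=None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LSODA integration split at dosing discontinuities."""
    breaks = [t0, t1]
    if driver is not None:
        breaks += [td for td, _ in driver.protocol.dose_events() if t0 < td < t1]
    breaks = sorted(set(breaks))
    t_eval = np.asarray(t_eval, dtype=float) if t_eval is not None else np.array([t1])
    out_t, out_y = [], []
    y = np.array(y0, dtype=float)
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = t_eval[(t_eval > a) & (t_eval <= b)]
        sol = solve_ivp(
            lambda t, yy: model.rhs_single(t, yy, driver),
            (a, b), y, method="LSODA", rtol=RTOL, atol=state_atol(),
            t_eval=np.unique(np.append(seg_eval, b)), max_step=np.inf,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            if tt in seg_eval:
                out_t.append(tt)
                out_y.append(yy)
        y = sol.y[:, -1]
    return np.array(out_t), (np.array(out_y) if out_y else np.empty((0, len(y0)))), y


def solve_steady_state(spec: NetworkSpec, patient: VirtualPatient,
                       init: SynoviumState, t_max: float = 1000.0,
                       tol: float = STEADY_TOL,
                       policy: CapPolicy | None = None) -> SteadyStateResult:
    """Integrate until the scaled derivative norm drops below ``tol``.

    Non-convergence within ``t_max`` days is reported through the
    ``converged`` flag, not an exception.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    model = compile_model(spec, patient, policy)
    y = init.vector()
    t, chunk = 0.0, 100.0
    res = float(model.residual(t, y[None, :])[0])
    while res >= tol and t < t_max:
        span = min(chunk, t_max - t)
        _, _, y = _solve_segments(model, y, t, t + span, None)
        t += span
        res = float(model.residual(t, y[None, :])[0])
    y = np.maximum(y, 0.0)
    return SteadyStateResult(
        state=state_from_vector(model, y, time=t),
        converged=bool(res < tol),
        residual_norm=res,
    )


def simulate_timecourse(spec: NetworkSpec, patient: VirtualPatient,
                        init: SynoviumState, therapy: TrialProtocol | None = None,
                        duration: float | None = None, sample_times=None,
                        policy: CapPolicy | None = None,
                        therapy_driver: TherapyDriver | None = None) -> list[SynoviumState]:
    """Simulate forward from ``init`` and return sampled states.

    ``therapy`` may be a protocol (a default PK/PD driver is built) or
    ``None`` for an untreated run.  A zero-dose protocol reproduces
    the untreated trajectory exactly.
    """
    if therapy is not None and therapy_driver is None:
        therapy_driver = TherapyDriver(therapy)
    if duration is None:
        duration = therapy.duration_days if therapy is not None else 180.0
    if therapy is not None and duration + 1e-9 < therapy.readout_week * 7.0:
        raise ValueError("duration does not cover the protocol readout")
    sample_times = np.atleast_1d(
        np.asarray(sample_times if sample_times is not None else [duration], dtype=float)
    )
    if np.any(sample_times > duration + 1e-9):
        raise ValueError("sample time beyond duration")
    if therapy_driver is not None and therapy_driver.protocol.dose_mg == 0.0:
        therapy_driver = None  # null dose: identical to the untreated run
    model = compile_model(spec, patient, policy)
    ts, ys, _ = _solve_segments(model, init.vector(), 0.0, float(duration),
                                therapy_driver, t_eval=sample_times)
    return [state_from_vector(model, np.maximum(y, 0.0), time=t) for t, y in zip(ts, ys)]
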