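"""Compiled network evaluation and integrators.

The declarative :class:`~arthrosim.network.NetworkSpec` plus a batch
of virtual patients is compiled into flat index/parameter arrays so a
single right-hand-side evaluation is vectorized across patients.  The
same compiled object backs both integration paths:

* a stiff implicit path (scipy LSODA) used for single patients and as
  the reference integrator, and
* an exponential-Euler path used for cohort-scale work.  Each species
  obeys d(x)/dt = P(x) - L(x)*x with non-negative production P and a
  positive first-order loss coefficient L; the update
  ``x <- x*exp(-L*dt) + (P/L)*(1 - exp(-L*dt))`` treats the loss
  exactly, is unconditionally stable for the fast cytokine clearances
  and preserves positivity.

State layout: the 9 cell densities, then the 16 dynamic mediators
(CAM is algebraic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkSpec, IMMUNE_INFLUX_CELLS
from .patient import VirtualPatient
from .pkpd import TherapyDriver, TherapyEffects, ada_free_tnf
from .regulation import CapPolicy
from .tables import CELLS, MEDIATORS, ODE_MEDIATORS

N_CELLS = len(CELLS)
N_STATE = N_CELLS + len(ODE_MEDIATORS)

#: absolute state scales used in residual norms and solver tolerances
ATOL_CELLS = 1.0e-3
ATOL_MEDIATORS = 1.0e-9

_CELL_IDX = {c: i for i, c in enumerate(CELLS)}
_MED_IDX = {m: i for i, m in enumerate(MEDIATORS)}
_ODE_MED_IDX = {m: i for i, m in enumerate(ODE_MEDIATORS)}

#: F_* scale-factor parameter name per mediator
_F_NAME = {m: ("F_MIP3" if m == "MIP3a" else f"F_{m}") for m in MEDIATORS}


def state_atol() -> np.ndarray:
    atol = np.empty(N_STATE)
    atol[:N_CELLS] = ATOL_CELLS
    atol[N_CELLS:] = ATOL_MEDIATORS
    return atol


@dataclass
class _EdgeArrays:
    reg: np.ndarray    # mediator index (into MEDIATORS) per edge
    group: np.ndarray  # target group index per edge
    sign: np.ndarray   # +1 pro, -1 anti
    km: np.ndarray
    slope: np.ndarray
    vm: np.ndarray     # (n_edges, n_patients)


class CompiledModel:
    """Network + patient batch compiled to flat arrays."""

    def __init__(self, spec: NetworkSpec, patients: list[VirtualPatient],
                 policy: CapPolicy | None = None):
        spec.validate()
        self.spec = spec
        self.policy = policy or CapPolicy()
        self.n = len(patients)
        n = self.n

        def cellvec(getter, default=0.0):
            return np.array(
                [[getter(p).get(c, default) for p in patients] for c in CELLS]
            )  # (9, n)

        self.kg = cellvec(lambda p: p.baseline_prolif)
        self.kin = cellvec(lambda p: p.baseline_influx)
        self.kdeg = cellvec(lambda p: p.baseline_deg)
        self.kdiff = np.array([p.kdiff for p in patients])
        self.clr = np.array(
            [[p.mediator_clearance.get(m, 0.0) for p in patients] for m in ODE_MEDIATORS]
        )  # (16, n)
        self.f_med = np.array(
            [[p.scale_factors.get(_F_NAME[m], 1.0) for p in patients] for m in ODE_MEDIATORS]
        )
        self.f_cam = np.array([p.scale_factors.get("F_CAM", 1.0) for p in patients])

        # target groups
        groups: dict[tuple, int] = {}
        for e in spec.regulation_edges:
            groups.setdefault(e.target.key(), len(groups))
        self.n_groups = len(groups)
        self._group_of = groups

        def group_idx(kind, cell, mediator=None):
            return groups.get((kind, cell, mediator), -1)

        self.prolif_group = np.array([group_idx("proliferation", c) for c in CELLS])
        self.influx_group = np.array([group_idx("influx", c) for c in CELLS])
        self.apop_group = np.array([group_idx("apoptosis", c) for c in CELLS])
        self.diff_group = group_idx("differentiation", "BCell")

        # regulation edges, canonically ordered for deterministic sums
        edges = sorted(spec.regulation_edges, key=lambda e: (e.regulator, e.name))
        self.edges = _EdgeArrays(
            reg=np.array([_MED_IDX[e.regulator] for e in edges], dtype=int),
            group=np.array([groups[e.target.key()] for e in edges], dtype=int),
            sign=np.array([1 if e.sign == "pro" else -1 for e in edges], dtype=int),
            km=np.array([e.km_effect for e in edges]),
            slope=np.array([e.slope_effect for e in edges]),
            vm=np.array(
                [[p.edge_overrides.get(e.param, e.vm_effect) for p in patients] for e in edges]
            ),
        )

        # secretion terms
        self.sec_cell = np.array([_CELL_IDX[c] for c, m in spec.secretion_edges], dtype=int)
        self.sec_med = np.array([_ODE_MED_IDX[m] for c, m in spec.secretion_edges], dtype=int)
        self.sec_group = np.array(
            [group_idx("secretion", c, m) for c, m in spec.secretion_edges], dtype=int
        )
        self.sec_base = np.array(
            [[p.baseline_secretion.get((c, m), 0.0) for p in patients]
             for c, m in spec.secretion_edges]
        )  # (n_sec, n)
        self.sec_is_treg = np.array([c == "Treg" for c, m in spec.secretion_edges])
        # essential gates per secretion term
        self.sec_gates = [[] for _ in spec.secretion_edges]
        for g in spec.essential_edges:
            if g.target.kind != "secretion":
                raise ValueError("essential gates are supported on secretion terms")
            idx = spec.secretion_edges.index((g.target.cell, g.target.mediator))
            self.sec_gates[idx].append((_MED_IDX[g.mediator], g.km_gate, g.slope))

        self.immune_mask = np.array([c in IMMUNE_INFLUX_CELLS for c in CELLS])
        self.endo_idx = _CELL_IDX["Endothelial"]
        self.il6_ode_idx = _ODE_MED_IDX["IL6"]
        self.tnfa_med_idx = _MED_IDX["TNFa"]

    # --- right-hand side -------------------------------------------------

    def _concentrations(self, Y: np.ndarray, eff: TherapyEffects | None) -> np.ndarray:
        """(n, 17) mediator concentrations in MEDIATORS order, CAM
        derived from endothelial density, TNF-a replaced by its free
        fraction under ADA."""
        n = Y.shape[0]
        conc = np.zeros((n, len(MEDIATORS)))
        for m, j in _ODE_MED_IDX.items():
            conc[:, _MED_IDX[m]] = Y[:, N_CELLS + j]
        if self.spec.cam is not None:
            conc[:, _MED_IDX["CAM"]] = self.f_cam * self.spec.cam(Y[:, self.endo_idx])
        if eff is not None and eff.ada_syn_ngml > 0:
            j = self.tnfa_med_idx
            conc[:, j] = ada_free_tnf(conc[:, j], eff.ada_syn_ngml, eff.ada_kd_ngml)
        return conc

    def _factors(self, conc: np.ndarray) -> np.ndarray:
        """(n, n_groups) multiplicative regulation factors."""
        n = conc.shape[0]
        pro = np.zeros((n, self.n_groups))
        anti = np.zeros((n, self.n_groups))
        E = self.edges
        for i in range(len(E.reg)):
            c = conc[:, E.reg[i]]
            cs = np.power(c, E.slope[i])
            h = E.vm[i] * cs / (cs + E.km[i] ** E.slope[i])
            (pro if E.sign[i] > 0 else anti)[:, E.group[i]] += h
        np.minimum(pro, self.policy.pro_limit, out=pro)
        np.minimum(anti, self.policy.anti_limit, out=anti)
        return (1.0 + pro) * (1.0 - anti)

    def production_loss(self, t: float, Y: np.ndarray, driver: TherapyDriver | None = None):
        """Production terms P (n, 25) and loss coefficients L (n, 25)
        such that dY/dt = P - L*Y."""
        Yc = np.maximum(Y, 0.0)
        eff = driver.effects(t) if driver is not None else None
        conc = self._concentrations(Yc, eff)
        fac = self._factors(conc)

        def f(groups):
            out = np.ones((Yc.shape[0], N_CELLS))
            ok = groups >= 0
            out[:, ok] = fac[:, groups[ok]]
            return out

        fp, fi, fa = f(self.prolif_group), f(self.influx_group), f(self.apop_group)
        fd = fac[:, self.diff_group] if self.diff_group >= 0 else 1.0

        influx = self.kin.T * fi
        if eff is not None and eff.anti_cellinflux_mtx > 0:
            influx[:, self.immune_mask] *= 1.0 - eff.anti_cellinflux_mtx

        P = np.zeros_like(Yc)
        L = np.zeros_like(Yc)
        P[:, :N_CELLS] = self.kg.T * fp + influx
        L[:, :N_CELLS] = self.kdeg.T * fa

        # B-cell -> plasma-cell differentiation flux
        b, pc = _CELL_IDX["BCell"], _CELL_IDX["PlasmaCell"]
        kdiff_eff = self.kdiff * fd
        L[:, b] += kdiff_eff
        P[:, pc] += kdiff_eff * Yc[:, b]

        # secretion
        sec_fac = np.ones((Yc.shape[0], len(self.sec_cell)))
        ok = self.sec_group >= 0
        sec_fac[:, ok] = fac[:, self.sec_group[ok]]
        for s, gates in enumerate(self.sec_gates):
            for med_idx, km_gate, slope in gates:
                c = np.power(conc[:, med_idx], slope)
                sec_fac[:, s] *= c / (c + km_gate**slope)
        if eff is not None:
            if eff.anti_cytsec_mtx > 0:
                sec_fac[:, ~self.sec_is_treg] *= 1.0 - eff.anti_cytsec_mtx
            if eff.pro_cytsec_mtx > 0:
                sec_fac[:, self.sec_is_treg] *= 1.0 + eff.pro_cytsec_mtx
        rates = self.sec_base.T * Yc[:, self.sec_cell] * sec_fac  # (n, n_sec)
        for s in range(len(self.sec_cell)):
            P[:, N_CELLS + self.sec_med[s]] += rates[:, s]
        P[:, N_CELLS:] *= self.f_med.T

        L[:, N_CELLS:] = self.clr.T
        if eff is not None and eff.il6_clearance_divisor < 1.0:
            L[:, N_CELLS + self.il6_ode_idx] /= eff.il6_clearance_divisor
        return P, L

    def rhs(self, t: float, Y: np.ndarray, driver: TherapyDriver | None = None) -> np.ndarray:
        P, L = self.production_loss(t, Y, driver)
        return P - L * np.maximum(Y, 0.0)

    def rhs_single(self, t: float, y: np.ndarray, driver: TherapyDriver | None = None) -> np.ndarray:
        return self.rhs(t, y[None, :], driver)[0]

    # --- integrators -----------------------------------------------------

    def step_expeuler(self, t: float, Y: np.ndarray, dt: float,
                      driver: TherapyDriver | None = None) -> np.ndarray:
        P, L = self.production_loss(t, Y, driver)
        decay = np.exp(-L * dt)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(L > 1e-300, P / np.where(L > 1e-300, L, 1.0) * (1.0 - decay), P * dt)
        return np.maximum(Y, 0.0) * decay + gain

    def integrate(self, Y0: np.ndarray, t0: float, t1: float, dt: float,
                  driver: TherapyDriver | None = None) -> np.ndarray:
        """Exponential-Euler integration from t0 to t1."""
        Y = np.array(Y0, dtype=float)
        n_steps = max(1, int(np.ceil((t1 - t0) / dt)))
        h = (t1 - t0) / n_steps
        t = t0
        for _ in range(n_steps):
            Y = self.step_expeuler(t, Y, h, driver)
            t += h
        return Y

    def residual(self, t: float, Y: np.ndarray, driver: TherapyDriver | None = None) -> np.ndarray:
        """Per-patient max scaled |dY/dt| (1/day)."""
        dY = self.rhs(t, Y, driver)
        return np.max(np.abs(dY) / (np.abs(Y) + state_atol()), axis=1)

    def steady_state_batch(self, Y0: np.ndarray, t_max: float = 500.0, dt: float = 0.25,
                           tol: float = 1e-6, chunk: float = 100.0):
        """Relax a batch toward dynamic steady state.

        Returns (Y, residuals, converged).  Integrates in chunks and
        stops early once every patient's scaled derivative norm is
        below ``tol``.
        """
        Y = np.array(Y0, dtype=float)
        t = 0.0
        while t < t_max:
            span = min(chunk, t_max - t)
            Y = self.integrate(Y, t, t + span, dt)
            t += span
            res = self.residual(t, Y)
            if np.all(res < tol):
                break
        res = self.residual(t, Y)
        return Y, res, res < tol
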