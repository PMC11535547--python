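"""Pharmacokinetics and pharmacodynamics of MTX, ADA and TCZ.

PK is linear compartmental kinetics evaluated in closed form
(superposition of exponentials over the dosing schedule):

* methotrexate  — two-compartment model with bolus dosing,
* adalimumab    — one-compartment model with first-order subcutaneous
  absorption,
* tocilizumab   — two-compartment model with intravenous dosing.

Drug in the synovium is a fixed partition fraction of the central
concentration (quasi-equilibrium).  PD maps concentration to
multiplicative factors on model rates:

* MTX: three Hill effects sharing the published (Vm, Km, slope) =
  (0.5, 1e-5 mg/L, 2) triple — suppression of pro-inflammatory
  cytokine secretion, enhancement of Treg anti-inflammatory secretion,
  suppression of immune-cell influx,
* ADA: equilibrium binding; the free (unbound) fraction of synovial
  TNF-a is the physical root of the binding quadratic,
* TCZ: the IL-6 clearance is divided by KD/(TCZ + KD), mimicking
  receptor blockade as an equivalent fold reduction of free IL-6.

Numeric PK parameter defaults are standard published population values
(external-literature defaults); no result in this package depends on a
specific parameter set — the tests use closed-form PK identities and
model-relative PD statements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tables import MTX_PD
from .regulation import hill

__all__ = [
    "PKModel",
    "MTXEffectParameters",
    "TherapyEffects",
    "TrialProtocol",
    "default_pk",
    "simulate_pk",
    "mtx_effects",
    "ada_free_tnf",
    "tcz_il6_clearance_scaling",
    "TherapyDriver",
]


@dataclass(frozen=True)
class PKModel:
    """Linear compartmental PK model.

    structure: "2c_bolus" | "1c_sc" | "2c_iv".  Volumes in L,
    clearances in L/day, rate constants in 1/day.  The synovial
    concentration is ``synovial_partition`` times the central one.
    """

    drug: str
    structure: str
    v1: float
    cl: float
    v2: float = 0.0
    q: float = 0.0
    ka: float = 0.0
    bioavailability: float = 1.0
    synovial_partition: float = 0.3

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.cl <= 0:
            raise ValueError("V1 and CL must be positive")
        if not 0 < self.bioavailability <= 1:
            raise ValueError("bioavailability must be in (0, 1]")
        if self.structure not in ("2c_bolus", "1c_sc", "2c_iv"):
            raise ValueError(f"unsupported PK structure {self.structure!r}")

    def _unit_impulse(self, t: np.ndarray) -> np.ndarray:
        """Central concentration after a unit dose at t=0 (0 for t<0)."""
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        pos = t >= 0
        tp = t[pos]
        if self.structure in ("2c_bolus", "2c_iv"):
            k10 = self.cl / self.v1
            k12 = self.q / self.v1
            k21 = self.q / self.v2 if self.v2 > 0 else 0.0
            s = k10 + k12 + k21
            disc = math.sqrt(max(s * s - 4 * k10 * k21, 0.0))
            alpha = (s + disc) / 2
            beta = (s - disc) / 2
            if alpha == beta:
                c[pos] = np.exp(-alpha * tp) / self.v1
            else:
                a = (alpha - k21) / (alpha - beta)
                b = (k21 - beta) / (alpha - beta)
                c[pos] = (a * np.exp(-alpha * tp) + b * np.exp(-beta * tp)) / self.v1
        else:  # 1c_sc
            k = self.cl / self.v1
            ka = self.ka
            if ka <= 0:
                raise ValueError("SC model needs a positive absorption rate")
            if abs(ka - k) < 1e-12:
                c[pos] = self.bioavailability * ka * tp * np.exp(-k * tp) / self.v1
            else:
                c[pos] = (
                    self.bioavailability
                    * ka
                    / (self.v1 * (ka - k))
                    * (np.exp(-k * tp) - np.exp(-ka * tp))
                )
        return c

    def central_concentration(self, times, dose_events) -> np.ndarray:
        """Central concentration (mg/L) by superposition over
        (time, amount_mg) dose events."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        c = np.zeros_like(t)
        for t_dose, amount in dose_events:
            c += amount * self._unit_impulse(t - t_dose)
        return c

    def synovial_concentration(self, times, dose_events) -> np.ndarray:
        return self.synovial_partition * self.central_concentration(times, dose_events)


#: External-literature default PK parameter sets.
_PK_DEFAULTS = {
    "MTX": dict(structure="2c_bolus", v1=20.0, v2=15.0, cl=120.0, q=30.0,
                bioavailability=0.7),
    "ADA": dict(structure="1c_sc", v1=5.5, cl=0.30, ka=0.28, bioavailability=0.64),
    "TCZ": dict(structure="2c_iv", v1=3.5, v2=2.9, cl=0.30, q=0.85),
}


def default_pk(drug: str, synovial_partition: float = 0.3) -> PKModel:
    if drug not in _PK_DEFAULTS:
        raise KeyError(f"no default PK model for drug {drug!r}")
    return PKModel(drug=drug, synovial_partition=synovial_partition, **_PK_DEFAULTS[drug])


@dataclass(frozen=True)
class MTXEffectParameters:
    """Shared Hill parameterization of the three MTX effect pathways."""

    vm: float = MTX_PD["vm"]
    km: float = MTX_PD["km"]
    slope: float = MTX_PD["slope"]

    def __post_init__(self) -> None:
        if not 0 < self.vm < 1:
            raise ValueError("inhibitory Vm must lie in (0, 1)")
        if self.km <= 0 or self.slope <= 0:
            raise ValueError("Km and slope must be positive")


@dataclass
class TherapyEffects:
    """Multiplicative drug effects applied inside the network RHS."""

    anti_cytsec_mtx: float = 0.0
    pro_cytsec_mtx: float = 0.0
    anti_cellinflux_mtx: float = 0.0
    ada_syn_ngml: float = 0.0
    ada_kd_ngml: float = float("inf")
    il6_clearance_divisor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("anti_cytsec_mtx", "pro_cytsec_mtx", "anti_cellinflux_mtx"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.il6_clearance_divisor <= 1:
            raise ValueError("IL-6 clearance divisor must lie in (0, 1]")


@dataclass
class TrialProtocol:
    """Drug, dosing schedule and readout of one simulated trial arm.

    ``dose`` is mg, or mg/kg when ``dose_per_kg`` is set (resolved
    with ``body_weight_kg``).  Defaults follow the calibration trials:
    MTX 15 mg weekly, ADA 40 mg every 2 weeks SC, TCZ 8 mg/kg every
    4 weeks IV.
    """

    drug: str
    dose: float
    route: str
    interval_days: float
    n_doses: int
    readout_week: float
    dose_per_kg: bool = False
    body_weight_kg: float = 70.0
    entry_criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_doses < 0 or self.dose < 0:
            raise ValueError("dose and n_doses must be non-negative")
        if self.n_doses > 0 and self.interval_days <= 0:
            raise ValueError("dose interval must be positive")
        if self.readout_week <= 0:
            raise ValueError("readout week must be positive")

    @property
    def dose_mg(self) -> float:
        return self.dose * self.body_weight_kg if self.dose_per_kg else self.dose

    @property
    def duration_days(self) -> float:
        return max(self.readout_week * 7.0, self.n_doses * self.interval_days)

    def dose_events(self) -> list[tuple[float, float]]:
        return [(i * self.interval_days, self.dose_mg) for i in range(self.n_doses)]


def default_protocol(drug: str, readout_week: float | None = None) -> TrialProtocol:
    """Calibration-trial protocols: MTX week 12, ADA week 24, TCZ week 24."""
    if drug == "MTX":
        wk = readout_week if readout_week is not None else 12.0
        return TrialProtocol("MTX", 15.0, "oral_bolus", 7.0, int(wk), wk)
    if drug == "ADA":
        wk = readout_week if readout_week is not None else 24.0
        return TrialProtocol("ADA", 40.0, "sc", 14.0, int(np.ceil(wk / 2)), wk)
    if drug == "TCZ":
        wk = readout_week if readout_week is not None else 24.0
        return TrialProtocol("TCZ", 8.0, "iv", 28.0, int(np.ceil(wk / 4)), wk,
                             dose_per_kg=True)
    raise KeyError(f"no default protocol for drug {drug!r}")


def simulate_pk(model: PKModel, protocol: TrialProtocol, times):
    """Central and synovial concentration series (mg/L)."""
    if protocol.drug != model.drug:
        raise ValueError(f"protocol drug {protocol.drug} does not match model {model.drug}")
    central = model.central_concentration(times, protocol.dose_events())
    return central, model.synovial_partition * central


def mtx_effects(central_conc_available, params: MTXEffectParameters | None = None) -> TherapyEffects:
    """MTX effect fragment from the available central concentration
    (central concentration times bioavailability, mg/L)."""
    p = params or MTXEffectParameters()
    e = hill(central_conc_available, p.vm, p.km, p.slope)
    return TherapyEffects(anti_cytsec_mtx=e, pro_cytsec_mtx=e, anti_cellinflux_mtx=e)


def ada_free_tnf(total_tnf, ada_syn, kd):
    """Free TNF-a under equilibrium binding A + T <=> AT.

    Solves the conservation quadratic for the free target and returns
    its physical (non-negative) root, which satisfies
    ``free + bound == total`` exactly.  All three arguments share one
    concentration unit.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    total = np.asarray(total_tnf, dtype=float)
    ada = np.asarray(ada_syn, dtype=float)
    if np.any(total < 0) or np.any(ada < 0):
        raise ValueError("concentrations must be non-negative")
    b = kd + ada - total
    free = 0.5 * (-b + np.sqrt(b * b + 4.0 * kd * total))
    free = np.minimum(np.maximum(free, 0.0), total)
    if np.ndim(total_tnf) == 0 and np.ndim(ada_syn) == 0:
        return float(free)
    return free


def tcz_il6_clearance_scaling(tcz_syn: float, kd_tcz: float) -> float:
    """IL-6 clearance divisor KD/(TCZ + KD) in (0, 1]; the effective
    IL-6 clearance is the baseline divided by this value."""
    if kd_tcz <= 0:
        raise ValueError("kd must be positive")
    if tcz_syn < 0:
        raise ValueError("concentration must be non-negative")
    return kd_tcz / (tcz_syn + kd_tcz)


@dataclass
class TherapyDriver:
    """Precomputed drug forcing for a trial simulation.

    Evaluates the closed-form PK at any time and returns the
    :class:`TherapyEffects` the network RHS applies.  Binding
    constants are package PD defaults unless overridden.
    """

    protocol: TrialProtocol
    pk: PKModel | None = None
    mtx_params: MTXEffectParameters | None = None
    kd_ada_ngml: float = 15.0
    kd_tcz_mgl: float = 0.4

    def __post_init__(self) -> None:
        if self.pk is None:
            self.pk = default_pk(self.protocol.drug)
        if self.mtx_params is None:
            self.mtx_params = MTXEffectParameters()
        self._events = self.protocol.dose_events()

    def effects(self, t: float) -> TherapyEffects:
        drug = self.protocol.drug
        central = float(self.pk.central_concentration(t, self._events)[0])
        syn = self.pk.synovial_partition * central
        if drug == "MTX":
            available = central * self.pk.bioavailability
            return mtx_effects(available, self.mtx_params)
        if drug == "ADA":
            return TherapyEffects(ada_syn_ngml=syn * 1000.0, ada_kd_ngml=self.kd_ada_ngml)
        if drug == "TCZ":
            return TherapyEffects(
                il6_clearance_divisor=tcz_il6_clearance_scaling(syn, self.kd_tcz_mgl)
            )
        raise KeyError(f"unsupported drug {drug!r}")
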