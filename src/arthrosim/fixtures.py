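"""Reference inputs generated from the published tables.

Everything the pipeline needs is constructed here from printed
constants — no downloads: the default network, a reference virtual
patient whose coupled steady state sits at the geometric midpoints of
the physiological ranges, the apoptosis-percentage-to-rate conversion
used to parameterize cell death, and synthetic cohorts with planted
ground truth for selector tests.

Reference-patient calibration.  The regulation factors are evaluated
once at the target state (every cell at its range midpoint, every
mediator likewise); baseline proliferation, influx, differentiation
and secretion rates are then back-solved so the target state is an
exact equilibrium of the fully coupled system.  Proliferation is
apportioned the dominant share (80%) of each cell's production, in
line with the observation that proliferative flux dominates influx in
established disease; FLS receive no influx at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PopulationTable
from .network import (
    CELL_DEATH_RATES,
    MEDIATOR_CLEARANCE,
    NetworkSpec,
    ProcessRef,
    SECRETION_SHARES,
    default_network,
)
from .patient import SynoviumState, VirtualPatient
from .regulation import CapPolicy, aggregate_effects, hill, rate_factor
from .scoring import acr_category
from .tables import (
    CELLS,
    MEDIATORS,
    REFERENCE_CELL_DENSITIES,
    REFERENCE_MEDIATOR_CONCS,
)

__all__ = [
    "ApoptosisDatum",
    "apoptosis_rate",
    "ReferencePatientRecipe",
    "build_reference_patient",
    "reference_state",
    "make_synthetic_selector_cohort",
]


@dataclass(frozen=True)
class ApoptosisDatum:
    """An in-vitro apoptosis observation: percent apoptotic cells
    after a given duration."""

    pct_apoptosis: float
    duration_days: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_apoptosis < 100:
            raise ValueError("percent apoptosis must lie in [0, 100)")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")


def apoptosis_rate(datum: ApoptosisDatum) -> float:
    """First-order death rate (1/day) from an apoptosis percentage.

    ln(100 / (100 - pct)) / duration; e.g. 15% apoptosis in 6 hours
    gives 0.65/day, and 50% in one day gives ln 2.
    """
    return math.log(100.0 / (100.0 - datum.pct_apoptosis)) / datum.duration_days


@dataclass
class ReferencePatientRecipe:
    """Targets and split fractions for reference-patient calibration."""

    target_cell_densities: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_CELL_DENSITIES)
    )
    target_mediator_concs: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_MEDIATOR_CONCS)
    )
    prolif_share: float = 0.8       # proliferation dominates production
    plasma_diff_share: float = 0.5  # share of plasma-cell supply from B-cell differentiation


def reference_state(recipe: ReferencePatientRecipe | None = None) -> SynoviumState:
    r = recipe or ReferencePatientRecipe()
    return SynoviumState(dict(r.target_cell_densities), dict(r.target_mediator_concs))


def _target_factors(spec: NetworkSpec, conc: dict[str, float], policy: CapPolicy):
    def fac(kind: str, cell: str, mediator: str | None = None) -> float:
        edges = spec.edges_for(ProcessRef(kind, cell, mediator))
        if not edges:
            return 1.0
        return rate_factor(aggregate_effects(edges, conc, policy))

    return fac


def build_reference_patient(recipe: ReferencePatientRecipe | None = None,
                            spec: NetworkSpec | None = None,
                            policy: CapPolicy | None = None) -> VirtualPatient:
    """Back-solve baseline rates so the midpoint state is an exact
    coupled equilibrium (see module docstring).  With all regulation
    edges removed the same baselines reproduce the decoupled
    closed-form steady states (production/loss) exactly."""
    r = recipe or ReferencePatientRecipe()
    spec = spec or default_network()
    policy = policy or CapPolicy()
    C, M = r.target_cell_densities, r.target_mediator_concs
    fac = _target_factors(spec, M, policy)

    deg = dict(CELL_DEATH_RATES)
    prolif: dict[str, float] = {}
    influx: dict[str, float] = {}

    # plasma cells: supplied by proliferation and B-cell differentiation
    pc_loss = deg["PlasmaCell"] * C["PlasmaCell"] * fac("apoptosis", "PlasmaCell")
    diff_flux = r.plasma_diff_share * pc_loss
    kdiff = diff_flux / (C["BCell"] * fac("differentiation", "BCell"))
    prolif["PlasmaCell"] = (pc_loss - diff_flux) / fac("proliferation", "PlasmaCell")
    influx["PlasmaCell"] = 0.0

    for cell in CELLS:
        if cell == "PlasmaCell":
            continue
        loss = deg[cell] * C[cell] * fac("apoptosis", cell)
        if cell == "BCell":
            loss += kdiff * C[cell] * fac("differentiation", "BCell")
        if cell == "FLS":
            prolif[cell] = loss / fac("proliferation", cell)
            influx[cell] = 0.0
        else:
            prolif[cell] = r.prolif_share * loss / fac("proliferation", cell)
            influx[cell] = (1.0 - r.prolif_share) * loss / fac("influx", cell)

    # secretion: apportion each mediator's clearance flux across its
    # secreting cells, undoing regulation factors and essential gates
    gates = {}
    for g in spec.essential_edges:
        key = (g.target.cell, g.target.mediator)
        gates[key] = gates.get(key, 1.0) * hill(M[g.mediator], 1.0, g.km_gate, g.slope)
    secretion: dict[tuple[str, str], float] = {}
    for med, shares in SECRETION_SHARES.items():
        flux = MEDIATOR_CLEARANCE[med] * M[med]
        for cell, w in shares.items():
            denom = C[cell] * fac("secretion", cell, med) * gates.get((cell, med), 1.0)
            secretion[(cell, med)] = w * flux / denom

    return VirtualPatient(
        id="reference",
        baseline_prolif=prolif,
        baseline_influx=influx,
        baseline_deg=deg,
        baseline_secretion=secretion,
        mediator_clearance=dict(MEDIATOR_CLEARANCE),
        kdiff=kdiff,
        edge_overrides={},
        scale_factors={},
    )


def make_synthetic_selector_cohort(n: int, phenotype_fractions: dict[str, float],
                                   seed: int, trial: str = "MTX") -> tuple[PopulationTable, dict]:
    """Cohort of parameterized phenotypes with known ground truth.

    Synthetic stand-in for a simulated cohort: each phenotype draws
    baseline DAS from its own normal distribution and responds to the
    named trial with its own probability (responders draw a deep
    percent reduction, non-responders a shallow one).  Used to verify
    that the Vpop selector recovers planted mixing fractions and
    response rates; no network simulation is involved.
    """
    if abs(sum(phenotype_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("phenotype fractions must sum to 1")
    profiles = {
        "responder": {"das_mu": 6.0, "das_sd": 1.0, "p_respond": 0.85},
        "nonresponder": {"das_mu": 6.3, "das_sd": 1.0, "p_respond": 0.08},
    }
    rng = np.random.default_rng(seed)
    names = list(phenotype_fractions)
    counts = rng.multinomial(n, [phenotype_fractions[k] for k in names])
    rows = []
    for name, cnt in zip(names, counts):
        prof = profiles.get(name, {"das_mu": 6.0, "das_sd": 1.0, "p_respond": 0.5})
        for _ in range(cnt):
            base = float(np.clip(rng.normal(prof["das_mu"], prof["das_sd"]), 3.3, 9.7))
            responds = rng.random() < prof["p_respond"]
            pct = float(np.clip(rng.normal(60, 12) if responds else rng.normal(8, 8), -20, 95))
            out = acr_category(base, base * (1 - pct / 100.0))
            rows.append({
                "phenotype": name, "das28_baseline": base,
                f"{trial}_post_das": out.das28_post, f"{trial}_pct": out.pct_reduction,
                f"{trial}_ACR20": out.acr20, f"{trial}_ACR50": out.acr50,
                f"{trial}_ACR70": out.acr70, f"{trial}_das_lt_2_6": out.das_lt_2_6,
                f"{trial}_das_lt_3_2": out.das_lt_3_2,
                f"{trial}_IR": out.pct_reduction < 50 and out.das28_post > 3.2,
            })
    rng.shuffle(rows)
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"syn{i:06d}" for i in range(len(df))])
    df["plausible"] = True
    df["selected"] = False
    df["weight"] = 1.0
    truth = {
        "fractions": dict(phenotype_fractions),
        "p_respond": {k: profiles.get(k, {}).get("p_respond", 0.5) for k in names},
    }
    return PopulationTable(df), truth
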