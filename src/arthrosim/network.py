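"""Declarative wiring of the synovial cell/cytokine network.

The model tracks 9 cell types and 17 mediators in a well-mixed 1 mL
synovium.  Cells proliferate (zeroth order), flow in from the central
compartment (zeroth order; FLS do not migrate) and die (first order);
mediators are secreted by cells and cleared first order.  Every one of
these rates can be modulated by mediators through capped sums of Hill
terms (see :mod:`arthrosim.regulation`).

The default network is reconstructed from the published
virtual-population parameter list, whose entries encode the regulatory
edges verbatim (``FLSProlif_MaxbyTNFa`` is "TNF-a increases FLS
proliferation, with this maximal fold effect", and so on).  Two pieces
of wiring are not printed and are curated here from the cytokine
literature: the *sign* of each edge (whether the regulator promotes or
suppresses the process) and the secretion topology (which cell types
secrete which mediators, and their relative contributions in the
reference patient).  Both are data in this module and can be overridden
through the JSON network specification.

CAM (the lumped cell-adhesion-molecule factor) is algebraic rather
than dynamic: its level is a saturating Hill function of endothelial
density, scaled by the per-patient factor F_CAM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import tables
from .tables import (
    CELLS,
    MEDIATORS,
    ODE_MEDIATORS,
    PARAMETER_BOUNDS,
    REFERENCE_CELL_DENSITIES,
    REFERENCE_MEDIATOR_CONCS,
    geometric_midpoint,
)

PROCESSES = ("proliferation", "influx", "apoptosis", "secretion", "differentiation")


@dataclass(frozen=True)
class ProcessRef:
    """Target of a regulatory edge: a life-cycle process of one cell,
    one (cell, mediator) secretion term, or the B-cell differentiation
    flux."""

    kind: str
    cell: str
    mediator: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROCESSES:
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.kind == "secretion" and self.mediator is None:
            raise ValueError("secretion process needs a mediator")

    def key(self) -> tuple:
        return (self.kind, self.cell, self.mediator)


@dataclass(frozen=True)
class RegulatoryEdge:
    """One mediator -> process Hill edge.

    ``param`` is the published parameter name controlling the maximal
    fold effect; several edges may share one ``param`` (e.g.
    ``TCellProlif_MaxbyIL6`` expands to Th1, Th17 and CTL), in which
    case a single sampled value drives them all.  ``name`` is unique.
    """

    name: str
    param: str
    regulator: str
    target: ProcessRef
    sign: str  # "pro" | "anti"
    vm_effect: float
    km_effect: float
    slope_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in ("pro", "anti"):
            raise ValueError(f"edge sign must be 'pro' or 'anti', got {self.sign!r}")
        if self.vm_effect <= 0 or self.km_effect <= 0 or self.slope_effect <= 0:
            raise ValueError(f"edge {self.name}: Hill parameters must be positive")


# --- curated wiring data -------------------------------------------------

# Cell-name shorthands used inside the published parameter names.
_CELL_ALIASES = {
    "FLS": ("FLS",),
    "Endo": ("Endothelial",),
    "Macro": ("Macrophage",),
    "Th1": ("Th1",),
    "Th17": ("Th17",),
    "Treg": ("Treg",),
    "CTL": ("CTL",),
    "BCell": ("BCell",),
    "Plasma": ("PlasmaCell",),
    "PlasmaCell": ("PlasmaCell",),
    # Collective names: TCell covers the effector T cells; Lympho adds
    # Tregs and B cells; Leuko covers every immune cell with an influx
    # term (endothelium is recruited by its own named edges).
    "TCell": ("Th1", "Th17", "CTL"),
    "Lympho": ("Th1", "Th17", "CTL", "Treg", "BCell"),
    "Leuko": ("Macrophage", "Th1", "Th17", "CTL", "Treg", "BCell"),
}

_MEDIATOR_ALIASES = {m: m for m in MEDIATORS}
_MEDIATOR_ALIASES["MIP3"] = "MIP3a"

# Edges whose regulator *suppresses* the named process.  Everything
# else in the published parameter list is a pro edge.  Apoptosis edges
# listed here are survival signals (they reduce the death rate); the
# two unlisted apoptosis edges (EndoApop_MaxbyTNFa, CTLApop_MaxbyTGFb)
# are death signals.  Rationale per edge in docs/methods.md.
_ANTI_EDGES = {
    "Th1Prolif_MaxbyTGFb",
    "TCellProlif_MaxbyIL10",
    "BCellProlif_MaxbyTGFb",
    "CTLProlif_MaxbyTGFb",
    "TregProlif_MaxbyIL6",
    "IFNgSecTh1_MaxbyIL10",
    "IL1bSecFLS_MaxbyIL10",
    "TNFaSecFLS_MaxbyIL10",
    "TNFaSecMacro_MaxbyIL10",
    "IL6SecMacro_MaxbyIL10",
    "IFNgSecCTL_MaxbyTGFb",
    # survival (anti-apoptosis) signals
    "EndoApop_MaxbyVEGF",
    "BCellApop_MaxbyBAFF",
    "Th1Apop_MaxbyIL12",
    "TCellApop_MaxbyIL6",
    "MacroApop_MaxbyTNFa",
    "MacroApop_MaxbyIFNg",
    "MacroApop_MaxbyGMCSF",
    "PlasmaCellApop_MaxbyIL6",
}

#: Secretion topology: mediator -> {cell: reference share of the total
#: secretion flux}.  Shares are used only to apportion the reference
#: patient's baseline secretion rates; macrophages dominate TNF-a,
#: Th1 dominates IFN-g, etc.  CAM is algebraic and has no entry.
SECRETION_SHARES: dict[str, dict[str, float]] = {
    "TNFa": {"Macrophage": 0.60, "FLS": 0.15, "Th1": 0.15, "CTL": 0.05, "BCell": 0.05},
    "IL6": {"FLS": 0.60, "Macrophage": 0.40},
    "IL17": {"Th17": 0.80, "CTL": 0.20},
    "IL12": {"Macrophage": 1.00},
    "IL23": {"Macrophage": 1.00},
    "IL1b": {"Macrophage": 0.70, "FLS": 0.30},
    "IFNg": {"Th1": 0.60, "CTL": 0.30, "Macrophage": 0.10},
    "GMCSF": {"Macrophage": 0.50, "FLS": 0.50},
    "BAFF": {"Macrophage": 0.70, "FLS": 0.30},
    "IL10": {"Treg": 0.60, "Macrophage": 0.40},
    "TGFb": {"Treg": 0.50, "Macrophage": 0.50},
    "RANTES": {"FLS": 0.70, "Endothelial": 0.30},
    "MIP3a": {"FLS": 1.00},
    "MCP1": {"FLS": 0.50, "Macrophage": 0.50},
    "VEGF": {"FLS": 0.60, "Endothelial": 0.40},
    "AutoAb": {"PlasmaCell": 0.80, "BCell": 0.20},
}

#: Baseline first-order death rates (1/day).  The Th1 value is the
#: published activation-induced-cell-death conversion (15% apoptosis
#: in 6 h -> 0.65/day); the rest sit inside the "few hours to a few
#: days" half-life window, slower for structural and long-lived cells.
CELL_DEATH_RATES: dict[str, float] = {
    "FLS": 0.05,
    "Endothelial": 0.069,
    "Macrophage": 0.23,
    "Th1": 0.65,
    "Th17": 0.65,
    "Treg": 0.46,
    "CTL": 0.65,
    "BCell": 0.35,
    "PlasmaCell": 0.14,
}

#: First-order mediator clearance rates (1/day); cytokine half-lives
#: of minutes to hours, days for IgG-class autoantibody.
MEDIATOR_CLEARANCE: dict[str, float] = {
    "TNFa": 24.0,
    "IL6": 22.0,
    "IL17": 16.6,
    "IL12": 11.0,
    "IL23": 11.0,
    "IL1b": 24.0,
    "IFNg": 22.0,
    "GMCSF": 16.6,
    "BAFF": 5.5,
    "IL10": 22.0,
    "TGFb": 11.0,
    "RANTES": 16.6,
    "MIP3a": 16.6,
    "MCP1": 16.6,
    "VEGF": 11.0,
    "AutoAb": 0.35,
}

#: MTX anti-influx applies to immune cells only.
IMMUNE_INFLUX_CELLS = ("Macrophage", "Th1", "Th17", "Treg", "CTL", "BCell")

#: Default Hill slope of regulatory edges.  A moderately cooperative
#: slope separates responder from non-responder phenotypes when drug
#: therapy lowers a regulator by one to two orders of magnitude, and
#: matches the cooperativity of the published drug-effect Hill triple.
DEFAULT_EDGE_SLOPE = 2.0

#: Half-max placement of regulatory edges, as a multiple of each
#: mediator's reference (range-midpoint) concentration.  The
#: multiplier centers each Hill curve on the median concentration the
#: plausible virtual cohort actually reaches under the default wiring
#: (cell-range-constrained steady states sit well away from the naive
#: range midpoints for mediators secreted by cells with wide density
#: ranges, e.g. IL-17), so every regulator stays in its responsive
#: region across the cohort.
KM_PLACEMENT: dict[str, float] = {
    "TNFa": 7.8,
    "IL6": 1.1,
    "IL17": 290.0,
    "IL12": 0.29,
    "IL23": 0.23,
    "IL1b": 3.8,
    "IFNg": 44.0,
    "GMCSF": 2.1,
    "BAFF": 0.49,
    "IL10": 1.5,
    "TGFb": 0.93,
    "RANTES": 4.0,
    "MIP3a": 6.1,
    "MCP1": 1.0,
    "VEGF": 0.5,
    "AutoAb": 7.5,
    "CAM": 1.0,
}


def _expand_param(param: str) -> list[tuple[str, str, ProcessRef]]:
    """Expand one published ``..._Maxby...`` parameter name into
    (edge name, regulator, target) triples."""
    head, _, reg_short = param.rpartition("_Maxby")
    regulator = _MEDIATOR_ALIASES[reg_short]
    # strip nested "_by<Mediator>" qualifiers: a modifier of a secretion
    # edge is treated as an additional regulator of the same secretion
    # term (e.g. RANTESSecFLS_byTNFa_MaxbyIFNg -> IFNg on RANTES|FLS).
    if "_by" in head:
        head = head.split("_by")[0]
    out: list[tuple[str, str, ProcessRef]] = []
    for proc, kind in (("Prolif", "proliferation"), ("Influx", "influx"),
                       ("influx", "influx"), ("Apop", "apoptosis"), ("Diff", "differentiation")):
        if head.endswith(proc):
            cell_short = head[: -len(proc)]
            for cell in _CELL_ALIASES[cell_short]:
                out.append((f"{param}@{cell}", regulator, ProcessRef(kind, cell)))
            return out
    if "Sec" in head:
        med_short, _, cell_short = head.partition("Sec")
        mediator = _MEDIATOR_ALIASES[med_short]
        for cell in _CELL_ALIASES[cell_short]:
            out.append((f"{param}@{cell}", regulator, ProcessRef("secretion", cell, mediator)))
        return out
    raise ValueError(f"cannot parse regulation parameter name {param!r}")


@dataclass
class EssentialEdge:
    """An essential-mediator gate: the process rate is multiplied by a
    Hill term in the mediator and vanishes when the mediator does."""

    mediator: str
    target: ProcessRef
    km_gate: float
    slope: float = 1.0


@dataclass
class CamFunction:
    """Algebraic CAM level: cam_max * Hill(endothelial density)."""

    cam_max: float
    km: float
    slope: float = 1.0

    def __call__(self, endo_density):
        from .regulation import hill

        return hill(endo_density, self.cam_max, self.km, self.slope)


@dataclass
class NetworkSpec:
    """Full declarative wiring of the synovium network."""

    cells: tuple[str, ...] = CELLS
    mediators: tuple[str, ...] = MEDIATORS
    secretion_edges: list[tuple[str, str]] = field(default_factory=list)
    regulation_edges: list[RegulatoryEdge] = field(default_factory=list)
    differentiation_edges: list[tuple[str, str]] = field(default_factory=list)
    essential_edges: list[EssentialEdge] = field(default_factory=list)
    cam: CamFunction | None = None

    def validate(self) -> None:
        cells, meds = set(self.cells), set(self.mediators)
        sec = set(self.secretion_edges)
        for cell, med in self.secretion_edges:
            if cell not in cells or med not in meds:
                raise ValueError(f"secretion edge ({cell}, {med}) references unknown species")
        for e in self.regulation_edges:
            if e.regulator not in meds:
                raise ValueError(f"edge {e.name}: unknown regulator {e.regulator}")
            t = e.target
            if t.cell not in cells:
                raise ValueError(f"edge {e.name}: unknown target cell {t.cell}")
            if t.kind == "secretion" and (t.cell, t.mediator) not in sec:
                raise ValueError(
                    f"edge {e.name}: targets undeclared secretion edge ({t.cell}, {t.mediator})"
                )
        for src, dst in self.differentiation_edges:
            if src not in cells or dst not in cells:
                raise ValueError(f"differentiation edge ({src}, {dst}) references unknown cell")

    def edges_for(self, target: ProcessRef) -> list[RegulatoryEdge]:
        return [e for e in self.regulation_edges if e.target.key() == target.key()]

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cells": list(self.cells),
            "mediators": list(self.mediators),
            "secretion_edges": [list(x) for x in self.secretion_edges],
            "regulation_edges": [
                {**asdict(e), "target": {"kind": e.target.kind, "cell": e.target.cell,
                                          "mediator": e.target.mediator}}
                for e in self.regulation_edges
            ],
            "differentiation_edges": [list(x) for x in self.differentiation_edges],
            "essential_edges": [
                {"mediator": g.mediator,
                 "target": {"kind": g.target.kind, "cell": g.target.cell,
                            "mediator": g.target.mediator},
                 "km_gate": g.km_gate, "slope": g.slope}
                for g in self.essential_edges
            ],
            "cam": {"cam_max": self.cam.cam_max, "km": self.cam.km, "slope": self.cam.slope}
            if self.cam
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        def _pr(t: dict) -> ProcessRef:
            return ProcessRef(t["kind"], t["cell"], t.get("mediator"))

        spec = cls(
            cells=tuple(d["cells"]),
            mediators=tuple(d["mediators"]),
            secretion_edges=[tuple(x) for x in d["secretion_edges"]],
            regulation_edges=[
                RegulatoryEdge(
                    name=e["name"], param=e["param"], regulator=e["regulator"],
                    target=_pr(e["target"]), sign=e["sign"], vm_effect=e["vm_effect"],
                    km_effect=e["km_effect"], slope_effect=e["slope_effect"],
                )
                for e in d["regulation_edges"]
            ],
            differentiation_edges=[tuple(x) for x in d["differentiation_edges"]],
            essential_edges=[
                EssentialEdge(g["mediator"], _pr(g["target"]), g["km_gate"], g["slope"])
                for g in d["essential_edges"]
            ],
            cam=CamFunction(**d["cam"]) if d.get("cam") else None,
        )
        spec.validate()
        return spec

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_network() -> NetworkSpec:
    """Build the default network from the published parameter list.

    Edge defaults: the maximal fold effect is the geometric midpoint
    of the parameter's published sampling range; the half-max
    concentration is the regulator's reference concentration times its
    ``KM_PLACEMENT`` multiplier (the median level plausible cohorts
    reach), keeping each Hill curve responsive across the cohort; the
    Hill slope is ``DEFAULT_EDGE_SLOPE``.
    """
    reg_edges: list[RegulatoryEdge] = []
    for param, (lb, ub) in PARAMETER_BOUNDS.items():
        if "_Maxby" not in param:
            continue
        vm = geometric_midpoint(lb, ub)
        for name, regulator, target in _expand_param(param):
            reg_edges.append(
                RegulatoryEdge(
                    name=name,
                    param=param,
                    regulator=regulator,
                    target=target,
                    sign="anti" if param in _ANTI_EDGES else "pro",
                    vm_effect=vm,
                    km_effect=REFERENCE_MEDIATOR_CONCS[regulator] * KM_PLACEMENT[regulator],
                    slope_effect=DEFAULT_EDGE_SLOPE,
                )
            )

    secretion_edges = sorted(
        (cell, med) for med, shares in SECRETION_SHARES.items() for cell in shares
    )

    endo_mid = REFERENCE_CELL_DENSITIES["Endothelial"]
    cam_mid = REFERENCE_MEDIATOR_CONCS["CAM"]
    spec = NetworkSpec(
        secretion_edges=secretion_edges,
        regulation_edges=reg_edges,
        differentiation_edges=[("BCell", "PlasmaCell")],
        essential_edges=[
            EssentialEdge(
                mediator="IL12",
                target=ProcessRef("secretion", "Th1", "IFNg"),
                km_gate=REFERENCE_MEDIATOR_CONCS["IL12"],
            )
        ],
        # cam_max chosen so CAM sits at its reference midpoint when the
        # endothelium does (Hill = 1/2 at Km).
        cam=CamFunction(cam_max=2.0 * cam_mid, km=endo_mid),
    )
    spec.validate()
    return spec
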