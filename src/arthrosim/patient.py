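"""Virtual patients and synovium state containers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tables import CELLS, MEDIATORS, ODE_MEDIATORS, PARAMETER_BOUNDS


@dataclass
class SynoviumState:
    """Densities (cells/mL) of the 9 cell types and concentrations
    (ng/mL) of the 17 mediators at one time point, in a fixed 1 mL
    synovial volume."""

    cell_density: dict[str, float]
    mediator_conc: dict[str, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        for name, v in {**self.cell_density, **self.mediator_conc}.items():
            if v < 0:
                raise ValueError(f"negative state entry {name} = {v}")

    def vector(self) -> np.ndarray:
        """Flat ODE state: cells then dynamic mediators (CAM excluded)."""
        return np.array(
            [self.cell_density[c] for c in CELLS]
            + [self.mediator_conc[m] for m in ODE_MEDIATORS],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, cam: float, time: float = 0.0) -> "SynoviumState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        cells = dict(zip(CELLS, y[: len(CELLS)]))
        meds = dict(zip(ODE_MEDIATORS, y[len(CELLS):]))
        meds["CAM"] = cam
        return cls(cells, {m: meds[m] for m in MEDIATORS}, time)


@dataclass
class SteadyStateResult:
    state: SynoviumState
    converged: bool
    residual_norm: float


@dataclass
class VirtualPatient:
    """One parameter vector defining one simulated subject.

    All rates are per day; baseline proliferation and influx are
    zeroth-order (cells/mL/day), death and clearance first-order
    (1/day), secretion per-cell (ng/cell/day).  ``edge_overrides`` maps
    published ``*_Maxby*`` parameter names to maximal fold effects;
    ``scale_factors`` holds the F_* global secretion multipliers.
    """

    id: str
    baseline_prolif: dict[str, float]
    baseline_influx: dict[str, float]
    baseline_deg: dict[str, float]
    baseline_secretion: dict[tuple[str, str], float]
    mediator_clearance: dict[str, float]
    kdiff: float = 0.0
    edge_overrides: dict[str, float] = field(default_factory=dict)
    scale_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_influx.get("FLS", 0.0) != 0.0:
            raise ValueError("FLS do not migrate: FLS influx must be 0")
        for d in (self.baseline_prolif, self.baseline_influx, self.baseline_deg,
                  self.mediator_clearance, self.edge_overrides, self.scale_factors):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative parameter {k} = {v}")
        for (c, m), v in self.baseline_secretion.items():
            if v < 0:
                raise ValueError(f"negative secretion rate ({c}, {m}) = {v}")
            if c not in CELLS or m not in MEDIATORS:
                raise ValueError(f"unknown species in secretion rate ({c}, {m})")
        for c in list(self.baseline_prolif) + list(self.baseline_influx) + list(self.baseline_deg):
            if c not in CELLS:
                raise ValueError(f"unknown cell {c!r} in patient parameters")

    def with_table_values(self, values: dict[str, float], new_id: str | None = None) -> "VirtualPatient":
        """Return a copy with published-table parameter values applied.

        Accepts any subset of the 129 varied parameter names
        (kg_*/kIn_* baselines, kdiff, F_* factors, *_Maxby* effects).
        """
        p = self.copy(new_id or self.id)
        alias = {"BCells": "BCell", "Endo": "Endothelial"}
        for name, v in values.items():
            if name not in PARAMETER_BOUNDS:
                raise KeyError(f"unknown varied parameter {name!r}")
            if name.startswith("kg_"):
                cell = name[3:].removesuffix("_Baseline")
                p.baseline_prolif[alias.get(cell, cell)] = v
            elif name.startswith("kIn_"):
                cell = name[4:].removesuffix("_Baseline")
                p.baseline_influx[alias.get(cell, cell)] = v
            elif name == "kdiff_BCells_PlasmaCells":
                p.kdiff = v
            elif name.startswith("F_"):
                p.scale_factors[name] = v
            else:
                p.edge_overrides[name] = v
        return p

    def copy(self, new_id: str | None = None) -> "VirtualPatient":
        return VirtualPatient(
            id=new_id or self.id,
            baseline_prolif=dict(self.baseline_prolif),
            baseline_influx=dict(self.baseline_influx),
            baseline_deg=dict(self.baseline_deg),
            baseline_secretion=dict(self.baseline_secretion),
            mediator_clearance=dict(self.mediator_clearance),
            kdiff=self.kdiff,
            edge_overrides=dict(self.edge_overrides),
            scale_factors=dict(self.scale_factors),
        )

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "baseline_prolif": self.baseline_prolif,
            "baseline_influx": self.baseline_influx,
            "baseline_deg": self.baseline_deg,
            "baseline_secretion": {f"{c}|{m}": v for (c, m), v in self.baseline_secretion.items()},
            "mediator_clearance": self.mediator_clearance,
            "kdiff": self.kdiff,
            "edge_overrides": self.edge_overrides,
            "scale_factors": self.scale_factors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualPatient":
        sec = {tuple(k.split("|")): v for k, v in d["baseline_secretion"].items()}
        return cls(
            id=d["id"],
            baseline_prolif=dict(d["baseline_prolif"]),
            baseline_influx=dict(d["baseline_influx"]),
            baseline_deg=dict(d["baseline_deg"]),
            baseline_secretion=sec,
            mediator_clearance=dict(d["mediator_clearance"]),
            kdiff=d["kdiff"],
            edge_overrides=dict(d["edge_overrides"]),
            scale_factors=dict(d["scale_factors"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "VirtualPatient":
        return cls.from_dict(json.loads(Path(path).read_text()))
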