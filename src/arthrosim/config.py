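"""Run configuration: schema-validated loading and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .tables import PARAMETER_BOUNDS


class SolverSettings(BaseModel):
    rtol: float = 1e-8
    steady_tol: float = 1e-6
    t_max: float = 500.0
    batch_dt: float = 0.25


class CohortSettings(BaseModel):
    n_candidates: int = 5000
    n_select: int = 300
    seed: int = 0


class BoundsConfig(BaseModel):
    """Parameter-variation bounds; defaults to the published table."""

    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {k: tuple(v) for k, v in PARAMETER_BOUNDS.items()}
    )

    @field_validator("bounds")
    @classmethod
    def _check(cls, v):
        for name, (lo, hi) in v.items():
            if name not in PARAMETER_BOUNDS:
                import difflib

                near = difflib.get_close_matches(name, PARAMETER_BOUNDS, n=3)
                raise ValueError(f"unknown parameter {name!r}; nearest matches: {near}")
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 < lower < upper")
        return v


class RunConfig(BaseModel):
    """Top-level run configuration."""

    network_spec: str | None = None   # path to NetworkSpec JSON; None = default network
    patient: str | None = None        # path to VirtualPatient JSON; None = reference
    bounds: BoundsConfig = Field(default_factory=BoundsConfig)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    pro_limit: float = 10.0
    anti_limit: float = 0.75
    output_dir: str = "arthrosim_out"

    def resolve_paths(self, base: Path) -> None:
        for attr in ("network_spec", "patient"):
            p = getattr(self, attr)
            if p is not None:
                full = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
                if not full.exists():
                    raise FileNotFoundError(f"{attr} file {full} does not exist")
                setattr(self, attr, str(full))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    cfg = RunConfig.model_validate(data or {})
    cfg.resolve_paths(path.parent)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]


def write_manifest(path: str | Path, cfg: RunConfig | None, seed: int | None, **extra) -> None:
    from . import __version__

    manifest = {"arthrosim_version": __version__, "seed": seed,
                "config_hash": config_hash(cfg) if cfg else None, **extra}
    Path(path).write_text(json.dumps(manifest, indent=1))
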