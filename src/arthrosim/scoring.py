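"""Clinical score layer: DAS28-CRP from synovial state, ACR
categories as percent change from baseline, responder classification.

The modeled DAS28-CRP is a weighted sum of saturating (Hill)
transforms of the synovial cell densities; the positive weights sum to
10 so the score spans (0, 10) for pro-inflammatory expansion, and the
regulatory Treg pool enters with a negative weight.  ACR20/50/70 are
derived as >= 20/50/70 percent reduction of the modeled DAS28-CRP from
baseline.  Remission and low-disease-activity cutoffs are the standard
2.6 and 3.2; "response" additionally asks for a drop of more than 1.2
points.  An inadequate responder (IR) fails both: reduction below 50%
and a post-therapy score above 3.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patient import SynoviumState
from .tables import (
    CELL_RANGES,
    CELLS,
    DAS28_COEFFICIENTS,
    DAS28_GAMMA,
    DAS28_KM,
    geometric_midpoint,
)

__all__ = ["ScoreParameters", "ClinicalOutcome", "das28", "das28_from_densities",
           "acr_category", "classify_ir"]


def _default_km() -> dict[str, float]:
    km = dict(DAS28_KM)
    # CTL half-max is not published; default to the geometric mean of
    # its physiological density range.
    km["CTL"] = geometric_midpoint(*CELL_RANGES["CTL"])
    return km


@dataclass
class ScoreParameters:
    """Per-cell weights, half-max densities and Hill exponents.

    ``treg_hill`` selects whether the (negatively weighted) Treg term
    passes through the same Hill transform as the other cells (the
    default, keeping the score bounded) or enters as a raw density.
    """

    coefficients: dict[str, float] = field(default_factory=lambda: dict(DAS28_COEFFICIENTS))
    km: dict[str, float] = field(default_factory=_default_km)
    gamma: dict[str, float] = field(default_factory=lambda: {c: DAS28_GAMMA for c in CELLS})
    treg_hill: bool = True

    def __post_init__(self) -> None:
        for c, v in self.km.items():
            if v <= 0:
                raise ValueError(f"Km for {c} must be positive")
        for c, g in self.gamma.items():
            if g <= 0:
                raise ValueError(f"gamma for {c} must be positive")

    @property
    def positive_sum(self) -> float:
        return sum(v for v in self.coefficients.values() if v > 0)


def das28_from_densities(cell_density: dict, params: ScoreParameters | None = None):
    """DAS28-CRP from a mapping cell -> density (scalars or arrays)."""
    p = params or ScoreParameters()
    score = 0.0
    for cell, w in p.coefficients.items():
        if cell not in cell_density:
            raise KeyError(f"cell {cell!r} missing from the state")
        x = np.asarray(cell_density[cell], dtype=float)
        if np.any(x < 0):
            raise ValueError(f"negative density for {cell}")
        if w < 0 and not p.treg_hill:
            term = x
        else:
            g = p.gamma[cell]
            xg = np.power(x, g)
            term = xg / (xg + p.km[cell] ** g)
        score = score + w * term
    return float(score) if np.ndim(score) == 0 else score


def das28(state: SynoviumState, params: ScoreParameters | None = None) -> float:
    """Modeled DAS28-CRP of one synovium state."""
    return float(das28_from_densities(state.cell_density, params))


@dataclass
class ClinicalOutcome:
    """Baseline/post scores and the derived response categories."""

    das28_baseline: float
    das28_post: float
    delta_das: float
    pct_reduction: float
    acr_category: int  # 0 | 20 | 50 | 70
    das_lt_3_2: bool
    das_lt_2_6: bool
    delta_gt_1_2: bool

    @property
    def acr20(self) -> bool:
        return self.acr_category >= 20

    @property
    def acr50(self) -> bool:
        return self.acr_category >= 50

    @property
    def acr70(self) -> bool:
        return self.acr_category >= 70


def acr_category(baseline_score: float, post_score: float) -> ClinicalOutcome:
    """Derive the ACR category and DAS flags for one patient.

    ACR is the percent reduction of the modeled DAS28-CRP from
    baseline; the 20/50/70 thresholds define the nested categories.
    """
    if baseline_score <= 0:
        raise ValueError("baseline score must be positive")
    delta = baseline_score - post_score
    pct = 100.0 * delta / baseline_score
    cat = 70 if pct >= 70 else 50 if pct >= 50 else 20 if pct >= 20 else 0
    return ClinicalOutcome(
        das28_baseline=baseline_score,
        das28_post=post_score,
        delta_das=delta,
        pct_reduction=pct,
        acr_category=cat,
        das_lt_3_2=post_score < 3.2,
        das_lt_2_6=post_score < 2.6,
        delta_gt_1_2=delta > 1.2,
    )


def classify_ir(outcome: ClinicalOutcome) -> bool:
    """Inadequate responder: reduction < 50% AND post score > 3.2."""
    return outcome.pct_reduction < 50.0 and outcome.das28_post > 3.2
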