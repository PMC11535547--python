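"""Published constants of the RA synovium model.

Everything in this module is a printed literature value: the
virtual-population parameter bounds (name -> (lower, upper)), the
physiological plausibility ranges for synovial cell densities
(cells/mL) and mediator concentrations (ng/mL), the DAS28-CRP score
parameterization, and the clinical-trial summary statistics used as
calibration targets.  Units follow the package convention of days,
cells/mL and ng/mL; drug concentrations are mg/L.
"""

from __future__ import annotations

import math

CELLS = (
    "FLS",
    "Endothelial",
    "Macrophage",
    "Th1",
    "Th17",
    "Treg",
    "CTL",
    "BCell",
    "PlasmaCell",
)

#: CAM is an algebraic mediator (a saturating function of endothelial
#: density); the other 16 mediators carry their own ODE.
MEDIATORS = (
    "TNFa",
    "IL6",
    "IL17",
    "IL12",
    "IL23",
    "IL1b",
    "IFNg",
    "GMCSF",
    "BAFF",
    "IL10",
    "TGFb",
    "RANTES",
    "MIP3a",
    "MCP1",
    "VEGF",
    "CAM",
    "AutoAb",
)

ODE_MEDIATORS = tuple(m for m in MEDIATORS if m != "CAM")

#: Parameter bounds varied for the virtual population: 129 rows,
#: name -> (lower bound, upper bound).  Baseline proliferation (kg_*)
#: and influx (kIn_*) rates are cells/mL/day; kdiff is 1/day; F_* are
#: dimensionless secretion scale factors; *_Maxby* entries are the
#: dimensionless maximal fold effects (VmEffect) of regulatory edges.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "kg_BCells_Baseline": (9.55e2, 6.61e7),
    "kg_CTL_Baseline": (1.26e3, 3.16e7),
    "kg_Endo_Baseline": (4.62e5, 2.07e7),
    "kg_FLS_Baseline": (1.55e4, 4.28e6),
    "kg_Macrophage_Baseline": (4.51e3, 7.35e6),
    "kdiff_BCells_PlasmaCells": (3.80e-6, 2.63e-1),
    "kg_Th1_Baseline": (1.32e2, 1.91e8),
    "kg_Th17_Baseline": (3.09e-2, 2.04e5),
    "kg_Treg_Baseline": (1.38e3, 7.24e8),
    "F_AutoAb": (8.59e-2, 3.85e2),
    "F_BAFF": (2.17e-2, 8.79e1),
    "F_CAM": (1.39e-2, 4.15e1),
    "F_VEGF": (2.19e-2, 6.90e1),
    "F_TNFa": (2.17e-2, 8.38e1),
    "F_TGFb": (1.75e-2, 5.22e1),
    "F_RANTES": (1.39e-2, 4.15e1),
    "F_MIP3": (3.45e-2, 1.26e2),
    "F_MCP1": (1.10e-2, 3.30e1),
    "F_IL6": (2.20e-2, 6.58e1),
    "F_IL23": (1.73e-2, 6.04e1),
    "F_IL1b": (1.36e-2, 6.41e1),
    "F_IL17": (4.33e-2, 1.75e2),
    "F_IL12": (1.73e-2, 6.34e1),
    "F_IL10": (1.37e-2, 5.28e1),
    "F_IFNg": (5.47e-2, 2.00e2),
    "F_GMCSF": (1.74e-2, 5.48e1),
    "kIn_Treg_Baseline": (9.77e2, 4.07e7),
    "kIn_Th1_Baseline": (1.55e3, 6.46e7),
    "kIn_Macrophage_Baseline": (6.17e1, 2.57e6),
    "kIn_CTL_Baseline": (6.17e1, 2.57e6),
    "kIn_BCells_Baseline": (9.55e1, 6.61e6),
    "kIn_Th17_Baseline": (1.55e2, 6.46e6),
    "kIn_Endo_Baseline": (2.45e2, 1.02e7),
    "Endoinflux_MaxbyVEGF": (1.30e-1, 9.66e0),
    "EndoProlif_MaxbyVEGF": (3.30e-1, 2.10e1),
    "Endoinflux_MaxbyTNFa": (3.15e-1, 2.00e1),
    "EndoApop_MaxbyTNFa": (1.96e-1, 1.02e1),
    "EndoApop_MaxbyVEGF": (8.77e-2, 4.34e0),
    "FLSProlif_MaxbyTNFa": (1.95e-1, 1.07e1),
    "Endoinflux_MaxbyIL6": (1.96e-1, 1.02e1),
    "IL6SecFLS_MaxbyIL1b": (1.43e-1, 6.38e0),
    "MacroInflux_MaxbyIL17": (1.96e-1, 1.02e1),
    "FLSProlif_MaxbyIL1b": (1.95e-1, 1.07e1),
    "FLSProlif_MaxbyIL17": (1.66e-1, 9.55e0),
    "FLSProlif_MaxbyTGFb": (1.88e-1, 1.40e1),
    "EndoProlif_MaxbyIL1b": (2.82e-2, 1.62e0),
    "Th1Prolif_MaxbyTGFb": (7.43e-2, 4.06e0),
    "TCellProlif_MaxbyIL6": (6.87e-1, 4.60e1),
    "TregProlif_MaxbyTGFb": (3.18e-1, 1.57e1),
    "IL6SecMacro_MaxbyTNFa": (2.72e-1, 2.02e1),
    "IL1bSecMacro_MaxbyIL17": (1.08e-1, 8.04e0),
    "TNFaSecMacro_MaxbyIL17": (1.02e-1, 6.81e0),
    "TCellinflux_MaxbyTNFa": (3.94e-1, 2.78e1),
    "IFNgSecTh1_MaxbyIL10": (7.40e-2, 4.48e0),
    "Endoinflux_MaxbyIL17": (1.43e-1, 6.70e0),
    "Endoinflux_MaxbyTGFb": (7.52e-2, 5.30e0),
    "VEGFSecFLS_MaxbyIL1b": (1.30e-1, 9.66e0),
    "VEGFSecFLS_MaxbyIL6": (4.58e-2, 2.51e0),
    "VEGFSecFLS_MaxbyTNFa": (4.55e-2, 2.90e0),
    "VEGFSecFLS_MaxbyIL17": (1.30e-1, 1.01e1),
    "IL6SecFLS_MaxbyIL17": (7.16e-1, 3.20e1),
    "LymphoInflux_MaxbyMIP3": (7.11e-1, 3.70e1),
    "MacroProlif_MaxbyGMCSF": (2.71e-1, 1.34e1),
    "GMCSFSecFLS_MaxbyTNFa": (6.00e-1, 3.82e1),
    "GMCSFSecMacro_MaxbyTNFa": (1.08e-1, 8.04e0),
    "MacroInflux_MaxbyMCP1": (2.30e-1, 1.20e1),
    "IL6SecFLS_MaxbyIFNg": (1.41e-1, 8.53e0),
    "IL1bSecFLS_MaxbyIL10": (6.30e-2, 3.81e0),
    "VEGFSecFLS_MaxbyTGFb": (1.35e0, 7.76e1),
    "TNFaSecFLS_MaxbyIL10": (7.48e-2, 5.83e0),
    "LeukoInflux_MaxbyCAM": (1.08e-1, 8.04e0),
    "TCellProlif_MaxbyIL10": (9.04e-2, 6.37e0),
    "BCellApop_MaxbyBAFF": (7.36e-2, 4.93e0),
    "TNFaSecMacro_MaxbyIL10": (9.08e-2, 5.78e0),
    "IL6SecMacro_MaxbyIL10": (9.06e-2, 6.07e0),
    "MacroInflux_MaxbyTGFb": (5.14e-1, 2.81e1),
    "TNFaSecMacro_MaxbyAutoAb": (8.32e-1, 4.79e1),
    "BCellProlif_MaxbyIL6": (3.16e-1, 1.82e1),
    "BCellProlif_MaxbyIFNg": (7.50e-2, 5.56e0),
    "BCellProlif_MaxbyIL10": (9.89e-1, 7.33e1),
    "BCellProlif_MaxbyTGFb": (1.73e-2, 1.10e0),
    "IFNgSecCTL_MaxbyIL6": (5.21e-2, 3.49e0),
    "CTLProlif_MaxbyIL1b": (1.68e-1, 7.14e0),
    "CTLProlif_MaxbyTGFb": (6.27e-2, 4.20e0),
    "IFNgSecCTL_MaxbyTGFb": (9.04e-2, 6.37e0),
    "VEGFSecEndo_MaxbyTGFb": (3.28e-1, 2.31e1),
    "MIP3SecFLS_MaxbyTNFa": (1.14e0, 7.28e1),
    "MIP3SecFLS_MaxbyIL1b": (1.35e0, 7.76e1),
    "MIP3SecFLS_MaxbyIL17": (6.04e-1, 3.30e1),
    "MCP1SecFLS_MaxbyIL1b": (1.19e0, 8.00e1),
    "MCP1SecMacro_MaxbyIL1b": (4.34e-2, 2.90e0),
    "IL17SecTh17_MaxbyIL1b": (1.35e0, 7.76e1),
    "IL17SecTh17_MaxbyIL6": (1.09e-1, 7.29e0),
    "CTLApop_MaxbyTGFb": (7.45e-2, 3.87e0),
    "AutoAbSecBCell_MaxbyIL6": (4.55e-2, 2.90e0),
    "BCellDiff_MaxbyIL6": (1.03e-1, 5.35e0),
    "EndoProlif_MaxbyGMCSF": (7.41e-2, 4.27e0),
    "Endoinflux_MaxbyGMCSF": (1.88e-1, 1.47e1),
    "TNFaSecMacro_MaxbyGMCSF": (3.16e-1, 1.82e1),
    "CTLProlif_MaxbyIL12": (6.01e-1, 3.64e1),
    "Th1Apop_MaxbyIL12": (2.99e-2, 2.11e0),
    "Th17Prolif_MaxbyIL23": (1.08e-1, 8.04e0),
    "IL17SecCTL_MaxbyIL23": (3.18e-1, 1.65e1),
    "IL17SecTh17_MaxbyIL23": (1.09e-1, 7.66e0),
    "MacroProlif_MaxbyTNFa": (1.09e-1, 7.29e0),
    "RANTESSecFLS_MaxbyTNFa": (2.28e-1, 1.45e1),
    "RANTESSecFLS_MaxbyIL1b": (1.09e-1, 7.29e0),
    "RANTESSecFLS_byTNFa_MaxbyIFNg": (3.30e-1, 2.00e1),
    "RANTESSecEndo_MaxbyTNFa": (1.60e0, 7.52e1),
    "RANTESSecEndo_byTNFa_MaxbyIFNg": (4.58e-2, 2.51e0),
    "IL6SecFLS_MaxbyRANTES": (8.79e-2, 4.13e0),
    "TCellinflux_MaxbyRANTES": (1.20e0, 7.26e1),
    "RANTESSecEndo_MaxbyIL1b": (4.40e-1, 2.17e1),
    "RANTESSecFLS_byIL1b_MaxbyIFNg": (2.31e-1, 1.09e1),
    "MacroInflux_MaxbyRANTES": (2.40e-2, 1.32e0),
    "CTLInflux_MaxbyRANTES": (1.06e-1, 4.30e0),
    "MCP1SecFLS_MaxbyTNFa": (9.86e-1, 7.69e1),
    "FLSProlif_MaxbyIL6": (2.28e-1, 1.45e1),
    "IFNgSecMacro_MaxbyIL12": (1.09e-1, 7.29e0),
    "Th1Prolif_MaxbyIL12": (4.35e-1, 2.77e1),
    "Th17Prolif_MaxbyIL1b": (8.36e-1, 4.35e1),
    "TregProlif_MaxbyIL6": (4.32e-2, 3.20e0),
    "IFNgSecCTL_MaxbyIL12": (1.08e-1, 8.04e0),
    "PlasmaProlif_MaxbyIL6": (1.89e-1, 1.27e1),
    "TCellApop_MaxbyIL6": (5.19e-2, 3.85e0),
    "MacroApop_MaxbyTNFa": (9.08e-2, 5.78e0),
    "MacroApop_MaxbyIFNg": (1.02e-1, 6.18e0),
    "MacroApop_MaxbyGMCSF": (9.08e-2, 5.78e0),
    "PlasmaCellApop_MaxbyIL6": (1.09e-1, 6.95e0),
}

#: Physiological ranges of baseline synovial cell densities (cells/mL).
CELL_RANGES: dict[str, tuple[float, float]] = {
    "FLS": (1.31e6, 1.53e8),
    "Endothelial": (4.13e7, 8.31e7),
    "Macrophage": (3.73e6, 1.94e8),
    "Th1": (3.32e4, 2.88e8),
    "Th17": (1.64e3, 2.02e7),
    "CTL": (8.38e2, 6.56e6),
    "BCell": (6.03e3, 4.17e8),
    "PlasmaCell": (7.08e4, 1.41e8),
    "Treg": (3.51e4, 9.02e7),
}

#: Physiological ranges of baseline mediator concentrations (ng/mL).
MEDIATOR_RANGES: dict[str, tuple[float, float]] = {
    "VEGF": (1.48e-2, 1.70e3),
    "RANTES": (2.34e-4, 2.69e1),
    "TGFb": (2.40e-4, 1.66e1),
    "TNFa": (5.25e-4, 7.59e2),
    "IL23": (2.40e-4, 1.66e1),
    "IL6": (9.12e-1, 1.74e5),
    "MCP1": (2.34e-2, 2.69e3),
    "MIP3a": (5.25e-5, 7.59e1),
    "IL1b": (8.32e-4, 1.20e3),
    "GMCSF": (9.12e-5, 1.74e1),
    "IFNg": (3.31e-6, 7.59e2),
    "IL10": (4.90e-3, 2.04e2),
    "IL12": (3.72e-5, 4.27e0),
    "IL17": (9.33e-7, 1.70e1),
    "BAFF": (3.80e-3, 2.63e2),
    "CAM": (1.08e-3, 5.09e0),
    "AutoAb": (3.16e1, 1.26e8),
}

#: DAS28-CRP score layer: per-cell weight, half-max density (cells/mL)
#: and Hill exponent.  The CTL Km is not published; the default is the
#: geometric mean of the CTL plausibility range (see scoring module).
DAS28_COEFFICIENTS: dict[str, float] = {
    "Macrophage": 2.5,
    "FLS": 2.0,
    "Th1": 1.5,
    "BCell": 1.5,
    "PlasmaCell": 1.0,
    "Th17": 0.5,
    "Endothelial": 0.5,
    "CTL": 0.5,
    "Treg": -0.5,
}

DAS28_KM: dict[str, float] = {
    "FLS": 1.3e7,
    "Endothelial": 4.2e7,
    "Macrophage": 2.2e7,
    "Th1": 4.0e6,
    "Th17": 1.0e5,
    "Treg": 2.0e6,
    "BCell": 3.0e6,
    "PlasmaCell": 1.8e6,
}

DAS28_GAMMA = 2.5

#: Clinical-trial summary statistics (percent responders per arm).
#: ACR categories here are percent reduction in DAS28-CRP from
#: baseline; das_lt columns are percent of the arm below the cutoff.
TRIAL_STATS: dict[str, dict] = {
    "MTX": {
        "baseline_das": None,  # not reported
        "treatment": {"ACR20": 46.0, "ACR50": 23.0, "ACR70": 9.0},
        "placebo": {"ACR20": 26.0, "ACR50": 8.0, "ACR70": 4.0},
    },
    "ADA": {
        "baseline_das": (6.0, 1.0),
        "treatment": {
            "ACR20": 70.0,
            "ACR50": 52.0,
            "ACR70": 35.0,
            "das_lt_2_6": 34.0,
            "das_lt_3_2": 47.0,
        },
        "placebo": {
            "ACR20": 57.0,
            "ACR50": 34.0,
            "ACR70": 17.0,
            "das_lt_2_6": 17.0,
            "das_lt_3_2": 26.0,
        },
    },
    "TCZ": {
        "baseline_das": (6.53, 1.03),
        "treatment": {
            "ACR20": 45.0,
            "ACR50": 30.1,
            "ACR70": 13.9,
            "das_lt_2_6": 38.4,
            "das_lt_3_2": 50.7,
        },
        "placebo": {
            "ACR20": 25.0,
            "ACR50": 11.2,
            "ACR70": 1.9,
            "das_lt_2_6": 2.0,
            "das_lt_3_2": 10.4,
        },
    },
}

#: Methotrexate pharmacodynamic Hill triple shared by the three MTX
#: effect pathways: (Vm, Km in mg/L, Hill slope).
MTX_PD = {"vm": 0.5, "km": 1.0e-5, "slope": 2.0}

#: Caps on aggregated multi-cytokine effects.
PRO_LIMIT_DEFAULT = 10.0
ANTI_LIMIT_DEFAULT = 0.75

#: Entry criterion: active disease only.
MIN_BASELINE_DAS = 3.2


def geometric_midpoint(lo: float, hi: float) -> float:
    """Geometric midpoint of a (positive) range."""
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError(f"invalid range ({lo}, {hi})")
    return math.sqrt(lo * hi)


#: Reference ("median") baseline state used throughout: the geometric
#: midpoint of each plausibility range.
REFERENCE_CELL_DENSITIES: dict[str, float] = {
    c: geometric_midpoint(*CELL_RANGES[c]) for c in CELLS
}
REFERENCE_MEDIATOR_CONCS: dict[str, float] = {
    m: geometric_midpoint(*MEDIATOR_RANGES[m]) for m in MEDIATORS
}
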