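"""Saturating, capped multi-cytokine modulation of life-cycle rates.

Every proliferation, influx, apoptosis, secretion and differentiation
rate in the synovium model is a baseline multiplied by
``(1 + ProRate) * (1 - AntiRate)``, where ProRate and AntiRate are sums
of Hill terms, one per regulating mediator, capped at a configurable
limit.  The cap applies to the *sum*, not to each term.  Some processes
additionally carry an essential-mediator gate: the rate falls to zero
as the essential mediator vanishes (e.g. IFN-g secretion by Th1 cells
requires IL-12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import ANTI_LIMIT_DEFAULT, PRO_LIMIT_DEFAULT

__all__ = [
    "CapPolicy",
    "EffectAggregate",
    "hill",
    "aggregate_effects",
    "rate_factor",
    "essential_gate",
]


@dataclass(frozen=True)
class CapPolicy:
    """Caps on the aggregated pro and anti effects.

    ``pro_limit`` bounds the summed fold-increase (default 10, i.e. a
    rate can reach at most 11x baseline); ``anti_limit`` bounds the
    summed fractional decrease and must stay below 1 (default 0.75,
    i.e. a rate can fall to at most 0.25x baseline).
    """

    pro_limit: float = PRO_LIMIT_DEFAULT
    anti_limit: float = ANTI_LIMIT_DEFAULT

    def __post_init__(self) -> None:
        if self.pro_limit <= 0:
            raise ValueError("pro_limit must be positive")
        if not 0 < self.anti_limit < 1:
            raise ValueError("anti_limit must lie in (0, 1)")


@dataclass
class EffectAggregate:
    """Capped pro/anti sums for one target process.

    ``contributions`` holds the per-edge Hill values before capping,
    keyed by edge name, for diagnostics.
    """

    pro_rate: float
    anti_rate: float
    contributions: dict[str, float] = field(default_factory=dict)


def hill(conc, vm: float, km: float, slope: float = 1.0):
    """Hill response ``vm * c^s / (c^s + km^s)``.

    Monotone nondecreasing in ``conc``, zero at zero, bounded by
    ``vm``.  Accepts scalars or arrays for ``conc``.
    """
    if km <= 0:
        raise ValueError("km must be positive")
    if slope <= 0:
        raise ValueError("slope must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cs = np.power(c, slope)
    out = vm * cs / (cs + km**slope)
    if np.isscalar(conc) or np.ndim(conc) == 0:
        return float(out)
    return out


def aggregate_effects(edges, mediator_conc: dict, policy: CapPolicy | None = None) -> EffectAggregate:
    """Aggregate the Hill contributions of a set of regulatory edges.

    All edges must share one target process; ``mediator_conc`` maps
    mediator name -> concentration (ng/mL).  Edges are summed in a
    canonical order (regulator name, then edge name) so the result is
    independent of the input ordering, bit for bit.
    """
    policy = policy or CapPolicy()
    ordered = sorted(edges, key=lambda e: (e.regulator, e.name))
    pro_sum = 0.0
    anti_sum = 0.0
    contributions: dict[str, float] = {}
    for edge in ordered:
        if edge.regulator not in mediator_conc:
            raise KeyError(
                f"regulator {edge.regulator!r} of edge {edge.name!r} missing "
                "from the concentration map"
            )
        h = hill(mediator_conc[edge.regulator], edge.vm_effect, edge.km_effect, edge.slope_effect)
        contributions[edge.name] = h
        if edge.sign == "pro":
            pro_sum += h
        else:
            anti_sum += h
    return EffectAggregate(
        pro_rate=min(policy.pro_limit, pro_sum),
        anti_rate=min(policy.anti_limit, anti_sum),
        contributions=contributions,
    )


def rate_factor(aggregate: EffectAggregate) -> float:
    """Multiplicative factor on the baseline rate: (1+pro)*(1-anti)."""
    return (1.0 + aggregate.pro_rate) * (1.0 - aggregate.anti_rate)


def essential_gate(process_rate, essential_mediator_conc, km_gate: float, slope: float = 1.0):
    """Gate a rate by an essential mediator.

    Multiplies ``process_rate`` by ``c^s / (c^s + km_gate^s)`` so the
    rate vanishes as the essential mediator does, and recovers the
    ungated rate at saturating concentrations.
    """
    if km_gate <= 0:
        raise ValueError("km_gate must be positive")
    return process_rate * hill(essential_mediator_conc, 1.0, km_gate, slope)
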