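"""Analytic parallelization cost model for semilocal potentials.

For a homogeneous system of edge length L (per periodic dimension, with
N ∝ L^d) the evaluation cost of one domain is proportional to the atoms
it touches, (L_dom + 2TR)^d, because the halo of copied atoms extends
the domain by the receptive radius TR on every side. Splitting over P
processors gives domains of edge P^{-1/d} L, hence the speedup

    S = ((L + 2TR) / (P^{-1/d} L + 2TR))^d

and parallel efficiency ε = S / P. The model counts work only; it has
no communication-latency term, so it is an estimate of attainable
scaling, not an exact wall-clock predictor. L here is the *system*
edge; the per-domain edge is derived, which matters when comparing with
conventions that quote the domain edge directly.

Non-periodic dimensions are excluded from d (a slab has d = 2): the
slab thickness multiplies cost by a constant that cancels in S.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScalingScenario", "speedup", "efficiency", "scaling_curves"]


@dataclass(frozen=True)
class ScalingScenario:
    """System edge L (Å), receptive radius TR (Å), processor count P,
    and periodic dimensionality d."""

    L: float
    TR: float
    P: int
    d: int = 3

    def __post_init__(self) -> None:
        if self.L < 0 or self.TR < 0:
            raise ValueError("L and TR must be >= 0")
        if self.L == 0 and self.TR == 0:
            raise ValueError("L and TR cannot both be zero")
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.d not in (1, 2, 3):
            raise ValueError("d must be 1, 2 or 3")


def speedup(scn: ScalingScenario) -> float:
    """S = ((L + 2TR) / (P^{-1/d} L + 2TR))^d."""
    num = scn.L + 2.0 * scn.TR
    den = scn.P ** (-1.0 / scn.d) * scn.L + 2.0 * scn.TR
    return (num / den) ** scn.d


def efficiency(scn: ScalingScenario) -> float:
    """Parallel efficiency ε = S / P."""
    return speedup(scn) / scn.P


def scaling_curves(base: ScalingScenario, P_list: list[int]) -> list[dict]:
    """Rows of (P, S, ε, ideal S=P) for a strong-scaling sweep."""
    if not P_list:
        raise ValueError("P_list must be non-empty")
    rows = []
    for P in P_list:
        scn = ScalingScenario(L=base.L, TR=base.TR, P=int(P), d=base.d)
        s = speedup(scn)
        rows.append({"P": int(P), "S": s, "efficiency": s / P, "ideal_S": float(P)})
    return rows
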