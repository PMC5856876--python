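"""Discrete 2D distances, step-category banding and stepping rates.

A walker may step from its current anchorage to any anchorage within the
maximum interaction distance, at a rate that falls off with distance.  On
the design grid the piecewise rate function becomes a three-band
classification of anchorage pairs — SHORT / MEDIUM / LONG — with rates
k_s, k_s/50 and k_s/100.  Band membership is decided in exact integer
arithmetic on squared distances: ``d <= r  iff  d² <= r²``, so no floating
point enters the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit import GridPoint

__all__ = [
    "DistanceParams",
    "PhysicalParams",
    "StepCategory",
    "squared_distance",
    "minkowski_distance",
    "manhattan_distance",
    "chebyshev_distance",
    "step_category",
    "step_rate",
    "short_neighbourhood_stencil",
]


class StepCategory:
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"
    NONE = "NONE"  # out of interaction range

    BANDS = (SHORT, MEDIUM, LONG)


@dataclass(frozen=True)
class DistanceParams:
    """Banding radii (grid units) and stepping rates.

    Defaults: dS=3, dMgrid=5, dL=8 grid units and a base stepping rate
    k_s = 0.009 s⁻¹ with divisors 50 (medium) and 100 (long).
    """

    dS: int = 3
    dMgrid: int = 5
    dL: int = 8
    k_s: float = 0.009
    medium_divisor: float = 50.0
    long_divisor: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.dS < self.dMgrid < self.dL):
            raise ValueError("require 0 < dS < dMgrid < dL")
        if self.k_s <= 0:
            raise ValueError("k_s must be positive")
        if self.medium_divisor <= 1 or self.long_divisor <= 1:
            raise ValueError("band divisors must exceed 1")


@dataclass(frozen=True)
class PhysicalParams:
    """Physical banding alternative: average anchorage distance d_a (nm),
    maximum interaction distance d_M (nm) and the grid pitch in nm.

    With grid_unit = d_a/2 = 3.1 nm the discrete radii dS=3 and dMgrid=5
    coincide exactly with the physical cutoffs 1.5·d_a and 2.5·d_a, and
    dL=8 corresponds to 24.8 nm ≈ d_M.
    """

    d_a: float = 6.2
    d_M: float = 24.0
    grid_unit: float = 3.1

    def __post_init__(self) -> None:
        if self.d_a <= 0:
            raise ValueError("d_a must be positive")
        if self.d_M <= 1.5 * self.d_a:
            raise ValueError("require d_M > 1.5 * d_a")

    def to_grid_bands(self) -> tuple[float, float, float]:
        """Band radii in grid units implied by the physical cutoffs."""
        return (
            1.5 * self.d_a / self.grid_unit,
            2.5 * self.d_a / self.grid_unit,
            self.d_M / self.grid_unit,
        )


def squared_distance(p1: GridPoint, p2: GridPoint) -> int:
    return (p1.x - p2.x) ** 2 + (p1.y - p2.y) ** 2


def minkowski_distance(p1: GridPoint, p2: GridPoint, m: float) -> float:
    """L_m distance; rejects orders below 1 (not a metric)."""
    if m < 1:
        raise ValueError("Minkowski order must be >= 1")
    return (abs(p1.x - p2.x) ** m + abs(p1.y - p2.y) ** m) ** (1.0 / m)


def manhattan_distance(p1: GridPoint, p2: GridPoint) -> int:
    return abs(p1.x - p2.x) + abs(p1.y - p2.y)


def chebyshev_distance(p1: GridPoint, p2: GridPoint) -> int:
    return max(abs(p1.x - p2.x), abs(p1.y - p2.y))


def step_category(p1: GridPoint, p2: GridPoint, params: DistanceParams) -> str:
    """Band of the ordered pair (p1, p2): SHORT, MEDIUM, LONG or NONE.

    Self-pairs are rejected: a walker has no zero-length step.
    """
    d2 = squared_distance(p1, p2)
    if d2 == 0:
        raise ValueError(f"no self-steps: both points are ({p1.x}, {p1.y})")
    if d2 <= params.dS * params.dS:
        return StepCategory.SHORT
    if d2 <= params.dMgrid * params.dMgrid:
        return StepCategory.MEDIUM
    if d2 <= params.dL * params.dL:
        return StepCategory.LONG
    return StepCategory.NONE


def step_rate(category: str, params: DistanceParams) -> float:
    """Stepping rate (s⁻¹) for a band; NONE maps to 0."""
    if category == StepCategory.SHORT:
        return params.k_s
    if category == StepCategory.MEDIUM:
        return params.k_s / params.medium_divisor
    if category == StepCategory.LONG:
        return params.k_s / params.long_divisor
    if category == StepCategory.NONE:
        return 0.0
    raise ValueError(f"unknown step category {category!r}")


def short_neighbourhood_stencil(params: DistanceParams) -> set[tuple[int, int]]:
    """All nonzero integer offsets (dx, dy) with dx² + dy² <= dS².

    For dS=3 this equals the union of the L1<=3 diamond and the L∞<=2
    square (minus the origin) — the classical discrete realisation of the
    lattice-Euclidean disc of radius 3.
    """
    r = params.dS
    return {
        (dx, dy)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        if (dx, dy) != (0, 0) and dx * dx + dy * dy <= r * r
    }
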