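"""Dietary greenhouse-gas accounting.

Emissions are linear in the diet: each food group contributes its
consumption (g/day) times its life-cycle GHG intensity (kgCO2e/g).  Low,
central and high intensity variants support the parameter sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import GHG_VARIANTS, FoodGroupTable


@dataclass(frozen=True)
class EmissionsResult:
    """Dietary GHG emissions for one diet vector, kgCO2e per person-day."""

    total: float
    by_group: np.ndarray
    variant: str

    def __post_init__(self) -> None:
        if self.variant not in GHG_VARIANTS:
            raise ValueError(f"unknown GHG variant {self.variant!r}")
        if (np.asarray(self.by_group) < 0).any():
            raise ValueError("negative per-group emissions")


def diet_emissions(
    x: np.ndarray, table: FoodGroupTable, sex: str, variant: str = "central"
) -> EmissionsResult:
    """Total and per-group emissions of the diet ``x`` for one sex."""
    x = np.asarray(x, float)
    if (x < 0).any():
        raise ValueError("diet vector must be non-negative")
    g = table.ghg_intensity(sex, variant)
    if x.shape != g.shape:
        raise ValueError("diet vector does not match the food table")
    by_group = x * g
    return EmissionsResult(total=float(by_group.sum()), by_group=by_group, variant=variant)


def achieved_reduction(baseline: EmissionsResult, scenario: EmissionsResult) -> float:
    """Fractional emissions reduction of ``scenario`` relative to ``baseline``.

    Negative when scenario emissions exceed the baseline.
    """
    if baseline.variant != scenario.variant:
        raise ValueError(
            f"variant mismatch: {baseline.variant!r} vs {scenario.variant!r}")
    if baseline.total <= 0:
        raise ValueError("baseline emissions must be positive")
    return 1.0 - scenario.total / baseline.total


def population_reduction(
    per_sex: dict[str, float], weights: dict[str, float] | None = None
) -> float:
    """Aggregate per-sex reductions into one population figure.

    Defaults to the equal-weight mean of the sexes; pass person counts (or
    any positive weights) to weight differently.
    """
    if not per_sex:
        raise ValueError("no per-sex reductions given")
    if weights is None:
        weights = {s: 1.0 for s in per_sex}
    w = np.array([weights[s] for s in per_sex], float)
    r = np.array(list(per_sex.values()), float)
    return float((w * r).sum() / w.sum())
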