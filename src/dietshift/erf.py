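"""Log-linear exposure-response machinery.

Changes in consumption of tagged food exposures (fruit, vegetables, red
meat, processed meat) are converted into per-disease hazard multipliers.
Risk scales log-linearly: a change ``delta`` applied to a pathway with
relative risk RR per reference increment multiplies the disease hazard by
``RR ** (delta / increment)``.  When several exposures affect one disease
their multipliers are combined by multiplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tables import ExposureResponse, FoodGroupTable

RR_WHICH = ("central", "low", "high")


@dataclass(frozen=True)
class ExposureDelta:
    """Signed change in one exposure's intake, g/day, for one sex."""

    exposure: str
    sex: str
    delta: float


@dataclass(frozen=True)
class HazardMultiplier:
    """Full-effect (un-lagged) hazard multiplier for one disease and sex."""

    disease: str
    sex: str
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("hazard multiplier must be positive")


def scale_rr(erf: ExposureResponse, delta: float, which: str = "central") -> float:
    """Scale a relative risk to an arbitrary intake change.

    Parameters
    ----------
    erf
        The pathway, holding RR per ``erf.increment`` g/day.
    delta
        Signed intake change in g/day.
    which
        Which RR to scale: ``central`` or the ``low``/``high`` CI bound.

    Returns
    -------
    float
        ``rr ** (delta / increment)``; 1.0 when ``delta`` is 0.
    """
    if which not in RR_WHICH:
        raise ValueError(f"unknown RR variant {which!r}")
    rr = getattr(erf, f"rr_{which}")
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return float(math.exp((delta / erf.increment) * math.log(rr)))


def combine_multipliers(
    values: Iterable[float], disease: str, sex: str = ""
) -> HazardMultiplier:
    """Multiply per-exposure multipliers into one per-disease multiplier.

    An empty input yields the identity multiplier 1.0.
    """
    product = 1.0
    for v in values:
        if v <= 0:
            raise ValueError("multipliers must be positive")
        product *= v
    return HazardMultiplier(disease=disease, sex=sex, value=product)


def deltas_from_scenario(
    baseline: np.ndarray,
    scenario_x: np.ndarray,
    table: FoodGroupTable,
    sex: str,
) -> list[ExposureDelta]:
    """Per-exposure intake changes between a scenario diet and the baseline.

    The change for each tag is the summed g/day difference over the food
    groups carrying that tag; ``other`` groups contribute nothing.
    """
    baseline = np.asarray(baseline, float)
    scenario_x = np.asarray(scenario_x, float)
    if baseline.shape != scenario_x.shape:
        raise ValueError("baseline and scenario vectors are not conformable")
    tags = table.for_sex(sex)["exposure_tag"].to_numpy()
    out = []
    for tag in ("fruit", "vegetable", "red_meat", "processed_meat"):
        mask = tags == tag
        out.append(ExposureDelta(tag, sex, float((scenario_x - baseline)[mask].sum())))
    return out


def hazard_multipliers(
    erfs: Sequence[ExposureResponse],
    deltas: Sequence[ExposureDelta],
    which: str = "central",
    exposure_mask: Iterable[str] | None = None,
    impact_direction: str | None = None,
) -> dict[str, HazardMultiplier]:
    """Combine all pathways into one hazard multiplier per disease.

    Parameters
    ----------
    erfs
        The exposure-response table.
    deltas
        One :class:`ExposureDelta` per exposure tag (one sex).
    which
        ``central``, ``low`` or ``high`` relative-risk variant, applied to
        every pathway alike.
    exposure_mask
        If given, only pathways whose exposure is in this set contribute;
        used for the fruit-only / vegetables-only structural variants.
    impact_direction
        If given (``low``/``central``/``high``), overrides ``which`` per
        pathway via :func:`sensitivity_which`, so that ``low`` always
        weakens and ``high`` always strengthens each effect regardless of
        whether the risk is protective or harmful.

    Returns
    -------
    dict
        Disease name -> :class:`HazardMultiplier` (value 1.0 when no active
        pathway touches the disease).
    """
    sexes = {d.sex for d in deltas}
    if len(sexes) > 1:
        raise ValueError("deltas mix sexes; build multipliers per sex")
    sex = sexes.pop() if sexes else ""
    delta_by_tag = {d.exposure: d.delta for d in deltas}
    mask = set(exposure_mask) if exposure_mask is not None else None

    diseases = list(dict.fromkeys(e.disease for e in erfs))
    out: dict[str, HazardMultiplier] = {}
    for disease in diseases:
        parts = []
        for e in erfs:
            if e.disease != disease or (mask is not None and e.exposure not in mask):
                continue
            w = which if impact_direction is None else \
                sensitivity_which(impact_direction, e.rr_central)
            parts.append(scale_rr(e, delta_by_tag.get(e.exposure, 0.0), w))
        out[disease] = combine_multipliers(parts, disease, sex)
    return out


def sensitivity_which(direction: str, rr_central: float) -> str:
    """Map an impact direction to the CI bound to use for one pathway.

    ``low`` impact uses the bound nearest 1 (weakest effect) for protective
    and harmful risks alike; ``high`` impact the far bound.  ``central``
    passes through.
    """
    if direction == "central":
        return "central"
    if direction not in ("low", "high"):
        raise ValueError(f"unknown sensitivity direction {direction!r}")
    protective = rr_central < 1.0
    if direction == "low":
        return "high" if protective else "low"
    return "low" if protective else "high"
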