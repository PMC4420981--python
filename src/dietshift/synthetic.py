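"""Synthetic input generation.

Real analyses of this kind consume three national datasets that cannot be
shipped: a dietary survey aggregated to representative food groups, a
life-cycle inventory of food GHG intensities, and national population and
mortality counts.  This module generates tabular stand-ins with the
statistical structure the pipeline assumes — a food-group table whose
category composition, nutrient contents, GHG intensities and price
behaviour are plausible for a Western diet; a population with
Gompertz-Makeham mortality and age-ramped cause-specific fractions; and
the exposure-response table, available either as the packaged literature
fixture or with randomised relative risks.

Everything is driven by a single integer seed and is bit-for-bit
reproducible.  No claim of fidelity to any specific national survey is
made: magnitudes are chosen so that baseline intakes sit in realistic
ranges (fruit around 140 g/day, total energy 2000-3000 kcal/day, dietary
emissions a few kgCO2e/day) and so that the baseline mildly violates the
default nutritional constraints in the directions typical of a Western
diet (too much saturated fat, free sugars and sodium; too little fibre,
fruit and vegetables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .tables import (
    ExposureResponse,
    FoodGroupTable,
    NutrientConstraintSet,
    PopulationTable,
    erfs_from_frame,
)

DEFAULT_NUTRIENTS = ("energy", "fat", "saturated_fat", "free_sugars", "fibre", "sodium")
DEFAULT_DISEASES = (
    "coronary_heart_disease", "stroke", "oral_cancer", "oesophageal_cancer",
    "lung_cancer", "stomach_cancer", "colorectal_cancer", "type2_diabetes",
)


class FixtureError(ValueError):
    """The requested synthetic problem cannot carry the required structure."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic generators; the defaults are the study setup."""

    n_food_groups: int = 42
    sexes: tuple[str, ...] = ("male", "female")
    max_age: int = 100
    seed: int = 0
    nutrient_names: tuple[str, ...] = DEFAULT_NUTRIENTS
    disease_names: tuple[str, ...] = DEFAULT_DISEASES

    def __post_init__(self) -> None:
        if self.n_food_groups < 2:
            raise FixtureError("need at least 2 food groups")
        if self.max_age < 1:
            raise FixtureError("max_age must be at least 1")


# ---------------------------------------------------------------------------
# Food-group categories
# ---------------------------------------------------------------------------

# Per-category template: exposure tag, liquid flag, total baseline
# consumption (g/day, male/female), nutrient content per gram (energy kcal,
# then grams of fat / saturated fat / free sugars / fibre / sodium), central
# GHG intensity (kgCO2e/g), count within a 42-group table, and a relative
# price level feeding the expenditure shares.
_CATEGORIES: dict[str, dict] = {
    "fruit":          dict(tag="fruit", liquid=False, male=137.0, female=145.0,
                           nut=(0.55, 0.002, 0.0005, 0.0, 0.020, 0.00002),
                           ghg=0.0023, count=3, price=1.2),
    "vegetables":     dict(tag="vegetable", liquid=False, male=99.0, female=101.0,
                           nut=(0.30, 0.003, 0.001, 0.0, 0.025, 0.0001),
                           ghg=0.0014, count=4, price=1.2),
    "red_meat":       dict(tag="red_meat", liquid=False, male=43.0, female=28.0,
                           nut=(2.0, 0.14, 0.055, 0.0, 0.0, 0.0008),
                           ghg=0.022, count=2, price=3.0),
    "processed_meat": dict(tag="processed_meat", liquid=False, male=59.0, female=36.0,
                           nut=(2.8, 0.22, 0.085, 0.001, 0.001, 0.012),
                           ghg=0.013, count=2, price=2.5),
    "cereals":        dict(tag="other", liquid=False, male=320.0, female=240.0,
                           nut=(2.4, 0.025, 0.006, 0.010, 0.040, 0.0015),
                           ghg=0.0010, count=6, price=0.8),
    "milk":           dict(tag="other", liquid=True, male=250.0, female=220.0,
                           nut=(0.55, 0.020, 0.013, 0.0, 0.0, 0.0004),
                           ghg=0.0016, count=2, price=0.7),
    "dairy":          dict(tag="other", liquid=False, male=80.0, female=70.0,
                           nut=(2.5, 0.20, 0.125, 0.005, 0.0, 0.003),
                           ghg=0.0085, count=3, price=2.0),
    "fish":           dict(tag="other", liquid=False, male=40.0, female=35.0,
                           nut=(1.5, 0.08, 0.018, 0.0, 0.0, 0.0015),
                           ghg=0.005, count=2, price=3.0),
    "eggs":           dict(tag="other", liquid=False, male=25.0, female=20.0,
                           nut=(1.4, 0.10, 0.028, 0.0, 0.0, 0.0014),
                           ghg=0.0045, count=1, price=1.5),
    "snacks":         dict(tag="other", liquid=False, male=120.0, female=100.0,
                           nut=(4.5, 0.22, 0.10, 0.30, 0.005, 0.0025),
                           ghg=0.0030, count=5, price=1.8),
    "soft_drinks":    dict(tag="other", liquid=True, male=300.0, female=260.0,
                           nut=(0.40, 0.001, 0.0005, 0.10, 0.0, 0.00005),
                           ghg=0.0009, count=2, price=0.5),
    "hot_drinks":     dict(tag="other", liquid=True, male=1000.0, female=950.0,
                           nut=(0.05, 0.001, 0.0005, 0.001, 0.0, 0.00005),
                           ghg=0.0003, count=3, price=0.3),
    "other":          dict(tag="other", liquid=False, male=350.0, female=300.0,
                           nut=(1.5, 0.08, 0.025, 0.020, 0.010, 0.0015),
                           ghg=0.0025, count=7, price=1.0),
}

#: Categories that must be present for the pipeline to be exercised.
_REQUIRED = ("fruit", "vegetables", "red_meat", "processed_meat", "cereals")


def _allocate_categories(n: int) -> list[str]:
    """Assign each of ``n`` groups to a category.

    The five structurally required categories come first; remaining slots
    follow the 42-group template proportions.
    """
    if n < len(_REQUIRED):
        raise FixtureError(
            f"{n} food groups cannot host the required exposure tags "
            f"(need at least {len(_REQUIRED)})")
    order = [name for name, c in _CATEGORIES.items() for _ in range(c["count"])]
    out = list(_REQUIRED)
    for name in order:
        if len(out) >= n:
            break
        out.append(name)
    while len(out) < n:  # n beyond 42: keep cycling the template
        out.append(order[(len(out) - len(_REQUIRED)) % len(order)])
    return out[:n]


def generate_food_table(cfg: SyntheticConfig) -> FoodGroupTable:
    """Synthesise the per-sex food-group table.

    Composition, GHG intensity and elasticity are shared between the
    sexes (they are properties of the food); consumption levels and hence
    expenditure shares differ.
    """
    if cfg.nutrient_names != DEFAULT_NUTRIENTS:
        raise FixtureError(
            "the synthetic food generator models the default nutrient set")
    rng = np.random.default_rng([cfg.seed, 101])
    cats = _allocate_categories(cfg.n_food_groups)
    n = len(cats)

    # Per-group properties shared across sexes.
    jitter = rng.lognormal(0.0, 0.15, size=(n, 6))
    nut = np.array([_CATEGORIES[c]["nut"] for c in cats]) * jitter
    ghg_c = np.array([_CATEGORIES[c]["ghg"] for c in cats]) * rng.lognormal(0, 0.15, n)
    ghg_lo = ghg_c * rng.uniform(0.60, 0.85, n)
    ghg_hi = ghg_c * rng.uniform(1.20, 1.60, n)
    elast = -rng.uniform(0.25, 1.30, n)
    price = np.array([_CATEGORIES[c]["price"] for c in cats]) * rng.lognormal(0, 0.2, n)

    counts = pd.Series(cats).value_counts()
    frames = []
    for sex in cfg.sexes:
        cons = np.empty(n)
        for cat in counts.index:
            idx = [i for i, c in enumerate(cats) if c == cat]
            total = _CATEGORIES[cat][sex if sex in ("male", "female") else "male"]
            total *= rng.uniform(0.95, 1.05)
            split = rng.gamma(4.0, 1.0, size=len(idx))
            cons[idx] = total * split / split.sum()
        spend = cons * price
        frames.append(pd.DataFrame({
            "sex": sex,
            "group_id": [f"{c}_{i:02d}" for i, c in enumerate(cats)],
            "consumption": cons,
            "ghg_low": ghg_lo, "ghg_central": ghg_c, "ghg_high": ghg_hi,
            "elasticity": elast,
            "share": spend / spend.sum(),
            "liquid": [_CATEGORIES[c]["liquid"] for c in cats],
            "exposure_tag": [_CATEGORIES[c]["tag"] for c in cats],
            **{f"nut_{name}": nut[:, k] for k, name in enumerate(DEFAULT_NUTRIENTS)},
        }))
    return FoodGroupTable(pd.concat(frames, ignore_index=True), DEFAULT_NUTRIENTS)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

# Gompertz-Makeham parameters per sex: baseline hazard, level and slope of
# the senescent term, and an added infant-mortality excess at age 0.
_MORTALITY = {
    "male": dict(makeham=1.6e-4, level=2.6e-5, slope=0.095, infant=4e-3),
    "female": dict(makeham=1.0e-4, level=1.4e-5, slope=0.099, infant=3.5e-3),
}

# Maximum fraction of all-cause mortality attributed to each disease at old
# age; fractions ramp up logistically around midlife.
_CAUSE_MAX = {
    "male": {
        "coronary_heart_disease": 0.18, "stroke": 0.07, "oral_cancer": 0.004,
        "oesophageal_cancer": 0.012, "lung_cancer": 0.050,
        "stomach_cancer": 0.008, "colorectal_cancer": 0.027,
        "type2_diabetes": 0.012,
    },
    "female": {
        "coronary_heart_disease": 0.12, "stroke": 0.09, "oral_cancer": 0.002,
        "oesophageal_cancer": 0.006, "lung_cancer": 0.038,
        "stomach_cancer": 0.005, "colorectal_cancer": 0.022,
        "type2_diabetes": 0.010,
    },
}

_COHORT_SIZE = 400_000  # births per sex per year


def generate_population_table(cfg: SyntheticConfig) -> PopulationTable:
    """Synthesise the per-sex population and mortality schedule.

    All-cause mortality follows a Gompertz-Makeham curve with an infant
    excess at age 0, capped at 1, with the terminal age closed at rate 1.
    Cause-specific rates are logistic age-ramped fractions of all-cause
    mortality, which guarantees they can never sum beyond it.  Population
    counts follow the stationary age structure implied by the mortality
    schedule, with mild random perturbation standing in for migration and
    cohort-size history.
    """
    unknown = set(cfg.disease_names) - set(DEFAULT_DISEASES)
    if unknown:
        raise FixtureError(f"no cause-fraction template for: {sorted(unknown)}")
    rng = np.random.default_rng([cfg.seed, 202])
    ages = np.arange(cfg.max_age + 1)
    frames = []
    for sex in cfg.sexes:
        p = _MORTALITY.get(sex, _MORTALITY["male"])
        m = p["makeham"] + p["level"] * np.exp(p["slope"] * ages)
        m[0] += p["infant"]
        m = np.clip(m, 1e-6, 1.0)
        m[-1] = 1.0

        # stationary age structure with +-5% perturbation
        surv = np.concatenate([[1.0], np.exp(-np.cumsum(m[:-1]))])
        popn = _COHORT_SIZE * surv * rng.uniform(0.95, 1.05, size=len(ages))

        ramp = 1.0 / (1.0 + np.exp(-(ages - 50.0) / 8.0))
        cause_max = _CAUSE_MAX.get(sex, _CAUSE_MAX["male"])
        frame = pd.DataFrame({"sex": sex, "age": ages,
                              "population": popn, "all_cause": m})
        for d in cfg.disease_names:
            frame[d] = cause_max[d] * ramp * m
        frames.append(frame)
    return PopulationTable(pd.concat(frames, ignore_index=True), cfg.disease_names)


# ---------------------------------------------------------------------------
# Exposure-response table
# ---------------------------------------------------------------------------

def load_packaged_erfs() -> list[ExposureResponse]:
    """The packaged literature exposure-response fixture (17 pathways)."""
    with resources.files("dietshift.data").joinpath("table1_erfs.csv").open() as fh:
        return erfs_from_frame(pd.read_csv(fh))


def generate_erf_table(
    cfg: SyntheticConfig, use_paper_values: bool = True
) -> list[ExposureResponse]:
    """Exposure-response pathways for the health model.

    With ``use_paper_values`` (the default) the packaged literature fixture
    is returned verbatim.  Otherwise the same 17 pathway structure is kept
    but central relative risks are drawn uniformly from [0.5, 1.6] with a
    CI spanning the central value.
    """
    base = load_packaged_erfs()
    if use_paper_values:
        return base
    rng = np.random.default_rng([cfg.seed, 303])
    out = []
    for e in base:
        rr = rng.uniform(0.5, 1.6)
        half = rng.uniform(0.02, 0.15)
        out.append(ExposureResponse(
            exposure=e.exposure, disease=e.disease,
            rr_central=rr, rr_low=rr * (1 - half), rr_high=rr * (1 + half),
            increment=e.increment,
        ))
    return out


def default_constraints() -> NutrientConstraintSet:
    """The packaged default nutritional constraint set."""
    with resources.as_file(
        resources.files("dietshift.data").joinpath("who_constraints.yaml")
    ) as path:
        return NutrientConstraintSet.from_yaml(path)


@dataclass
class SyntheticInputs:
    """Everything the pipeline needs, generated from one config."""

    food: FoodGroupTable
    population: PopulationTable
    erfs: list[ExposureResponse]
    constraints: NutrientConstraintSet = field(default_factory=default_constraints)


def generate_all(cfg: SyntheticConfig, use_paper_erfs: bool = True) -> SyntheticInputs:
    """Generate the full input bundle for a pipeline run."""
    return SyntheticInputs(
        food=generate_food_table(cfg),
        population=generate_population_table(cfg),
        erfs=generate_erf_table(cfg, use_paper_values=use_paper_erfs),
        constraints=default_constraints(),
    )
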