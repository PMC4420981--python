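"""Core tabular containers shared across the pipeline.

All containers wrap :class:`pandas.DataFrame` objects with a fixed column
contract, so they round-trip through plain CSV and stay easy to inspect.
Quantities follow the conventions used throughout the package:

* consumption and exposure changes in g/day,
* nutrient composition per gram of food,
* greenhouse-gas (GHG) intensity in kgCO2e per gram,
* mortality rates in deaths per person-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Recognised dietary exposure tags. ``other`` groups carry no health effect.
EXPOSURE_TAGS = ("fruit", "vegetable", "red_meat", "processed_meat", "other")

#: GHG intensity variants available on a food-group table.
GHG_VARIANTS = ("low", "central", "high")

NUTRIENT_PREFIX = "nut_"


class TableError(ValueError):
    """Raised when a table violates its column or value contract."""


# ---------------------------------------------------------------------------
# Food groups
# ---------------------------------------------------------------------------

@dataclass
class FoodGroupTable:
    """Per-sex food-group table: consumption, nutrients, GHG, behaviour.

    ``data`` has one row per (sex, food group) with columns::

        sex, group_id, consumption, ghg_low, ghg_central, ghg_high,
        elasticity, share, liquid, exposure_tag, nut_<name>...

    ``share`` is the group's expenditure share (sums to 1 within each sex),
    ``elasticity`` its own-price elasticity (negative), and ``exposure_tag``
    one of :data:`EXPOSURE_TAGS`.
    """

    data: pd.DataFrame
    nutrient_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.nutrient_names = tuple(self.nutrient_names)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        required = {
            "sex", "group_id", "consumption", "ghg_low", "ghg_central",
            "ghg_high", "elasticity", "share", "liquid", "exposure_tag",
        } | {NUTRIENT_PREFIX + n for n in self.nutrient_names}
        missing = required - set(self.data.columns)
        if missing:
            raise TableError(f"food table missing columns: {sorted(missing)}")
        if (self.data["consumption"] <= 0).any():
            raise TableError("baseline consumption must be strictly positive")
        if (self.data["elasticity"] >= 0).any():
            raise TableError("price elasticities must be negative")
        bad_tags = set(self.data["exposure_tag"]) - set(EXPOSURE_TAGS)
        if bad_tags:
            raise TableError(f"unknown exposure tags: {sorted(bad_tags)}")
        g = self.data
        if not ((g["ghg_low"] <= g["ghg_central"] + 1e-15).all()
                and (g["ghg_central"] <= g["ghg_high"] + 1e-15).all()):
            raise TableError("GHG variants must satisfy low <= central <= high")
        for sex, sub in self.data.groupby("sex"):
            if abs(sub["share"].sum() - 1.0) > 1e-9:
                raise TableError(f"expenditure shares for {sex!r} do not sum to 1")

    # -- accessors ----------------------------------------------------------
    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["sex"]))

    def for_sex(self, sex: str) -> pd.DataFrame:
        sub = self.data[self.data["sex"] == sex].reset_index(drop=True)
        if sub.empty:
            raise TableError(f"no rows for sex {sex!r}")
        return sub

    def consumption(self, sex: str) -> np.ndarray:
        return self.for_sex(sex)["consumption"].to_numpy(float)

    def ghg_intensity(self, sex: str, variant: str = "central") -> np.ndarray:
        if variant not in GHG_VARIANTS:
            raise TableError(f"unknown GHG variant {variant!r}")
        return self.for_sex(sex)[f"ghg_{variant}"].to_numpy(float)

    def nutrient_matrix(self, sex: str) -> pd.DataFrame:
        """Nutrient content per gram: rows = food groups, columns = nutrients."""
        sub = self.for_sex(sex)
        mat = sub[[NUTRIENT_PREFIX + n for n in self.nutrient_names]].copy()
        mat.columns = list(self.nutrient_names)
        mat.index = sub["group_id"]
        return mat

    def tag_mask(self, sex: str, tag: str) -> np.ndarray:
        return (self.for_sex(sex)["exposure_tag"] == tag).to_numpy()

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoodGroupTable":
        df = pd.read_csv(path)
        nutrients = tuple(
            c[len(NUTRIENT_PREFIX):] for c in df.columns if c.startswith(NUTRIENT_PREFIX)
        )
        df["liquid"] = df["liquid"].astype(bool)
        return cls(df, nutrients)


# ---------------------------------------------------------------------------
# Nutrient constraints
# ---------------------------------------------------------------------------

@dataclass
class NutrientBound:
    """Lower/upper bound on daily intake of one nutrient.

    If ``percent_energy`` is set, the bound is a percentage of total dietary
    energy and ``energy_per_g`` (kcal per gram of the nutrient) converts the
    nutrient mass into energy.  Because the optimiser holds total energy
    fixed at its baseline value, percent-of-energy bounds stay linear in the
    consumption vector.
    """

    nutrient: str
    lower: float | None = None
    upper: float | None = None
    percent_energy: bool = False
    energy_per_g: float = 0.0

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise TableError(f"bound on {self.nutrient!r} has neither side")
        if (self.lower is not None and self.upper is not None
                and self.lower > self.upper):
            raise TableError(f"bound on {self.nutrient!r} has lower > upper")
        if self.percent_energy and self.energy_per_g <= 0:
            raise TableError(
                f"percent-energy bound on {self.nutrient!r} needs energy_per_g > 0")


@dataclass
class NutrientConstraintSet:
    """The nutritional side of the optimisation problem.

    Holds per-nutrient bounds, an optional minimum on combined fruit and
    vegetable mass, and the two structural equalities: total energy and the
    liquid share of diet mass are held at their baseline values.
    """

    bounds: list[NutrientBound] = field(default_factory=list)
    fruit_veg_min: float | None = None
    energy_equality: bool = True
    liquid_proportion_equality: bool = True
    energy_nutrient: str = "energy"

    # -- I/O ----------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "energy_nutrient": self.energy_nutrient,
            "energy_equality": self.energy_equality,
            "liquid_proportion_equality": self.liquid_proportion_equality,
            "fruit_veg_min_g": self.fruit_veg_min,
            "nutrients": {
                b.nutrient: {
                    k: v for k, v in (
                        ("lower", b.lower), ("upper", b.upper),
                        ("percent_energy", b.percent_energy or None),
                        ("energy_per_g", b.energy_per_g or None),
                    ) if v is not None
                }
                for b in self.bounds
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NutrientConstraintSet":
        payload = yaml.safe_load(Path(path).read_text())
        bounds = [
            NutrientBound(
                nutrient=name,
                lower=spec.get("lower"),
                upper=spec.get("upper"),
                percent_energy=bool(spec.get("percent_energy", False)),
                energy_per_g=float(spec.get("energy_per_g", 0.0)),
            )
            for name, spec in (payload.get("nutrients") or {}).items()
        ]
        return cls(
            bounds=bounds,
            fruit_veg_min=payload.get("fruit_veg_min_g"),
            energy_equality=bool(payload.get("energy_equality", True)),
            liquid_proportion_equality=bool(
                payload.get("liquid_proportion_equality", True)),
            energy_nutrient=payload.get("energy_nutrient", "energy"),
        )


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

@dataclass
class PopulationTable:
    """Per-sex, single-year-of-age population and mortality schedule.

    ``data`` has one row per (sex, age) with columns ``sex``, ``age``,
    ``population``, ``all_cause`` and one rate column per modelled disease.
    The table is closed: the all-cause rate at the terminal age is 1.
    """

    data: pd.DataFrame
    disease_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.disease_names = tuple(self.disease_names)
        self.validate()

    def validate(self) -> None:
        required = {"sex", "age", "population", "all_cause"} | set(self.disease_names)
        missing = required - set(self.data.columns)
        if missing:
            raise TableError(f"population table missing columns: {sorted(missing)}")
        if (self.data["population"] < 0).any():
            raise TableError("population counts must be non-negative")
        if ((self.data["all_cause"] <= 0) | (self.data["all_cause"] > 1)).any():
            raise TableError("all-cause rates must lie in (0, 1]")
        cause_sum = self.data[list(self.disease_names)].sum(axis=1)
        if (cause_sum > self.data["all_cause"] + 1e-12).any():
            raise TableError("cause-specific rates exceed all-cause rate")

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["sex"]))

    @property
    def max_age(self) -> int:
        return int(self.data["age"].max())

    def for_sex(self, sex: str) -> pd.DataFrame:
        sub = self.data[self.data["sex"] == sex].sort_values("age")
        if sub.empty:
            raise TableError(f"no rows for sex {sex!r}")
        ages = sub["age"].to_numpy()
        if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)):
            raise TableError(f"ages for {sex!r} are not contiguous single years")
        return sub.reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        df = pd.read_csv(path)
        diseases = tuple(
            c for c in df.columns if c not in ("sex", "age", "population", "all_cause")
        )
        return cls(df, diseases)


# ---------------------------------------------------------------------------
# Exposure-response rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureResponse:
    """One exposure-disease pathway: relative risk per reference increment.

    The relative risk applies log-linearly: a change of ``delta`` g/day in
    the exposure multiplies the disease hazard by ``rr_central**(delta /
    increment)`` (see :mod:`dietshift.erf`).
    """

    exposure: str
    disease: str
    rr_central: float
    rr_low: float
    rr_high: float
    increment: float

    def __post_init__(self) -> None:
        if self.exposure not in EXPOSURE_TAGS or self.exposure == "other":
            raise TableError(f"invalid exposure tag {self.exposure!r}")
        if min(self.rr_central, self.rr_low, self.rr_high) <= 0:
            raise TableError("relative risks must be positive")
        if not self.rr_low <= self.rr_central <= self.rr_high:
            raise TableError("require rr_low <= rr_central <= rr_high")
        if self.increment <= 0:
            raise TableError("reference increment must be positive")


ERF_COLUMNS = ("exposure", "disease", "rr_central", "rr_low", "rr_high", "increment")


def erfs_to_frame(erfs: Iterable[ExposureResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(e, c) for c in ERF_COLUMNS} for e in erfs], columns=ERF_COLUMNS
    )


def erfs_from_frame(df: pd.DataFrame) -> list[ExposureResponse]:
    return [
        ExposureResponse(
            exposure=row.exposure, disease=row.disease,
            rr_central=float(row.rr_central), rr_low=float(row.rr_low),
            rr_high=float(row.rr_high), increment=float(row.increment),
        )
        for row in df.itertuples()
    ]


def write_erfs(erfs: Sequence[ExposureResponse], path: str | Path) -> None:
    erfs_to_frame(erfs).to_csv(path, index=False)


def read_erfs(path: str | Path) -> list[ExposureResponse]:
    return erfs_from_frame(pd.read_csv(path))
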