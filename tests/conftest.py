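"""Shared fixtures: the default synthetic inputs and small hand-built tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dietshift as ds

SEED = 1


@pytest.fixture(scope="session")
def cfg() -> ds.SyntheticConfig:
    return ds.SyntheticConfig(seed=SEED)


@pytest.fixture(scope="session")
def inputs(cfg) -> ds.SyntheticInputs:
    return ds.generate_all(cfg)


@pytest.fixture(scope="session")
def sweep(inputs) -> ds.SweepResult:
    """The full target-ladder sweep on the default fixture (computed once)."""
    return ds.run_sweep(inputs, seed=SEED)


@pytest.fixture(scope="session")
def erfs() -> list[ds.ExposureResponse]:
    return ds.load_packaged_erfs()


def make_food_table(
    consumption: list[float],
    energy: list[float],
    tags: list[str] | None = None,
    liquid: list[bool] | None = None,
    ghg: list[float] | None = None,
    elasticity: list[float] | None = None,
    share: list[float] | None = None,
    extra_nutrients: dict[str, list[float]] | None = None,
    sex: str = "male",
) -> ds.FoodGroupTable:
    """Tiny hand-built food table for oracle problems."""
    n = len(consumption)
    tags = tags or ["other"] * n
    ghg = ghg or [0.001] * n
    share = share or [1.0 / n] * n
    df = pd.DataFrame({
        "sex": sex,
        "group_id": [f"g{i}" for i in range(n)],
        "consumption": consumption,
        "ghg_low": np.asarray(ghg) * 0.8,
        "ghg_central": ghg,
        "ghg_high": np.asarray(ghg) * 1.2,
        "elasticity": elasticity or [-1.0] * n,
        "share": share,
        "liquid": liquid or [False] * n,
        "exposure_tag": tags,
        "nut_energy": energy,
    })
    nutrients = ["energy"]
    for name, vals in (extra_nutrients or {}).items():
        df[f"nut_{name}"] = vals
        nutrients.append(name)
    return ds.FoodGroupTable(df, tuple(nutrients))


def make_population(
    all_cause: np.ndarray,
    cause_rates: dict[str, np.ndarray],
    population: np.ndarray | None = None,
    sex: str = "male",
) -> ds.PopulationTable:
    """Hand-built single-sex population table."""
    ages = np.arange(len(all_cause))
    df = pd.DataFrame({
        "sex": sex,
        "age": ages,
        "population": population if population is not None else np.full(len(ages), 1000.0),
        "all_cause": all_cause,
    })
    for d, r in cause_rates.items():
        df[d] = r
    return ds.PopulationTable(df, tuple(cause_rates))
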