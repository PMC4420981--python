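"""Diet optimiser: weights, objective, constraint reports, oracle checks.

The solver is validated against dense grid-search oracles on problems
small enough to enumerate, and against structural invariances (reordering,
weight rescaling, multi-start agreement) on a 6-food problem.
"""

import numpy as np
import pandas as pd
import pytest

import dietshift as ds
from dietshift.optimiser import InfeasibleError, build_weights, objective
from tests.conftest import make_food_table


class TestBuildWeights:
    def test_uniform_inputs_normalise_to_one(self):
        w = build_weights([-0.8] * 4, [0.25] * 4)
        np.testing.assert_allclose(w, 1.0)

    def test_hand_computed_example(self):
        w = build_weights([-0.5, -1.0], [0.5, 0.5])
        np.testing.assert_allclose(w, [4 / 3, 2 / 3])

    def test_monotone_in_share(self):
        base = build_weights([-1.0, -1.0], [0.5, 0.5])
        shifted = build_weights([-1.0, -1.0], [2 / 3, 1 / 3])
        assert shifted[0] / shifted[1] > base[0] / base[1]

    def test_monotone_in_elasticity(self):
        w = build_weights([-0.5, -1.5], [0.5, 0.5])
        assert w[0] > w[1]  # less price-responsive food is harder to change

    def test_zero_elasticity_rejected(self):
        with pytest.raises(ValueError):
            build_weights([0.0, -1.0], [0.5, 0.5])


class TestObjective:
    def test_identity_is_zero(self):
        c = np.array([10.0, 20.0])
        assert objective(c, c, np.ones(2)) == 0.0

    def test_ten_percent_deviation(self):
        c = np.array([50.0])
        assert objective(1.1 * c, c, np.ones(1)) == pytest.approx(100.0)

    def test_weighted_two_group_example(self):
        c = np.array([100.0, 100.0])
        x = np.array([110.0, 80.0])
        assert objective(x, c, np.array([2.0, 1.0])) == pytest.approx(600.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            objective(np.array([1.0]), np.array([0.0]), np.ones(1))


def _two_food_problem():
    table = make_food_table(
        [100.0, 100.0], [1.0, 1.0],
        extra_nutrients={"prot": [1.0, 0.0]},
    )
    cons = ds.NutrientConstraintSet(
        bounds=[ds.NutrientBound("prot", lower=120.0)],
        liquid_proportion_equality=False,
    )
    return table, cons


def _grid_oracle_2food(table, cons):
    """Enumerate the energy-equality line densely and pick the best diet."""
    c = table.consumption("male")
    total = c.sum()  # unit energy density: equality pins total mass
    x1 = np.linspace(0.0, total, 40001)
    x2 = total - x1
    feasible = (x1 >= 120.0) & (x2 >= 0.0)
    w = np.ones(2)
    obj = [objective(np.array([a, b]), c, w) for a, b in
           zip(x1[feasible], x2[feasible])]
    k = int(np.argmin(obj))
    return np.array([x1[feasible][k], x2[feasible][k]])


class TestGridOracles:
    def test_two_food_equality_plus_bound(self):
        table, cons = _two_food_problem()
        oracle = _grid_oracle_2food(table, cons)
        np.testing.assert_allclose(oracle, [120.0, 80.0], atol=0.01)
        scen = ds.optimise_diet(table, cons, None, "male", n_starts=4, seed=0)
        c = table.consumption("male")
        assert np.abs(scen.x - oracle).max() / c.max() < 0.005

    def test_three_food_with_ghg_target(self):
        table = make_food_table(
            [100.0, 150.0, 80.0],
            [2.0, 1.0, 3.0],
            ghg=[0.005, 0.002, 0.001],
            elasticity=[-0.6, -1.0, -1.2],
            share=[0.4, 0.35, 0.25],
        )
        cons = ds.NutrientConstraintSet(liquid_proportion_equality=False)
        target = 0.2
        c = table.consumption("male")
        e = np.array([2.0, 1.0, 3.0])
        g = np.array([0.005, 0.002, 0.001])
        w = build_weights(table.for_sex("male")["elasticity"],
                          table.for_sex("male")["share"])
        E0, cap = float(e @ c), (1 - target) * float(g @ c)

        def grid_best(lo, hi, n=200):
            x1 = np.linspace(lo[0], hi[0], n)
            x2 = np.linspace(lo[1], hi[1], n)
            best, best_obj = None, np.inf
            for a in x1:
                x3 = (E0 - e[0] * a - e[1] * x2) / e[2]
                ok = (x3 >= 0) & (x2 >= 0) & (a >= 0) & \
                     (g[0] * a + g[1] * x2 + g[2] * x3 <= cap + 1e-12)
                for b, cc in zip(x2[ok], x3[ok]):
                    o = objective(np.array([a, b, cc]), c, w)
                    if o < best_obj:
                        best, best_obj = np.array([a, b, cc]), o
            return best

        # coarse 200x200 grid, then a refined 200x200 pass around the best
        coarse = grid_best(np.zeros(2), 2 * c[:2])
        # refine over a +-4-cell window: the active GHG constraint leaves
        # only sparsely aligned coarse grid points near the optimum
        span = 4 * 2 * c[:2] / 199
        oracle = grid_best(np.maximum(coarse[:2] - span, 0),
                           coarse[:2] + span)

        scen = ds.optimise_diet(table, cons, target, "male", n_starts=4, seed=0)
        assert (np.abs(scen.x - oracle) / c).max() < 0.005
        assert scen.achieved_reduction >= target - 1e-6


def _six_food_problem():
    table = make_food_table(
        [300.0, 200.0, 150.0, 100.0, 80.0, 500.0],
        [2.5, 0.6, 0.3, 2.0, 3.0, 0.05],
        tags=["other", "fruit", "vegetable", "red_meat", "other", "other"],
        liquid=[False] * 5 + [True],
        ghg=[0.001, 0.0023, 0.0014, 0.022, 0.003, 0.0003],
        elasticity=[-0.4, -0.9, -1.1, -0.7, -1.3, -0.5],
        share=[0.25, 0.15, 0.1, 0.25, 0.15, 0.1],
    )
    cons = ds.NutrientConstraintSet(fruit_veg_min=400.0)
    return table, cons


class TestOptimiseDiet:
    def test_unconstrained_minimum_is_baseline(self):
        table, _ = _six_food_problem()
        cons = ds.NutrientConstraintSet(
            energy_equality=False, liquid_proportion_equality=False)
        scen = ds.optimise_diet(table, cons, None, "male", n_starts=2, seed=0)
        np.testing.assert_allclose(scen.x, table.consumption("male"), rtol=1e-4)
        assert scen.objective_value < 1e-6

    def test_target_inequality_feasibility(self):
        table, cons = _six_food_problem()
        scen = ds.optimise_diet(table, cons, 0.2, "male", n_starts=4, seed=0)
        assert scen.converged
        assert scen.achieved_reduction >= 0.2 - 1e-6
        assert not scen.constraint_report["violated"].any()

    def test_reordering_invariance(self):
        table, cons = _six_food_problem()
        scen = ds.optimise_diet(table, cons, 0.2, "male", n_starts=2, seed=0)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = ds.FoodGroupTable(
            table.data.iloc[perm].reset_index(drop=True), table.nutrient_names)
        scen_p = ds.optimise_diet(shuffled, cons, 0.2, "male", n_starts=2, seed=0)
        # map the permuted solution back to the original group order
        inv = np.argsort(perm)
        np.testing.assert_allclose(scen_p.x[inv], scen.x, rtol=1e-4, atol=1e-6)

    def test_weight_rescaling_invariance(self):
        table, cons = _six_food_problem()
        sub = table.for_sex("male")
        w = build_weights(sub["elasticity"].to_numpy(), sub["share"].to_numpy())
        a = ds.optimise_diet(table, cons, 0.2, "male", n_starts=2, seed=0,
                             weights=w)
        b = ds.optimise_diet(table, cons, 0.2, "male", n_starts=2, seed=0,
                             weights=7.0 * w)
        np.testing.assert_allclose(a.x, b.x, rtol=1e-4, atol=1e-6)

    def test_multi_start_agreement(self):
        # convex problem: different start seeds must land on the same point
        table, cons = _six_food_problem()
        sols = [ds.optimise_diet(table, cons, 0.3, "male", n_starts=3, seed=s).x
                for s in (0, 7, 99)]
        for s in sols[1:]:
            np.testing.assert_allclose(s, sols[0], rtol=1e-4, atol=1e-6)

    def test_infeasible_set_names_culprit(self):
        table, _ = _two_food_problem()
        cons = ds.NutrientConstraintSet(
            bounds=[ds.NutrientBound("prot", lower=1e6)],
            liquid_proportion_equality=False,
        )
        with pytest.raises(InfeasibleError, match="nutrient:prot"):
            ds.optimise_diet(table, cons, None, "male", n_starts=2, seed=0)


class TestEvaluateConstraints:
    def test_baseline_equality_slacks_zero(self, inputs):
        food = inputs.food
        c = food.consumption("male")
        report = ds.evaluate_constraints(c, food, "male", inputs.constraints)
        eq = report[report["kind"] == "eq"]
        assert (eq["slack"].abs() < 1e-9).all()

    def test_baseline_violates_ghg_target(self, inputs):
        food = inputs.food
        c = food.consumption("male")
        report = ds.evaluate_constraints(c, food, "male", inputs.constraints,
                                         ghg_target=0.10)
        row = report[report["name"].str.startswith("ghg_target")].iloc[0]
        baseline_total = ds.diet_emissions(c, food, "male").total
        assert row["violated"]
        assert row["slack"] == pytest.approx(-0.10 * baseline_total, rel=1e-9)

    def test_optimised_diet_clean_report(self, sweep):
        for row in sweep.rows:
            assert row.ok, f"target {row.target}: {row.error}"
            for scen in row.scenarios.values():
                assert not scen.constraint_report["violated"].any()


def test_scenario_json_round_trip(tmp_path):
    table, cons = _six_food_problem()
    scen = ds.optimise_diet(table, cons, 0.2, "male", n_starts=2, seed=0)
    path = tmp_path / "scenario.json"
    scen.to_json(path)
    back = ds.DietScenario.from_json(path)
    np.testing.assert_allclose(back.x, scen.x)
    assert back.sex == scen.sex
    assert back.achieved_reduction == pytest.approx(scen.achieved_reduction)
    pd.testing.assert_frame_equal(back.constraint_report, scen.constraint_report)
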