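"""Constrained optimisation of average dietary patterns.

The optimiser searches for the consumption vector closest to the current
diet — in welfare-weighted squared-percentage terms — that satisfies the
nutritional constraints and, optionally, a greenhouse-gas reduction
target.  "Closest" reflects how unwilling consumers are to modify each
food group: deviations are weighted by the group's expenditure share
divided by the magnitude of its own-price elasticity, so large-share,
price-inelastic foods are the hardest to change.

The objective is convex quadratic and all constraints are linear in the
consumption vector (percent-of-energy bounds become linear because total
energy is held at its baseline value), so the problem is a convex QP.  It
is solved with SLSQP from multiple deterministic starting points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, minimize

from . import ghg
from .tables import FoodGroupTable, NutrientConstraintSet

#: Relative feasibility tolerance on constraints.
CONSTRAINT_RTOL = 1e-6


class InfeasibleError(RuntimeError):
    """No diet satisfies the constraint set; names the worst constraint."""


class ConvergenceError(RuntimeError):
    """The solver failed to converge after all restarts."""


# ---------------------------------------------------------------------------
# Welfare weights and objective
# ---------------------------------------------------------------------------

def build_weights(elasticities: np.ndarray, shares: np.ndarray) -> np.ndarray:
    """Welfare weights from price elasticities and expenditure shares.

    ``w_i = s_i / |e_i|``, normalised to mean 1.  The weight grows with the
    group's share of spending and shrinks with its price responsiveness.
    """
    e = np.asarray(elasticities, float)
    s = np.asarray(shares, float)
    if (e == 0).any():
        raise ValueError("zero price elasticity: weight undefined")
    if (e > 0).any():
        raise ValueError("price elasticities must be negative")
    if (s <= 0).any():
        raise ValueError("expenditure shares must be positive")
    w = s / np.abs(e)
    return w / w.mean()


def objective(x: np.ndarray, c: np.ndarray, w: np.ndarray) -> float:
    """Welfare-weighted sum of squared percentage deviations from baseline."""
    x = np.asarray(x, float)
    c = np.asarray(c, float)
    w = np.asarray(w, float)
    if (c <= 0).any():
        raise ValueError("baseline consumption must be strictly positive")
    if not (x.shape == c.shape == w.shape):
        raise ValueError("vectors are not conformable")
    pct = 100.0 * (x - c) / c
    return float((w * pct * pct).sum())


# ---------------------------------------------------------------------------
# Linear constraint assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Row:
    """One linear constraint lb <= a.x <= ub (lb == ub for equalities)."""

    name: str
    a: np.ndarray
    lb: float
    ub: float

    @property
    def is_equality(self) -> bool:
        return self.lb == self.ub


def _constraint_rows(
    table: FoodGroupTable,
    sex: str,
    cons: NutrientConstraintSet,
    ghg_target: float | None,
    ghg_variant: str = "central",
) -> list[_Row]:
    sub = table.for_sex(sex)
    c = sub["consumption"].to_numpy(float)
    n = len(c)
    nut = table.nutrient_matrix(sex)
    rows: list[_Row] = []

    energy_per_g = nut[cons.energy_nutrient].to_numpy(float)
    baseline_energy = float(energy_per_g @ c)

    if cons.energy_equality:
        rows.append(_Row("energy_equality", energy_per_g, baseline_energy, baseline_energy))

    if cons.liquid_proportion_equality:
        liquid = sub["liquid"].to_numpy(bool).astype(float)
        p0 = float((liquid * c).sum() / c.sum())
        # liquid mass share fixed at baseline: sum_L x - p0 * sum x = 0
        rows.append(_Row("liquid_proportion", liquid - p0, 0.0, 0.0))

    for b in cons.bounds:
        a = nut[b.nutrient].to_numpy(float).copy()
        lo, hi = b.lower, b.upper
        if b.percent_energy:
            # percent of (fixed) baseline energy -> absolute energy bound
            a = a * b.energy_per_g
            lo = None if lo is None else lo / 100.0 * baseline_energy
            hi = None if hi is None else hi / 100.0 * baseline_energy
        rows.append(_Row(
            f"nutrient:{b.nutrient}", a,
            -np.inf if lo is None else lo,
            np.inf if hi is None else hi,
        ))

    if cons.fruit_veg_min is not None:
        mask = sub["exposure_tag"].isin(["fruit", "vegetable"]).to_numpy().astype(float)
        rows.append(_Row("fruit_veg_min", mask, float(cons.fruit_veg_min), np.inf))

    if ghg_target is not None:
        g = table.ghg_intensity(sex, ghg_variant)
        cap = (1.0 - ghg_target) * float(g @ c)
        rows.append(_Row(f"ghg_target:{ghg_target:g}", g, -np.inf, cap))

    assert all(r.a.shape == (n,) for r in rows)
    return rows


def _row_scale(row: _Row, c: np.ndarray) -> float:
    """Magnitude used for relative slack: the larger of the bound and the
    baseline scale of the constrained quantity (absolute coefficients, so
    rows that cancel exactly at baseline still get a meaningful scale)."""
    return max(abs(float(np.abs(row.a) @ c)),
               abs(row.lb) if np.isfinite(row.lb) else 0.0,
               abs(row.ub) if np.isfinite(row.ub) else 0.0,
               1e-9)


def evaluate_constraints(
    x: np.ndarray,
    table: FoodGroupTable,
    sex: str,
    cons: NutrientConstraintSet,
    ghg_target: float | None = None,
    ghg_variant: str = "central",
    rtol: float = CONSTRAINT_RTOL,
) -> pd.DataFrame:
    """Signed slack report for every constraint at the diet ``x``.

    Columns: constraint name, kind, achieved value, lower/upper bound,
    slack (minimum signed distance into the feasible side, negative when
    violated), relative violation and a boolean flag beyond ``rtol``.
    Non-negativity of the diet vector is reported as a single summary row.
    """
    x = np.asarray(x, float)
    sub = table.for_sex(sex)
    c = sub["consumption"].to_numpy(float)
    rows = _constraint_rows(table, sex, cons, ghg_target, ghg_variant)

    records = []
    for r in rows:
        val = float(r.a @ x)
        scale = _row_scale(r, c)
        if r.is_equality:
            slack = -abs(val - r.lb)
        else:
            slack = min(val - r.lb if np.isfinite(r.lb) else np.inf,
                        r.ub - val if np.isfinite(r.ub) else np.inf)
        rel = max(0.0, -slack) / scale
        records.append({
            "name": r.name,
            "kind": "eq" if r.is_equality else "ineq",
            "value": val,
            "lower": r.lb,
            "upper": r.ub,
            "slack": slack,
            "rel_violation": rel,
            "violated": rel > rtol,
        })

    neg = np.minimum(x, 0.0)
    records.append({
        "name": "non_negativity", "kind": "bound",
        "value": float(x.min()), "lower": 0.0, "upper": np.inf,
        "slack": float(neg.min()),
        "rel_violation": float(-neg.min() / max(c.max(), 1e-9)),
        "violated": bool((neg < -rtol * c.max()).any()),
    })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Scenarios and the solver
# ---------------------------------------------------------------------------

@dataclass
class DietScenario:
    """An optimised diet for one sex, with diagnostics."""

    sex: str
    group_ids: list[str]
    x: np.ndarray
    target_reduction: float | None
    achieved_reduction: float
    objective_value: float
    converged: bool
    constraint_report: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sex": self.sex,
            "group_ids": list(self.group_ids),
            "x": [float(v) for v in self.x],
            "target_reduction": self.target_reduction,
            "achieved_reduction": self.achieved_reduction,
            "objective_value": self.objective_value,
            "converged": self.converged,
            "constraint_report": self.constraint_report.replace(
                {np.inf: "inf", -np.inf: "-inf"}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DietScenario":
        payload = json.loads(Path(path).read_text())
        report = pd.DataFrame(payload["constraint_report"])
        for col in ("value", "lower", "upper", "slack", "rel_violation"):
            report[col] = report[col].map(
                lambda v: np.inf if v == "inf"
                else -np.inf if v == "-inf" else float(v))
        return cls(
            sex=payload["sex"],
            group_ids=payload["group_ids"],
            x=np.asarray(payload["x"], float),
            target_reduction=payload["target_reduction"],
            achieved_reduction=payload["achieved_reduction"],
            objective_value=payload["objective_value"],
            converged=payload["converged"],
            constraint_report=report,
        )


def optimise_diet(
    table: FoodGroupTable,
    cons: NutrientConstraintSet,
    ghg_target: float | None,
    sex: str,
    ghg_variant: str = "central",
    n_starts: int = 8,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> DietScenario:
    """Solve the diet problem for one sex.

    The search runs in units of the baseline diet (``u = x / c``), which
    keeps the quadratic well conditioned.  Because the objective is a
    diagonal quadratic and every constraint is linear, the problem is a
    convex QP; it is solved with the trust-region interior method
    (``trust-constr``) using analytic gradient and Hessian, from the
    baseline plus ``n_starts - 1`` deterministic perturbed starts seeded
    by ``seed`` (the starts must agree on a convex problem; keeping them
    is a cheap safeguard and feeds the multi-start agreement checks).
    Raises :class:`InfeasibleError` when no run finds a feasible point and
    :class:`ConvergenceError` when no run converges.
    """
    sub = table.for_sex(sex)
    c = sub["consumption"].to_numpy(float)
    n = len(c)
    w = build_weights(sub["elasticity"].to_numpy(float), sub["share"].to_numpy(float)) \
        if weights is None else np.asarray(weights, float)

    rows = _constraint_rows(table, sex, cons, ghg_target, ghg_variant)
    scales = np.array([_row_scale(r, c) for r in rows])

    # u-space objective: sum w (100 (u - 1))^2
    hess_diag = np.diag(2e4 * w)

    def fun(u: np.ndarray) -> float:
        d = u - 1.0
        return float(1e4 * (w * d * d).sum())

    def jac(u: np.ndarray) -> np.ndarray:
        return 2e4 * w * (u - 1.0)

    constraints = []
    if rows:
        A = np.vstack([r.a * c / sc for r, sc in zip(rows, scales)])
        lb = np.array([r.lb / sc for r, sc in zip(rows, scales)])
        ub = np.array([r.ub / sc for r, sc in zip(rows, scales)])
        constraints = [LinearConstraint(A, lb, ub)]

    rng = np.random.default_rng(seed)
    starts = [np.ones(n)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(1.0 + rng.uniform(-0.5, 0.5, size=n), 0.01, None))

    best = None
    any_converged = False
    for u0 in starts:
        with warnings.catch_warnings():
            # trust-constr warns about singular Jacobians on degenerate /
            # infeasible active sets; it falls back to SVD and carries on
            warnings.filterwarnings("ignore", message="Singular Jacobian")
            res = minimize(
                fun, u0, jac=jac, hess=lambda u: hess_diag, method="trust-constr",
                bounds=Bounds(np.zeros(n), np.full(n, np.inf)),
                constraints=constraints,
                options={"maxiter": 3000, "gtol": 1e-10, "xtol": 1e-12},
            )
        if res.status not in (1, 2):  # gradient / step-size convergence
            continue
        any_converged = True
        x = np.clip(res.x, 0.0, None) * c
        report = evaluate_constraints(x, table, sex, cons, ghg_target, ghg_variant)
        feasible = not report["violated"].any()
        if feasible and (best is None or res.fun < best[0]):
            best = (res.fun, x, report)

    if best is None:
        # Diagnose: minimise the worst relative violation to name the culprit.
        report = _infeasibility_report(table, sex, cons, ghg_target, ghg_variant)
        worst = report.sort_values("rel_violation", ascending=False).iloc[0]
        if worst["rel_violation"] > CONSTRAINT_RTOL:
            raise InfeasibleError(
                f"no feasible diet for sex={sex!r}, target={ghg_target}; "
                f"most violated constraint: {worst['name']} "
                f"(relative violation {worst['rel_violation']:.3g})")
        if not any_converged:
            raise ConvergenceError(
                f"SLSQP failed to converge from all {len(starts)} starts "
                f"for sex={sex!r}, target={ghg_target}")
        raise ConvergenceError(
            f"no feasible solution retained for sex={sex!r}, target={ghg_target}")

    _, x, report = best
    base_em = ghg.diet_emissions(c, table, sex, ghg_variant)
    scen_em = ghg.diet_emissions(x, table, sex, ghg_variant)
    return DietScenario(
        sex=sex,
        group_ids=list(sub["group_id"]),
        x=x,
        target_reduction=ghg_target,
        achieved_reduction=ghg.achieved_reduction(base_em, scen_em),
        objective_value=objective(x, c, w),
        converged=True,
        constraint_report=report,
    )


def _infeasibility_report(
    table: FoodGroupTable,
    sex: str,
    cons: NutrientConstraintSet,
    ghg_target: float | None,
    ghg_variant: str,
) -> pd.DataFrame:
    """Constraint report at the point minimising total relative violation."""
    sub = table.for_sex(sex)
    c = sub["consumption"].to_numpy(float)
    rows = _constraint_rows(table, sex, cons, ghg_target, ghg_variant)
    scales = np.array([_row_scale(r, c) for r in rows])

    def total_violation(u: np.ndarray) -> float:
        x = u * c
        v = 0.0
        for r, sc in zip(rows, scales):
            val = float(r.a @ x)
            if r.is_equality:
                v += (abs(val - r.lb) / sc) ** 2
            else:
                if np.isfinite(r.lb):
                    v += (max(0.0, r.lb - val) / sc) ** 2
                if np.isfinite(r.ub):
                    v += (max(0.0, val - r.ub) / sc) ** 2
        return v

    res = minimize(total_violation, np.ones(len(c)), method="L-BFGS-B",
                   bounds=[(0.0, None)] * len(c), options={"maxiter": 2000})
    return evaluate_constraints(np.clip(res.x, 0, None) * c, table, sex, cons,
                                ghg_target, ghg_variant)
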