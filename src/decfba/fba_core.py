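"""Steady-state flux balance analysis with an aggregate enzyme-pool constraint.

The LP solved here is

    max  v_obj
    s.t. S v = 0
         lb <= v <= ub
         sum_i a_i v_i <= P

where ``a_i`` is the enzyme cost of reaction ``i`` (g gCDW^-1 per unit flux)
and ``P`` the total enzyme mass budget. With a huge ``P`` this reduces to
plain FBA. An optional parsimonious second solve (minimize total absolute
flux at fixed optimal growth) stabilizes the flux distribution among
alternate optima, which matters when enzyme composition is read off the flux
vector between time steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel

__all__ = ["FluxSolution", "solve_fba", "FEASIBILITY_TOLERANCE"]

# glpk's default feasibility tolerance (1e-6) produces numerical artifacts
# once flux upper bounds are derived from interpolated enzyme compositions;
# 1e-9 avoids them.
FEASIBILITY_TOLERANCE = 1e-9

BoundOverrides = dict[str, tuple[float | None, float | None]]


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    v: np.ndarray          # flux per reaction, mmol gCDW^-1 h^-1
    mu: float              # objective value = growth rate, h^-1
    status: str            # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _apply_overrides(
    model: MetabolicModel, overrides: BoundOverrides | None
) -> tuple[np.ndarray, np.ndarray]:
    lb = model.lb.copy()
    ub = model.ub.copy()
    if overrides:
        for rid, (lo, hi) in overrides.items():
            j = model.reaction_index(rid)
            if lo is not None:
                lb[j] = lo
            if hi is not None:
                ub[j] = hi
    if np.any(lb > ub):
        # can legitimately happen when a composition-derived ub undercuts a
        # configured lb; treat as an empty feasible region, not a crash
        bad = lb > ub
        mid = np.where(bad, np.minimum(lb, ub), lb)
        return mid, np.where(bad, mid, ub)
    return lb, ub


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds, tol):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": tol,
            "dual_feasibility_tolerance": tol,
        },
    )


def solve_fba(
    model: MetabolicModel,
    bound_overrides: BoundOverrides | None = None,
    pfba: bool = False,
    feasibility_tolerance: float = FEASIBILITY_TOLERANCE,
) -> FluxSolution:
    """Maximize the biomass objective under mass balance, bounds and pool.

    Parameters
    ----------
    bound_overrides
        ``{reaction_id: (lb, ub)}``; ``None`` entries keep the model bound.
    pfba
        If True, a second LP minimizes total absolute flux at the optimal
        growth rate, picking a canonical representative among alternate
        optima. ``mu`` and exchange fluxes are the reproducible outputs;
        internal fluxes of non-parsimonious solves may vary between solvers.
    """
    n = model.n_reactions
    lb, ub = _apply_overrides(model, bound_overrides)
    c = np.zeros(n)
    c[model.objective_index] = -1.0  # linprog minimizes
    A_pool = model.enzyme_cost.reshape(1, -1)
    b_pool = np.array([model.pool])

    res = _linprog(c, A_pool, b_pool, model.S, np.zeros(model.n_metabolites),
                   list(zip(lb, ub)), feasibility_tolerance)
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(v=np.zeros(n), mu=0.0, status=status)
    mu = float(-res.fun)
    v = np.asarray(res.x)

    if pfba:
        v2 = _parsimonious(model, lb, ub, mu, feasibility_tolerance)
        if v2 is not None:
            v = v2
    return FluxSolution(v=v, mu=mu, status="optimal")


def _parsimonious(model, lb, ub, mu, tol) -> np.ndarray | None:
    """Minimize sum |v_i| subject to the original constraints and v_obj >= mu.

    Split formulation: variables (v, t), minimize sum t with t >= |v|.
    Returns None if the second solve fails (the first solution is kept).
    """
    n = model.n_reactions
    m = model.n_metabolites
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([model.S, np.zeros((m, n))])
    I = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([model.enzyme_cost.reshape(1, -1), np.zeros((1, n))]),
            np.hstack([I, -I]),    # v - t <= 0
            np.hstack([-I, -I]),   # -v - t <= 0
        ]
    )
    b_ub = np.concatenate([[model.pool], np.zeros(2 * n)])
    # hold growth at the optimum (tiny relaxation guards round-off)
    obj_row = np.zeros(2 * n)
    obj_row[model.objective_index] = -1.0
    A_ub = np.vstack([A_ub, obj_row])
    b_ub = np.append(b_ub, -mu * (1 - 1e-9) if mu >= 0 else -mu * (1 + 1e-9))
    bounds = list(zip(lb, ub)) + [(0, None)] * n
    res = _linprog(c, A_ub, b_ub, A_eq, np.zeros(m), bounds, tol)
    if res.status != 0:
        return None
    return np.asarray(res.x[:n])
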