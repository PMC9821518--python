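"""Enzyme-composition tracking and the enzyme change constraint (ecc).

A cell cannot re-build its proteome instantaneously. The ecc limits how much
enzyme mass may be *newly allocated* per unit time to a rate gamma
(g gCDW^-1 h^-1). Between SOA time steps the procedure is:

1. Solve the unconstrained ec-FBA problem for the step.
2. Read the optimal enzyme composition off the fluxes, m_o,i = a_i * v_i
   (the model is assumed to dedicate exactly the enzyme mass each flux
   requires, no more).
3. Compare with the stored composition m_{t-1}; the reallocation demand is
   the sum of the positive entries of m_o - m_{t-1}.
4. If the demand fits within the per-step budget gamma*dt, adopt m_o.
5. Otherwise interpolate, m_t = alpha*m_o + (1-alpha)*m_{t-1} with
   alpha = gamma*dt / demand, convert m_t into per-reaction flux upper
   bounds ub_i = m_t,i / a_i, and re-solve under those bounds.

gamma sentinels: -1 leaves composition unconstrained (plain decFBA);
0 freezes the composition entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fba_core import BoundOverrides, FluxSolution, solve_fba
from .model_io import MetabolicModel

__all__ = [
    "EnzymeState",
    "EccPolicy",
    "composition_from_flux",
    "composition_difference",
    "interpolation_alpha",
    "interpolate_composition",
    "bounds_from_composition",
    "ecc_step",
]

logger = logging.getLogger(__name__)


@dataclass
class EnzymeState:
    """Enzyme mass per reaction slot (g gCDW^-1) at simulation time t (h)."""

    m: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.m.sum())


@dataclass(frozen=True)
class EccPolicy:
    """Enzyme change constraint configuration.

    gamma : rate limit in g gCDW^-1 h^-1. Sentinels: -1 = composition free
    (no tracking constraint), 0 = composition frozen.

    signed_denominator : if True, alpha's denominator is the plain sum of the
    difference vector rather than the sum of its positive part. The positive
    part is the default: a signed sum can leave [0, 1] when much enzyme mass
    is being released, which breaks the interpolation's meaning.
    """

    gamma: float
    signed_denominator: bool = False

    def __post_init__(self) -> None:
        if self.gamma != -1 and self.gamma < 0:
            raise ValueError(
                f"gamma must be -1 (unconstrained) or >= 0, got {self.gamma}"
            )

    @property
    def unconstrained(self) -> bool:
        return self.gamma == -1


def composition_from_flux(model: MetabolicModel, v: np.ndarray) -> EnzymeState:
    """Enzyme mass implied by a flux vector: m_i = a_i * v_i.

    Zero for cost-free reactions. Tiny negative fluxes on cost-bearing
    reactions (solver round-off below the feasibility tolerance) are
    truncated to zero; anything larger is a sign error in the model.
    """
    v = np.asarray(v, dtype=float)
    m = model.enzyme_cost * v
    if np.any(m < -1e-6):
        j = int(np.argmin(m))
        raise ValueError(
            f"negative enzyme mass for reaction {model.reaction_ids[j]!r} "
            f"(flux {v[j]:g}, cost {model.enzyme_cost[j]:g}); cost-bearing "
            "reactions must carry non-negative flux"
        )
    return EnzymeState(m=np.maximum(m, 0.0))


def composition_difference(
    m_target: np.ndarray | EnzymeState, m_prev: np.ndarray | EnzymeState
) -> tuple[np.ndarray, float]:
    """Difference vector m_d = m_o - m_{t-1} and the reallocation demand.

    The demand is the sum of the positive entries of m_d: the mass of enzyme
    that must be newly built (released mass is free).
    """
    mo = m_target.m if isinstance(m_target, EnzymeState) else np.asarray(m_target, float)
    mp = m_prev.m if isinstance(m_prev, EnzymeState) else np.asarray(m_prev, float)
    m_d = mo - mp
    demand = float(np.clip(m_d, 0.0, None).sum())
    return m_d, demand


def interpolation_alpha(demand: float, gamma: float, dt: float) -> float:
    """Fraction of the composition change realizable this step.

    The per-step budget is gamma*dt; alpha = 1 when the demand fits,
    otherwise gamma*dt / demand. Zero demand always yields alpha = 1.
    """
    if demand < 0:
        raise ValueError("demand must be non-negative")
    if gamma < 0:
        raise ValueError("gamma must be non-negative here (sentinel -1 is handled upstream)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    budget = gamma * dt
    if demand <= budget:
        return 1.0
    return budget / demand


def interpolate_composition(
    m_target: EnzymeState, m_prev: EnzymeState, alpha: float
) -> EnzymeState:
    """Convex combination m_t = alpha*m_o + (1-alpha)*m_{t-1}."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return EnzymeState(m=alpha * m_target.m + (1.0 - alpha) * m_prev.m, t=m_target.t)


def bounds_from_composition(
    model: MetabolicModel, m: np.ndarray | EnzymeState
) -> BoundOverrides:
    """Flux upper bounds implied by an enzyme composition: ub_i = m_i / a_i.

    Only cost-bearing reactions are bounded; m_i = 0 disables the reaction.
    """
    marr = m.m if isinstance(m, EnzymeState) else np.asarray(m, float)
    overrides: BoundOverrides = {}
    for j, rid in enumerate(model.reaction_ids):
        a = model.enzyme_cost[j]
        if a > 0:
            overrides[rid] = (None, marr[j] / a)
        elif marr[j] > 1e-12:
            raise ValueError(
                f"reaction {rid!r} has enzyme mass {marr[j]:g} but zero cost; "
                "composition and cost vector are inconsistent"
            )
    return overrides


@dataclass
class EccStepDiagnostics:
    """Per-step bookkeeping for the interpolate-and-resolve procedure."""

    alpha: float = 1.0
    demand: float = 0.0
    constrained: bool = False
    # gap between stored capacity m_t and the mass implied by realized fluxes
    capacity_usage_gap: float = 0.0


def ecc_step(
    model: MetabolicModel,
    m_prev: EnzymeState | None,
    policy: EccPolicy,
    dt: float,
    bound_overrides: BoundOverrides | None = None,
    pfba: bool = False,
) -> tuple[FluxSolution, EnzymeState, EccStepDiagnostics]:
    """One SOA step under the enzyme change constraint.

    ``m_prev=None`` marks the first step: the composition is initialized from
    the unconstrained optimum (a culture pre-adapted to its initial
    substrate), so the constraint never binds at t=0.

    After a constrained step the stored state is the interpolated *capacity*
    vector m_t, not the composition implied by the re-solve's fluxes; the
    discrepancy is reported in the diagnostics.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    diag = EccStepDiagnostics()

    sol = solve_fba(model, bound_overrides, pfba=pfba)
    if not sol.optimal:
        m_t = m_prev if m_prev is not None else EnzymeState(np.zeros(model.n_reactions))
        return sol, m_t, diag
    m_o = composition_from_flux(model, sol.v)

    if policy.unconstrained or m_prev is None:
        return sol, m_o, diag

    m_d, demand = composition_difference(m_o, m_prev)
    diag.demand = demand
    budget = policy.gamma * dt
    if demand <= budget:
        return sol, m_o, diag

    denom = float(m_d.sum()) if policy.signed_denominator else demand
    if denom <= 0:
        alpha = 1.0
    else:
        alpha = min(budget / denom, 1.0)
    diag.alpha = alpha
    diag.constrained = True

    m_t = interpolate_composition(m_o, m_prev, alpha)
    capacity_bounds = bounds_from_composition(model, m_t)
    merged: BoundOverrides = dict(bound_overrides or {})
    for rid, (_, cap_ub) in capacity_bounds.items():
        lo, hi = merged.get(rid, (None, None))
        hi = cap_ub if hi is None else min(hi, cap_ub)
        merged[rid] = (lo, hi)
    sol2 = solve_fba(model, merged, pfba=pfba)
    if sol2.optimal:
        used = composition_from_flux(model, sol2.v)
        diag.capacity_usage_gap = float(np.abs(m_t.m - used.m).sum())
        if diag.capacity_usage_gap > 1e-6:
            logger.debug(
                "capacity-vs-usage gap %.3g g/gCDW at alpha=%.3g",
                diag.capacity_usage_gap, alpha,
            )
    return sol2, m_t, diag
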