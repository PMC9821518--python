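"""The SOA time loop: batch-reactor state propagation around FBA solves.

Each step translates the current medium into exchange-flux bounds, solves
one FBA problem (plain, enzyme-constrained, or enzyme-change-constrained),
and propagates biomass and medium concentrations forward by forward Euler:

    c_k(t+dt) = c_k(t) + v_ex,k * X * dt        (tracked compounds, mM)
    X(t+dt)   = X(t) * (1 + mu * dt)            (gCDW L^-1)

Exchange fluxes follow the COBRA sign convention: negative = uptake,
positive = excretion. Compounds declared non-limiting (ions, trace minerals,
dissolved oxygen in a stirred fermentor) are never decremented; oxygen can
still be rate-limited through its exchange lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecc_engine import EccPolicy, EccStepDiagnostics, EnzymeState, ecc_step
from .fba_core import BoundOverrides, FluxSolution
from .feedback import excretion_bound
from .model_io import MetabolicModel, set_pool

__all__ = ["ReactorState", "Trajectory", "uptake_caps_from_medium", "advance_state", "run_simulation"]

logger = logging.getLogger(__name__)

# pool size that effectively removes the enzyme constraint (plain dFBA)
UNCONSTRAINED_POOL = 5000.0


@dataclass
class ReactorState:
    """Batch reactor snapshot."""

    t: float                      # h
    X: float                      # biomass density, gCDW L^-1
    V: float                      # working volume, L
    conc: dict[str, float]        # compound -> mmol L^-1
    nonlimiting: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.X < 0:
            raise ValueError("biomass density must be non-negative")
        for k, v in self.conc.items():
            if v < 0:
                raise ValueError(f"negative concentration for {k!r}: {v}")
        self.nonlimiting = frozenset(self.nonlimiting)

    def copy(self) -> "ReactorState":
        return ReactorState(self.t, self.X, self.V, dict(self.conc), self.nonlimiting)


@dataclass
class Trajectory:
    """Time-indexed record of reactor state, fluxes and enzyme composition."""

    model: MetabolicModel
    states: list[ReactorState] = field(default_factory=list)
    solutions: list[FluxSolution] = field(default_factory=list)
    enzyme_states: list[EnzymeState] = field(default_factory=list)
    diagnostics: list[EccStepDiagnostics] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def biomass(self) -> np.ndarray:
        return np.array([s.X for s in self.states])

    @property
    def mu(self) -> np.ndarray:
        return np.array([s.mu for s in self.solutions])

    def concentration(self, compound: str) -> np.ndarray:
        return np.array([s.conc[compound] for s in self.states])

    def exchange_flux(self, rid: str) -> np.ndarray:
        j = self.model.reaction_index(rid)
        return np.array([s.v[j] for s in self.solutions])

    def to_dataframe(self, include_exchanges: bool = False) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "time_h": self.times,
            "biomass_gCDW_L": self.biomass,
        }
        for compound in self.states[0].conc:
            cols[f"{compound}_mM"] = self.concentration(compound)
        cols["mu_h"] = self.mu
        if include_exchanges:
            for rid in self.model.exchange_ids:
                cols[f"v_{rid}"] = self.exchange_flux(rid)
        return pd.DataFrame(cols)

    def write_csv(self, path: str, include_exchanges: bool = False) -> None:
        self.to_dataframe(include_exchanges).to_csv(path, index=False)


def uptake_caps_from_medium(
    state: ReactorState,
    model: MetabolicModel,
    dt: float,
    base_overrides: BoundOverrides | None = None,
) -> BoundOverrides:
    """Exchange lower bounds ensuring one step cannot overdraw the medium.

    For each tracked limiting compound: effective lb = max(configured lb,
    -c/(X*dt)), so uptake over the step removes at most what is present.
    The configured lb is the model bound unless *base_overrides* (the
    scenario's) replaces it. Non-limiting compounds keep configured bounds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    overrides: BoundOverrides = {}
    comp_to_ex = model.compound_to_exchange()
    for compound, c in state.conc.items():
        if compound in state.nonlimiting:
            continue
        rid = comp_to_ex.get(compound)
        if rid is None:
            continue
        configured = model.lb[model.reaction_index(rid)]
        if base_overrides and rid in base_overrides:
            lo = base_overrides[rid][0]
            if lo is not None:
                configured = lo
        cap = 0.0 if state.X == 0 else -c / (state.X * dt)
        overrides[rid] = (max(configured, cap), None)
    return overrides


def advance_state(state: ReactorState, flux: FluxSolution, model: MetabolicModel, dt: float) -> ReactorState:
    """Forward-Euler propagation of medium and biomass over one step."""
    new = state.copy()
    new.t = state.t + dt
    comp_to_ex = model.compound_to_exchange()
    for compound in state.conc:
        if compound in state.nonlimiting:
            continue
        rid = comp_to_ex.get(compound)
        if rid is None:
            continue
        v_ex = float(flux.v[model.reaction_index(rid)])
        c = state.conc[compound] + v_ex * state.X * dt
        if c < 0:
            logger.warning(
                "clipped %s at t=%.3f h: %.3g mM below zero", compound, new.t, c
            )
            c = 0.0
        new.conc[compound] = c
    new.X = state.X * (1.0 + flux.mu * dt)
    return new


def _merge_overrides(*layers: BoundOverrides | None) -> BoundOverrides:
    """Later layers win per bound component (None keeps the earlier value)."""
    merged: BoundOverrides = {}
    for layer in layers:
        if not layer:
            continue
        for rid, (lo, hi) in layer.items():
            plo, phi = merged.get(rid, (None, None))
            merged[rid] = (lo if lo is not None else plo, hi if hi is not None else phi)
    return merged


def run_simulation(model: MetabolicModel, scenario, initial_state: ReactorState) -> Trajectory:
    """Run one batch simulation in dFBA, decFBA or decFBAecc mode.

    Modes differ only in the enzyme pool and the ecc policy:
    dFBA uses a huge pool (enzyme constraint off) with composition free;
    decFBA keeps the model pool with composition free; decFBAecc keeps the
    pool and limits composition change to scenario.gamma per hour.

    An infeasible step (e.g. maintenance demand after substrate exhaustion)
    records zero growth and zero exchange fluxes and carries state forward.
    """
    scenario.validate(model)
    mode = scenario.mode
    sim_model = model
    if scenario.pool_override is not None:
        sim_model = set_pool(model, scenario.pool_override)
    elif mode == "dFBA":
        sim_model = set_pool(model, UNCONSTRAINED_POOL)

    if mode == "decFBAecc":
        policy = EccPolicy(scenario.gamma, signed_denominator=scenario.signed_denominator)
    else:
        policy = EccPolicy(-1)

    n_steps = int(round(scenario.duration / scenario.dt))
    state = initial_state.copy()
    state.nonlimiting = frozenset(scenario.nonlimiting) | state.nonlimiting
    traj = Trajectory(model=sim_model)
    m_prev: EnzymeState | None = None
    comp_to_ex = sim_model.compound_to_exchange()

    for _ in range(n_steps):
        medium_caps = uptake_caps_from_medium(
            state, sim_model, scenario.dt, scenario.bound_overrides
        )
        fb_caps: BoundOverrides = {}
        if scenario.feedback is not None:
            fb = scenario.feedback
            rid = comp_to_ex.get(fb.compound)
            if rid is not None:
                cap = excretion_bound(state.conc.get(fb.compound, 0.0), fb)
                j = sim_model.reaction_index(rid)
                hi = min(cap, sim_model.ub[j])
                over = scenario.bound_overrides.get(rid)
                if over and over[1] is not None:
                    hi = min(hi, over[1])
                fb_caps[rid] = (None, hi)
        overrides = _merge_overrides(scenario.bound_overrides, medium_caps, fb_caps)

        sol, m_t, diag = ecc_step(
            sim_model, m_prev, policy, scenario.dt, overrides, pfba=scenario.pfba
        )
        if not sol.optimal:
            # e.g. maintenance demand exceeds the current enzyme capacity:
            # growth stalls, but m_t (possibly interpolated toward the new
            # optimum) is kept so reallocation continues through the stall.
            logger.warning(
                "infeasible step at t=%.3f h (%s); freezing growth", state.t, sol.status
            )
            sol = FluxSolution(v=np.zeros(sim_model.n_reactions), mu=0.0, status=sol.status)
        m_t = EnzymeState(m=m_t.m.copy(), t=state.t)
        traj.states.append(state.copy())
        traj.solutions.append(sol)
        traj.enzyme_states.append(m_t)
        traj.diagnostics.append(diag)
        state = advance_state(state, sol, sim_model, scenario.dt)
        m_prev = m_t
    return traj
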