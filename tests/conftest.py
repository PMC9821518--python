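import itertools
import logging

import numpy as np
import pytest

from decfba import build_toy_overflow_model
from decfba.model_io import ToyParams
from decfba.reactor_dynamics import ReactorState

logging.getLogger("decfba").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_overflow_model()


@pytest.fixture(scope="session")
def toy_params():
    return ToyParams()


def initial_state(scenario) -> ReactorState:
    return ReactorState(
        t=0.0,
        X=scenario.initial_X,
        V=scenario.initial_V,
        conc=dict(scenario.medium),
        nonlimiting=frozenset(scenario.nonlimiting),
    )


def brute_force_toy_optimum(
    params: ToyParams,
    pool: float | None = None,
    glc_max: float | None = None,
    o2_max: float = 1000.0,
    ac_uptake_max: float = 0.0,
    ac_excretion_max: float = 1000.0,
    ngam: float = 0.0,
    route_caps: tuple[float, float, float] = (np.inf, np.inf, np.inf),
):
    """Vertex-enumeration oracle for the toy overflow model.

    The model's steady-state polytope reduces to the three route fluxes
    (respiration, fermentation, acetate consumption); every exchange flux
    follows by mass balance. All inequality constraints are enumerated in
    triples, each 3x3 system solved directly, feasible vertices scored by
    mu = Y.v - ngam. Independent of any LP solver.

    Returns (mu, v_routes) of the best vertex, or (-inf, None) if no
    feasible vertex exists (empty or degenerate polytope).
    """
    p = params
    P = pool if pool is not None else p.pool
    G = glc_max if glc_max is not None else p.glc_uptake_max
    Y = np.array([p.yield_resp, p.yield_ferm, p.yield_ac])
    # rows: glc supply, o2 supply, ac uptake, ac excretion, pool,
    # route caps (from enzyme capacity), non-negativity
    A = np.array(
        [
            [1.0, 1.0, 0.0],
            [p.o2_per_glc_resp, 0.0, p.o2_per_ac],
            [0.0, -p.ac_per_glc_ferm, 1.0],
            [0.0, p.ac_per_glc_ferm, -1.0],
            [p.cost_resp, p.cost_ferm, p.cost_ac],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [-1.0, 0.0, 0.0],
            [0.0, -1.0, 0.0],
            [0.0, 0.0, -1.0],
        ]
    )
    b = np.array(
        [G, o2_max, ac_uptake_max, ac_excretion_max, P,
         route_caps[0], route_caps[1], route_caps[2], 0.0, 0.0, 0.0]
    )
    finite = np.isfinite(b)
    A, b = A[finite], b[finite]
    best_mu, best_v = -np.inf, None
    for rows in itertools.combinations(range(len(b)), 3):
        Asub = A[list(rows)]
        if abs(np.linalg.det(Asub)) < 1e-12:
            continue
        v = np.linalg.solve(Asub, b[list(rows)])
        if np.all(A @ v <= b + 1e-9):
            mu = float(Y @ v) - ngam
            if mu > best_mu:
                best_mu, best_v = mu, v
    return best_mu, best_v
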