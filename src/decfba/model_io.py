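"""Loading, validation and construction of enzyme-constrained metabolic models.

An enzyme-constrained model in the sMOMENT formulation carries one extra
pseudo-metabolite row in the stoichiometric matrix whose entry for reaction
``i`` is ``-MW_i/kcat_i`` (grams of enzyme per gCDW needed to sustain one
unit of flux), plus a pool pseudo-reaction that delivers the pseudo-metabolite
with an upper bound equal to the total enzyme mass budget ``P`` (g gCDW^-1).
This module reads such models from SBML-fbc or COBRA-JSON via cobrapy,
extracts the per-reaction enzyme costs ``a_i`` (sign-flipped, so a_i >= 0)
and the pool size, and exposes a plain in-memory :class:`MetabolicModel`
that the LP and time-stepping layers operate on.

It also builds a small self-contained overflow-metabolism fixture model with
two glucose-utilization routes of different biomass yield and enzyme cost,
whose optimum is cheap to verify by exhaustive vertex enumeration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetabolicModel",
    "ModelFormatError",
    "load_model",
    "save_model",
    "set_pool",
    "build_toy_overflow_model",
    "POOL_METABOLITE_PATTERN",
    "POOL_REACTION_PATTERN",
]

# AutoPACMEN's sMOMENT convention: pseudo-metabolite "prot_pool" delivered by
# the pseudo-reaction "ER_pool_TG_". Patterns are overridable for third-party
# models that follow the same structure under different identifiers.
POOL_METABOLITE_PATTERN = r"prot_pool"
POOL_REACTION_PATTERN = r"ER_pool"


class ModelFormatError(ValueError):
    """Raised when a model file does not follow the expected convention."""


@dataclass
class MetabolicModel:
    """In-memory enzyme-constrained metabolic model.

    Parameters
    ----------
    reaction_ids, metabolite_ids
        Identifiers indexing the columns / rows of ``S``.
    S
        Stoichiometric matrix, metabolites x reactions (dimensionless).
    lb, ub
        Flux bounds per reaction (mmol gCDW^-1 h^-1).
    objective_id
        Identifier of the biomass objective reaction; its flux is the
        growth rate mu (h^-1).
    enzyme_cost
        Per-reaction enzyme cost a_i = MW_i/kcat_i (g gCDW^-1 per unit
        flux); 0 for non-enzymatic and exchange reactions.
    pool
        Total enzyme mass budget P (g gCDW^-1).
    exchange_to_compound
        Maps each exchange reaction id to its medium compound name.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective_id: str
    enzyme_cost: np.ndarray
    pool: float
    exchange_to_compound: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.enzyme_cost = np.asarray(self.enzyme_cost, dtype=float)
        self.validate()

    # -- basic queries -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id: {rid!r}") from None

    @property
    def objective_index(self) -> int:
        return self.reaction_index(self.objective_id)

    @property
    def exchange_ids(self) -> list[str]:
        return list(self.exchange_to_compound)

    def compound_to_exchange(self) -> dict[str, str]:
        return {c: r for r, c in self.exchange_to_compound.items()}

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n, m = self.n_reactions, self.n_metabolites
        if self.S.shape != (m, n):
            raise ValueError(f"S has shape {self.S.shape}, expected {(m, n)}")
        for arr, name in ((self.lb, "lb"), (self.ub, "ub"), (self.enzyme_cost, "enzyme_cost")):
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
        if np.any(self.lb > self.ub):
            bad = self.reaction_ids[int(np.argmax(self.lb > self.ub))]
            raise ValueError(f"lb > ub for reaction {bad!r}")
        if np.any(self.enzyme_cost < 0):
            raise ValueError("enzyme costs must be non-negative")
        if not self.pool > 0:
            raise ValueError(f"enzyme pool must be positive, got {self.pool}")
        if self.objective_id not in self.reaction_ids:
            raise ValueError(f"objective reaction {self.objective_id!r} not in model")
        # cost-bearing reactions must be unidirectional: the composition
        # bookkeeping m_i = a_i * v_i requires sign-definite fluxes.
        costly = self.enzyme_cost > 0
        if np.any(self.lb[costly] < 0):
            bad = np.asarray(self.reaction_ids)[costly & (self.lb < 0)]
            raise ValueError(
                "cost-bearing reactions must have lb >= 0 (split reversible "
                f"reactions first): {list(bad)}"
            )
        for rid in self.exchange_to_compound:
            if rid not in self.reaction_ids:
                raise ValueError(f"exchange id {rid!r} not in model")

    # -- serialization (native JSON, bit-for-bit round trip) -----------
    def to_dict(self) -> dict:
        return {
            "reaction_ids": self.reaction_ids,
            "metabolite_ids": self.metabolite_ids,
            "S": self.S.tolist(),
            "lb": self.lb.tolist(),
            "ub": self.ub.tolist(),
            "objective_id": self.objective_id,
            "enzyme_cost": self.enzyme_cost.tolist(),
            "pool": self.pool,
            "exchange_to_compound": self.exchange_to_compound,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        return cls(**d)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel.from_dict(self.to_dict())


def set_pool(model: MetabolicModel, pool: float) -> MetabolicModel:
    """Return a copy of *model* with the enzyme mass budget replaced.

    Setting a very large pool (e.g. 5000 g gCDW^-1) effectively disables
    the enzyme constraint, turning ec-FBA into plain FBA.
    """
    if not pool > 0:
        raise ValueError(f"enzyme pool must be positive, got {pool}")
    out = model.copy()
    out.pool = float(pool)
    return out


# ---------------------------------------------------------------------------
# cobrapy-backed file I/O
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("ec_model")
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids}
    pool_met = cobra.Metabolite("prot_pool", compartment="c")
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        stoich = {
            mets[mid]: float(model.S[i, j])
            for i, mid in enumerate(model.metabolite_ids)
            if model.S[i, j] != 0.0
        }
        if model.enzyme_cost[j] > 0:
            stoich[pool_met] = -float(model.enzyme_cost[j])
        rxn.add_metabolites(stoich)
        rxns.append(rxn)
    pool_rxn = cobra.Reaction("ER_pool_TG_")
    pool_rxn.lower_bound = 0.0
    pool_rxn.upper_bound = float(model.pool)
    pool_rxn.add_metabolites({pool_met: 1.0})
    cm.add_reactions(rxns + [pool_rxn])
    cm.objective = model.objective_id
    # stash the exchange -> compound map as reaction annotations
    for rid, compound in model.exchange_to_compound.items():
        cm.reactions.get_by_id(rid).annotation["medium_compound"] = compound
    return cm


def _from_cobra(
    cm,
    pool_metabolite_pattern: str = POOL_METABOLITE_PATTERN,
    pool_reaction_pattern: str = POOL_REACTION_PATTERN,
) -> MetabolicModel:
    met_pat = re.compile(pool_metabolite_pattern)
    rxn_pat = re.compile(pool_reaction_pattern)

    pool_mets = [m for m in cm.metabolites if met_pat.search(m.id)]
    if not pool_mets:
        raise ModelFormatError(
            "no enzyme-pool pseudo-metabolite found (expected an id matching "
            f"{pool_metabolite_pattern!r}, the sMOMENT/AutoPACMEN convention)"
        )
    pool_met = pool_mets[0]
    pool_rxns = [r for r in pool_met.reactions if rxn_pat.search(r.id)]
    if not pool_rxns:
        # fall back: the delivering reaction is the one with coefficient +1
        pool_rxns = [r for r in pool_met.reactions if r.metabolites[pool_met] > 0]
    if not pool_rxns:
        raise ModelFormatError(
            "no pool pseudo-reaction delivering the enzyme pool found "
            f"(expected an id matching {pool_reaction_pattern!r})"
        )
    pool_rxn = pool_rxns[0]
    pool = float(pool_rxn.upper_bound)

    reactions = [r for r in cm.reactions if r.id != pool_rxn.id]
    reaction_ids = [r.id for r in reactions]
    metabolite_ids = [m.id for m in cm.metabolites if m.id != pool_met.id]
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}

    S = np.zeros((len(metabolite_ids), len(reactions)))
    enzyme_cost = np.zeros(len(reactions))
    lb = np.zeros(len(reactions))
    ub = np.zeros(len(reactions))
    for j, r in enumerate(reactions):
        lb[j] = r.lower_bound
        ub[j] = r.upper_bound
        for met, coef in r.metabolites.items():
            if met.id == pool_met.id:
                # the pool row is all-negative in sMOMENT; flip the sign
                enzyme_cost[j] = -coef
            else:
                S[met_index[met.id], j] = coef
    if np.any(enzyme_cost < 0):
        raise ModelFormatError(
            "positive pool-row coefficients found; the sMOMENT pool row must "
            "be all-negative (-MW/kcat per reaction)"
        )

    objective_ids = [r.id for r in reactions if r.objective_coefficient]
    if len(objective_ids) != 1:
        raise ModelFormatError(
            f"expected exactly one objective reaction, found {objective_ids}"
        )

    exchange_to_compound: dict[str, str] = {}
    for r in reactions:
        if "medium_compound" in r.annotation:
            exchange_to_compound[r.id] = r.annotation["medium_compound"]
        elif r.boundary and r.id.startswith(("EX_", "DM_", "SK_")):
            # boundary prefix convention; keeps biomass/maintenance sinks out
            mets = [m for m in r.metabolites if m.id != pool_met.id]
            if len(mets) == 1:
                exchange_to_compound[r.id] = mets[0].id

    return MetabolicModel(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        S=S,
        lb=lb,
        ub=ub,
        objective_id=objective_ids[0],
        enzyme_cost=enzyme_cost,
        pool=pool,
        exchange_to_compound=exchange_to_compound,
    )


def load_model(
    path: str,
    format: str | None = None,
    pool_metabolite_pattern: str = POOL_METABOLITE_PATTERN,
    pool_reaction_pattern: str = POOL_REACTION_PATTERN,
) -> MetabolicModel:
    """Load an enzyme-constrained model from SBML-fbc, COBRA-JSON or native JSON.

    ``format`` is one of ``"sbml"``, ``"cobra-json"``, ``"json"`` (native
    dataclass dump); guessed from the file extension when omitted
    (``.xml``/``.sbml`` -> sbml, ``.json`` -> tried as native then COBRA).
    """
    import cobra.io

    if format is None:
        if path.endswith((".xml", ".sbml")):
            format = "sbml"
        elif path.endswith(".json"):
            format = "json"
        else:
            raise ModelFormatError(f"cannot guess model format from path {path!r}")

    if format == "sbml":
        try:
            cm = cobra.io.read_sbml_model(path)
        except Exception as exc:  # libsbml raises a zoo of error types
            raise ModelFormatError(f"could not parse SBML file {path!r}: {exc}") from exc
        return _from_cobra(cm, pool_metabolite_pattern, pool_reaction_pattern)
    if format == "cobra-json":
        cm = cobra.io.load_json_model(path)
        return _from_cobra(cm, pool_metabolite_pattern, pool_reaction_pattern)
    if format == "json":
        with open(path) as fh:
            d = json.load(fh)
        if "S" in d:  # native dump
            return MetabolicModel.from_dict(d)
        cm = cobra.io.load_json_model(path)
        return _from_cobra(cm, pool_metabolite_pattern, pool_reaction_pattern)
    raise ModelFormatError(f"unknown model format {format!r}")


def save_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    """Write *model* to SBML-fbc, COBRA-JSON, or the native JSON dump.

    The native JSON dump round-trips every field bit-for-bit.
    """
    import cobra.io

    if format is None:
        if path.endswith((".xml", ".sbml")):
            format = "sbml"
        elif path.endswith(".json"):
            format = "json"
        else:
            raise ModelFormatError(f"cannot guess model format from path {path!r}")
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model.to_dict(), fh, indent=1)
    elif format == "sbml":
        cobra.io.write_sbml_model(_to_cobra(model), path)
    elif format == "cobra-json":
        cobra.io.save_json_model(_to_cobra(model), path)
    else:
        raise ModelFormatError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Toy overflow fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyParams:
    """Parameters of the toy overflow network.

    Yields are gCDW per mmol substrate; enzyme costs are g gCDW^-1 per unit
    flux (mmol gCDW^-1 h^-1). Respiration has the higher biomass yield but
    also the higher enzyme cost, so a tight pool makes the cheap fermentation
    route (which excretes acetate) worthwhile: overflow metabolism.
    """

    yield_resp: float = 0.10      # gCDW per mmol glucose, respiration
    yield_ferm: float = 0.03      # gCDW per mmol glucose, fermentation
    yield_ac: float = 0.02        # gCDW per mmol acetate
    cost_resp: float = 0.013      # g gCDW^-1 per unit respiratory flux
    cost_ferm: float = 0.002
    cost_ac: float = 0.008
    o2_per_glc_resp: float = 2.0  # mmol O2 per mmol glucose respired
    o2_per_ac: float = 2.0        # mmol O2 per mmol acetate oxidized
    ac_per_glc_ferm: float = 1.0  # mmol acetate excreted per mmol glucose fermented
    pool: float = 0.0948          # g enzyme per gCDW
    glc_uptake_max: float = 10.0  # mmol gCDW^-1 h^-1


def build_toy_overflow_model(params: ToyParams | None = None) -> MetabolicModel:
    """Build an 8-reaction enzyme-constrained model exhibiting overflow.

    Reactions (cost-bearing ones are unidirectional):

    ========  =================================================  ========
    id        stoichiometry                                      cost a_i
    ========  =================================================  ========
    RESP      glc + 2 o2 -> Y_r bm                               a_resp
    FERM      glc -> Y_f bm + ac                                 a_ferm
    ACUP      ac + 2 o2 -> Y_a bm                                a_ac
    GROWTH    bm ->                      (objective, mu)         0
    NGAM      bm ->    (maintenance drain; lb = ub = 0 here,     0
                        forced via a scenario bound override)
    EX_glc    glc <->  (lb = -glc_uptake_max)                    0
    EX_ac     ac <->   (lb = 0: no acetate in a fresh medium)    0
    EX_o2     o2 <->   (lb = -1000)                              0
    ========  =================================================  ========

    At a generous pool the optimum respires all glucose; at the default
    tight pool it splits flux between the routes and excretes acetate.
    When a maintenance flux is forced through NGAM, substrate exhaustion
    makes the step infeasible, which the reactor loop turns into a growth
    stall.
    """
    p = params or ToyParams()
    if min(p.yield_resp, p.yield_ferm, p.yield_ac) <= 0:
        raise ValueError("biomass yields must be positive")
    if p.yield_resp <= p.yield_ferm:
        raise ValueError("respiration must out-yield fermentation (Y_resp > Y_ferm)")
    if min(p.cost_resp, p.cost_ferm, p.cost_ac) < 0:
        raise ValueError("enzyme costs must be non-negative")
    if p.cost_resp <= p.cost_ferm:
        raise ValueError("respiration must cost more enzyme than fermentation")
    if not p.pool > 0:
        raise ValueError("enzyme pool must be positive")

    metabolite_ids = ["glc", "ac", "o2", "bm"]
    reaction_ids = ["RESP", "FERM", "ACUP", "GROWTH", "NGAM", "EX_glc", "EX_ac", "EX_o2"]
    S = np.array(
        [
            # RESP   FERM            ACUP  GROWTH NGAM  EX_glc EX_ac EX_o2
            [-1.0,  -1.0,            0.0,  0.0,  0.0,  -1.0,  0.0,  0.0],   # glc
            [0.0,   p.ac_per_glc_ferm, -1.0, 0.0, 0.0,  0.0, -1.0,  0.0],   # ac
            [-p.o2_per_glc_resp, 0.0, -p.o2_per_ac, 0.0, 0.0, 0.0, 0.0, -1.0],  # o2
            [p.yield_resp, p.yield_ferm, p.yield_ac, -1.0, -1.0, 0.0, 0.0, 0.0],  # bm
        ]
    )
    lb = np.array([0.0, 0.0, 0.0, 0.0, 0.0, -p.glc_uptake_max, 0.0, -1000.0])
    ub = np.array([1000.0, 1000.0, 1000.0, 1000.0, 0.0, 1000.0, 1000.0, 1000.0])
    enzyme_cost = np.array([p.cost_resp, p.cost_ferm, p.cost_ac, 0, 0, 0, 0, 0])
    return MetabolicModel(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        S=S,
        lb=lb,
        ub=ub,
        objective_id="GROWTH",
        enzyme_cost=enzyme_cost,
        pool=p.pool,
        exchange_to_compound={"EX_glc": "glc", "EX_ac": "ac", "EX_o2": "o2"},
    )
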