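"""Scenario configuration: medium tables, bound overrides and presets.

A Scenario gathers every knob of one batch simulation: the mode
(dFBA / decFBA / decFBAecc), the time grid, the ecc rate gamma, exchange
bound overrides, the optional excretion feedback, the medium composition,
and the initial reactor state. Scenarios round-trip through a flat TOML
file so a run is fully described by (model file, scenario file).

Two preset families are provided. The fermentation-tuning presets
(iterations A-D) are the successive constraint sets used to reconcile an
E. coli iJO1366* simulation with a glucose minimal-medium batch
fermentation: first everything open, then oxygen uptake capped at 15 and
lactate/dihydroxyacetone export blocked, then acetate exchange tightened
(excretion <= 2.2, uptake <= 10) with pyruvate export blocked, and finally
the concentration-dependent acetate feedback switched on. The approach
presets select the pool/ecc combination: dFBA (pool 5000, composition
free), decFBA (pool 0.0948, composition free), decFBAecc (pool 0.0948,
ecc 0.01 g gCDW^-1 h^-1).
"""

from __future__ import annotations

import csv
import logging
import tomllib
from dataclasses import dataclass, field, asdict

from .fba_core import BoundOverrides
from .feedback import FeedbackParams

__all__ = [
    "Scenario",
    "parse_medium_csv",
    "table1_preset",
    "table2_preset",
    "toy_scenario",
    "replaceable_fraction",
    "MODES",
]

logger = logging.getLogger(__name__)

MODES = ("dFBA", "decFBA", "decFBAecc")


@dataclass
class Scenario:
    """All knobs of one batch simulation."""

    mode: str = "decFBAecc"
    dt: float = 0.01                 # h
    duration: float = 10.0           # h
    gamma: float = 0.01              # ecc, g gCDW^-1 h^-1; -1 free, 0 frozen
    pool_override: float | None = None
    nonlimiting: list[str] = field(default_factory=list)
    bound_overrides: BoundOverrides = field(default_factory=dict)
    feedback: FeedbackParams | None = None
    initial_X: float = 0.1           # gCDW L^-1
    initial_V: float = 1.0           # L
    medium: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    pfba: bool = True
    signed_denominator: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one time step")
        if self.gamma != -1 and self.gamma < 0:
            raise ValueError("gamma must be -1 (free) or >= 0")
        for compound, c in self.medium.items():
            if c < 0:
                raise ValueError(f"negative medium concentration for {compound!r}")

    def validate(self, model) -> None:
        """Check that overrides and feedback reference model reactions."""
        for rid in self.bound_overrides:
            model.reaction_index(rid)  # raises KeyError if absent
        if self.feedback is not None:
            if self.feedback.compound not in model.compound_to_exchange():
                raise ValueError(
                    f"feedback compound {self.feedback.compound!r} has no "
                    "exchange reaction in the model"
                )

    # -- TOML round trip ------------------------------------------------
    def to_toml(self) -> str:
        lines = [
            f'mode = "{self.mode}"',
            f"dt = {self.dt!r}",
            f"duration = {self.duration!r}",
            f"gamma = {self.gamma!r}",
            f"initial_X = {self.initial_X!r}",
            f"initial_V = {self.initial_V!r}",
            f"seed = {self.seed}",
            f"pfba = {str(self.pfba).lower()}",
            f"signed_denominator = {str(self.signed_denominator).lower()}",
        ]
        if self.pool_override is not None:
            lines.append(f"pool_override = {self.pool_override!r}")
        lines.append("nonlimiting = [" + ", ".join(f'"{c}"' for c in self.nonlimiting) + "]")
        lines.append("")
        lines.append("[medium]")
        for compound, c in self.medium.items():
            lines.append(f'"{compound}" = {c!r}')
        for rid, (lo, hi) in self.bound_overrides.items():
            lines.append("")
            lines.append(f'[bound_overrides."{rid}"]')
            if lo is not None:
                lines.append(f"lb = {lo!r}")
            if hi is not None:
                lines.append(f"ub = {hi!r}")
        if self.feedback is not None:
            lines += [
                "",
                "[feedback]",
                f"v_max = {self.feedback.v_max!r}",
                f"c_sat = {self.feedback.c_sat!r}",
                f'compound = "{self.feedback.compound}"',
            ]
        return "\n".join(lines) + "\n"

    def write_toml(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_toml())

    @classmethod
    def from_toml(cls, path: str) -> "Scenario":
        with open(path, "rb") as fh:
            try:
                raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ValueError(f"could not parse scenario file {path!r}: {exc}") from exc
        fb = None
        if "feedback" in raw:
            fb = FeedbackParams(**raw.pop("feedback"))
        overrides: BoundOverrides = {}
        for rid, d in raw.pop("bound_overrides", {}).items():
            overrides[rid] = (d.get("lb"), d.get("ub"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(bound_overrides=overrides, feedback=fb, **raw)


def parse_medium_csv(path: str) -> dict[str, float]:
    """Parse a two-column (compound, mmol L^-1) medium table.

    Raises a ValueError naming the offending row for negative or
    non-numeric concentrations; an empty file yields an empty mapping with
    a warning.
    """
    medium: dict[str, float] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ValueError(f"medium file {path!r}, row {i}: expected 2 columns")
            compound = row[0].strip()
            if i == 1 and not _is_number(row[1]):
                continue  # header line
            try:
                c = float(row[1])
            except ValueError:
                raise ValueError(
                    f"medium file {path!r}, row {i}: non-numeric concentration {row[1]!r}"
                ) from None
            if c < 0:
                raise ValueError(
                    f"medium file {path!r}, row {i}: negative concentration {c}"
                )
            medium[compound] = c
    if not medium:
        logger.warning("medium file %r contains no compounds", path)
    return medium


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# iJO1366 exchange reaction ids used by the fermentation-tuning presets;
# both stereoisomers are constrained where applicable.
_EX = {
    "o2": "EX_o2_e",
    "lac_d": "EX_lac__D_e",
    "lac_l": "EX_lac__L_e",
    "dha": "EX_dha_e",
    "ac": "EX_ac_e",
    "pyr": "EX_pyr_e",
}


def table1_preset(iteration: str) -> tuple[BoundOverrides, bool]:
    """Fermentation-tuning constraint sets A-D.

    Returns (bound overrides keyed by iJO1366 exchange ids, feedback flag).
    A: everything open at +/-1000. B: oxygen uptake capped at 15, lactate and
    dihydroxyacetone export blocked. C: B plus acetate excretion <= 2.2,
    acetate uptake <= 10, pyruvate export blocked. D: C plus the acetate
    excretion feedback.
    """
    it = iteration.upper()
    if it == "A":
        overrides: BoundOverrides = {
            _EX["o2"]: (-1000.0, None),
            _EX["lac_d"]: (None, 1000.0),
            _EX["lac_l"]: (None, 1000.0),
            _EX["dha"]: (None, 1000.0),
            _EX["ac"]: (-1000.0, 1000.0),
            _EX["pyr"]: (None, 1000.0),
        }
        return overrides, False
    if it == "B":
        overrides = {
            _EX["o2"]: (-15.0, None),
            _EX["lac_d"]: (None, 0.0),
            _EX["lac_l"]: (None, 0.0),
            _EX["dha"]: (None, 0.0),
            _EX["ac"]: (-1000.0, 1000.0),
            _EX["pyr"]: (None, 1000.0),
        }
        return overrides, False
    if it in ("C", "D"):
        overrides = {
            _EX["o2"]: (-15.0, None),
            _EX["lac_d"]: (None, 0.0),
            _EX["lac_l"]: (None, 0.0),
            _EX["dha"]: (None, 0.0),
            _EX["ac"]: (-10.0, 2.2),
            _EX["pyr"]: (None, 0.0),
        }
        return overrides, it == "D"
    raise ValueError(f"unknown tuning iteration {iteration!r}; expected A-D")


def table2_preset(approach: str) -> tuple[float, float]:
    """Pool/ecc combination for each approach: (pool g gCDW^-1, gamma).

    gamma -1 means composition unconstrained.
    """
    presets = {
        "dFBA": (5000.0, -1.0),
        "decFBA": (0.0948, -1.0),
        "decFBAecc": (0.0948, 0.01),
    }
    try:
        return presets[approach]
    except KeyError:
        raise ValueError(
            f"unknown approach {approach!r}; expected one of {sorted(presets)}"
        ) from None


def toy_scenario(
    mode: str = "decFBAecc",
    gamma: float | None = None,
    dt: float = 0.02,
    duration: float = 8.0,
    ngam: float = 0.02,
    feedback: FeedbackParams | None = None,
) -> Scenario:
    """Diauxic batch scenario for the toy overflow model.

    1 L of fresh medium with 10 mM glucose and no acetate, inoculated at
    0.1 gCDW L^-1. Glucose uptake is capped at 10.5 and oxygen uptake at
    15 mmol gCDW^-1 h^-1; acetate uptake is open so the culture can turn to
    its own overflow product once glucose runs out; a small maintenance
    flux is forced so post-depletion stalls show up as lost biomass.
    gamma defaults to the approach preset for *mode*.
    """
    pool, preset_gamma = table2_preset(mode)
    if gamma is None:
        gamma = preset_gamma
    return Scenario(
        mode=mode,
        dt=dt,
        duration=duration,
        gamma=gamma,
        pool_override=pool if mode == "dFBA" else None,
        bound_overrides={
            "EX_glc": (-10.5, None),
            "EX_o2": (-15.0, None),
            "EX_ac": (-1000.0, None),
            "NGAM": (ngam, ngam),
        },
        feedback=feedback,
        initial_X=0.1,
        initial_V=1.0,
        medium={"glc": 10.0, "ac": 0.0},
    )


def replaceable_fraction(gamma: float, pool: float) -> float:
    """Fraction of the total enzyme pool replaceable per hour, gamma / pool.

    E.g. an ecc of 0.1 g gCDW^-1 h^-1 against a pool of 0.0948 g gCDW^-1
    allows replacing 1.05 (105%) of the pool each hour.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if pool <= 0:
        raise ValueError("pool must be positive")
    return gamma / pool
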