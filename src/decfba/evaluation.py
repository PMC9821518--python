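"""Comparison of simulated trajectories with measured fermentation series.

Measurements are sparse (time, biomass gCDW L^-1, glucose mM, acetate mM)
tables with gaps allowed; the simulated trajectory is linearly interpolated
onto the sample times and the fit is scored as a single pooled RMSD over
every available (variable, time) pair, unnormalized and equally weighted,
with biomass in gCDW L^-1 and concentrations in mM. The ecc parameter is
fitted by a grid sweep: one full simulation and one RMSD per candidate
gamma, reporting the argmin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reactor_dynamics import Trajectory, run_simulation

__all__ = ["Measurements", "resample_trajectory", "rmsd", "ecc_sweep"]

# measurement variable -> trajectory accessor
_BIOMASS = "biomass"


@dataclass
class Measurements:
    """Sparse measured time series; NaN marks a missing observation."""

    times: np.ndarray                       # h, strictly increasing
    values: dict[str, np.ndarray]           # variable -> observed values

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        for k, v in self.values.items():
            if v.shape != self.times.shape:
                raise ValueError(f"variable {k!r} length does not match times")
        present = np.zeros(len(self.times), dtype=bool)
        for v in self.values.values():
            present |= ~np.isnan(v)
        if not present.all():
            raise ValueError("every time point needs at least one observed variable")

    @classmethod
    def from_csv(cls, path: str) -> "Measurements":
        """Read (time_h, biomass, glucose_mM, acetate_mM, ...) CSV; blank = missing."""
        df = pd.read_csv(path)
        if "time_h" not in df.columns:
            raise ValueError(f"measurements file {path!r} needs a time_h column")
        values = {}
        for col in df.columns:
            if col == "time_h":
                continue
            values[_strip_unit(col)] = df[col].to_numpy(dtype=float)
        return cls(times=df["time_h"].to_numpy(dtype=float), values=values)


def _strip_unit(col: str) -> str:
    for suffix in ("_mM", "_gCDW_L"):
        if col.endswith(suffix):
            return col[: -len(suffix)]
    return col


def resample_trajectory(
    trajectory: Trajectory, times: np.ndarray, variables: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Linearly interpolate trajectory variables onto sample times.

    ``variables`` are compound names plus ``"biomass"``; defaults to biomass
    and every tracked compound. Times outside the simulated range are an
    error rather than an extrapolation.
    """
    times = np.asarray(times, dtype=float)
    grid = trajectory.times
    if times.min() < grid[0] - 1e-12 or times.max() > grid[-1] + 1e-12:
        raise ValueError(
            f"sample times [{times.min():g}, {times.max():g}] h fall outside "
            f"the simulated range [{grid[0]:g}, {grid[-1]:g}] h"
        )
    if variables is None:
        variables = [_BIOMASS] + list(trajectory.states[0].conc)
    out = {}
    for var in variables:
        series = trajectory.biomass if var == _BIOMASS else trajectory.concentration(var)
        out[var] = np.interp(times, grid, series)
    return out


def rmsd(simulated: dict[str, np.ndarray], observed: Measurements) -> float:
    """Pooled root-mean-square deviation over all available observations.

    Variables with no simulated counterpart are ignored; missing (NaN)
    observations are skipped. Raises if no (variable, time) pair overlaps.
    """
    sq_sum = 0.0
    n = 0
    for var, obs in observed.values.items():
        sim = simulated.get(var)
        if sim is None:
            continue
        mask = ~np.isnan(obs)
        d = sim[mask] - obs[mask]
        sq_sum += float(np.dot(d, d))
        n += int(mask.sum())
    if n == 0:
        raise ValueError("no overlapping (variable, time) observations to compare")
    return float(np.sqrt(sq_sum / n))


def ecc_sweep(
    model,
    scenario,
    measurements: Measurements,
    gamma_grid,
) -> pd.DataFrame:
    """One simulation + RMSD per candidate ecc rate; lowest RMSD wins.

    Returns a DataFrame (gamma, rmsd) in grid order with the argmin row
    flagged in a ``best`` column.
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma grid must be non-empty")
    rows = []
    for gamma in gamma_grid:
        sc = _with_gamma(scenario, gamma)
        traj = run_simulation(model, sc, _initial_state_of(sc))
        sim = resample_trajectory(traj, measurements.times)
        rows.append((float(gamma), rmsd(sim, measurements)))
    df = pd.DataFrame(rows, columns=["gamma", "rmsd"])
    df["best"] = df["rmsd"] == df["rmsd"].min()
    return df


def _with_gamma(scenario, gamma: float):
    import copy

    sc = copy.deepcopy(scenario)
    sc.gamma = float(gamma)
    sc.mode = "decFBAecc"
    return sc


def _initial_state_of(scenario):
    from .reactor_dynamics import ReactorState

    return ReactorState(
        t=0.0,
        X=scenario.initial_X,
        V=scenario.initial_V,
        conc=dict(scenario.medium),
        nonlimiting=frozenset(scenario.nonlimiting),
    )
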