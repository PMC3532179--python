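"""Deterministic numerical integration of compiled networks.

The bundled apoptosis model is mildly stiff (rate constants span
0.0035–10), so the default integrator is LSODA, an adaptive method that
switches to BDF when stiffness is detected.  All readouts are reported on
an evenly spaced output grid that always contains both endpoints, so
values "at t_end" are exact solver outputs, not interpolations past the
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SimulationError
from .network import ReactionNetwork, build_rhs

#: Name of the cumulative apoptosis readout species in the bundled model.
APOPTOSIS = "Apop"


def write_csv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a table with shortest-round-trip float formatting, so reading
    the CSV back with :func:`read_csv` reproduces every value bit for bit."""
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a table written by :func:`write_csv` with exact float parsing."""
    return pd.read_csv(path, float_precision="round_trip")

STIFF_METHODS = ("LSODA", "BDF", "Radau")


@dataclass(frozen=True)
class SimulationSettings:
    """Integration horizon, tolerances and output grid.

    ``t_end`` is in the model's dimensionless time units (default 24, one
    unit per nominal hour of the simulated exposure window).  ``n_points``
    is the number of evenly spaced sample times including both endpoints.
    """

    t_end: float = 24.0
    rtol: float = 1e-8
    atol: float = 1e-10
    n_points: int = 2401
    method: str = "LSODA"

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if self.method not in STIFF_METHODS:
            raise ValueError(f"method must be one of {STIFF_METHODS}")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)


@dataclass(frozen=True)
class Trajectory:
    """Time grid x dynamic-species matrix from one integration."""

    times: np.ndarray
    states: np.ndarray
    species_index: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "species_index", dict(self.species_index))

    def __getitem__(self, name: str) -> np.ndarray:
        """Full time course of one species."""
        return self.states[:, self.species_index[name]]

    @property
    def species_names(self):
        return list(self.species_index)

    def at_time(self, t: float) -> Dict[str, float]:
        """State at the grid point nearest ``t`` as a name -> value mapping."""
        i = self._grid_index(t)
        return {n: float(self.states[i, j]) for n, j in self.species_index.items()}

    def value(self, name: str, t: float) -> float:
        """Value of one species at the grid point nearest ``t``.

        Exact at grid points; otherwise nearest-neighbour on the output
        grid (spacing ``t_end / (n_points - 1)``).
        """
        return float(self.states[self._grid_index(t), self.species_index[name]])

    def _grid_index(self, t: float) -> int:
        t0, t1 = self.times[0], self.times[-1]
        if not (t0 - 1e-12 <= t <= t1 + 1e-12):
            raise ValueError(f"time {t} outside trajectory range [{t0}, {t1}]")
        return int(np.argmin(np.abs(self.times - t)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species_index))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path: Union[str, Path]) -> None:
        write_csv(self.to_frame(), path)


def simulate(
    network: ReactionNetwork,
    settings: Optional[SimulationSettings] = None,
    dense: bool = False,
):
    """Integrate a network's mass-action ODEs over [0, t_end].

    Returns a :class:`Trajectory`; with ``dense=True`` returns
    ``(trajectory, sol)`` where ``sol`` is the SciPy solution object with a
    dense interpolant (used for horizon calibration).  Raises
    :class:`SimulationError` carrying the failure time and state if the
    integrator cannot complete the interval.
    """
    settings = settings or SimulationSettings()
    rhs = build_rhs(network)
    y0 = network.initial_state()
    sol = solve_ivp(
        rhs,
        (0.0, settings.t_end),
        y0,
        method=settings.method,
        t_eval=settings.grid,
        rtol=settings.rtol,
        atol=settings.atol,
        dense_output=dense,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        y_fail = sol.y[:, -1] if sol.t.size else y0
        raise SimulationError(
            f"integration failed at t={t_fail:.6g}: {sol.message}",
            time=t_fail,
            state=y_fail,
        )
    traj = Trajectory(
        times=sol.t.copy(),
        states=sol.y.T.copy(),
        species_index=network.species_index,
    )
    return (traj, sol) if dense else traj


def apoptosis_level(trajectory: Trajectory, at_time: float) -> float:
    """Cumulative apoptosis readout at the grid point nearest ``at_time``."""
    return trajectory.value(APOPTOSIS, at_time)
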