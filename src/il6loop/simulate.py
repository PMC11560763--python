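"""Numerical integration and readout of the loop model.

Simulations start, as in the published protocol, from a "switch-off"
configuration (no transcript, no secreted ligand, no receptor occupancy,
fully dephosphorylated STAT3) and read extracellular IL-6 at a fixed time.
Integration is stiff-capable and deterministic; non-negativity and the two
conservation laws are enforced structurally (free STAT3 and free receptor
are reconstructed from the conserved totals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import State, SystemSpec, make_rhs, rhs_vector

__all__ = [
    "Trajectory",
    "SteadyStateResult",
    "switch_off_state",
    "integrate",
    "steady_state",
    "readout_IL6",
]

#: default integrator tolerances
RTOL = 1e-8
ATOL = 1e-10

_SPECIES = ("m", "pS", "C")


@dataclass
class Trajectory:
    """Time-resolved model states on an even output grid."""

    times: np.ndarray               # (n_out,), h, strictly increasing
    Y: np.ndarray                   # (n_out, n_states) packed [m, pS, C, I_ext]
    system: SystemSpec

    @property
    def I_ext(self) -> np.ndarray:
        return self.Y[:, -1]

    def state(self, i: int) -> State:
        return State.from_vector(self.Y[i], self.system, t=float(self.times[i]))

    def species(self, name: str, compartment: int = 0) -> np.ndarray:
        """Time course of one species in one compartment (or the pool)."""
        if name == "I_ext":
            return self.I_ext
        n = self.system.n_cells
        offset = _SPECIES.index(name) * n + compartment
        return self.Y[:, offset]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time, compartment, species, value."""
        n = self.system.n_cells
        rows = []
        for j, name in enumerate(_SPECIES):
            for c in range(n):
                rows.append(pd.DataFrame({
                    "time": self.times,
                    "compartment": self.system.cells[c].cell_type,
                    "species": name,
                    "value": self.Y[:, j * n + c],
                }))
        rows.append(pd.DataFrame({"time": self.times, "compartment": "medium",
                                  "species": "I_ext", "value": self.I_ext}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str, metadata_path: str | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if metadata_path:
            meta = {
                "n_cells": self.system.n_cells,
                "cell_types": [c.cell_type for c in self.system.cells],
                "t_end": float(self.times[-1]),
                "n_out": int(len(self.times)),
                "rtol": RTOL,
                "atol": ATOL,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)


@dataclass
class SteadyStateResult:
    state: State
    converged: bool
    residual_norm: float            # ||rhs||_inf, a.u./h
    t_reached: float                # h


def switch_off_state(system: SystemSpec) -> State:
    """The switch-off configuration: everything inactive at t = 0.

    No mRNA, no extracellular IL-6, no occupied receptor, all STAT3
    unphosphorylated; both conservation laws hold exactly.
    """
    n = system.n_cells
    zeros = np.zeros(n)
    return State(m=zeros.copy(), pS=zeros.copy(), C=zeros.copy(),
                 S=np.array([c.S_tot for c in system.cells], dtype=float),
                 R=np.array([c.R_tot for c in system.cells], dtype=float),
                 I_ext=0.0, t=0.0)


def integrate(system: SystemSpec, state0: State | None = None, t_end: float = 100.0,
              n_out: int = 101, rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the model on [t0, t_end] with output on an even grid.

    Uses LSODA (adaptive, stiffness-switching).  Output values in
    (-atol, 0) are clamped to zero; anything below -atol raises, since the
    model is forward-invariant on the non-negative orthant and a larger
    excursion indicates an integration failure.
    """
    if state0 is None:
        state0 = switch_off_state(system)
    t0 = state0.t
    if t_end <= t0:
        raise ValueError("t_end must exceed the initial time")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    times = np.linspace(t0, t_end, n_out)
    sol = solve_ivp(make_rhs(system), (t0, t_end), state0.to_vector(),
                    method="LSODA", t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    Y = sol.y.T
    if Y.min() < -atol:
        raise RuntimeError(f"negative state beyond tolerance: min={Y.min():.3e}")
    Y = np.where(Y < 0, 0.0, Y)
    return Trajectory(times=times, Y=Y, system=system)


def steady_state(system: SystemSpec, state0: State | None = None,
                 tol: float = 1e-9, t_max: float = 1e5) -> SteadyStateResult:
    """Integrate in doubling windows until the RHS residual falls below tol.

    The steady state is defined operationally: ``||rhs||_inf < tol``.
    Returns the last state with a convergence flag; no eigenvalue analysis.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if state0 is None:
        state0 = switch_off_state(system)
    f = make_rhs(system)
    y = state0.to_vector()
    t = state0.t
    window = 50.0
    res = float(np.max(np.abs(f(t, y))))
    while res >= tol and t < t_max:
        window = min(window, t_max - t)
        sol = solve_ivp(f, (t, t + window), y, method="LSODA", rtol=RTOL, atol=ATOL)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        t = float(sol.t[-1])
        window *= 2.0
        res = float(np.max(np.abs(f(t, y))))
    y = np.where((y < 0) & (y > -ATOL), 0.0, y)
    return SteadyStateResult(state=State.from_vector(y, system, t=t),
                             converged=res < tol, residual_norm=res, t_reached=t)


def readout_IL6(trajectory: Trajectory, t: float) -> float:
    """Extracellular IL-6 at time t (grid value, else linear interpolation).

    This is the quantity an ELISA on the culture supernatant measures.
    """
    times = trajectory.times
    if t < times[0] - 1e-12 or t > times[-1] + 1e-12:
        raise ValueError(f"readout time {t} outside trajectory span "
                         f"[{times[0]}, {times[-1]}]")
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) < 1e-9 * max(1.0, abs(t)):
        return float(trajectory.I_ext[i])
    return float(np.interp(t, times, trajectory.I_ext))
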