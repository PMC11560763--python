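"""Expression-scan protocols and dose-response shape analysis.

Implements the two published scan protocols (E2F1 from 0.1 to 100 a.u.;
E2F1 x STAT3 from 0.1 to 10 a.u., both read at 100 h from a switch-off
start), iso-response contours of the 2-D scan, apparent-Hill-coefficient
ultrasensitivity metrics (EC90/EC10 convention), and a hysteresis screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SystemSpec
from .simulate import integrate, readout_IL6, steady_state, switch_off_state

__all__ = [
    "ScanResult",
    "Scan2DResult",
    "UltrasensitivityMetrics",
    "BistabilityReport",
    "scan_E2F1",
    "scan_E2F1_STAT3",
    "iso_response_contour",
    "ultrasensitivity",
    "bistability_screen",
]

READOUT_TIME = 100.0  # h, protocol constant for expression scans


def _log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    if not (0 < lo < hi):
        raise ValueError("grid requires 0 < lo < hi")
    if n < 2:
        raise ValueError("grid needs n >= 2")
    return np.geomspace(lo, hi, n)


def _melanoma_index(system: SystemSpec) -> int:
    try:
        return system.cell_index("melanoma")
    except KeyError:
        return 0


@dataclass
class ScanResult:
    """1-D expression scan: IL-6 readout per knob level."""

    knob: str                       # "E2F1" or "STAT3"
    grid: np.ndarray                # a.u., strictly increasing
    response: np.ndarray            # IL-6 at readout time, a.u.
    protocol: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.knob: self.grid, "IL6": self.response})

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Scan2DResult:
    """2-D E2F1 x STAT3 scan: matrix of IL-6 readouts."""

    grid_E2F1: np.ndarray
    grid_STAT3: np.ndarray
    response: np.ndarray            # shape (len(grid_STAT3), len(grid_E2F1))
    protocol: dict

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (E2F1, STAT3) pair."""
        E, S = np.meshgrid(self.grid_E2F1, self.grid_STAT3)
        return pd.DataFrame({"E2F1": E.ravel(), "STAT3": S.ravel(),
                             "IL6": self.response.ravel()})

    def to_csv(self, path: str) -> None:
        dense = pd.DataFrame(self.response, index=self.grid_STAT3,
                             columns=self.grid_E2F1)
        dense.index.name = "STAT3"
        dense.columns.name = "E2F1"
        dense.to_csv(path)


@dataclass
class UltrasensitivityMetrics:
    EC10: float
    EC50: float
    EC90: float
    n_H: float                      # apparent Hill coefficient
    dynamic_range: float            # max/min response ratio
    classification: str             # graded | ultrasensitive | switch-like

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class BistabilityReport:
    knob: str
    grid: np.ndarray
    up_response: np.ndarray         # steady I_ext, upward sweep
    down_response: np.ndarray       # steady I_ext, downward sweep
    hysteresis_window: list         # knob levels with >5% up/down discrepancy

    @property
    def bistable(self) -> bool:
        return len(self.hysteresis_window) > 0


def _simulate_level(system: SystemSpec, readout_time: float, t_end: float) -> float:
    traj = integrate(system, switch_off_state(system), t_end=t_end, n_out=51)
    return readout_IL6(traj, readout_time)


def scan_E2F1(system: SystemSpec, lo: float = 0.1, hi: float = 100.0, n: int = 41,
              readout_time: float = READOUT_TIME) -> ScanResult:
    """E2F1 expression scan at fixed readout time.

    For each level the model is reset to the switch-off state, the melanoma
    compartment's E2F1 set to the level, integrated to the readout time and
    the extracellular IL-6 recorded.
    """
    grid = _log_grid(lo, hi, n)
    idx = _melanoma_index(system)
    response = np.empty(n)
    for i, level in enumerate(grid):
        sys_i = system.with_cell(idx, system.cells[idx].replace(E2F1=float(level)))
        response[i] = _simulate_level(sys_i, readout_time, readout_time)
    return ScanResult(knob="E2F1", grid=grid, response=response,
                      protocol={"readout_time": readout_time,
                                "initial_state": "switch_off",
                                "compartment": system.cells[idx].cell_type})


def scan_E2F1_STAT3(system: SystemSpec, lo: float = 0.1, hi: float = 10.0,
                    n: int = 25, readout_time: float = READOUT_TIME) -> Scan2DResult:
    """Joint E2F1 x total-STAT3 scan of the melanoma compartment."""
    grid = _log_grid(lo, hi, n)
    idx = _melanoma_index(system)
    response = np.empty((n, n))
    for j, s_tot in enumerate(grid):          # rows: STAT3
        for i, e2f1 in enumerate(grid):       # cols: E2F1
            cell = system.cells[idx].replace(E2F1=float(e2f1), S_tot=float(s_tot))
            response[j, i] = _simulate_level(system.with_cell(idx, cell),
                                             readout_time, readout_time)
    return Scan2DResult(grid_E2F1=grid, grid_STAT3=grid.copy(), response=response,
                        protocol={"readout_time": readout_time,
                                  "initial_state": "switch_off"})


def iso_response_contour(scan2d: Scan2DResult, level: float) -> list[tuple[float, float]]:
    """Minimal E2F1 reaching a response level, per STAT3 row.

    Linear interpolation between the bracketing E2F1 grid points; rows that
    never reach the level are omitted.  The resulting trade-off curve is
    the model's answer to "which expression levels suffice to trigger IL-6
    secretion": high E2F1 with little STAT3, high STAT3 with little E2F1,
    or moderate levels of both.
    """
    R = scan2d.response
    if not (R.min() <= level <= R.max()):
        raise ValueError(f"level {level} outside response range "
                         f"[{R.min():.4g}, {R.max():.4g}]")
    contour = []
    for j, s_tot in enumerate(scan2d.grid_STAT3):
        row = R[j]
        above = np.nonzero(row >= level)[0]
        if len(above) == 0:
            continue
        i = int(above[0])
        if i == 0:
            e2f1 = float(scan2d.grid_E2F1[0])
        else:
            x0, x1 = scan2d.grid_E2F1[i - 1], scan2d.grid_E2F1[i]
            y0, y1 = row[i - 1], row[i]
            e2f1 = float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))
        contour.append((e2f1, float(s_tot)))
    return contour


def ultrasensitivity(scan: ScanResult) -> UltrasensitivityMetrics:
    """Dose-response shape metrics via the EC90/EC10 convention.

    n_H = log(81) / log(EC90/EC10); for an exact Hill curve this recovers
    the Hill exponent.  Classification: graded (n_H < 1.2), ultrasensitive
    (1.2 <= n_H < 4), switch-like (n_H >= 4).
    """
    x = np.asarray(scan.grid, dtype=float)
    y = np.asarray(scan.response, dtype=float)
    ymin, ymax = float(y.min()), float(y.max())
    if ymin <= 0:
        span = np.inf
    else:
        span = ymax / ymin
    if span < 5:
        raise ValueError(f"response spans only {span:.2f}-fold; need >= 5-fold")
    dif = np.diff(y)
    if np.any(dif < -1e-9 * max(ymax, 1.0)):
        raise ValueError("scan response is not monotone nondecreasing")
    r = (y - ymin) / (ymax - ymin)
    logx = np.log(x)

    def ec(q: float) -> float:
        # first crossing of normalised response level q, interpolated in log x
        return float(np.exp(np.interp(q, r, logx)))

    ec10, ec50, ec90 = ec(0.10), ec(0.50), ec(0.90)
    n_h = np.log(81.0) / np.log(ec90 / ec10)
    if n_h < 1.2:
        cls = "graded"
    elif n_h < 4:
        cls = "ultrasensitive"
    else:
        cls = "switch-like"
    return UltrasensitivityMetrics(EC10=ec10, EC50=ec50, EC90=ec90, n_H=float(n_h),
                                   dynamic_range=span, classification=cls)


def bistability_screen(system: SystemSpec, grid, knob: str = "E2F1",
                       rel_threshold: float = 0.05) -> BistabilityReport:
    """Hysteresis screen: up- and down-sweep of steady states over a knob.

    Each sweep seeds the next level's steady-state search with the previous
    level's steady state; levels where the two sweeps' steady IL-6 differ
    by more than ``rel_threshold`` (relative to the larger value) form the
    hysteresis window.  Empty window = no hysteresis detected.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("knob grid must be strictly increasing")
    idx = _melanoma_index(system)

    def set_level(level: float) -> SystemSpec:
        cell = system.cells[idx]
        if knob == "E2F1":
            cell = cell.replace(E2F1=float(level))
        elif knob == "STAT3":
            cell = cell.replace(S_tot=float(level))
        else:
            raise ValueError(f"unknown knob {knob!r}")
        return system.with_cell(idx, cell)

    def sweep(levels) -> np.ndarray:
        out = np.empty(len(levels))
        state = None
        for i, level in enumerate(levels):
            sys_i = set_level(level)
            if state is not None:
                state = state.__class__.from_vector(state.to_vector(), sys_i, t=0.0)
            res = steady_state(sys_i, state0=state)
            if not res.converged:
                raise RuntimeError(f"no steady state at {knob}={level}")
            out[i] = res.state.I_ext
            state = res.state
        return out

    up = sweep(grid)
    down = sweep(grid[::-1])[::-1]
    scale = np.maximum(np.maximum(np.abs(up), np.abs(down)), 1e-12)
    window = [float(g) for g, u, d, s in zip(grid, up, down, scale)
              if abs(u - d) / s > rel_threshold]
    return BistabilityReport(knob=knob, grid=grid, up_response=up,
                             down_response=down, hysteresis_window=window)
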