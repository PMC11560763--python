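"""Virtual coculture experiments: condition grids and perturbations.

Maps the wet-lab culture conditions onto model modifications:

* indirect coculture  -> two compartments sharing one IL-6 pool
* E2F1 knockdown      -> multiplicative reduction of the E2F1 input
* STAT3 inhibition    -> multiplicative reduction of the phosphorylation
  rate (Stattic blocks activation/dimerisation)
* neutralising anti-IL-6 -> first-order sink on the medium pool
* recombinant IL-6    -> constant infusion into the medium

Doses are dimensionless knobs (the model is qualitative; wet-lab doses
have no a.u. conversion) with defaults in the shipped configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .model import CellInstance, SystemSpec, cell_defaults, load_config
from .simulate import Trajectory, integrate, readout_IL6, switch_off_state

__all__ = [
    "Perturbation",
    "ConditionSpec",
    "PanelResult",
    "apply_perturbation",
    "build_system",
    "run_condition",
    "run_panel",
    "standard_panel",
    "PERTURBATION_KINDS",
]

PERTURBATION_KINDS = ("e2f1_kd", "stat3_inhibition", "il6_neutralization",
                      "exogenous_il6")

PANEL_T_END = 72.0  # h, the culture duration of the coculture protocol


@dataclass(frozen=True)
class Perturbation:
    """One experimental intervention.

    ``strength`` is a residual fraction (<= 1) for the two knockdown-type
    perturbations, a rate for the medium-level ones; ``None`` uses the
    configured default.  ``target`` names a compartment for cell-level
    perturbations and is ignored for medium-level ones.
    """

    kind: str
    strength: float | None = None
    target: str = "melanoma"

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}; "
                             f"expected one of {PERTURBATION_KINDS}")
        if self.strength is not None:
            if self.strength < 0:
                raise ValueError("perturbation strength must be >= 0")
            if self.kind in ("e2f1_kd", "stat3_inhibition") and self.strength > 1:
                raise ValueError(f"{self.kind} strength is a residual fraction <= 1")

    def resolved_strength(self, config: dict | None = None) -> float:
        if self.strength is not None:
            return self.strength
        cfg = load_config() if config is None else config
        return float(cfg["perturbations"][self.kind])


@dataclass(frozen=True)
class ConditionSpec:
    """One culture condition: cells, perturbations, timing."""

    name: str
    cells: tuple[str, ...]                       # cell_type labels
    perturbations: tuple[Perturbation, ...] = ()
    t_end: float = PANEL_T_END
    readout_time: float | None = None            # default: t_end

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))


@dataclass
class PanelResult:
    """Condition-wise IL-6 readouts plus the full trajectories."""

    table: pd.DataFrame                          # condition, perturbations, IL6_readout
    trajectories: dict[str, Trajectory]

    def readout(self, condition: str) -> float:
        row = self.table.loc[self.table["condition"] == condition, "IL6_readout"]
        if row.empty:
            raise KeyError(f"no condition named {condition!r}")
        return float(row.iloc[0])

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def apply_perturbation(system: SystemSpec, p: Perturbation,
                       config: dict | None = None) -> SystemSpec:
    """Return a new system with one perturbation applied.

    Perturbations compose multiplicatively / additively on disjoint knobs,
    so application order does not matter.
    """
    s = p.resolved_strength(config)
    if p.kind == "il6_neutralization":
        return replace(system, il6_sink=system.il6_sink + s)
    if p.kind == "exogenous_il6":
        return replace(system, il6_infusion=system.il6_infusion + s)
    idx = system.cell_index(p.target)  # raises KeyError if absent
    cell = system.cells[idx]
    if p.kind == "e2f1_kd":
        cell = cell.replace(E2F1=cell.E2F1 * s)
    else:  # stat3_inhibition
        cell = cell.replace(params=cell.params.replace(k_p=cell.params.k_p * s))
    return system.with_cell(idx, cell)


def build_system(spec: ConditionSpec, config: dict | None = None) -> SystemSpec:
    """SystemSpec for a condition: defaults, coupling, perturbations."""
    cfg = load_config() if config is None else config
    cells = tuple(cell_defaults(ct, cfg) for ct in spec.cells)
    system = SystemSpec(cells=cells, shared_medium=len(cells) == 2)
    for p in spec.perturbations:
        system = apply_perturbation(system, p, cfg)
    return system


def run_condition(spec: ConditionSpec, config: dict | None = None,
                  n_out: int = 73) -> tuple[float, Trajectory]:
    """Integrate one condition from switch-off and read IL-6.

    Returns (IL-6 at readout_time, full trajectory).
    """
    system = build_system(spec, config)
    traj = integrate(system, switch_off_state(system), t_end=spec.t_end, n_out=n_out)
    t_read = spec.t_end if spec.readout_time is None else spec.readout_time
    return readout_IL6(traj, t_read), traj


def _describe(perturbations: tuple[Perturbation, ...]) -> str:
    return "+".join(p.kind for p in perturbations) or "none"


def run_panel(conditions: list[ConditionSpec] | None = None,
              config: dict | None = None) -> PanelResult:
    """Run a condition panel and collect readouts (deterministic)."""
    if conditions is None:
        conditions = standard_panel()
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise ValueError("condition names must be unique within a panel")
    cfg = load_config() if config is None else config
    rows, trajs = [], {}
    for spec in conditions:
        il6, traj = run_condition(spec, cfg)
        rows.append({"condition": spec.name,
                     "cells": "+".join(spec.cells),
                     "perturbations": _describe(spec.perturbations),
                     "IL6_readout": il6})
        trajs[spec.name] = traj
    return PanelResult(table=pd.DataFrame(rows), trajectories=trajs)


def standard_panel() -> list[ConditionSpec]:
    """The 10-condition mono/co x perturbation grid.

    Three monocultures (melanoma ctrl, melanoma KD, cd4); the four
    {ctrl, KD} x {none, anti-IL-6} cocultures; melanoma ctrl + anti-IL-6;
    cd4 + recombinant IL-6; and the melanoma KD + recombinant IL-6 rescue.
    """
    kd = Perturbation("e2f1_kd", target="melanoma")
    anti = Perturbation("il6_neutralization")
    exo = Perturbation("exogenous_il6")
    mono_mel, mono_cd4 = ("melanoma",), ("cd4",)
    co = ("melanoma", "cd4")
    return [
        ConditionSpec("melanoma_mono_ctrl", mono_mel),
        ConditionSpec("melanoma_mono_kd", mono_mel, (kd,)),
        ConditionSpec("cd4_mono", mono_cd4),
        ConditionSpec("coculture_ctrl", co),
        ConditionSpec("coculture_kd", co, (kd,)),
        ConditionSpec("coculture_ctrl_anti_il6", co, (anti,)),
        ConditionSpec("coculture_kd_anti_il6", co, (kd, anti)),
        ConditionSpec("melanoma_mono_ctrl_anti_il6", mono_mel, (anti,)),
        ConditionSpec("cd4_mono_exo_il6", mono_cd4, (exo,)),
        ConditionSpec("melanoma_mono_kd_exo_il6", mono_mel, (kd, exo)),
    ]
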