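"""Core ODE model of the E2F1-STAT3/IL-6/IL6R signalling loop.

The model describes one or two cell compartments (melanoma, CD4+ T cell)
secreting interleukin-6 into a shared, well-mixed extracellular pool.
Per compartment the species are IL6 mRNA (``m``), free and phosphorylated
STAT3 (``S``, ``pS``), and free and IL-6-occupied membrane receptor
(``R``, ``C``); the pool holds extracellular IL-6 (``I_ext``).

IL6 transcription is an AND-gate of two Hill terms: the transcription
factor E2F1 (a constant input per simulation, in arbitrary units) and
active (phosphorylated) STAT3 jointly activate the promoter, encoding
their synergy as a product of saturable activation functions.  Secreted
IL-6 binds the receptor; the occupied receptor phosphorylates STAT3,
closing an autocrine positive feedback loop within a compartment and a
paracrine loop between compartments sharing the medium.

Both cell types obey the same kinetic scheme and the same kinetic
constants; they differ only in expression levels (E2F1, total STAT3,
total receptor).  All concentrations are in arbitrary units (a.u.),
time in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "CellInstance",
    "SystemSpec",
    "State",
    "hill",
    "transcription_rate",
    "rhs",
    "rhs_vector",
    "make_rhs",
    "load_config",
    "kinetics_defaults",
    "cell_defaults",
    "CELL_TYPES",
]

CELL_TYPES = ("melanoma", "cd4")

_KINETIC_FIELDS = (
    "k0", "k1", "K_E", "h_E", "K_S", "h_S",
    "d_m", "k_sec", "d_I", "k_on", "k_off", "k_int", "k_p", "k_dp",
)
_EXPRESSION_FIELDS = ("E2F1", "S_tot", "R_tot")


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants of the loop.

    k0      basal IL6 transcription rate, a.u./h
    k1      maximal induced IL6 transcription rate, a.u./h
    K_E/h_E E2F1 half-activation constant (a.u.) and Hill exponent
    K_S/h_S pSTAT3 half-activation constant (a.u.) and Hill exponent
    d_m     IL6 mRNA decay rate, 1/h
    k_sec   IL-6 synthesis-and-secretion rate per mRNA, a.u./h per a.u. mRNA
    d_I     extracellular IL-6 clearance rate, 1/h
    k_on    IL-6/receptor association rate, 1/(a.u. h)
    k_off   complex dissociation rate, 1/h
    k_int   complex internalisation rate (receptor recycled, ligand
            destroyed), 1/h
    k_p     STAT3 phosphorylation rate per occupied receptor, 1/(a.u. h)
    k_dp    STAT3 dephosphorylation rate, 1/h
    """

    k0: float
    k1: float
    K_E: float
    h_E: float
    K_S: float
    h_S: float
    d_m: float
    k_sec: float
    d_I: float
    k_on: float
    k_off: float
    k_int: float
    k_p: float
    k_dp: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.h_E < 1 or self.h_S < 1:
            raise ValueError("Hill exponents h_E and h_S must be >= 1")

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)


@dataclass(frozen=True)
class CellInstance:
    """Expression configuration of one cell compartment."""

    cell_type: str
    E2F1: float
    S_tot: float
    R_tot: float
    params: ParameterSet

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}; expected one of {CELL_TYPES}")
        for name in _EXPRESSION_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"expression level {name} must be finite and >= 0, got {v}")

    def replace(self, **changes) -> "CellInstance":
        return replace(self, **changes)


@dataclass(frozen=True)
class SystemSpec:
    """One (monoculture) or two (coculture) compartments sharing a medium.

    ``il6_infusion`` is a constant exogenous IL-6 supply rate (a.u./h),
    ``il6_sink`` a first-order extracellular IL-6 removal rate (1/h) on top
    of the intrinsic clearance (used for neutralising-antibody
    perturbations).
    """

    cells: tuple[CellInstance, ...]
    shared_medium: bool = True
    il6_infusion: float = 0.0
    il6_sink: float = 0.0

    def __post_init__(self) -> None:
        cells = tuple(self.cells)
        object.__setattr__(self, "cells", cells)
        if len(cells) not in (1, 2):
            raise ValueError("SystemSpec needs exactly one (mono) or two (coculture) cells")
        if len(cells) == 2 and not self.shared_medium:
            raise ValueError("coculture requires shared_medium=True")
        if self.il6_infusion < 0 or self.il6_sink < 0:
            raise ValueError("il6_infusion and il6_sink must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_states(self) -> int:
        # m, pS, C per compartment + shared I_ext
        return 3 * len(self.cells) + 1

    def cell_index(self, label: str) -> int:
        for i, c in enumerate(self.cells):
            if c.cell_type == label:
                return i
        raise KeyError(f"no compartment with cell_type {label!r}")

    def with_cell(self, index: int, cell: CellInstance) -> "SystemSpec":
        cells = list(self.cells)
        cells[index] = cell
        return replace(self, cells=tuple(cells))


@dataclass
class State:
    """Full model state: per-compartment species plus the shared pool.

    Free STAT3 and free receptor are carried explicitly but are redundant
    under the conservation laws S + pS = S_tot and R + C = R_tot, which the
    integrator enforces exactly by construction.
    """

    m: np.ndarray
    pS: np.ndarray
    C: np.ndarray
    S: np.ndarray
    R: np.ndarray
    I_ext: float
    t: float = 0.0

    @classmethod
    def from_vector(cls, y: Sequence[float], system: SystemSpec, t: float = 0.0) -> "State":
        y = np.asarray(y, dtype=float)
        n = system.n_cells
        if y.shape != (3 * n + 1,):
            raise ValueError(f"state vector has shape {y.shape}, expected ({3 * n + 1},)")
        m, pS, C = y[0:n], y[n:2 * n], y[2 * n:3 * n]
        S_tot = np.array([c.S_tot for c in system.cells])
        R_tot = np.array([c.R_tot for c in system.cells])
        return cls(m=m.copy(), pS=pS.copy(), C=C.copy(),
                   S=S_tot - pS, R=R_tot - C, I_ext=float(y[-1]), t=t)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.m, self.pS, self.C, [self.I_ext]])


def hill(x: float | np.ndarray, K: float, h: float) -> float | np.ndarray:
    """Hill activation x^h / (K^h + x^h); 0 at x=0, saturating at 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be >= 0")
    with np.errstate(over="ignore"):
        xh = np.power(x, h)
        out = xh / (K ** h + xh)
    out = np.where(np.isfinite(xh), out, 1.0)  # x**h overflow => saturated
    return float(out) if out.ndim == 0 else out


def transcription_rate(E2F1: float, pS: float, p: ParameterSet) -> float:
    """IL6 transcription rate: basal + AND-gate of E2F1 and active STAT3.

    k0 + k1 * H(E2F1; K_E, h_E) * H(pS; K_S, h_S).  The multiplicative
    composition encodes the synergy of the two factors: either input at
    zero shuts the induced term off entirely.
    """
    if E2F1 < 0 or pS < 0:
        raise ValueError("transcription_rate inputs must be >= 0")
    return p.k0 + p.k1 * hill(E2F1, p.K_E, p.h_E) * hill(pS, p.K_S, p.h_S)


def make_rhs(system: SystemSpec):
    """Compile the right-hand side for one system into a fast closure.

    Per compartment c:
      dm_c  = k0 + k1 H_E(E2F1_c) H_S(pS_c) - d_m m_c
      dC_c  = k_on I R_c - (k_off + k_int) C_c,   R_c = R_tot_c - C_c
      dpS_c = k_p C_c (S_tot_c - pS_c) - k_dp pS_c
    Shared pool:
      dI = sum_c k_sec m_c - (d_I + il6_sink) I
           - sum_c (k_on I R_c - k_off C_c) + il6_infusion
    Internalisation destroys the ligand and recycles the receptor, so k_int
    drains C without returning IL-6 to the pool.  E2F1 is a constant input,
    so its Hill term is precomputed; the state is so small that plain
    scalar arithmetic beats array operations by an order of magnitude.
    """
    n = system.n_cells
    pre = []
    for cell in system.cells:
        p = cell.params
        pre.append((p.k0, p.k1 * float(hill(cell.E2F1, p.K_E, p.h_E)),
                    p.d_m, p.k_sec, p.k_on, p.k_off + p.k_int, p.k_int,
                    p.k_p, p.k_dp, p.K_S ** p.h_S, p.h_S, cell.S_tot, cell.R_tot))
    # one well-mixed medium: the pool uses the first compartment's d_I
    clear = system.cells[0].params.d_I + system.il6_sink
    infusion = system.il6_infusion

    def f(t: float, y) -> np.ndarray:
        if isinstance(y, np.ndarray):
            y = y.tolist()          # scalar arithmetic on floats, not 0-d arrays
        I = y[-1]
        out = np.empty(3 * n + 1)
        dI = infusion - clear * I
        for i in range(n):
            (k0, k1HE, d_m, k_sec, k_on, k_offint, k_int,
             k_p, k_dp, KSh, h_S, S_tot, R_tot) = pre[i]
            m, pS, C = y[i], y[n + i], y[2 * n + i]
            pSh = pS ** h_S if pS > 0 else 0.0
            bind = k_on * I * (R_tot - C) - (k_offint - k_int) * C
            out[i] = k0 + k1HE * pSh / (KSh + pSh) - d_m * m
            out[n + i] = k_p * C * (S_tot - pS) - k_dp * pS
            out[2 * n + i] = bind - k_int * C
            dI += k_sec * m - bind
        out[-1] = dI
        return out

    return f


def rhs_vector(t: float, y: np.ndarray, system: SystemSpec) -> np.ndarray:
    """Right-hand side on the packed vector [m_*, pS_*, C_*, I_ext]."""
    return make_rhs(system)(t, np.asarray(y, dtype=float))


def rhs(state: State, system: SystemSpec) -> State:
    """Time derivative of a State (conserved complements implied)."""
    n = system.n_cells
    if state.m.shape != (n,):
        raise ValueError("state/system dimension mismatch")
    dy = rhs_vector(state.t, state.to_vector(), system)
    dm, dpS, dC = dy[0:n], dy[n:2 * n], dy[2 * n:3 * n]
    return State(m=dm, pS=dpS, C=dC, S=-dpS, R=-dC, I_ext=float(dy[-1]), t=state.t)


# ---------------------------------------------------------------------------
# configuration


def _default_config_text() -> str:
    return (resources.files("il6loop") / "data" / "defaults.yaml").read_text()


_ALLOWED_TOP = {"kinetics", "melanoma", "cd4", "perturbations", "protocol", "screen"}
_ALLOWED_PERT = {"e2f1_kd", "stat3_inhibition", "il6_neutralization", "exogenous_il6"}
_ALLOWED_PROTOCOL = {"scan_readout_h", "panel_t_end_h"}
_ALLOWED_SCREEN = {"p_cut", "fc_cut", "score_cut", "motif_threshold", "max_gap_bp",
                   "pseudocount", "background_gc"}


def load_config(path: str | None = None) -> dict:
    """Load (and validate keys of) the model configuration.

    The shipped file defines one ``kinetics`` block (shared by both cell
    types), one expression block per cell type, default perturbation
    strengths, protocol constants and screen cut-offs.  Unknown keys are an
    error so typos cannot silently fall back to defaults.
    """
    if path is None:
        cfg = yaml.safe_load(_default_config_text())
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cell_keys = set(_EXPRESSION_FIELDS) | {"k0"}
    for block, allowed in (("kinetics", set(_KINETIC_FIELDS)),
                           ("melanoma", cell_keys),
                           ("cd4", cell_keys),
                           ("perturbations", _ALLOWED_PERT),
                           ("protocol", _ALLOWED_PROTOCOL),
                           ("screen", _ALLOWED_SCREEN)):
        sub = cfg.get(block, {})
        bad = set(sub) - allowed
        if bad:
            raise ValueError(f"unknown keys in config block {block!r}: {sorted(bad)}")
    return cfg


def kinetics_defaults(config: dict | None = None) -> ParameterSet:
    """Shared kinetic constants from the (shipped or given) configuration."""
    cfg = load_config() if config is None else config
    return ParameterSet(**cfg["kinetics"])


def cell_defaults(cell_type: str, config: dict | None = None) -> CellInstance:
    """Default expression configuration for one cell type.

    Melanoma defaults carry high E2F1 and low-moderate receptor; CD4+ T
    cell defaults low E2F1 and high receptor (membrane IL6R is largely
    leukocyte-restricted).  The per-cell block may override ``k0``: basal
    IL6 transcription is treated as cell state (melanoma cells express
    IL-6 constitutively, resting T cells barely at all); all remaining
    kinetic constants are shared.  Pure function of its arguments.
    """
    cfg = load_config() if config is None else config
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}; expected one of {CELL_TYPES}")
    expr = dict(cfg[cell_type])
    kin = dict(cfg["kinetics"])
    if "k0" in expr:
        kin["k0"] = expr.pop("k0")
    return CellInstance(cell_type=cell_type, params=ParameterSet(**kin), **expr)


def monoculture(cell_type: str, config: dict | None = None) -> SystemSpec:
    """Single-compartment system for one cell type under defaults."""
    return SystemSpec(cells=(cell_defaults(cell_type, config),), shared_medium=False)


def coculture(config: dict | None = None) -> SystemSpec:
    """Melanoma + CD4 compartments coupled through one IL-6 pool."""
    return SystemSpec(cells=(cell_defaults("melanoma", config),
                             cell_defaults("cd4", config)), shared_medium=True)
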