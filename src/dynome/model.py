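"""Graded-potential network model: membrane/synapse ODE right-hand side and
the threshold-potential linear system.

The model is a single-compartment conductance model per neuron, coupled by
ohmic gap junctions and graded chemical synapses:

    C dV_i/dt = -Gc (V_i - E_cell) - I_gap_i - I_syn_i + I_ext_i
    I_gap_i   = sum_j Ggap_ij (V_i - V_j)
    I_syn_i   = sum_j Gsyn_ij s_j (V_i - E_j)          (E_j of the presynaptic cell)
    ds_i/dt   = a_r Phi(V_i; beta, Vth_i) (1 - s_i) - a_d s_i
    Phi(V)    = 1 / (1 + exp(-beta (V - Vth)))

All internal arithmetic is performed in normalized units obtained by dividing
the voltage equation by a reference conductance of 100 pS: conductances become
dimensionless multiples of 100 pS (Gc -> 0.1, one junction -> 1.0), the
membrane time constant C/Gc stays 0.15 s, voltages stay in mV, time in s,
and one arbitrary unit (arb) of injected current equals 0.1 pA.  User-facing
stimulus interfaces speak nA; 1 nA = 10,000 arb.

The per-neuron threshold voltage ``Vth`` — the sigmoid midpoint of synaptic
activation — is the network's zero-derivative fixed point with the synaptic
activity frozen at its half-activation equilibrium ``s_eq = a_r/(a_r + 2 a_d)``,
obtained by solving a linear system (see :func:`compute_vth`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.linalg

from .connectome import Connectome

__all__ = [
    "ModelParams",
    "NetworkState",
    "NORM_CONDUCTANCE_PS",
    "ARB_PER_NA",
    "arb_from_nA",
    "nA_from_arb",
    "sigmoid_phi",
    "s_equilibrium",
    "rhs",
    "compute_vth",
    "VthSolver",
]

#: reference conductance dividing the voltage equation, pS
NORM_CONDUCTANCE_PS = 100.0

#: 1 arb = 0.1 pA = 1e-4 nA, hence 10,000 arb per nA (1000 arb = 0.1 nA)
ARB_PER_NA = 1.0e4


def arb_from_nA(i_nA):
    """Convert injected current from nA to internal arbitrary units."""
    return np.asarray(i_nA, dtype=float) * ARB_PER_NA


def nA_from_arb(i_arb):
    """Convert internal arbitrary current units back to nA."""
    return np.asarray(i_arb, dtype=float) / ARB_PER_NA


@dataclass
class ModelParams:
    """Biophysical constants plus the derived per-neuron threshold vector.

    Scalars may be replaced by length-N arrays (used by robustness scans that
    perturb each neuron's parameters independently).

    Parameters
    ----------
    capacitance_pF:
        Cell membrane capacitance C, pF (default 1.5).
    leak_conductance_pS:
        Cell membrane (leak) conductance Gc, pS (default 10).
    leak_potential_mV:
        Leakage potential E_cell, mV (default -35).
    junction_conductance_pS:
        Conductance of a single gap/synaptic junction g, pS (default 100);
        only used when scaling count matrices.
    rise_rate, decay_rate:
        Synaptic activity rise a_r and decay a_d rates, 1/s
        (defaults 1/1.5 and 5/1.5).
    beta_per_mV:
        Width of the synaptic activation sigmoid, 1/mV (default 0.125).
    reversal_mV:
        Per-neuron presynaptic reversal potentials E_j, mV (0 excitatory,
        -48 inhibitory); taken from the roster by :meth:`for_connectome`.
    vth_mV:
        Derived threshold potentials; ``None`` until computed.
    """

    capacitance_pF: float | np.ndarray = 1.5
    leak_conductance_pS: float | np.ndarray = 10.0
    leak_potential_mV: float = -35.0
    junction_conductance_pS: float = 100.0
    rise_rate: float = 1.0 / 1.5
    decay_rate: float = 5.0 / 1.5
    beta_per_mV: float = 0.125
    reversal_mV: np.ndarray | None = None
    vth_mV: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("capacitance_pF", "leak_conductance_pS", "junction_conductance_pS",
                     "rise_rate", "decay_rate", "beta_per_mV"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.reversal_mV is not None:
            self.reversal_mV = np.asarray(self.reversal_mV, dtype=float)
        if self.vth_mV is not None:
            self.vth_mV = np.asarray(self.vth_mV, dtype=float)

    @classmethod
    def for_connectome(cls, c: Connectome, **overrides) -> "ModelParams":
        """Defaults with reversal potentials taken from the roster."""
        return cls(reversal_mV=c.reversal_potentials, **overrides)

    # normalized (divide-by-100 pS) quantities used by the equations
    @property
    def C_norm(self) -> float | np.ndarray:
        """C / 100 pS — units of seconds (1.5 pF -> 0.015 s)."""
        return np.asarray(self.capacitance_pF) * 1e-12 / (NORM_CONDUCTANCE_PS * 1e-12)

    @property
    def Gc_norm(self) -> float | np.ndarray:
        """Gc / 100 pS — dimensionless (10 pS -> 0.1)."""
        return np.asarray(self.leak_conductance_pS) / NORM_CONDUCTANCE_PS

    @property
    def s_eq(self) -> float:
        return s_equilibrium(self.rise_rate, self.decay_rate)

    def with_vth(self, vth: np.ndarray) -> "ModelParams":
        return replace(self, vth_mV=np.asarray(vth, dtype=float))

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "capacitance_pF": self.capacitance_pF,
            "leak_conductance_pS": self.leak_conductance_pS,
            "leak_potential_mV": self.leak_potential_mV,
            "junction_conductance_pS": self.junction_conductance_pS,
            "rise_rate": self.rise_rate,
            "decay_rate": self.decay_rate,
            "beta_per_mV": self.beta_per_mV,
        }
        for k in ("capacitance_pF", "leak_conductance_pS"):
            if isinstance(d[k], np.ndarray):
                d[k] = d[k].tolist()
        if self.reversal_mV is not None:
            d["reversal_mV"] = self.reversal_mV.tolist()
        return d

    def save(self, path: str | Path) -> None:
        text = json.dumps(self.to_dict(), indent=1)
        Path(path).write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        d = json.loads(Path(path).read_text())
        for k in ("capacitance_pF", "leak_conductance_pS"):
            if isinstance(d.get(k), list):
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class NetworkState:
    """Voltages and synaptic activities at one time point (2n dimensions)."""

    t: float
    V: np.ndarray  # (n,) mV
    s: np.ndarray  # (n,) dimensionless, in [0, 1]

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.V.shape != self.s.shape or self.V.ndim != 1:
            raise ValueError("V and s must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return self.V.size

    @property
    def dim(self) -> int:
        """Total ODE dimension, 2n (e.g. 558 for the 279-neuron network)."""
        return 2 * self.n

    def pack(self) -> np.ndarray:
        return np.concatenate([self.V, self.s])

    @classmethod
    def unpack(cls, t: float, y: np.ndarray) -> "NetworkState":
        n = y.size // 2
        return cls(t=t, V=y[:n].copy(), s=y[n:].copy())


def sigmoid_phi(V, beta: float, vth) -> np.ndarray | float:
    """Synaptic activation sigmoid Phi(V) = 1/(1 + exp(-beta (V - vth))).

    Overflow-safe for large |beta (V - vth)| via the exp-of-negative-
    absolute-value form.
    """
    x = beta * (np.asarray(V, dtype=float) - vth)
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def s_equilibrium(a_r: float, a_d: float) -> float:
    """Equilibrium synaptic activity at half activation: a_r / (a_r + 2 a_d)."""
    if a_r <= 0 or a_d < 0:
        raise ValueError("rates must be positive")
    return a_r / (a_r + 2.0 * a_d)


def _norm_matrices(c: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Coupling matrices as dimensionless multiples of 100 pS."""
    return c.gap / NORM_CONDUCTANCE_PS, c.syn / NORM_CONDUCTANCE_PS


def rhs(state: NetworkState, c: Connectome, p: ModelParams,
        I_ext: np.ndarray | float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Time derivative (dV/dt, ds/dt) of the network state.

    ``I_ext`` is in internal arbitrary units (1 arb = 0.1 pA).  Ablated
    neurons have zero rows/columns, so their coupling terms vanish and they
    relax under leak alone.
    """
    V, s = state.V, state.s
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(s))):
        raise FloatingPointError(f"non-finite state at t={state.t}")
    if p.vth_mV is None:
        raise ValueError("ModelParams.vth_mV not set; call compute_vth first")
    Gg, Gs = _norm_matrices(c)
    Ej = p.reversal_mV
    I_ext = np.broadcast_to(np.asarray(I_ext, dtype=float), V.shape)

    gap_in = Gg @ V                       # sum_j Ggap_ij V_j
    gap_deg = Gg.sum(axis=1)              # sum_j Ggap_ij
    I_gap = gap_deg * V - gap_in

    syn_drive = Gs @ s                    # sum_j Gsyn_ij s_j
    I_syn = syn_drive * V - Gs @ (s * Ej)

    dV = (-p.Gc_norm * (V - p.leak_potential_mV) - I_gap - I_syn + I_ext) / p.C_norm
    phi = sigmoid_phi(V, p.beta_per_mV, p.vth_mV)
    ds = p.rise_rate * phi * (1.0 - s) - p.decay_rate * s
    return dV, ds


def rhs_packed(t: float, y: np.ndarray, c: Connectome, p: ModelParams,
               I_ext_fn) -> np.ndarray:
    """solve_ivp-compatible wrapper; ``I_ext_fn(t)`` returns arb amplitudes."""
    n = y.size // 2
    state = NetworkState(t=t, V=y[:n], s=y[n:])
    dV, ds = rhs(state, c, p, I_ext_fn(t))
    return np.concatenate([dV, ds])


# -- threshold potential ---------------------------------------------------


def _vth_system(c: Connectome, p: ModelParams,
                mode: Literal["laplacian", "diagonal"]) -> np.ndarray:
    """Left-hand matrix A of the threshold fixed-point system A Vth = b."""
    Gg, Gs = _norm_matrices(c)
    n = c.n
    Gc = np.broadcast_to(np.asarray(p.Gc_norm, dtype=float), (n,))
    M1 = np.diag(-Gc)
    gap_deg = Gg.sum(axis=1)
    if mode == "laplacian":
        # full dV/dt = 0 condition: -(D - Ggap) = -Laplacian
        M2 = -np.diag(gap_deg) + Gg
    elif mode == "diagonal":
        M2 = -np.diag(gap_deg)
    else:
        raise ValueError(f"unknown vth mode {mode!r}")
    M3 = np.diag(-p.s_eq * Gs.sum(axis=1))
    return M1 + M2 + M3


def _vth_rhs(c: Connectome, p: ModelParams, I_ext: np.ndarray) -> np.ndarray:
    _, Gs = _norm_matrices(c)
    n = c.n
    Gc = np.broadcast_to(np.asarray(p.Gc_norm, dtype=float), (n,))
    b1 = Gc * p.leak_potential_mV
    b3 = Gs @ (p.s_eq * p.reversal_mV)
    I = np.broadcast_to(np.asarray(I_ext, dtype=float), (n,))
    return -b1 - b3 - I


def compute_vth(c: Connectome, p: ModelParams, I_ext: np.ndarray | float = 0.0,
                mode: Literal["laplacian", "diagonal"] = "laplacian") -> np.ndarray:
    """Solve the threshold-potential linear system A Vth = b.

    The system freezes synaptic activity at ``s_eq`` and the activation at
    1/2 and imposes dV/dt = 0.  The default ``laplacian`` mode keeps the
    off-diagonal gap-junction terms of the fixed-point condition (the
    mathematically consistent choice); ``diagonal`` drops them, retaining
    only each neuron's total gap conductance on the diagonal.

    Raises if inputs contain NaN or the system is singular.  The residual
    satisfies ``||A x - b||_inf <= 1e-10 ||b||_inf`` for Gc > 0.
    """
    if np.any(~np.isfinite(np.asarray(I_ext, dtype=float))):
        raise ValueError("non-finite entries in I_ext")
    A = _vth_system(c, p, mode)
    b = _vth_rhs(c, p, np.broadcast_to(np.asarray(I_ext, dtype=float), (c.n,)))
    x = scipy.linalg.solve(A, b)
    resid = np.max(np.abs(A @ x - b))
    bound = 1e-10 * max(np.max(np.abs(b)), 1e-30)
    if resid > bound:
        # one step of iterative refinement covers ill-conditioned cases
        x = x + scipy.linalg.solve(A, b - A @ x)
        resid = np.max(np.abs(A @ x - b))
        if resid > bound:
            raise ArithmeticError(
                f"threshold system residual {resid:.3e} exceeds bound {bound:.3e}"
            )
    return x


class VthSolver:
    """Threshold solver with the matrix factorization cached per structure.

    ``A`` depends only on the connectome structure and parameters, not on the
    stimulus, so repeated solves under changing input reuse the LU factors
    (O(n^2) per solve).  Call :meth:`invalidate` after any structural edit
    (ablation/reinsertion).
    """

    def __init__(self, c: Connectome, p: ModelParams,
                 mode: Literal["laplacian", "diagonal"] = "laplacian"):
        self.c = c
        self.p = p
        self.mode = mode
        self._lu = None

    def invalidate(self) -> None:
        self._lu = None

    def solve(self, I_ext: np.ndarray | float = 0.0) -> np.ndarray:
        if self._lu is None:
            self._lu = scipy.linalg.lu_factor(_vth_system(self.c, self.p, self.mode))
        b = _vth_rhs(self.c, self.p,
                     np.broadcast_to(np.asarray(I_ext, dtype=float), (self.c.n,)))
        return scipy.linalg.lu_solve(self._lu, b)
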