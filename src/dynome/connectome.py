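"""Connectome bundles: loading, validation, structural editing (ablation).

A connectome here is two coupling matrices over a common neuron roster:

* ``gap`` — electrical (gap-junction) couplings, inherently symmetric, in pS;
* ``syn`` — chemical synapse couplings, directed, in pS, oriented so that
  ``syn[i, j]`` is the maximum total conductivity of synapses TO neuron *i*
  FROM neuron *j* (postsynaptic row, presynaptic column).

Matrices may be supplied as integer junction counts, in which case each
junction contributes a per-junction conductance ``g`` (default 100 pS).

Ablation zeroes a neuron's row and column in both matrices; pristine
reference copies are kept so reinsertion is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NeuronInfo",
    "Connectome",
    "load_connectome",
    "save_connectome",
    "synaptic_degree",
    "edge_width",
    "ablate",
    "reinsert",
]

#: per-junction conductance applied when matrices hold integer counts, pS
DEFAULT_JUNCTION_CONDUCTANCE_PS = 100.0

#: reversal potential of excitatory (glutamatergic/cholinergic) synapses, mV
E_REV_EXCITATORY_MV = 0.0
#: reversal potential of inhibitory (GABAergic) synapses, mV
E_REV_INHIBITORY_MV = -48.0

GROUPS = ("sensory", "inter", "motor")

#: tolerance for declaring an input gap matrix asymmetric
GAP_SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class NeuronInfo:
    """Static annotation of one neuron.

    ``reversal_potential`` is the potential presynaptic partners see when this
    neuron transmits: 0 mV for excitatory transmitters, -48 mV for GABAergic.
    """

    name: str
    group: str = "inter"
    inhibitory: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown neuron group {self.group!r}; expected one of {GROUPS}")

    @property
    def reversal_potential(self) -> float:
        return E_REV_INHIBITORY_MV if self.inhibitory else E_REV_EXCITATORY_MV


@dataclass
class Connectome:
    """Roster + coupling matrices + active mask.

    ``reference_gap``/``reference_syn`` are pristine copies used to restore
    rows/columns on reinsertion after ablation.
    """

    roster: list[NeuronInfo]
    gap: np.ndarray  # (n, n) pS, symmetric, zero diagonal
    syn: np.ndarray  # (n, n) pS, syn[i, j] = conductivity to i from j
    active: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_gap: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_syn: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gap = np.asarray(self.gap, dtype=float)
        self.syn = np.asarray(self.syn, dtype=float)
        n = len(self.roster)
        if self.gap.shape != (n, n) or self.syn.shape != (n, n):
            raise ValueError(
                f"matrix shapes {self.gap.shape}/{self.syn.shape} do not match roster size {n}"
            )
        names = [info.name for info in self.roster]
        if len(set(names)) != n:
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate neuron names: {dupes}")
        if np.any(self.gap < 0) or np.any(self.syn < 0):
            raise ValueError("coupling matrices must be non-negative")
        scale = max(float(np.abs(self.gap).max()), 1.0)
        if not np.allclose(self.gap, self.gap.T, atol=GAP_SYMMETRY_RTOL * scale):
            raise ValueError("gap-junction matrix must be symmetric")
        np.fill_diagonal(self.gap, 0.0)
        np.fill_diagonal(self.syn, 0.0)
        if self.active is None:
            self.active = np.ones(n, dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
        if self.reference_gap is None:
            self.reference_gap = self.gap.copy()
        if self.reference_syn is None:
            self.reference_syn = self.syn.copy()

    # -- roster helpers ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def names(self) -> list[str]:
        return [info.name for info in self.roster]

    def index(self, name: str) -> int:
        """Resolve a neuron name ("AVBL") to its 0-based index."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown neuron name {name!r}") from None

    def indices(self, neurons: Iterable[int | str]) -> list[int]:
        out = []
        for x in neurons:
            i = self.index(x) if isinstance(x, str) else int(x)
            if not 0 <= i < self.n:
                raise IndexError(f"neuron index {i} out of range [0, {self.n})")
            out.append(i)
        return out

    @property
    def reversal_potentials(self) -> np.ndarray:
        """Per-neuron presynaptic reversal potentials E_j, mV."""
        return np.array([info.reversal_potential for info in self.roster])

    def copy(self) -> "Connectome":
        return Connectome(
            roster=list(self.roster),
            gap=self.gap.copy(),
            syn=self.syn.copy(),
            active=self.active.copy(),
            reference_gap=self.reference_gap.copy(),
            reference_syn=self.reference_syn.copy(),
        )

    def subnetwork(self, keep: Sequence[int]) -> "Connectome":
        """Sub-connectome restricted to the given neuron indices (in order)."""
        keep = list(self.indices(keep))
        ix = np.ix_(keep, keep)
        return Connectome(
            roster=[self.roster[i] for i in keep],
            gap=self.gap[ix].copy(),
            syn=self.syn[ix].copy(),
            active=self.active[keep].copy(),
            reference_gap=self.reference_gap[ix].copy(),
            reference_syn=self.reference_syn[ix].copy(),
        )


# -- static layout quantities ---------------------------------------------


def synaptic_degree(c: Connectome, i: int) -> int:
    """Number of nonzero incoming plus outgoing synaptic connections of *i*.

    Used for degree-scaled node radii in static layouts.
    """
    if not 0 <= i < c.n:
        raise IndexError(f"neuron index {i} out of range [0, {c.n})")
    incoming = int(np.count_nonzero(c.syn[i, :]))
    outgoing = int(np.count_nonzero(c.syn[:, i]))
    return incoming + outgoing


def edge_width(c: Connectome, a: int, b: int) -> float:
    """max(w(a -> b), w(b -> a)): the display width of the a--b synaptic edge."""
    if a == b:
        raise ValueError("edge_width requires two distinct neurons")
    for i in (a, b):
        if not 0 <= i < c.n:
            raise IndexError(f"neuron index {i} out of range [0, {c.n})")
    return float(max(c.syn[b, a], c.syn[a, b]))


# -- ablation --------------------------------------------------------------


def ablate(c: Connectome, neurons: Iterable[int | str]) -> Connectome:
    """Disconnect neurons: zero their rows and columns in both matrices.

    Operates in place and returns ``c``. Idempotent; reference copies are
    untouched so :func:`reinsert` can restore exactly.
    """
    for i in c.indices(neurons):
        c.active[i] = False
        c.gap[i, :] = 0.0
        c.gap[:, i] = 0.0
        c.syn[i, :] = 0.0
        c.syn[:, i] = 0.0
    return c


def reinsert(c: Connectome, neurons: Iterable[int | str]) -> Connectome:
    """Restore previously ablated neurons' rows/columns from the reference copies.

    Entries shared with a still-ablated neuron stay zero.
    """
    for i in c.indices(neurons):
        c.active[i] = True
    alive = c.active
    for i in c.indices(neurons):
        c.gap[i, :] = np.where(alive, c.reference_gap[i, :], 0.0)
        c.gap[:, i] = np.where(alive, c.reference_gap[:, i], 0.0)
        c.syn[i, :] = np.where(alive, c.reference_syn[i, :], 0.0)
        c.syn[:, i] = np.where(alive, c.reference_syn[:, i], 0.0)
    return c


# -- bundle I/O ------------------------------------------------------------
#
# Bundle layout (directory):
#   neurons.json  [{"name": ..., "group": ..., "inhibitory": ...}, ...]
#   meta.json     {"weights": "counts"|"conductance_pS",
#                  "junction_conductance_pS": 100.0, "transpose_syn": false}
#   gap.csv + syn.csv (dense, header row of names)  OR  Gg.npy + Gs.npy


def _read_matrix(path: Path, stem: str, n: int) -> np.ndarray:
    csv = path / f"{stem}.csv"
    if csv.exists():
        df = pd.read_csv(csv, index_col=0)
        return df.to_numpy(dtype=float)
    for npy_name in (f"G{stem[0]}.npy", f"{stem}.npy"):
        npy = path / npy_name
        if npy.exists():
            return np.load(npy).astype(float)
    raise FileNotFoundError(f"no {stem}.csv or npy matrix found in {path}")


def load_connectome(path: str | Path, transpose_syn: bool | None = None) -> Connectome:
    """Load a connectome bundle directory.

    ``meta.json`` declares whether matrices store integer junction counts
    (scaled by ``junction_conductance_pS`` on load) or conductances in pS,
    and whether the synapse matrix needs transposing to reach the
    to-row/from-column orientation used here. ``transpose_syn`` overrides
    the metadata flag when given.
    """
    path = Path(path)
    with open(path / "neurons.json") as fh:
        roster = [
            NeuronInfo(name=d["name"], group=d.get("group", "inter"),
                       inhibitory=bool(d.get("inhibitory", False)))
            for d in json.load(fh)
        ]
    meta: dict = {}
    if (path / "meta.json").exists():
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
    n = len(roster)
    gap = _read_matrix(path, "gap", n)
    syn = _read_matrix(path, "syn", n)
    if gap.shape != syn.shape or gap.shape != (n, n):
        raise ValueError(
            f"matrix shapes {gap.shape}/{syn.shape} inconsistent with roster size {n}"
        )
    if transpose_syn is None:
        transpose_syn = bool(meta.get("transpose_syn", False))
    if transpose_syn:
        syn = syn.T
    weights = meta.get("weights", "counts")
    if weights == "counts":
        g = float(meta.get("junction_conductance_pS", DEFAULT_JUNCTION_CONDUCTANCE_PS))
        gap = gap * g
        syn = syn * g
    elif weights != "conductance_pS":
        raise ValueError(f"unknown weights declaration {weights!r}")
    return Connectome(roster=roster, gap=gap, syn=syn)


def save_connectome(c: Connectome, path: str | Path, fmt: str = "csv") -> Path:
    """Write a bundle directory; matrices stored as conductances in pS.

    ``fmt`` is "csv" or "npy".
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "neurons.json", "w") as fh:
        json.dump(
            [
                {"name": i.name, "group": i.group, "inhibitory": i.inhibitory}
                for i in c.roster
            ],
            fh,
            indent=1,
        )
    with open(path / "meta.json", "w") as fh:
        json.dump({"weights": "conductance_pS", "transpose_syn": False}, fh)
    if fmt == "csv":
        for stem, m in (("gap", c.gap), ("syn", c.syn)):
            pd.DataFrame(m, index=c.names, columns=c.names).to_csv(
                path / f"{stem}.csv", float_format="%.17g"
            )
    elif fmt == "npy":
        np.save(path / "Gg.npy", c.gap)
        np.save(path / "Gs.npy", c.syn)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
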