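"""Synthetic connectomes and analytically tractable micro-fixtures.

Real connectome bundles are optional external data; everything in this
package is testable against (a) random networks with the same structure —
non-negative integer junction-count matrices scaled by a per-junction
conductance, a symmetric gap layer, signed (excitatory/inhibitory) synapse
classes — and (b) tiny hand-built fixtures whose behavior is known in
closed form (leak relaxation, gap-pair threshold split, synaptic threshold
shift) or from a committed golden trajectory (ring oscillator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectome import (DEFAULT_JUNCTION_CONDUCTANCE_PS, Connectome,
                         NeuronInfo)
from .model import ModelParams, s_equilibrium

__all__ = ["SynthSpec", "random_connectome", "fixture", "FIXTURE_NAMES"]

GOLDEN_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a random connectome draw."""

    n: int = 20
    gap_density: float = 0.10
    syn_density: float = 0.15
    inhibitory_fraction: float = 0.30
    max_multiplicity: int = 5
    group_proportions: tuple = (0.3, 0.3, 0.4)  # sensory, inter, motor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("gap_density", "syn_density", "inhibitory_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_multiplicity < 1:
            raise ValueError("max_multiplicity must be >= 1")


def random_connectome(spec: SynthSpec) -> Connectome:
    """Draw a random connectome with realistic structure.

    Gap layer: symmetric Bernoulli(gap_density) adjacency with integer
    multiplicities Uniform{1..max_multiplicity}; synaptic layer: directed
    likewise; inhibitory flags i.i.d. Bernoulli(inhibitory_fraction).
    Counts are scaled by the per-junction conductance (100 pS).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    g = DEFAULT_JUNCTION_CONDUCTANCE_PS

    upper = np.triu(rng.random((n, n)) < spec.gap_density, k=1)
    mult = rng.integers(1, spec.max_multiplicity + 1, size=(n, n))
    gap_counts = np.where(upper, mult, 0)
    gap_counts = gap_counts + gap_counts.T

    syn_mask = rng.random((n, n)) < spec.syn_density
    np.fill_diagonal(syn_mask, False)
    syn_counts = np.where(
        syn_mask, rng.integers(1, spec.max_multiplicity + 1, size=(n, n)), 0)

    inhib = rng.random(n) < spec.inhibitory_fraction
    props = np.asarray(spec.group_proportions, dtype=float)
    props = props / props.sum()
    groups = rng.choice(["sensory", "inter", "motor"], size=n, p=props)
    roster = [
        NeuronInfo(name=f"N{i:03d}", group=groups[i], inhibitory=bool(inhib[i]))
        for i in range(n)
    ]
    return Connectome(roster=roster, gap=gap_counts * g, syn=syn_counts * g)


# -- micro-fixtures --------------------------------------------------------

FIXTURE_NAMES = ("single", "gap_pair", "syn_pair", "inhib_pair",
                 "ring_oscillator")

#: constant drive to every ring-oscillator neuron, nA
RING_DRIVE_NA = 2e-3
#: inhibitory synapse multiplicity in the ring (x 100 pS)
RING_SYN_COUNT = 5
#: integration seed of the committed golden trajectory
RING_GOLDEN_SEED = 1


def _params(c: Connectome) -> ModelParams:
    return ModelParams.for_connectome(c)


def fixture(name: str) -> tuple[Connectome, ModelParams, dict]:
    """Hand-built micro-network plus its expected quantities.

    Returns ``(connectome, params, expected)`` where ``expected`` holds the
    closed-form values the fixture realizes:

    * ``single`` — isolated neuron: Vth = E_cell = -35 mV; with 1 arb of
      input, Vth = -25 mV; leak time constant 0.15 s.
    * ``gap_pair`` — one gap junction (100 pS); under I = (1 arb, 0) the
      thresholds split around E_cell + I/(2 Gc): -29.7619.. / -30.2381.. mV.
    * ``syn_pair`` — one excitatory synapse (100 pS) onto neuron 1:
      Vth_post = Gc E_cell / (Gc + s_eq Gsyn) = -18.333.. mV.
    * ``inhib_pair`` — same wiring, inhibitory presynapse: Vth_post is the
      conductance-weighted mean of E_cell and -48 mV, inside (-48, -35).
    * ``ring_oscillator`` — three neurons in a directed inhibitory ring
      under constant drive; oscillates with the period recorded in the
      committed golden trajectory (data/ring_oscillator_golden.json).
    """
    if name == "single":
        c = Connectome(roster=[NeuronInfo("S0")],
                       gap=np.zeros((1, 1)), syn=np.zeros((1, 1)))
        p = _params(c)
        expected = {
            "vth_mV": np.array([-35.0]),
            "vth_mV_at_1arb": np.array([-25.0]),
            "tau_s": 0.15,
        }
        return c, p, expected

    if name == "gap_pair":
        gap = np.array([[0.0, 100.0], [100.0, 0.0]])
        c = Connectome(roster=[NeuronInfo("G0"), NeuronInfo("G1")],
                       gap=gap, syn=np.zeros((2, 2)))
        p = _params(c)
        # A Vth = b with Gc=0.1, g=1: mean shift I/(2Gc), split I/(Gc+2g)
        I = np.array([1.0, 0.0])
        mean = -35.0 + I.sum() / (2 * 0.1)
        split = (I[0] - I[1]) / (0.1 + 2.0)
        expected = {
            "I_arb": I,
            "vth_mV": np.array([mean + split / 2, mean - split / 2]),
        }
        return c, p, expected

    if name in ("syn_pair", "inhib_pair"):
        inhib = name == "inhib_pair"
        syn = np.array([[0.0, 0.0], [100.0, 0.0]])  # to 1 from 0
        c = Connectome(
            roster=[NeuronInfo("P0", inhibitory=inhib), NeuronInfo("P1")],
            gap=np.zeros((2, 2)), syn=syn)
        p = _params(c)
        seq = s_equilibrium(p.rise_rate, p.decay_rate)  # 1/11
        Ej = -48.0 if inhib else 0.0
        vth_post = (0.1 * -35.0 + seq * 1.0 * Ej) / (0.1 + seq * 1.0)
        expected = {"vth_mV": np.array([-35.0, vth_post]), "s_eq": seq}
        if inhib:
            expected["vth_post_bounds"] = (-48.0, -35.0)
        return c, p, expected

    if name == "ring_oscillator":
        n = 3
        syn = np.zeros((n, n))
        for j in range(n):  # inhibitory synapse from j onto j+1
            syn[(j + 1) % n, j] = RING_SYN_COUNT * 100.0
        c = Connectome(
            roster=[NeuronInfo(f"R{i}", inhibitory=True) for i in range(n)],
            gap=np.zeros((n, n)), syn=syn)
        p = _params(c)
        expected = {"drive_nA": RING_DRIVE_NA}
        golden = GOLDEN_DIR / "ring_oscillator_golden.json"
        if golden.exists():
            expected["golden"] = json.loads(golden.read_text())
        return c, p, expected

    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
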