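"""Stimulus schedules with smooth tanh transitions, and saved presets.

Changing an injected current mid-simulation must not introduce a jump, so
every amplitude change is executed as a blend of two hyperbolic tangents:

    S(t) = S_old (1/2 - 1/2 tanh u) + S_new (1/2 + 1/2 tanh u),
    u = (t - (t_switch + t_offset)) / r

With the defaults t_offset = 0.150 s and r = 0.025 s the transition is
(numerically) complete about 2 * t_offset = 300 ms after the switch: at
t_switch the blend weight is tanh(-6), within 1e-5 of pure S_old, and at
t_switch + 300 ms it is within 1e-5 of pure S_new.

Amplitudes at this API boundary are nA; conversion to the model's internal
arbitrary units happens in :mod:`dynome.model` (1 nA = 10,000 arb).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .connectome import Connectome

__all__ = [
    "TransitionEvent",
    "StimulusSchedule",
    "Preset",
    "transition_value",
    "save_preset",
    "load_preset",
]

DEFAULT_T_OFFSET_S = 0.150
DEFAULT_R_S = 0.025


@dataclass(frozen=True)
class TransitionEvent:
    """One smooth amplitude change on one neuron."""

    neuron: int
    S_old: float
    S_new: float
    t_switch: float
    t_offset: float = DEFAULT_T_OFFSET_S
    r: float = DEFAULT_R_S

    def __post_init__(self) -> None:
        if self.t_offset <= 0 or self.r <= 0:
            raise ValueError("t_offset and r must be positive")

    @property
    def t_complete(self) -> float:
        """Time after which the value is within ~1e-5 of S_new."""
        return self.t_switch + 2.0 * self.t_offset


def transition_value(t: float, e: TransitionEvent) -> float:
    """Evaluate the tanh blend at time ``t``; monotone from S_old to S_new."""
    u = 0.5 * (1.0 + np.tanh((t - (e.t_switch + e.t_offset)) / e.r))
    return float(e.S_old * (1.0 - u) + e.S_new * u)


@dataclass
class StimulusSchedule:
    """Per-neuron baseline amplitudes overlaid with tanh transition events.

    At most one transition per neuron is in flight at any time: a new event
    reads its ``S_old`` from the schedule's current evaluated value, so rapid
    successive changes stay continuous.
    """

    baseline: np.ndarray  # (n,) amplitudes, nA
    events: list[TransitionEvent] = field(default_factory=list)
    t_offset: float = DEFAULT_T_OFFSET_S
    r: float = DEFAULT_R_S

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float).copy()
        self.events = sorted(self.events, key=lambda e: e.t_switch)

    @classmethod
    def zeros(cls, n: int, **kw) -> "StimulusSchedule":
        return cls(baseline=np.zeros(n), **kw)

    @property
    def n(self) -> int:
        return self.baseline.size

    def copy(self) -> "StimulusSchedule":
        return StimulusSchedule(baseline=self.baseline, events=list(self.events),
                                t_offset=self.t_offset, r=self.r)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, t: float) -> np.ndarray:
        """Amplitude vector at time ``t`` (continuous in ``t``)."""
        out = self.baseline.copy()
        for e in self.events:
            # later events supersede earlier ones on the same neuron; each
            # event's S_old already encodes the history at its switch time
            out[e.neuron] = transition_value(t, e)
        return out

    def evaluate_neuron(self, i: int, t: float) -> float:
        val = float(self.baseline[i])
        for e in self.events:
            if e.neuron == i:
                val = transition_value(t, e)
        return val

    def settled(self, t: float) -> np.ndarray:
        """Amplitudes counting only transitions complete by ``t``.

        In-flight transitions contribute their starting value.  Used for the
        threshold-recomputation policy: thresholds follow completed stimulus
        changes, not instantaneous mid-transition values.
        """
        out = self.baseline.copy()
        for e in self.events:
            out[e.neuron] = e.S_new if e.t_complete <= t else e.S_old
        return out

    # -- mutation ----------------------------------------------------------
    def set_stimulus(self, neuron: int | str, amplitude: float, t_now: float,
                     c: Connectome | None = None) -> "StimulusSchedule":
        """Schedule a change of ``neuron``'s amplitude starting at ``t_now``.

        Before the run starts (``t_now <= 0``) the baseline is set directly;
        during a run a transition event is appended whose S_old is the live
        evaluated value, preserving continuity under rapid changes.
        Returns ``self``.
        """
        if isinstance(neuron, str):
            if c is None:
                raise ValueError("resolving a neuron name requires a connectome")
            neuron = c.index(neuron)
        if not 0 <= neuron < self.n:
            raise IndexError(f"neuron index {neuron} out of range")
        if t_now <= 0:
            self.baseline[neuron] = amplitude
            self.events = [e for e in self.events if e.neuron != neuron]
            return self
        current = self.evaluate_neuron(neuron, t_now)
        self.events.append(TransitionEvent(
            neuron=neuron, S_old=current, S_new=float(amplitude),
            t_switch=float(t_now), t_offset=self.t_offset, r=self.r))
        self.events.sort(key=lambda e: e.t_switch)
        return self


# -- presets ---------------------------------------------------------------


@dataclass
class Preset:
    """A saved interface configuration: stimuli (nA) plus ablated neurons."""

    name: str
    stimuli_nA: dict[str, float] = field(default_factory=dict)
    ablated: set[str] = field(default_factory=set)

    def resolve(self, c: Connectome) -> tuple[np.ndarray, list[int]]:
        """(baseline amplitude vector nA, ablated indices) against a roster."""
        baseline = np.zeros(c.n)
        for name, amp in self.stimuli_nA.items():
            baseline[c.index(name)] = amp
        return baseline, c.indices(sorted(self.ablated))


def save_preset(p: Preset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"name": p.name, "stimuli_nA": dict(sorted(p.stimuli_nA.items())),
         "ablated": sorted(p.ablated)}, indent=1))


def load_preset(path: str | Path, c: Connectome | None = None) -> Preset:
    """Load a preset; with a connectome given, neuron names are validated."""
    d = json.loads(Path(path).read_text())
    p = Preset(name=d["name"], stimuli_nA=dict(d.get("stimuli_nA", {})),
               ablated=set(d.get("ablated", [])))
    if c is not None:
        for name in list(p.stimuli_nA) + sorted(p.ablated):
            c.index(name)  # raises KeyError on unknown names
    return p


#: canonical stimulation scenarios (amplitudes in nA)
BUILTIN_PRESETS: dict[str, Preset] = {
    "forward": Preset(
        name="forward",
        stimuli_nA={"PLML": 1.4, "PLMR": 1.4, "AVBL": 2.3, "AVBR": 2.3},
    ),
    "backward": Preset(
        name="backward",
        stimuli_nA={"ALML": 5.8, "ALMR": 5.8, "AVAL": 2.0, "AVAR": 2.0,
                    "AVDL": 1.0, "AVDR": 1.0, "AVEL": 1.0, "AVER": 1.0},
    ),
    "nictation": Preset(
        name="nictation",
        stimuli_nA={"IL2DL": 1.0, "IL2DR": 1.0, "IL2L": 1.0, "IL2R": 1.0,
                    "IL2VL": 1.0, "IL2VR": 1.0},
    ),
    "forward_avb_ablated": Preset(
        name="forward_avb_ablated",
        stimuli_nA={"PLML": 1.4, "PLMR": 1.4, "AVBL": 2.3, "AVBR": 2.3},
        ablated={"AVBL", "AVBR"},
    ),
    "forward_ava_ablated": Preset(
        name="forward_ava_ablated",
        stimuli_nA={"PLML": 1.4, "PLMR": 1.4, "AVBL": 2.3, "AVBR": 2.3},
        ablated={"AVAL", "AVAR"},
    ),
}
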