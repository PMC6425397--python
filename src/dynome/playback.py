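"""Computation/playback synchronization, session timelines, seek and replay.

The backend integrates the network in blocks of ``block_dt`` (50 ms) and a
consumer plays the samples back at a configurable rate.  The producer is
allowed to run ahead of the playback clock by at most ``t_buffer`` (100 ms):
a new block is computed only while

    t_computed - t_visualization <= t_buffer,

otherwise the producer waits a refractory period ``tau`` and polls again.
This keeps the backend responsive to live interaction (the next block always
starts near the visualized time) while maintaining a cushion of precomputed
solution.  The protocol only schedules computation — it never alters the
dynamics: a session with a fixed event log produces samples identical to
offline block integration with the same events.

Interaction (stimulus changes, ablation/reinsertion) is quantized to block
boundaries; within a block stimuli remain continuous through their tanh
transitions.  All computed blocks are cached in a timeline, so any earlier
time can be revisited (seek) and playback resumed without recomputation.

Timing here is simulated (wall-clock free) so sessions are deterministic and
testable; the lag diagnostics (desync aggregate x stutter count) quantify
how well a given ``block_dt``/``t_buffer`` choice keeps playback smooth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .connectome import Connectome
from .integrate import (SolutionBlock, SolverConfig, StructuralEvent,
                        apply_structural_event, init_state, integrate_block)
from .model import ModelParams, NetworkState, VthSolver, arb_from_nA
from .stimulus import StimulusSchedule

__all__ = [
    "SyncState",
    "SessionEvent",
    "SessionTimeline",
    "Session",
    "should_compute",
    "run_session",
    "seek",
    "lag_metric",
    "save_dynamics",
]


@dataclass
class SyncState:
    """Clocks and parameters of the buffering protocol.

    ``rate_normal``/``rate_transition`` are playback speeds in simulated
    seconds per wall second (playback slows down while a stimulus transition
    or ablation is in flight so the user can follow the induced dynamics).
    ``tau`` is the producer's wall-clock refractory period between failed
    buffer polls.
    """

    t_computed: float = 0.0
    t_visualization: float = 0.0
    t_buffer: float = 0.100
    block_dt: float = 0.050
    tau: float = 0.050
    rate_normal: float = 0.100
    rate_transition: float = 0.040

    def __post_init__(self) -> None:
        for name in ("t_buffer", "block_dt", "tau", "rate_normal", "rate_transition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.t_visualization <= max(self.t_computed, 0):
            raise ValueError("clocks must satisfy 0 <= t_visualization <= t_computed")


def should_compute(s: SyncState) -> bool:
    """Buffer condition: compute the next block iff the producer's lead
    over playback does not exceed the buffer."""
    return s.t_computed - s.t_visualization <= s.t_buffer


def lag_metric(desync: float, stutters: int) -> float:
    """Session lag score: aggregated desync times stutter count (lower is
    better); zero stutters means perfectly smooth playback regardless of
    the producer's lead."""
    if desync < 0 or stutters < 0:
        raise ValueError("desync and stutters must be non-negative")
    return desync * stutters


@dataclass(frozen=True)
class SessionEvent:
    """A timestamped interaction: stimulus change or structural edit.

    ``t`` is simulation time; events are applied at the first block boundary
    >= t.  Ties at a boundary apply in timestamp order, structural edits
    before stimulus changes.
    """

    t: float
    kind: str                     # "stimulus" | "ablate" | "reinsert"
    neurons: tuple = ()
    amplitude_nA: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("stimulus", "ablate", "reinsert"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def sort_key(self) -> tuple:
        return (self.t, 0 if self.kind in ("ablate", "reinsert") else 1)

    def to_dict(self) -> dict:
        return {"t": self.t, "kind": self.kind, "neurons": list(self.neurons),
                "amplitude_nA": self.amplitude_nA}


@dataclass
class SessionTimeline:
    """Cached blocks + event log + sync diagnostics of one session."""

    initial_state: NetworkState
    blocks: list[SolutionBlock] = field(default_factory=list)
    events: list[SessionEvent] = field(default_factory=list)
    sync: SyncState = field(default_factory=SyncState)
    output_dt: float = 0.010
    stutters: int = 0
    desync_samples: list[float] = field(default_factory=list)
    max_gap: float = 0.0

    @property
    def t_computed(self) -> float:
        return self.blocks[-1].t_end if self.blocks else 0.0

    def grid(self) -> np.ndarray:
        """Global uniform sample grid including t = 0."""
        times = [np.array([self.initial_state.t])]
        times += [b.times for b in self.blocks]
        return np.concatenate(times)

    def samples(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, V, s) arrays over the whole cached session, t=0 included."""
        t = self.grid()
        V = np.vstack([self.initial_state.V[None, :]]
                      + [b.V_samples for b in self.blocks])
        s = np.vstack([self.initial_state.s[None, :]]
                      + [b.s_samples for b in self.blocks])
        return t, V, s

    @property
    def desync_mean(self) -> float:
        return float(np.mean(self.desync_samples)) if self.desync_samples else 0.0

    @property
    def desync_max(self) -> float:
        return float(np.max(self.desync_samples)) if self.desync_samples else 0.0

    def lag(self, aggregate: str = "mean") -> float:
        desync = self.desync_mean if aggregate == "mean" else self.desync_max
        return lag_metric(desync, self.stutters)


def seek(tl: SessionTimeline, t: float) -> tuple[NetworkState, int]:
    """State at the cached grid sample nearest ``t`` (ties -> earlier).

    Returns the reconstructed :class:`NetworkState` and the grid index, so a
    consumer can resume playback from cached data without recomputation.
    """
    if not tl.blocks and t != 0.0:
        raise ValueError("nothing computed yet")
    if t < 0 or t > tl.t_computed + 1e-12:
        raise ValueError(f"seek time {t} outside computed range [0, {tl.t_computed}]")
    grid, V, s = tl.samples()
    idx = int(np.argmin(np.abs(grid - t)))  # argmin returns the earlier tie
    return NetworkState(t=float(grid[idx]), V=V[idx].copy(), s=s[idx].copy()), idx


class Session:
    """Stateful driver of the block loop; the handle callbacks interact with.

    Commands issued by callbacks (:meth:`set_stimulus`, :meth:`ablate`,
    :meth:`reinsert`) are logged with the current block-boundary timestamp,
    so a run driven by callbacks is bit-identical to one replaying the same
    pre-declared event list.
    """

    def __init__(self, c: Connectome, p: ModelParams, sched: StimulusSchedule,
                 cfg: SolverConfig, sync: SyncState | None = None,
                 state: NetworkState | None = None,
                 events: Sequence[SessionEvent] = ()):
        self.c = c.copy()
        self.p = replace(p)
        self.sched = sched.copy()
        self.cfg = cfg
        self.sync = sync or SyncState(block_dt=cfg.block_dt)
        self.state = state if state is not None else init_state(c.n, cfg.seed)
        self.pending = sorted(events, key=lambda e: e.sort_key)
        self.timeline = SessionTimeline(
            initial_state=self.state, sync=self.sync, output_dt=cfg.output_dt)
        self._vth_solver = VthSolver(self.c, self.p)
        self._settled = None
        self._structure_dirty = True
        self._transition_until = 0.0  # sim time until which playback slows down
        self._refresh_vth(0.0)

    # -- interaction API ---------------------------------------------------
    @property
    def t(self) -> float:
        return self.state.t

    def set_stimulus(self, neuron: int | str, amplitude_nA: float,
                     t: float | None = None) -> None:
        i = self.c.index(neuron) if isinstance(neuron, str) else int(neuron)
        self.pending.append(SessionEvent(
            t=self.t if t is None else t, kind="stimulus", neurons=(i,),
            amplitude_nA=float(amplitude_nA)))
        self.pending.sort(key=lambda e: e.sort_key)

    def ablate(self, neurons: Iterable[int | str], t: float | None = None) -> None:
        idx = tuple(self.c.indices(neurons))
        self.pending.append(SessionEvent(
            t=self.t if t is None else t, kind="ablate", neurons=idx))
        self.pending.sort(key=lambda e: e.sort_key)

    def reinsert(self, neurons: Iterable[int | str], t: float | None = None) -> None:
        idx = tuple(self.c.indices(neurons))
        self.pending.append(SessionEvent(
            t=self.t if t is None else t, kind="reinsert", neurons=idx))
        self.pending.sort(key=lambda e: e.sort_key)

    # -- internals ---------------------------------------------------------
    def _refresh_vth(self, t0: float) -> None:
        settled_arb = arb_from_nA(self.sched.settled(t0))
        if self._structure_dirty:
            self._vth_solver.invalidate()
        if self._structure_dirty or self._settled is None \
                or not np.array_equal(settled_arb, self._settled):
            self.p.vth_mV = self._vth_solver.solve(settled_arb)
            self._settled = settled_arb
            self._structure_dirty = False

    def _apply_due_events(self, t0: float) -> None:
        due = [e for e in self.pending if e.t <= t0 + 1e-12]
        self.pending = [e for e in self.pending if e.t > t0 + 1e-12]
        for e in due:
            applied = replace(e, t=t0)
            if e.kind == "stimulus":
                self.sched.set_stimulus(e.neurons[0], e.amplitude_nA, t0)
                if t0 > 0:
                    self._transition_until = max(
                        self._transition_until,
                        t0 + 2 * self.sched.t_offset)
            else:
                apply_structural_event(
                    self.state, self.c, self.p,
                    StructuralEvent(kind=e.kind, neurons=e.neurons),
                    vth_solver=self._vth_solver,
                    I_ext=arb_from_nA(self.sched.settled(t0)))
                self._settled = arb_from_nA(self.sched.settled(t0))
                self._structure_dirty = False
                self._transition_until = max(
                    self._transition_until, t0 + 2 * self.sched.t_offset)
            self.timeline.events.append(applied)

    def step_block(self) -> SolutionBlock:
        """Apply due events at the boundary, refresh thresholds, integrate
        one block, and cache it."""
        t0 = self.state.t
        self._apply_due_events(t0)
        self._refresh_vth(t0)
        block = integrate_block(self.state, self.c, self.p, self.sched, self.cfg)
        self.state = block.end_state
        self.timeline.blocks.append(block)
        return block

    def in_transition(self, t: float) -> bool:
        return t < self._transition_until


def run_session(duration: float, c: Connectome, p: ModelParams,
                sched: StimulusSchedule, cfg: SolverConfig,
                on_block: Callable[[Session, float], None] | None = None,
                events: Sequence[SessionEvent] = (),
                sync: SyncState | None = None,
                state: NetworkState | None = None,
                timed: bool = False,
                compute_cost: float | Callable[[float], float] = 0.02,
                ) -> SessionTimeline:
    """Run a full session of ``duration`` simulated seconds.

    ``on_block(session, t0)`` is invoked before each block is integrated and
    may issue interaction commands; ``events`` is an equivalent pre-declared
    log.  With ``timed=False`` (headless) playback consumes each block
    instantly and the timeline equals offline block integration.  With
    ``timed=True`` a simulated wall clock interleaves production (each block
    costing ``compute_cost`` wall seconds) with playback at the configured
    rates, populating the stutter/desync diagnostics; the computed samples
    are identical in both modes.

    The buffer bound ``t_computed - t_visualization <= t_buffer + block_dt``
    is asserted at every loop iteration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    sync = sync or SyncState(block_dt=cfg.block_dt)
    session = Session(c, p, sched, cfg, sync=sync, state=state, events=events)
    tl = session.timeline
    n_blocks = round(duration / cfg.block_dt)
    if abs(n_blocks * cfg.block_dt - duration) > 1e-9:
        n_blocks = int(np.ceil(duration / cfg.block_dt - 1e-12))

    cost = compute_cost if callable(compute_cost) else (lambda dt: compute_cost)

    def advance_playback(wall_dt: float) -> None:
        """Move the playback clock for ``wall_dt`` wall seconds, clipped at
        t_computed; a clipped advance is one stutter."""
        budget = wall_dt
        while budget > 1e-15:
            rate = (sync.rate_transition
                    if session.in_transition(sync.t_visualization)
                    else sync.rate_normal)
            target = sync.t_visualization + rate * budget
            limit = sync.t_computed
            if session.in_transition(sync.t_visualization):
                # do not overrun the transition window at the slow rate
                limit = min(limit, max(session._transition_until,
                                       sync.t_visualization))
            if target <= limit + 1e-15:
                sync.t_visualization = min(target, sync.t_computed)
                return
            consumed = (limit - sync.t_visualization) / rate if rate > 0 else budget
            sync.t_visualization = limit
            budget -= max(consumed, 0.0)
            if limit >= sync.t_computed - 1e-15:
                tl.stutters += 1
                return

    while sync.t_computed < duration * (1 - 1e-12) or \
            (timed and sync.t_visualization < sync.t_computed - 1e-12):
        if sync.t_computed < duration * (1 - 1e-12) and should_compute(sync):
            if on_block is not None:
                on_block(session, session.t)
            block = session.step_block()
            sync.t_computed = block.t_end
            if timed:
                advance_playback(cost(cfg.block_dt))
            else:
                sync.t_visualization = sync.t_computed
        else:
            advance_playback(sync.tau)
        gap = sync.t_computed - sync.t_visualization
        tl.desync_samples.append(gap)
        tl.max_gap = max(tl.max_gap, gap)
        if gap > sync.t_buffer + sync.block_dt + 1e-12:
            raise AssertionError(
                f"buffer bound violated: gap {gap:.6f} > "
                f"{sync.t_buffer + sync.block_dt:.6f}")
    return tl


def save_dynamics(tl: SessionTimeline, directory: str | Path,
                  stem: str = "dynamics") -> tuple[Path, Path]:
    """Write the session's time x 2N sample array (npy) and its event log
    (JSON) for exact replay."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t, V, s = tl.samples()
    arr = np.column_stack([t, V, s])
    npy_path = directory / f"{stem}.npy"
    np.save(npy_path, arr)
    log_path = directory / f"{stem}_events.json"
    log_path.write_text(json.dumps(
        {"events": [e.to_dict() for e in tl.events],
         "stutters": tl.stutters,
         "desync_mean": tl.desync_mean,
         "desync_max": tl.desync_max}, indent=1))
    return npy_path, log_path
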