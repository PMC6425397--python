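"""Mapping of dynamics to visual attributes, and static layout export.

Activity is displayed on the connectivity graph by modulating node radii and
sign colors: the radius saturates with the activity magnitude,

    |R| = R_max V^2 / (rho + V^2),    sign(R) = sign(V),

so small voltages produce small nodes and large ones approach ``R_max``
without ever reaching it.  By default the activity variable is the voltage
relative to the neuron's threshold potential (V - Vth) — around rest all
neurons sit near their thresholds, so the threshold-relative signal is what
alternates in sign during oscillations; an absolute-voltage mode is also
available.

Layout geometry itself (force-directed placement) is left to the renderer;
this module only exports the static quantities a renderer needs: per-node
degree-scaled radii and group color classes, per-edge widths and layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectome import Connectome, edge_width, synaptic_degree
from .model import ModelParams, NetworkState

__all__ = ["VizConfig", "node_radius", "frame", "layout_export"]

GROUP_COLORS = {"sensory": "blue", "inter": "green", "motor": "red"}


@dataclass(frozen=True)
class VizConfig:
    """Activity-to-radius mapping parameters.

    ``rho`` (mV^2) sets the half-saturation point: |R| = R_max/2 when
    |V| = sqrt(rho).  The default 225 places half-saturation at 15 mV of
    threshold-relative activity — a display choice, adjustable per taste.
    """

    R_max: float = 15.0
    rho: float = 225.0
    activity_reference: str = "threshold_relative"  # or "absolute"

    def __post_init__(self) -> None:
        if self.R_max <= 0 or self.rho <= 0:
            raise ValueError("R_max and rho must be positive")
        if self.activity_reference not in ("threshold_relative", "absolute"):
            raise ValueError(
                f"unknown activity reference {self.activity_reference!r}")


def node_radius(V, cfg: VizConfig = VizConfig()):
    """Signed, saturating radius of an activity value (vectorized).

    Odd in V, strictly increasing in |V|, bounded by R_max.
    """
    V = np.asarray(V, dtype=float)
    mag = cfg.R_max * V**2 / (cfg.rho + V**2)
    return np.sign(V) * mag


def frame(state: NetworkState, p: ModelParams, c: Connectome,
          cfg: VizConfig = VizConfig()) -> dict:
    """One renderable frame: per-neuron radius, sign and ablation flag."""
    if cfg.activity_reference == "threshold_relative":
        if p.vth_mV is None:
            raise ValueError("threshold-relative frames require vth_mV")
        activity = state.V - p.vth_mV
    else:
        activity = state.V
    radii = node_radius(activity, cfg)
    return {
        "t": state.t,
        "nodes": [
            {
                "name": info.name,
                "radius": float(abs(radii[i])),
                "sign": int(np.sign(radii[i])),
                "ablated": bool(not c.active[i]),
            }
            for i, info in enumerate(c.roster)
        ],
    }


def layout_export(c: Connectome, cfg: VizConfig = VizConfig(),
                  path: str | Path | None = None) -> dict:
    """Static graph description for a force-directed renderer.

    Nodes carry their group color class and a radius scaled by total in+out
    synaptic degree (hub neurons render larger); edges carry the layer
    ("gap" or "syn") and, for synaptic edges, the max of the two directed
    weights as display width.  Coordinates are not computed here.
    """
    degrees = np.array([synaptic_degree(c, i) for i in range(c.n)], dtype=float)
    max_deg = degrees.max() if c.n and degrees.max() > 0 else 1.0
    min_radius = 0.1 * cfg.R_max
    nodes = [
        {
            "name": info.name,
            "group": info.group,
            "color": GROUP_COLORS[info.group],
            "radius": float(min_radius + (cfg.R_max - min_radius)
                            * degrees[i] / max_deg),
            "degree": int(degrees[i]),
        }
        for i, info in enumerate(c.roster)
    ]
    edges = []
    for i in range(c.n):
        for j in range(i + 1, c.n):
            if c.gap[i, j] > 0:
                edges.append({"source": c.roster[j].name,
                              "target": c.roster[i].name,
                              "layer": "gap", "width": float(c.gap[i, j])})
            if c.syn[i, j] > 0 or c.syn[j, i] > 0:
                edges.append({"source": c.roster[j].name,
                              "target": c.roster[i].name,
                              "layer": "syn", "width": edge_width(c, i, j)})
    doc = {"nodes": nodes, "edges": edges}
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc
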