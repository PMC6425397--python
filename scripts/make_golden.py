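"""Regenerate the committed golden trajectory of the ring-oscillator fixture.

Usage:  python scripts/make_golden.py

Integrates the three-neuron inhibitory ring under its standard constant
drive from the fixed seed, estimates the oscillation period from the
post-transient window, and writes src/dynome/data/ring_oscillator_golden.json
(down-sampled neuron-0 voltage trace plus metadata).
"""

import json
from pathlib import Path

import numpy as np

import dynome as dy
from dynome.analysis import estimate_period
from dynome.synthetic import (GOLDEN_DIR, RING_DRIVE_NA, RING_GOLDEN_SEED,
                              RING_SYN_COUNT)

DURATION = 30.0
SETTLE = 10.0
STORE_DT = 0.02  # down-sampled storage resolution, s


def main() -> None:
    c, p, _ = dy.fixture("ring_oscillator")
    p.vth_mV = dy.compute_vth(c, p, dy.arb_from_nA(RING_DRIVE_NA))
    sched = dy.StimulusSchedule(baseline=np.full(c.n, RING_DRIVE_NA))
    cfg = dy.SolverConfig(seed=RING_GOLDEN_SEED)
    state = dy.init_state(c.n, RING_GOLDEN_SEED)
    block = dy.integrate_interval(state, c, p, sched, cfg, DURATION)

    keep = block.times >= SETTLE - 1e-12
    t = block.times[keep]
    v0 = block.V_samples[keep, 0]
    period = estimate_period(v0, cfg.output_dt)

    stride = round(STORE_DT / cfg.output_dt)
    doc = {
        "seed": RING_GOLDEN_SEED,
        "drive_nA": RING_DRIVE_NA,
        "syn_count": RING_SYN_COUNT,
        "duration_s": DURATION,
        "settle_s": SETTLE,
        "dt_s": STORE_DT,
        "period_s": round(float(period), 6),
        "neuron": "R0",
        "t0_s": float(t[0]),
        "V_mV": [round(float(x), 4) for x in v0[::stride]],
    }
    GOLDEN_DIR.mkdir(exist_ok=True)
    out = GOLDEN_DIR / "ring_oscillator_golden.json"
    out.write_text(json.dumps(doc, indent=0))
    print(f"wrote {out}: period {period:.4f} s, {len(doc['V_mV'])} samples")


if __name__ == "__main__":
    main()
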