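# dynome

Scriptable simulation of connectome-constrained neural dynamics — a "dynome":
a biophysical dynamical system layered on a static wiring diagram — built for
the *C. elegans* somatic nervous system (279 neurons) but applicable to any
network given as gap-junction and chemical-synapse coupling matrices.

It is aimed at computational neuroscientists who want to probe how a resolved
connectome shapes network activity: inject currents into named neurons
("clamping"), change stimuli smoothly mid-run, ablate and reinsert neurons in
silico, replay any part of a session, and quantify the induced dynamics
(oscillation periods, phase relations, responsive-neuron sets).

## Model

Each neuron is a single graded-potential compartment. Membrane voltage
$V_i$ (mV) and synaptic activity $s_i \in [0,1]$ obey

$$C \dot V_i = -G^c (V_i - E_{cell}) - \sum_j G^g_{ij}(V_i - V_j)
  - \sum_j G^s_{ij}\, s_j (V_i - E_j) + I^{ext}_i$$

$$\dot s_i = a_r\, \Phi(V_i)\, (1 - s_i) - a_d\, s_i, \qquad
  \Phi(V_i) = \frac{1}{1 + e^{-\beta (V_i - V^{th}_i)}}$$

with $G^g$ the symmetric gap-junction conductivities, $G^s_{ij}$ the maximum
synaptic conductivity **to** $i$ **from** $j$, and $E_j$ the presynaptic
reversal potential (0 mV excitatory, −48 mV GABAergic). Defaults:
$C = 1.5$ pF, $G^c = 10$ pS, $E_{cell} = -35$ mV, 100 pS per junction,
$a_r = 1/1.5$, $a_d = 5/1.5$ s⁻¹, $\beta = 0.125$ mV⁻¹.

The per-neuron threshold $V^{th}$ — the sigmoid midpoint — is the network's
zero-derivative fixed point with $s$ frozen at its half-activation
equilibrium $s_{eq} = a_r/(a_r + 2a_d)$, obtained by solving the linear
system $A\,V^{th} = b$ (see `dynome.model.compute_vth`); it is refreshed
after every ablation/reinsertion and completed stimulus change.

Stimulus changes are never stepwise: an amplitude change at $t_{switch}$ is a
blend of two hyperbolic tangents with offset 150 ms and width 0.025 s, so the
transition completes smoothly about 300 ms after the switch.

Integration runs in 50 ms blocks sampled on a 10 ms grid (scipy adaptive
Runge–Kutta, rtol 1e-9 / atol 1e-10). A buffering protocol lets a consumer
play blocks back while the producer keeps at most a 100 ms lead — the
protocol schedules computation but never alters the dynamics — and the cached
timeline supports seek/replay and export (npy/CSV/HDF5 + JSON event logs).

## Worked example

The built-in three-neuron inhibitory ring fixture oscillates under a constant
2×10⁻³ nA drive to each cell:

```python
import dynome as dy
from dynome.analysis import ScenarioSpec, run_scenario
from dynome.synthetic import RING_DRIVE_NA

c, p, expected = dy.fixture("ring_oscillator")
print("thresholds (mV):", dy.compute_vth(c, p, dy.arb_from_nA(RING_DRIVE_NA)).round(3))

spec = ScenarioSpec(name="ring",
                    stimuli_nA={f"R{i}": RING_DRIVE_NA for i in range(3)},
                    duration=30.0, settle_time=10.0, seed=1)
res = run_scenario(spec, c)
print("responsive:", sorted(res.responsive))
print("periods (s):", {k: round(v, 3) for k, v in res.periods.items()})
print("phases (rad):", {k: round(v, 3) for k, v in res.phases.items()})
print("consensus period (s):", round(res.consensus_period, 3))
```

prints

```
thresholds (mV): [-9.59 -9.59 -9.59]
responsive: ['R0', 'R1', 'R2']
periods (s): {'R0': 1.293, 'R1': 1.287, 'R2': 1.294}
phases (rad): {'R0': 0.0, 'R1': -2.086, 'R2': 2.083}
consensus period (s): 1.293
```

All three neurons oscillate with a common ~1.29 s period, phase-shifted by
2π/3 — the signature of a symmetric inhibitory ring: each cell fires in turn
as its inhibitor decays. With real connectome data the same runner reproduces
the classic touch-response scenarios (`dynome scenario --name forward
--connectome DIR` stimulates PLM at 1.4 nA and AVB at 2.3 nA and reports the
motor-neuron oscillation period and phases).

Synthetic bundles for experimentation come from the generator:

```
dynome synth --n 30 --gap-density 0.1 --syn-density 0.15 --seed 7 --out mynet
```

A connectome bundle is a directory with `neurons.json` (roster),
`gap.csv`/`syn.csv` or `Gg.npy`/`Gs.npy` (dense matrices) and `meta.json`
declaring whether entries are junction counts or conductances in pS.

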