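# Methods

## Model and assumptions

The simulator implements a single-compartment conductance model for
graded-potential neurons, the established regime for *C. elegans*, whose
neurons do not fire classical action potentials. Two coupling layers act on
the static connectome: ohmic gap junctions (current proportional to the
voltage difference of the coupled pair, inherently symmetric) and graded
chemical synapses, in which a presynaptic activity variable
$s_j \in [0, 1]$ gates a conductance toward the presynaptic cell's reversal
potential (0 mV for excitatory transmitters, −48 mV for GABAergic). Synaptic
activation follows first-order rise/decay kinetics driven by a sigmoid of
the presynaptic voltage relative to a per-neuron threshold.

The model deliberately excludes multi-compartment morphology,
Hodgkin–Huxley channel dynamics, synaptic transmission delays and autaptic
terms, and any muscle/body mechanics: it describes the electrical state of
the somatic network only.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| C | 1.5 | pF | membrane capacitance |
| G^c | 10 | pS | leak conductance (membrane time constant C/G^c = 150 ms) |
| E_cell | −35 | mV | leak reversal |
| g | 100 | pS | conductance of one gap/synaptic junction (count matrices are scaled by g) |
| E_j | 0 / −48 | mV | excitatory / inhibitory synaptic reversal |
| a_r, a_d | 1/1.5, 5/1.5 | s⁻¹ | synaptic rise and decay rates |
| β | 0.125 | mV⁻¹ | activation sigmoid width |
| t_offset, r | 150, 25 | ms | stimulus-transition midpoint offset and width |
| Δt, t_buffer, τ | 50, 100, 50 | ms | block length, playback buffer, producer refractory |
| output_dt | 10 | ms | uniform sample grid |
| rtol, atol | 1e-9, 1e-10 | — | solver tolerances |

All internal arithmetic divides the voltage equation by a reference
conductance of 100 pS, which makes the coupling matrices dimensionless
junction counts, G^c = 0.1, C = 15 ms·(100 pS), and one arbitrary unit of
injected current equal to 0.1 pA. User-facing interfaces accept nA
(1 nA = 10,000 arb). Scalar parameters C and G^c may be replaced by
per-neuron vectors; the robustness scan uses this to perturb each neuron
independently.

## Threshold potentials

The sigmoid midpoint V_th is the network's fixed point under the
conventions s ≡ s_eq = a_r/(a_r + 2 a_d) and Φ ≡ 1/2, which turns
dV/dt = 0 into a linear system A V_th = b with
A = −diag(G^c) − L_gap − diag(s_eq Σ_j G^s_ij) and
b = −G^c E_cell − G^s (s_eq E_j) − I_ext. Two treatments of the gap term are
provided. The default keeps the full weighted gap Laplacian L_gap
(diagonal total conductance minus off-diagonal couplings), which is the
literal dV/dt = 0 condition and yields physically sensible thresholds for
strongly coupled neurons. A `diagonal` mode drops the off-diagonal terms,
retaining only each neuron's summed gap conductance; it is kept because some
descriptions of this fixed point use the diagonal-only form, but for a
driven gap pair it places the threshold near −2.3 mV where the consistent
solution gives ≈ −30 mV, so it is not the default.

V_th depends on the stimulus vector and on the wiring, so it must be
refreshed as a session evolves. Policy: thresholds are recomputed at block
boundaries whenever the structure changed (ablation/reinsertion) or a
stimulus transition has *completed* (t ≥ t_switch + 2 t_offset); in-flight
transitions do not move thresholds. This keeps the refresh schedule
deterministic and identical between callback-driven and pre-declared runs.
The matrix factorization is cached per structure, so repeated solves under
changing input are O(n²).

## Integration and the playback protocol

Blocks of 50 ms are integrated with scipy's adaptive RK45 at
rtol 1e-9 / atol 1e-10 and sampled on the 10 ms output grid; identical
inputs reproduce identical samples bit-for-bit. Chaining blocks agrees with
a single longer solve to the solver's mixed error scale
(≈ atol + rtol·|V|, i.e. tens of nanovolts at typical voltages) — adaptive
step sequences differ, so agreement beyond that scale is not expected.

Structural events apply only at block boundaries (the interaction protocol
already quantizes user actions to blocks); simultaneous events at one
boundary apply in timestamp order with structural edits before stimulus
changes. The state vector is never edited: an ablated neuron keeps
integrating as an isolated leak cell. Stimulus changes are continuous inside
blocks via the tanh transition, so the solver never sees a discontinuity.
A superseding stimulus change reads its starting value from the live
evaluated amplitude, keeping the injected current continuous under rapid
successive commands; after a supersede, the schedule's closed form
re-evaluates history to within the tanh tail (~10⁻⁵ of the step), while
replay of past samples always comes from the cached timeline and is exact.

The producer/consumer protocol computes a new block only while the computed
time leads the playback clock by at most t_buffer, otherwise it waits a
refractory τ and polls again; the lead is therefore bounded by
t_buffer + Δt, which the session loop asserts at every iteration. Playback
runs at 100 ms of simulated time per wall second, dropping to 40 ms/s while
a transition or ablation is in flight. Timing is simulated (no wall clock),
so sessions are deterministic and the protocol's lag diagnostics — an
aggregated desync (both mean and max are reported) times the stutter count,
where a stutter is a playback advance that drains the buffer — can be
computed in tests. The protocol never changes the mathematics: a session
with a fixed event log is sample-identical to offline block integration of
the same schedule.

Initial conditions draw V and s i.i.d. from Normal(0, 0.94)·10⁻⁴ — a tiny
unbiased perturbation around zero; s is clamped into [0, 1] since the draw
can be slightly negative (the clamp changes nothing at reported precision).
V is treated as the literal voltage variable of the model.

## Visualization mapping

Activity maps to signed node radii |R| = R_max V²/(ρ + V²) with R_max = 15.
The slope factor ρ is a display choice with no canonical value; the default
225 mV² puts half-saturation at 15 mV. The mapped variable defaults to the
threshold-relative voltage V − V_th: absolute voltages all rest near −35 mV,
which would render the sign/color channel constant, whereas the
threshold-relative signal alternates sign during oscillations. An absolute
mode is available. Static layout export (degree-scaled radii, max-of-both-
directions edge widths, group color classes) leaves force-directed placement
to the renderer.

## Analysis choices

Oscillation periods come from the first autocorrelation peak with height
≥ 0.2 and prominence ≥ 0.1 (mean-removed, overlap-corrected, lags to half
the window), smoothed around the candidate with a window of one eighth of
the candidate lag to suppress ripple from faster components, then refined by
parabolic interpolation; traces with peak-to-peak range under 1 µV or no
qualifying peak are reported aperiodic. Phase differences use the circular
cross-correlation argmax over a whole number of cycles, mapped to (−π, π]
with positive meaning the second trace lags. A neuron is "responsive" when
its maximum threshold-relative excursion over the post-settle window reaches
5 mV (configurable; reported active fractions depend directly on this
cut-off and should be read qualitatively). Scenario consensus periods are
the median over responsive periodic neurons. Scenario defaults are 30 s
duration with a 10 s settle window — at least five cycles of the slowest
oscillation of interest (~6 s) — and the limit cycles need several seconds
to grow from the 10⁻⁴-scale initial state, so shorter windows undercount
oscillators.

Robustness scans multiply every nonzero connection (gap kept symmetric) and
each neuron's C and G^c by independent Uniform(1−p, 1+p) factors with
p = 0.20 and rerun the scenario, recording whether the oscillation and its
period persist.

## Synthetic data

The generator emulates the *structure* of real connectome data: symmetric
non-negative integer gap-junction count matrices, directed synaptic count
matrices, per-junction conductance scaling, and a roster with group types
and a GABAergic (inhibitory) fraction. Defaults (n = 20, gap density 0.10,
synapse density 0.15, inhibitory fraction 0.30, multiplicities 1–5) give
sparse networks of roughly the real network's connection density scale. It
does **not** reproduce the real network's degree distribution, community
structure, left/right symmetry or neuron classes, so passing tests on
synthetic networks validate the mechanics of the simulator, not biological
conclusions; scenario-level biological claims require the real 279-neuron
bundle, which is optional external data.

The micro-fixtures realize closed forms: an isolated cell (threshold at the
leak potential, 150 ms relaxation), a gap pair (threshold split
I/(G^c + 2g) around a mean shift I/2G^c), excitatory and inhibitory synapse
pairs (conductance-weighted threshold averages), and a three-neuron
inhibitory ring under constant 2×10⁻³ nA drive whose limit cycle
(period ≈ 1.29 s, three-way 2π/3 phase balance) is frozen in a committed
golden trajectory (JSON, regenerated by `scripts/make_golden.py` at seed 1).
The ring's drive and synapse strength sit in the regime where each cell's
release from inhibition swings it well above threshold; weaker coupling or
drive lets the symmetric fixed point win and the oscillation die — a real
bifurcation that the single-connection sweep test skirts by staying within
±15% of the reference coupling.

## Numerical notes and limitations

* The threshold solve uses LAPACK LU with one step of iterative refinement
  if the residual exceeds 10⁻¹⁰·‖b‖∞; the system is nonsingular whenever
  G^c > 0.
* The overflow-safe sigmoid uses the exp-of-negative-absolute-value form.
* Voltages are unbounded above in the model itself; strong drives produce
  physically implausible voltages (the model has no saturating channels).
* Seek snaps to the nearest 10 ms grid sample (ties to the earlier one) and
  replays cached data; it never re-integrates.
* Determinism holds per platform/BLAS build: bit-identical reruns are
  guaranteed on the same stack, cross-platform agreement only to solver
  tolerance (golden-trajectory comparisons use a 2% period tolerance for
  this reason).
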