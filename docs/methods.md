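# Methods

## Model

### Synapse dynamics

Each presynaptic unit *j* owns one pair of Tsodyks–Markram variables,
shared by all of its outgoing connections:

* `u_j` — release probability ("utilization"), resting at the parameter
  `U`, jumping by `U(1 − u)` at each presynaptic spike and relaxing back to
  `U` with time constant `τ_f`;
* `x_j` — available resources, resting at 1, dropping by the released
  fraction at each spike and recovering with `τ_d`.

At a spike the release probability jumps first and the released fraction is
`u⁺·x⁻` (the standard convention for facilitating synapses: the calcium
transient of the spike itself boosts release). The pre-jump reading
`u⁻·x⁻` is selectable via `use_post_jump_u=False` so both interpretations
of the jump term can be compared. One textual description of the first
spike ("u(t₁) = 1 − u(t₀)") contradicts the jump term of the governing
equation; the equation is taken as authoritative.

Two evaluation schemes are provided and tested against each other:
event-driven (closed-form exponentials between spikes; exact) and
fixed-step forward Euler (relaxation first, then the jump terms of any
spike falling in the step, then sampling — this ordering converges to the
event-driven solution as dt → 0). After every Euler update `u` and `x` are
clamped to [0, 1]; clamping events are counted on the trajectory
(`n_clamped`) and are zero in normal operation.

### Current and membrane

The current into unit *i* is `I_i = A · Σ_j w_ij u_j x_j`, evaluated every
integration step from the instantaneous efficacies. Note a consequence that
the tests codify: with no presynaptic input, `u = U` and `x = 1`, so a
*constant resting current* `A·Σw·U` flows and the membrane settles at the
subthreshold value `V_rest + R_m·A·Σw·U` rather than at `V_rest`. This is
inherent to gating the current by `u·x` continuously; the spike-gated
alternative would leave the network unable to fire at all under the default
drive.

Membranes are leaky integrate-and-fire,
`τ_m dV/dt = −(V − V_rest) + R_m·I`, integrated by forward Euler at
dt = 1 ms; at `V ≥ θ` a spike is recorded, V resets to `V_rest`, and the
unit is refractory (held at rest) for `τ_arp`. `R_m = 200` is treated as a
plain gain (mV per unit of the dimensionless STP current): only the product
`R_m·A` is physically meaningful here, and both factors are configurable.
The within-step update order is: synapses, then currents, then membranes,
so the current at time t uses the synaptic state at t. Spikes are
timestamped at the step of the presynaptic column that produced them.

### Default parameters

| parameter | value | meaning |
|---|---|---|
| τ_f | 750 ms | facilitation recovery of u |
| τ_d | 50 ms | depression recovery of x |
| x₀ | 1 | initial resource availability |
| A | 0.039 | current gain (×2 in the two-unit build) |
| θ | −55 mV | spike threshold |
| V_rest | −70 mV | resting / reset potential |
| R_m | 200 | membrane gain, mV per unit current |
| τ_m | 30 ms | membrane time constant |
| τ_arp | 2 ms | absolute refractory period |
| dt | 1 ms | integration step |
| T | 1000 ms | direction-step duration |

The two-unit build doubles A so that its units — which sum 2 synapses
instead of ~3 — fire in the same rate range as the six-unit network.

### Architecture

Six units in two subpopulations of three. Within each subpopulation the
binary connectivity is all-to-all including self-connections (9 directed
links ⇒ 6 undirected counting self-links); between subpopulations a single
reciprocal pair (units 2 ↔ 3) keeps the graph connected while preserving
"densely within, sparsely between". The exact between-population link set
is a free choice (the reference wiring diagram is not machine-readable);
one pair is the minimal connected option and is configurable
(`cross_links`). The two-unit control is the 2 × 2 all-ones matrix.

## Stimulus generator

The generator emulates a camera watching a vertical bar sweep across a
monitor. What it reproduces: binary 6 × 1000 frames (row = unit,
column = ms), spike count per unit equal to the row sum, spike timing tied
to bar position, a bidirectional 200-step sweep, and optional salt noise
(each background pixel flipped to 1 with probability `noise_prob`,
seeded per step) standing in for real-camera luminance noise. What it does
not reproduce: grayscale imaging, perspective or luminance calibration,
continuous motion within a step, or any hardware timing. Passing tests
therefore demonstrate the model's behaviour under idealized inputs, not
robustness to real camera artifacts (noise robustness can be probed via
`noise_prob`).

Defaults chosen once where unspecified by the reference tables: bar width
50 columns and shift 5 columns/step — about 50 presynaptic spikes per
1000-ms step, a regime where facilitation builds within a step; positions
wrap at the frame edge so every step delivers the same spike count. The
100 → 6 row reduction for camera-resolution input ORs 6 contiguous blocks
of 17/17/17/17/16/16 rows, so a black pixel anywhere in a unit's receptive
strip drives that unit. Grayscale file input binarizes at half of the
intensity range.

### Release-probability schedule

The per-step pairs `(U1, U2)` use mirrored linear ramps over
[U_min, U_max] = [0.05, 0.6]: subpopulation 1 ascends through the upper
half-range on its 100 preferred (right) steps and through the lower
half-range on null steps; subpopulation 2 uses the same two ramps with the
direction blocks swapped. This makes (a) each subpopulation's mean U higher
for its preferred direction, (b) the preferred-direction trajectories of
the two subpopulations identical step for step, and (c) the value multisets
exactly mirrored — so any rate asymmetry between subpopulations is
attributable to the schedule, not to different U statistics. The exact
numeric values of the original schedule are not recoverable from its
source; only these qualitative constraints are enforced, and the linear
ramp is the simplest schedule satisfying all three.

## Analyses

Rates are spike counts over a half-open window divided by its length; the
window is configurable so that onset-transient skipping (e.g. (280, 1280)
ms as used for evoked cortical recordings) is expressible. The direction
decision compares subpopulation mean rates; exact ties return "undecided"
rather than defaulting to a direction. SCC bins each unit's spikes in
nonoverlapping 1-ms windows, concatenates the series across all 200 steps
(a per-direction mode is provided, since either pooling is defensible) and
computes Pearson coefficients; zero-variance (silent) series make r
undefined, so such pairs are excluded from the within/between means and
reported explicitly.

## Numerical choices

* Euler/event-driven agreement is verified at dt = 0.01 ms to 1e-3
  absolute in u and x over 100 random trains (0–40 spikes in 200 ms, fixed
  seed); the circuit itself integrates at the reference dt = 1 ms.
* The LIF integrator is validated against the closed-form constant-current
  period `τ_arp + τ_m ln((V∞ − V_rest)/(V∞ − θ))` at dt = 0.01 ms, within
  one dt, for threshold margins of 2–25 mV.
* Per-step reset: each direction step reinitializes u = U(step), x = 1,
  V = V_rest — a step "recruits" a fresh release-probability pair.
  `carry_over_state=True` preserves (u, x, V) across steps instead.
* Determinism: the only randomness is frame noise, drawn from
  `numpy.random.default_rng` seeded per step from the experiment seed;
  noise-free runs are bit-reproducible by construction.

## Problem sizes

The default experiment is 6 units × 200 steps × 1000 ms at dt = 1 ms
(≈1.2 M unit updates, a few seconds on one core); the test suite reuses
one session-level run of the six-unit and two-unit experiments for all
experiment-scale assertions.

## Known limitations

* The model is deterministic; stochastic vesicle release is out of scope
  (the averaged phenomenological model is the object of study).
* Unit spikes do not feed back into the synapses by default: synapse j is
  driven only by the external train of frame row j. The alternative
  recurrent reading is available (`recurrent_spikes=True`) but untuned.
* The between-subpopulation SCC under the default conditions is negative
  but small (≈ −3e-4): at 1-ms resolution correlations are dominated by
  spike-timing coincidence, and the anticorrelation contributed by
  direction-dependent rate modulation across steps is diluted over 200 000
  bins. The sign structure, not the magnitude, is the claim tested.
* Comparisons with primate V1 recordings are out of scope; the analysis
  procedures they motivate (onset-skip rate windows, SCC) are implemented
  generically and exercised on simulated rasters only.
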