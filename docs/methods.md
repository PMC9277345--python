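# Methods

## Scope and model of the node

`hncsim` is a functional (not cycle-accurate) twin of a single hybrid
neuromorphic compute node: P = 16 processing units of N_P = 64 neurons
(N_M = 1024 per node), two presynaptic data streams, step size
h = 0.1 ms equal to the minimum synaptic delay d_min. The simulation
schedule per step is: ring-buffer read → Euler update → spike
serialisation in ascending (unit, slot) order → delivery of each firing
neuron's target packet, completed before the next step. Hardware
plumbing (bus protocols, DMA, clock domains, recording transport) is
out of scope functionally and enters only through the latency constants
of the performance model. Plasticity is out of scope entirely.

## Fixed-point arithmetic (s16.23)

State variables and synaptic weights are 40-bit signed fixed point with
23 fractional bits: values in [−65536, 65536 − 2⁻²³], resolution
2⁻²³ ≈ 1.2e−7. The hardware's rounding/overflow behaviour is not
publicly specified, so the package makes three documented choices:

* **Overflow saturates** and every saturation event is counted.
  Saturation-free runs are exactly integer-arithmetic runs, hence
  commutative and replicable; tests assert zero saturation wherever
  spike-identicality is claimed.
* **Multiplication truncates toward −∞** (arithmetic right shift of the
  78-bit product); a round-to-nearest mode exists for sensitivity
  studies. Truncation bias per multiply is < 1 ulp.
* **Constants are encoded round-to-nearest-even.** This matters: h and
  0.04 are not exactly representable, and their encoding errors
  (2.4e−8 and 3.8e−8) dominate the fixed-vs-float step difference.
  At the RS rest state the 0.04 error alone shifts the equilibrium by
  ≈3e−4 mV (bounded, self-correcting); across the subthreshold range
  the per-step difference is bounded by
  12 ulp + |acc|·err(h) + h·v²·err(0.04), which the tests assert
  sample-wise. A blanket "few ulp" bound is *not* attainable with
  s16.23 constants.

The fixed-point Euler pipeline order is fixed and documented in
`neuron.py` (v² → ×0.04 → +5v → +140 − u + i_syn + i_ext → ×h;
u-update via pre-encoded a·h). The vectorised int64 path is
bit-identical to the scalar reference (asserted in tests); operand
pairs whose 64-bit product could wrap are recomputed with exact Python
integers.

## Neuron model and verification

RS (0.02, 0.2, −65, 8) and FS (0.1, 0.2, −65, 2) Izhikevich
parameterisations; threshold v ≥ 30 mV applied to the post-update
value, reported membrane value clamped at the 30 mV peak on spike
steps. Verification follows the calculation-verification pattern: the
forward-Euler pipeline (fixed and float) is compared against an
adaptive embedded Runge–Kutta 4(5) integration (scipy `RK45`,
atol = 1e−6, event-located threshold crossings). For the constant-drive
protocol (RS at 10 pA, 1 s) all three agree in spike count (23);
Euler's phase drift accumulates to ≈7 ms over 1 s, so spike matching
uses a 10 ms window — counts, not phases, are the contract.

## Ring buffer semantics

K_RB = 64 segments (maximum delay 6.4 ms) × N_P slots; K_RB must be a
power of two because the validity stamp is k_target >> log2(K_RB).
Reads return (0, 0) for entries whose stamp does not match the current
buffer cycle; stale entries are never cleared. Accumulation is exact
integer addition in two signed lanes (lumped excitatory/inhibitory,
the static-synapse path). The two hardware read-before-write hazards
are handled as in the design: minimum-delay deliveries are flagged for
the performance accounting (functionally, deliveries always complete
before the next step), and a greedy stable reordering separates
multapse duplicates by a configurable gap (default 4 positions, a
pipeline-depth proxy; the required separation is not published).

## Performance model calibration

All four published design points share f_clk = 200 MHz and
h·f_clk = 20000 cycles per step (evaluated as an exact integer budget).
The per-component latency table of the original characterisation is not
available in the sources used here, so the model carries two calibrated
totals: L_SYNC = 3 (giving L_Σ = IL_N + 3 = 67 for the prototype) and a
spike-path base of 49 cycles (giving L_Σ^SE = 49 + IL_N/2 = 81). These
totals reproduce the full prototype column and all four maxima of the
published table to one decimal. The non-prototype mid-workload entries
of that table are internally inconsistent with any single
(L_Σ^SE, L_DS) pair under the stated equations (e.g. the high-stream
column's F_S(1) computes to 210.5 against a printed 177.0); they are
deliberately not pinned. Related printed loss percentages mix rounding
conventions (consistent with recomputation from one-decimal table
entries); tests allow 0.2–0.5 percentage points there. The finite-k
startup form needs L_RD + L_ODE alone, which is not recoverable from
the totals; a nominal 20-cycle default is used and only the k→∞
convergence is asserted. Below one event per step F_S can exceed
F_S^MAX when L_Σ^SE + L_DS < L_Σ (the low-proc design point);
monotonicity holds whenever the spike path is the more expensive one,
as for the prototype.

Communication defaults: T_COM = 500 ns (L_COM = 100 cycles at 200 MHz),
α = 0.05 (5 cycles per spike event), a deliberately simple
fixed-latency broadcast abstraction — no topology or queueing effects.

## Synthetic benchmark network

The two-population benchmark is generated programmatically: 800 RS +
200 FS neurons, fixed in-degree K_in = 100 drawn without replacement,
inhibitory neurons projecting only to excitatory targets, excitatory
neurons to both; deterministic per seed down to byte-identical files.
The published network's weight, delay and stimulus distributions live
in supplementary material not available here; the defaults are
**documented stand-ins** in the same lineage: w_exc ~ U(0, 5] pA,
w_inh ~ U[−10, 0) pA, excitatory delays uniform on the 0.1 ms grid in
[1.0, 6.4] ms, inhibitory delays fixed at the network's 1 ms minimum,
and a random input of one XNOR-shift-selected neuron per step receiving
a 1000 pA one-step pulse (≈1 mV·ms of charge per h·i, enough to fire a
resting cell). Under these defaults the resting-state rate is
≈10 spks/s (ν̄ₖ ≈ 1) with zero saturation events — the same order as
the published ≈7 spks/s operating point, which is therefore treated as
a diagnostic, never asserted. Because out-degrees are random while the
node caps a source at 128 targets, sources at capacity are excluded
from further in-degree draws (affects ≈1 % of excitatory sources).
What passing tests show is therefore the engine's internal consistency
and regime, not distribution-level agreement with the original
network's activity.

The node PRNG is a 32-bit XNOR-shift (complemented Marsaglia xorshift,
triplet 13/17/5). Its recurrence has a unique fixed point at
0x3FFFFFFF, which is rejected as a seed (remapped with a warning); the
generator shows no state repetition over 10⁶ draws and mean 0.500 over
10⁵ draws.

## Validation statistics

Per-neuron firing rates (silent neurons included as zero), CV of
inter-spike intervals (≥ 3 spikes required; exclusions counted),
pairwise Pearson correlation of 2 ms-binned trains (all within-
population pairs up to 20000, seeded subsampling beyond; zero-variance
trains excluded). Distributions use Freedman–Diaconis bin widths
(2·IQR·n^(−1/3)) and a Gaussian KDE whose bandwidth rule (default
Scott's — the original rule is unpublished) is configurable; densities
are normalised to unit mass on their evaluation grid. Equivalence is
always quantified by the two-sample Kolmogorov–Smirnov statistic on the
**raw** samples; the smoothed densities are presentation only. The
package's self-consistency contract — two benchmark runs differing only
in the stimulus seed — uses D < 0.1 across all six measure sets
(FR/CV/CC × EXC/INH), a package-chosen threshold at the 800/200
population sizes; measured values in the suite are ≤ 0.07 at 10 s of
biological time.

## Problem sizes used by the test suite

Chosen as the package's own defaults: oracle-equivalence at 10⁴
ring-buffer events and 50 random small networks (≤ 48 neurons, 120
steps); replicability and relabelling at 150 steps; statistical
self-consistency on two 10 s benchmark runs; the benchmark-scale run at
60 s of biological time (6·10⁵ steps, ~10⁶ spikes) with the measured
workload fed back into the analytic acceleration curve.

## Known limitations

* Functional, not cycle-accurate: no BRAM port contention, FIFO depth,
  or restart stalls; these appear only as calibrated latency totals.
* Single node only; clusters exist solely in the analytic model.
* Benchmark distributions are stand-ins (above); absolute rates should
  not be compared against published measurements.
* The packed 64-bit connectivity item stores weights as s8.23
  (±256 pA) — lossless for the benchmark's range, lossy beyond.
* Wall-clock acceleration of the hardware cannot be, and is not,
  reproduced in software; only the model predictions are.
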