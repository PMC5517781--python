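# Methods

## Models

### Leaky integrate-and-fire with delta synapses

The membrane potential of every neuron in the PING network follows
`dv/dt = -v/τ` between synaptic events; an event arriving at delay `d`
after a presynaptic spike adds its weight `g` (mV, signed) to `v`
instantaneously. Crossing the threshold `θ` resets `v` to `v_r` and marks
the neuron refractory for `t_ref`. Because the subthreshold equation is
linear and homogeneous, the update `v ← v·e^{−dt/τ}` is *exact*: the
integration error of the whole scheme is zero off the event grid, and event
times are quantized to the step anyway. Defaults: τ = 10 ms, θ = 1 mV,
v_r = 0 mV, t_ref = 5.01 ms.

Two refractory semantics are supported. `clamp` (default) holds `v = v_r`
and discards inputs arriving during refractoriness; `integrate` lets the
membrane integrate but disables the threshold. The clamp variant mimics the
stock LIF modules of the major simulators. Refractory expiry is evaluated
in continuous time: the neuron integrates again at the first grid point
`≥ last_spike + t_ref`. Since t_ref = 5.01 ms is deliberately off the
0.1 ms grid, the effective per-neuron minimum inter-spike interval is
5.1 ms — one grid point past the floor, never below it.

### Classical Hodgkin–Huxley

The conductance-based neuron uses the modern shifted-voltage convention
(rest near −65 mV): g_Na = 120, g_K = 36, g_L = 0.3 mS/cm², E_Na = 50,
E_K = −77, E_L = −54.4 mV, c = 1 µF/cm², with the six standard rate
functions

    α_m = 0.1(v+40)/(1−e^{−(v+40)/10})   β_m = 4 e^{−(v+65)/18}
    α_h = 0.07 e^{−(v+65)/20}            β_h = 1/(1+e^{−(v+35)/10})
    α_n = 0.01(v+55)/(1−e^{−(v+55)/10})  β_n = 0.125 e^{−(v+65)/80}

The removable singularities of the α_m, α_n quotient forms are evaluated by
their analytic limits whenever the offset voltage is within 1e-7 mV of the
singular point; elsewhere `expm1` keeps the quotient accurate. Spikes are
detected as upward crossings of 0 mV.

Synaptic conductances are absolute (nS) and divided by the membrane area to
enter the current balance as densities. The library default area is
1e-4 cm² (a 100 pF cell); the PIR-ING case study overrides it — see below.

### Synapses

Double-exponential conductances are represented by two trace variables
(a: fast/rise, b: slow/decay) incremented together on each delivered spike
and decayed exactly (`e^{−dt/τ}`) between deliveries, independent of the
membrane solver — the traces are linear ODEs and admit exact propagation.
The waveform `b − a` is scaled by `k = 1/max_t(e^{−t/τ_decay} −
e^{−t/τ_rise})`, computed in closed form from the analytic peak time, so
that the configured `g_peak` is the per-spike peak conductance (for the
benchmark constants τ = 0.99/1.0 ms, k ≈ 270.5). Traces accumulate the
per-spike weight, so heterogeneous weights superpose linearly. A config
flag (`literal_weights`) reproduces the alternative convention in which the
weight additionally multiplies the conductance prefactor (weight applied
twice); it exists for comparison only.

The degenerate alpha-function limit τ_rise = τ_decay is rejected rather
than special-cased: the benchmark never uses it and silently switching
functional forms would change `k` discontinuously.

## Numerics

- **Event queue.** A ring buffer with one dense accumulator slot per step;
  a spike emitted at grid point `k` with delay `d` is delivered at exactly
  `k + round(d/dt)`, never earlier. Delays must be ≥ dt (causality) and on
  the dt grid within 1e-6 ms; all benchmark delays (0.5, 0.8, 2.1 ms at
  dt = 0.1; 3 ms at dt = 0.05) are on-grid.
- **Update order** per step, fixed: deliver due events → advance synapse
  traces → advance membranes → threshold/reset/refractory → record →
  enqueue emitted spikes. The order changes same-step semantics, so it is
  part of the contract; identical (config, seed) give byte-identical spike
  records.
- **Solvers.** LIF: exact propagator. HH: classical RK4 on (v, m, h, n)
  with the synaptic conductances evaluated analytically at the stage
  offsets 0, dt/2, dt (exact trace decay), or exponential Euler — gating
  relaxed exactly toward α/(α+β), membrane relaxed toward its
  conductance-weighted equilibrium. RK4 at dt = 0.05 ms agrees with
  dt = 0.005 ms to < 0.1 mV on subthreshold trajectories; exponential Euler
  is ~3× faster and agrees with RK4 on network statistics (not on exact
  spike times).
- **Lookup tables.** Uniform voltage grid over [−100, +50] mV (151 entries
  at 1 mV), linear interpolation, no extrapolation. Accuracy is quantified
  as the maximum relative error of interpolated vs directly evaluated rate
  functions over ≥ 10 probes per sample; the alternative reading of
  accuracy (error in simulated spike timing) is not implemented. Measured:
  < 0.3% at 0.1 mV steps, < 5% at 1 mV steps, non-increasing as the step
  shrinks.
- **Poisson generators.** Per-step Bernoulli thinning, p = rate·dt/1000,
  valid for p ≤ 0.1 (p = 0.005 for the benchmark's 50 Hz at 0.1 ms). The
  generator consumes one uniform per step regardless of rate so that
  changing the rate does not shift the random stream.
- **Oscillation detection.** The 1 ms-binned, mean-subtracted population
  rate is spectrally estimated with Welch's method (nperseg ≤ 256); the
  largest peak inside the requested band is reported, and flagged
  significant only above 5× the median non-DC power. Segment averaging is
  what makes the 5× rule meaningful: the raw periodogram of a flat
  (Poisson) record exceeds 5× its median with high probability by
  extreme-value statistics alone.
- **Failure handling.** Non-finite state aborts the run naming the step
  and variable. RK4 raises on non-finite stage derivatives.

## Randomness and reproducibility

All randomness flows through numpy `Generator`s (PCG64). Case-study
builders spawn independent child seeds from the experiment seed via
`SeedSequence` in a fixed order (one child per projection, one for initial
conditions, one for drive), so connectivity, initial state and drive are
independently reproducible. Bernoulli wiring consumes one uniform per
candidate pair in row-major order over presynaptic ids; fixed-out-degree
wiring consumes one `choice` call per source in ascending order — the
generation order is part of the format so edge lists are byte-stable.
Autapses and duplicate pairs are never generated (the stock connectors of
the major simulators behave the same; multapse-permitting wiring would
make the exact edge counts untestable).

## Case-study conditions and design choices

- **PING initial state:** all membranes at v_r. The first ~50 ms transient
  therefore differs from runs initialized at random potentials; the
  steady-state rhythm does not.
- **PING layout:** excitatory ids [0, 4000), inhibitory [4000, 5000),
  generators [5000, 5500).
- **PIR-ING initial state:** v ~ U(−75, −55) mV per neuron, gating at the
  steady state for the drawn voltage. Started instead from identical
  resting states with no drive, the network is provably silent — the
  rebound mechanism requires heterogeneity, and the test suite asserts
  both regimes.
- **PIR-ING membrane area: 8e-6 cm² (8 pF).** The benchmark description
  fixes g_i = 2 nS but not the cell size that converts it to a density.
  With a 100 pF cell the compound inhibition of ~14 coincident 2 nS inputs
  peaks near 0.3 mS/cm² for ~2 ms — too weak and too brief to
  de-inactivate sodium channels, so the network fires one volley and dies.
  An 8 pF cell (typical of small interneurons) scales the same conductance
  to levels at which release from inhibition reliably triggers rebound: a
  sweep over areas {100, 50, 20, 10, 8, 6, 5} pF showed sustained,
  significant ~62 Hz gamma in 10/10 seeds at ≤ 8 pF for both solvers, and
  8 pF is the adopted default. This is a calibration of an unspecified
  physical parameter to the qualitative regime the model is known for, not
  a fitted quantity.
- **PIR-ING silent excitatory synapse:** integrated every step with zero
  peak conductance and no afferents, purely to keep seven ODEs per neuron
  in the state vector (equation-count parity with simulators whose HH
  module has two built-in synapses).
- **Wall-clock build/simulation times** are measured and reported but
  never asserted: they are hardware facts, not model facts.

## Code metrics

LOC counts non-empty lines and NOC counts non-newline characters after
normalization: comments stripped per dialect (hash `#`, C `//` + `/*…*/`,
colon `:` as in NMODL), blank lines dropped, horizontal whitespace runs
collapsed to one space and line ends trimmed. String literals are protected
in the hash and C dialects so embedded comment markers survive.
Collapsing — rather than deleting — internal spaces is the default because
deletion merges tokens (`int x` → `intx`) and changes what a user would
actually have to type; a `remove` mode implements the stricter reading.
Normalization is idempotent, and the metric is additive over concatenated
normalized files.

## What the tests do and do not show

The synthetic experiments are the study conditions themselves (the
benchmark networks are fully specified by parameters, not data), so the
suite checks the model-level claims directly: exactness of the linear
propagators, solver convergence order, conductance peak calibration,
refractory floor on the full 5,000-neuron run, gamma-band spectral peaks
over multiple seeds, and bit-level determinism. What passing does *not*
show: agreement with any specific third-party simulator's spike-by-spike
trajectory (chaotic network dynamics amplify solver-level differences; the
benchmarked simulators disagree with each other in the same way), absolute
wall-clock performance, and behavior of the HH model outside the tabulated
voltage range. Problem sizes in the suite are the full benchmark sizes for
both case studies; only auxiliary property checks (determinism,
solver-agreement) use reduced networks, chosen because the properties are
size-independent code-path facts.
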