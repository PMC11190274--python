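# Methods

`biosnn` is a desk-scale software simulator for biomimetic spiking neural
networks of the kind implemented on real-time neuromorphic FPGA platforms:
conductance-based neurons advanced in fixed 31.25 µs steps, with the gating
kinetics folded into premultiplied lookup tables, kinetic receptor synapses,
Ornstein–Uhlenbeck background noise, distance-dependent network generators,
burst analytics and a closed-loop stimulation harness.  This note documents
the models, the numerical choices, and what the shipped tests do and do not
demonstrate.

## Neuron model

Neurons are single-compartment Hodgkin–Huxley cells in the Pospischil
cortical formulation.  The membrane equation (units: mV, ms, µA/cm²,
mS/cm², µF/cm²) is

    C_m dV/dt = −g_leak (V − E_leak) − Σ_c g_c Π_k x_k^{p_k} (V − E_c)
                + I_noise + I_syn + I_stim

with up to five voltage-gated currents besides the leak: fast Na (m³h),
delayed-rectifier K (n⁴), slow muscarinic K (p; spike-frequency adaptation),
and high-threshold (q²r) or low-threshold (s²u, s instantaneous) Ca currents.
Each gate x follows first-order kinetics in either the α/β or the x∞/τ form.
Four presets are shipped as JSON data files:

| preset | currents                | character |
|--------|-------------------------|-----------|
| FS     | leak, Na, Kd            | fast spiking, non-adapting (inhibitory) |
| RS     | leak, Na, Kd, M         | regular spiking with adaptation (excitatory) |
| IB     | leak, Na, Kd, M, Ca-L   | initial burst at stimulus onset |
| LTS    | leak, Na, Kd, M, Ca-T   | low-threshold rebound bursting |

Parameter values are representative published values of this model family.
Two deliberate preset choices: FS carries no M current (the class is defined
by its absence of adaptation), and IB uses g_CaL = 0.17, g_M = 0.07 mS/cm²,
which we verified produce the class-defining initial doublet/burst under step
current.  The kinetics are data: every gate references a named rate-function
family with parameters, so new channel dynamics are added without touching
the solver.

Spike detection is a strict upward crossing of a per-preset threshold
(default 0 mV); one event per crossing.  Refractoriness is intrinsic to the
model (Na inactivation), not imposed.

## Premultiplied rate tables

The engine never evaluates rate functions at run time.  For each gate a
table stores, on a voltage grid, the pair

    r1(V) = 1 − dt·(α(V) + β(V))      r2(V) = dt·α(V)          (α/β form)
    r1(V) = 1 − dt/τ(V)               r2(V) = dt·x∞(V)/τ(V)    (x∞/τ form)

so one gate step is a single multiply-add `x ← r1·x + r2`, clamped to [0,1].
Instantaneous gates store r1 = 0, r2 = x∞, pinning them to steady state with
the same operation.  The default grid is 2048 entries spanning −76..52 mV
(the fixed block-RAM size and voltage range of the mirrored hardware); both
are configurable.

Numerical choices, fixed for bit-reproducibility:

* **Indexing** is floor of `(V − vmin)/step`, clamped at both ends, without
  interpolation — one memory read, exactly as a hardware table lookup.
  Out-of-range voltages reuse the boundary kinetics.
* **Evaluation voltages are entry centers** (`vmin + (i + ½)·step`), making
  the lookup a nearest-sample quantization of V.  Evaluating at left edges
  instead introduces a systematic half-bin rate bias that accumulates to
  multi-millisecond spike-time drift over tens of seconds; center evaluation
  removes the bias at identical cost.
* **Clamping after the multiply-add** guarantees gates stay in [0,1] under
  arbitrarily coarse tables.
* Update ordering per step mirrors a staged datapath: gates advance first
  from V_n, ionic currents are assembled from the *new* gates at V_n, the
  voltage integrates last, and the noise sample entering the sum is the
  previous step's.  The exact-rate reference stepper uses the identical
  ordering and the identical multiply-add arrangement, so for constant-rate
  kinetics the two paths are bit-identical.

### Oracle equivalence and its protocol

The table engine is validated against a double-precision stepper that
evaluates the rate functions exactly.  The comparison protocol is 40 ms
current pulses every 500 ms for 10 s (amplitudes per preset: RS 1.0, FS 1.0,
IB 3.0, LTS 1.0 µA/cm²), after which spike counts must be equal and
spike-time offsets below 1 ms.  Pulses are used rather than sustained
current because a tonically firing neuron is a free-running oscillator: any
method difference, however small, accumulates as phase drift linear in time,
which measures elapsed cycles rather than table accuracy.  Between pulses
the membrane returns to rest, so each evoked response is an independent
locked comparison.  Under sustained drive the same comparison holds to
within 1 ms over 2 s.

The refinement property (doubling table entries never increases the maximum
voltage deviation from the oracle) is checked on a subthreshold pulse
protocol, where the voltage trace is smooth and the deviation directly
reflects table quantization rather than spike-edge timing.

## Noise

Background synaptic bombardment is an Ornstein–Uhlenbeck current per neuron,

    I' = I + θ(µ − I)dt + σ√dt·N(0,1),

integrated with the Euler–Maruyama step (the same named solver as the
voltage path, not the exact exponential update).  Stationary moments are
mean µ and variance σ²/2θ.  Defaults shipped with every preset:
µ = 0 µA/cm², θ = 1/15 ms⁻¹ (15 ms correlation time), σ = 0.2 µA/cm²·ms^−½,
calibrated once so an isolated neuron fires spontaneously at ~1 Hz — the
sparse background typical of organoid cultures.  Every neuron owns an
independent generator spawned from the run's master seed, so trajectories
are bit-reproducible and independent of how many neurons are monitored.

## Synapses

Receptors follow the Destexhe kinetic scheme.  A presynaptic spike releases
a 1 mM transmitter pulse for 1 ms; the bound fraction r obeys
`dr/dt = α[T](1−r) − βr`.  Conductance activations: r for AMPA and GABA_A;
B(V)·r for NMDA with the magnesium block `B(V) = 1/(1 + exp(−0.062 V)·[Mg]/3.57)`;
and `s⁴/(s⁴ + Kd)` for GABA_B, whose second messenger follows
`ds/dt = K3·r − K4·s`.  Kinetic constants default to the published values
(AMPA α=1.1 mM⁻¹ms⁻¹ β=0.19 ms⁻¹; NMDA 0.072/0.0066, Mg 1 mM;
GABA_A 5.0/0.18; GABA_B K1=0.09, K2=0.0012, K3=0.18, K4=0.034, Kd=100, n=4).

Receptor state is stored per presynaptic neuron and kind — exact, because
all synapses of a kind leaving one neuron share their kinetics — so the
per-step synaptic drive is one sparse matrix–vector product per receptor
kind.  Spikes reach synapses with a one-step (31.25 µs) latency, mirroring a
pipelined datapath.  Weights are 14-bit fixed-point codes scaled by a global
software weight factor (the mechanism for mimicking a larger network with
few neurons); there are no transmission delays (a per-synapse delay field is
reserved, default 0) and no plasticity.

## Mixed-precision emulation

The mirrored hardware computes channel states and currents in 32-bit float
and the remaining paths in fixed point (32-bit accumulation, 25-bit noise,
18-bit synapses, 14-bit weights).  The exact Q-splits and rounding modes are
not public, so `faithful` mode implements an explicit emulation policy:
truncation toward −∞ with silent, counted saturation, and the splits
weight 14/12, synapse 18/16, noise 25/20, accumulator 32/20.  The
accumulator integer width (±2048 µA/cm²) was sized to cover spike-peak
ionic currents; a narrower split saturates at the action-potential peak and
audibly distorts firing, which the saturation counters expose.  `float64`
mode (default) bypasses all quantization.  The policy is validated by an
accuracy-neutrality property: spike trains in the two modes stay within
1 ms of each other for the preset neurons under tonic drive, with zero
saturation events.

## Network generation

Neurons get normally distributed XY positions around their group center
(σ = 1 spatial unit by default); the organoid radius is r_org = 2σ unless
given.  Ordered pairs connect independently with

* within an organoid: `p = p_max·(1 − d/r_org)` clamped to [0,1]
  (close-neighbor rule, default maximum 10%),
* between the two organoids of a connectoid:
  `p = p_max·½·(d_pre/r_pre + d_post/r_post)` clamped (exterior-ring rule,
  default maximum 2%),
* between clusters of the brain-like variant: a flat probability, with the
  close-neighbor kernel inside each cluster.

Excitation/inhibition: 20% of each group are FS inhibitory neurons emitting
GABA_A synapses, the rest RS excitatory neurons emitting AMPA, with the
count deterministic (`round(ei_ratio·n)`) and membership seed-shuffled, so
the configured ratio holds exactly.  Autapses are excluded by the generators
(though the engine accepts them).  Networks are capped at 1024 neurons and
2²⁰ = 1024² synapse slots.  Receptor antagonists (e.g. CNQX for AMPA,
bicuculline for GABA_A) are emulated by removing all — or a seeded random
fraction of — synapses of one kind.

### Scaled organoid demonstration

The headline network demonstration runs at 2×128 neurons (scaled down from
2×512) for 10 s.  At that scale the recurrent weights are calibrated once to
AMPA 0.85 / GABA_A 1.4 (`netgen.organoid_demo_spec`), chosen so an isolated
organoid produces sparse spontaneous network bursts over ~1 Hz background.
Under these fixed conditions the connectoid synchronizes bursts across
organoids (matching fraction ≈ 1 within ±100 ms) while the separated
structure's organoids burst independently (matching fraction ≈ 0).  The
comparison is directional and stochastic; it is asserted per seed, not as a
population statistic.

## Analytics

Bursts use the string method: maximal runs of spikes with inter-spike
intervals ≤ 100 ms and at least 5 spikes.  (The published description of
this detector garbles the second parameter as "5 ms as minimum number of
intra-burst spikes"; it is read here as a minimum of 5 spikes.)  Biomarkers:
MFR (spikes/s, per unit by default; a network-total variant is a flag), MBR
(bursts/min), BD (ms), ISI (ms), and IBI defined end-of-burst to
start-of-next (the start-to-start alternative is a one-line change and was
not taken, since end-to-start reflects the silent gap).  Network bursts
threshold a sliding-window sum of all-neuron spike counts (10 ms window on
the SNN side, 250 ms on the biological counterpart side) with a one-window
lockout against retriggering; thresholds are experiment-specific required
configuration.

Configuration grading min–max-normalizes |simulated − target| per biomarker
across a configuration set: the closest configuration grades 1, the
farthest 0, ties guarded to 1.  The aggregate grade is the unweighted mean
across biomarkers (weights configurable); ranking uses the aggregate.
Group comparison is the two-sided Mann–Whitney rank-sum test.

## Closed loop

The harness couples a running simulation to any counterpart implementing a
two-method contract (`emit_counts(frame)` at 1 ms cadence,
`receive_pulse(t, pulse)`).  Detection on the counterpart stream (250 ms
window) triggers a 3.120 ms, 30 µA/cm² (= 0.03 mA/cm²) current pulse to the
exterior-ring neurons of the organoid — the quantile-based farthest 25% from
their group center, the fraction being configurable since "exterior ring" is
not quantified.  Detection on the SNN stream (10 ms window) sends a 500 µs /
500 mV electrode pulse descriptor to the counterpart.  Command latency is a
configurable simulated quantity (default 0); wall-clock behavior is out of
scope.  The scripted mock counterpart can echo stimulation artifacts into
its own stream to reproduce the escalation hazard of real setups.

## Raster formats

Three formats mirror the monitoring streams: bit-packed (1 bit per neuron
per collection interval, little-endian within bytes — exact occupancy,
aliases multiple spikes per interval), cumulative (running per-neuron uint32
counts — exact per-frame counts), and CSV (`neuron_id,time_ms` — lossless).
The hardware stream frames out of band, so files here prepend a
self-describing little-endian header with a version byte.  Collection
intervals are restricted to 1–255 ms.  For lossless counts the cumulative
format is recommended.

## Problem sizes and limitations

Shipped checks run at desk scale: 10 s single-neuron validations, 2×128
network demonstrations, 40-generation connectivity statistics — sizes chosen
so the whole suite completes in minutes on one CPU while exercising every
code path at the fidelity the claims require.  The generator emulates
organoid-like geometry and connectivity statistics, not axon-bundle growth,
microfluidic geometry, plasticity, conduction delays, temperature
dependence, or multi-compartment morphology.  Passing tests show the
numerical machinery reproduces its own exact-rate oracle and the documented
emergent regime under the calibrated study conditions; they do not certify
agreement with any particular biological recording, and the biological-side
thresholds of the closed loop remain experiment-specific inputs.
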