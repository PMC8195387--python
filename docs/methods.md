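# Methods

`reweave` simulates homeostatic structural plasticity in a balanced cortical
spiking network subjected to a peripheral lesion, and the analysis used to
characterise the repair process. This note documents the model, the choices
made where the design was open, the desk-scale study conditions, and what
the test suite does and does not demonstrate.

## The network model

**Neurons.** Conductance-based leaky integrate-and-fire point neurons:

    C dV/dt = -g_L (V - E_L) - g_exc (V - E_exc) - g_inh (V - E_inh) + I_e

with C = 200 pF, g_L = 10 nS, E_L = V_reset = -60 mV, V_th = -50 mV,
E_exc = 0 mV, E_inh = -80 mV, t_ref = 5 ms. Synaptic conductances decay
exponentially (tau_exc = 5 ms, tau_inh = 10 ms) and jump by the synaptic
weight on each presynaptic spike. The membrane is integrated by forward
Euler at 0.1 ms with exact exponential decay of the conductances; spikes are
detected on the upward threshold crossing. Each neuron also carries a
calcium trace — the activity proxy for structural plasticity — that decays
with tau_Ca (50 s at full clocks) and jumps by beta = 0.1 per spike, so its
mean under rate r is `beta * r * tau_Ca`.

**Populations and space.** 8000 excitatory (E) neurons on a jittered
100 x 80 lattice (150 +/- 15 um spacing) and 2000 inhibitory (I) neurons
interleaved on a 50 x 40 lattice (300 um spacing), wrapped into a torus.
Regions are assigned by per-population distance rank from the grid centre:
the nearest 2.5% form the lesion projection zone centre (LPZ-C), the next
2.5% its inner border (LPZ-B), the next 5% the peri-LPZ, the remaining 90%
"other". Rank-based assignment hits these fractions exactly at any scale
and keeps the E:I ratio uniform across regions.

**Wiring.** Every neuron makes `n_out = round(0.02 (N-1))` outgoing
synapses, targets drawn without replacement (no autapses; parallel synapses
allowed) with Gaussian spatial weights `exp(-(d / (w mu_dE))^2)`, w = 8 for
excitatory sources and w = 24 for inhibitory ones — the same kernel family
used for synapse formation during rewiring, so a single spatial model
governs the connectome throughout. EE and EI conductances are drawn from
N(0.5, 0.1) nS, II from N(5, 0.1) nS; IE synapses are plastic and start
at zero.

**Inhibitory STDP.** IE conductances follow the symmetric inhibitory STDP
rule: per-neuron spike traces x decay with tau_STDP = 20 ms and increment by
1 at each spike; on a presynaptic (I) spike the weight changes by
`eta ḡ (x_post - alpha)` and on a postsynaptic (E) spike by `eta ḡ x_pre`
(eta = 0.05, alpha = 0.12, ḡ the unit conductance), clipped at zero. The
fixed point pushes excitatory firing toward `alpha / (2 tau_STDP)` = 3 Hz.
The published source gives the rule's parameters but not its equations;
this canonical form of the cited mechanism reproduces the required
balancing behaviour. Traces of all neurons that spike in a time step are
incremented before spike propagation; pre/post updates landing in the same
0.1 ms step therefore see each other's increment, a convention whose effect
is far below the learning-rate scale.

**External drive.** Each neuron receives an independent 10 Hz Poisson train
(Bernoulli thinning at the membrane step) through 8 nS (E) or 12 nS (I)
conductances. Deafferentation permanently disconnects this drive from all
LPZ-C and LPZ-B neurons of both populations; recurrent synapses are
untouched.

## Structural plasticity

Each neuron owns three element pools: axonal (carrying its population's
polarity), dendritic-excitatory and dendritic-inhibitory. A continuous
count z per pool evolves every 0.1 s growth step by the Gaussian growth
rule

    dz/dt = nu (2 exp(-((Ca - xi)/zeta)^2) - omega),

which is positive exactly on (eta, epsilon), peaks at `nu (2 - omega)` at
the window midpoint and tends to `-nu omega` at high calcium; z is clamped
at zero. Windows are positioned per neuron as multiples of its optimal
activity psi. The reference ("G2") configuration:

| pool               | window            | nu (per s) | omega |
|--------------------|-------------------|-----------:|------:|
| E axonal           | (psi, 1.75 psi)   | 1.5e-2     | 1e-2  |
| I axonal           | (0.25 psi, psi)   | 0.3        | 4e-4  |
| dendritic E (on E) | (0.25 psi, psi)   | 3e-4       | 0.4   |
| dendritic I (on E) | (psi, 3.5 psi)    | 3e-3       | 4e-2  |
| dendritic E (on I) | (0.25 psi, psi)   | 3e-4       | 0.4   |
| dendritic I (on I) | (psi, 3.5 psi)    | 3e-4       | 0.4   |

(The published scaling factors are quoted per 0.1 s step; they are stored
per second so the growth step is configurable.) Excitatory dendritic
elements thus sprout below the optimum (stable fixed point at epsilon =
psi) and inhibitory dendritic elements above it (stable fixed point at
eta = psi); excitatory axons sprout above, inhibitory axons below. The
regime battery G0-G5 (plus G0' = activity-independent constant sprouting)
re-positions the axonal windows only.

**Connectivity updates** run every 1 s of simulated time, in order:

1. *Deletion.* Each pool whose continuous count fell below its connected
   count loses `floor(z_connected - z)` synapses. Excitatory-class pools
   delete uniformly at random; inhibitory-class pools (II and IE compete)
   delete with probability weights `exp(-(g / 2 g_th)^2)` among non-immune
   candidates — synapses with g >= g_th are never candidates. Pools are
   visited in random order and each recomputes its remaining need, since a
   deletion serves both of its endpoint pools. Both endpoints' elements
   return to their free pools (where decay will claim them if unused).
2. *Harvest.* `z_free = floor(max(z - z_connected, 0))` per pool.
3. *Formation.* Per polarity, each free axonal element draws one candidate
   from the network-wide supply of free dendritic slots (uniformly per
   slot, excluding its own neuron) and forms a synapse with probability
   `p̂ exp(-(d / (w mu_dE))^2)` (p̂ = 0.8 / 0.3, w = 8 / 24 for E / I), so
   the acceptance rate over distance follows the kernel exactly. Sources
   are visited in random order; formation never exceeds either side's free
   supply. New EE/EI conductances are drawn from N(ḡ, 0.1) nS, II from
   N(10ḡ, 0.1) nS, and IE from a Gaussian around the mean learned IE
   conductance recorded at balance, so rewired inhibition is neither
   instantly deleted as weakest-in-pool nor invisible to the deletion rule.
4. *Decay.* Free elements decay by `z_free <- floor(z_free - tau_free
   z_free)` once per growth step (tau_free = 0.01), with the continuous
   total reduced by the same amount so decayed elements cannot be
   re-harvested.

The immunity threshold g_th is not given in the published parameter tables
("calculated during the simulation"); here it is set to the mean learned IE
conductance recorded at the end of balancing — the only simulation-derived
conductance scale the model names for inhibitory synapses.

## Experiment protocol

Phase 1 (0..t1): inhibitory STDP only, from a fresh connectome, until the
network reaches its low-rate asynchronous-irregular (AI) state. At t1 each
neuron's optimal activity psi is recorded and its growth curves are
instantiated; psi is the *time average* of the calcium trace over the last
~20 s of balancing rather than a point sample — the trace fluctuates with
relative SD `1/sqrt(2 r tau_Ca)`, and a point sample would freeze that
fluctuation into a permanent per-neuron growth bias. The mean IE
conductance (hence g_th and the new-IE mean) is recorded at the same
moment. Element counts are initialised to the connected counts, so
structural plasticity starts at its fixed point. Phase 1b (t1..t2): both
mechanisms on, verifying the network stays balanced. At t2 the LPZ is
deafferented and the network reorganises until t_end. Runaway activity
(mean rate above 10x the balanced rate sustained for 10 s, or a spike
buffer sized at 400 Hz/neuron overflowing) terminates a run and marks its
artifacts; for some regimes and toggle settings this is the expected
outcome.

The AI criterion is evaluated as: mean ISI coefficient of variation > 1
(neurons with fewer than two intervals excluded) AND the SD of the
population rate < 5 Hz, with the population rate estimated from the spike
histogram at the 5 ms synchrony bin converted to Hz per neuron. Mean
pairwise Pearson correlation of 5 ms-binned trains (sampling: all neurons
if <= 800, else the larger of 800 and 10%) is reported against the 0.1
asynchrony convention.

## Desk-scale study conditions

The published experiment (10,000 neurons, 18,000 s, on the order of a week
of cluster time) is supported but not what the test suite runs. The
`make_fixture` conditions compress the model in size and time while
preserving its structure; all compressions are recorded in the run
manifest:

- **Size.** `scale` multiplies neuron counts (0.2 -> 1600 E + 400 I);
  lattices stay even-by-even near the full aspect ratio; sparsity, E:I
  ratio, region fractions and all per-neuron constants are preserved.
- **Coupling.** Recurrent unit conductances scale as `scale^-0.75`,
  between mean-input-preserving (1/scale) and fluctuation-preserving
  (1/sqrt(scale)) downscaling. At 1/scale the reduced network's pairwise
  correlations inflate until the population-rate SD breaches the AI bound;
  at 1/sqrt(scale) firing becomes externally driven and too regular
  (ISI CV < 1). The intermediate exponent satisfies both AI components
  with margin across seeds.
- **Spatial kernels** shrink with the torus's linear size (w multiplied by
  sqrt(scale)), preserving the reach of excitatory/inhibitory projections
  relative to the lesion geometry.
- **Clocks.** STDP learning runs 10x fast during set-up (balancing:
  1500 s -> 160 s) and at its published rate after the lesion, so that
  post-lesion activity deviations persist on the calcium-trace timescale
  instead of being cancelled before the growth rules can integrate them.
  Neurite growth runs 50x fast (repair: 16,000 s -> ~600 s), and the
  free-element decay clock compresses by the same factor (tau_free
  0.01 -> `1 - 0.99^50` ~ 0.39 per step), keeping the standing crop of
  unpaired elements — growth rate over decay rate — at its full-clock
  value. The calcium time constant shrinks 50 s -> 10 s so the activity
  estimate can track the compressed schedule.

**What the fixture does not emulate.** Absolute synapse counts (the
published ~3x10^4 -> ~5x10^4 growth of excitatory inputs to the LPZ centre
is a full-scale quantity), exact firing-rate percentages, and any quantity
that depends on the slow-fluctuation statistics of the 50 s calcium trace.
Desk-scale lesion results are read as directions and orderings (collapse,
recovery, ingrowth, outgrowth, dis-inhibition, border-before-centre), not
magnitudes. Passing tests show the mechanisms interlock as described at
reduced size and compressed time; they do not certify the full-scale
numbers.

A finding about the lesion response in this reconstruction: with
kernel-based initial wiring, the silenced zone removes long-range
inhibition from the outside bulk but short-range excitation from the
adjacent ring. At a converged balance the two nearly cancel: frozen-weight
probes show the outside rate within a few percent of baseline at 0.2 scale
and moderately *below* it at 0.4 scale, with the adjacent ring dipping
clearly (-15 to -30%) before recovering. The outside activity *gain*
reported for the published model does not emerge robustly here at desk
scale (probes taken before the balance had converged do show apparent
gains, but those are rebound artifacts of freezing a still-adapting
network). The corresponding acceptance check is asserted as published and
fails; repair in these runs is carried by the disinhibition of the LPZ and
by fluctuation-driven element turnover rather than by a sustained
supra-optimal drive outside the LPZ.

## Single-neuron experiment

An isolated neuron under constant current defines psi; under a reduced
(sub-optimal) current it grows dendritic elements with identical windows
for both polarities and a 4:1 excitatory:inhibitory speed ratio, matching
the in-degree composition of the balanced network (the 4.0 ratio is exact
because both pools integrate the same normalised curve). The baseline
current is then restored, the reference dendritic rules re-instated, and
the current modulated sinusoidally starting with an activity dip — the
deprivation the dendritic rules are built to counter. The implied net
input conductance `g_net = z_postE g_EE - z_postI g_IE` (g_EE = 0.5 nS,
g_IE = 2 nS per element, the balanced-network means) is tracked as a
deviation from baseline; its Pearson correlation with the calcium
deviation from psi is negative: turnover opposes the imposed activity
fluctuation. Because element counts integrate the growth rule, the
response lags the stimulus; the correlation's magnitude depends on the
modulation period and count, its sign on the asymmetry of the
above-optimum and below-optimum responses. The baseline current (120 pA)
sits safely above the 100 pA rheobase; the grow-in current (87.5% of
baseline) keeps the neuron inside the sub-optimal growth window rather
than silencing it.

## Numerical choices and degenerate inputs

- Growth-curve construction rejects eta >= epsilon, nu < 0 and omega
  outside (0, 2); the constant-sprouting curve (G0') is realised as a
  window vastly wider than any attainable calcium value.
- psi is floored at a small positive value (1e-3) so that a neuron silent
  at balance still receives well-formed curves.
- Element counts: continuous totals clamp at zero; harvested free counts
  and losses use floor arithmetic exactly as specified; the engine
  validates after every update (optionally) that per-pool connected counts
  equal the synapse table's incident counts, aborting on mismatch.
- All randomness flows from named, independent streams (placement, wiring,
  membrane/drive, plasticity) spawned from one seed; the compiled kernel
  carries an explicit xorshift128+ state so identical seeds give
  bit-identical rasters.
- Deletion with every candidate immune deletes nothing (the pool's deficit
  is re-evaluated at the next update); formation with no counterpart slots
  leaves free elements to decay.

## Known limitations

- Point neurons carry a single calcium trace, so a neuron can only sprout
  or retract a given element class as a whole; no compartmental or
  morphological detail.
- No synaptic transmission delays beyond the membrane step.
- The inhibitory STDP equations are the canonical form of the cited rule,
  not transcribed from the source (which lists only parameters).
- Desk-scale conditions cannot reproduce full-scale synapse counts or the
  published percentage rate changes; those remain full-scale quantities.
- The "Mexican hat" connectivity family is out of scope; the spatial
  kernel is a single Gaussian per source class.
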