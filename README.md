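# reweave

Homeostatic structural plasticity in balanced spiking networks: a simulator
of cortical remapping after peripheral lesions.

## The problem

After a peripheral lesion, the cortical region deprived of its input — the
lesion projection zone (LPZ) — falls silent, and over weeks the surrounding
network rewires: excitatory axons sprout *into* the LPZ, inhibitory axons
grow *out* of it, the LPZ is transiently dis-inhibited, and activity
returns from the border inward. `reweave` models this process in a
conductance-based leaky integrate-and-fire network (8000 excitatory + 2000
inhibitory neurons on a torus, 2% connectivity) balanced to the low-rate
asynchronous-irregular (AI) regime by inhibitory spike-timing-dependent
plasticity, with every neuron growing and retracting *synaptic elements* —
abstract axonal and dendritic contact points — according to Gaussian growth
rules driven by its calcium trace Ca (an exponential average of its own
spiking):

    dz/dt = nu * ( 2 exp( -((Ca - xi)/zeta)^2 ) - omega ),
    xi = (eta + epsilon)/2,   zeta = (epsilon - eta) / (2 sqrt(-ln(omega/2)))

Elements sprout for eta < Ca < epsilon and retract outside; free elements
pair across neurons (excitatory axonal with excitatory dendritic, likewise
inhibitory) with a distance-dependent probability to form synapses, and a
weight-dependent rule with an immunity threshold deletes them. Opposing
growth windows for excitatory and inhibitory neurites — excitatory dendrites
and inhibitory axons sprout *below* each neuron's optimal activity psi,
inhibitory dendrites and excitatory axons *above* it — turn out to be the
configuration that reproduces the experimentally observed course of repair.

The package is for computational neuroscientists who want to run, perturb
and analyse such lesion experiments: the growth-regime battery (G0–G5),
mechanism toggles (synaptic-only / structural-only / both), a single-neuron
homeostasis experiment, and the analysis stack (rate maps, ISI CV, binned
pairwise correlations, the AI criterion, region-resolved connectivity
summaries and the repair-feature checklist).

## Worked example

Balance a desk-scale network (1600 E + 400 I, compressed clocks) and verify
its AI state:

```bash
reweave balance --scale 0.2 --seed 1 --out runs/balance
```

which prints (seed 1):

```json
{"ai_ok": true, "isi_cv": 1.0878612983054776, "rate_sd_hz": 2.3534113452603225, "mean_rate_hz": 3.6748}
```

— the network fires irregularly (ISI coefficient of variation 1.09 > 1) at
3.7 Hz with small population-rate fluctuations (2.4 Hz < 5 Hz): the AI
state. The same in Python, continuing into a lesion experiment:

```python
from reweave import make_fixture, run_lesion_experiment, repair_feature_checklist

cfg = make_fixture(0.4, seed=1, t_repair_s=600.0)
art = run_lesion_experiment(cfg)
print(repair_feature_checklist(art))
```

The checklist reports, for the reference growth regime, whether the run
showed initial stability, LPZ rate collapse and recovery, normalisation
outside the LPZ, a final balanced state, border-before-centre recovery
ordering, excitatory ingrowth into the LPZ centre, inhibitory outgrowth
from the LPZ, and transient dis-inhibition. (Two rows — the strict
dip-then-recover form of dis-inhibition and the border-before-centre
ordering — report `False` on desk-scale runs; `docs/methods.md` discusses
which published repair features survive the compression and which do
not.) `reweave lesion --no-structural` and `--no-istdp` run the
mechanism-toggle controls; `reweave regimes` runs the axonal growth-curve
battery. `reweave single-neuron --seed 1` runs the isolated-neuron
experiment and prints

```json
{"psi": 12.204187242078964, "init_ratio": 4.0, "corr_ca_dgnet": -0.2260047205354516}
```

— the neuron's optimal calcium level, the exact 4:1 excitatory:inhibitory
dendritic element ratio after initialisation, and the negative correlation
between the activity deviation and the implied net input-conductance
change: dendritic turnover counteracts imposed activity fluctuations.

Full-scale runs (`--scale 1.0`, published clocks, 18,000 s) are supported
but take cluster-order time; see `docs/methods.md` for the desk-scale
compression and exactly what it preserves.

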