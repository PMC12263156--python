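# navdissect

Tools for dissecting the distinct contributions of the sodium-channel
isoforms NaV1.2 (*Scn2a*) and NaV1.6 (*Scn8a*) to neocortical
pyramidal-cell excitability, built around state-dependent aryl-sulfonamide
(ASC) channel blockers and the chemico-genetic YW→SR motif substitution
that renders a channel drug-insensitive.

It is written for computational neuroscientists and electrophysiologists
who want to (a) simulate a reduced layer-5 pyramidal cell in which each
isoform's density, spatial distribution, and pharmacological availability
can be manipulated independently, and (b) analyse voltage recordings and
voltage-clamp data with the same feature definitions and curve fits used
at the rig.

## What is inside

* **Channel kinetics** — Hodgkin–Huxley m³h sodium channels parameterized
  by measured steady-state Boltzmann curves,

      activation:    G/Gmax = 1 − 1/(1 + e^((V − V½)/k))
      inactivation:  I/Imax = 1/(1 + e^((V − V½)/k)),

  with the single m-gate back-computed so that a *simulated* voltage-clamp
  protocol, fitted the way experiments are fitted, returns the tabulated
  (V½, k) for each isoform/genotype.
* **ASC pharmacology** — a two-state binding model gated by the
  inactivated fraction,

      db/dt = k_on·[drug]·(1 − h)·(1 − b) − k_off(V)·b,

  with k_off log-linear between the measured unbinding time constants
  (100 s at −80 mV, 1000 s at −40 mV) and k_on tied to the equilibrium
  IC50 by detailed balance.  Packaged potencies: NaV1.2 5.1 nM (YW) /
  1861 nM (SR); NaV1.6 184 nM (YW) / 87 µM (SR).
* **Neuron model** — a chain-cable compartmental cell (dendrite – soma –
  AIS – myelinated axon – node) with the empirical isoform layout: equal
  somatic densities, NaV1.2-only distal dendrites, proximal-AIS NaV1.2 /
  distal-AIS NaV1.6 ramps crossing at a configurable position, and
  NaV1.6-only axon.  Implicit (Crank–Nicolson / backward-Euler) cable
  integration with a numba core.
* **Protocols** — density and crossover sweeps, the −12 mV
  onboarding/recovery ladder, nucleated-patch pulse trains with P/8 leak
  subtraction, 10 s current-clamp trains, and a Poisson-PSP seizure-like
  protocol.
* **AP features** — phase-plane (dV/dt vs V) analysis: threshold at the
  15 V/s crossing, AIS inflection and AIS max from the second derivative,
  somatic peak dV/dt with a prominence fallback, AHP, and instantaneous
  frequency.
* **Curve fitting / synthetic data** — Boltzmann and Hill (IC50) least
  squares, and generators for every input class with serialized ground
  truth.

## Worked example

Simulate the calibrated cell's baseline response (a 300 ms somatic step
tuned to evoke 5–6 APs) and extract phase-plane features:

```bash
navdissect simulate --out demo/
```

`demo/features.csv` (first spikes, rounded):

```
   threshold  ais_inflection_dvdt  ais_max_dvdt  somatic_peak_dvdt  inst_freq
0     -46.30               120.77        210.44             561.67        NaN
1     -45.35                92.35        182.26             415.01      14.47
2     -45.34                90.90        181.99             412.71      14.43
```

Reading: the first AP fires at −46.3 mV (the 15 V/s threshold), its rising
phase carries two components — the axon-initial-segment component
(inflection at 121 V/s, AIS-to-soma handoff at 210 V/s) and the somatic
component peaking at 562 V/s — and the train settles near 14.5 Hz.
Subsequent spikes are smaller because sodium availability only partially
recovers between spikes, as in real trains.

The isoform dissection in two lines of Python:

```python
from navdissect.neuron_model import build_model
from navdissect.protocols import run_density_sweep

sweep = run_density_sweep(build_model(), "nav16")   # 100% → 0% in 10% steps
```

Reducing NaV1.6 depolarizes threshold monotonically (−46.3 → −39.6 mV by
10% density) and lowers every dV/dt component; the same sweep for NaV1.2
leaves threshold within ±0.05 mV while somatic dV/dt falls — and at
strong NaV1.2 reduction the spike count *rises* as the
afterhyperpolarization depolarizes, the dendritic NaV1.2→Kv interplay
that makes NaV1.2 block paradoxically excitatory.

## Layout

```
src/navdissect/
  channel_kinetics.py   # Boltzmann gating, HH specs, packaged parameters
  asc_pharmacology.py   # state-dependent block kinetics, potency table
  neuron_model.py       # reduced compartmental cell + cable integrator
  _engine.py            # numba time-stepping kernel
  protocols.py          # stimulation/recovery/seizure protocols
  ap_features.py        # phase-plane feature extraction
  curve_fitting.py      # Boltzmann / Hill least squares
  synthetic_data.py     # generators with ground truth
  cli_io.py             # CLI, config schema, trace formats, manifests
  data/default_model.yaml  # calibrated model parameters
```

See `docs/methods.md` for the model description, calibration choices, and
known limitations.
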