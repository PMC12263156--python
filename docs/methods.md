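# Methods

## Scope and model overview

`navdissect` implements a reduced biophysical model of a layer-5
pyramidal-tract neuron expressing two sodium-channel isoforms, NaV1.2 and
NaV1.6, together with the measurement apparatus used to study them:
voltage-clamp protocol emulation, state-dependent blocker kinetics,
phase-plane action-potential analysis, and Boltzmann/Hill curve fitting.
The package's central question is architectural: given the isoforms'
distinct spatial distributions, what does acute, selective block of each
one do to action-potential initiation, backpropagation, and firing rate?

## Channel gating

Steady-state gating is described by two-parameter Boltzmann curves
(half-voltage V½, slope factor k).  The packaged parameter set holds one
row per (isoform, genotype):

| channel      | act V½ | act k | inact V½ | inact k |
|--------------|-------:|------:|---------:|--------:|
| NaV1.2 YW    | −20.1  | 6.6   | −68.3    | 6.9     |
| NaV1.2 SR    | −18.7  | 6.4   | −68.1    | 7.1     |
| NaV1.6 YW    | −23.9  | 6.7   | −74.6    | 6.9     |
| NaV1.6 SR    | −26.1  | 6.5   | −71.9    | 7.0     |

Channels gate as m³h.  Because the *observable* in a voltage-clamp
experiment is the fitted peak-conductance curve, not the single-gate
curve, the m-gate Boltzmann is obtained by numerically inverting the
fitting map: we solve for the (V½m, km) whose cubed curve, evaluated on
the standard activation grid (−100…−20 mV in 5 mV steps), normalized, and
least-squares fitted with a free plateau, returns exactly the tabulated
parameters.  A consequence worth noting is that the m³ parameterization
decays roughly three times faster in its hyperpolarized tail than the
fitted Boltzmann — this is what lets a membrane rest stably at −80 mV
while still spiking at −46 mV.

Time constants are not observable from steady-state data.  We use
bell-shaped (Gaussian-in-voltage) τm and τh with τm ≈ 0.05–0.15 ms and,
in the cell-line context, τh ≈ 2–9 ms, shaped so the τh/τm ratio is
large and nearly voltage-independent over the test-pulse range; this
keeps simulated peak-conductance curves faithful to the steady-state
parameters (verified: every isoform/genotype row round-trips through the
simulated activation and inactivation protocols to within 0.1 mV).

### Cell-line vs neuron context

Gating measured in heterologous cells (HEK, ND7) is systematically
offset from gating in the native neuronal membrane (auxiliary subunits,
phosphorylation state, recording conditions).  `make_nav_spec` therefore
exposes two parameterization contexts:

* **cell_line** (default): the tabulated rows verbatim — used for all
  voltage-clamp protocol emulation and fitting round-trips;
* **neuron**: three documented calibration adjustments, identical for
  both isoforms and genotypes so that every isoform-relative and
  genotype-relative difference of the table is preserved:
  1. inactivation V½ depolarized by +20 mV (native availability at
     inter-spike voltages; without it, the table's V½h of −68/−75 mV
     leaves ~3% availability at a −50 mV afterhyperpolarization and no
     parameter set yields repetitive firing),
  2. the m-gate slope set to 6 mV (native channels gate more steeply
     than the heterologous-fit inversion implies), keeping the inverted
     per-isoform V½m offsets,
  3. slow subthreshold inactivation (τh up to ~50 ms between −75 and
     −45 mV, ~1.5 ms when depolarized), so availability lags fast
     trajectories — the behaviour of native transient Na current, and
     the source of a well-defined dynamic threshold.

  In the neuron context both genotypes use the wildtype gating rows: the
  chemico-genetic design premise is that the SR substitution changes
  drug binding, not gating, so any simulated genotype difference is
  attributable to block.  The reported ~2 mV NaV1.6 hyperpolarization in
  SR cells is available as an option (`sr_gating_shift`).

Supporting conductances: a fast, high-threshold Kv (V½ −5 mV, k 7,
τ ≲ 1 ms; Kv3-like) repolarizes spikes in soma/AIS/axon; a slow dendritic
Kv (V½ −20 mV, k 6, τ 25 ms) is recruited by backpropagating APs and
carries hyperpolarizing current between spikes; ohmic leak (E = −82 mV)
sets the resting input resistance.  No separate slow-inactivation gate is
implemented; at protocol timescales its phenomenology is covered by the
slow subthreshold τh.

## Drug binding

GNE-4076-class aryl sulfonamides bind a voltage-sensing-domain-IV pocket
exposed only in activated/inactivated channels and stabilize the
inactivated state.  The model is two-state per compartment and isoform:

    db/dt = k_on·C·(1 − h)·(1 − b) − k_off(V)·b

with C the bath concentration (nM), (1 − h) the inactivated fraction,
k_off(V) log-linear between the anchors τ_off(−80 mV) = 100 s and
τ_off(−40 mV) = 1000 s (clamped outside), and k_on fixed by detailed
balance against the equilibrium IC50 at the −80 mV anchor,
k_on = 1/(IC50·100 s).  Anchoring at −80 mV (rather than −40 mV) makes
200 nM onboarding of wildtype NaV1.2 > 90% complete within a 10 s
depolarization, matching nucleated-patch behaviour; the anchor is
configurable.  Bound channels conduct nothing but keep gating, so they
resume conduction in their current gating state upon unbinding.  Blocked
fractions are advanced with the exact exponential of the frozen-rate
linear ODE, so the update is unconditionally stable.

A consequence of tying k_on to IC50: NaV1.6 (IC50 184 nM) binds ~36-fold
slower than NaV1.2 (5.1 nM) at the same dose.  During a 10 s
current-clamp train, NaV1.2 accumulates roughly ten times more block than
NaV1.6, so the wildtype-plus-drug train shows progressive threshold
depolarization and falling peak dV/dt, but its firing rate drifts
slightly *up* (the NaV1.2-block excitability paradox outweighs the weak
NaV1.6 block) rather than down.  Near-complete NaV1.6 block is reached
only via long depolarized holds (the onboarding protocol).

## Morphology and channel distribution

The morphology is a chain of cylinders rooted at the soma — 500 µm
apical/distal dendrite (d 4 µm), 20 µm proximal dendrite, 30×30 µm soma,
50 µm AIS (d 1.5 µm, 20 segments), 500 µm myelinated-equivalent distal
axon (Cm 0.02 µF/cm²), and a node of Ranvier.  A chain keeps the implicit
cable system tridiagonal while retaining every compartment class the
distribution rules address.  Distribution rules:

* soma and proximal 20 µm of dendrite: equal NaV1.2/NaV1.6 densities;
* distal dendrites: NaV1.2 only;
* AIS: piecewise-linear ramps on a constant total Na density — NaV1.2
  falls to zero at twice the crossover position, NaV1.6 rises
  complementarily, so the profiles intersect at the crossover (default
  15 µm; sensitivity analysis shifts it in 3.75 µm increments over
  7.5–33.75 µm);
* distal axon and node: NaV1.6 only, the node enriched ×3 (configurable).

Global per-isoform scale factors (1 → 0) emulate graded block or
expression loss.

## Numerics

Voltage uses Crank–Nicolson (implicit half-step plus extrapolation) on
the tridiagonal cable, falling back to backward Euler during somatic
voltage clamp, where extra damping is preferable; gating uses staggered
Rush–Larsen exponential updates from 0.05 mV lookup tables built per time
step.  Default dt is 10 µs for AP-resolution phases, 100 µs for
subthreshold holds, and 50 µs for the minute-long seizure protocol.  At
10 µs, halving dt changes the measured somatic peak dV/dt by < 0.01%
(features are always measured on a fixed 50 kHz recording grid, because
the finite-difference estimate of peak dV/dt itself depends on the
sampling rate).  Voltage clamp is ideal (no series resistance); the
single-sample capacitive transient at a command step is excluded from
peak-current measurements.

## Calibration

Absolute densities were set by a calibration targeting the empirical
baseline AP of layer-5b pyramidal-tract neurons — threshold ≈ −42.5 mV,
somatic peak dV/dt ≈ 556 V/s, 5–6 spikes per 300 ms step, AP initiation
in the distal AIS, and a two-component phase-plane rising phase — and
stored in `data/default_model.yaml` so runs are deterministic.  The
calibrated baseline produces: threshold −46.3 mV, somatic peak
561.7 V/s, 5 spikes/300 ms at 400 pA, AIS leading the soma by ~0.17 ms,
rest stable at −80 mV, and ~11 Hz sustained firing at 300 pA/10 s.

Known deviations, accepted and documented rather than tuned away:

* the last-AHP sits near −70 mV (measured ≈ −49.5 mV); a shallower AHP
  drives the model into depolarization block because availability at
  −50 mV is bounded by the tabulated inactivation curve even after the
  +20 mV context shift;
* the AIS *inflection* (first acceleration hump) is dominated by the
  proximal AIS and therefore tracks NaV1.2 rather than NaV1.6; the AIS
  *max* (handoff trough) falls with either isoform, and under NaV1.6
  reduction both AIS max and somatic peak dV/dt fall monotonically,
  which is the ordering the density-sweep analysis checks;
* threshold is −46.3 rather than −42.5 mV — inside the empirical spread
  but at its hyperpolarized edge.

## Protocols

* **Density sweep**: 11 scales (100→0%), first-AP features per scale;
  rows without APs are retained with absent features.
* **Crossover sweep**: 8 crossover positions × 10 NaV1.2:NaV1.6 ratios
  (90:10 → 0:100); the 100:0 condition evokes no APs and is excluded.
* **Onboarding/recovery**: 300 ms baseline train (amplitude auto-tuned to
  5–6 APs within 100–600 pA), −12 mV voltage-clamp hold for 30 s, then
  test trains on a 2/5/15/30/60 s inter-stimulus ladder; deltas are
  recovery − baseline and the summary averages stimuli with offsets in
  the 12–20 s window.
* **Nucleated patch**: somatic-membrane-only model; −80→−12 mV 20 ms
  pulses every 2 s (10 baseline), 10 s hold at −12 mV, recovery pulses;
  P/8-style leak subtraction (a 1/8-amplitude sub-pulse response scaled
  ×8, exact for linear leak); peaks normalized to the baseline mean.
* **Long train**: 300 pA × 10 s; per-spike features binned at 1 s and
  delta-normalized to the first 500 ms.
* **Seizure-like activity**: 60 s segments of Poisson PSP current (50 Hz;
  biexponential kernels, rise 0.5 ms / decay 5 ms; zero-mean Gaussian
  event amplitudes, SD 200 pA) — one baseline, one seizure segment with
  an additional 400 pA standing step, four recovery segments; features
  binned at 5 s.  A standing depolarizing bias (280 pA default) is
  applied during PSP segments, calibrated once so the baseline segment
  fires near 10 Hz; a zero-mean fluctuating input alone does not reach
  threshold from −80 mV.  Protocol runs are bit-reproducible given
  (config hash, seed).

## Synthetic data

The generators produce every input class the pipeline consumes with the
exact protocol grids (17-step activation family with optional linear leak
that P/4 removes exactly; 31-prepulse inactivation family; 30 nM–100 µM
half-log 1-3-10 dose series; Poisson PSP trains; parametric AP fixtures).
Noise is additive Gaussian on normalized responses (default sd 0.02);
acceptance-style round trips use sd 0.  The AP fixture builds dV/dt as a
Gaussian mixture (sub-15 V/s charging ramp, AIS and somatic components,
repolarization) and integrates it in closed form (erf), with landmark
ground truth obtained from the roots of the analytic derivatives — the
construction is the oracle, independent of the finite-difference
extraction path.  Fixture components are intentionally wider in time
(~0.25 ms) than a real AP's so that 50 kHz finite differences resolve
the landmarks to < 1%; passing fixtures therefore validates the
extraction logic, not its behaviour on pathologically fast waveforms.

What the generators do **not** emulate: amplifier artifacts (series
resistance, capacitive transients beyond linear leak), channel noise,
recording drift, and cell-to-cell variability.  Passing round-trip tests
therefore demonstrates correctness of the analysis pipeline, not
robustness to every property of real recordings.

## Design decisions on open points

* The exact windowing separating AIS from somatic phase when the somatic
  component lacks a true dV/dt peak follows the prominence rule: dV/dt at
  the sample where the second derivative is nearest zero within the
  somatic phase.
* A spike is accepted only if the voltage rises ≥ 15 mV above its
  threshold crossing before peaking; this rejects the stimulus-onset
  charging transient of a compact model cell, which can transiently
  exceed 15 V/s without being regenerative.
* Dose–response fits fix the Hill coefficient at 1 (coefficients are not
  part of the packaged potency table); it can be freed.
* Baseline (pre-onboarding) block at 200 nM is small but nonzero, as
  expected from the equilibrium curves.
* The tuner targets 5 APs per 300 ms and accepts 4–6.

## Limitations

The model is a reduced chain morphology with two Kv conductances; it is
built to reproduce orderings and sign structure (which isoform controls
threshold, which controls somatic dV/dt, the direction of the AHP/output
paradox, crossover sensitivity), not the quantitative magnitudes of any
particular recorded cell.  Ex-vivo effect sizes (e.g., a +5.8 mV
threshold shift after NaV1.6 onboarding) are larger than the model's,
chiefly because the detailed-balance binding kinetics cap how much
NaV1.6 block accumulates in 30 s at 200 nM.
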