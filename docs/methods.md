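# Methods

## Scope

The package models why distal synaptic input drives axonal output in CA2 but
not CA1 pyramidal neurons. It contains five parts: a synthetic-morphology
generator (SWC in/out, Sholl and path-distance metrics), a biophysics layer
(passive constants, spine correction, channel kinetics, density rules), a
compartmental simulator (implicit branched-cable integration, synapses,
current injections, regional Na⁺ block), trace-analysis operators (dV/dt,
phase plane, AP/spikelet detection, EPSP metrics, PPR, sag, passive
constants, latency), and a config-driven experiment pipeline with a CLI.

## Synthetic morphologies

Reconstructions of the original cells are not publicly available, so the
generator emulates the two architectures at the level that matters for cable
electrophysiology — lengths, diameters, and branching topology. The 3-D
embedding is a planar fan chosen for readability; electrical behaviour
depends only on lengths and diameters.

**CA2-like** (defaults): a 15 µm sphere-equivalent soma; an apical trunk of
2.5 µm diameter whose length (the split distance) is drawn uniformly in
50–100 µm; exactly `n_secondary` (12) secondary branches of 1.0 µm running
from the split to 450 µm path distance, each continuing as a 0.5 µm tuft
segment to 600 µm; four basal dendrites of 150 µm. Every apical route
therefore crosses the 300 µm band (the branch-stimulation site) and carries
eligible synaptic cable beyond 400 µm.

**CA1-like**: a single 2.5 µm apical trunk to 400 µm (the SR/SLM border),
then a fine tuft built as a two-level binary cascade — two 0.7 µm secondary
tuft branches of 100 µm, each splitting into two 0.5 µm tertiary terminals of
100 µm. The cascade is deliberate: a single-point fan of tuft branches would
recreate the CA2 hot-spot architecture (many spiking branches converging on
one node) at the tuft origin and let their summation ignite the trunk. With
per-junction convergence of two, tuft spikes boost the trunk end but cannot
relay down it.

The CA1 trunk is uniform (no taper) by default. A trunk tapering to 1.5 µm
makes its distal end electrically similar to a CA2 secondary branch —
ignitable by the converging tuft — and the model then fires somatic APs under
strong stimulation, which is not what CA1 cells do. A constant 2.5 µm trunk
keeps the distal trunk's source-to-load ratio unfavourable for re-ignition.
Both choices are exposed as `MorphogenParams` fields.

Sholl analysis uses Euclidean radius from the soma centre (the anatomical
convention); all electrical rules (synapse eligibility, density gradients,
TTX masks) use path distance along the tree.

## Biophysics

Passive: R_m = 40 000 Ω·cm², C_m = 0.75 µF/cm², R_i = 150 Ω·cm. Spine scale
factors multiply C_m and divide R_m of dendritic (never somatic)
compartments: CA1 1 (below 150 µm) / 2 (beyond); CA2 2 / 3. The product
R_m·C_m, hence τ_m = 30 ms, is factor-invariant.

Conductance densities: G_Na 0.022 S/cm² and G_Kdr 0.035 S/cm², uniform in
both classes; G_KA 0.035 S/cm² at the soma with a linear sixfold rise along
path distance; G_h with a sevenfold rise in CA1 and uniform in CA2. Linear
gradients ramp over 350 µm and saturate beyond (the `span` parameter,
configurable). Reversal potentials: E_Na +55, E_K −90, E_h −30 mV (standard
hippocampal values; configurable).

Gate kinetics are Boltzmann steady states with sigmoidal voltage-dependent
time constants; all constants live in `src/dendrospike/data/kinetics_default.yaml`
(version 1) and can be swapped per run. The family is Na = m³h,
Kdr = n, KA = a·b, H = l. Constants were chosen within the shapes and ranges
of published rat CA1 dendrite models and then calibrated as a set so that the
model reproduces the experimentally observed regime:

* tuft branches fire full local Na⁺ spikes under sufficient synaptic drive
  (Na activation −38 mV, slope 6; inactivation −47 mV, slope 4, with a slow
  τ_h near threshold so slow depolarization accommodates);
* conduction of a single spike toward the soma is decremental, not
  saltatory-regenerative — controlled mainly by the A-type current, whose
  activation (V½ +11 mV, slope 11.5, τ ≳ 0.5 ms) produces a large sub-spike
  shunt in the distal high-density region;
* the CA2 primary branch point, where the A-density is still low, re-ignites
  when several branch remnants summate.

Two free quantities the source constants do not determine: the somatic G_h
density (set once to 5 × 10⁻⁴ S/cm²; it yields a clearly larger somatic sag
in CA1 than CA2 — 0.45 vs 0.27 under −100 pA — and contributes a
CA1-specific distal shunt through the sevenfold gradient) and the kinetic
constants themselves, which are recorded in the parameter file rather than
asserted against any reference.

## Simulator

Discretization: compartments of ≤ 10 µm (≈ λ/100 at DC for the default
calibres); per-compartment densities evaluated at the path-distance midpoint;
frustum (mean-diameter) lateral areas, which conserve total membrane area
under refinement for piecewise-linear tapers; axial conductances from the
half-cylinder resistances on each side of a joint. The soma is one
isopotential compartment.

Integration: backward Euler with a Hines solve — elimination from the leaves
into the root in O(N) per step, exact for the tree-structured system (verified
against dense `numpy.linalg.solve` to 10⁻¹⁰ mV on random trees). Gates advance
by exact exponential relaxation toward their steady state using the
start-of-step voltage (staggered update). dt defaults to 0.025 ms; halving dt
or the compartment length moves the strong-stimulation somatic peak by
< 0.05 mV.

Rest: −70 mV is made an exact fixed point by calibrating each compartment's
leak reversal so its net membrane current vanishes there with gates at steady
state; a stimulus-free settle run verifies somatic drift < 0.5 mV. This
treats the stated resting potential as a state, not a protocol, and keeps
cells comparable without holding currents.

Synapses share a peak-normalized double-exponential conductance kernel
(0.2/2 ms, E = 0 mV, 0.0002 µS per synapse); activation is synchronous by
default, with an optional Gaussian jitter (off, σ configurable). "EPSC-like"
injected currents use the same kernel shape. TTX masks zero the Na density of
all compartments within a path radius of a centre: somatic mask 30 µm;
dendritic (stratum radiatum) mask centred 150 µm along every apical route
with radius 75 µm, which silences the proximal dendritic relay zone while
sparing the soma and the distal spike-initiation territory.

## Trace analysis

Operational definitions follow current-clamp practice: derivatives are
central differences (mV/ms ≡ V/s); AP threshold is the start of the
contiguous dV/dt ≥ criterion (10 or 50 V/s) run that carries the upstroke
into a voltage peak above 0 mV — a brief stimulus-onset transient that decays
below the criterion before the spike does not count. Spikelets are local
dV/dt maxima ≥ 10 V/s (the lower AP criterion, used as detection floor) whose
following voltage peak stays below 0 mV; a qualifying dV/dt hump preceding a
full AP upstroke is reported as a pre-AP spikelet. Traces are box-smoothed
over 0.5 ms before differentiation so that recording-scale noise (σ ≈ 0.2 mV)
does not fragment events. The dendritic-spike-aware EPSP amplitude excludes
the first 5 ms after the stimulus (dendritic-spike latency window); the EPSP
itself peaks later (> 8 ms). Baseline is the mean of the 5 ms preceding the
stimulus. PPR divides the second EPSP amplitude (measured from the
pre-second-stimulus voltage) by the first, at 50 ms spacing. The 0 mV
AP/spikelet separator is justified by the observed regimes: full APs peak
above 0 mV from a −70 mV rest, spikelets reach ≈ −30 mV.

## Experiments

* **Weak/strong matrix**: 75 vs 1000 synapses > 400 µm, both classes, five
  replicate seeds (placement only; morphology fixed per class). Flags per
  replicate: local tuft spike (any tuft site peaking above −20 mV — the
  regenerative range, unreachable passively once the synaptic driving force
  collapses), branch-point spike (same criterion at the distal trunk end),
  somatic AP, and branch-point → soma latency (first dV/dt ≥ 10 V/s
  crossings).
* **Branch recruitment**: for k = 1..12, seven seeded random k-subsets of the
  branches crossing the 300 µm band, ~150 synapses each (placed in the band
  ±50 µm); the minimal k with a majority of AP-firing draws, verified at
  k + 1. With the default synthetic morphology the answer is 5 of 12; it is
  insensitive to synaptic gain (saturation at the 0 mV synaptic reversal plus
  the passive sister-branch current sink make it geometry-dominated).
* **TTX analogs**: dendritic block abolishes the somatic AP to strong input
  while changing the weak-input somatic EPSP by < 0.1%; somatic block
  converts the AP into a single spikelet (peak ≈ −30 mV, dV/dt ≈ 40 V/s).
* **Characterization dashboard**: R_input, τ_m, sag ratio, rheobase and AP
  threshold from somatic steps, dendritic-spike threshold current at a
  mid-apical site.

The "~" counts in the protocols (75, 150, 1000) are implemented as exact
defaults with config override. Problem sizes used throughout (five seeds,
seven subset draws, 60 ms of simulated time per stimulation run, ≤ 10 µm
compartments) were chosen as the smallest sizes at which the summaries are
seed-stable.

## What the synthetic data do and do not show

The generator reproduces the *topological* contrast between the two cell
classes and plausible calibres, not any individual reconstructed neuron:
real arbors have oblique branches, irregular diameters, non-planar geometry,
and heterogeneous branch counts. Passing the suite therefore shows that the
mechanism — decremental single-branch conduction plus branch-point summation
— follows from the class architecture under the published conductance set; it
does not validate absolute quantities (input resistance, rheobase, exact
recruitment count) against real CA2 cells. The recruitment count in
particular depends on branch calibre and count: the default morphology gives
5 of 12, in the neighbourhood of the reference value of 6 obtained with a
reconstructed cell. NMDA receptor conductances, synaptic inhibition, Ca²⁺
channels and an axon are deliberately absent; AP initiation here is somatic,
standing in for axonal initiation.

## Numerical notes and degenerate inputs

Backward Euler is first-order; at dt = 0.025 ms spike peaks are converged to
< 0.05 mV. The Hines elimination requires topological (parent-before-child)
ordering, which the discretizer guarantees. Zero-length sections are
rejected; a point soma is expanded to a sphere-equivalent cylinder. Synapse
placement with no eligible cable raises; stimulus amplitudes must be finite.
The event detectors assume uniform sampling and at least three samples.
Divergence (non-finite voltage) aborts integration with the failing step
index. Step-current windows are half-open ([onset, onset+duration)), so a
steady-state readout at the final sample should use a `hold` stimulus or a
window outlasting the run.
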