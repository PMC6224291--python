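# Methods

This note records the model, the parameter choices and their rationale, the
numerical methods, and what the synthetic test bed can and cannot say about
real tissue.

## Volume conductor

The field problem is quasi-static: at stimulation frequencies well below
10 kHz, inductive and wave effects are negligible and the tissue is a
resistive (optionally capacitive) volume conductor. The voxelized tissue is
discretized with the admittance method: each hexahedral element becomes a
circuit node at its center, and each face-adjacency becomes a branch whose
conductance is the series combination of the two half-cells,
G = A/(ρ₁d₁ + ρ₂d₂). When capacitive tissue is enabled, a parallel
capacitance C = A/(d₁/ε₁ + d₂/ε₂) accompanies each branch.

**Multi-resolution mesh.** Elements are octree blocks of side 1, 2 or 4
voxels (maximum 64-voxel elements). Merging is vetoed for any block that
contains a region boundary, and for all voxels within 6 voxels of a current
source; adjacent element sides never differ by more than a factor of two. A
coarse element connects to each fine face it abuts with the conductance of
the shared sub-face area, which conserves total face conductance across
transitions. The 6-voxel source halo was chosen so that the coarse-fine
transition shell sits where the source field is already weak; the
merged-vs-fine comparison in the test suite measures sub-percent agreement
at probes three or more voxels from any transition.

**Electrodes and boundaries.** Microwires are voxelized with their axis on
the voxel-corner grid (so a 48 μm wire is exactly 4 voxels wide), insulated
along the shaft (teflon, 10¹⁶ Ω·m, treated as an open circuit) and exposed
only at the tip disc. All metal voxels of one wire collapse to a single
equipotential super-node (platinum, 10⁻⁸ Ω·m, makes this numerically
forced). The double layer (10 μF/cm² by default) is added as one capacitor
per exposed-surface branch, in parallel with the interface resistor and
sized by that branch's share of exposed area, with no spatial extent. The
reference electrode is not modeled as a wire: bath elements on the outer
box faces are grounded through their half-cell conductance (a distant
return path), configurable to all faces or none. Monopolar sources return
through this boundary; on fully floating fixtures the solver pins one
reference node at 0 V.

**Solvers.** Static solves use bi-conjugate gradient (stabilized) with
Jacobi preconditioning, convergence ‖Ax − b‖/‖b‖ ≤ 10⁻⁸, iteration cap
50·√N; small systems fall back to a direct sparse solve. Dirichlet-pinned
nodes are supported (used by the analytic-monopole validation, which fixes
the boundary to ρI/4πr and checks the interior). Transient solves use
backward-Euler companion models with a single LU factorization; because the
tissue and interface time constants are microseconds while output sampling
is 0.1 ms, each output step is integrated with fine internal substeps
(1 μs by default) and the piecewise-constant source is evaluated at substep
midpoints so that pulse edges never coincide with an output sample.
Sampling anywhere in the volume expands node voltages onto the fine voxel
grid (coarse elements broadcast their value; insulation voxels take the
nearest conducting value) and interpolates trilinearly.

## Tissue and dielectric parameters

| Region | ρ (Ω·m) | note |
|---|---|---|
| molecular layer (3 thirds) | 2.7 | dendritic-layer impedance measurements |
| cell-body layer | 2.28 × 2.7 = 6.156 | control ratio 2.28; swept 1:1–5:1 |
| hilus | 2.7 | no separate measurement; molecular value |
| bath | 0.6 | CSF/ACSF-like |
| tissue ε (optional) | 2.79 × 10⁻⁶ F/m | for the capacitance-negligibility check |

τ_RC = ρε ≈ 7 μs, so a 1 ms pulse charges tissue capacitance to 95% in
~21 μs — the basis for running purely resistive field solves by default.
The transient comparison (capacitive vs resistive, 100 μA, 1 ms per phase)
is recomputed by `scripts/acceptance.py` rather than asserted.

## Synthetic anatomy

The generator replaces a digitized atlas with two circular arcs
(suprapyramidal and infrapyramidal blades, radii 430/370 μm to the
hilus/cell-body boundary, spans 100°/85°) sharing the crest point and its
tangent. Radial bands define hilus, a 60 μm cell-body layer, and a 240 μm
molecular layer split into equal thirds; the cross-section is extruded
400 μm septotemporally; everything else is bath. It reproduces the
topological features the results depend on — two blades meeting at a crest,
laminar thirds, a resistive cell-body band separating molecular layer from
hilus — and is deterministic given its parameters.

It does **not** reproduce: real blade curvature or thickness variation,
septotemporal curvature, cell-density gradients, or any subject-specific
anatomy. Quantities tied to full anatomical geometry (absolute activation
thresholds, absolute PS sizes) are therefore reported only as orderings and
signs, not as values to compare with recordings.

The canonical 3 × 3 stimulation-site grid (transverse: supra-blade, crest,
infra-blade × laminar: lateral/medial perforant-path interface, outer
molecular, cell-body layer) is an interpretation of the usual experimental
placements; sites snap to the named layer's mid-thickness at voxel centers.
Site ids 1–3 are the perforant-path row (2 = crest).

## Neurons

**Granule cells.** Soma plus 2 primary dendrites that bifurcate once at 35%
of the radial span and terminate exactly on the outer molecular boundary,
with 40 μm uniform compartments — 27 compartments per cell, matching the
one-field-sample-per-compartment budget of 20–30. Arbors are flattened
septotemporally (out-of-plane step fraction ≤ 0.4, compressed by 0.3),
as real granule-cell arbors are, which also keeps them inside the extruded
slab. Azimuthal wander is the per-cell randomness; the radial step cosine
is chosen per segment chain so terminals land on the boundary while lengths
stay uniform.

**Axons.** Each perforant-path axon is a singly-branched cable: a radial
stem entering at the crest from the outer surface, one bifurcation just
above the crest, and two branches following the transverse arc within the
pathway's third (lateral → outer, medial → middle), with 20 μm compartments,
0.25 μm inter-varicosity diameter, 0.6 μm varicosities every 40 μm, and
small radial jitter clamped inside the third. Axon excitability is strongly
diameter-dependent; the diameter profile is configuration, not code.

**Membranes.** Fast Na, delayed-rectifier K and leak with classic
squid-type kinetics at granule-cell-plausible densities (soma/axon
gNa = 1200, gK = 360, gL = 3 S/m², E_Na = 50, E_K = −77 mV, rest near
−65 mV; dendrites passive with Rm = 3 Ω·m²), Cm = 1 μF/cm², Ra = 200 Ω·cm.
This is a deliberately reduced channel set: population-level orderings, not
single-cell electrophysiology, are the target, and densities live in
configuration.

**Coupling.** Membrane potential is intracellular minus extracellular;
extracellular samples enter the cable equation as series sources in the
axial terms, so the capacitive coupling current Cm·dVe/dt emerges from the
implicit update and the activating-function (second-difference) drive is
included. A literal injection of Cm·dVe/dt alone would omit the axial
pathway that field-driven axonal excitation requires. GCs are sampled at
every compartment center; axons at 100 arc-length-uniform sites, each
compartment inheriting its nearest site. Compartments overhanging the slab
faces by up to two voxels take the boundary field value; anything farther
out is an error naming the compartment.

**Synapses.** Conductance synapses g(t) = gmax·N·(e^(−t/τ_d) − e^(−t/τ_r)),
τ = 1.05/5.75 ms, reversal 0 mV, normalized so the peak equals gmax (peak
time ln(τ_d/τ_r)·τ_rτ_d/(τ_d−τ_r) ≈ 2.184 ms); equal time constants fall
back to the alpha function. gmax is calibrated by a bracketed secant search
so one event depolarizes the soma by 0.22 mV (measured against a
synapse-free control run so settling transients cancel). A synapse fires
when its varicosity compartment spikes, plus a 0.5 ms release latency;
conduction delay therefore emerges from active propagation rather than the
stored arc-length/velocity estimate (kept as metadata, velocity default
0.25 m/s).

**Integration.** Backward Euler at dt = 0.025 ms with staggered analytic
gate updates and a tree-ordered direct solve per cell per step
(compartments are stored child-after-parent). Cells are initialized at the
gating steady state of −65 mV. Integration aborts on non-finite voltages;
the single-cell API also accepts a magnitude threshold (default 200 mV),
which network simulations disable because compartments within tens of
micrometres of a stimulating electrode are legitimately polarized beyond
spiking range by volt-scale extracellular gradients.

## Downscaling

Defaults are desk scale: 400 GCs and 80 axons in a ~4 × 10⁵-voxel volume
(full-scale counts remain configuration). Connectivity preserves the
full-scale per-cell synaptic convergence — 232.5 synapses per GC, split
120 lateral (outer third) / 112.5 medial (middle third) — rather than total
synapse counts, because a GC's probability of reaching threshold depends on
its convergent drive; preserving totals at reduced cell counts would
abolish the synaptic population spike entirely. Absolute pathway totals are
available through `target_totals` (met exactly by sampling candidate
varicosity–dendrite pairs within the 60 μm proximity radius, with
replacement only if candidates run short). Test configurations are smaller
still (8 GCs / 4 axons on a half-scale volume); the problem sizes used by
each analysis are recorded in its output metadata.

## Evoked potentials

Each compartment is a point source; Φ at a site is (1/4π) Σ Iᵢρ̄ᵢ/rᵢ with
ρ̄ the path-length-weighted mean resistivity along the straight source–site
segment (exact voxel traversal; traversed lengths sum to the Euclidean
distance). Sources within one voxel of a site are clamped to one voxel.
Electrode metal and insulation voxels are excluded from the path average —
return currents flow around a microwire, and including 10¹⁶ Ω·m teflon in a
straight-line average would be meaningless. Point sources (rather than line
sources) are adequate because compartments are short relative to
source–site distances at this scale; a line-source variant is a natural
extension point. The population-spike polarity check (negative-going at a
cell-body-layer site, positive-going at an outer-molecular site) is
evaluated in the window around the synchronized somatic spikes; outside
that window the synaptic sink in the mid-molecular band dominates with the
opposite sign, which is itself the expected EPSP dipole.

## Metrics

Direct activation is split from the synaptic phase at 3 ms after pulse
onset (configuration; the separation exists because axonal activation,
synaptic conductance and GC integration delay the indirect response).
PSmax counts unique GCs per 2 ms bin as a proportion of all GCs; efficiency
counts total GC spikes per μA; both are kept distinct deliberately. HHW is
the FWHM of a Gaussian least-squares fit to the binned time course
(moment-based initialization); if the fit fails, the empirical
half-maximum width is reported instead, floored at one bin and flagged.
U normalizes PSmax, efficiency and max(HHW)−HHW min–max across the cases
passed in (the sweep); a metric that is constant across cases contributes
its full weight by convention, and the log notes it. NRMSE between field
variants is the RMSE over a box divided by the control's range in that box;
the default box is 10 × 10 fine voxels centered 60 μm radially inward of
the electrode tip, evaluated on three slices 24/48/72 μm beyond the tip
along the insertion axis (the exact experimental box is not recoverable, so
this is fixed once as the package's definition).

## Known limitations

- No dentate interneurons or feedback inhibition; no ephaptic feedback of
  neuronal currents into the field grid (the recording step uses a
  different volume-conductor approximation than the stimulation step).
- The field-to-neuron coupling is one-way and, for resistive networks,
  separable (spatial profile × waveform); time-resolved capacitive drive of
  neurons is not implemented.
- One stimulating wire with a boundary return is the default; paired
  anode/cathode wires can be built from the same primitives but the
  experiment pipelines do not orchestrate them.
- The "1 ms width" of the biphasic pulse is read as 1 ms per phase
  (charge-balanced, cathodic-first); total-duration reading is available by
  halving `phase_ms`.
- Absolute thresholds, PS amplitudes and sweep optima at desk scale depend
  on the synthetic anatomy and the reduced channel set; only orderings and
  signs (perforant-path vs cell-body thresholds, hilar shielding direction,
  dipole polarity, monotone recruitment) are meaningful claims, and those
  are what the test suite asserts.
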