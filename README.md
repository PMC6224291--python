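# hippostim

Multi-scale simulation of extracellular electrical stimulation in laminated
hippocampal tissue: an admittance-method (AM) volume conductor coupled to a
compartmental network of dentate granule cells and perforant-path axons, with
evoked-potential estimation and population-spike scoring of electrode
placement and pulse amplitude.

It is written for neural engineers and computational neuroscientists who want
to evaluate stimulating-electrode configurations against a laminated tissue
model at desk scale (a laptop core, seconds to minutes per experiment),
without a cluster or a proprietary atlas.

## What it computes

**Field solving (admittance method).** A labeled voxel volume (12 μm cubic
voxels) is coarsened into an octree-style hexahedral mesh (element sides 1, 2
or 4 voxels, i.e. up to 64-voxel elements; merging is vetoed at region
boundaries and near current sources) and overlaid with a lumped circuit:
branch conductance between face-adjacent elements

&nbsp;&nbsp;&nbsp;&nbsp;G = A / (ρ₁d₁ + ρ₂d₂),

with A the shared face area and dᵢ the center-to-face distances. Nodal
equations are solved by the bi-conjugate-gradient method to a residual of
10⁻⁸. The electrode–electrolyte double layer (10 μF/cm²) is distributed as
parallel capacitors over the exposed metal surface; tissue capacitance can be
toggled to verify it is negligible for ~1 ms pulses (τ_RC = ρε ≈ 7 μs).

**Neural response.** Granule cells (GC, simplified morphologies spanning the
three molecular thirds, 20–30 compartments) and singly-branched
perforant-path axons (lateral → outer third, medial → middle third, periodic
varicosities, one bifurcation above the crest) are integrated as branched
cables with Na/K/leak membrane dynamics. Extracellular potentials Ve enter as
series sources, so axial currents are driven by (Vm + Ve) differences — a
spatially uniform Ve has no effect. En-passant AMPA synapses use the
difference-of-two-exponentials conductance (τ = 1.05/5.75 ms), with the peak
conductance calibrated so a single EPSP depolarizes the soma by 0.22 mV.

**Evoked potentials.** Field potentials at virtual recording sites are the
point-source sums Φ = (1/4π) Σᵢ Iᵢ ρ̄ᵢ / rᵢ over per-compartment
transmembrane currents, with ρ̄ the path-length-weighted average resistivity
along the source–site segment.

**Metrics and sweeps.** The synaptic population spike (PS) is scored by
PSmax (peak proportion of GCs active in 2 ms bins), total proportion active,
maximum cumulative-activity slope, half-height width (Gaussian-fit FWHM =
2√(2 ln 2)·σ), and efficiency (GC spikes per μA); cases from the canonical
9-location × 50–650 μA (step 50) = 117-case sweep are ranked by the
weighted-sums score

&nbsp;&nbsp;&nbsp;&nbsp;U = (w₁·PSmax + w₂·PSefficiency + w₃·[max(HHW) − HHW]) / (w₁+w₂+w₃),

each metric min–max normalized across cases.

## Worked example

```python
import numpy as np
from hippostim import geometry, admittance

# synthetic laminated dentate-like volume and the canonical site grid
vol = geometry.generate_synthetic_dentate(geometry.SyntheticAnatomyParams.small())
site = geometry.electrode_location_grid(vol)[1]       # crest, perforant path
vol_e = geometry.place_electrode(vol, geometry.ElectrodeSpec(tip=site.position))

# solve the static field for a 100 uA source at the electrode tip
mesh = admittance.build_multires_mesh(vol_e, source_positions=[site.position])
net = admittance.assemble_network(mesh, geometry.DielectricTable.default())
node = net.node_at(site.position)
v = admittance.solve_static(net, [((node, None), 100e-6)])
sol = admittance.FieldSolution.static(net, v)
print(f"{net.n_nodes} nodes; electrode at {v[node]:.2f} V")
print(f"field 30 um lateral of the tip: "
      f"{sol.sample(np.asarray(site.position) + [30, 0, 0]):.2f} V")
```

prints

```
15054 nodes; electrode at 3.15 V
field 30 um lateral of the tip: 1.71 V
```

3.15 V at the metal for 100 μA corresponds to an access resistance of about
31 kΩ, as expected for a 48 μm exposed disc in ~2.7 Ω·m tissue, and the
potential has fallen to 1.71 V one electrode radius away — the steep
near-field gradient that recruits nearby axons.

An end-to-end sweep (field → network → metrics → U) runs from one config:

```bash
hippostim init-config --out cfg.toml
hippostim sweep --config cfg.toml --out results/ --seed 1
```

`results/sweep_metrics.csv` holds one row per (location, amplitude) case
with activation counts, all PS descriptors, and U; the sweep is restartable.

## Layout

- `hippostim.geometry` — synthetic laminated volume, electrodes, dielectric
  tables, NRRD I/O
- `hippostim.admittance` — multi-resolution mesh, RC network, static and
  transient solvers, trilinear field sampling
- `hippostim.cablenet` — morphologies (SWC I/O), cable integration,
  synapses, network construction, simulation
- `hippostim.lfp` — weighted-path-resistivity evoked-potential estimation
- `hippostim.metrics` — PS descriptors, multi-objective score, NRMSE, RC and
  spectrum utilities
- `hippostim.experiments` — sweep, sensitivity analyses, LFP validation,
  TOML configuration
- `hippostim.cli` — `hippostim` command-line entry point

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
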