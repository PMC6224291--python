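"""Laminated network construction, extracellular drive, and simulation.

Granule cells sit along the cell-body layer with dendrites radiating
through the molecular thirds; perforant-path axons run transversely in
their laminar third (lateral -> outer, medial -> middle). En passant
synapses connect axon varicosities to nearby granule-cell dendrite
compartments in the matching third.

Downscaled defaults preserve the full-scale per-cell synaptic convergence
(232.5 synapses per granule cell, 120 lateral / 112.5 medial) rather than
total synapse counts, so that population synaptic drive remains realistic
at reduced cell counts; absolute totals are available via target_totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..admittance import FieldSolution, StimWaveform
from ..geometry import SyntheticAnatomyParams, laminar_offset
from .cable import (MembraneModel, SynapseOnCell, detect_spikes,
                    simulate_cell)
from .morphology import (AxonParams, GCMorphParams, Morphology,
                         generate_granule_morphology, generate_pp_axon)

__all__ = [
    "NetworkParams", "Cell", "SynapseSpec", "NetworkModel",
    "ExtracellularDrive", "SpikeRaster", "SimOutput",
    "build_network", "apply_extracellular", "simulate",
]

_THIRD_BOUNDS = {"medial": (1, 2), "lateral": (2, 3)}  # in units of t3 above cb


@dataclass(frozen=True)
class NetworkParams:
    """Connectivity and synapse parameters."""

    proximity_radius_um: float = 60.0
    convergence_lateral: float = 120.0  # synapses per GC, outer third
    convergence_medial: float = 112.5  # synapses per GC, middle third
    target_totals: dict | None = None  # overrides: {"lateral": N, "medial": M}
    conduction_velocity_m_s: float = 0.25
    gmax_s: float = 1.0e-9  # per-synapse peak conductance (S); calibrate!
    tau1_ms: float = 1.05
    tau2_ms: float = 5.75
    e_rev_mv: float = 0.0
    syn_latency_ms: float = 0.5
    gc_morph: GCMorphParams | None = None
    axon_morph: AxonParams | None = None

    def __post_init__(self):
        if self.proximity_radius_um < 0:
            raise ValueError("proximity radius must be >= 0")
        if self.conduction_velocity_m_s <= 0:
            raise ValueError("conduction velocity must be > 0")


@dataclass
class Cell:
    id: int
    kind: str  # "gc" | "axon"
    morphology: Morphology
    membrane: MembraneModel
    meta: dict = field(default_factory=dict)


@dataclass
class SynapseSpec:
    """An en passant AMPA synapse from an axon varicosity onto a GC
    dendrite compartment. ``delay_ms`` is the conduction-delay estimate
    (axonal arc length from root to varicosity over the conduction
    velocity); during simulation the delay emerges from active propagation
    to the varicosity, and this field documents the proximity-rule value."""

    pre_cell: int
    pre_comp: int
    post_cell: int
    post_comp: int
    gmax_s: float
    tau1_ms: float = 1.05
    tau2_ms: float = 5.75
    e_rev_mv: float = 0.0
    delay_ms: float = 0.0

    def __post_init__(self):
        if self.tau1_ms == self.tau2_ms:
            # permitted but the conductance falls back to the alpha limit
            pass
        if self.delay_ms < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class NetworkModel:
    gcs: list
    axons: list
    synapses: list
    anatomy: SyntheticAnatomyParams
    params: NetworkParams
    seed: int = 0

    @property
    def n_gc(self) -> int:
        return len(self.gcs)

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    def check_lamination(self) -> bool:
        """True iff every synapse's postsynaptic compartment lies in the
        laminar third matching its axon's pathway."""
        t_cb = self.anatomy.cell_body_thickness
        t3 = self.anatomy.molecular_thickness / 3.0
        for s in self.synapses:
            pathway = self.axons[s.pre_cell].meta["pathway"]
            lo, hi = _THIRD_BOUNDS[pathway]
            c = self.gcs[s.post_cell].morphology.centers[s.post_comp]
            dr, _ = laminar_offset(c[None, :], self.anatomy)
            if not (t_cb + lo * t3 <= float(dr[0]) < t_cb + hi * t3):
                return False
        return True


def _gc_transform(phi, sign, r0, r_soma, z, spin):
    """World placement for a local (+y radial) granule cell."""
    dx, dy = sign * np.sin(phi), -np.cos(phi)
    cs, ss = np.cos(spin), np.sin(spin)
    spin_m = np.array([[cs, 0.0, ss], [0.0, 1.0, 0.0], [-ss, 0.0, cs]])
    align = np.array([[dy, dx, 0.0], [-dx, dy, 0.0], [0.0, 0.0, 1.0]]).T
    rot = align @ spin_m
    soma = np.array([sign * r_soma * np.sin(phi), r0 - r_soma * np.cos(phi), z])
    return rot, soma


def build_network(anatomy: SyntheticAnatomyParams, n_gc: int, n_axons: int,
                  params: NetworkParams | None = None, seed: int = 0) -> NetworkModel:
    """Build a laminated GC/axon network with en passant synapses.

    Per-cell RNG streams are derived from ``(seed, kind, index)`` so the
    result is reproducible and insensitive to generation order.
    """
    if n_gc < 1 or n_axons < 1:
        raise ValueError("need at least one GC and one axon")
    if params is None:
        params = NetworkParams()
    from ..geometry import _side_params

    (ra, spana), (rb, spanb) = _side_params(anatomy)
    t_cb = anatomy.cell_body_thickness
    t3 = anatomy.molecular_thickness / 3.0
    depth = anatomy.septotemporal_depth
    gc_params = params.gc_morph or GCMorphParams(
        radial_span=t_cb / 2.0 + anatomy.molecular_thickness)

    rng_place = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    # transverse angles over both blades (signed: + supra, - infra)
    lo, hi = -0.88 * spanb, 0.88 * spana
    angles = np.sort(rng_place.uniform(lo, hi, n_gc))
    # keep flattened arbors (z half-extent up to ~70 um) inside the slab
    mz = min(0.33 * depth, 80.0)
    zs = rng_place.uniform(mz, depth - mz, n_gc)
    # arbor planes stay transversely aligned (flattened septotemporally);
    # only a slight wobble about the dendritic axis
    spins = rng_place.uniform(-0.15, 0.15, n_gc)

    gcs = []
    for i in range(n_gc):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, i]))
        local = generate_granule_morphology(rng, gc_params)
        phi = abs(angles[i])
        sign = 1.0 if angles[i] >= 0 else -1.0
        r0 = ra if sign > 0 else rb
        rot, soma = _gc_transform(phi, sign, r0, r0 + t_cb / 2.0, zs[i], spins[i])
        world = local.transformed(rot, soma)
        world.meta["soma_um"] = soma
        gcs.append(Cell(i, "gc", world, MembraneModel(), {"angle": angles[i]}))

    axons = []
    ax_params = params.axon_morph or AxonParams()
    for j in range(n_axons):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3, j]))
        pathway = "lateral" if j % 2 == 0 else "medial"
        z = rng.uniform(0.08 * depth, 0.92 * depth)
        m = generate_pp_axon(anatomy, pathway, rng, ax_params, z_um=z)
        axons.append(Cell(j, "axon", m, MembraneModel(),
                          {"pathway": pathway,
                           "varicosities": m.meta["varicosities"]}))

    # candidate postsynaptic compartments per pathway third
    synapses = []
    rng_conn = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    for pathway in ("lateral", "medial"):
        blo, bhi = _THIRD_BOUNDS[pathway]
        post = []  # (gc, comp, xyz)
        for g in gcs:
            c = g.morphology.centers
            dr, _ = laminar_offset(c, anatomy)
            dend = g.morphology.region == 3
            ok = dend & (dr >= t_cb + blo * t3) & (dr < t_cb + bhi * t3)
            for k in np.flatnonzero(ok):
                post.append((g.id, int(k), c[k]))
        pre = []  # (axon, comp, arc_len_um, xyz)
        for a in axons:
            if a.meta["pathway"] != pathway:
                continue
            arc = a.morphology.path_length_to_root()
            c = a.morphology.centers
            for k in a.meta["varicosities"]:
                pre.append((a.id, int(k), float(arc[k]), c[k]))
        if not post or not pre or params.proximity_radius_um == 0:
            continue
        tree = cKDTree(np.array([p[2] for p in post]))
        pairs = []
        for (aid, comp, arc_len, xyz) in pre:
            for pidx in tree.query_ball_point(xyz, params.proximity_radius_um):
                pairs.append((aid, comp, arc_len, post[pidx][0], post[pidx][1]))
        if params.target_totals is not None:
            n_target = int(params.target_totals.get(pathway, 0))
        else:
            conv = (params.convergence_lateral if pathway == "lateral"
                    else params.convergence_medial)
            n_target = int(round(conv * n_gc))
        if not pairs:
            warnings.warn(f"no feasible {pathway} synapse pairs", stacklevel=2)
            continue
        take = rng_conn.choice(len(pairs), size=n_target,
                               replace=n_target > len(pairs))
        for t in take:
            aid, comp, arc_len, gid, gcomp = pairs[int(t)]
            delay = arc_len * 1e-3 / params.conduction_velocity_m_s  # ms
            synapses.append(SynapseSpec(aid, comp, gid, gcomp, params.gmax_s,
                                        params.tau1_ms, params.tau2_ms,
                                        params.e_rev_mv, delay))
    if not synapses:
        warnings.warn("network has an empty synapse list", stacklevel=2)
    return NetworkModel(gcs, axons, synapses, anatomy, params, seed)


# ---------------------------------------------------------------------------
# extracellular drive


@dataclass
class ExtracellularDrive:
    """Per-compartment extracellular potential time series (mV).

    ``cells`` maps ("gc"|"axon", id) -> (n_comp, n_t) array sampled at the
    step edges of ``times_ms``. GCs are sampled at each compartment center
    (20-30 per cell at default morphology); axons at 100 sites evenly
    spaced along the cable arc length (``site_tables``), each compartment
    inheriting its nearest site's value.
    """

    times_ms: np.ndarray
    cells: dict
    site_tables: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, network: NetworkModel, times_ms) -> "ExtracellularDrive":
        t = np.asarray(times_ms)
        cells = {}
        for c in network.gcs:
            cells[("gc", c.id)] = np.zeros((c.morphology.n, len(t)))
        for c in network.axons:
            cells[("axon", c.id)] = np.zeros((c.morphology.n, len(t)))
        return cls(t, cells)


def _axon_sites(morph: Morphology, n_sites: int = 100):
    """Evenly spaced arc-length sample sites and the compartment -> site
    map (compartments in storage order, offsets cumulative)."""
    L = morph.lengths
    total = L.sum()
    starts = np.concatenate([[0.0], np.cumsum(L)[:-1]])
    s = (np.arange(n_sites) + 0.5) * total / n_sites
    comp_of_site = np.searchsorted(starts + L, s)
    comp_of_site = np.clip(comp_of_site, 0, morph.n - 1)
    frac = (s - starts[comp_of_site]) / L[comp_of_site]
    xyz = (morph.prox[comp_of_site]
           + frac[:, None] * (morph.dist[comp_of_site] - morph.prox[comp_of_site]))
    centers_s = starts + L / 2.0
    site_of_comp = np.clip((centers_s / total * n_sites).astype(int), 0, n_sites - 1)
    return xyz, site_of_comp


def apply_extracellular(network: NetworkModel, field_sol: FieldSolution,
                        waveform: StimWaveform, dt_ms: float = 0.025,
                        duration_ms: float | None = None,
                        n_axon_sites: int = 100) -> ExtracellularDrive:
    """Sample the solved field at the network's compartments.

    ``field_sol`` should be a static solution per unit stimulus (its meta
    key ``amplitude_ua``, default 1); the waveform then scales the spatial
    profile in time, which is exact for resistive networks.
    """
    if duration_ms is None:
        duration_ms = waveform.end_ms + 5.0
    n_t = int(round(duration_ms / dt_ms))
    times = np.arange(n_t + 1) * dt_ms
    ref_amp = float(field_sol.meta.get("amplitude_ua", 1.0))
    scale = waveform.current_ua(times) / ref_amp  # unitless
    if field_sol.n_times > 1:
        raise NotImplementedError(
            "time-resolved field drive not supported; pass a static profile")

    vol = field_sol.mesh.volume
    clip_tol = 2.0 * vol.voxel_size

    def _sample(points, who):
        p = np.asarray(points, float)
        lo = vol.origin + 1e-9
        hi = vol.origin + vol.extent - 1e-9
        over = np.maximum(np.maximum(lo - p, p - hi), 0.0).max(axis=1)
        if np.any(over > clip_tol):
            bad = int(np.argmax(over))
            raise ValueError(
                f"{who} compartment {bad} at {p[bad]} lies outside the field "
                f"volume by {over[bad]:.1f} um")
        # marginal overhangs (e.g. dendrites poking past the slab faces)
        # take the boundary field value
        return field_sol.sample(np.clip(p, lo, hi))

    cells = {}
    site_tables = {}
    for c in network.gcs:
        prof = _sample(c.morphology.centers, "gc") * 1e3  # mV per ref amp
        if not (20 <= c.morphology.n <= 30):
            warnings.warn(
                f"GC {c.id} has {c.morphology.n} drive sites (expected 20-30)",
                stacklevel=2)
        cells[("gc", c.id)] = prof[:, None] * scale[None, :]
    for c in network.axons:
        xyz, site_of_comp = _axon_sites(c.morphology, n_axon_sites)
        prof_sites = _sample(xyz, "axon") * 1e3
        ve_sites = prof_sites[:, None] * scale[None, :]
        site_tables[("axon", c.id)] = (xyz, ve_sites)
        cells[("axon", c.id)] = ve_sites[site_of_comp]
    return ExtracellularDrive(times, cells, site_tables,
                              meta={"waveform": waveform})


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SpikeRaster:
    """Spike events, sorted by time."""

    events: pd.DataFrame  # columns: cell_id, cell_type, compartment_id, t_ms

    @classmethod
    def from_events(cls, rows) -> "SpikeRaster":
        df = pd.DataFrame(rows, columns=["cell_id", "cell_type",
                                         "compartment_id", "t_ms"])
        df = df.sort_values("t_ms", kind="stable").reset_index(drop=True)
        return cls(df)

    def __len__(self):
        return len(self.events)

    def of_type(self, cell_type: str) -> pd.DataFrame:
        return self.events[self.events.cell_type == cell_type]

    def active_cells(self, cell_type: str) -> int:
        return self.of_type(cell_type).cell_id.nunique()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeRaster":
        return cls(pd.read_csv(path))


@dataclass
class SimOutput:
    """Network simulation output: shared time base, per-compartment
    transmembrane currents (A, outward positive), compartment positions,
    and the spike raster."""

    times_ms: np.ndarray
    comp_positions: np.ndarray  # (N, 3) um
    comp_cell: pd.DataFrame  # columns: cell_type, cell_id, compartment_id
    currents_a: np.ndarray | None  # (N, n_t)
    raster: SpikeRaster
    vm_soma: dict = field(default_factory=dict)  # gc id -> (n_t,) mV
    meta: dict = field(default_factory=dict)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times_ms", data=self.times_ms)
            if self.currents_a is not None:
                f.create_dataset("currents", data=self.currents_a)
            g = f.create_group("compartments")
            g.create_dataset("positions_um", data=self.comp_positions)
            g.create_dataset("cell_id", data=self.comp_cell.cell_id.to_numpy())
            g.create_dataset("compartment_id",
                             data=self.comp_cell.compartment_id.to_numpy())
            g.create_dataset("cell_type",
                             data=self.comp_cell.cell_type.to_numpy(dtype="S8"))


def simulate(network: NetworkModel, drive: ExtracellularDrive,
             duration_ms: float, dt_ms: float = 0.025,
             record_currents: bool = True,
             record_vm_soma: bool = True) -> SimOutput:
    """Simulate axons then granule cells under the extracellular drive.

    Axons are integrated first; each synapse fires when its varicosity
    compartment spikes, after the release latency. GC spike events are
    taken at the soma. Currents are recorded per compartment for
    field-potential estimation.
    """
    n_t = int(round(duration_ms / dt_ms))
    times = np.arange(n_t + 1) * dt_ms
    if drive.times_ms[-1] < duration_ms - 1e-9:
        raise ValueError("drive does not cover the simulation window")

    def ve_for(key, n_comp):
        ve = drive.cells.get(key)
        if ve is None:
            return None
        # align to the simulation step edges
        if ve.shape[1] < n_t + 1:
            raise ValueError(f"drive for {key} shorter than simulation")
        return ve[:, :n_t + 1]

    rows = []
    events_per_syn = {}
    positions = []
    cell_rows = []
    currents = [] if record_currents else None

    vari_spikes = {}  # (axon, comp) -> times
    for c in network.axons:
        rec = simulate_cell(c.morphology, c.membrane, duration_ms, dt_ms,
                            ve_mv=ve_for(("axon", c.id), c.morphology.n),
                            record_currents=record_currents, abort_mv=None)
        for comp in range(c.morphology.n):
            st = detect_spikes(rec.times_ms, rec.vm[comp])
            for t in st:
                rows.append((c.id, "axon", comp, t))
            if len(st):
                vari_spikes[(c.id, comp)] = st
        positions.append(c.morphology.centers)
        cell_rows.extend(("axon", c.id, k) for k in range(c.morphology.n))
        if record_currents:
            currents.append(rec.i_mem_na * 1e-9)

    lat = network.params.syn_latency_ms
    syn_by_gc = {}
    for s in network.synapses:
        pre = vari_spikes.get((s.pre_cell, s.pre_comp))
        if pre is None or len(pre) == 0:
            continue
        syn_by_gc.setdefault(s.post_cell, []).append(
            SynapseOnCell(s.post_comp, s.gmax_s, s.tau1_ms, s.tau2_ms,
                          s.e_rev_mv, events_ms=pre + lat))

    vm_soma = {}
    for c in network.gcs:
        rec = simulate_cell(c.morphology, c.membrane, duration_ms, dt_ms,
                            ve_mv=ve_for(("gc", c.id), c.morphology.n),
                            synapses=syn_by_gc.get(c.id, []),
                            record_currents=record_currents, abort_mv=None)
        for t in detect_spikes(rec.times_ms, rec.vm[0]):
            rows.append((c.id, "gc", 0, t))
        positions.append(c.morphology.centers)
        cell_rows.extend(("gc", c.id, k) for k in range(c.morphology.n))
        if record_currents:
            currents.append(rec.i_mem_na * 1e-9)
        if record_vm_soma:
            vm_soma[c.id] = rec.vm[0].copy()

    raster = SpikeRaster.from_events(rows)
    comp_cell = pd.DataFrame(cell_rows,
                             columns=["cell_type", "cell_id", "compartment_id"])
    return SimOutput(
        times_ms=times,
        comp_positions=np.concatenate(positions) if positions else np.zeros((0, 3)),
        comp_cell=comp_cell,
        currents_a=np.concatenate(currents) if currents else None,
        raster=raster, vm_soma=vm_soma,
        meta={"dt_ms": dt_ms, "duration_ms": duration_ms},
    )
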