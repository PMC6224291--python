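"""Multi-resolution admittance-method volume conductor.

The labeled voxel volume is coarsened into an octree-style hexahedral mesh
(element sides of 1, 2, or 4 voxels; merging is vetoed at region boundaries
and current-source locations), overlaid with a lumped resistor/capacitor
network, and solved nodally for potentials under injected currents with the
bi-conjugate-gradient method. Potentials anywhere in the volume come from
trilinear interpolation over a fine-resolution virtual grid.

Internally everything is SI (metres, ohms, farads, volts, amps); micrometre
and millisecond quantities appear only at the interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .geometry import DielectricTable, ElectrodeSpec, RegionLabel, VoxelVolume

__all__ = [
    "MultiResMesh",
    "AdmittanceNetwork",
    "StimWaveform",
    "FieldSolution",
    "SolverError",
    "build_multires_mesh",
    "assemble_network",
    "attach_double_layer",
    "solve_static",
    "solve_transient",
    "sample_potential",
    "analytic_point_source",
]


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# mesh


@dataclass
class MultiResMesh:
    """Octree-coarsened hexahedral mesh over a voxel volume.

    ``side`` is the element edge length in voxels (1, 2 or 4 -> 1/8/64-voxel
    elements); ``anchor`` the minimum voxel index of each element.
    """

    volume: VoxelVolume
    side: np.ndarray  # (n_e,)
    anchor: np.ndarray  # (n_e, 3)
    label: np.ndarray  # (n_e,)
    centers: np.ndarray  # (n_e, 3) micrometres
    voxel_to_element: np.ndarray  # (nx, ny, nz) int32
    adj_i: np.ndarray
    adj_j: np.ndarray
    adj_area: np.ndarray  # shared face area, m^2

    @property
    def n_elements(self) -> int:
        return len(self.side)

    def element_at(self, pos) -> int:
        return int(self.voxel_to_element[self.volume.index_of(pos)])


def _block_ok(lab_p, must_p, s):
    nx, ny, nz = lab_p.shape
    v = lab_p.reshape(nx // s, s, ny // s, s, nz // s, s)
    uniform = (v == v[:, :1, :, :1, :, :1]).all(axis=(1, 3, 5))
    dirty = must_p.reshape(nx // s, s, ny // s, s, nz // s, s).any(axis=(1, 3, 5))
    return uniform & ~dirty


def build_multires_mesh(volume: VoxelVolume, source_positions=(), max_side: int = 4) -> MultiResMesh:
    """Coarsen the voxel grid, keeping single voxels at region boundaries and
    around current sources, with at most a factor-2 side change between
    face neighbors. Deterministic."""
    if max_side not in (1, 2, 4):
        raise ValueError("max_side must be 1, 2 or 4")
    lab = volume.labels
    nx, ny, nz = lab.shape
    h = volume.voxel_size

    must = np.zeros(lab.shape, bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        d = lab[tuple(sl_a)] != lab[tuple(sl_b)]
        must[tuple(sl_a)] |= d
        must[tuple(sl_b)] |= d
    # keep single-voxel resolution within 6 voxels of any source: the
    # coarse-transition shell then sits in a weak-field region, keeping the
    # merged solution within a fraction of a percent of the fine one
    halo = 6
    for p in source_positions:
        i, j, k = volume.index_of(p)
        must[max(i - halo, 0):i + halo + 1,
             max(j - halo, 0):j + halo + 1,
             max(k - halo, 0):k + halo + 1] = True

    # pad to a multiple of 4 with a sentinel label so edge blocks stay fine
    pads = [(0, (-n) % 4) for n in (nx, ny, nz)]
    lab_p = np.pad(lab, pads, constant_values=255)
    must_p = np.pad(must, pads, constant_values=True)

    vox_side = np.ones(lab_p.shape, np.int8)
    if max_side >= 2:
        ok2 = _block_ok(lab_p, must_p, 2)
        vox_side[np.repeat(np.repeat(np.repeat(ok2, 2, 0), 2, 1), 2, 2)] = 2
    if max_side >= 4:
        ok4 = _block_ok(lab_p, must_p, 4)
        vox_side[np.repeat(np.repeat(np.repeat(ok4, 4, 0), 4, 1), 4, 2)] = 4
        # 2:1 balance - split any 4-block that touches a single voxel
        fine1 = vox_side == 1
        touch = ndi.binary_dilation(fine1, structure=ndi.generate_binary_structure(3, 1))
        bad4 = (touch & (vox_side == 4)).reshape(
            lab_p.shape[0] // 4, 4, lab_p.shape[1] // 4, 4, lab_p.shape[2] // 4, 4
        ).any(axis=(1, 3, 5))
        demote = np.repeat(np.repeat(np.repeat(bad4, 4, 0), 4, 1), 4, 2) & (vox_side == 4)
        vox_side[demote] = 2

    vox_side = vox_side[:nx, :ny, :nz]

    ids = np.full(lab.shape, -1, np.int32)
    sides, anchors = [], []
    eid = 0
    m1 = vox_side == 1
    n1 = int(m1.sum())
    if n1:
        ids[m1] = np.arange(n1, dtype=np.int32)
        a1 = np.argwhere(m1)
        anchors.append(a1)
        sides.append(np.ones(n1, np.int16))
        eid = n1
    for s in (2, 4):
        am = np.zeros(lab.shape, bool)
        am[::s, ::s, ::s] = vox_side[::s, ::s, ::s] == s
        blocks = np.argwhere(am)
        if len(blocks) == 0:
            continue
        for b in blocks:
            i, j, k = b
            ids[i:i + s, j:j + s, k:k + s] = eid
            eid += 1
        anchors.append(blocks)
        sides.append(np.full(len(blocks), s, np.int16))

    anchor = np.concatenate(anchors) if anchors else np.zeros((0, 3), int)
    side = np.concatenate(sides) if sides else np.zeros(0, np.int16)
    label = lab[anchor[:, 0], anchor[:, 1], anchor[:, 2]]
    centers = volume.origin + (anchor + side[:, None] / 2.0) * h

    # face adjacency from voxel-face crossings between distinct elements
    pi, pj = [], []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a = ids[tuple(sl_a)].ravel()
        b = ids[tuple(sl_b)].ravel()
        m = a != b
        pi.append(a[m])
        pj.append(b[m])
    pi = np.concatenate(pi)
    pj = np.concatenate(pj)
    lo = np.minimum(pi, pj).astype(np.int64)
    hi = np.maximum(pi, pj).astype(np.int64)
    key = lo * eid + hi
    ukey, counts = np.unique(key, return_counts=True)
    adj_i = (ukey // eid).astype(np.int32)
    adj_j = (ukey % eid).astype(np.int32)
    h_m = h * 1e-6
    adj_area = counts * h_m * h_m

    return MultiResMesh(volume, side, anchor, label, centers, ids, adj_i, adj_j, adj_area)


# ---------------------------------------------------------------------------
# network


@dataclass
class AdmittanceNetwork:
    """Lumped resistor/capacitor network over a mesh.

    Node -1 in ``element_to_node`` marks non-conducting (insulation)
    elements. Metal elements of one electrode collapse to a single
    equipotential super-node. ``ground_G``/``ground_C`` are branches to the
    reference (0 V) boundary.
    """

    mesh: MultiResMesh
    n_nodes: int
    node_pos: np.ndarray  # (n, 3) micrometres
    node_region: np.ndarray  # (n,)
    branch_i: np.ndarray
    branch_j: np.ndarray
    branch_G: np.ndarray  # S
    branch_C: np.ndarray  # F
    branch_area: np.ndarray  # m^2
    ground_G: np.ndarray  # (n,) S
    ground_C: np.ndarray = None
    element_to_node: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ground_C is None:
            self.ground_C = np.zeros(self.n_nodes)
        bad = self.branch_G <= 0
        if bad.any():
            raise ValueError("all branch conductances must be > 0")

    def laplacian(self, values=None) -> sp.csr_matrix:
        """Nodal matrix sum_j g_ij (V_i - V_j) + g_i,gnd V_i from branch
        values (default: conductances)."""
        g = self.branch_G if values is None else values
        n = self.n_nodes
        i, j = self.branch_i, self.branch_j
        rows = np.concatenate([i, j, i, j, np.arange(n)])
        cols = np.concatenate([j, i, i, j, np.arange(n)])
        diag_extra = self.ground_G if values is None else self.ground_C
        data = np.concatenate([-g, -g, g, g, diag_extra])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def capacitance_matrix(self) -> sp.csr_matrix:
        return self.laplacian(values=self.branch_C)

    def node_at(self, pos) -> int:
        e = self.mesh.element_at(pos)
        node = int(self.element_to_node[e])
        if node < 0:
            raise ValueError(f"position {pos} lies in a non-conducting region")
        return node

    def is_connected(self) -> bool:
        """True if all conducting nodes form one component (the reference
        boundary counts as one extra node)."""
        n = self.n_nodes
        g = np.flatnonzero(self.ground_G > 0)
        rows = np.concatenate([self.branch_i, g])
        cols = np.concatenate([self.branch_j, np.full(len(g), n)])
        a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n + 1, n + 1))
        ncomp, _ = csgraph.connected_components(a, directed=False)
        return ncomp == 1

    def kirchhoff_residual(self, v: np.ndarray, sources=()) -> float:
        """max |node current residual| / |injected current| (relative)."""
        b = np.zeros(self.n_nodes)
        itot = 0.0
        for na, nb, cur in _norm_sources(sources):
            b[na] += cur
            itot = max(itot, abs(cur))
            if nb is not None:
                b[nb] -= cur
        r = self.laplacian() @ v - b
        return float(np.abs(r).max() / max(itot, 1e-300))


def assemble_network(mesh: MultiResMesh, dielectrics: DielectricTable,
                     capacitive_tissue: bool = False,
                     reference: str = "bath_faces") -> AdmittanceNetwork:
    """Overlay the mesh with lumped resistors (and capacitors).

    A branch between face-adjacent elements is the series combination of the
    two half-cells: G = A / (rho1 d1 + rho2 d2) with A the shared face area
    and d_i the center-to-face distances. Insulation (rho above the
    open-circuit threshold) is excluded; each electrode's metal collapses to
    one super-node. ``reference`` grounds bath elements on the outer box
    faces ("bath_faces") or nothing ("none").
    """
    h_m = mesh.volume.voxel_size * 1e-6
    rho = np.array([dielectrics.rho(l) for l in mesh.label])
    eps = np.array([dielectrics.eps(l) for l in mesh.label]) if capacitive_tissue else np.zeros(len(mesh.label))
    conducting = rho < dielectrics.OPEN_CIRCUIT
    metal = mesh.label == int(RegionLabel.ELECTRODE_METAL)

    # node numbering: conducting non-metal elements first, then one node per
    # connected metal component
    n_e = mesh.n_elements
    e2n = np.full(n_e, -1, np.int64)
    plain = conducting & ~metal
    e2n[plain] = np.arange(plain.sum())
    n_plain = int(plain.sum())
    n_nodes = n_plain
    if metal.any():
        mm = metal[mesh.adj_i] & metal[mesh.adj_j]
        sub = sp.coo_matrix(
            (np.ones(mm.sum()), (mesh.adj_i[mm], mesh.adj_j[mm])), shape=(n_e, n_e))
        ncomp, comp = csgraph.connected_components(sub, directed=False)
        metal_comps = np.unique(comp[metal])
        remap = {c: n_plain + k for k, c in enumerate(metal_comps)}
        for e in np.flatnonzero(metal):
            e2n[e] = remap[comp[e]]
        n_nodes = n_plain + len(metal_comps)

    node_pos = np.zeros((n_nodes, 3))
    node_region = np.zeros(n_nodes, np.uint8)
    node_pos[e2n[plain]] = mesh.centers[plain]
    node_region[e2n[plain]] = mesh.label[plain]
    for e in np.flatnonzero(metal):  # super-node position: mean of members
        node_region[e2n[e]] = mesh.label[e]
    if metal.any():
        for node in range(n_plain, n_nodes):
            members = np.flatnonzero(e2n == node)
            node_pos[node] = mesh.centers[members].mean(axis=0)

    i, j = mesh.adj_i, mesh.adj_j
    ok = conducting[i] & conducting[j]
    i, j, area = i[ok], j[ok], mesh.adj_area[ok]
    d_i = mesh.side[i] * h_m / 2.0
    d_j = mesh.side[j] * h_m / 2.0
    G = area / (rho[i] * d_i + rho[j] * d_j)
    with np.errstate(divide="ignore"):
        inv_ci = np.where(eps[i] > 0, d_i / (eps[i] * area), np.inf)
        inv_cj = np.where(eps[j] > 0, d_j / (eps[j] * area), np.inf)
    C = np.where(np.isfinite(inv_ci + inv_cj), 1.0 / (inv_ci + inv_cj), 0.0)

    ni, nj = e2n[i], e2n[j]
    keep = ni != nj  # drop metal-internal branches
    ni, nj, G, C, area = ni[keep], nj[keep], G[keep], C[keep], area[keep]
    lo, hi = np.minimum(ni, nj), np.maximum(ni, nj)
    key = lo * n_nodes + hi
    ukey, inv = np.unique(key, return_inverse=True)
    bG = np.zeros(len(ukey)); np.add.at(bG, inv, G)
    bC = np.zeros(len(ukey)); np.add.at(bC, inv, C)
    bA = np.zeros(len(ukey)); np.add.at(bA, inv, area)
    bi = (ukey // n_nodes).astype(np.int32)
    bj = (ukey % n_nodes).astype(np.int32)

    # reference: ground branches for bath elements on the outer box faces
    ground_G = np.zeros(n_nodes)
    ground_C = np.zeros(n_nodes)
    if reference in ("bath_faces", "all_faces"):
        shape = np.asarray(mesh.volume.shape)
        for axis in range(3):
            for end in (0, 1):
                on_face = (mesh.anchor[:, axis] == 0) if end == 0 else \
                    (mesh.anchor[:, axis] + mesh.side == shape[axis])
                sel = on_face & conducting & ~metal
                if reference == "bath_faces":
                    sel &= mesh.label == int(RegionLabel.BATH)
                a_face = (mesh.side[sel] * h_m) ** 2
                d = mesh.side[sel] * h_m / 2.0
                np.add.at(ground_G, e2n[sel], a_face / (rho[sel] * d))
                if capacitive_tissue:
                    e_sel = eps[sel]
                    np.add.at(ground_C, e2n[sel],
                              np.where(e_sel > 0, e_sel * a_face / d, 0.0))
    elif reference != "none":
        raise ValueError(f"unknown reference scheme {reference!r}")

    return AdmittanceNetwork(
        mesh=mesh, n_nodes=n_nodes, node_pos=node_pos, node_region=node_region,
        branch_i=bi, branch_j=bj, branch_G=bG, branch_C=bC, branch_area=bA,
        ground_G=ground_G, ground_C=ground_C, element_to_node=e2n,
        meta={"capacitive_tissue": capacitive_tissue, "reference": reference},
    )


def attach_double_layer(network: AdmittanceNetwork, electrode: ElectrodeSpec,
                        mesh: MultiResMesh | None = None) -> AdmittanceNetwork:
    """Add the electrode-electrolyte double layer.

    Every branch between the electrode's metal super-node and a conducting
    neighbor (i.e. the exposed surface; insulated faces have no branch) gains
    a capacitor in parallel with the interface resistor, sized as the
    specific capacitance times that branch's share of exposed area. The sum
    of the added capacitances is exactly c_spec x total exposed area.
    """
    metal_node = network.node_at(electrode.tip)
    if network.node_region[metal_node] != int(RegionLabel.ELECTRODE_METAL):
        raise ValueError("electrode tip does not map to a metal node")
    sel = (network.branch_i == metal_node) | (network.branch_j == metal_node)
    if not sel.any():
        raise ValueError("electrode has no exposed surface (fully insulated)")
    network.branch_C = network.branch_C.copy()
    network.branch_C[sel] += electrode.double_layer_capacitance * network.branch_area[sel]
    return network


# ---------------------------------------------------------------------------
# waveform


@dataclass(frozen=True)
class StimWaveform:
    """Charge-balanced biphasic square pulse (cathodic phase first by
    default). Amplitude in microamps, times in milliseconds."""

    amplitude_ua: float = 100.0
    phase_ms: float = 1.0
    gap_ms: float = 0.0
    onset_ms: float = 0.0
    cathodic_first: bool = True

    def __post_init__(self):
        if self.amplitude_ua < 0:
            raise ValueError("amplitude must be >= 0")
        if self.phase_ms <= 0:
            raise ValueError("phase width must be > 0")

    @property
    def end_ms(self) -> float:
        return self.onset_ms + 2 * self.phase_ms + self.gap_ms

    def current_ua(self, t_ms) -> np.ndarray:
        """Signed source current (uA) at time(s) t; cathodic = negative."""
        t = np.asarray(t_ms, float) - self.onset_ms
        first = -1.0 if self.cathodic_first else 1.0
        out = np.zeros_like(t)
        out = np.where((t >= 0) & (t < self.phase_ms), first, out)
        t2 = self.phase_ms + self.gap_ms
        out = np.where((t >= t2) & (t < t2 + self.phase_ms), -first, out)
        return out * self.amplitude_ua

    def current_a(self, t_ms) -> np.ndarray:
        return self.current_ua(t_ms) * 1e-6

    def charge_per_phase_c(self) -> float:
        return self.amplitude_ua * 1e-6 * self.phase_ms * 1e-3


# ---------------------------------------------------------------------------
# solving


def _norm_sources(sources):
    out = []
    for s in sources:
        (na, nb), cur = s
        out.append((na, nb, cur))
    return out


def solve_static(network: AdmittanceNetwork, sources, tol: float = 1e-8,
                 method: str = "bicgstab", fixed: dict | None = None,
                 x0: np.ndarray | None = None) -> np.ndarray:
    """Nodal solve: returns node voltages (V) with the reference at 0 V.

    ``sources`` is a list of ``((node_a, node_b), I_amps)`` pairs; node_b may
    be None for a monopolar source returning through the reference boundary.
    ``fixed`` optionally pins node voltages (Dirichlet). Convergence is
    ||Ax - b|| / ||b|| <= tol (per-node Kirchhoff residual).
    """
    n = network.n_nodes
    A = network.laplacian().tocsr()
    b = np.zeros(n)
    srcs = _norm_sources(sources)
    for na, nb, cur in srcs:
        b[na] += cur
        if nb is not None:
            b[nb] -= cur

    if not fixed and network.ground_G.sum() == 0:
        # floating network: pin a reference node at 0 V (a source return
        # node if one exists)
        ref = next((nb for _, nb, _ in srcs if nb is not None), 0)
        fixed = {int(ref): 0.0}

    if fixed:
        fixed_idx = np.array(sorted(fixed), int)
        fixed_val = np.array([fixed[k] for k in fixed_idx], float)
        free = np.setdiff1d(np.arange(n), fixed_idx)
        Auu = A[free][:, free]
        bu = b[free] - A[free][:, fixed_idx] @ fixed_val
        vu = _solve_linear(Auu, bu, tol, method,
                           None if x0 is None else x0[free])
        v = np.zeros(n)
        v[fixed_idx] = fixed_val
        v[free] = vu
        return v
    return _solve_linear(A, b, tol, method, x0)


def _solve_linear(A, b, tol, method, x0=None):
    if not np.any(b):
        return np.zeros(A.shape[0])
    if method == "direct" or A.shape[0] < 600:
        v = spla.spsolve(A.tocsc(), b)
        return v
    if method != "bicgstab":
        raise ValueError(f"unknown method {method!r}")
    d = A.diagonal()
    d = np.where(d > 0, d, 1.0)
    M = spla.LinearOperator(A.shape, matvec=lambda x: x / d)
    maxiter = int(50 * math.sqrt(A.shape[0])) + 100
    v, info = spla.bicgstab(A, b, rtol=tol, atol=0.0, M=M, maxiter=maxiter, x0=x0)
    if info != 0:
        res = np.linalg.norm(A @ v - b) / np.linalg.norm(b)
        if res > tol * 10:
            raise SolverError(
                f"bi-conjugate-gradient failed (info={info}, residual={res:.3e})")
    if not np.all(np.isfinite(v)):
        raise SolverError("solver produced non-finite voltages")
    return v


@dataclass
class FieldSolution:
    """Node voltages over time on a multi-resolution mesh."""

    mesh: MultiResMesh
    times_ms: np.ndarray  # (n_t,)
    voltages: np.ndarray  # (n_t, n_nodes) volts
    element_to_node: np.ndarray
    residual: float = 0.0
    meta: dict = field(default_factory=dict)
    _fill_idx: tuple = field(default=None, repr=False)

    @classmethod
    def static(cls, network: AdmittanceNetwork, v: np.ndarray, **meta) -> "FieldSolution":
        return cls(network.mesh, np.zeros(1), np.asarray(v)[None, :],
                   network.element_to_node, meta=meta)

    @property
    def n_times(self) -> int:
        return len(self.times_ms)

    def fine_grid(self, time_index: int = 0) -> np.ndarray:
        """Node voltages expanded to the fine voxel grid (volts).

        Coarse elements broadcast their center value to all constituent
        voxels; non-conducting voxels take the nearest conducting value.
        """
        node_of_vox = self.element_to_node[self.mesh.voxel_to_element]
        v = self.voltages[time_index]
        grid = np.where(node_of_vox >= 0, v[np.maximum(node_of_vox, 0)], np.nan)
        if np.isnan(grid).any():
            if self._fill_idx is None:
                _, idx = ndi.distance_transform_edt(node_of_vox < 0, return_indices=True)
                self._fill_idx = tuple(idx)
            grid = grid[self._fill_idx]
        return grid

    def sample(self, positions, time_index: int = 0) -> np.ndarray:
        """Trilinear interpolation of the fine-grid field at positions (um)."""
        vol = self.mesh.volume
        pos = np.asarray(positions, float)
        single = pos.ndim == 1
        p = np.atleast_2d(pos)
        lo = vol.origin
        hi = vol.origin + vol.extent
        if np.any(p < lo) or np.any(p >= hi):
            raise ValueError("sample position outside the volume")
        coords = ((p - vol.origin) / vol.voxel_size - 0.5).T
        grid = self.fine_grid(time_index)
        out = ndi.map_coordinates(grid, coords, order=1, mode="nearest")
        return float(out[0]) if single else out

    # -- persistence -------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("mesh")
            g.create_dataset("centers_um", data=self.mesh.centers)
            g.create_dataset("side_voxels", data=self.mesh.side)
            g.create_dataset("element_to_node", data=self.element_to_node)
            f.create_dataset("voltages", data=self.voltages)
            f.create_dataset("times_ms", data=self.times_ms)
            m = f.create_group("meta")
            m.attrs["residual"] = self.residual
            for k, v in self.meta.items():
                try:
                    m.attrs[k] = v
                except TypeError:
                    m.attrs[k] = str(v)


def sample_potential(solution: FieldSolution, position, time_index: int = 0) -> float:
    """Potential (V) at a position by trilinear interpolation."""
    return float(np.asarray(solution.sample(position, time_index)).ravel()[0])


def solve_transient(network: AdmittanceNetwork, waveform: StimWaveform,
                    source, dt_ms: float, duration_ms: float | None = None,
                    substeps: int = 1, record_every: int = 1) -> FieldSolution:
    """Backward-Euler companion-model time stepping.

    ``source`` is a ``(node_a, node_b_or_None)`` pair carrying the waveform
    current. ``dt_ms`` is the output sampling step; each output step is
    integrated with ``substeps`` internal backward-Euler steps so that fast
    interface/tissue charging (tau typically a few microseconds) is resolved
    without flooding the output. For a purely resistive network the result
    equals the static solution scaled by the waveform sample.
    """
    if dt_ms <= 0 or substeps < 1:
        raise ValueError("dt must be > 0 and substeps >= 1")
    if duration_ms is None:
        duration_ms = waveform.end_ms + 2 * dt_ms
    na, nb = source
    n = network.n_nodes
    G = network.laplacian().tocsc()
    C = network.capacitance_matrix().tocsc()
    dt_s = dt_ms * 1e-3 / substeps
    dynamic = C.nnz > 0 and abs(C).sum() > 0
    n_out = int(round(duration_ms / dt_ms))
    times = np.arange(1, n_out + 1) * dt_ms
    volts = np.zeros((n_out, n))

    if not dynamic:
        # memoryless: one unit solve, scaled per sample
        unit = solve_static(network, [((na, nb), 1.0)])
        amps = waveform.current_a(times)
        volts = amps[:, None] * unit[None, :]
        return FieldSolution(network.mesh, times, volts, network.element_to_node,
                             meta={"waveform": waveform, "transient": "scaled-static"})

    A = (G + C / dt_s).tocsc()
    lu = spla.splu(A)
    v = np.zeros(n)
    t = 0.0
    for k in range(n_out):
        for _ in range(substeps):
            t += dt_s * 1e3
            # piecewise-constant source evaluated at the substep midpoint so
            # that phase edges never coincide with an output sample
            cur = float(waveform.current_a(t - 0.5 * dt_s * 1e3))
            b = (C @ v) / dt_s
            b[na] += cur
            if nb is not None:
                b[nb] -= cur
            v = lu.solve(b)
        volts[k] = v
    return FieldSolution(network.mesh, times, volts, network.element_to_node,
                         meta={"waveform": waveform, "transient": "backward-euler",
                               "substeps": substeps})


def analytic_point_source(current_a: float, rho: float, r_m) -> float:
    """Potential of a monopole in an infinite homogeneous medium:
    V = rho I / (4 pi r). SI units."""
    r = np.asarray(r_m, float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    out = rho * current_a / (4.0 * math.pi * r)
    return float(out) if out.ndim == 0 else out
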