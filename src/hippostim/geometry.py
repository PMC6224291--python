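"""Voxelized laminated tissue geometry.

A synthetic dentate-gyrus-like volume stands in for a digitized atlas: two
curved laminated blades (suprapyramidal and infrapyramidal) meet at a crest,
with, from inside out along the dendritic axis, hilus, the granule cell-body
layer, and a molecular layer split into inner/middle/outer thirds, all
surrounded by bath. The cross-section is extruded along the septotemporal
(z) axis.

Coordinates are right-handed, in micrometres; voxel indices are 0-based and
voxel centers sit at ``origin + (i + 0.5) * voxel_size``. The crest is at
(x, y) = (0, -total_thickness) .. (0, 0) with the blades opening upward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from . import io as _io

__all__ = [
    "RegionLabel",
    "VoxelVolume",
    "DielectricTable",
    "ElectrodeSpec",
    "SyntheticAnatomyParams",
    "ElectrodeSite",
    "generate_synthetic_dentate",
    "place_electrode",
    "electrode_location_grid",
    "classify_points",
]


class RegionLabel(IntEnum):
    """Voxel region labels. Every voxel carries exactly one."""

    BATH = 0
    MOLECULAR_OUTER = 1
    MOLECULAR_MIDDLE = 2
    MOLECULAR_INNER = 3
    CELL_BODY = 4
    HILUS = 5
    ELECTRODE_METAL = 6
    ELECTRODE_INSULATION = 7


MOLECULAR_LABELS = (
    RegionLabel.MOLECULAR_OUTER,
    RegionLabel.MOLECULAR_MIDDLE,
    RegionLabel.MOLECULAR_INNER,
)
TISSUE_LABELS = MOLECULAR_LABELS + (RegionLabel.CELL_BODY, RegionLabel.HILUS)


class SizingError(ValueError):
    """A layer is thinner than one voxel (or otherwise unrepresentable)."""


@dataclass
class VoxelVolume:
    """A labeled 3-D voxel grid (labels: uint8 :class:`RegionLabel` values)."""

    labels: np.ndarray
    voxel_size: float = 12.0  # micrometres
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def extent(self):
        """Physical size (micrometres) per axis."""
        return np.asarray(self.shape) * self.voxel_size

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, float) + 0.5) * self.voxel_size

    def contains(self, pos) -> bool:
        p = np.asarray(pos, float)
        return bool(np.all(p >= self.origin) and np.all(p < self.origin + self.extent))

    def index_of(self, pos):
        """Voxel index containing a physical position (error if outside)."""
        p = np.asarray(pos, float)
        if not self.contains(p):
            raise ValueError(f"position {p} outside volume bounds")
        return tuple(((p - self.origin) // self.voxel_size).astype(int))

    def label_at(self, pos) -> RegionLabel:
        return RegionLabel(self.labels[self.index_of(pos)])

    def label_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {RegionLabel(int(v)): int(c) for v, c in zip(vals, counts)}

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.labels.copy(), self.voxel_size,
                           self.origin.copy(), dict(self.meta))

    # -- persistence -------------------------------------------------------
    def save_nrrd(self, path) -> None:
        _io.write_nrrd(path, self.labels, self.voxel_size, self.origin)

    @classmethod
    def load_nrrd(cls, path) -> "VoxelVolume":
        data, spacings, origin = _io.read_nrrd(path)
        if not np.allclose(spacings, spacings[0]):
            raise ValueError("anisotropic spacings are not supported")
        return cls(data, float(spacings[0]), origin)


@dataclass(frozen=True)
class DielectricTable:
    """Per-region resistivity (Ohm·m) and permittivity (F/m).

    Permittivities are only consulted when a capacitive-tissue solve is
    requested; the default table is purely resistive (all eps = 0).
    """

    resistivity: dict
    permittivity: dict

    # resistivities at or above this are treated as open circuits
    OPEN_CIRCUIT: float = 1e12

    def __post_init__(self):
        for lab, rho in self.resistivity.items():
            if rho <= 0:
                raise ValueError(f"resistivity for {lab!r} must be > 0")
        for lab, eps in self.permittivity.items():
            if eps < 0:
                raise ValueError(f"permittivity for {lab!r} must be >= 0")

    @classmethod
    def default(cls, molecular: float = 2.7, ratio: float = 2.28,
                bath: float = 0.6, hilus: float = 2.7,
                tissue_permittivity: float = 0.0) -> "DielectricTable":
        """Four-region table: uniform molecular resistivity and a cell-body
        layer at ``ratio`` times the molecular value."""
        rho = {
            RegionLabel.BATH: bath,
            RegionLabel.MOLECULAR_OUTER: molecular,
            RegionLabel.MOLECULAR_MIDDLE: molecular,
            RegionLabel.MOLECULAR_INNER: molecular,
            RegionLabel.CELL_BODY: ratio * molecular,
            RegionLabel.HILUS: hilus,
            RegionLabel.ELECTRODE_METAL: 1e-8,
            RegionLabel.ELECTRODE_INSULATION: 1e16,
        }
        eps = {lab: (tissue_permittivity if lab in TISSUE_LABELS else 0.0)
               for lab in rho}
        return cls(rho, eps)

    def rho(self, label) -> float:
        try:
            return self.resistivity[RegionLabel(label)]
        except KeyError:
            raise KeyError(f"no dielectric entry for label {RegionLabel(label)!r}") from None

    def eps(self, label) -> float:
        return self.permittivity.get(RegionLabel(label), 0.0)

    @property
    def resistivity_ratio(self) -> float:
        """Cell-body : molecular resistivity ratio (derived)."""
        return (self.resistivity[RegionLabel.CELL_BODY]
                / self.resistivity[RegionLabel.MOLECULAR_MIDDLE])

    def with_ratio(self, ratio: float) -> "DielectricTable":
        """A copy with the cell-body layer set to ``ratio`` x molecular rho."""
        rho = dict(self.resistivity)
        rho[RegionLabel.CELL_BODY] = ratio * rho[RegionLabel.MOLECULAR_MIDDLE]
        return DielectricTable(rho, dict(self.permittivity))

    def with_tissue_permittivity(self, eps: float) -> "DielectricTable":
        em = dict(self.permittivity)
        for lab in TISSUE_LABELS:
            em[lab] = eps
        return DielectricTable(dict(self.resistivity), em)

    def to_json(self) -> str:
        return json.dumps({
            "resistivity": {l.name: v for l, v in self.resistivity.items()},
            "permittivity": {l.name: v for l, v in self.permittivity.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "DielectricTable":
        d = json.loads(s)
        return cls({RegionLabel[k]: v for k, v in d["resistivity"].items()},
                   {RegionLabel[k]: v for k, v in d["permittivity"].items()})


@dataclass(frozen=True)
class ElectrodeSpec:
    """An insulated microwire electrode.

    The shaft runs from the volume boundary along ``axis`` (an axis-aligned
    unit vector pointing in the insertion direction) and ends at ``tip``. The
    insulation is cut flush with the metal tip, so only the tip disc is
    exposed.
    """

    tip: tuple  # micrometres
    axis: tuple = (0.0, 0.0, 1.0)
    diameter: float = 48.0  # micrometres
    insulation_thickness: float = 24.0  # micrometres
    metal_resistivity: float = 1e-8  # Ohm·m (platinum)
    insulation_resistivity: float = 1e16  # Ohm·m (teflon)
    double_layer_capacitance: float = 0.10  # F/m^2 (10 uF/cm^2)
    role: str = "cathode"  # anode | cathode | reference

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.insulation_thickness < 0:
            raise ValueError("insulation thickness must be >= 0")
        if self.double_layer_capacitance < 0:
            raise ValueError("double-layer capacitance must be >= 0")
        a = np.asarray(self.axis, float)
        if np.count_nonzero(a) != 1:
            raise ValueError("electrode axis must be axis-aligned")
        if self.role not in ("anode", "cathode", "reference"):
            raise ValueError(f"unknown electrode role {self.role!r}")

    def to_json(self) -> str:
        return json.dumps({
            "tip": list(self.tip), "axis": list(self.axis),
            "diameter": self.diameter,
            "insulation_thickness": self.insulation_thickness,
            "metal_resistivity": self.metal_resistivity,
            "insulation_resistivity": self.insulation_resistivity,
            "double_layer_capacitance": self.double_layer_capacitance,
            "role": self.role,
        }, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ElectrodeSpec":
        d = json.loads(s)
        d["tip"] = tuple(d["tip"])
        d["axis"] = tuple(d["axis"])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticAnatomyParams:
    """Parameters of the synthetic laminated geometry.

    Two circular arcs (suprapyramidal at positive x, infrapyramidal at
    negative x) share the crest point and a common tangent there. Radii are
    measured to the hilus/cell-body boundary. All lengths in micrometres.
    """

    supra_radius: float = 430.0
    infra_radius: float = 370.0
    supra_span_deg: float = 100.0
    infra_span_deg: float = 85.0
    cell_body_thickness: float = 60.0
    molecular_thickness: float = 240.0
    hilus_fill: bool = True
    septotemporal_depth: float = 400.0
    margin: float = 96.0
    voxel_size: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.cell_body_thickness <= 0 or self.molecular_thickness <= 0:
            raise SizingError("layer thicknesses must be > 0")
        if self.cell_body_thickness < self.voxel_size:
            raise SizingError("cell-body layer thinner than one voxel")
        if self.molecular_thickness / 3.0 < self.voxel_size:
            raise SizingError("a molecular third is thinner than one voxel")
        if self.septotemporal_depth < self.voxel_size:
            raise SizingError("septotemporal depth thinner than one voxel")

    @property
    def total_thickness(self) -> float:
        return self.cell_body_thickness + self.molecular_thickness

    @classmethod
    def small(cls, **overrides) -> "SyntheticAnatomyParams":
        """A reduced geometry for transient solves and quick tests."""
        kw = dict(supra_radius=215.0, infra_radius=185.0,
                  supra_span_deg=100.0, infra_span_deg=85.0,
                  cell_body_thickness=36.0, molecular_thickness=120.0,
                  septotemporal_depth=120.0, margin=72.0)
        kw.update(overrides)
        return cls(**kw)

    def scaled(self, s: float, **overrides) -> "SyntheticAnatomyParams":
        kw = dict(
            supra_radius=self.supra_radius * s,
            infra_radius=self.infra_radius * s,
            supra_span_deg=self.supra_span_deg,
            infra_span_deg=self.infra_span_deg,
            cell_body_thickness=max(self.cell_body_thickness * s, 3 * self.voxel_size),
            molecular_thickness=max(self.molecular_thickness * s, 3 * self.voxel_size),
            hilus_fill=self.hilus_fill,
            septotemporal_depth=self.septotemporal_depth * s,
            margin=self.margin, voxel_size=self.voxel_size, seed=self.seed,
        )
        kw.update(overrides)
        return SyntheticAnatomyParams(**kw)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "SyntheticAnatomyParams":
        return cls(**json.loads(s))


def _side_params(params):
    """(arc center y, radius-to-R0, span in radians) per side; crest at origin."""
    a = (params.supra_radius, math.radians(params.supra_span_deg))
    b = (params.infra_radius, math.radians(params.infra_span_deg))
    return a, b


def classify_points(xy: np.ndarray, params: SyntheticAnatomyParams) -> np.ndarray:
    """Label 2-D cross-section points (crest-centered coordinates).

    Returns an array of :class:`RegionLabel` values. The laminar structure is
    radial about each side's arc center; the crest plane is x = 0.
    """
    xy = np.asarray(xy, float)
    x, y = xy[..., 0], xy[..., 1]
    (ra, spana), (rb, spanb) = _side_params(params)
    t_cb = params.cell_body_thickness
    t3 = params.molecular_thickness / 3.0

    out = np.full(x.shape, int(RegionLabel.BATH), dtype=np.uint8)
    for side, (r0, span) in (("A", (ra, spana)), ("B", (rb, spanb))):
        if side == "A":
            mask = x >= 0
            dx = x
        else:
            mask = x < 0
            dx = -x
        cy = r0  # arc center at (0, r0)
        rr = np.hypot(dx, y - cy)
        phi = np.arctan2(dx, -(y - cy))  # 0 at crest, grows toward blade end
        dr = rr - r0
        inside = mask & (phi <= span)
        lab = np.full(x.shape, int(RegionLabel.BATH), dtype=np.uint8)
        if params.hilus_fill:
            lab[inside & (dr < 0)] = int(RegionLabel.HILUS)
        lab[inside & (dr >= 0) & (dr < t_cb)] = int(RegionLabel.CELL_BODY)
        lab[inside & (dr >= t_cb) & (dr < t_cb + t3)] = int(RegionLabel.MOLECULAR_INNER)
        lab[inside & (dr >= t_cb + t3) & (dr < t_cb + 2 * t3)] = int(RegionLabel.MOLECULAR_MIDDLE)
        lab[inside & (dr >= t_cb + 2 * t3) & (dr < t_cb + 3 * t3)] = int(RegionLabel.MOLECULAR_OUTER)
        out[mask] = lab[mask]
    return out


def laminar_offset(points: np.ndarray, params: SyntheticAnatomyParams):
    """Radial offset dr (micrometres, from the hilus/cell-body boundary) and
    transverse angle phi for 3-D points in crest-centered coordinates."""
    p = np.asarray(points, float)
    x, y = p[..., 0], p[..., 1]
    (ra, spana), (rb, spanb) = _side_params(params)
    r0 = np.where(x >= 0, ra, rb)
    dx = np.abs(x)
    rr = np.hypot(dx, y - r0)
    phi = np.arctan2(dx, -(y - r0))
    return rr - r0, np.where(x >= 0, phi, -phi)


def generate_synthetic_dentate(params: SyntheticAnatomyParams | None = None) -> VoxelVolume:
    """Generate the synthetic laminated volume.

    Deterministic for a given parameter set (the seed is carried in the
    volume metadata for downstream consumers). Raises :class:`SizingError`
    for layers thinner than a voxel.
    """
    if params is None:
        params = SyntheticAnatomyParams()
    h = params.voxel_size
    (ra, spana), (rb, spanb) = _side_params(params)
    t = params.total_thickness

    x_max = (ra + t) * (1.0 if spana >= math.pi / 2 else math.sin(spana))
    x_min = -(rb + t) * (1.0 if spanb >= math.pi / 2 else math.sin(spanb))
    y_min = -t
    y_max = max(ra, rb,
                ra - (ra + t) * math.cos(spana),
                rb - (rb + t) * math.cos(spanb))
    m = params.margin
    origin = np.array([x_min - m, y_min - m, 0.0])
    nx = int(math.ceil((x_max - x_min + 2 * m) / h))
    ny = int(math.ceil((y_max - y_min + 2 * m) / h))
    nz = max(1, int(round(params.septotemporal_depth / h)))

    xc = origin[0] + (np.arange(nx) + 0.5) * h
    yc = origin[1] + (np.arange(ny) + 0.5) * h
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    section = classify_points(np.stack([gx, gy], axis=-1), params)
    labels = np.repeat(section[:, :, None], nz, axis=2)

    vol = VoxelVolume(labels, h, origin, meta={"anatomy": params})
    present = set(vol.label_counts())
    needed = set(TISSUE_LABELS) | {RegionLabel.BATH}
    missing = needed - present
    if missing:
        raise SizingError(f"generated volume missing labels: {sorted(l.name for l in missing)}")
    return vol


def place_electrode(volume: VoxelVolume, spec: ElectrodeSpec) -> VoxelVolume:
    """Embed an insulated microwire into a copy of the volume.

    The shaft axis is snapped to the voxel-corner grid in-plane (so a 48 um
    wire in 12 um voxels is exactly 4 voxels wide) and the tip to a voxel
    center along the axis. Voxels within diameter/2 of the axis become metal;
    an annulus of insulation surrounds the shaft, absent at the tip face.
    """
    if not volume.contains(spec.tip):
        raise ValueError(f"electrode tip {spec.tip} outside volume bounds")
    h = volume.voxel_size
    a = np.asarray(spec.axis, float)
    ax = int(np.argmax(np.abs(a)))
    sgn = 1.0 if a[ax] > 0 else -1.0
    perp = [i for i in range(3) if i != ax]

    tip = np.asarray(spec.tip, float).copy()
    for i in perp:  # snap to voxel boundary (corner grid)
        tip[i] = volume.origin[i] + round((tip[i] - volume.origin[i]) / h) * h
    # snap axial coordinate to a voxel center
    tip[ax] = volume.origin[ax] + (math.floor((tip[ax] - volume.origin[ax]) / h) + 0.5) * h

    out = volume.copy()
    centers = [volume.axis_centers(i) for i in range(3)]
    grids = np.meshgrid(*centers, indexing="ij")
    radial = np.sqrt(sum((grids[i] - tip[i]) ** 2 for i in perp))
    axial = (grids[ax] - tip[ax]) * sgn  # <= 0 behind the tip

    r_metal = spec.diameter / 2.0
    r_ins = r_metal + spec.insulation_thickness
    shaft = axial <= 1e-9
    metal = shaft & (radial < r_metal)
    ins = shaft & (radial >= r_metal) & (radial < r_ins)
    if not metal.any():
        raise ValueError("electrode metal does not cover any voxel")
    out.labels[ins] = int(RegionLabel.ELECTRODE_INSULATION)
    out.labels[metal] = int(RegionLabel.ELECTRODE_METAL)
    electrodes = list(out.meta.get("electrodes", ())) + [replace(spec, tip=tuple(tip))]
    out.meta["electrodes"] = electrodes
    return out


@dataclass(frozen=True)
class ElectrodeSite:
    """One of the canonical stimulation sites."""

    id: int
    position: tuple  # micrometres
    transverse: str  # supra | crest | infra
    laminar: str  # pp_boundary | outer_molecular | cell_body


def electrode_location_grid(volume: VoxelVolume) -> list:
    """The canonical 3 x 3 grid of stimulating-tip positions.

    Transverse: suprapyramidal mid-blade, crest, infrapyramidal mid-blade.
    Laminar: the lateral/medial perforant-path boundary (outer/middle third
    interface), mid outer-molecular, and mid cell-body layer. Sites 1-3 are
    the perforant-path row (site 2 = crest), 4-6 outer molecular, 7-9 cell
    body. Positions are snapped to voxel centers.
    """
    params = volume.meta.get("anatomy")
    if params is None:
        raise ValueError("volume has no synthetic-anatomy metadata")
    (ra, spana), (rb, spanb) = _side_params(params)
    t_cb = params.cell_body_thickness
    t_mol = params.molecular_thickness
    laminar = [
        ("pp_boundary", t_cb + (2.0 / 3.0) * t_mol),
        ("outer_molecular", t_cb + (5.0 / 6.0) * t_mol),
        ("cell_body", 0.5 * t_cb),
    ]
    transverse = [
        ("supra", +1, ra, 0.5 * spana),
        ("crest", +1, ra, 0.0),
        ("infra", -1, rb, 0.5 * spanb),
    ]
    zmid = volume.origin[2] + volume.extent[2] / 2.0
    sites = []
    sid = 1
    for lname, dr in laminar:
        for tname, sx, r0, phi in transverse:
            r = r0 + dr
            pos = np.array([sx * r * math.sin(phi), r0 - r * math.cos(phi), zmid])
            idx = volume.index_of(pos)
            pos = volume.voxel_center(idx)
            sites.append(ElectrodeSite(sid, tuple(pos), tname, lname))
            sid += 1
    return sites
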