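"""Simplified neuronal morphologies.

Granule cells are built in a local frame with +y the dendritic (radial)
axis: a short somatic compartment at the origin and 2-4 primary dendrites
that bifurcate once on their way to the outer molecular boundary.
Perforant-path axons are singly-branched cables laid out directly in the
anatomical (crest-centered) frame: a radial stem that enters near the crest
and bifurcates just above it into two branches following the transverse arc
within the pathway's molecular third, with periodic varicosities.

Compartment lengths are uniform within a cell (the soma excepted). Polar
step angles are chosen so terminal tips land exactly on the target laminar
boundary while keeping the uniform step; the randomness lives in azimuthal
wander and branch spreading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..geometry import SyntheticAnatomyParams, _side_params

SOMA, AXON, DEND = 1, 2, 3

__all__ = [
    "Morphology", "GCMorphParams", "AxonParams",
    "generate_granule_morphology", "generate_pp_axon",
    "SOMA", "AXON", "DEND",
]


@dataclass
class Morphology:
    """A rooted tree of cylindrical compartments (positions in um).

    ``parent[i] < i`` always (root has parent -1), so child-after-parent
    ordering can be assumed by solvers.
    """

    parent: np.ndarray
    prox: np.ndarray  # (n, 3)
    dist: np.ndarray  # (n, 3)
    diam: np.ndarray  # (n,)
    region: np.ndarray  # (n,) SWC type codes
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, int)
        self.prox = np.asarray(self.prox, float)
        self.dist = np.asarray(self.dist, float)
        self.diam = np.asarray(self.diam, float)
        self.region = np.asarray(self.region, int)

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.dist - self.prox, axis=1)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.prox + self.dist)

    def path_length_to_root(self) -> np.ndarray:
        """Arc length from the root's proximal end to each compartment's
        distal end."""
        L = self.lengths
        out = np.zeros(self.n)
        for i in range(self.n):
            p = self.parent[i]
            out[i] = L[i] + (out[p] if p >= 0 else 0.0)
        return out

    def children(self):
        ch = [[] for _ in range(self.n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def validate(self, length_rtol: float = 0.05) -> None:
        if self.parent[0] != -1 or np.sum(self.parent == -1) != 1:
            raise ValueError("morphology must have exactly one root")
        if np.any(self.parent[1:] >= np.arange(1, self.n)):
            raise ValueError("parents must precede children")
        nonsoma = self.region != SOMA
        if nonsoma.sum() > 1:
            L = self.lengths[nonsoma]
            if (L.max() - L.min()) > length_rtol * L.mean():
                raise ValueError("compartment lengths are not uniform")

    def transformed(self, rotation: np.ndarray, translation) -> "Morphology":
        t = np.asarray(translation, float)
        return replace(self, prox=self.prox @ rotation.T + t,
                       dist=self.dist @ rotation.T + t,
                       parent=self.parent.copy(), diam=self.diam.copy(),
                       region=self.region.copy(), meta=dict(self.meta))

    # SWC round trip
    def to_swc(self, path) -> None:
        from .. import io
        io.write_swc(path, self)

    @classmethod
    def from_swc(cls, path) -> "Morphology":
        from .. import io
        return io.read_swc(path)


@dataclass(frozen=True)
class GCMorphParams:
    """Granule-cell generator parameters (lengths in um).

    Defaults give 20-30 compartments for the default anatomy, matching the
    one-extracellular-sample-per-section budget.
    """

    n_primary: int = 2
    comp_length: float = 40.0
    radial_span: float = 270.0  # soma center to outer molecular boundary
    branch_frac: float = 0.35
    soma_diam: float = 12.0
    soma_length: float = 12.0
    primary_diam: float = 2.0
    daughter_diam: float = 1.2
    azimuth_jitter_deg: float = 15.0
    daughter_spread_deg: float = 50.0
    # granule-cell arbors are flattened septotemporally: the out-of-plane
    # (local z) component of each step is compressed by this factor
    z_flatten: float = 0.3

    def __post_init__(self):
        if not 2 <= self.n_primary <= 4:
            raise ValueError("n_primary must be in 2..4")
        if self.comp_length <= 0 or self.radial_span <= self.comp_length:
            raise ValueError("invalid lengths")


def _steps_and_cos(dy: float, step: float, max_cos_budget: float):
    """Number of uniform steps and the per-step radial cosine so the chain
    advances exactly ``dy`` along +y."""
    n = max(1, round(dy / step / max_cos_budget))
    cos = dy / (n * step)
    while cos > 0.999:
        n += 1
        cos = dy / (n * step)
    return n, cos


def generate_granule_morphology(rng, params: GCMorphParams | None = None) -> Morphology:
    """Generate one granule cell (local frame, +y dendritic axis).

    The soma sits just below the origin; every dendritic terminal lands
    exactly at y = radial_span (the outer molecular boundary). Unique per
    RNG stream; compartment length is fixed by ``params``.
    """
    if params is None:
        params = GCMorphParams()
    p = params
    step = p.comp_length
    parent = [-1]
    prox = [np.array([0.0, -p.soma_length, 0.0])]
    dist = [np.zeros(3)]
    diam = [p.soma_diam]
    region = [SOMA]

    y_branch = p.branch_frac * p.radial_span
    n1, cos1 = _steps_and_cos(y_branch, step, 0.90)
    n2, cos2 = _steps_and_cos(p.radial_span - y_branch, step, 0.85)
    sin1 = math.sqrt(max(0.0, 1 - cos1 * cos1))
    sin2 = math.sqrt(max(0.0, 1 - cos2 * cos2))
    jit = math.radians(p.azimuth_jitter_deg)

    def grow(start_idx, start_pos, n_steps, cos_t, sin_t, az0, d):
        pos = start_pos.copy()
        par = start_idx
        az = az0
        z_cap = 0.4  # max fraction of the horizontal step going out of plane
        for _ in range(n_steps):
            az += rng.normal(0.0, jit)
            hx, hz = math.cos(az), p.z_flatten * math.sin(az)
            hn = math.hypot(hx, hz)
            hx, hz = hx / hn, hz / hn
            if abs(hz) > z_cap:
                hz = math.copysign(z_cap, hz)
                hx = math.copysign(math.sqrt(1.0 - z_cap * z_cap), hx)
            stepv = step * np.array([sin_t * hx, cos_t, sin_t * hz])
            newpos = pos + stepv
            parent.append(par)
            prox.append(pos)
            dist.append(newpos)
            diam.append(d)
            region.append(DEND)
            par = len(parent) - 1
            pos = newpos
        return par, pos

    spread = math.radians(p.daughter_spread_deg)
    for k in range(p.n_primary):
        az0 = math.pi * (k % 2) + rng.uniform(-0.3, 0.3)
        bidx, bpos = grow(0, dist[0], n1, cos1, sin1, az0, p.primary_diam)
        for sgn in (+1.0, -1.0):
            grow(bidx, bpos, n2, cos2, sin2,
                 az0 + sgn * (spread + rng.uniform(-0.2, 0.2)), p.daughter_diam)

    m = Morphology(np.array(parent), np.array(prox), np.array(dist),
                   np.array(diam), np.array(region),
                   meta={"kind": "granule", "params": p})
    m.validate()
    return m


@dataclass(frozen=True)
class AxonParams:
    """Perforant-path axon generator parameters (lengths in um)."""

    comp_length: float = 20.0
    varicosity_period: float = 40.0
    diam: float = 0.25  # inter-varicosity shaft; must stay >= 0.1
    varicosity_diam: float = 0.6
    radial_jitter: float = 5.0
    end_margin_deg: float = 6.0
    entry_overshoot: float = 24.0  # how far into the bath the stem starts

    def __post_init__(self):
        if self.diam < 0.1:
            raise ValueError("inter-varicosity diameter must be >= 0.1 um")
        if self.varicosity_period < self.comp_length:
            raise ValueError("varicosity period shorter than one compartment")


def generate_pp_axon(anatomy: SyntheticAnatomyParams, pathway: str, rng,
                     params: AxonParams | None = None,
                     z_um: float | None = None) -> Morphology:
    """Generate one singly-branched perforant-path axon (anatomical frame).

    A radial stem enters at the crest from the outer surface, reaches the
    pathway's molecular third, and bifurcates once into two branches that
    follow the transverse arc of each blade within that third. Compartments
    marked as varicosities (``meta['varicosities']``) recur at the
    configured arc-length period and are the potential presynaptic sites.
    Lateral axons stay in the outer third, medial in the middle third.
    """
    if pathway not in ("lateral", "medial"):
        raise ValueError("pathway must be 'lateral' or 'medial'")
    if params is None:
        params = AxonParams()
    p = params
    t_cb = anatomy.cell_body_thickness
    t3 = anatomy.molecular_thickness / 3.0
    third = 2 if pathway == "lateral" else 1  # outer / middle
    dr_lo = t_cb + third * t3
    dr_hi = dr_lo + t3
    dr_mid = 0.5 * (dr_lo + dr_hi)
    if z_um is None:
        z_um = anatomy.septotemporal_depth / 2.0
    (ra, spana), (rb, spanb) = _side_params(anatomy)
    step = p.comp_length

    parent, prox, dist, diam, region = [], [], [], [], []

    # stem: radial entry at the crest, from the bath inward to dr_mid
    entry_dr = anatomy.total_thickness + p.entry_overshoot
    n_stem = max(1, round((entry_dr - dr_mid) / step))
    y0 = -(dr_mid + n_stem * step)  # crest frame: dr -> y = -dr
    pos = np.array([0.0, y0, z_um])
    par = -1
    for _ in range(n_stem):
        new = pos + np.array([0.0, step, 0.0])
        parent.append(par)
        prox.append(pos.copy())
        dist.append(new)
        diam.append(p.diam)
        region.append(AXON)
        par = len(parent) - 1
        pos = new
    branch_idx = par  # bifurcation just above the crest

    stride = max(1, round(p.varicosity_period / step))
    varicosities = []
    margin = math.radians(p.end_margin_deg)
    for sgn, r0, span in ((+1.0, ra, spana), (-1.0, rb, spanb)):
        r_mid = r0 + dr_mid
        dphi = step / r_mid
        n_arc = max(2, int((span - margin) / dphi))
        par_b = branch_idx
        dr = dr_mid
        prev = np.array([0.0, -dr_mid, z_um])  # stem endpoint (crest)
        k_since = 0
        for k in range(n_arc):
            dr = float(np.clip(dr + rng.normal(0.0, p.radial_jitter * 0.3),
                               dr_lo + 0.1 * t3, dr_hi - 0.1 * t3))
            r = r0 + dr
            phi1 = (k + 1) * dphi
            b = np.array([sgn * r * math.sin(phi1), r0 - r * math.cos(phi1), z_um])
            parent.append(par_b)
            prox.append(prev.copy())
            dist.append(b)
            prev = b
            k_since += 1
            if k_since == stride:
                diam.append(p.varicosity_diam)
                varicosities.append(len(parent) - 1)
                k_since = 0
            else:
                diam.append(p.diam)
            region.append(AXON)
            par_b = len(parent) - 1

    m = Morphology(np.array(parent), np.array(prox), np.array(dist),
                   np.array(diam), np.array(region),
                   meta={"kind": "pp_axon", "pathway": pathway,
                         "varicosities": varicosities, "params": p,
                         "branch_index": branch_idx})
    # arc chords differ slightly from the stem step; allow that slack
    m.validate(length_rtol=0.08)
    return m
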