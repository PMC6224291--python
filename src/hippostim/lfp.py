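"""Evoked-potential estimation from transmembrane currents.

Each compartment is treated as a point current source and summed at a
virtual recording site as Phi = (1/4pi) * sum_i I_i * rho_bar_i / r_i,
where rho_bar_i is the path-length-weighted average of the region
resistivities along the straight segment from source to site (a variant of
the line-source method suited to heterogeneous laminated tissue), and r_i
the Euclidean source-site distance, clamped below at one voxel to avoid
the point-source singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DielectricTable, RegionLabel, VoxelVolume

__all__ = ["RecordingSite", "LFPTrace", "weighted_path_resistivity",
           "estimate_evoked_potential"]


@dataclass(frozen=True)
class RecordingSite:
    """A virtual point electrode (position in um)."""

    position: tuple

    def validate_in(self, volume: VoxelVolume) -> None:
        if not volume.contains(self.position):
            raise ValueError(f"recording site {self.position} outside volume")


@dataclass
class LFPTrace:
    site: RecordingSite
    times_ms: np.ndarray
    phi_mv: np.ndarray
    n_sources: int = 0

    def peak_polarity(self, t_from: float = 0.0, t_to: float | None = None) -> int:
        """Sign of the largest-|.| deflection within a window."""
        m = self.times_ms >= t_from
        if t_to is not None:
            m &= self.times_ms <= t_to
        seg = self.phi_mv[m]
        if seg.size == 0 or np.all(seg == 0):
            return 0
        return int(np.sign(seg[np.argmax(np.abs(seg))]))


def weighted_path_resistivity(volume: VoxelVolume, dielectrics: DielectricTable,
                              p_src, p_rec) -> float:
    """Path-length-weighted mean resistivity along the straight segment
    from source to recording point (Ohm·m).

    Marches the segment through the voxel grid (exact axis-crossing
    traversal); the traversed lengths sum to the Euclidean distance.

    Electrode metal and insulation voxels are excluded from the average
    (return currents flow around a microwire, they are not summed through
    teflon); a segment lying entirely inside the electrode falls back to
    the molecular-layer resistivity.
    """
    a = np.asarray(p_src, float)
    b = np.asarray(p_rec, float)
    d = b - a
    dist = np.linalg.norm(d)
    if dist == 0:
        raise ValueError("source and recording point coincide")
    h = volume.voxel_size
    shape = np.asarray(volume.shape)

    def vox_of(p):
        return np.clip(((p - volume.origin) // h).astype(int), 0, shape - 1)

    # collect parametric crossings of voxel planes along each axis
    ts = [0.0, 1.0]
    for ax in range(3):
        if d[ax] == 0:
            continue
        f0 = (a[ax] - volume.origin[ax]) / h
        f1 = (b[ax] - volume.origin[ax]) / h
        lo, hi = sorted((f0, f1))
        for plane in range(int(np.floor(lo)) + 1, int(np.ceil(hi))):
            t = (plane - f0) / (f1 - f0)
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = np.unique(np.asarray(ts))
    skip = (int(RegionLabel.ELECTRODE_METAL), int(RegionLabel.ELECTRODE_INSULATION))
    acc = 0.0
    length = 0.0
    for t0, t1 in zip(ts[:-1], ts[1:]):
        mid = a + d * (0.5 * (t0 + t1))
        lab = int(volume.labels[tuple(vox_of(mid))])
        if lab in skip:
            continue
        acc += dielectrics.rho(RegionLabel(lab)) * (t1 - t0) * dist
        length += (t1 - t0) * dist
    if length == 0.0:
        return dielectrics.rho(RegionLabel.MOLECULAR_MIDDLE)
    return acc / length


def estimate_evoked_potential(sim, sites, volume: VoxelVolume,
                              dielectrics: DielectricTable,
                              min_radius_um: float | None = None) -> list:
    """Estimate Phi(t) (mV) at each recording site from a
    :class:`~hippostim.cablenet.SimOutput`.

    Sources within ``min_radius_um`` (default one voxel) of a site are
    clamped to that radius. Returns a list of :class:`LFPTrace`.
    """
    if sim.currents_a is None:
        raise ValueError("simulation was run without current recording")
    if min_radius_um is None:
        min_radius_um = volume.voxel_size
    pos = sim.comp_positions
    out = []
    for site in sites:
        if not isinstance(site, RecordingSite):
            site = RecordingSite(tuple(site))
        site.validate_in(volume)
        p0 = np.asarray(site.position, float)
        r = np.linalg.norm(pos - p0, axis=1)
        r = np.maximum(r, min_radius_um)
        rho_bar = np.empty(len(pos))
        for i, p in enumerate(pos):
            src = p
            if np.allclose(src, p0):
                # clamped coincident source: nudge one voxel along +x
                src = src + np.array([volume.voxel_size, 0.0, 0.0])
            rho_bar[i] = weighted_path_resistivity(volume, dielectrics, src, p0)
        w = rho_bar / (4.0 * np.pi * r * 1e-6)  # Ohm/m -> V per A
        phi_v = w @ sim.currents_a
        out.append(LFPTrace(site, sim.times_ms, phi_v * 1e3, n_sources=len(pos)))
    return out


def lfp_traces_to_frame(traces) -> pd.DataFrame:
    """Tabulate traces: one t_ms column plus one column per site."""
    if not traces:
        return pd.DataFrame()
    data = {"t_ms": traces[0].times_ms}
    for k, tr in enumerate(traces):
        x, y, z = tr.site.position
        data[f"site{k}_{x:.0f}_{y:.0f}_{z:.0f}"] = tr.phi_mv
    return pd.DataFrame(data)
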