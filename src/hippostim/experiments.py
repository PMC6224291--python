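"""End-to-end experiment orchestration.

Single-config pipelines: the electrode-location x stimulus-amplitude sweep
(9 canonical sites x 50-650 uA in 50 uA steps = 117 cases), the
resistivity-ratio sensitivity analysis, the tissue-capacitance on/off
comparison, and the evoked-potential validation run.

Default problem sizes are desk scale (hundreds of granule cells, tens of
axons, a ~10^5-voxel volume); the full-scale counts remain configuration
options.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .admittance import (FieldSolution, StimWaveform, assemble_network,
                         attach_double_layer, build_multires_mesh,
                         solve_static, solve_transient)
from .cablenet import (MembraneModel, NetworkParams, apply_extracellular,
                       build_network, calibrate_epsp,
                       generate_granule_morphology, simulate)
from .cablenet.morphology import GCMorphParams
from .geometry import (DielectricTable, ElectrodeSpec, RegionLabel,
                       SyntheticAnatomyParams, TISSUE_LABELS,
                       electrode_location_grid, generate_synthetic_dentate,
                       place_electrode)
from .lfp import RecordingSite, estimate_evoked_potential, lfp_traces_to_frame
from .metrics import (ObjectiveWeights, multi_objective_u, nrmse, ps_metrics,
                      split_direct_synaptic)

__all__ = [
    "ExperimentConfig", "SweepPlan", "plan_sweep", "run_sweep",
    "sensitivity_resistivity", "sensitivity_capacitance", "validate_lfp",
    "solve_location_field", "calibrated_gmax",
]


@dataclass
class ExperimentConfig:
    """Everything one run needs; see :meth:`tiny` and :meth:`desk`."""

    anatomy: SyntheticAnatomyParams = field(default_factory=SyntheticAnatomyParams)
    dielectrics: DielectricTable = field(default_factory=DielectricTable.default)
    waveform: StimWaveform = field(default_factory=lambda: StimWaveform(onset_ms=2.0))
    network: NetworkParams = field(default_factory=NetworkParams)
    n_gc: int = 400
    n_axons: int = 80
    dt_ms: float = 0.025
    duration_ms: float = 20.0
    direct_cutoff_ms: float = 3.0
    amp_min_ua: float = 50.0
    amp_max_ua: float = 650.0
    amp_step_ua: float = 50.0
    location_ids: tuple | None = None
    seed: int = 0
    solver_tol: float = 1e-8

    @classmethod
    def desk(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(seed=seed)

    @classmethod
    def tiny(cls, seed: int = 0) -> "ExperimentConfig":
        """A miniature setup for smoke tests."""
        return cls(
            anatomy=SyntheticAnatomyParams.small(),
            n_gc=8, n_axons=4, duration_ms=14.0,
            network=NetworkParams(proximity_radius_um=80.0,
                                  convergence_lateral=120.0,
                                  convergence_medial=112.5),
            seed=seed,
        )

    @classmethod
    def from_toml(cls, path) -> "ExperimentConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        if "anatomy" in raw:
            cfg.anatomy = SyntheticAnatomyParams(**raw["anatomy"])
        if "dielectrics" in raw:
            cfg.dielectrics = DielectricTable.default(**raw["dielectrics"])
        if "waveform" in raw:
            cfg.waveform = StimWaveform(**raw["waveform"])
        if "network" in raw:
            cfg.network = NetworkParams(**raw["network"])
        for key in ("n_gc", "n_axons", "dt_ms", "duration_ms",
                    "direct_cutoff_ms", "amp_min_ua", "amp_max_ua",
                    "amp_step_ua", "seed", "solver_tol"):
            if key in raw.get("run", {}):
                setattr(cfg, key, raw["run"][key])
        if "location_ids" in raw.get("run", {}):
            cfg.location_ids = tuple(raw["run"]["location_ids"])
        return cfg

    def manifest(self) -> dict:
        return {
            "seed": self.seed, "n_gc": self.n_gc, "n_axons": self.n_axons,
            "dt_ms": self.dt_ms, "duration_ms": self.duration_ms,
            "anatomy": json.loads(self.anatomy.to_json()),
            "resistivity_ratio": self.dielectrics.resistivity_ratio,
        }


DEFAULT_TOML = """\
# hippostim experiment configuration (units: um, ms, uA unless noted)
[anatomy]
supra_radius = 430.0
infra_radius = 370.0
cell_body_thickness = 60.0
molecular_thickness = 240.0
septotemporal_depth = 400.0

[dielectrics]
molecular = 2.7
ratio = 2.28
bath = 0.6
hilus = 2.7

[waveform]
amplitude_ua = 100.0
phase_ms = 1.0
onset_ms = 2.0

[network]
proximity_radius_um = 60.0
convergence_lateral = 120.0
convergence_medial = 112.5

[run]
n_gc = 400
n_axons = 80
dt_ms = 0.025
duration_ms = 20.0
seed = 0
"""


# ---------------------------------------------------------------------------
# sweep planning


@dataclass
class SweepPlan:
    """Ordered (location id, amplitude) cases."""

    cases: list  # of (location_id, amplitude_ua)

    def __len__(self):
        return len(self.cases)


def plan_sweep(locations, amp_min: float = 50.0, amp_max: float = 650.0,
               step: float = 50.0) -> SweepPlan:
    """Cartesian product of locations x amplitudes (inclusive, ascending)."""
    locations = list(locations)
    if not locations:
        raise ValueError("empty location list")
    if step <= 0 or amp_min > amp_max:
        raise ValueError("need step > 0 and amp_min <= amp_max")
    n_amp = int(np.floor((amp_max - amp_min) / step + 1e-9)) + 1
    amps = [amp_min + k * step for k in range(n_amp)]
    return SweepPlan([(loc, a) for loc in locations for a in amps])


# ---------------------------------------------------------------------------
# shared pipeline pieces


def solve_location_field(volume, dielectrics, tip, tol: float = 1e-8,
                         with_double_layer: bool = False,
                         electrode: ElectrodeSpec | None = None) -> FieldSolution:
    """Place-and-solve helper: static unit-amplitude (1 uA) field for an
    electrode already embedded at ``tip`` (returns through the grounded
    bath boundary)."""
    mesh = build_multires_mesh(volume, source_positions=[tip])
    net = assemble_network(mesh, dielectrics)
    if with_double_layer and electrode is not None:
        attach_double_layer(net, electrode, mesh)
    node = net.node_at(tip)
    v = solve_static(net, [((node, None), 1e-6)], tol=tol)
    sol = FieldSolution.static(net, v, amplitude_ua=1.0)
    sol.residual = net.kirchhoff_residual(v, [((node, None), 1e-6)])
    return sol


def calibrated_gmax(config: ExperimentConfig, target_mv: float = 0.22):
    """Calibrate the per-synapse peak conductance on a reference granule
    cell with a mid-molecular synapse; returns (gmax_S, achieved_mv)."""
    anat = config.anatomy
    gc_params = config.network.gc_morph or GCMorphParams(
        radial_span=anat.cell_body_thickness / 2.0 + anat.molecular_thickness)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
    morph = generate_granule_morphology(rng, gc_params)
    comp = mid_molecular_compartment(morph, anat)
    return calibrate_epsp(morph, MembraneModel(), comp, target_mv,
                          config.network.tau1_ms, config.network.tau2_ms,
                          config.network.e_rev_mv, config.dt_ms)


def mid_molecular_compartment(morph, anatomy: SyntheticAnatomyParams) -> int:
    """Dendritic compartment (local frame) closest to the middle-third
    midline of the molecular layer."""
    t_cb = anatomy.cell_body_thickness
    t3 = anatomy.molecular_thickness / 3.0
    target_y = t_cb / 2.0 + 1.5 * t3
    dend = np.flatnonzero(morph.region == 3)
    ys = morph.centers[dend, 1]
    return int(dend[np.argmin(np.abs(ys - target_y))])


def _site_by_id(volume, loc_id: int):
    for s in electrode_location_grid(volume):
        if s.id == loc_id:
            return s
    raise KeyError(f"no electrode site with id {loc_id}")


# ---------------------------------------------------------------------------
# the bilinear sweep


def run_sweep(config: ExperimentConfig, out_dir=None,
              weights: ObjectiveWeights | None = None) -> pd.DataFrame:
    """Run the (location x amplitude) sweep and score each case.

    Resistive fields are solved once per location at unit amplitude and
    scaled per case. Results are appended to ``out_dir/sweep_metrics.csv``
    case by case, and existing rows are skipped on restart, so an
    interrupted sweep resumes where it stopped.
    """
    volume = generate_synthetic_dentate(config.anatomy)
    sites = electrode_location_grid(volume)
    loc_ids = config.location_ids or tuple(s.id for s in sites)
    plan = plan_sweep(loc_ids, config.amp_min_ua, config.amp_max_ua,
                      config.amp_step_ua)

    gmax, achieved = calibrated_gmax(config)
    net_params = replace(config.network, gmax_s=gmax)
    network = build_network(config.anatomy, config.n_gc, config.n_axons,
                            net_params, seed=config.seed)

    csv_path = None
    done = set()
    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "sweep_metrics.csv"
        if csv_path.exists():
            prev = pd.read_csv(csv_path)
            rows = prev.to_dict("records")
            done = {(int(r["location_id"]), float(r["amplitude_ua"]))
                    for r in rows}
        (out_dir / "manifest.json").write_text(json.dumps({
            **config.manifest(), "gmax_S": gmax, "epsp_mv": achieved,
            "n_cases": len(plan)}, indent=2))

    fields = {}
    for loc_id, amp in plan.cases:
        if (loc_id, float(amp)) in done:
            continue
        if loc_id not in fields:
            site = _site_by_id(volume, loc_id)
            vol_e = place_electrode(volume, ElectrodeSpec(tip=site.position))
            fields[loc_id] = (site, solve_location_field(
                vol_e, config.dielectrics, site.position, config.solver_tol))
        site, fsol = fields[loc_id]
        row = _run_case(config, network, site, fsol, amp)
        rows.append(row)
        if csv_path is not None:
            pd.DataFrame(rows).to_csv(csv_path, index=False)

    df = pd.DataFrame(rows).sort_values(["location_id", "amplitude_ua"])
    df = df.reset_index(drop=True)
    if len(df) >= 2:
        ms = [_metrics_from_row(r) for r in df.to_dict("records")]
        df["U"] = multi_objective_u(ms, weights)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def _run_case(config, network, site, fsol, amp):
    wave = replace(config.waveform, amplitude_ua=amp)
    drive = apply_extracellular(network, fsol, wave, config.dt_ms,
                                config.duration_ms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate(network, drive, config.duration_ms, config.dt_ms,
                       record_currents=False)
    direct, synaptic = split_direct_synaptic(sim.raster, wave.onset_ms,
                                             config.direct_cutoff_ms)
    pm = ps_metrics(synaptic, network.n_gc, amp,
                    t_ref_ms=wave.onset_ms)
    return {
        "location_id": site.id, "amplitude_ua": amp,
        "transverse": site.transverse, "laminar": site.laminar,
        "n_axon_active": sim.raster.active_cells("axon"),
        "n_gc_direct": direct.events.cell_id.nunique(),
        "n_gc_synaptic": synaptic.events.cell_id.nunique(),
        "total_proportion": pm.total_proportion, "ps_max": pm.ps_max,
        "max_cdf_slope": pm.max_cdf_slope, "hhw_ms": pm.hhw_ms,
        "hhw_from_fit": pm.hhw_from_fit, "efficiency": pm.efficiency,
        "n_spikes": pm.n_spikes,
    }


def _metrics_from_row(r):
    from .metrics import PSMetrics

    return PSMetrics(r["total_proportion"], r["ps_max"], r["max_cdf_slope"],
                     r["hhw_ms"], np.isfinite(r["hhw_ms"]),
                     bool(r["hhw_from_fit"]), r["efficiency"],
                     int(r["n_spikes"]))


# ---------------------------------------------------------------------------
# sensitivity analyses


def _sensitivity_box(volume, tip_idx, half: int = 5, inward_um: float = 60.0):
    """(x, y) index slices of the analysis box: a 10x10-voxel band centered
    ``inward_um`` radially inward (toward the hilus) of the electrode tip."""
    h = volume.voxel_size
    tip = volume.voxel_center(tip_idx)
    anat = volume.meta["anatomy"]
    from .geometry import _side_params

    (ra, _), (rb, _) = _side_params(anat)
    r0 = ra if tip[0] >= 0 else rb
    center = np.array([0.0, r0])
    d = center - tip[:2]
    d = d / np.linalg.norm(d)
    c = tip[:2] + inward_um * d
    ci = ((c - volume.origin[:2]) // h).astype(int)
    sx = slice(max(ci[0] - half, 0), min(ci[0] + half, volume.shape[0]))
    sy = slice(max(ci[1] - half, 0), min(ci[1] + half, volume.shape[1]))
    return sx, sy


def sensitivity_resistivity(config: ExperimentConfig,
                            ratios=(1.0, 2.28, 5.0), control: float = 2.28,
                            electrodes=("pp_crest", "cell_body_crest"),
                            depths_vox=(2, 4, 6),
                            include_network: bool = False):
    """NRMSE of the stimulus field against the control resistivity ratio.

    For each electrode site (crest perforant-path and crest cell-body by
    default) the static 100 uA field is solved at each cell-body:molecular
    ratio and compared with the control within a 10x10-voxel molecular/
    hilar box at three depths beyond the tip along the insertion axis.
    Returns (table, details); details carries the per-ratio mean hilar
    current-density proxy under the electrode.
    """
    if control not in ratios:
        raise ValueError("ratios must include the control")
    volume = generate_synthetic_dentate(config.anatomy)
    site_ids = {"pp_crest": 2, "cell_body_crest": 8}
    amp_a = 100e-6
    rows = []
    details = {}
    for elec in electrodes:
        site = _site_by_id(volume, site_ids[elec])
        vol_e = place_electrode(volume, ElectrodeSpec(tip=site.position))
        mesh = build_multires_mesh(vol_e, source_positions=[site.position])
        tip_idx = vol_e.index_of(site.position)
        sx, sy = _sensitivity_box(vol_e, tip_idx)
        grids = {}
        for ratio in ratios:
            diel = config.dielectrics.with_ratio(ratio)
            net = assemble_network(mesh, diel)
            node = net.node_at(site.position)
            v = solve_static(net, [((node, None), amp_a)], tol=config.solver_tol)
            grids[ratio] = FieldSolution.static(net, v).fine_grid()
        ctrl = grids[control]
        hilus_mask = vol_e.labels == int(RegionLabel.HILUS)
        dens = {}
        h_m = vol_e.voxel_size * 1e-6
        for ratio in ratios:
            for d in depths_vox:
                k = min(tip_idx[2] + d, vol_e.shape[2] - 1)
                val = nrmse(grids[ratio][sx, sy, k], ctrl[sx, sy, k])
                rows.append({"electrode": elec, "ratio": ratio,
                             "depth_um": d * vol_e.voxel_size, "nrmse": val})
            # hilar current-density proxy |grad V| / rho over the hilus
            # within a transverse window under the electrode
            g = np.gradient(grids[ratio], h_m)
            mag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
            m = np.zeros_like(hilus_mask)
            i0 = tip_idx[0]
            m[max(i0 - 10, 0):i0 + 10, :, :] = hilus_mask[max(i0 - 10, 0):i0 + 10, :, :]
            rho_h = config.dielectrics.rho(RegionLabel.HILUS)
            dens[ratio] = float(mag[m].mean() / rho_h) if m.any() else 0.0
        details[elec] = {"hilar_current_density": dens,
                         "box": (sx, sy), "tip_idx": tip_idx}
        if include_network:
            details[elec]["network"] = _network_response_per_ratio(
                config, vol_e, site, mesh, ratios)
    return pd.DataFrame(rows), details


def _network_response_per_ratio(config, vol_e, site, mesh, ratios):
    gmax, _ = calibrated_gmax(config)
    net_params = replace(config.network, gmax_s=gmax)
    network = build_network(config.anatomy, config.n_gc, config.n_axons,
                            net_params, seed=config.seed)
    out = {}
    for ratio in ratios:
        diel = config.dielectrics.with_ratio(ratio)
        net = assemble_network(mesh, diel)
        node = net.node_at(site.position)
        v = solve_static(net, [((node, None), 1e-6)], tol=config.solver_tol)
        fsol = FieldSolution.static(net, v, amplitude_ua=1.0)
        row = _run_case(config, network, site, fsol,
                        config.waveform.amplitude_ua)
        out[ratio] = row
    return out


def sensitivity_capacitance(config: ExperimentConfig,
                            eps_tissue: float = 2.79e-6,
                            amplitude_ua: float = 100.0,
                            sample_ms: float = 0.1,
                            substep_us: float = 1.0) -> dict:
    """Capacitive vs purely resistive transient fields.

    Solves the same biphasic pulse with tissue permittivity on and off
    (the electrode double layer is present in both) and reports the
    maximum over tissue nodes and output samples of |V_cap - V_res| /
    max|V_res|, in percent. Output samples every ``sample_ms``; internal
    backward-Euler substeps of ``substep_us`` resolve the microsecond
    tissue charging.
    """
    volume = generate_synthetic_dentate(config.anatomy)
    site = _site_by_id(volume, 2)  # crest, mid-molecular (perforant path)
    spec = ElectrodeSpec(tip=site.position)
    vol_e = place_electrode(volume, spec)
    spec = vol_e.meta["electrodes"][-1]
    mesh = build_multires_mesh(vol_e, source_positions=[spec.tip])
    wave = StimWaveform(amplitude_ua=amplitude_ua, phase_ms=1.0, onset_ms=0.0)
    substeps = max(1, int(round(sample_ms * 1e3 / substep_us)))
    duration = wave.end_ms + 2 * sample_ms

    sols = {}
    for name, eps in (("resistive", 0.0), ("capacitive", eps_tissue)):
        diel = config.dielectrics.with_tissue_permittivity(eps)
        net = assemble_network(mesh, diel, capacitive_tissue=True)
        attach_double_layer(net, spec, mesh)
        node = net.node_at(spec.tip)
        sols[name] = (solve_transient(net, wave, (node, None), sample_ms,
                                      duration, substeps=substeps), net)
    sol_r, net_r = sols["resistive"]
    sol_c, _ = sols["capacitive"]
    tissue = np.isin(net_r.node_region, [int(l) for l in TISSUE_LABELS])
    vr = sol_r.voltages[:, tissue]
    vc = sol_c.voltages[:, tissue]
    ref = np.abs(vr).max()
    diff = np.abs(vc - vr).max() / ref * 100.0
    return {"max_rel_diff_pct": float(diff), "reference_v": float(ref),
            "n_nodes": int(net_r.n_nodes), "n_samples": sol_r.n_times,
            "eps_tissue": eps_tissue}


def validate_lfp(config: ExperimentConfig, amplitude_ua: float = 200.0,
                 n_track_sites: int = 5):
    """Crest stimulation and evoked-potential polarity along a
    dendritic-to-somatic track.

    Returns a dict with the trace table, the per-site peak polarity of the
    population-spike window, and the site layer names.
    """
    volume = generate_synthetic_dentate(config.anatomy)
    site = _site_by_id(volume, 2)
    vol_e = place_electrode(volume, ElectrodeSpec(tip=site.position))
    fsol = solve_location_field(vol_e, config.dielectrics, site.position,
                                config.solver_tol)
    gmax, _ = calibrated_gmax(config)
    net_params = replace(config.network, gmax_s=gmax)
    network = build_network(config.anatomy, config.n_gc, config.n_axons,
                            net_params, seed=config.seed)
    wave = replace(config.waveform, amplitude_ua=amplitude_ua)
    drive = apply_extracellular(network, fsol, wave, config.dt_ms,
                                config.duration_ms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate(network, drive, config.duration_ms, config.dt_ms,
                       record_currents=True)
    anat = config.anatomy
    t_cb = anat.cell_body_thickness
    t3 = anat.molecular_thickness / 3.0
    zmid = volume.origin[2] + volume.extent[2] / 2.0
    track = np.linspace(t_cb + 2.5 * t3, 0.5 * t_cb, n_track_sites)
    # offset transversally off the crest so sites do not sit inside the
    # electrode shaft
    phi = 0.12
    from .geometry import _side_params

    (ra, _), _ = _side_params(anat)
    sites = []
    layers = []
    for dr in track:
        r = ra + dr
        sites.append(RecordingSite((r * np.sin(phi), ra - r * np.cos(phi), zmid)))
        layers.append("molecular" if dr > t_cb else "cell_body")
    traces = estimate_evoked_potential(sim, sites, vol_e, config.dielectrics)
    # polarity is judged in the population-spike window (around the
    # synchronized somatic spikes), where the soma-layer sink dominates
    t0 = wave.onset_ms + config.direct_cutoff_ms
    gc_syn = sim.raster.of_type("gc")
    gc_syn = gc_syn[gc_syn.t_ms > t0]
    if len(gc_syn):
        w0, w1 = gc_syn.t_ms.min() - 0.3, gc_syn.t_ms.max() + 1.5
    else:
        w0, w1 = t0, None
    pol = [tr.peak_polarity(t_from=w0, t_to=w1) for tr in traces]
    return {"traces": lfp_traces_to_frame(traces), "polarities": pol,
            "layers": layers, "raster": sim.raster, "sites": sites,
            "ps_window_ms": (w0, w1)}
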