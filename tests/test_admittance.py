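"""Admittance-method mesh, network assembly, and field solvers."""

import math

import numpy as np
import pytest
import scipy.ndimage as ndi

from hippostim.admittance import (FieldSolution, StimWaveform,
                                  analytic_point_source, assemble_network,
                                  attach_double_layer, build_multires_mesh,
                                  sample_potential, solve_static,
                                  solve_transient)
from hippostim.geometry import (DielectricTable, ElectrodeSpec, RegionLabel,
                                VoxelVolume, electrode_location_grid,
                                place_electrode)

RHO = 2.7
H = 12e-6


class TestMesh:
    def test_uniform_cube_merges_to_64_voxel_elements(self, homogeneous_cube):
        mesh = build_multires_mesh(homogeneous_cube(8))
        assert mesh.n_elements == 8
        assert (mesh.side == 4).all()

    def test_source_vetoes_merging(self, homogeneous_cube):
        vol = homogeneous_cube(8)
        mesh = build_multires_mesh(vol, source_positions=[vol.voxel_center((0, 0, 0))])
        assert mesh.n_elements > 8

    def test_label_boundary_keeps_single_voxels(self, homogeneous_cube):
        vol = homogeneous_cube(8)
        vol.labels[:, :4, :] = int(RegionLabel.CELL_BODY)
        mesh = build_multires_mesh(vol)
        touching = (mesh.anchor[:, 1] + mesh.side == 4) | (mesh.anchor[:, 1] == 4)
        assert (mesh.side[touching] == 1).all()

    def test_elements_tile_volume_exactly(self, small_volume):
        mesh = build_multires_mesh(small_volume)
        assert (mesh.voxel_to_element >= 0).all()
        vols = (mesh.side.astype(int) ** 3).sum()
        assert vols == int(np.prod(small_volume.shape))

    def test_neighbor_sides_within_factor_two(self, small_volume):
        mesh = build_multires_mesh(small_volume)
        si = mesh.side[mesh.adj_i].astype(float)
        sj = mesh.side[mesh.adj_j].astype(float)
        assert (np.maximum(si, sj) / np.minimum(si, sj) <= 2).all()


class TestAssembly:
    def test_branch_conductance_between_equal_cubes(self, homogeneous_cube):
        """G = A / (rho d) for two adjacent fine cubes at 2.7 Ohm·m."""
        vol = homogeneous_cube(2)
        mesh = build_multires_mesh(vol, max_side=1)
        net = assemble_network(mesh, DielectricTable.default(), reference="none")
        expected = (H * H) / (RHO * H)  # 4.444e-6 S
        assert np.allclose(net.branch_G, expected, rtol=1e-12)
        assert expected == pytest.approx(4.444e-6, rel=1e-3)

    def test_chain_end_to_end_resistance_is_series_sum(self):
        n = 6
        labels = np.full((n, 1, 1), int(RegionLabel.MOLECULAR_MIDDLE), np.uint8)
        vol = VoxelVolume(labels, 12.0)
        mesh = build_multires_mesh(vol, max_side=1)
        net = assemble_network(mesh, DielectricTable.default(), reference="none")
        a = net.node_at(vol.voxel_center((0, 0, 0)))
        b = net.node_at(vol.voxel_center((n - 1, 0, 0)))
        v = solve_static(net, [((a, b), 1e-6)])
        r = (v[a] - v[b]) / 1e-6
        assert r == pytest.approx((n - 1) * RHO * H / (H * H), rel=1e-8)

    def test_missing_dielectric_entry_raises(self, homogeneous_cube):
        mesh = build_multires_mesh(homogeneous_cube(4))
        broken = DielectricTable({RegionLabel.BATH: 0.6}, {})
        with pytest.raises(KeyError):
            assemble_network(mesh, broken)

    def test_network_connected_excluding_insulation(self, small_volume):
        site = electrode_location_grid(small_volume)[1]
        vol = place_electrode(small_volume, ElectrodeSpec(tip=site.position))
        net = assemble_network(build_multires_mesh(vol), DielectricTable.default())
        assert net.is_connected()


class TestDoubleLayer:
    def _network(self, small_volume):
        site = electrode_location_grid(small_volume)[1]
        vol = place_electrode(small_volume, ElectrodeSpec(tip=site.position))
        spec = vol.meta["electrodes"][-1]
        mesh = build_multires_mesh(vol, source_positions=[spec.tip])
        net = assemble_network(mesh, DielectricTable.default())
        return net, spec

    def test_total_capacitance_is_spec_times_exposed_area(self, small_volume):
        net, spec = self._network(small_volume)
        metal = net.node_at(spec.tip)
        sel = (net.branch_i == metal) | (net.branch_j == metal)
        exposed = net.branch_area[sel].sum()
        attach_double_layer(net, spec)
        assert net.branch_C[sel].sum() == pytest.approx(
            spec.double_layer_capacitance * exposed, rel=1e-12)
        # voxelized 48 um tip disc is close to the analytic disc area
        assert exposed == pytest.approx(math.pi * (24e-6) ** 2, rel=0.1)

    def test_zero_specific_capacitance_is_noop(self, small_volume):
        net, spec = self._network(small_volume)
        before = net.branch_C.copy()
        attach_double_layer(net, ElectrodeSpec(tip=spec.tip,
                                               double_layer_capacitance=0.0))
        assert np.array_equal(net.branch_C, before)

    def test_fully_insulated_electrode_rejected(self, small_volume):
        net, spec = self._network(small_volume)
        metal = net.node_at(spec.tip)
        sel = (net.branch_i == metal) | (net.branch_j == metal)
        net.branch_i = net.branch_i[~sel]
        net.branch_j = net.branch_j[~sel]
        net.branch_G = net.branch_G[~sel]
        net.branch_C = net.branch_C[~sel]
        net.branch_area = net.branch_area[~sel]
        with pytest.raises(ValueError):
            attach_double_layer(net, spec)


class TestStaticSolve:
    def test_single_branch_ohms_law(self):
        labels = np.full((2, 1, 1), int(RegionLabel.MOLECULAR_MIDDLE), np.uint8)
        vol = VoxelVolume(labels, 12.0)
        net = assemble_network(build_multires_mesh(vol, max_side=1),
                               DielectricTable.default(), reference="none")
        a, b = 0, 1
        v = solve_static(net, [((a, b), 1e-6)])
        r = RHO * H / (H * H)
        assert v[a] - v[b] == pytest.approx(1e-6 * r, rel=1e-9)

    def test_linearity_doubling_current_doubles_voltage(self, small_volume):
        net = assemble_network(build_multires_mesh(small_volume),
                               DielectricTable.default())
        node = net.node_at(small_volume.voxel_center(
            tuple(s // 2 for s in small_volume.shape)))
        v1 = solve_static(net, [((node, None), 1e-6)])
        v2 = solve_static(net, [((node, None), 2e-6)])
        assert np.allclose(v2, 2 * v1, rtol=1e-6, atol=1e-12)

    def test_superposition_of_two_sources(self, homogeneous_cube):
        vol = homogeneous_cube(12)
        net = assemble_network(build_multires_mesh(vol, max_side=1),
                               DielectricTable.default(), reference="all_faces")
        na = net.node_at(vol.voxel_center((3, 3, 3)))
        nb = net.node_at(vol.voxel_center((8, 8, 8)))
        va = solve_static(net, [((na, None), 1e-6)], method="direct")
        vb = solve_static(net, [((nb, None), 2e-6)], method="direct")
        vab = solve_static(net, [((na, None), 1e-6), ((nb, None), 2e-6)],
                           method="direct")
        assert np.allclose(vab, va + vb, rtol=1e-9, atol=1e-15)

    def test_reciprocity_of_transfer_voltage(self, homogeneous_cube):
        vol = homogeneous_cube(12)
        vol.labels[:, :5, :] = int(RegionLabel.CELL_BODY)
        net = assemble_network(build_multires_mesh(vol),
                               DielectricTable.default(), reference="all_faces")
        na = net.node_at(vol.voxel_center((2, 2, 2)))
        nb = net.node_at(vol.voxel_center((9, 9, 9)))
        v1 = solve_static(net, [((na, None), 1e-6)], method="direct")
        v2 = solve_static(net, [((nb, None), 1e-6)], method="direct")
        assert v1[nb] == pytest.approx(v2[na], rel=1e-9)

    def test_kirchhoff_residual_within_tolerance(self, small_volume):
        net = assemble_network(build_multires_mesh(small_volume),
                               DielectricTable.default())
        node = net.node_at(small_volume.voxel_center(
            tuple(s // 2 for s in small_volume.shape)))
        src = [((node, None), 100e-6)]
        v = solve_static(net, src, tol=1e-10)
        assert net.kirchhoff_residual(v, src) <= 1e-8


class TestTransient:
    def _electrode_net(self, small_volume, eps=0.0, dl=True):
        site = electrode_location_grid(small_volume)[1]
        vol = place_electrode(small_volume, ElectrodeSpec(tip=site.position))
        spec = vol.meta["electrodes"][-1]
        mesh = build_multires_mesh(vol, source_positions=[spec.tip])
        diel = DielectricTable.default().with_tissue_permittivity(eps)
        net = assemble_network(mesh, diel, capacitive_tissue=True)
        if dl:
            attach_double_layer(net, spec)
        return net, spec

    def test_resistive_network_scales_static_solution(self, small_volume):
        net, spec = self._electrode_net(small_volume, dl=False)
        node = net.node_at(spec.tip)
        wave = StimWaveform(amplitude_ua=100.0, phase_ms=1.0)
        sol = solve_transient(net, wave, (node, None), dt_ms=0.25)
        unit = solve_static(net, [((node, None), 1e-6)])
        scale = np.abs(unit).max() * wave.amplitude_ua
        for k, t in enumerate(sol.times_ms):
            expect = unit * float(wave.current_ua(t))
            # both sides are iterative solves at rtol 1e-8
            assert np.allclose(sol.voltages[k], expect, rtol=1e-4,
                               atol=1e-6 * scale)

    def test_zero_amplitude_gives_zero_field(self, small_volume):
        net, spec = self._electrode_net(small_volume)
        node = net.node_at(spec.tip)
        wave = StimWaveform(amplitude_ua=0.0)
        sol = solve_transient(net, wave, (node, None), dt_ms=0.25)
        assert np.all(sol.voltages == 0)

    def test_interface_rc_step_response_matches_single_pole(self):
        """Electrode-interface charging on a reduced two-node fixture follows
        1 - exp(-t/RC) with R the access resistor and C the interface cap."""
        labels = np.full((2, 1, 1), int(RegionLabel.MOLECULAR_MIDDLE), np.uint8)
        vol = VoxelVolume(labels, 12.0)
        net = assemble_network(build_multires_mesh(vol, max_side=1),
                               DielectricTable.default(), reference="none")
        # ground node 1, add a capacitor in series-parallel at the branch
        c = 1e-9
        net.branch_C = net.branch_C + c
        net.ground_G[1] = 1e3  # effectively pins node 1 to 0 V
        g = net.branch_G[0]
        wave = StimWaveform(amplitude_ua=1.0, phase_ms=5.0)
        dt = 0.005
        sol = solve_transient(net, wave, (0, None), dt_ms=dt, duration_ms=4.0,
                              substeps=20)
        tau_ms = c / g * 1e3
        i0 = -1e-6  # cathodic first
        t = sol.times_ms
        expect = (i0 / g) * (1 - np.exp(-t / tau_ms))
        got = sol.voltages[:, 0]
        assert np.allclose(got, expect, rtol=0.02, atol=abs(i0 / g) * 0.01)

    def test_capacitance_effect_grows_with_permittivity(self, small_anatomy):
        """Residual field deviation after one sample interval increases
        monotonically with tissue permittivity (RC charging fraction)."""
        from hippostim.experiments import (ExperimentConfig,
                                           sensitivity_capacitance)
        cfg = ExperimentConfig(anatomy=small_anatomy.scaled(
            0.8, septotemporal_depth=96.0, margin=60.0))
        diffs = [sensitivity_capacitance(cfg, eps_tissue=e, sample_ms=0.25,
                                         substep_us=4.0)["max_rel_diff_pct"]
                 for e in (1e-6, 1e-5, 1e-4)]
        assert diffs[0] < diffs[1] < diffs[2]


class TestSampling:
    def test_trilinear_reproduces_linear_field(self, homogeneous_cube):
        vol = homogeneous_cube(8)
        mesh = build_multires_mesh(vol, max_side=1)
        net = assemble_network(mesh, DielectricTable.default(), reference="none")
        a, b = 3.0, 1.0  # volts per um, offset
        v = a * net.node_pos[:, 0] + b
        sol = FieldSolution.static(net, v)
        rng = np.random.default_rng(0)
        lo = vol.origin + vol.voxel_size
        hi = vol.origin + vol.extent - vol.voxel_size
        pts = rng.uniform(lo, hi, size=(20, 3))
        got = sol.sample(pts)
        assert np.allclose(got, a * pts[:, 0] + b, rtol=1e-9, atol=1e-9)

    def test_sample_at_node_center_returns_node_voltage(self, homogeneous_cube):
        vol = homogeneous_cube(4)
        mesh = build_multires_mesh(vol, max_side=1)
        net = assemble_network(mesh, DielectricTable.default(), reference="none")
        v = np.arange(net.n_nodes, dtype=float)
        sol = FieldSolution.static(net, v)
        node = net.node_at(vol.voxel_center((2, 1, 3)))
        assert sample_potential(sol, vol.voxel_center((2, 1, 3))) == pytest.approx(v[node])

    def test_off_node_sample_within_bracketing_extremes(self, homogeneous_cube):
        vol = homogeneous_cube(6)
        mesh = build_multires_mesh(vol, max_side=1)
        net = assemble_network(mesh, DielectricTable.default(), reference="none")
        rng = np.random.default_rng(1)
        v = rng.normal(size=net.n_nodes)
        sol = FieldSolution.static(net, v)
        p = vol.voxel_center((2, 2, 2)) + np.array([5.0, -3.0, 4.0])
        assert v.min() - 1e-12 <= sol.sample(p) <= v.max() + 1e-12

    def test_out_of_bounds_sample_raises(self, small_volume):
        mesh = build_multires_mesh(small_volume)
        net = assemble_network(mesh, DielectricTable.default())
        sol = FieldSolution.static(net, np.zeros(net.n_nodes))
        with pytest.raises(ValueError):
            sol.sample(small_volume.origin - 100.0)


class TestAnalyticPointSource:
    def test_printed_example(self):
        assert analytic_point_source(100e-6, 2.7, 100e-6) == pytest.approx(
            0.2149, abs=5e-5)

    def test_zero_current(self):
        assert analytic_point_source(0.0, 2.7, 1e-4) == 0.0

    def test_inverse_distance_scaling(self):
        v1 = analytic_point_source(1e-6, 2.7, 50e-6)
        v2 = analytic_point_source(1e-6, 2.7, 100e-6)
        assert v1 == pytest.approx(2 * v2)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            analytic_point_source(1e-6, 2.7, 0.0)


def test_waveform_is_charge_balanced_and_cathodic_first():
    w = StimWaveform(amplitude_ua=150.0, phase_ms=1.0)
    dt = 1e-4  # midpoint rule is exact for a square wave on this grid
    mids = np.arange(0, w.end_ms, dt) + dt / 2
    q = w.current_ua(mids).sum() * dt
    assert abs(q) < 1e-9 * w.amplitude_ua * w.phase_ms
    assert w.current_ua(0.5) == -150.0
    assert w.current_ua(1.5) == 150.0
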