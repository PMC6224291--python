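"""Morphologies, cable dynamics, synapses, and network construction."""

import math

import numpy as np
import pytest

from hippostim.cablenet import (AxonParams, GCMorphParams, MembraneModel,
                                Morphology, NetworkParams, SynapseOnCell,
                                build_network, calibrate_epsp, detect_spikes,
                                double_exp_peak_time,
                                generate_granule_morphology, generate_pp_axon,
                                simulate_cell, syn_conductance)
from hippostim.cablenet.morphology import AXON, DEND
from hippostim.geometry import SyntheticAnatomyParams, laminar_offset


def straight_axon(n=100, length=20.0, diam=0.25):
    parent = np.arange(-1, n - 1)
    prox = np.zeros((n, 3))
    dist = np.zeros((n, 3))
    prox[:, 0] = np.arange(n) * length
    dist[:, 0] = np.arange(1, n + 1) * length
    return Morphology(parent, prox, dist, np.full(n, diam), np.full(n, AXON))


class TestGranuleMorphology:
    def test_terminals_reach_outer_boundary_with_uniform_compartments(self):
        p = GCMorphParams()
        m = generate_granule_morphology(np.random.default_rng(3), p)
        children = m.children()
        tips = [i for i in range(m.n) if not children[i]]
        assert all(abs(m.dist[i, 1] - p.radial_span) < 1e-6 for i in tips)
        dend = m.region == DEND
        assert np.allclose(m.lengths[dend], p.comp_length, rtol=1e-9)
        # path spans all three molecular thirds by construction
        assert m.centers[dend, 1].min() < p.radial_span / 3
        assert m.centers[dend, 1].max() > 2 * p.radial_span / 3

    def test_seeds_differ_in_shape_not_compartment_length(self):
        a = generate_granule_morphology(np.random.default_rng(0))
        b = generate_granule_morphology(np.random.default_rng(1))
        assert not np.allclose(a.dist, b.dist)
        la = a.lengths[a.region == DEND]
        lb = b.lengths[b.region == DEND]
        assert la.mean() == pytest.approx(lb.mean(), rel=1e-9)
        assert np.ptp(la) < 1e-6 and np.ptp(lb) < 1e-6

    def test_swc_round_trip_preserves_topology_and_coordinates(self, tmp_path):
        m = generate_granule_morphology(np.random.default_rng(7))
        path = tmp_path / "gc.swc"
        m.to_swc(path)
        back = Morphology.from_swc(path)
        assert np.array_equal(back.parent, m.parent)
        assert np.allclose(back.prox, m.prox, atol=1e-4)
        assert np.allclose(back.dist, m.dist, atol=1e-4)
        assert np.array_equal(back.region, m.region)

    def test_compartment_count_fits_drive_site_budget(self):
        m = generate_granule_morphology(np.random.default_rng(11))
        assert 20 <= m.n <= 30


@pytest.fixture(scope="module")
def anatomy():
    return SyntheticAnatomyParams()


@pytest.fixture(scope="module")
def threshold_axon(anatomy):
    return anatomy, generate_pp_axon(anatomy, "lateral",
                                     np.random.default_rng(1))


@pytest.fixture(scope="module")
def reference_cell():
    return generate_granule_morphology(np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_net_anatomy():
    return SyntheticAnatomyParams.small()


class TestAxonMorphology:
    def test_lateral_varicosities_in_outer_third(self, anatomy):
        m = generate_pp_axon(anatomy, "lateral", np.random.default_rng(0))
        t_cb = anatomy.cell_body_thickness
        t3 = anatomy.molecular_thickness / 3
        centers = m.centers[m.meta["varicosities"]]
        dr, _ = laminar_offset(centers, anatomy)
        assert np.all(dr >= t_cb + 2 * t3)
        assert np.all(dr < t_cb + 3 * t3)

    def test_medial_varicosities_in_middle_third(self, anatomy):
        m = generate_pp_axon(anatomy, "medial", np.random.default_rng(0))
        t_cb = anatomy.cell_body_thickness
        t3 = anatomy.molecular_thickness / 3
        dr, _ = laminar_offset(m.centers[m.meta["varicosities"]], anatomy)
        assert np.all(dr >= t_cb + t3)
        assert np.all(dr < t_cb + 2 * t3)

    def test_exactly_one_bifurcation(self, anatomy):
        m = generate_pp_axon(anatomy, "medial", np.random.default_rng(5))
        n_children = np.bincount(m.parent[m.parent >= 0], minlength=m.n)
        assert (n_children > 1).sum() == 1
        assert n_children.max() == 2

    def test_varicosity_spacing_matches_period(self, anatomy):
        p = AxonParams(comp_length=20.0, varicosity_period=40.0)
        m = generate_pp_axon(anatomy, "lateral", np.random.default_rng(2), p)
        arc = m.path_length_to_root()
        # branch id per compartment: a new branch starts wherever the parent
        # is not the previous compartment
        branch = np.zeros(m.n, int)
        bid = 0
        for i in range(1, m.n):
            if m.parent[i] != i - 1:
                bid += 1
            branch[i] = bid
        vari = sorted(m.meta["varicosities"])
        gaps = []
        for a, b in zip(vari[:-1], vari[1:]):
            if branch[a] == branch[b]:
                gaps.append(arc[b] - arc[a])
        gaps = np.asarray(gaps)
        assert len(gaps) > 10
        assert np.all(np.abs(gaps - p.varicosity_period) <= p.comp_length + 1e-6)

    def test_shaft_diameter_floor(self):
        with pytest.raises(ValueError):
            AxonParams(diam=0.05)


class TestSynapseKinetics:
    def test_conductance_zero_at_onset(self):
        assert syn_conductance(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_peak_time_closed_form(self):
        tp = double_exp_peak_time(1.05, 5.75)
        assert tp == pytest.approx(2.184, abs=5e-4)
        t = np.linspace(0, 20, 40001)
        g = syn_conductance(t, 1.05, 5.75, gmax=1.0)
        assert t[np.argmax(g)] == pytest.approx(tp, abs=1e-3)

    def test_peak_equals_gmax(self):
        t = np.linspace(0, 30, 300001)
        g = syn_conductance(t, 1.05, 5.75, gmax=3.2e-9)
        assert g.max() == pytest.approx(3.2e-9, rel=1e-9)

    def test_equal_taus_alpha_limit(self):
        t = np.linspace(0, 20, 20001)
        g = syn_conductance(t, 2.0, 2.0, gmax=1.0)
        assert g.max() == pytest.approx(1.0, rel=1e-6)
        assert t[np.argmax(g)] == pytest.approx(2.0, abs=1e-2)


class TestCableDynamics:
    def test_uniform_extracellular_potential_is_noop(self):
        """A spatially uniform Ve(t) leaves the membrane trajectory
        untouched (only Ve differences drive the cable)."""
        m = generate_granule_morphology(np.random.default_rng(0))
        n_t = int(10.0 / 0.025)
        ve = np.tile(50.0 * np.sin(np.arange(n_t + 1) * 0.05), (m.n, 1))
        a = simulate_cell(m, MembraneModel(), 10.0, ve_mv=ve)
        b = simulate_cell(m, MembraneModel(), 10.0)
        assert np.allclose(a.vm, b.vm, atol=1e-9)

    def test_passive_input_resistance_matches_closed_forms(self):
        """Steady end dV = I * R_in. The exact oracle is the analytic fold of
        the equivalent resistor ladder; the continuum finite-cable formula
        r_a * lambda * coth(L/lambda) agrees to the discretization error."""
        from hippostim.cablenet.cable import ChannelDensities
        n, L, d = 50, 40.0, 1.0
        m = straight_axon(n, L, d)
        mem = MembraneModel(densities={AXON: ChannelDensities(0.0, 0.0, 3.0,
                                                              el=-65.0)})
        rec = simulate_cell(m, mem, 80.0, i_inj=(0, 0.01, 0.0, 80.0))
        dv = rec.vm[0, -1] - (-65.0)
        rm = 1.0 / 3.0  # Ohm m^2
        ra = mem.ra
        area = math.pi * d * 1e-6 * L * 1e-6
        r_shunt = rm / area
        r_ser = ra * L * 1e-6 / (math.pi * (d * 1e-6) ** 2 / 4)
        # fold the ladder from the sealed end back to the injection node
        r_eq = r_shunt
        for _ in range(n - 1):
            r_eq = 1.0 / (1.0 / r_shunt + 1.0 / (r_ser + r_eq))
        assert dv == pytest.approx(0.01e-9 * r_eq * 1e3, rel=0.01)
        lam = math.sqrt(rm * d * 1e-6 / (4 * ra))
        r_cont = (4 * ra / (math.pi * (d * 1e-6) ** 2)) * lam \
            / math.tanh(n * L * 1e-6 / lam)
        assert r_eq == pytest.approx(r_cont, rel=L * 1e-6 / (2 * lam) + 0.01)

    def test_passive_space_constant_within_3pct(self):
        """Voltage decay along a long passive cable follows exp(-x/lambda)."""
        n, L, d = 60, 40.0, 0.5
        m = straight_axon(n, L, d)
        from hippostim.cablenet.cable import ChannelDensities
        mem = MembraneModel(densities={AXON: ChannelDensities(0.0, 0.0, 3.0,
                                                              el=-65.0)})
        rec = simulate_cell(m, mem, 60.0, i_inj=(0, 0.01, 0.0, 60.0))
        prof = rec.vm[:, -1] - (-65.0)
        x = (np.arange(n) + 0.5) * L * 1e-6
        lam = math.sqrt((1.0 / 3.0) * d * 1e-6 / (4 * 2.0))
        sel = slice(4, 18)  # away from injection end and sealed end
        fit = np.polyfit(x[sel], np.log(prof[sel]), 1)
        assert -1.0 / fit[0] == pytest.approx(lam, rel=0.03)

    def test_charge_bookkeeping_total_membrane_current_is_zero(self):
        """A closed cell's transmembrane currents sum to zero each step."""
        m = generate_granule_morphology(np.random.default_rng(4))
        syn = SynapseOnCell(10, 1e-9, events_ms=np.array([3.0]))
        nt = int(12.0 / 0.025)
        ve = np.zeros((m.n, nt + 1))
        ve[:5] = 20.0  # non-uniform drive
        rec = simulate_cell(m, MembraneModel(), 12.0, ve_mv=ve, synapses=[syn],
                            record_currents=True)
        total = rec.i_mem_na.sum(axis=0)
        assert np.abs(total).max() <= 1e-6 * max(np.abs(rec.i_mem_na).max(), 1e-12) + 1e-9

    def test_field_driven_axon_spike_propagates_to_both_ends(self):
        anatomy = SyntheticAnatomyParams()
        ax = generate_pp_axon(anatomy, "lateral", np.random.default_rng(0))
        centers = ax.centers
        vi = ax.meta["varicosities"][len(ax.meta["varicosities"]) // 4]
        src = centers[vi] + np.array([0.0, 0.0, 30.0])
        r = np.linalg.norm(centers - src, axis=1) * 1e-6
        prof = 2.7 * (-60e-6) / (4 * np.pi * np.maximum(r, 1e-6)) * 1e3
        nt = int(25.0 / 0.025)
        ve = np.zeros((ax.n, nt + 1))
        ve[:, np.arange(nt + 1) * 0.025 < 1.0] = prof[:, None]
        rec = simulate_cell(ax, MembraneModel(), 25.0, ve_mv=ve, abort_mv=None)
        children = ax.children()
        tips = [i for i in range(ax.n) if not children[i]]
        assert len(tips) == 2
        for tip in tips:
            assert len(detect_spikes(rec.times_ms, rec.vm[tip])) >= 1

    def test_divergence_aborts_with_diagnostic(self):
        m = straight_axon(5)
        with pytest.raises(RuntimeError, match="diverged"):
            nt = int(2.0 / 0.025)
            ve = np.zeros((5, nt + 1))
            ve[0] = 1e4
            simulate_cell(m, MembraneModel(), 2.0, ve_mv=ve, abort_mv=200.0)


class TestThresholdProperties:
    def _threshold(self, polarity, dist_um, anatomy, ax):
        centers = ax.centers
        vi = ax.meta["varicosities"][len(ax.meta["varicosities"]) // 3]
        src = centers[vi] + np.array([0.0, 0.0, dist_um])
        r = np.linalg.norm(centers - src, axis=1) * 1e-6

        def fires(amp_ua):
            prof = 2.7 * (polarity * amp_ua * 1e-6) / (
                4 * np.pi * np.maximum(r, 1e-6)) * 1e3
            nt = int(6.0 / 0.025)
            ve = np.zeros((ax.n, nt + 1))
            ve[:, np.arange(nt + 1) * 0.025 < 1.0] = prof[:, None]
            rec = simulate_cell(ax, MembraneModel(), 6.0, ve_mv=ve,
                                abort_mv=None)
            return any(len(detect_spikes(rec.times_ms, rec.vm[c])) > 0
                       for c in range(0, ax.n, 5))

        lo, hi = 0.0, 2.0
        while not fires(hi):
            hi *= 2
            if hi > 5000:
                return np.inf
        for _ in range(9):
            mid = 0.5 * (lo + hi)
            lo, hi = (lo, mid) if fires(mid) else (mid, hi)
        return hi

    def test_cathodal_threshold_below_anodal(self, threshold_axon):
        anatomy, ax = threshold_axon
        th_cat = self._threshold(-1.0, 40.0, anatomy, ax)
        th_an = self._threshold(+1.0, 40.0, anatomy, ax)
        assert th_cat < th_an

    def test_threshold_monotone_in_distance(self, threshold_axon):
        anatomy, ax = threshold_axon
        ths = [self._threshold(-1.0, d, anatomy, ax)
               for d in (20.0, 40.0, 60.0, 90.0, 130.0)]
        assert all(a <= b + 1e-9 for a, b in zip(ths[:-1], ths[1:]))


class TestCalibration:
    def test_zero_target_gives_zero_conductance(self, reference_cell):
        g, peak = calibrate_epsp(reference_cell, MembraneModel(), 10, target_mv=0.0)
        assert g == 0.0 and peak == 0.0

    def test_passive_subthreshold_linearity(self, reference_cell):
        mem = MembraneModel().passive()
        g1, p1 = calibrate_epsp(reference_cell, mem, 10, target_mv=0.1)
        g2, p2 = calibrate_epsp(reference_cell, mem, 10, target_mv=0.2)
        assert g2 / g1 == pytest.approx(2.0, rel=0.05)

    def test_unreachable_target_raises(self, reference_cell):
        from hippostim.cablenet import CalibrationError
        with pytest.raises(CalibrationError):
            calibrate_epsp(reference_cell, MembraneModel().passive(), 10,
                           target_mv=500.0)


class TestNetworkConstruction:
    def test_zero_proximity_radius_gives_no_synapses(self, small_net_anatomy):
        params = NetworkParams(proximity_radius_um=0.0)
        with pytest.warns(UserWarning):
            net = build_network(small_net_anatomy, 3, 2, params, seed=0)
        assert net.synapses == []

    def test_synapses_form_with_positive_delay(self, small_net_anatomy):
        params = NetworkParams(proximity_radius_um=80.0,
                               target_totals={"lateral": 20, "medial": 20})
        net = build_network(small_net_anatomy, 4, 2, params, seed=0)
        assert len(net.synapses) > 0
        assert all(s.delay_ms > 0 for s in net.synapses)

    def test_target_totals_are_met_exactly(self, small_net_anatomy):
        params = NetworkParams(proximity_radius_um=80.0,
                               target_totals={"lateral": 35, "medial": 15})
        net = build_network(small_net_anatomy, 6, 4, params, seed=1)
        lateral = sum(net.axons[s.pre_cell].meta["pathway"] == "lateral"
                      for s in net.synapses)
        assert lateral == 35
        assert len(net.synapses) - lateral == 15

    def test_lamination_invariant_holds(self, small_net_anatomy):
        net = build_network(small_net_anatomy, 6, 4,
                            NetworkParams(proximity_radius_um=80.0), seed=2)
        assert net.check_lamination()

    def test_same_seed_reproduces_network(self, small_net_anatomy):
        p = NetworkParams(proximity_radius_um=80.0,
                          target_totals={"lateral": 10, "medial": 10})
        a = build_network(small_net_anatomy, 3, 2, p, seed=5)
        b = build_network(small_net_anatomy, 3, 2, p, seed=5)
        assert len(a.synapses) == len(b.synapses)
        for sa, sb in zip(a.synapses, b.synapses):
            assert (sa.pre_cell, sa.pre_comp, sa.post_cell, sa.post_comp) == \
                (sb.pre_cell, sb.pre_comp, sb.post_cell, sb.post_comp)
        assert np.allclose(a.gcs[0].morphology.dist, b.gcs[0].morphology.dist)


class TestSpikeDetection:
    def test_single_upward_crossing(self):
        t = np.arange(0, 10, 0.1)
        v = np.where(t > 5, 20.0, -70.0)
        sp = detect_spikes(t, v)
        assert len(sp) == 1
        assert 4.9 <= sp[0] <= 5.1

    def test_constant_subthreshold_trace_silent(self):
        t = np.arange(0, 10, 0.1)
        assert len(detect_spikes(t, np.full_like(t, -70.0))) == 0

    def test_refractory_lockout_merges_close_crossings(self):
        t = np.arange(0, 5, 0.05)
        v = np.full_like(t, -70.0)
        for tc in (1.0, 1.2):  # 0.2 ms apart
            v[(t >= tc) & (t < tc + 0.1)] = 10.0
        assert len(detect_spikes(t, v, lockout_ms=1.0)) == 1
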