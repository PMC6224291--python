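"""Branched-cable dynamics with extracellular coupling.

Membrane potential is intracellular minus extracellular, so a spatially
varying extracellular field enters the axial current terms as series
voltage sources: axial current between compartments i and its parent p is
g_axial * ((v_p + Ve_p) - (v_i + Ve_i)). A spatially uniform Ve therefore
has no effect, and the capacitive coupling term (Cm * dVe/dt charging the
membrane) emerges from the implicit update rather than being injected
literally.

Integration is backward Euler (Crank-Nicolson optional) on the voltages
with staggered gate updates (gates advanced analytically at frozen voltage,
NEURON-style), solved per step by a tree-ordered direct elimination over
the morphology (compartments are stored child-after-parent).

Internal unit system: mV, ms, uS, nF -> currents in nA. Densities at the
interface are SI (S/m^2, F/m^2, Ohm·m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import AXON, DEND, SOMA, Morphology

__all__ = [
    "ChannelDensities", "MembraneModel", "SynapseOnCell", "CableSolver",
    "CellRecording", "simulate_cell", "detect_spikes", "syn_conductance",
    "double_exp_peak_time", "calibrate_epsp", "CalibrationError",
]


@dataclass(frozen=True)
class ChannelDensities:
    """Fast Na / delayed-rectifier K / leak densities (S/m^2) and
    reversals (mV)."""

    gna: float = 0.0
    gk: float = 0.0
    gl: float = 0.333
    ena: float = 50.0
    ek: float = -77.0
    el: float = -65.0

    def __post_init__(self):
        if min(self.gna, self.gk, self.gl) < 0:
            raise ValueError("channel densities must be >= 0")


@dataclass(frozen=True)
class MembraneModel:
    """Membrane and axial parameters with per-region channel densities.

    Defaults: an active soma and axon (classic squid-type kinetics at
    granule-cell-plausible densities, resting near -65 mV) and passive
    dendrites with Rm = 3 Ohm·m^2.
    """

    cm: float = 0.01  # F/m^2 (1 uF/cm^2)
    ra: float = 2.0  # Ohm·m (200 Ohm·cm)
    densities: dict = field(default_factory=lambda: {
        SOMA: ChannelDensities(gna=1200.0, gk=360.0, gl=3.0, el=-54.3),
        AXON: ChannelDensities(gna=1200.0, gk=360.0, gl=3.0, el=-54.3),
        DEND: ChannelDensities(gna=0.0, gk=0.0, gl=0.333, el=-65.0),
    })
    v_init: float = -65.0  # mV

    def __post_init__(self):
        if self.cm <= 0 or self.ra <= 0:
            raise ValueError("cm and ra must be > 0")

    def passive(self) -> "MembraneModel":
        dens = {k: ChannelDensities(0.0, 0.0, d.gl if d.gl > 0 else 0.333,
                                    el=self.v_init)
                for k, d in self.densities.items()}
        return MembraneModel(self.cm, self.ra, dens, self.v_init)


def _safe_exp_ratio(x):
    """x / (1 - exp(-x)) with the removable singularity handled."""
    x = np.asarray(x, float)
    small = np.abs(x) < 1e-6
    return np.where(small, 1.0 + x / 2.0, x / (1.0 - np.exp(-np.where(small, 1.0, x))))


def _hh_rates(v):
    # alpha_m = 0.1 (v+40) / (1 - exp(-(v+40)/10)) etc.; the ratio helper
    # absorbs the numerator's linear factor
    am = _safe_exp_ratio((v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _safe_exp_ratio((v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def syn_conductance(t_ms, tau1: float = 1.05, tau2: float = 5.75,
                    gmax: float = 1.0):
    """Normalized difference-of-exponentials conductance.

    g(t) = gmax * N * (exp(-t/tau_decay) - exp(-t/tau_rise)), with N chosen
    so the peak equals gmax. Equal time constants fall back to the alpha
    function limit. t < 0 gives 0.
    """
    t = np.asarray(t_ms, float)
    tr, td = min(tau1, tau2), max(tau1, tau2)
    if math.isclose(tr, td, rel_tol=1e-9):
        g = gmax * (t / td) * np.exp(1.0 - t / td)
    else:
        tp = double_exp_peak_time(tau1, tau2)
        norm = 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))
        g = gmax * norm * (np.exp(-t / td) - np.exp(-t / tr))
    g = np.where(t >= 0, g, 0.0)
    return float(g) if g.ndim == 0 else g


def double_exp_peak_time(tau1: float, tau2: float) -> float:
    """Peak time of exp(-t/tau_decay) - exp(-t/tau_rise)."""
    tr, td = min(tau1, tau2), max(tau1, tau2)
    if math.isclose(tr, td, rel_tol=1e-9):
        return td
    return math.log(td / tr) * tr * td / (td - tr)


@dataclass
class SynapseOnCell:
    """A conductance synapse placed on one compartment of a cell."""

    comp: int
    gmax_s: float  # S (peak conductance)
    tau1: float = 1.05  # ms
    tau2: float = 5.75  # ms
    e_rev: float = 0.0  # mV
    events_ms: np.ndarray = field(default_factory=lambda: np.zeros(0))


class CableSolver:
    """Implicit integrator for one cell. Reusable across runs via reset()."""

    def __init__(self, morph: Morphology, membrane: MembraneModel):
        self.morph = morph
        self.mem = membrane
        n = morph.n
        L = morph.lengths * 1e-6
        d = morph.diam * 1e-6
        area = math.pi * d * L  # m^2, cylinder lateral surface
        self.area_m2 = area
        self.c_nf = membrane.cm * area * 1e9
        dens = [membrane.densities.get(int(r)) for r in morph.region]
        if any(x is None for x in dens):
            missing = {int(r) for r, x in zip(morph.region, dens) if x is None}
            raise KeyError(f"no channel densities for region codes {missing}")
        self.gna = np.array([x.gna for x in dens]) * area * 1e6  # uS
        self.gk = np.array([x.gk for x in dens]) * area * 1e6
        self.gl = np.array([x.gl for x in dens]) * area * 1e6
        self.ena = np.array([x.ena for x in dens])
        self.ek = np.array([x.ek for x in dens])
        self.el = np.array([x.el for x in dens])
        self.active = (self.gna > 0) | (self.gk > 0)

        # axial conductance to parent (uS); series of the two half-cylinders
        ax = np.zeros(n)
        xsec = math.pi * d * d / 4.0
        for i in range(1, n):
            p = morph.parent[i]
            r_half = membrane.ra * (L[i] / (2 * xsec[i]) + L[p] / (2 * xsec[p]))
            ax[i] = 1.0 / r_half * 1e6
        self.g_ax = ax
        self.parent = morph.parent
        self.reset()

    def reset(self, v0: float | None = None):
        v = self.mem.v_init if v0 is None else v0
        n = self.morph.n
        self.v = np.full(n, float(v))
        am, bm, ah, bh, an, bn = _hh_rates(self.v)
        self.m = am / (am + bm)
        self.h = ah / (ah + bh)
        self.n_gate = an / (an + bn)

    def step(self, dt: float, ve_next=None, syn_g=None, syn_ge=None,
             i_inj=None):
        """Advance one backward-Euler step of ``dt`` ms.

        ``ve_next`` is the extracellular potential (mV) per compartment at
        the end of the step; ``syn_g``/``syn_ge`` are summed synaptic
        conductance (uS) and conductance*reversal (uS*mV); ``i_inj`` is
        injected intracellular current (nA). Returns (v, i_membrane_nA).
        """
        n = self.morph.n
        v = self.v
        # gate update (analytic at frozen voltage)
        if self.active.any():
            am, bm, ah, bh, an, bn = _hh_rates(v)
            for gate, a, b in ((self.m, am, bm), (self.h, ah, bh),
                               (self.n_gate, an, bn)):
                tau = 1.0 / (a + b)
                inf = a * tau
                gate += (inf - gate) * (1.0 - np.exp(-dt / tau))
        gna = self.gna * self.m ** 3 * self.h
        gk = self.gk * self.n_gate ** 4
        g_ion = gna + gk + self.gl
        e_ion = gna * self.ena + gk * self.ek + self.gl * self.el

        diag = self.c_nf / dt + g_ion
        rhs = self.c_nf / dt * v + e_ion
        if syn_g is not None:
            diag = diag + syn_g
            rhs = rhs + syn_ge
        if i_inj is not None:
            rhs = rhs + i_inj
        off = -self.g_ax  # coupling of i to parent
        par = self.parent
        g_ax = self.g_ax
        # add axial diagonal terms and extracellular driving
        d2 = diag.copy()
        r2 = rhs.copy()
        for i in range(1, n):
            p = par[i]
            d2[i] += g_ax[i]
            d2[p] += g_ax[i]
            if ve_next is not None:
                drive = g_ax[i] * (ve_next[p] - ve_next[i])
                r2[i] += drive
                r2[p] -= drive
        # tree-ordered elimination (children have larger indices)
        for i in range(n - 1, 0, -1):
            p = par[i]
            f = off[i] / d2[i]
            d2[p] -= f * off[i]
            r2[p] -= f * r2[i]
        vn = np.empty(n)
        vn[0] = r2[0] / d2[0]
        for i in range(1, n):
            vn[i] = (r2[i] - off[i] * vn[par[i]]) / d2[i]

        i_mem = (self.c_nf * (vn - v) / dt + g_ion * vn - e_ion)
        if syn_g is not None:
            i_mem = i_mem + syn_g * vn - syn_ge
        self.v = vn
        return vn, i_mem


@dataclass
class CellRecording:
    """Per-cell traces from :func:`simulate_cell` (mV / nA / ms)."""

    times_ms: np.ndarray
    vm: np.ndarray  # (n_comp, n_t)
    i_mem_na: np.ndarray | None


def simulate_cell(morph: Morphology, membrane: MembraneModel,
                  duration_ms: float, dt_ms: float = 0.025,
                  ve_mv: np.ndarray | None = None,
                  synapses: list | None = None,
                  i_inj: tuple | None = None,
                  record_currents: bool = False,
                  abort_mv: float | None = 200.0) -> CellRecording:
    """Integrate one cell.

    ``ve_mv`` is (n_comp, n_t+1) extracellular potential samples at the
    step edges t = 0, dt, ..., duration (a (n_comp,) vector is treated as
    static). ``i_inj`` is (comp_index, amplitude_nA, t_on_ms, t_off_ms).
    Raises RuntimeError on numerical blow-up (|v| > abort_mv).
    """
    n_t = int(round(duration_ms / dt_ms))
    times = np.arange(n_t + 1) * dt_ms
    solver = CableSolver(morph, membrane)
    n = morph.n
    if ve_mv is not None:
        ve_mv = np.asarray(ve_mv, float)
        if ve_mv.ndim == 1:
            ve_mv = np.repeat(ve_mv[:, None], n_t + 1, axis=1)
        if ve_mv.shape != (n, n_t + 1):
            raise ValueError(f"ve must be (n_comp, n_steps+1) = ({n}, {n_t + 1})")
        if not np.all(np.isfinite(ve_mv)):
            raise ValueError("extracellular drive contains non-finite values")

    syn = synapses or []
    syn_state = []
    for s in syn:
        tr, td = min(s.tau1, s.tau2), max(s.tau1, s.tau2)
        alpha = math.isclose(tr, td, rel_tol=1e-9)
        if alpha:
            norm = 1.0
        else:
            tp = double_exp_peak_time(s.tau1, s.tau2)
            norm = 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))
        syn_state.append({
            "s": s, "A": 0.0, "B": 0.0, "q": 0.0, "alpha": alpha,
            "tr": tr, "td": td, "norm": norm,
            "events": np.sort(np.asarray(s.events_ms, float)), "next": 0,
            "g_uS": s.gmax_s * 1e6,
        })

    vm = np.empty((n, n_t + 1))
    vm[:, 0] = solver.v
    im = np.zeros((n, n_t + 1)) if record_currents else None

    for k in range(n_t):
        t_next = times[k + 1]
        syn_g = None
        syn_ge = None
        if syn_state:
            syn_g = np.zeros(n)
            syn_ge = np.zeros(n)
            for st in syn_state:
                # trigger events that fall inside this step
                ev = st["events"]
                while st["next"] < len(ev) and ev[st["next"]] <= t_next:
                    if st["alpha"]:
                        st["q"] += 1.0
                    else:
                        st["A"] += 1.0
                        st["B"] += 1.0
                    st["next"] += 1
                if st["alpha"]:
                    ea = math.exp(-dt_ms / st["td"])
                    st["A"] = ea * (st["A"] + (math.e / st["td"]) * dt_ms * st["q"])
                    st["q"] *= ea
                    g = st["g_uS"] * st["A"]
                else:
                    st["A"] *= math.exp(-dt_ms / st["tr"])
                    st["B"] *= math.exp(-dt_ms / st["td"])
                    g = st["g_uS"] * st["norm"] * (st["B"] - st["A"])
                c = st["s"].comp
                syn_g[c] += g
                syn_ge[c] += g * st["s"].e_rev
        inj = None
        if i_inj is not None:
            comp, amp, t_on, t_off = i_inj
            if t_on < t_next <= t_off + 1e-12:
                inj = np.zeros(n)
                inj[comp] = amp
        ve_col = None if ve_mv is None else ve_mv[:, k + 1]
        v, imem = solver.step(dt_ms, ve_next=ve_col, syn_g=syn_g,
                              syn_ge=syn_ge, i_inj=inj)
        vmax = np.abs(v).max()
        if not np.isfinite(vmax) or (abort_mv is not None and vmax > abort_mv):
            raise RuntimeError(
                f"membrane potential diverged (|v|={vmax:.3g} mV) at t={t_next} ms")
        vm[:, k + 1] = v
        if record_currents:
            im[:, k + 1] = imem
    return CellRecording(times, vm, im)


def detect_spikes(times_ms, v_mv, threshold_mv: float = 0.0,
                  lockout_ms: float = 1.0) -> np.ndarray:
    """Upward threshold-crossing times with linear interpolation and a
    refractory lockout."""
    t = np.asarray(times_ms, float)
    v = np.asarray(v_mv, float)
    idx = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))
    out = []
    last = -math.inf
    for i in idx:
        frac = (threshold_mv - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= lockout_ms:
            out.append(tc)
            last = tc
    return np.asarray(out)


class CalibrationError(RuntimeError):
    pass


def calibrate_epsp(morph: Morphology, membrane: MembraneModel, syn_comp: int,
                   target_mv: float = 0.22, tau1: float = 1.05,
                   tau2: float = 5.75, e_rev: float = 0.0,
                   dt_ms: float = 0.025, rtol: float = 2e-3):
    """Find the synaptic peak conductance giving a somatic EPSP of
    ``target_mv`` from rest.

    Returns ``(gmax_S, achieved_mv)``. The peak is measured against a
    synapse-free control run, so residual settling transients cancel.
    Raises :class:`CalibrationError` if the target is unreachable
    (saturation before the target amplitude).
    """
    if target_mv == 0:
        return 0.0, 0.0
    settle, window = 20.0, 35.0
    duration = settle + window

    base = simulate_cell(morph, membrane, duration, dt_ms).vm[0]

    def peak(g):
        s = SynapseOnCell(syn_comp, g, tau1, tau2, e_rev,
                          events_ms=np.array([settle]))
        rec = simulate_cell(morph, membrane, duration, dt_ms, synapses=[s])
        return float(np.max(rec.vm[0] - base))

    # bracket
    g = 1e-10
    p = peak(g)
    grow = 0
    while p < target_mv and grow < 40:
        g *= 2.0
        p = peak(g)
        grow += 1
    if p < target_mv:
        raise CalibrationError(f"target {target_mv} mV unreachable (max {p:.4g})")
    # secant refinement (sub-threshold response is nearly linear in gmax)
    g_lo, p_lo = g / 2.0 if grow else 0.0, None
    for _ in range(30):
        if abs(p - target_mv) <= rtol * target_mv:
            return g, p
        g_new = g * target_mv / p
        g_new = min(max(g_new, 0.25 * g), 4.0 * g)
        g, p = g_new, peak(g_new)
    raise CalibrationError("EPSP calibration did not converge")
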