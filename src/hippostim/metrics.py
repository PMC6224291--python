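"""Population-response metrics and field-comparison utilities.

The synaptically driven population spike (PS) is characterized by the peak
instantaneous proportion of granule cells active in 2 ms bins (PSmax), the
total proportion active, the maximum slope of the cumulative activity
curve, the half-height width (FWHM of a Gaussian fit to the binned time
course, with the empirical FWHM as fallback), and a power efficiency (GC
spikes per unit stimulus amplitude). Cases are ranked with a weighted-sums
multi-objective score over independently min-max-normalized metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PSMetrics", "ObjectiveWeights", "split_direct_synaptic", "ps_metrics",
    "multi_objective_u", "nrmse", "tau_rc", "charge_time",
    "spectrum_fraction", "gaussian_fwhm",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class PSMetrics:
    """Descriptors of one stimulation case's synaptic population response."""

    total_proportion: float
    ps_max: float  # peak instantaneous proportion (2 ms bins)
    max_cdf_slope: float  # proportion / ms
    hhw_ms: float  # half-height width; NaN when undefined
    hhw_defined: bool
    hhw_from_fit: bool
    efficiency: float  # GC spikes per uA
    n_spikes: int = 0

    def __post_init__(self):
        for p in (self.total_proportion, self.ps_max):
            if not (0.0 <= p <= 1.0 + 1e-12):
                raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class ObjectiveWeights:
    w1: float = 1.0  # PSmax
    w2: float = 1.0  # efficiency
    w3: float = 1.0  # short HHW

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3) < 0 or (self.w1 + self.w2 + self.w3) == 0:
            raise ValueError("weights must be >= 0 and not all zero")


def split_direct_synaptic(raster, stim_onset_ms: float, cutoff_ms: float = 3.0):
    """Partition GC spikes into direct (within ``cutoff_ms`` of the pulse)
    and synaptic (later) rasters. Axon spikes are excluded from both (they
    are reported separately by construction)."""
    if cutoff_ms <= 0:
        raise ValueError("cutoff must be > 0")
    from .cablenet.network import SpikeRaster

    gc = raster.events[raster.events.cell_type == "gc"]
    rel = gc.t_ms - stim_onset_ms
    direct = gc[rel <= cutoff_ms]
    synaptic = gc[rel > cutoff_ms]
    return (SpikeRaster(direct.reset_index(drop=True)),
            SpikeRaster(synaptic.reset_index(drop=True)))


def gaussian_fwhm(sigma: float) -> float:
    return FWHM_FACTOR * sigma


def _fit_hhw(centers, counts, bin_ms):
    """Gaussian least-squares FWHM; (value, from_fit). Falls back to the
    empirical half-maximum width of the binned curve (floored at one bin,
    the temporal resolution)."""
    total = counts.sum()
    mu0 = float((centers * counts).sum() / total)
    var0 = float(((centers - mu0) ** 2 * counts).sum() / total)
    sig0 = max(math.sqrt(max(var0, 1e-6)), 1e-3)

    def gauss(t, a, mu, sig):
        return a * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    try:
        if np.count_nonzero(counts) < 3:
            raise RuntimeError("too few occupied bins for a Gaussian fit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(gauss, centers, counts,
                                p0=[counts.max(), mu0, sig0], maxfev=5000)
        sig = abs(popt[2])
        if not np.isfinite(sig) or sig <= 0:
            raise RuntimeError("degenerate fit")
        return gaussian_fwhm(sig), True
    except Exception:
        half = counts.max() / 2.0
        idx = np.flatnonzero(counts >= half)
        width = centers[idx[-1]] - centers[idx[0]] if len(idx) else 0.0
        return float(max(width, bin_ms)), False


def ps_metrics(synaptic_raster, n_gc: int, amplitude_ua: float,
               bin_ms: float = 2.0, t_ref_ms: float = 0.0) -> PSMetrics:
    """Population-spike metrics from the synaptic-phase GC raster.

    PSmax counts unique GCs per bin (a proportion of cells); efficiency
    counts total spikes per uA. Bins are anchored at ``t_ref_ms`` so a
    rigidly time-shifted raster (with a matching reference) scores
    identically.
    """
    if n_gc < 1:
        raise ValueError("n_gc must be >= 1")
    ev = synaptic_raster.events
    n_spikes = len(ev)
    if n_spikes == 0:
        return PSMetrics(0.0, 0.0, 0.0, float("nan"), False, False, 0.0, 0)
    t = ev.t_ms.to_numpy() - t_ref_ms
    cells = ev.cell_id.to_numpy()
    t0 = math.floor(t.min() / bin_ms) * bin_ms
    edges = np.arange(t0, t.max() + bin_ms, bin_ms)
    if len(edges) < 2:
        edges = np.array([t0, t0 + bin_ms])
    which = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    uniq_per_bin = np.zeros(len(edges) - 1)
    count_per_bin = np.zeros(len(edges) - 1)
    for b in range(len(edges) - 1):
        m = which == b
        count_per_bin[b] = m.sum()
        uniq_per_bin[b] = len(np.unique(cells[m]))

    ps_max = uniq_per_bin.max() / n_gc
    total = len(np.unique(cells)) / n_gc
    cdf = np.cumsum(count_per_bin) / n_gc
    slope = float(np.max(np.diff(np.concatenate([[0.0], cdf]))) / bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    hhw, from_fit = _fit_hhw(centers, count_per_bin, bin_ms)
    eff = n_spikes / amplitude_ua if amplitude_ua > 0 else 0.0
    return PSMetrics(total, ps_max, slope, hhw, True, from_fit, eff, n_spikes)


def multi_objective_u(case_metrics, weights: ObjectiveWeights | None = None):
    """Weighted-sums score U per case over min-max-normalized PSmax,
    efficiency, and shortness of HHW (max(HHW) - HHW).

    U = (w1 n1 + w2 n2 + w3 n3) / (w1 + w2 + w3), in [0, 1]. A metric that
    is identical across cases contributes its full weight (normalized
    value 1) by convention.
    """
    if weights is None:
        weights = ObjectiveWeights()
    if len(case_metrics) < 2:
        raise ValueError("normalization needs at least 2 cases")
    psm = np.array([m.ps_max for m in case_metrics], float)
    eff = np.array([m.efficiency for m in case_metrics], float)
    hhw = np.array([m.hhw_ms for m in case_metrics], float)
    hhw = np.where(np.isfinite(hhw), hhw, np.nanmax(hhw) if np.any(np.isfinite(hhw)) else 0.0)
    short = np.max(hhw) - hhw

    def norm(x):
        rng = x.max() - x.min()
        if rng == 0:
            return np.ones_like(x)
        return (x - x.min()) / rng

    n1, n2, n3 = norm(psm), norm(eff), norm(short)
    w = weights
    u = (w.w1 * n1 + w.w2 * n2 + w.w3 * n3) / (w.w1 + w.w2 + w.w3)
    return u


def nrmse(field_a: np.ndarray, field_b: np.ndarray, box=None) -> float:
    """Root-mean-squared error of a vs b (the control), normalized by the
    control's range, over an optional box of index slices."""
    a = np.asarray(field_a, float)
    b = np.asarray(field_b, float)
    if a.shape != b.shape:
        raise ValueError("fields must share a grid")
    if box is not None:
        a = a[box]
        b = b[box]
    rng = b.max() - b.min()
    if rng == 0:
        raise ValueError("control field has zero range in the box")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)


def tau_rc(rho: float, eps: float) -> float:
    """RC time constant (s) of a tissue element: tau = rho * eps."""
    if rho <= 0 or eps <= 0:
        raise ValueError("rho and eps must be > 0")
    return rho * eps


def charge_time(fraction: float, tau: float) -> float:
    """Time (s) for an RC element to charge to ``fraction`` of its
    steady-state voltage: -tau * ln(1 - fraction)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return -tau * math.log1p(-fraction)


def spectrum_fraction(waveform, f_cut_hz: float, dt_s: float = 1e-5,
                      pad_factor: float = 4.0) -> float:
    """Fraction of the waveform's signal energy below ``f_cut_hz``.

    The waveform is sampled at ``dt_s`` over its active window plus
    padding and the cumulative squared-magnitude spectrum is evaluated at
    the cutoff.
    """
    if f_cut_hz <= 0:
        raise ValueError("f_cut must be > 0")
    dur_ms = waveform.end_ms * pad_factor + 1.0
    t = np.arange(0.0, dur_ms, dt_s * 1e3)
    x = waveform.current_ua(t)
    if not np.any(x):
        # degenerate zero waveform: treat as DC -> all energy below any cut
        return 1.0
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=dt_s)
    total = spec.sum()
    return float(spec[freqs <= f_cut_hz].sum() / total)
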