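"""Breathing-rate estimation from PPG respiratory modulations.

Respiration leaves three imprints on the PPG: baseline wander (RIIV,
respiratory-induced intensity variation), pulse-amplitude modulation
(RIAV) and pulse-interval modulation (RIFV, respiratory sinus
arrhythmia). Each is extracted per pulse, resampled to a uniform 4 Hz
grid, and analysed per window (32 or 64 s) with a Welch spectrum over the
respiratory band. Per-window single-modulation rates are then fused by a
quality-weighted Kalman smoother: the breathing rate is a scalar
random-walk state observed once per modulation, with measurement variance
inversely proportional to that modulation's spectral quality index (peak
band-power concentration). A forward filter plus Rauch–Tung–Striebel
backward pass yields the smoothed nightly trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import butter, filtfilt, welch

from .config import RespirationConfig
from .heart import PulseSeries

__all__ = [
    "ModulationSet",
    "WindowEstimate",
    "extract_modulations",
    "window_estimate",
    "estimate_windows",
    "kalman_fuse",
    "estimate_breathing_rate",
]

MODULATIONS = ("riiv", "riav", "rifv")


@dataclass
class ModulationSet:
    """The three respiration-modulated series on a shared uniform grid."""

    t: np.ndarray          # seconds, uniform grid_fs grid
    riiv: np.ndarray       # baseline wander, signal units
    riav: np.ndarray       # pulse amplitude, signal units
    rifv: np.ndarray       # inter-pulse interval, ms
    grid_fs: float

    def series(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class WindowEstimate:
    window_start_s: float
    window_len_s: float
    br_bpm: dict[str, float]       # per modulation, NaN when below floor
    quality: dict[str, float]
    fused_br_bpm: float = float("nan")


def _pulse_amplitudes(ppg: np.ndarray, peak_idx: np.ndarray) -> np.ndarray:
    """Peak-to-trough amplitude per pulse (trough before each peak)."""
    amps = np.empty(len(peak_idx))
    for k, p in enumerate(peak_idx):
        lo = peak_idx[k - 1] if k > 0 else max(0, p - 50)
        amps[k] = ppg[p] - ppg[lo:p + 1].min()
    return amps


def extract_modulations(ppg: np.ndarray, pulses: PulseSeries, fs: float = 100.0,
                        config: RespirationConfig | None = None) -> ModulationSet:
    """Extract RIIV/RIAV/RIFV and resample to the uniform analysis grid.

    RIAV is the per-pulse peak-to-trough amplitude; RIFV the inter-pulse
    interval series; RIIV the low-pass (<0.5 Hz) baseline sampled at pulse
    times. All three are cubic-interpolated onto the same 4 Hz grid.
    """
    cfg = config or RespirationConfig()
    if len(pulses) < 2:
        raise ValueError("need at least 2 pulses")
    x = np.asarray(ppg, dtype=float)
    peak_idx = np.round(pulses.pulse_times * fs).astype(int)
    peak_idx = np.clip(peak_idx, 0, len(x) - 1)

    b, a = butter(4, cfg.riiv_cutoff_hz / (fs / 2), btype="low")
    baseline = filtfilt(b, a, x)

    t_pulse = pulses.pulse_times
    riav_p = _pulse_amplitudes(x, peak_idx)
    riiv_p = baseline[peak_idx]
    t_ipi = t_pulse[1:]
    rifv_p = pulses.ipi

    t0, t1 = t_pulse[1], t_pulse[-1]
    n = int(np.floor((t1 - t0) * cfg.grid_fs)) + 1
    grid = t0 + np.arange(n) / cfg.grid_fs
    kind = "cubic" if len(t_pulse) >= 4 else "linear"

    def _interp(tp: np.ndarray, yp: np.ndarray) -> np.ndarray:
        f = interp1d(tp, yp, kind=kind, bounds_error=False,
                     fill_value=(yp[0], yp[-1]))
        return f(grid)

    return ModulationSet(
        t=grid,
        riiv=_interp(t_pulse, riiv_p),
        riav=_interp(t_pulse, riav_p),
        rifv=_interp(t_ipi, rifv_p),
        grid_fs=cfg.grid_fs,
    )


def _spectral_peak(x: np.ndarray, fs: float, band_hz: tuple[float, float]
                   ) -> tuple[float, float]:
    """Dominant in-band frequency (parabolic-refined) and its quality.

    Quality is the fraction of band power concentrated in the peak bin and
    its two neighbours — close to 1 for a clean tone, ~1/n_bins for noise.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0):
        return float("nan"), 0.0
    nperseg = min(len(x), max(32, len(x) // 2))
    f, p = welch(x, fs=fs, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    if sel.sum() < 3 or p[sel].sum() <= 0:
        return float("nan"), 0.0
    fb, pb = f[sel], p[sel]
    k = int(np.argmax(pb))
    total = pb.sum()
    lo, hi = max(0, k - 1), min(len(pb), k + 2)
    quality = float(pb[lo:hi].sum() / total)
    freq = fb[k]
    if 0 < k < len(pb) - 1:  # parabolic refinement of the peak bin
        y0, y1, y2 = np.log(pb[k - 1] + 1e-30), np.log(pb[k] + 1e-30), np.log(pb[k + 1] + 1e-30)
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            freq = fb[k] + 0.5 * (y0 - y2) / denom * (fb[1] - fb[0])
    return float(freq), quality


def window_estimate(mods: ModulationSet, window_start_s: float,
                    window_len_s: float,
                    config: RespirationConfig | None = None) -> WindowEstimate:
    """Per-modulation breathing rate and quality for one analysis window."""
    cfg = config or RespirationConfig()
    band_hz = (cfg.band_breaths_min[0] / 60.0, cfg.band_breaths_min[1] / 60.0)
    i0 = int(np.searchsorted(mods.t, window_start_s))
    i1 = int(np.searchsorted(mods.t, window_start_s + window_len_s))
    br: dict[str, float] = {}
    quality: dict[str, float] = {}
    for name in MODULATIONS:
        seg = mods.series(name)[i0:i1]
        if len(seg) < 8:
            br[name], quality[name] = float("nan"), 0.0
            continue
        freq, q = _spectral_peak(seg, mods.grid_fs, band_hz)
        br[name] = freq * 60.0 if np.isfinite(freq) else float("nan")
        quality[name] = q
    return WindowEstimate(window_start_s, window_len_s, br, quality)


def estimate_windows(mods: ModulationSet,
                     config: RespirationConfig | None = None
                     ) -> list[WindowEstimate]:
    """Slide the analysis window over the night and fuse the estimates."""
    cfg = config or RespirationConfig()
    wl = float(cfg.window_len_s)
    hop = cfg.hop_s if cfg.hop_s is not None else wl / 2
    t_end = mods.t[-1]
    starts = np.arange(mods.t[0], t_end - wl + 1e-9, hop)
    wins = [window_estimate(mods, s, wl, cfg) for s in starts]
    if not wins:
        return wins
    est = np.array([[w.br_bpm[m] for m in MODULATIONS] for w in wins])
    qual = np.array([[w.quality[m] for m in MODULATIONS] for w in wins])
    fused = kalman_fuse(est, qual, config=cfg)
    for w, f in zip(wins, fused):
        w.fused_br_bpm = float(f)
    return wins


def kalman_fuse(estimates: np.ndarray, qualities: np.ndarray,
                config: RespirationConfig | None = None) -> np.ndarray:
    """Fuse per-modulation rate series with a random-walk Kalman smoother.

    ``estimates``/``qualities`` are (n_windows, n_modulations). Steps where
    every quality is below the floor contribute no measurement (pure
    prediction). Measurement variance for a modulation is
    ``measurement_sd_bpm**2 / quality``.
    """
    cfg = config or RespirationConfig()
    z = np.atleast_2d(np.asarray(estimates, dtype=float))
    q = np.atleast_2d(np.asarray(qualities, dtype=float))
    n = z.shape[0]
    use = (q >= cfg.quality_floor) & np.isfinite(z)
    if not use.any():
        return np.array([])
    qvar = cfg.process_sd_bpm ** 2
    r0 = cfg.measurement_sd_bpm ** 2

    x = np.empty(n)
    p = np.empty(n)
    x_pred = np.empty(n)
    p_pred = np.empty(n)
    # initialize at the first usable step's inverse-variance combination so
    # a constant input is an exact fixed point of the smoother
    first = int(np.argmax(use.any(axis=1)))
    w0 = q[first][use[first]]
    xk = float(np.sum(w0 * z[first][use[first]]) / np.sum(w0))
    pk = 1e6
    for k in range(n):
        if k == 0:
            x_pred[k], p_pred[k] = xk, pk
        else:
            x_pred[k], p_pred[k] = xk, pk + qvar
        xk, pk = x_pred[k], p_pred[k]
        for j in np.flatnonzero(use[k]):
            r = r0 / max(q[k, j], 1e-9)
            gain = pk / (pk + r)
            xk = xk + gain * (z[k, j] - xk)
            pk = (1 - gain) * pk
        x[k], p[k] = xk, pk
    # RTS backward smoothing
    xs = x.copy()
    ps = p.copy()
    for k in range(n - 2, -1, -1):
        c = p[k] / p_pred[k + 1]
        xs[k] = x[k] + c * (xs[k + 1] - x_pred[k + 1])
        ps[k] = p[k] + c ** 2 * (ps[k + 1] - p_pred[k + 1])
    # steps before the first usable measurement carry no information
    xs[:first] = xs[first]
    return xs


def estimate_breathing_rate(ppg: np.ndarray, pulses: PulseSeries,
                            fs: float = 100.0,
                            config: RespirationConfig | None = None
                            ) -> list[WindowEstimate]:
    """Convenience wrapper: modulations → windows → fused estimates."""
    cfg = config or RespirationConfig()
    mods = extract_modulations(ppg, pulses, fs, cfg)
    return estimate_windows(mods, cfg)


def per_minute_br(windows: list[WindowEstimate], n_minutes: int) -> np.ndarray:
    """Average fused window estimates into per-minute breathing rates."""
    out = np.full(n_minutes, np.nan)
    sums = np.zeros(n_minutes)
    counts = np.zeros(n_minutes)
    for w in windows:
        if not np.isfinite(w.fused_br_bpm):
            continue
        m = int((w.window_start_s + w.window_len_s / 2) // 60)
        if 0 <= m < n_minutes:
            sums[m] += w.fused_br_bpm
            counts[m] += 1
    has = counts > 0
    out[has] = sums[has] / counts[has]
    # minutes not covered by any window centre inherit the nearest estimate
    if has.any() and not has.all():
        idx = np.arange(n_minutes)
        out[~has] = np.interp(idx[~has], idx[has], out[has])
    return out
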