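"""PPG pulse detection and per-minute heart-rate analytics.

The pulse series derived from the PPG is treated as a surrogate for the
ECG beat series: inter-pulse intervals (IPI, ms) stand in for inter-beat
intervals. Per one-minute window the module labels bradycardia (mean IPI
> 1200 ms, i.e. HR < 50 bpm), tachycardia (mean IPI < 500 ms, HR > 120
bpm), and flags possible atrial fibrillation / premature ventricular
contraction minutes with the ±50 ms rule around the minute's mean
interval: any interval exceeding the mean by more than 50 ms suggests AF,
any interval dropping more than 50 ms below it suggests a PVC; one
detection suffices to flag the minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import HeartConfig

__all__ = [
    "PulseSeries",
    "MinuteCardiacLabel",
    "zscore_normalize",
    "detect_pulses",
    "clean_ectopic",
    "label_brady_tachy",
    "detect_af_pvc",
    "minute_cardiac_labels",
]


@dataclass
class PulseSeries:
    """Pulse occurrence times (s) and inter-pulse intervals (ms)."""

    pulse_times: np.ndarray
    ipi: np.ndarray = field(init=False)
    quality_mask: np.ndarray | None = None   # True = interval kept as-is

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        self.ipi = np.diff(self.pulse_times) * 1000.0
        if self.quality_mask is None:
            self.quality_mask = np.ones(len(self.ipi), dtype=bool)

    def __len__(self) -> int:
        return len(self.pulse_times)


@dataclass
class MinuteCardiacLabel:
    minute_index: int
    mean_hr_bpm: float
    is_brady: bool | None
    is_tachy: bool | None
    is_af: bool | None
    is_pvc: bool | None


def zscore_normalize(ppg: np.ndarray) -> np.ndarray:
    """Remove the mean and scale to unit (sample) standard deviation."""
    x = np.asarray(ppg, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("constant signal has no z-score")
    return (x - np.mean(x)) / sd


def detect_pulses(ppg: np.ndarray, fs: float = 100.0,
                  config: HeartConfig | None = None) -> PulseSeries:
    """Detect systolic peaks on a z-scored PPG.

    Peaks need a minimum topographic prominence and are separated by a
    refractory period so the dicrotic notch (a secondary bump within the
    same pulse) is not double-counted.
    """
    cfg = config or HeartConfig()
    x = np.asarray(ppg, dtype=float)
    peaks, _ = find_peaks(
        x,
        prominence=cfg.min_prominence,
        distance=max(1, int(round(cfg.refractory_s * fs))),
    )
    return PulseSeries(pulse_times=peaks / fs)


def clean_ectopic(ipi: np.ndarray, deviation: float = 0.3,
                  kernel: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Mask ectopic intervals against a centered running median.

    Intervals deviating more than ``deviation`` (fraction) from the running
    median of ``kernel`` neighbours are masked and replaced by linear
    interpolation — for rate averaging only; rhythm rules use the raw
    series. Returns ``(cleaned, mask)`` with ``mask`` True for masked beats.
    """
    x = np.asarray(ipi, dtype=float)
    if len(x) < 3:
        return x.copy(), np.zeros(len(x), dtype=bool)
    med = (
        pd.Series(x).rolling(kernel, center=True, min_periods=1).median().to_numpy()
    )
    mask = np.abs(x - med) > deviation * med
    cleaned = x.copy()
    if mask.any() and not mask.all():
        idx = np.arange(len(x))
        cleaned[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return cleaned, mask


def label_brady_tachy(minute_ipi: np.ndarray, config: HeartConfig | None = None
                      ) -> tuple[bool, bool]:
    """Brady/tachy flags for one minute of (cleaned) intervals.

    Under the default ``episode_rule='mean'`` the minute's average IPI is
    compared with the 1200/500 ms thresholds; ``'any'`` flags on any single
    interval crossing.
    """
    cfg = config or HeartConfig()
    x = np.asarray(minute_ipi, dtype=float)
    if len(x) == 0:
        raise ValueError("empty minute")
    if cfg.episode_rule == "mean":
        m = float(np.mean(x))
        return m > cfg.brady_ibi_ms, m < cfg.tachy_ibi_ms
    return bool(np.any(x > cfg.brady_ibi_ms)), bool(np.any(x < cfg.tachy_ibi_ms))


def detect_af_pvc(minute_ipi: np.ndarray, config: HeartConfig | None = None
                  ) -> tuple[bool, bool]:
    """AF / PVC flags from the minute's raw intervals (±50 ms rule).

    The average threshold is the mean interval of the minute. A possible AF
    is an interval more than ``af_pvc_delta_ms`` above it; a possible PVC is
    one more than that below it (strict inequalities; boundary equality is
    no detection). ``deviation_rule='consecutive'`` applies the same margins
    to successive-interval differences instead.
    """
    cfg = config or HeartConfig()
    x = np.asarray(minute_ipi, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 intervals")
    if cfg.deviation_rule == "consecutive":
        d = np.diff(x)
        return bool(np.any(d > cfg.af_pvc_delta_ms)), bool(np.any(d < -cfg.af_pvc_delta_ms))
    m = float(np.mean(x))
    is_af = bool(np.any(x > m + cfg.af_pvc_delta_ms))
    is_pvc = bool(np.any(x < m - cfg.af_pvc_delta_ms))
    return is_af, is_pvc


def minute_cardiac_labels(pulses: PulseSeries, n_minutes: int,
                          config: HeartConfig | None = None
                          ) -> list[MinuteCardiacLabel]:
    """Per-minute cardiac labels for a whole night.

    An interval belongs to the minute of its starting pulse. Minutes with
    fewer than 2 pulses are unanalyzable (null flags, NaN rate); the AF/PVC
    rule additionally needs 4 intervals.
    """
    cfg = config or HeartConfig()
    cleaned, mask = clean_ectopic(pulses.ipi, cfg.ectopic_deviation,
                                  cfg.ectopic_kernel)
    pulses.quality_mask = ~mask
    start_minute = np.floor(pulses.pulse_times[:-1] / 60.0).astype(int) \
        if len(pulses) > 1 else np.array([], dtype=int)
    labels: list[MinuteCardiacLabel] = []
    for m in range(n_minutes):
        sel = start_minute == m
        raw = pulses.ipi[sel]
        if len(raw) < 1:
            labels.append(MinuteCardiacLabel(m, float("nan"), None, None, None, None))
            continue
        mean_ipi = float(np.mean(cleaned[sel]))
        hr = 60000.0 / mean_ipi
        brady, tachy = label_brady_tachy(cleaned[sel], cfg)
        if len(raw) >= 4:
            af, pvc = detect_af_pvc(raw, cfg)
        else:
            af = pvc = None
        labels.append(MinuteCardiacLabel(m, hr, brady, tachy, af, pvc))
    return labels
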