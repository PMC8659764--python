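"""Sleep staging from accelerometer movement counts.

Every 20 ms the device compares consecutive 3-axis accelerometer samples
through the movement derivative

    D_i = (|x_i - x_{i-1}| + |y_i - y_{i-1}| + |z_i - z_{i-1}|) / delta

(absolute differences: a movement magnitude cannot be negative). A
movement is a rising-edge crossing of D above a hardware-dependent
threshold; crossings are tallied per minute into N_j. When the night
ends, the whole-night mean m_N and standard deviation sigma_N of the
minute counts fix the stage rule:

    N_j > m_N + 3 sigma_N  -> AW (awake)
    N_j > m_N + sigma_N    -> LS (light sleep)
    otherwise              -> DS (deep sleep)

Strict inequalities; with sigma_N = 0 every minute is deep sleep. The
rule is scale-free: multiplying all counts by a positive constant moves
the thresholds with them.
"""

from __future__ import annotations

import numpy as np

from .config import StagesConfig

__all__ = [
    "movement_derivative",
    "movement_derivatives",
    "movement_counts",
    "classify_stages",
    "stage_durations",
    "count_wake_ups",
]

STAGE_LABELS = ("AW", "LS", "DS")


def movement_derivative(prev: tuple[float, float, float],
                        cur: tuple[float, float, float],
                        delta_s: float = 0.02) -> float:
    """Movement derivative between two consecutive accelerometer samples."""
    if delta_s <= 0:
        raise ValueError("delta must be positive")
    return (abs(cur[0] - prev[0]) + abs(cur[1] - prev[1])
            + abs(cur[2] - prev[2])) / delta_s


def movement_derivatives(accel: np.ndarray, delta_s: float = 0.02) -> np.ndarray:
    """Vectorized movement derivative for an (n, 3) accelerometer array."""
    a = np.asarray(accel, dtype=float)
    return np.sum(np.abs(np.diff(a, axis=0)), axis=1) / delta_s


def movement_counts(accel: np.ndarray, fs: float = 50.0,
                    config: StagesConfig | None = None) -> np.ndarray:
    """Per-minute movement counts N_j from raw 3-axis accelerometry.

    A movement is a rising edge of the derivative crossing the threshold
    (samples-above-threshold within one crossing count once).
    """
    cfg = config or StagesConfig()
    d = movement_derivatives(accel, cfg.delta_s)
    above = d > cfg.movement_threshold
    rising = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    if above.size and above[0]:
        rising = np.concatenate([[0], rising])
    per_min = int(fs * 60)
    n_minutes = int(np.ceil(len(accel) / per_min))
    counts = np.zeros(n_minutes, dtype=np.int64)
    minute_of = (rising + 1) // per_min      # derivative k sits at sample k+1
    for m in minute_of:
        if m < n_minutes:
            counts[m] += 1
    return counts


def classify_stages(counts: np.ndarray,
                    config: StagesConfig | None = None) -> np.ndarray:
    """Assign AW/LS/DS per minute from whole-night count statistics."""
    cfg = config or StagesConfig()
    n = np.asarray(counts, dtype=float)
    if len(n) < 2:
        raise ValueError("need at least 2 minutes")
    m = float(np.mean(n))
    s = float(np.std(n, ddof=cfg.sd_ddof))
    labels = np.full(len(n), "DS", dtype=object)
    labels[n > m + s] = "LS"
    labels[n > m + 3 * s] = "AW"
    return labels.astype(str)


def stage_durations(labels: np.ndarray) -> dict[str, int]:
    """Minutes spent per stage; values sum to the night length."""
    labels = np.asarray(labels)
    return {s: int(np.sum(labels == s)) for s in STAGE_LABELS}


def count_wake_ups(labels: np.ndarray) -> int:
    """Number of maximal awake runs during the night."""
    awake = np.asarray(labels) == "AW"
    if not awake.any():
        return 0
    edges = np.diff(awake.astype(int))
    return int(np.sum(edges == 1)) + int(awake[0])
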