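"""Seeded generator of synthetic overnight recordings with ground truth.

The generator emulates every statistical structure the analysis stack
assumes, without claiming physiological waveform fidelity:

* a pulsatile PPG at 100 Hz built from a template pulse (systolic peak
  plus a dicrotic notch at 40% amplitude) placed at interval-driven times,
  carrying the three respiratory modulations — amplitude (RIAV), interval
  (RIFV) and baseline wander (RIIV) — at the scenario's breathing rate;
* DAP events that scale the pulse amplitude by (1 - depth); central
  events additionally suspend the respiratory interval modulation (no
  breathing effort), obstructive events append a 20 s sympathetic-surge
  surrogate (intervals shortened 15%) after the event, which is the
  recoverable contrast the subtype classifier keys on;
* an SpO2 channel at 97% baseline with desaturations lagged 5-12 s after
  apneic events (apneas ~5 points deep, hypopneas ~3);
* arrhythmic minutes: bradycardic (1300 ms intervals), tachycardic
  (450 ms), AF-like (random interval jumps) and PVC-like (premature beat
  plus compensatory pause);
* 50 Hz 3-axis accelerometry: Gaussian sensor noise plus square movement
  bursts in minutes designated awake or light sleep.

All channels are integer-quantized to the 18-bit device range; the pulse
amplitude and template are sized so that successive PPG deltas of a clean
night fit in signed 8 bits, matching the device's delta coder. A fixed
seed makes the recording byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import stages as stages_mod
from .codec import PPG_FS, PPG_MAX, SampleStream
from .config import StagesConfig

__all__ = ["EventSpec", "NightScenario", "GroundTruth", "generate_night"]

ACCEL_FS = 50.0

_DEFAULT_DEPTH = {"CA": 0.6, "OA": 0.6, "CH": 0.35, "OH": 0.35,
                  "control_dap": 0.5}
_DEFAULT_DESAT = {"CA": 5.0, "OA": 5.0, "CH": 3.0, "OH": 3.0,
                  "control_dap": 0.0}


@dataclass
class EventSpec:
    """One respiratory event: CA/CH/OA/OH or an uncoupled control DAP."""

    type: str
    onset_s: float
    duration_s: float = 15.0
    depth: float | None = None
    desat_drop: float | None = None

    def __post_init__(self) -> None:
        if self.type not in _DEFAULT_DEPTH:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.depth is None:
            self.depth = _DEFAULT_DEPTH[self.type]
        if self.desat_drop is None:
            self.desat_drop = _DEFAULT_DESAT[self.type]

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def is_central(self) -> bool:
        return self.type in ("CA", "CH")

    @property
    def is_obstructive(self) -> bool:
        return self.type in ("OA", "OH")


@dataclass
class NightScenario:
    """Declarative description of one synthetic night.

    ``hr_profile``/``br_profile`` are piecewise-constant segments as
    ``(start_minute, value)`` pairs. Arrhythmia minutes override the HR
    profile for their whole minute. ``movement_profile`` maps minute
    indices to movement-burst counts (awake ~ tens, light sleep ~ a few).
    """

    duration_h: float = 8.0
    hr_profile: list[tuple[float, float]] = field(default_factory=lambda: [(0, 60.0)])
    br_profile: list[tuple[float, float]] = field(default_factory=lambda: [(0, 15.0)])
    events: list[EventSpec] = field(default_factory=list)
    brady_minutes: list[int] = field(default_factory=list)
    tachy_minutes: list[int] = field(default_factory=list)
    af_minutes: list[int] = field(default_factory=list)
    pvc_minutes: list[int] = field(default_factory=list)
    movement_profile: dict[int, int] = field(default_factory=dict)
    # signal scaling / noise (device counts)
    ppg_baseline: float = 6000.0
    pulse_amp: float = 500.0
    am_depth: float = 0.2
    fm_depth: float = 0.04
    bw_amp: float = 50.0
    ppg_noise_sd: float = 2.0
    accel_noise_sd: float = 0.01
    spo2_baseline: float = 97.0
    surge_dur_s: float = 20.0
    surge_shortening: float = 0.15

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(ev, ev[1:]):
            if b.onset_s < a.end_s:
                raise ValueError(
                    f"overlapping events at {a.onset_s} s and {b.onset_s} s")
        total = self.duration_h * 3600
        for e in ev:
            if e.onset_s < 0 or e.end_s > total:
                raise ValueError(f"event at {e.onset_s} s outside recording")
        self.events = ev

    @property
    def n_minutes(self) -> int:
        return int(round(self.duration_h * 60))


@dataclass
class GroundTruth:
    """Per-minute and per-event truth serialized alongside the recording."""

    minute_hr: list[float]
    minute_br: list[float]
    minute_brady: list[bool]
    minute_tachy: list[bool]
    minute_af: list[bool]
    minute_pvc: list[bool]
    minute_apnea: list[bool]
    minute_stage: list[str]
    events: list[dict]
    movement_counts: list[int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _piecewise(profile: list[tuple[float, float]], minute: float) -> float:
    val = profile[0][1]
    for start, v in profile:
        if minute >= start:
            val = v
    return val


def _pulse_template() -> np.ndarray:
    """Systolic peak + 40% dicrotic notch, unit peak amplitude, 0.6 s."""
    t = np.arange(0, 0.6, 1.0 / PPG_FS)
    wave = (np.exp(-0.5 * ((t - 0.15) / 0.045) ** 2)
            + 0.4 * np.exp(-0.5 * ((t - 0.40) / 0.06) ** 2))
    return wave / wave.max()


def generate_night(scenario: NightScenario, seed: int = 0
                   ) -> tuple[SampleStream, GroundTruth]:
    """Synthesize one night and its ground-truth ledger (deterministic)."""
    rng = np.random.default_rng(seed)
    sc = scenario
    total_s = sc.duration_h * 3600.0
    n_ppg = int(round(total_s * PPG_FS))
    n_min = sc.n_minutes

    # breathing-rate phase, continuous across profile segments
    t_grid = np.arange(n_ppg) / PPG_FS
    f_br_grid = np.array([_piecewise(sc.br_profile, m) / 60.0
                          for m in range(n_min)])
    f_of_t = f_br_grid[np.minimum((t_grid // 60).astype(int), n_min - 1)]
    phase_grid = 2 * np.pi * np.cumsum(f_of_t) / PPG_FS

    def br_phase(t: float) -> float:
        k = min(int(t * PPG_FS), n_ppg - 1)
        return phase_grid[k]

    central_spans = [(e.onset_s, e.end_s) for e in sc.events if e.is_central]
    surge_spans = [(e.end_s, e.end_s + sc.surge_dur_s)
                   for e in sc.events if e.is_obstructive]
    dap_spans = [(e.onset_s, e.end_s, e.depth) for e in sc.events]

    def _in(spans, t: float) -> bool:
        return any(a <= t < b for a, b in spans)

    # --- beat times -------------------------------------------------------
    pulse_t: list[float] = []
    pulse_amp: list[float] = []
    t = float(rng.uniform(0.1, 0.6))
    pvc_next_long = False
    while t < total_s - 0.7:
        m = min(int(t // 60), n_min - 1)
        if m in sc.brady_minutes:
            base = 1.3
        elif m in sc.tachy_minutes:
            base = 0.45
        else:
            base = 60.0 / _piecewise(sc.hr_profile, m)
        ipi = base
        if pvc_next_long:
            ipi = 1.35 * base
            pvc_next_long = False
        elif m in sc.pvc_minutes and rng.random() < 0.15:
            ipi = 0.65 * base
            pvc_next_long = True
        elif m in sc.af_minutes and rng.random() < 0.25:
            ipi = base + 0.25
        if not _in(central_spans, t):
            ipi *= 1.0 + sc.fm_depth * np.sin(br_phase(t))
        if _in(surge_spans, t):
            ipi *= 1.0 - sc.surge_shortening
        amp = sc.pulse_amp * (1.0 + sc.am_depth * np.sin(br_phase(t)))
        for a, b, depth in dap_spans:
            if a <= t < b:
                amp *= 1.0 - depth
                break
        pulse_t.append(t)
        pulse_amp.append(amp)
        t += ipi
    pulse_t_arr = np.array(pulse_t)
    pulse_amp_arr = np.array(pulse_amp)

    # --- PPG waveform -----------------------------------------------------
    template = _pulse_template()
    ppg = sc.ppg_baseline + sc.bw_amp * np.sin(phase_grid)
    ppg += rng.normal(0.0, sc.ppg_noise_sd, n_ppg)
    start_idx = np.round((pulse_t_arr - 0.15) * PPG_FS).astype(int)
    lt = len(template)
    for s, a in zip(start_idx, pulse_amp_arr):
        lo = max(s, 0)
        hi = min(s + lt, n_ppg)
        if hi > lo:
            ppg[lo:hi] += a * template[lo - s : hi - s]
    ppg = np.clip(np.rint(ppg), 0, PPG_MAX).astype(np.int64)

    # --- SpO2 -------------------------------------------------------------
    n_spo2 = int(total_s)
    spo2 = np.full(n_spo2, sc.spo2_baseline)
    spo2 += rng.choice([-1, 0, 0, 0, 1], size=n_spo2) * 0.0  # reserved hook
    desat_truth = []
    for e in sc.events:
        if not e.desat_drop or e.type == "control_dap":
            continue
        lag = float(rng.uniform(5.0, 12.0))
        start = int(e.onset_s + lag)
        drop = float(e.desat_drop)
        prof = np.concatenate([
            np.linspace(0, drop, 5)[1:],        # 4 s descent
            np.full(6, drop),                   # 6 s nadir hold
            np.linspace(drop, 0, 9)[1:-1],      # 7 s recovery
        ])
        hi = min(start + len(prof), n_spo2)
        if hi > start >= 0:
            spo2[start:hi] -= prof[: hi - start]
            desat_truth.append({"event_onset_s": e.onset_s,
                                "desat_start_s": float(start), "drop": drop})
    spo2 = np.clip(np.rint(spo2), 0, 100).astype(np.int64)

    # --- accelerometer / movements ---------------------------------------
    n_acc = int(total_s * ACCEL_FS)
    accel = rng.normal(0.0, sc.accel_noise_sd, (n_acc, 3))
    per_min = int(ACCEL_FS * 60)
    for m, n_bursts in sc.movement_profile.items():
        if not 0 <= m < n_min or n_bursts <= 0:
            continue
        offs = rng.choice(per_min - 30, size=n_bursts, replace=False)
        for o in np.sort(offs):
            s = m * per_min + int(o)
            accel[s : s + 10, 0] += 0.5       # one up + one down edge
    counts = stages_mod.movement_counts(accel, ACCEL_FS, StagesConfig())
    counts = counts[:n_min] if len(counts) >= n_min else np.pad(
        counts, (0, n_min - len(counts)))

    stream = SampleStream(ppg=ppg, spo2=spo2, movements=counts)

    # --- ground truth -----------------------------------------------------
    minute_hr = []
    start_minute = np.floor(pulse_t_arr[:-1] / 60.0).astype(int)
    ipis = np.diff(pulse_t_arr) * 1000.0
    for m in range(n_min):
        sel = start_minute == m
        minute_hr.append(float(60000.0 / np.mean(ipis[sel])) if sel.any()
                         else float("nan"))
    minute_apnea = [False] * n_min
    for e in sc.events:
        if e.type == "control_dap":
            continue
        for m in range(int(e.onset_s // 60), min(int(e.end_s // 60) + 1, n_min)):
            minute_apnea[m] = True
    stage = []
    for m in range(n_min):
        nb = sc.movement_profile.get(m, 0)
        stage.append("AW" if nb >= 20 else ("LS" if nb > 0 else "DS"))
    truth = GroundTruth(
        minute_hr=minute_hr,
        minute_br=[_piecewise(sc.br_profile, m) for m in range(n_min)],
        minute_brady=[m in sc.brady_minutes for m in range(n_min)],
        minute_tachy=[m in sc.tachy_minutes for m in range(n_min)],
        minute_af=[m in sc.af_minutes for m in range(n_min)],
        minute_pvc=[m in sc.pvc_minutes for m in range(n_min)],
        minute_apnea=minute_apnea,
        minute_stage=stage,
        events=[{**asdict(e), "desaturations": [d for d in desat_truth
                                                if d["event_onset_s"] == e.onset_s]}
                for e in sc.events],
        movement_counts=[int(c) for c in counts],
    )
    return stream, truth
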