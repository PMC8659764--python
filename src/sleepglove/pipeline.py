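"""Overnight analysis pipeline.

Orchestrates decode → heart → respiration → sleep-disordered breathing →
stages over one recording and writes the two report tables (the
``SleepEvents`` per-minute table and the single-row ``NightSleepSummary``)
plus an events table and a JSON report, as flat CSV/JSON files. Minutes
falling inside decode gaps (corrupt blocks, garbage-coded artifacts) are
nulled; summary counters are computed over valid minutes only and every
counter is re-derivable from the minute table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, heart, respiration, sdb, stages
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["NightResult", "run_night"]

SLEEP_EVENTS_FIELDS = [
    "UserId", "EventStartDate", "HeartRate", "BreathingRate",
    "OxygenSaturation", "IsApnea", "ApneaType",
    "IsPrematureVentricularContraction", "IsAtrialFibrillation",
    "IsBradycardia", "IsTachycardia",
]
SUMMARY_FIELDS = [
    "UserId", "UpNEAId", "EventStartDate", "EventEndDate",
    "LightSleepDuration", "DeepSleepDuration", "SleepDuration",
    "WakeUpsCounter", "ApneaCounter", "MeanHeartRate", "MeanBreathingRate",
    "MeanOxygenSaturation", "PrematureVentricularContractionCounter",
    "AtrialFibrillationCounter", "BradycardiaCounter", "TachycardiaCounter",
]


@dataclass
class NightResult:
    sleep_events: pd.DataFrame
    night_summary: pd.DataFrame
    events: pd.DataFrame
    report: dict


def _load(input_path: str | Path) -> codec.SampleStream:
    path = Path(input_path)
    if path.suffix == ".bin":
        return codec.decode_file(codec.read_bin(path))
    return codec.stream_from_csv(path)


def run_night(input_path: str | Path | codec.SampleStream,
              config: RunConfig | None = None,
              out_dir: str | Path | None = None,
              user_id: str = "user-0",
              start_date: str = "1970-01-01T00:00:00") -> NightResult:
    """Run all six analyses on one night and write the report tables.

    ``input_path`` may be a .bin recording, an unpacked CSV, or an
    in-memory :class:`~sleepglove.codec.SampleStream`. Outputs (when
    ``out_dir`` is given): ``sleep_events.csv``, ``night_summary.csv``,
    ``events.csv`` and ``report.json``. The run is deterministic, so
    re-running on the same input reproduces the files byte for byte.
    """
    cfg = config or RunConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    stream = input_path if isinstance(input_path, codec.SampleStream) \
        else _load(input_path)
    timings["decode"] = time.perf_counter() - t0

    n_minutes = int(len(stream.ppg) // (codec.PPG_FS * 60))
    if n_minutes < 10:
        raise ValueError("recording shorter than 10 minutes of valid signal")

    # minutes touched by decode gaps or garbage segments are nulled
    bad_minute = np.zeros(n_minutes, dtype=bool)
    for a, b in stream.gaps:
        m0 = int(a // (codec.PPG_FS * 60))
        m1 = int((b - 1) // (codec.PPG_FS * 60))
        bad_minute[m0 : min(m1 + 1, n_minutes)] = True

    # --- heart ------------------------------------------------------------
    t0 = time.perf_counter()
    ppg = stream.ppg.astype(float)
    if (~stream.ppg_valid).any():
        idx = np.arange(len(ppg))
        ppg[~stream.ppg_valid] = np.interp(
            idx[~stream.ppg_valid], idx[stream.ppg_valid],
            ppg[stream.ppg_valid])
    z = heart.zscore_normalize(ppg)
    pulses = heart.detect_pulses(z, codec.PPG_FS, cfg.heart)
    cardiac = heart.minute_cardiac_labels(pulses, n_minutes, cfg.heart)
    timings["heart"] = time.perf_counter() - t0

    # --- respiration --------------------------------------------------------
    t0 = time.perf_counter()
    windows = respiration.estimate_breathing_rate(z, pulses, codec.PPG_FS,
                                                  cfg.respiration)
    br_minute = respiration.per_minute_br(windows, n_minutes)
    timings["respiration"] = time.perf_counter() - t0

    # --- sleep-disordered breathing ----------------------------------------
    t0 = time.perf_counter()
    env = sdb.amplitude_envelope(z, pulses, codec.PPG_FS, cfg.sdb)
    daps = sdb.detect_dap(env, cfg.sdb)
    desats = sdb.detect_desaturation(stream.spo2, 1.0, stream.spo2_valid,
                                     cfg.sdb)
    daps = sdb.couple_dap_desat(daps, desats, cfg.sdb)
    apnea_minute, ahi = sdb.minute_labels(daps, n_minutes)
    timings["sdb"] = time.perf_counter() - t0

    # --- stages -------------------------------------------------------------
    t0 = time.perf_counter()
    counts = stream.movements[:n_minutes]
    stage_labels = stages.classify_stages(counts, cfg.stages)
    durations = stages.stage_durations(stage_labels)
    wake_ups = stages.count_wake_ups(stage_labels)
    timings["stages"] = time.perf_counter() - t0

    # --- per-minute SpO2 ----------------------------------------------------
    spo2_minute = np.full(n_minutes, np.nan)
    for m in range(n_minutes):
        seg = stream.spo2[m * 60 : (m + 1) * 60]
        ok = (seg > codec.SPO2_OFFSET) & stream.spo2_valid[m * 60 : (m + 1) * 60]
        if ok.any():
            spo2_minute[m] = float(np.mean(seg[ok]))

    # --- assemble tables ----------------------------------------------------
    rows = []
    for m in range(n_minutes):
        lab = cardiac[m]
        null = bad_minute[m]
        apneic = bool(apnea_minute[m]) if not null else None
        subtype = None
        if apneic:
            for d in daps:
                if d.label == "apneic_hypopneic" and \
                        int(d.onset_s // 60) <= m <= int(d.end_s // 60):
                    subtype = d.subtype or "unclassified"
                    break
        rows.append({
            "UserId": user_id,
            "EventStartDate": f"{start_date}+{m}min",
            "HeartRate": None if null else _nan_none(lab.mean_hr_bpm),
            "BreathingRate": None if null else _nan_none(br_minute[m]),
            "OxygenSaturation": None if null else _nan_none(spo2_minute[m]),
            "IsApnea": apneic,
            "ApneaType": subtype,
            "IsPrematureVentricularContraction": None if null else lab.is_pvc,
            "IsAtrialFibrillation": None if null else lab.is_af,
            "IsBradycardia": None if null else lab.is_brady,
            "IsTachycardia": None if null else lab.is_tachy,
        })
    sleep_events = pd.DataFrame(rows, columns=SLEEP_EVENTS_FIELDS)

    n_apnea_events = sum(1 for d in daps if d.label == "apneic_hypopneic")
    summary = pd.DataFrame([{
        "UserId": user_id,
        "UpNEAId": cfg.codec.device_id,
        "EventStartDate": start_date,
        "EventEndDate": f"{start_date}+{n_minutes}min",
        "LightSleepDuration": durations["LS"],
        "DeepSleepDuration": durations["DS"],
        "SleepDuration": n_minutes,
        "WakeUpsCounter": wake_ups,
        "ApneaCounter": n_apnea_events,
        "MeanHeartRate": _nan_none(pd.to_numeric(
            sleep_events["HeartRate"], errors="coerce").mean()),
        "MeanBreathingRate": _nan_none(pd.to_numeric(
            sleep_events["BreathingRate"], errors="coerce").mean()),
        "MeanOxygenSaturation": _nan_none(pd.to_numeric(
            sleep_events["OxygenSaturation"], errors="coerce").mean()),
        "PrematureVentricularContractionCounter": int(
            (sleep_events["IsPrematureVentricularContraction"] == True).sum()),
        "AtrialFibrillationCounter": int(
            (sleep_events["IsAtrialFibrillation"] == True).sum()),
        "BradycardiaCounter": int((sleep_events["IsBradycardia"] == True).sum()),
        "TachycardiaCounter": int((sleep_events["IsTachycardia"] == True).sum()),
    }], columns=SUMMARY_FIELDS)

    events = pd.DataFrame([{
        "onset_s": d.onset_s, "duration_s": d.duration_s, "depth": d.depth,
        "coupled_desat": d.coupled_desat, "label": d.label,
        "subtype": d.subtype,
    } for d in daps])

    report = {
        "n_minutes": n_minutes,
        "n_dap_events": len(daps),
        "n_apneic_events": n_apnea_events,
        "apnea_minutes": int((sleep_events["IsApnea"] == True).sum()),
        "ahi": ahi,
        "n_desaturations": len(desats),
        "n_gap_minutes": int(bad_minute.sum()),
        "stage_durations": durations,
    }
    logger.info("per-stage timings: %s",
                {k: round(v, 3) for k, v in timings.items()})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sleep_events.to_csv(out / "sleep_events.csv", index=False)
        summary.to_csv(out / "night_summary.csv", index=False)
        events.to_csv(out / "events.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            for k, v in timings.items():
                fh.write(f"{k}: {v:.3f} s\n")
    return NightResult(sleep_events, summary, events, report)


def _nan_none(x: float) -> float | None:
    return None if x is None or not np.isfinite(x) else round(float(x), 2)
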