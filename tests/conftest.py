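"""Shared synthetic-recording fixtures (session-scoped: nights are reused)."""

from __future__ import annotations

import numpy as np
import pytest

from sleepglove import heart, sdb, synth


@pytest.fixture(scope="session")
def clean_night():
    """Half an hour of clean signal: HR 60 bpm, BR 15 breaths/min."""
    sc = synth.NightScenario(duration_h=0.5, hr_profile=[(0, 60.0)],
                             br_profile=[(0, 15.0)])
    return synth.generate_night(sc, seed=1)


@pytest.fixture(scope="session")
def clean_pulses(clean_night):
    stream, _ = clean_night
    z = heart.zscore_normalize(stream.ppg.astype(float))
    return z, heart.detect_pulses(z, 100.0)


@pytest.fixture(scope="session")
def arrhythmia_night():
    """Two hours with 15 bradycardic, 15 tachycardic, 5 AF, 5 PVC minutes."""
    rng = np.random.default_rng(5)
    mins = rng.permutation(120)
    sc = synth.NightScenario(
        duration_h=2.0,
        hr_profile=[(0, 60.0)],
        brady_minutes=sorted(int(m) for m in mins[:15]),
        tachy_minutes=sorted(int(m) for m in mins[15:30]),
        af_minutes=sorted(int(m) for m in mins[30:35]),
        pvc_minutes=sorted(int(m) for m in mins[35:40]),
    )
    return synth.generate_night(sc, seed=5)


@pytest.fixture(scope="session")
def event_night():
    """Three hours with alternating obstructive/central apneas every 130 s."""
    events = []
    t, k = 120.0, 0
    while t < 3 * 3600 - 200:
        events.append(synth.EventSpec(type="OA" if k % 2 == 0 else "CA",
                                      onset_s=t, duration_s=15.0))
        t += 130.0
        k += 1
    sc = synth.NightScenario(duration_h=3.0, hr_profile=[(0, 72.0)],
                             events=events)
    stream, truth = synth.generate_night(sc, seed=3)
    return stream, truth, events


@pytest.fixture(scope="session")
def event_night_analysis(event_night):
    """Detection + coupling + per-event features for the event night."""
    stream, truth, events = event_night
    z = heart.zscore_normalize(stream.ppg.astype(float))
    pulses = heart.detect_pulses(z, 100.0)
    env = sdb.amplitude_envelope(z, pulses)
    daps = sdb.detect_dap(env)
    desats = sdb.detect_desaturation(stream.spo2)
    daps = sdb.couple_dap_desat(daps, desats)
    X, y = [], []
    for d in daps:
        for e in events:
            if abs(d.onset_s - e.onset_s) < 10.0:
                vec = sdb.extract_features(z, stream.spo2, pulses, env, d)
                if vec is not None:
                    X.append(vec)
                    y.append(e.type)
                break
    return {
        "z": z, "pulses": pulses, "env": env, "daps": daps,
        "desats": desats, "X": np.array(X), "y": np.array(y),
        "events": events, "stream": stream, "truth": truth,
    }
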