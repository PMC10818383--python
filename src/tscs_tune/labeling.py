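"""EMG ground-truth labeling from double-pulse response amplitudes.

The averaged double-pulse EMG of each event is reduced to three numbers:
A1 and A2, the peak-to-peak amplitudes of the responses to the first and
second pulse, and the suppression

    S = (1 - A2/A1) * 100  [%].

Strong suppression of the second response marks a reflex (afferent,
posterior-root mediated) response; weak suppression marks a direct muscular
response. Classes:

    3-class:  0 no response (A1 < 50 μV)
              1 reflex response (A1 > 50 μV and S > 60 %)
              2 muscle response (A1 > 50 μV and S < 60 %)
    2-class:  0 no response, 1 any response (3-class 1 or 2 merged)

Boundary values (A1 = 50 μV, S = 60 %) fall to the lower class (0 and 2
respectively); A1 = 0 gives class 0 with S reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AveragedEvent, CROP_PRE_MS, EMG_RATE

A1_THRESHOLD_UV = 50.0
S_THRESHOLD_PCT = 60.0

#: default measurement windows (ms after pulse 1); the second window is the
#: first shifted by the 50 ms inter-pulse interval. Both end before the
#: next pulse / end of crop.
WIN1_MS = (5.0, 45.0)
WIN2_MS = (55.0, 95.0)


@dataclass(frozen=True)
class ResponseMetrics:
    a1: float  # μV peak-to-peak, pulse 1
    a2: float  # μV peak-to-peak, pulse 2
    s: float  # % suppression
    a1_zero: bool = False  # A1 was zero; S undefined, reported as 0


def _window_slice(n: int, rate: float, t0_ms: float,
                  win_ms: tuple[float, float]) -> slice:
    i0 = int(round((win_ms[0] - t0_ms) * rate / 1000.0))
    i1 = int(round((win_ms[1] - t0_ms) * rate / 1000.0))
    if i0 < 0 or i1 > n or i1 <= i0:
        raise ValueError(f"window {win_ms} outside cropped signal")
    return slice(i0, i1)


def response_metrics(emg_double_avg: np.ndarray,
                     rate: float = EMG_RATE, t0_ms: float = -CROP_PRE_MS,
                     win1_ms: tuple[float, float] = WIN1_MS,
                     win2_ms: tuple[float, float] = WIN2_MS
                     ) -> ResponseMetrics:
    """Measure A1, A2 and S on an averaged double-pulse EMG."""
    x = np.asarray(emg_double_avg, dtype=float)
    s1 = x[_window_slice(x.size, rate, t0_ms, win1_ms)]
    s2 = x[_window_slice(x.size, rate, t0_ms, win2_ms)]
    a1 = float(np.ptp(s1))
    a2 = float(np.ptp(s2))
    if a1 > 0:
        s = (1.0 - a2 / a1) * 100.0
        return ResponseMetrics(a1=a1, a2=a2, s=s)
    return ResponseMetrics(a1=a1, a2=a2, s=0.0, a1_zero=True)


def classify_event(metrics: ResponseMetrics, scheme: int = 3) -> int:
    """Assign the response class from A1 and S."""
    if scheme not in (2, 3):
        raise ValueError("scheme must be 2 or 3")
    if metrics.a1 <= A1_THRESHOLD_UV:
        return 0
    if scheme == 2:
        return 1
    return 1 if metrics.s > S_THRESHOLD_PCT else 2


def label_events(events: list[AveragedEvent],
                 win1_ms: tuple[float, float] = WIN1_MS,
                 win2_ms: tuple[float, float] = WIN2_MS) -> pd.DataFrame:
    """Label a list of averaged events under both class schemes.

    Returns one row per event (valid or not) with keys, A1/A2/S and both
    labels; invalid events carry NaN metrics and label -1.
    """
    rows = []
    for ev in events:
        if ev.valid and ev.emg_double_avg is not None:
            m = response_metrics(ev.emg_double_avg, win1_ms=win1_ms,
                                 win2_ms=win2_ms)
            rows.append({
                "subject_id": ev.subject_id, "group": ev.group,
                "position": ev.position, "day": ev.day,
                "current_ma": ev.current, "muscle": ev.muscle,
                "a1_uv": m.a1, "a2_uv": m.a2, "s_pct": m.s,
                "label_2": classify_event(m, 2),
                "label_3": classify_event(m, 3),
                "valid": True,
            })
        else:
            rows.append({
                "subject_id": ev.subject_id, "group": ev.group,
                "position": ev.position, "day": ev.day,
                "current_ma": ev.current, "muscle": ev.muscle,
                "a1_uv": np.nan, "a2_uv": np.nan, "s_pct": np.nan,
                "label_2": -1, "label_3": -1, "valid": False,
            })
    return pd.DataFrame(rows)


def label_session(events: list[AveragedEvent], scheme: int = 3,
                  **window_kw) -> pd.DataFrame:
    """Class grid over (position, current, muscle) for one session's events.

    Invalid events are carried with label -1 and ``valid == False`` so that
    they never enter downstream class counts.
    """
    df = label_events(events, **window_kw)
    col = f"label_{scheme}"
    grid = df[["subject_id", "position", "day", "current_ma", "muscle",
               col, "valid"]].rename(columns={col: "label"})
    return grid
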