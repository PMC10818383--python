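"""Raw-sweep preprocessing: artifact detection, cropping, filtering,
similarity-checked averaging, and the double-minus-single DIFF signal.

Each stimulation event is cut to a common window from 10 ms before to
400 ms after the first pulse (half-open, i.e. 410 samples at 1 kHz and 205
at 0.5 kHz). EMG sweeps get a zero-phase 50 Hz notch and a 31-sample
running-median subtraction (a high-pass without ringing); acceleration
sweeps get the mean of their first 10 ms subtracted as a static gravity
filter. The three repetitions per pulse type are averaged after a
connectivity check on their pairwise coefficients of determination; events
whose repetitions never agree are marked faulty rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .cohort import (ACC_RATE, EMG_RATE, MUSCLES, PULSE_DOUBLE, PULSE_SINGLE,
                     SessionRecording, SubjectMeta)

CROP_PRE_MS = 10.0
CROP_POST_MS = 400.0
#: samples in the [-10, 400) ms crop at the two rates
N_EMG_CROP = int((CROP_PRE_MS + CROP_POST_MS) * EMG_RATE / 1000.0)  # 410
N_ACC_CROP = int((CROP_PRE_MS + CROP_POST_MS) * ACC_RATE / 1000.0)  # 205


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing stage.

    The artifact detector thresholds the double-differenced EMG at
    ``k_mad`` scaled median absolute deviations; detections closer than
    ``refractory_ms`` are merged. ``r2_threshold`` is the minimum pairwise
    R² for two repetitions to count as connected. ``noisy_rms_uv`` bounds
    the pre-stimulus baseline RMS of the averaged EMG.
    """

    k_mad: float = 8.0
    refractory_ms: float = 10.0
    r2_threshold: float = 0.8
    notch_freq: float = 50.0
    notch_q: float = 30.0
    median_kernel: int = 31
    noisy_rms_uv: float = 20.0
    #: RMS (m/s^2) below which two acceleration sweeps count as similar
    #: (no detectable response in either, so averaging them is safe)
    acc_low_rms: float = 0.05


@dataclass
class CroppedSweep:
    """One repetition (or average) on the common [-10, 400) ms window."""

    samples: np.ndarray
    rate: float
    t0_ms: float = -CROP_PRE_MS
    modality: str = "EMG"
    muscle_id: str | None = None
    pulse_type: str | None = None
    repetition_index: int | None = None


@dataclass
class AveragedEvent:
    """Averaged, validated signals of one (muscle, current) event."""

    subject_id: str
    group: str
    position: float
    day: int
    current: float
    muscle: str
    meta: SubjectMeta | None = None
    emg_double_avg: np.ndarray | None = None
    acc_single_avg: np.ndarray | None = None
    acc_double_avg: np.ndarray | None = None
    acc_diff: np.ndarray | None = None
    valid: bool = True
    invalid_reason: str = "none"  # none | similarity_fail | noisy_emg

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.position, self.day,
                self.current, self.muscle)


# ---------------------------------------------------------------------------
# artifact detection
# ---------------------------------------------------------------------------

def detect_stimulation_artifacts(emg_sweep: np.ndarray,
                                 rate: float = EMG_RATE,
                                 dd_threshold: float | None = None,
                                 k_mad: float = 8.0,
                                 refractory_ms: float = 10.0) -> np.ndarray:
    """Locate stimulation artifacts in an EMG sweep.

    An artifact is marked where the double derivative of the signal exceeds
    a threshold — by default an adaptive ``k_mad`` multiple of the scaled
    median absolute deviation of the double-differenced sweep. Detections
    within ``refractory_ms`` of a previous one are suppressed. Returns
    artifact onset times in seconds from sweep start (possibly empty).
    """
    x = np.asarray(emg_sweep, dtype=float)
    if x.size < 3:
        return np.array([])
    dd = np.abs(np.diff(x, 2))
    if dd_threshold is None:
        mad = np.median(np.abs(dd - np.median(dd)))
        dd_threshold = k_mad * 1.4826 * mad
        if dd_threshold <= 0:  # noise-free baseline: fall back to a fraction
            dd_threshold = 0.1 * dd.max()
    if dd_threshold <= 0:
        return np.array([])
    cand = np.flatnonzero(dd > dd_threshold)
    refractory = int(round(refractory_ms * rate / 1000.0))
    onsets = []
    last = -np.inf
    for i in cand:
        if i - last >= refractory:
            onsets.append(i + 2)  # d²x[i] spans x[i..i+2]; jump lands at i+2
        last = i
    return np.asarray(onsets, dtype=float) / rate


# ---------------------------------------------------------------------------
# cropping and filtering
# ---------------------------------------------------------------------------

def running_median_highpass(x: np.ndarray, kernel: int = 31) -> np.ndarray:
    """Subtract a sliding median (reflect-padded) — ringing-free high-pass."""
    med = ndimage.median_filter(np.asarray(x, dtype=float), size=kernel,
                                mode="reflect")
    return x - med


def crop_and_filter_emg(emg_sweep: np.ndarray, artifact_time_s: float,
                        rate: float = EMG_RATE,
                        config: PreprocessConfig | None = None,
                        **sweep_kw) -> CroppedSweep:
    """Crop an EMG sweep around an artifact and filter it.

    Crops to [-10, 400) ms relative to the artifact, applies a zero-phase
    second-order IIR notch at 50 Hz (anti-hum) and subtracts a 31-sample
    running median (high-pass without ringing).
    """
    config = config or PreprocessConfig()
    x = np.asarray(emg_sweep, dtype=float)
    i_art = int(round(artifact_time_s * rate))
    i0 = i_art - int(round(CROP_PRE_MS * rate / 1000.0))
    i1 = i_art + int(round(CROP_POST_MS * rate / 1000.0))
    if i0 < 0 or i1 > x.size:
        raise ValueError("crop window exceeds sweep bounds")
    seg = x[i0:i1]
    b, a = signal.iirnotch(config.notch_freq, config.notch_q, fs=rate)
    seg = signal.filtfilt(b, a, seg)
    seg = running_median_highpass(seg, config.median_kernel)
    return CroppedSweep(samples=seg, rate=rate, modality="EMG", **sweep_kw)


def preprocess_acc(acc_sweep: np.ndarray, emg_artifact_time_s: float,
                   rate: float = ACC_RATE, **sweep_kw) -> CroppedSweep:
    """Crop an acceleration sweep to the EMG artifact's [-10, 400) ms window
    and subtract the mean of the first 10 ms (static gravity filter).

    The acceleration channel carries no stimulation artifact of its own, so
    the EMG artifact timestamp provides the common time origin.
    """
    x = np.asarray(acc_sweep, dtype=float)
    i_art = int(round(emg_artifact_time_s * rate))
    n_pre = int(round(CROP_PRE_MS * rate / 1000.0))
    i0 = i_art - n_pre
    i1 = i_art + int(round(CROP_POST_MS * rate / 1000.0))
    if i0 < 0 or i1 > x.size:
        raise ValueError("crop window exceeds sweep bounds")
    seg = x[i0:i1].copy()
    seg -= seg[:n_pre].mean()
    return CroppedSweep(samples=seg, rate=rate, modality="ACC", **sweep_kw)


# ---------------------------------------------------------------------------
# similarity-checked averaging
# ---------------------------------------------------------------------------

def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; degenerate (constant) sweeps count as
    similar only when they are numerically identical."""
    if a.std() == 0.0 or b.std() == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def similarity_average(repetitions: list[np.ndarray],
                       r2_threshold: float = 0.8,
                       low_amplitude_rms: float | None = None
                       ) -> tuple[np.ndarray | None, list[int]]:
    """Average mutually similar repetitions via a connectivity matrix.

    Builds the pairwise R² matrix, links repetitions with R² at or above the
    threshold, and averages the largest connected group. A group of fewer
    than two repetitions means no two sweeps agree: the event is faulty and
    ``(None, [])`` is returned.

    ``low_amplitude_rms`` (used for the artifact-free acceleration channel)
    marks a pair as similar when both sweeps stay below that RMS: two
    no-response sweeps contain only sensor noise, whose mutual correlation
    is near zero although there is no disagreement to flag.
    """
    reps = [np.asarray(r, dtype=float) for r in repetitions]
    if len(reps) < 2:
        raise ValueError("need at least two repetitions")
    n = len(reps)
    if any(r.shape != reps[0].shape for r in reps):
        raise ValueError("repetition length mismatch")
    rms = [float(np.sqrt(np.mean(r**2))) for r in reps]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            link = _pairwise_r2(reps[i], reps[j]) >= r2_threshold
            if not link and low_amplitude_rms is not None:
                link = max(rms[i], rms[j]) < low_amplitude_rms
            adj[i, j] = adj[j, i] = link
    # connected components of the similarity graph
    seen: set[int] = set()
    best: list[int] = []
    for start in range(n):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(np.flatnonzero(adj[v]))
        if len(comp) > len(best):
            best = sorted(comp)
    if len(best) < 2:
        return None, []
    kept = [reps[i] for i in best]
    if all(np.array_equal(k, kept[0]) for k in kept[1:]):
        return kept[0].copy(), best  # exact for identical repetitions
    return np.mean(kept, axis=0), best


def compute_diff(acc_double_avg: np.ndarray,
                 acc_single_avg: np.ndarray) -> np.ndarray:
    """Sample-wise double-minus-single acceleration: the response to the
    second pulse of a double stimulus despite overlapping twitches."""
    d = np.asarray(acc_double_avg, dtype=float)
    s = np.asarray(acc_single_avg, dtype=float)
    if d.shape != s.shape:
        raise ValueError("double and single averages differ in shape")
    return d - s


# ---------------------------------------------------------------------------
# whole-session preprocessing
# ---------------------------------------------------------------------------

def _crop_event_window(channel: np.ndarray, t_event_s: float, rate: float,
                       pre_s: float = 0.05, post_s: float = 0.45
                       ) -> tuple[np.ndarray, float]:
    """Raw search window around a logged event; returns (window, t0_s)."""
    i0 = max(0, int(round((t_event_s - pre_s) * rate)))
    i1 = min(channel.size, int(round((t_event_s + post_s) * rate)))
    return channel[i0:i1], i0 / rate


def preprocess_session(session: SessionRecording,
                       config: PreprocessConfig | None = None
                       ) -> tuple[list[AveragedEvent], dict]:
    """Run the full preprocessing chain on one session.

    Produces one :class:`AveragedEvent` per (muscle, current): the averaged
    double-pulse EMG, averaged single- and double-pulse accelerations and
    their DIFF. Repetitions whose stimulation artifact cannot be found are
    dropped; events whose remaining repetitions never agree are flagged
    ``similarity_fail``, and averaged EMG with excessive pre-stimulus
    baseline RMS is flagged ``noisy_emg``. The exclusion report counts both.
    """
    config = config or PreprocessConfig()
    events_out: list[AveragedEvent] = []
    reasons = {"similarity_fail": 0, "noisy_emg": 0}
    currents = session.protocol.currents()
    log = session.events
    for ch, muscle in enumerate(MUSCLES):
        for current in currents:
            ev = AveragedEvent(
                subject_id=session.meta.subject_id, group=session.meta.group,
                position=session.position, day=session.day,
                current=float(current), muscle=muscle, meta=session.meta,
            )
            emg_crops: dict[str, list[np.ndarray]] = {PULSE_DOUBLE: [],
                                                      PULSE_SINGLE: []}
            acc_crops: dict[str, list[np.ndarray]] = {PULSE_DOUBLE: [],
                                                      PULSE_SINGLE: []}
            sel = log[np.isclose(log.current_ma, current)]
            for _, row in sel.iterrows():
                win, t0 = _crop_event_window(session.emg[ch], row.time_s,
                                             EMG_RATE)
                arts = detect_stimulation_artifacts(
                    win, EMG_RATE, k_mad=config.k_mad,
                    refractory_ms=config.refractory_ms)
                if arts.size == 0:
                    continue  # faulty repetition (artifact detection failed)
                t_art = t0 + arts[0]
                try:
                    crop = crop_and_filter_emg(
                        session.emg[ch], t_art, EMG_RATE, config,
                        muscle_id=muscle, pulse_type=row.pulse_type)
                    acc = preprocess_acc(
                        session.acc_z[ch], t_art, ACC_RATE,
                        muscle_id=muscle, pulse_type=row.pulse_type)
                except ValueError:
                    continue
                emg_crops[row.pulse_type].append(crop.samples)
                acc_crops[row.pulse_type].append(acc.samples)

            ok = True
            if len(emg_crops[PULSE_DOUBLE]) >= 2:
                ev.emg_double_avg, _ = similarity_average(
                    emg_crops[PULSE_DOUBLE], config.r2_threshold)
                ok &= ev.emg_double_avg is not None
            else:
                ok = False
            for ptype, attr in ((PULSE_DOUBLE, "acc_double_avg"),
                                (PULSE_SINGLE, "acc_single_avg")):
                if ok and len(acc_crops[ptype]) >= 2:
                    avg, _ = similarity_average(acc_crops[ptype],
                                                config.r2_threshold,
                                                config.acc_low_rms)
                    setattr(ev, attr, avg)
                    ok &= avg is not None
                else:
                    ok = False
            if not ok:
                ev.valid = False
                ev.invalid_reason = "similarity_fail"
                reasons["similarity_fail"] += 1
            else:
                n_pre = int(round(CROP_PRE_MS * EMG_RATE / 1000.0))
                baseline_rms = float(
                    np.sqrt(np.mean(ev.emg_double_avg[:n_pre] ** 2)))
                if baseline_rms > config.noisy_rms_uv:
                    ev.valid = False
                    ev.invalid_reason = "noisy_emg"
                    reasons["noisy_emg"] += 1
                else:
                    ev.acc_diff = compute_diff(ev.acc_double_avg,
                                               ev.acc_single_avg)
            events_out.append(ev)

    n_total = len(events_out)
    n_excluded = sum(reasons.values())
    report = {
        "n_events": n_total,
        "n_excluded": n_excluded,
        "fraction_excluded": n_excluded / n_total if n_total else 0.0,
        "reasons": reasons,
    }
    return events_out, report


def preprocess_cohort(sessions: list[SessionRecording],
                      config: PreprocessConfig | None = None
                      ) -> tuple[list[AveragedEvent], dict]:
    """Preprocess a list of sessions and pool events and exclusion counts."""
    all_events: list[AveragedEvent] = []
    reasons = {"similarity_fail": 0, "noisy_emg": 0}
    for session in sessions:
        events, report = preprocess_session(session, config)
        all_events.extend(events)
        for k in reasons:
            reasons[k] += report["reasons"][k]
    n_total = len(all_events)
    n_excluded = sum(reasons.values())
    return all_events, {
        "n_events": n_total,
        "n_excluded": n_excluded,
        "fraction_excluded": n_excluded / n_total if n_total else 0.0,
        "reasons": reasons,
    }
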