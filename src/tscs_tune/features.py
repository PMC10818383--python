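"""MMG feature extraction: 36 features per event in three categories.

Per event (one muscle at one position and current) the averaged single- and
double-pulse accelerations and their DIFF are summarized by time- and
frequency-domain features:

* meta (4): BMI, sex, age, height;
* stim (2): electrode position (cm from L3/L4) and current (mA);
* MMG data (30): windowed amplitude statistics, peak-to-peak amplitudes and
  maximum slopes, the discrete Fréchet distance between double and single
  responses, correlation between single and double responses, mean power
  frequency / area under / maximum of the power spectral density, zero
  crossing rates, plus the peak-to-peak amplitudes of the *other* muscle of
  the same leg (a crosstalk probe).

Amplitude windows: 10–60 ms after the first pulse (winA1) for the thigh
muscles and 15–65 ms for the calf muscles whose response onset is later;
winDIFF uses the same offsets after the second pulse. Spectral and
zero-crossing features use the full cropped signal; the power spectral
density is a Hann-windowed periodogram and the mean power frequency is
sum(f*P)/sum(P).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .preprocess import ACC_RATE, AveragedEvent, CROP_PRE_MS

#: winA1 in ms after pulse 1, per muscle group
WIN_A1_MS = {"Q": (10.0, 60.0), "TS": (15.0, 65.0)}
INTER_PULSE_MS = 50.0

META_FEATURES = ["f01_bmi", "f02_sex", "f03_age", "f04_height"]
STIM_FEATURES = ["f05_position", "f06_current"]
MMG_FEATURES = [
    "f07_sensor",
    "f08_mmg_single_mean", "f09_mmg_single_median", "f10_mmg_single_std",
    "f11_mmg_single_rms",
    "f12_mmg_diff_mean", "f13_mmg_diff_median", "f14_mmg_diff_std",
    "f15_mmg_diff_rms",
    "f16_frechet_mmg",
    "f17_p2p_mmg_single", "f18_p2p_mmg_diff",
    "f19_r2_mmg_single_double", "f20_r_mmg_single_double",
    "f21_mpf_double", "f22_mpf_single", "f23_mpf_diff",
    "f24_auc_psd_single", "f25_auc_psd_double", "f26_auc_psd_diff",
    "f27_max_psd_single", "f28_max_psd_double", "f29_max_psd_diff",
    "f30_zcr_single", "f31_zcr_double", "f32_zcr_diff",
    "f33_max_slope_diff", "f34_max_slope_single",
    "f35_p2p_mmg_single_2nd", "f36_p2p_mmg_diff_2nd",
]
FEATURE_NAMES = META_FEATURES + STIM_FEATURES + MMG_FEATURES
KEY_COLUMNS = ["subject_id", "group", "position", "day", "current_ma",
               "muscle"]
LABEL_COLUMNS = ["label_2", "label_3"]

FEATURE_SETS = {
    # observation approach: sensor data + subject metadata
    "SET-OBSERVE": MMG_FEATURES + META_FEATURES,
    # sensor-less prediction approach: metadata + stimulation parameters
    "SET-PREDICT": META_FEATURES + STIM_FEATURES,
}


def feature_registry() -> dict[str, dict]:
    """Machine-readable registry mapping feature names to categories."""
    reg = {}
    for i, name in enumerate(FEATURE_NAMES, start=1):
        cat = ("meta" if name in META_FEATURES
               else "stim" if name in STIM_FEATURES else "mmg_data")
        reg[name] = {"number": i, "category": cat}
    return reg


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def muscle_group(muscle_id: str) -> str:
    return muscle_id.split("_")[0]


def window_for(muscle_id: str, which: str) -> tuple[float, float]:
    """winA1 or winDIFF in ms relative to the *first* pulse.

    winDIFF is winA1 shifted by the 50 ms inter-pulse interval, i.e. the
    same offsets after the second pulse.
    """
    grp = muscle_group(muscle_id)
    if grp not in WIN_A1_MS:
        raise ValueError(f"unknown muscle {muscle_id!r}")
    lo, hi = WIN_A1_MS[grp]
    if which == "A1":
        return (lo, hi)
    if which == "DIFF":
        return (lo + INTER_PULSE_MS, hi + INTER_PULSE_MS)
    raise ValueError("which must be 'A1' or 'DIFF'")


def _win_slice(n: int, win_ms: tuple[float, float], rate: float = ACC_RATE,
               t0_ms: float = -CROP_PRE_MS) -> slice:
    i0 = int(round((win_ms[0] - t0_ms) * rate / 1000.0))
    i1 = int(round((win_ms[1] - t0_ms) * rate / 1000.0))
    return slice(max(0, i0), min(n, i1))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def discrete_frechet(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete Fréchet distance between two polylines.

    ``p`` and ``q`` are (n, d) arrays of curve vertices. Iterative dynamic
    program over the coupling matrix; symmetric, and zero exactly when the
    two curves are identical.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=-1))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]),
                           d[i, j])
    return float(ca[-1, -1])


def zero_crossing_rate(x: np.ndarray, rate: float = ACC_RATE) -> float:
    """Sign changes per second; zero samples inherit the previous sign."""
    s = np.sign(np.asarray(x, dtype=float))
    for i in range(1, s.size):  # sign(0) -> previous sign
        if s[i] == 0:
            s[i] = s[i - 1]
    nz = s != 0
    changes = np.count_nonzero(np.diff(s[nz]) != 0) if nz.any() else 0
    return changes * rate / x.size


def mean_power_frequency(x: np.ndarray, rate: float = ACC_RATE
                         ) -> tuple[float, float, float]:
    """(mean power frequency, area under PSD, max PSD) of a signal."""
    f, pxx = periodogram(np.asarray(x, dtype=float), fs=rate, window="hann")
    total = pxx.sum()
    mpf = float((f * pxx).sum() / total) if total > 0 else 0.0
    auc = float(np.trapezoid(pxx, f))
    return mpf, auc, float(pxx.max())


def max_slope(x: np.ndarray, rate: float = ACC_RATE) -> float:
    """Maximum forward difference scaled to units per second."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.max(np.diff(x)) * rate)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# per-event feature vector
# ---------------------------------------------------------------------------

def extract_event_features(event: AveragedEvent,
                           partner_event: AveragedEvent | None
                           ) -> dict[str, float]:
    """Compute the 36-entry feature vector of one valid event.

    ``partner_event`` is the other recorded muscle of the same leg
    (quadriceps <-> triceps surae); its peak-to-peak amplitudes fill the two
    crosstalk features, zero when the partner is missing or invalid.
    """
    if not event.valid:
        raise ValueError("cannot extract features from an invalid event")
    meta = event.meta
    single = np.asarray(event.acc_single_avg, dtype=float)
    double = np.asarray(event.acc_double_avg, dtype=float)
    diff = np.asarray(event.acc_diff, dtype=float)

    wa1 = _win_slice(single.size, window_for(event.muscle, "A1"))
    wdiff = _win_slice(diff.size, window_for(event.muscle, "DIFF"))
    s_a1 = single[wa1]
    d_w = diff[wdiff]

    # correlation window: 50 ms after pulse 1 to the end of the crop
    wc = _win_slice(single.size, (50.0, 400.0))
    r = _corr(single[wc], double[wc])

    t_ms = np.arange(single.size) * 1000.0 / ACC_RATE
    curve_d = np.column_stack([t_ms[wdiff], double[wdiff]])
    curve_s = np.column_stack([t_ms[wdiff], single[wdiff]])

    mpf_d, auc_d, max_d = mean_power_frequency(double)
    mpf_s, auc_s, max_s = mean_power_frequency(single)
    mpf_f, auc_f, max_f = mean_power_frequency(diff)

    def partner_p2p() -> tuple[float, float]:
        p = partner_event
        if p is None or not p.valid or p.acc_single_avg is None:
            return 0.0, 0.0
        ps = np.asarray(p.acc_single_avg, dtype=float)
        pf = np.asarray(p.acc_diff, dtype=float)
        pa1 = _win_slice(ps.size, window_for(p.muscle, "A1"))
        pdf = _win_slice(pf.size, window_for(p.muscle, "DIFF"))
        return float(np.ptp(ps[pa1])), float(np.ptp(pf[pdf]))

    p2p_single_2nd, p2p_diff_2nd = partner_p2p()

    return {
        "f01_bmi": meta.bmi,
        "f02_sex": float(meta.sex),
        "f03_age": meta.age,
        "f04_height": meta.height,
        "f05_position": event.position,
        "f06_current": event.current,
        "f07_sensor": 0.0 if muscle_group(event.muscle) == "Q" else 1.0,
        "f08_mmg_single_mean": float(s_a1.mean()),
        "f09_mmg_single_median": float(np.median(s_a1)),
        "f10_mmg_single_std": float(s_a1.std()),
        "f11_mmg_single_rms": float(np.sqrt(np.mean(s_a1**2))),
        "f12_mmg_diff_mean": float(d_w.mean()),
        "f13_mmg_diff_median": float(np.median(d_w)),
        "f14_mmg_diff_std": float(d_w.std()),
        "f15_mmg_diff_rms": float(np.sqrt(np.mean(d_w**2))),
        "f16_frechet_mmg": discrete_frechet(curve_d, curve_s),
        "f17_p2p_mmg_single": float(np.ptp(s_a1)),
        "f18_p2p_mmg_diff": float(np.ptp(d_w)),
        "f19_r2_mmg_single_double": r * r,
        "f20_r_mmg_single_double": r,
        "f21_mpf_double": mpf_d,
        "f22_mpf_single": mpf_s,
        "f23_mpf_diff": mpf_f,
        "f24_auc_psd_single": auc_s,
        "f25_auc_psd_double": auc_d,
        "f26_auc_psd_diff": auc_f,
        "f27_max_psd_single": max_s,
        "f28_max_psd_double": max_d,
        "f29_max_psd_diff": max_f,
        "f30_zcr_single": zero_crossing_rate(single),
        "f31_zcr_double": zero_crossing_rate(double),
        "f32_zcr_diff": zero_crossing_rate(diff),
        "f33_max_slope_diff": max_slope(d_w),
        "f34_max_slope_single": max_slope(s_a1),
        "f35_p2p_mmg_single_2nd": p2p_single_2nd,
        "f36_p2p_mmg_diff_2nd": p2p_diff_2nd,
    }


_PARTNER_GROUP = {"Q": "TS", "TS": "Q"}


def _partner_id(muscle_id: str) -> str:
    grp, side = muscle_id.split("_")
    return f"{_PARTNER_GROUP[grp]}_{side}"


def assemble_feature_table(events: list[AveragedEvent],
                           labels: pd.DataFrame) -> pd.DataFrame:
    """Build the events x features table (one row per valid event).

    ``labels`` is the output of :func:`tscs_tune.labeling.label_events`;
    its label columns are joined onto the feature rows by event key.
    """
    by_key = {ev.key: ev for ev in events}
    lab = labels.set_index(
        ["subject_id", "position", "day", "current_ma", "muscle"])
    rows = []
    for ev in events:
        if not ev.valid:
            continue
        partner = by_key.get((ev.subject_id, ev.position, ev.day, ev.current,
                              _partner_id(ev.muscle)))
        feats = extract_event_features(ev, partner)
        lrow = lab.loc[ev.key]
        rows.append({
            "subject_id": ev.subject_id, "group": ev.group,
            "position": ev.position, "day": ev.day,
            "current_ma": ev.current, "muscle": ev.muscle,
            "label_2": int(lrow.label_2), "label_3": int(lrow.label_3),
            **feats,
        })
    return pd.DataFrame(rows, columns=KEY_COLUMNS + LABEL_COLUMNS
                        + FEATURE_NAMES)


def select_feature_set(table: pd.DataFrame, set_name: str
                       ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Feature matrix, 3-class labels and subject groups for one feature set.

    SET-OBSERVE: 30 MMG-data + 4 meta features (34 columns).
    SET-PREDICT: 4 meta + 2 stim features (6 columns) — sensor-less.
    """
    if set_name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_name!r}")
    cols = FEATURE_SETS[set_name]
    return table[cols], table["label_3"], table["subject_id"]
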