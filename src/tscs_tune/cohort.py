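"""Synthetic evoked-response cohort generator for tSCS calibration.

Transcutaneous spinal cord stimulation (tSCS) calibration sweeps deliver
single and double (50 ms inter-pulse interval) biphasic pulses of increasing
current over the lumbar spine while recording surface EMG (1 kHz) and the
skin-normal accelerometer axis (MMG, 0.5 kHz) of four leg muscles
(left/right quadriceps and triceps surae).

This module simulates such sessions with known ground truth:

* sigmoidal recruitment of a low-threshold reflex (posterior-root afferent)
  pathway and a high-threshold direct motor pathway versus current;
* post-activation suppression of the second EMG response of a double pulse —
  strong for reflex responses, weak once motor fibres are recruited;
* long, overlapping mechanical twitches in the acceleration channel with an
  optional non-linear summation of the second twitch;
* biphasic stimulation artifacts in the EMG only, and additive Gaussian
  sensor noise in both modalities.

Waveform shapes: the EMG response is a Gaussian-derivative biphasic wave
(unit peak-to-peak) at the muscle's latency; the mechanical twitch is a
double-exponential rise/decay envelope (unit peak). Both are smooth
parametric stand-ins for real evoked shapes; latencies and durations follow
the qualitative time course of evoked leg responses (calf latency longer
than thigh, twitches lasting hundreds of milliseconds).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EMG_RATE = 1000.0  # Hz
ACC_RATE = 500.0  # Hz
MUSCLES = ("Q_left", "Q_right", "TS_left", "TS_right")
PULSE_SINGLE = "single"
PULSE_DOUBLE = "double"

#: offset of the first pulse inside a standalone simulated sweep (s)
SWEEP_PULSE_OFFSET_S = 0.1
#: total duration of a standalone simulated sweep (s)
SWEEP_DURATION_S = 1.0
#: support of the EMG response template and of the twitch template (ms)
_EMG_TEMPLATE_MS = 400.0
_TWITCH_TEMPLATE_MS = 500.0


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SubjectMeta:
    """Participant metadata (the four meta features plus identifiers)."""

    subject_id: str
    age: float  # years
    sex: int  # 0 male, 1 female
    height: float  # cm
    bmi: float  # kg/m^2
    group: str  # "healthy" | "patient"

    def __post_init__(self) -> None:
        if self.age <= 0 or self.height <= 0 or self.bmi <= 0:
            raise ValueError("age, height and bmi must be positive")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (male) or 1 (female)")
        if self.group not in ("healthy", "patient"):
            raise ValueError("group must be 'healthy' or 'patient'")


@dataclass(frozen=True)
class StimulationProtocol:
    """Current staircase and pulse-train layout of one calibration session.

    Defaults mirror the clinical protocol: start at 5 mA, increase in 5 mA
    steps, three double then three single biphasic pulses (1 ms per phase)
    per intensity, 50 ms inter-pulse interval within a double pulse, 5 s
    between stimulation incidences.
    """

    start_current: float = 5.0  # mA
    increment: float = 5.0  # mA
    max_current: float = 40.0  # mA, subject-specific (discomfort limit)
    reps_per_pulse_type: int = 3
    inter_pulse_interval_ms: float = 50.0
    phase_width_ms: float = 1.0
    inter_stimulus_gap_s: float = 5.0
    positions: tuple[float, ...] = (-4.0, 0.0, 4.0)  # cm from L3/L4

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be > 0")
        if self.max_current < self.start_current:
            raise ValueError("max_current must be >= start_current")
        if self.reps_per_pulse_type < 1:
            raise ValueError("reps_per_pulse_type must be >= 1")

    def currents(self) -> np.ndarray:
        """The staircase of stimulation currents (mA)."""
        return np.arange(
            self.start_current, self.max_current + 1e-9, self.increment
        )


@dataclass(frozen=True)
class MuscleResponseModel:
    """Generative model of one muscle's evoked responses.

    The reflex pathway recruits at ``reflex_threshold`` and the direct motor
    pathway at the higher ``direct_threshold`` (logistic recruitment with
    slope ``recruitment_slope``). EMG response amplitude is
    ``emg_gain * (reflex + direct recruitment)`` μV peak-to-peak. The second
    response of a double pulse is scaled by ``1 - S_eff/100`` where the
    effective suppression interpolates between ``s_true`` (pure reflex) and
    ``s_direct`` (motor fibres recruited) according to the recruitment mix.
    The mechanical twitch peak is ``twitch_amplitude`` m/s^2 per unit
    recruitment; the second twitch is additionally scaled by
    ``summation_gain`` (non-linear force summation).
    """

    muscle_id: str
    reflex_threshold: float  # mA
    direct_threshold: float  # mA
    latency_ms: float
    emg_gain: float = 400.0  # μV per unit recruitment
    s_true: float = 85.0  # % suppression of a second reflex response
    twitch_amplitude: float = 3.0  # m/s^2 per unit recruitment
    twitch_rise_ms: float = 30.0
    twitch_decay_ms: float = 80.0
    summation_gain: float = 1.3
    emg_noise_sd: float = 3.0  # μV
    acc_noise_sd: float = 0.02  # m/s^2
    artifact_amplitude: float = 3000.0  # μV
    recruitment_slope: float = 1.0  # mA
    s_direct: float = 10.0  # residual suppression once motor fibres recruit
    emg_sigma_ms: float = 2.0  # width of the biphasic EMG wave
    mech_delay_ms: float = 5.0  # electromechanical delay EMG -> twitch onset

    def __post_init__(self) -> None:
        if not self.reflex_threshold < self.direct_threshold:
            raise ValueError("reflex_threshold must be < direct_threshold")
        if not 0.0 <= self.s_true <= 100.0:
            raise ValueError("s_true must be in [0, 100]")
        if min(self.emg_noise_sd, self.acc_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.muscle_id not in MUSCLES:
            raise ValueError(f"unknown muscle_id {self.muscle_id!r}")

    # -- recruitment ------------------------------------------------------
    def recruitment(self, current: float) -> tuple[float, float]:
        """(reflex, direct) recruitment fractions in [0, 1] at ``current``."""
        r = _sigmoid((current - self.reflex_threshold) / self.recruitment_slope)
        d = _sigmoid((current - self.direct_threshold) / self.recruitment_slope)
        return float(r), float(d)

    def expected_a1_uv(self, current: float) -> float:
        """Expected noise-free peak-to-peak EMG response to pulse 1 (μV)."""
        r, d = self.recruitment(current)
        return self.emg_gain * (r + d)

    def effective_suppression(self, current: float) -> float:
        """Expected suppression S (%) of the second response at ``current``."""
        r, d = self.recruitment(current)
        w = r / (r + d + 1e-300)
        return w * self.s_true + (1.0 - w) * self.s_direct

    def intended_class(self, current: float) -> int:
        """Ground-truth 3-class label implied by the model at ``current``.

        Applies the EMG classification rules (A1 > 50 μV; S > 60 %) to the
        model's expected noise-free amplitudes.
        """
        a1 = self.expected_a1_uv(current)
        if a1 <= 50.0:
            return 0
        return 1 if self.effective_suppression(current) > 60.0 else 2


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------

def emg_response_waveform(model: MuscleResponseModel, rate: float = EMG_RATE,
                          duration_ms: float = _EMG_TEMPLATE_MS) -> np.ndarray:
    """Unit peak-to-peak biphasic EMG wave, time-locked to the pulse.

    Gaussian-derivative shape centred at the muscle latency; the returned
    array starts at the pulse sample.
    """
    t = np.arange(int(round(duration_ms * rate / 1000.0))) * 1000.0 / rate
    mu, s = model.latency_ms, model.emg_sigma_ms
    w = -(t - mu) * np.exp(-((t - mu) ** 2) / (2.0 * s**2))
    return w / np.ptp(w)


def twitch_waveform(model: MuscleResponseModel, rate: float = ACC_RATE,
                    duration_ms: float = _TWITCH_TEMPLATE_MS) -> np.ndarray:
    """Unit-peak mechanical twitch envelope, time-locked to the pulse.

    Double-exponential rise/decay starting one electromechanical delay after
    the EMG latency; much longer than the electrical response, so successive
    twitches of a double pulse overlap.
    """
    t = np.arange(int(round(duration_ms * rate / 1000.0))) * 1000.0 / rate
    onset = model.latency_ms + model.mech_delay_ms
    tt = np.clip(t - onset, 0.0, None)
    w = np.exp(-tt / model.twitch_decay_ms) - np.exp(-tt / model.twitch_rise_ms)
    w[t < onset] = 0.0
    return w / w.max()


def _add_event(emg: np.ndarray, acc: np.ndarray, model: MuscleResponseModel,
               current: float, pulse_type: str, i_emg: int,
               ipi_ms: float, phase_width_ms: float) -> None:
    """Add the noise-free content of one stimulation event in place.

    ``i_emg`` is the EMG sample index of the first pulse; the ACC channel
    shares the same time origin (index ``i_emg * ACC_RATE / EMG_RATE``).
    """
    if pulse_type not in (PULSE_SINGLE, PULSE_DOUBLE):
        raise ValueError(f"invalid pulse_type {pulse_type!r}")
    r, d = model.recruitment(current)
    drive = r + d
    a1 = model.emg_gain * drive
    m1 = model.twitch_amplitude * drive
    s_eff = model.effective_suppression(current)
    pulses_ms = [0.0] if pulse_type == PULSE_SINGLE else [0.0, ipi_ms]
    wave = emg_response_waveform(model)
    tw = twitch_waveform(model)
    pw = max(1, int(round(phase_width_ms * EMG_RATE / 1000.0)))
    for k, p_ms in enumerate(pulses_ms):
        i = i_emg + int(round(p_ms * EMG_RATE / 1000.0))
        # biphasic stimulation artifact (EMG only)
        emg[i:i + pw] += model.artifact_amplitude
        emg[i + pw:i + 2 * pw] -= model.artifact_amplitude
        amp = a1 if k == 0 else a1 * (1.0 - s_eff / 100.0)
        seg = emg[i:i + wave.size]
        seg += amp * wave[: seg.size]
        j = int(round(i / EMG_RATE * ACC_RATE))
        mech = m1 if k == 0 else m1 * (1.0 - s_eff / 100.0) * model.summation_gain
        aseg = acc[j:j + tw.size]
        aseg += mech * tw[: aseg.size]


def simulate_event_pair(model: MuscleResponseModel, current: float,
                        pulse_type: str,
                        rng_seed: int | np.random.Generator,
                        noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one stimulation event for one muscle.

    Returns a 1 s EMG sweep (1 kHz, μV) and the matching ACC sweep
    (0.5 kHz, m/s^2) with the first pulse at 0.1 s. Identical seed and
    arguments give identical sweeps.
    """
    if current <= 0:
        raise ValueError("current must be > 0")
    rng = np.random.default_rng(rng_seed)
    n_e = int(round(SWEEP_DURATION_S * EMG_RATE))
    n_a = int(round(SWEEP_DURATION_S * ACC_RATE))
    emg = rng.normal(0.0, model.emg_noise_sd, n_e) if noise else np.zeros(n_e)
    acc = rng.normal(0.0, model.acc_noise_sd, n_a) if noise else np.zeros(n_a)
    i0 = int(round(SWEEP_PULSE_OFFSET_S * EMG_RATE))
    _add_event(emg, acc, model, current, pulse_type, i0,
               ipi_ms=50.0, phase_width_ms=1.0)
    return emg, acc


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionRecording:
    """Raw multichannel recording of one (subject, position, day)."""

    meta: SubjectMeta
    position: float  # cm from L3/L4 (caudal negative)
    day: int
    protocol: StimulationProtocol
    emg: np.ndarray  # (4, n) μV @ 1 kHz
    acc_z: np.ndarray  # (4, m) m/s^2 @ 0.5 kHz
    events: pd.DataFrame  # time_s, pulse_type, current_ma
    ground_truth: pd.DataFrame  # muscle, current_ma, label_3, label_2

    @property
    def session_id(self) -> str:
        return f"{self.meta.subject_id}_pos{self.position:+g}_day{self.day}"


def generate_session(meta: SubjectMeta, protocol: StimulationProtocol,
                     models: dict[str, MuscleResponseModel], position: float,
                     seed: int | np.random.SeedSequence,
                     day: int = 1) -> SessionRecording:
    """Generate one calibration session.

    For each current of the staircase, ``reps_per_pulse_type`` double pulses
    are delivered followed by the same number of single pulses, 5 s apart.
    The event log is a pure function of the protocol; only the sensor noise
    depends on the seed.
    """
    currents = protocol.currents()
    rows = []
    t = protocol.inter_stimulus_gap_s  # leave a noise-only lead-in
    for c in currents:
        for ptype in (PULSE_DOUBLE, PULSE_SINGLE):
            for _ in range(protocol.reps_per_pulse_type):
                rows.append((t, ptype, float(c)))
                t += protocol.inter_stimulus_gap_s
    events = pd.DataFrame(rows, columns=["time_s", "pulse_type", "current_ma"])
    duration_s = t + 1.0
    n_e = int(round(duration_s * EMG_RATE))
    n_a = int(round(duration_s * ACC_RATE))

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = {m: np.random.default_rng(s) for m, s in zip(MUSCLES, ss.spawn(len(MUSCLES)))}

    emg = np.empty((len(MUSCLES), n_e))
    acc = np.empty((len(MUSCLES), n_a))
    for ch, muscle in enumerate(MUSCLES):
        model = models[muscle]
        rng = child[muscle]
        emg[ch] = rng.normal(0.0, model.emg_noise_sd, n_e)
        acc[ch] = rng.normal(0.0, model.acc_noise_sd, n_a)
        for _, ev in events.iterrows():
            i = int(round(ev.time_s * EMG_RATE))
            _add_event(emg[ch], acc[ch], model, ev.current_ma, ev.pulse_type,
                       i, protocol.inter_pulse_interval_ms,
                       protocol.phase_width_ms)

    gt_rows = [
        (m, float(c), models[m].intended_class(c),
         int(models[m].intended_class(c) > 0))
        for m in MUSCLES for c in currents
    ]
    ground_truth = pd.DataFrame(
        gt_rows, columns=["muscle", "current_ma", "label_3", "label_2"]
    )
    return SessionRecording(meta=meta, position=position, day=day,
                            protocol=protocol, emg=emg, acc_z=acc,
                            events=events, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSpec:
    """One subject of a cohort spec."""

    subject_id: str
    group: str  # "healthy" | "patient"
    positions: tuple[float, ...]  # electrode positions (cm from L3/L4)
    n_days: int = 1
    max_current: float | None = None  # mA; sampled if None


@dataclass(frozen=True)
class CohortSpec:
    """Study-level description of a synthetic cohort.

    ``noise_scale`` multiplies both sensor-noise SD ranges; 0 gives
    noise-free recordings, 1 the default study conditions.
    """

    subjects: tuple[SubjectSpec, ...]
    noise_scale: float = 1.0
    start_current: float = 5.0
    increment: float = 5.0
    reps_per_pulse_type: int = 3
    inter_stimulus_gap_s: float = 5.0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort spec lists no subjects")


# sampling ranges for per-muscle model parameters (study conditions)
_MODEL_RANGES: dict[str, tuple[float, float]] = {
    "reflex_threshold_jitter": (1.5, 3.5),  # mA above a 5 mA grid point
    "direct_offset": (10.0, 18.0),  # mA above reflex threshold
    "latency_q": (7.0, 9.0),  # ms
    "latency_ts": (16.0, 20.0),  # ms
    "emg_gain": (250.0, 500.0),  # μV
    "s_true": (70.0, 95.0),  # %
    "twitch_amplitude": (1.0, 4.0),  # m/s^2
    "twitch_rise": (25.0, 35.0),  # ms
    "twitch_decay": (70.0, 90.0),  # ms
    "summation_gain": (1.0, 1.5),
    "emg_noise_sd": (2.0, 5.0),  # μV
    "acc_noise_sd": (0.01, 0.03),  # m/s^2
}
_MAX_CURRENT_CHOICES = (25.0, 30.0, 35.0, 40.0, 45.0)


def _sample_models(rng: np.random.Generator, noise_scale: float
                   ) -> dict[str, MuscleResponseModel]:
    """Draw one subject's four muscle models from the study ranges."""
    r = _MODEL_RANGES
    base_grid = rng.choice([5.0, 10.0, 15.0])
    models = {}
    for muscle in MUSCLES:
        is_ts = muscle.startswith("TS")
        reflex = base_grid + rng.uniform(*r["reflex_threshold_jitter"])
        if is_ts:
            reflex += rng.uniform(0.0, 1.0)  # calf threshold slightly higher
        models[muscle] = MuscleResponseModel(
            muscle_id=muscle,
            reflex_threshold=float(reflex),
            direct_threshold=float(reflex + rng.uniform(*r["direct_offset"])),
            latency_ms=float(rng.uniform(*(r["latency_ts"] if is_ts
                                           else r["latency_q"]))),
            emg_gain=float(rng.uniform(*r["emg_gain"])),
            s_true=float(rng.uniform(*r["s_true"])),
            twitch_amplitude=float(rng.uniform(*r["twitch_amplitude"])),
            twitch_rise_ms=float(rng.uniform(*r["twitch_rise"])),
            twitch_decay_ms=float(rng.uniform(*r["twitch_decay"])),
            summation_gain=float(rng.uniform(*r["summation_gain"])),
            emg_noise_sd=float(rng.uniform(*r["emg_noise_sd"]) * noise_scale),
            acc_noise_sd=float(rng.uniform(*r["acc_noise_sd"]) * noise_scale),
        )
    return models


def _sample_meta(rng: np.random.Generator, spec: SubjectSpec) -> SubjectMeta:
    healthy = spec.group == "healthy"
    age = float(np.clip(rng.normal(34.0 if healthy else 56.0,
                                   7.0 if healthy else 9.0), 18.0, 80.0))
    return SubjectMeta(
        subject_id=spec.subject_id,
        age=round(age, 1),
        sex=int(rng.integers(0, 2)),
        height=round(float(np.clip(rng.normal(175.0, 10.0), 150.0, 205.0)), 1),
        bmi=round(float(np.clip(rng.normal(23.0, 3.0), 16.0, 32.0)), 1),
        group=spec.group,
    )


def generate_cohort(spec: CohortSpec, seed: int
                    ) -> tuple[list[SessionRecording], dict]:
    """Generate all sessions of a cohort plus the true-parameter registry.

    One session per (subject, position, day). The registry maps subject_id to
    its metadata, muscle models and max current so recovery tests can compare
    pipeline output against the generating truth. Different seeds change the
    noise realizations (and sampled parameters); the event-log layout is
    fixed by the protocol.
    """
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    sessions: list[SessionRecording] = []
    registry: dict[str, dict] = {}
    for subj in spec.subjects:
        models = _sample_models(param_rng, spec.noise_scale)
        meta = _sample_meta(param_rng, subj)
        max_current = subj.max_current
        if max_current is None:
            max_current = float(param_rng.choice(_MAX_CURRENT_CHOICES))
        registry[subj.subject_id] = {
            "meta": meta, "models": models, "max_current": max_current,
        }
        protocol = StimulationProtocol(
            start_current=spec.start_current, increment=spec.increment,
            max_current=max_current,
            reps_per_pulse_type=spec.reps_per_pulse_type,
            inter_stimulus_gap_s=spec.inter_stimulus_gap_s,
            positions=subj.positions,
        )
        for day in range(1, subj.n_days + 1):
            for pos in subj.positions:
                child = ss.spawn(1)[0]
                sessions.append(generate_session(meta, protocol, models,
                                                 position=pos, seed=child,
                                                 day=day))
    return sessions, registry


def study_cohort_spec() -> CohortSpec:
    """The full study layout: 11 healthy subjects measured at three electrode
    positions (two of them at a fourth, more cranial position) and 11
    patients measured on two days at a single position each."""
    subjects = []
    for i in range(1, 12):
        positions = (-4.0, 0.0, 4.0)
        if i in (4, 10):  # lack of thigh reflexes -> extra cranial position
            positions = (-4.0, 0.0, 4.0, 8.0)
        subjects.append(SubjectSpec(f"S{i}", "healthy", positions))
    patient_positions = (0.0, 1.5, 3.0, 4.5)
    for i in range(1, 12):
        subjects.append(SubjectSpec(
            f"P{i}", "patient",
            (patient_positions[(i - 1) % len(patient_positions)],),
            n_days=2,
        ))
    return CohortSpec(subjects=tuple(subjects))


def demo_cohort_spec(n_healthy: int = 4, n_patients: int = 0,
                     positions: tuple[float, ...] = (-4.0, 0.0),
                     max_current: float | None = 25.0,
                     noise_scale: float = 1.0) -> CohortSpec:
    """A reduced cohort for demos, tests and desk-scale experiments."""
    subjects = [
        SubjectSpec(f"S{i}", "healthy", positions, max_current=max_current)
        for i in range(1, n_healthy + 1)
    ]
    subjects += [
        SubjectSpec(f"P{i}", "patient", (positions[0],), n_days=2,
                    max_current=max_current)
        for i in range(1, n_patients + 1)
    ]
    return CohortSpec(subjects=tuple(subjects), noise_scale=noise_scale)


# ---------------------------------------------------------------------------
# session containers on disk
# ---------------------------------------------------------------------------

def save_session(session: SessionRecording, path: str | Path) -> None:
    """Write one session container (emg.csv, acc.csv, events.csv, meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t_e = np.arange(session.emg.shape[1]) / EMG_RATE
    pd.DataFrame({"time_s": t_e, **{m: session.emg[i]
                                    for i, m in enumerate(MUSCLES)}}
                 ).to_csv(path / "emg.csv", index=False)
    t_a = np.arange(session.acc_z.shape[1]) / ACC_RATE
    pd.DataFrame({"time_s": t_a, **{m: session.acc_z[i]
                                    for i, m in enumerate(MUSCLES)}}
                 ).to_csv(path / "acc.csv", index=False)
    session.events.to_csv(path / "events.csv", index=False)
    meta = {
        "meta": dataclasses.asdict(session.meta),
        "position": session.position,
        "day": session.day,
        "protocol": dataclasses.asdict(session.protocol),
        "ground_truth": session.ground_truth.to_dict("records"),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_session(path: str | Path) -> SessionRecording:
    """Read a session container written by :func:`save_session`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    emg_df = pd.read_csv(path / "emg.csv")
    acc_df = pd.read_csv(path / "acc.csv")
    proto = meta["protocol"]
    proto["positions"] = tuple(proto["positions"])
    return SessionRecording(
        meta=SubjectMeta(**meta["meta"]),
        position=meta["position"],
        day=meta["day"],
        protocol=StimulationProtocol(**proto),
        emg=emg_df[list(MUSCLES)].to_numpy().T,
        acc_z=acc_df[list(MUSCLES)].to_numpy().T,
        events=pd.read_csv(path / "events.csv"),
        ground_truth=pd.DataFrame(meta["ground_truth"]),
    )
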