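"""Synthetic cohort generator: latent mood drives both EEG and diary.

The generator emulates the study design the analysis assumes: nine
inpatients record 5 minutes of resting forehead EEG (Fp1/Fp2, 512 Hz,
12-bit ADC) twice daily (morning and evening) for two weeks, completing a
40-item diary at every session.

A per-subject latent mood trajectory (higher = more depressed) is the
single source of coupling:

* trajectory: baseline + piecewise-linear trend (declining in week 1;
  week 2 rebounds for a configurable fraction of subjects) + a positive
  morning offset (the morning-worse diurnal rhythm) + Gaussian noise;
* diary: item score = clip(round(50 + loading_k * latent + noise), 1, 100),
  with positive loadings on negative-mood items and negative loadings on
  vigor/self-mood items;
* EEG: 1/f-colored background noise plus one sinusoid per band, where the
  alpha amplitude increases monotonically with coupling_strength * latent;
  samples are quantized to a 12-bit grid over +/-100 microvolts.

Everything is deterministic given (config, seed): each (subject, session,
stream) draws from its own seeded generator, so cohorts are reproducible
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .items import ITEM_CATEGORY, ITEM_NAMES, N_ITEMS, NEGATIVE_MOOD_CATEGORIES
from .preprocess import CHANNELS, EEGRecording
from .qlog import ITEM_COLUMNS, QLogEntry

#: cohort start date (arbitrary but fixed for reproducibility)
EPOCH = datetime(2024, 3, 4)
MORNING_HOUR = 8
EVENING_HOUR = 20

#: ADC emulation: 12-bit uniform quantization over a +/-100 microvolt range
ADC_RANGE_UV = 100.0
ADC_LEVELS = 4096

#: band -> (center frequency Hz, baseline amplitude microvolts)
BAND_SINUSOIDS = {
    "delta": (3.0, 8.0),
    "theta": (6.0, 6.0),
    "alpha": (12.0, 6.0),
    "beta": (24.0, 4.0),
    "gamma": (48.0, 2.0),
}
ALPHA_GAIN = 0.8  # microvolts of alpha amplitude per unit of coupling * latent
PINK_NOISE_RMS = 4.0  # microvolts

# latent trajectory shape
BASELINE = 10.0
SLOPE_WEEK1 = -0.8  # per day; mood improves during week 1
SLOPE_WEEK2_REBOUND = 0.8
SLOPE_WEEK2_DECLINE = -0.4
DIURNAL_AMPLITUDE = 2.0  # morning sessions score higher (worse)


def _default_loadings() -> np.ndarray:
    """Item loadings: positive for negative-mood categories, negative for
    vigor/self-mood; depression items load strongest."""
    loadings = np.empty(N_ITEMS)
    for i, name in enumerate(ITEM_NAMES):
        cat = ITEM_CATEGORY[name]
        if cat == "depression-dejection":
            loadings[i] = 2.0
        elif cat in NEGATIVE_MOOD_CATEGORIES:
            loadings[i] = 1.5
        else:  # vigor-activity, self-mood
            loadings[i] = -1.5
    return loadings


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 9
    n_days: int = 14
    sessions_per_day: int = 2  # morning, evening
    eeg_duration_s: float = 300.0
    sample_rate_hz: float = 512.0
    coupling_strength: float = 1.0
    diary_noise_sd: float = 5.0
    latent_noise_sd: float = 0.3
    diurnal_amplitude: float = DIURNAL_AMPLITUDE
    rebound_fraction: float = 4.0 / 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_days, self.sessions_per_day) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.sample_rate_hz <= 2 * 64.0:
            raise ConfigurationError(
                "sample_rate_hz must exceed 128 Hz to resolve the gamma band"
            )
        if self.coupling_strength < 0:
            raise ConfigurationError("coupling_strength must be >= 0")
        if not 0.0 <= self.rebound_fraction <= 1.0:
            raise ConfigurationError("rebound_fraction must be in [0, 1]")
        if self.eeg_duration_s <= 0:
            raise ConfigurationError("eeg_duration_s must be positive")
        if self.diary_noise_sd < 0 or self.latent_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    @property
    def n_sessions(self) -> int:
        return self.n_days * self.sessions_per_day

    def is_rebound_subject(self, subject_index: int) -> bool:
        return subject_index < round(self.rebound_fraction * self.n_subjects)


@dataclass
class LatentMoodTrajectory:
    """Per-session latent mood values (higher = more depressed)."""

    subject_id: str
    session_times: list[datetime]
    values: np.ndarray
    periods: list[str]
    components: pd.DataFrame  # baseline, trend, diurnal, noise per session

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.session_times):
            raise SchemaError("values and session_times must align")
        times = self.session_times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SchemaError("session times must be strictly increasing")


@dataclass
class Cohort:
    """Paired recordings, diaries and ground-truth latents for every subject."""

    config: CohortConfig
    recordings: dict[tuple[str, datetime], EEGRecording]
    qlog_entries: dict[str, list[QLogEntry]]
    truths: dict[str, LatentMoodTrajectory]

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.truths)


def subject_label(subject_index: int) -> str:
    return f"S{subject_index + 1:02d}"


def _rng(config: CohortConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *stream])
    )


def _session_schedule(config: CohortConfig) -> list[tuple[datetime, str, float]]:
    """(timestamp, period, day_fraction) for every session in order."""
    hours = np.linspace(MORNING_HOUR, EVENING_HOUR, config.sessions_per_day)
    out = []
    for day in range(config.n_days):
        for s in range(config.sessions_per_day):
            t = EPOCH + timedelta(days=day, hours=float(hours[s]))
            period = "morning" if s == 0 else "evening"
            out.append((t, period, day + float(hours[s]) / 24.0))
    return out


def generate_mood_trajectory(
    config: CohortConfig, subject_index: int
) -> LatentMoodTrajectory:
    """Latent mood trajectory for one subject.

    value(t) = baseline + piecewise-linear trend(day) + diurnal morning
    offset + Gaussian noise.  Week 1 declines; week 2 rebounds only for
    rebound subjects.  Deterministic given (config.seed, subject_index).
    """
    if subject_index >= config.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} >= n_subjects {config.n_subjects}"
        )
    rng = _rng(config, 0, subject_index)
    rebound = config.is_rebound_subject(subject_index)
    slope2 = SLOPE_WEEK2_REBOUND if rebound else SLOPE_WEEK2_DECLINE
    schedule = _session_schedule(config)
    rows = []
    for t, period, day_frac in schedule:
        trend = SLOPE_WEEK1 * min(day_frac, 7.0) + slope2 * max(day_frac - 7.0, 0.0)
        diurnal = config.diurnal_amplitude if period == "morning" else 0.0
        noise = float(rng.normal(0.0, config.latent_noise_sd)) if config.latent_noise_sd else 0.0
        rows.append(
            {
                "session_time": t,
                "period": period,
                "baseline": BASELINE,
                "trend": trend,
                "diurnal": diurnal,
                "noise": noise,
            }
        )
    comp = pd.DataFrame(rows)
    values = (comp["baseline"] + comp["trend"] + comp["diurnal"] + comp["noise"]).to_numpy()
    return LatentMoodTrajectory(
        subject_id=subject_label(subject_index),
        session_times=[r["session_time"] for r in rows],
        values=values,
        periods=[r["period"] for r in rows],
        components=comp,
    )


def generate_qlog_scores(
    latent_value: float,
    loadings: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """40 diary item scores: clip(round(50 + loading_k * latent + noise), 1, 100)."""
    if loadings is None:
        loadings = _default_loadings()
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (N_ITEMS,):
        raise SchemaError(f"expected {N_ITEMS} loadings, got {loadings.shape}")
    noise = (
        rng.normal(0.0, noise_sd, size=N_ITEMS)
        if (noise_sd > 0 and rng is not None)
        else np.zeros(N_ITEMS)
    )
    raw = np.round(50.0 + loadings * float(latent_value) + noise)
    return np.clip(raw, 1, 100).astype(int)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-colored noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(F * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def alpha_amplitude(config: CohortConfig, latent_value: float) -> float:
    """Alpha sinusoid amplitude: monotone in coupling_strength * latent."""
    base = BAND_SINUSOIDS["alpha"][1]
    amp = base + ALPHA_GAIN * config.coupling_strength * float(latent_value)
    return max(amp, 0.5)


def quantize_adc(x: np.ndarray) -> np.ndarray:
    """Uniform 12-bit quantization over the +/-100 microvolt dynamic range."""
    step = 2 * ADC_RANGE_UV / ADC_LEVELS
    return np.clip(np.round(x / step) * step, -ADC_RANGE_UV, ADC_RANGE_UV - step)


def generate_eeg_session(
    latent_value: float,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "S00",
    session_time: datetime = EPOCH,
    period: str = "morning",
    noise_rms: float = PINK_NOISE_RMS,
) -> EEGRecording:
    """One two-channel EEG session driven by the latent mood value.

    Per channel: 1/f background noise plus one sinusoid per band with a
    random phase; the alpha amplitude is a monotone function of
    coupling_strength * latent.  Channel noise is independent.
    """
    n = int(round(config.eeg_duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    channels = []
    for _ in CHANNELS:
        sig = noise_rms * _pink_noise(n, rng) if noise_rms > 0 else np.zeros(n)
        for band, (f0, amp) in BAND_SINUSOIDS.items():
            if band == "alpha":
                amp = alpha_amplitude(config, latent_value)
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + amp * np.sin(2 * np.pi * f0 * t + phase)
        channels.append(quantize_adc(sig))
    return EEGRecording(
        subject_id=subject_id,
        session_time=session_time,
        period=period,
        sample_rate_hz=config.sample_rate_hz,
        channels=CHANNELS,
        samples=np.vstack(channels),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort: one recording and one diary entry per
    (subject, session), plus the ground-truth latent trajectories."""
    loadings = _default_loadings()
    recordings: dict[tuple[str, datetime], EEGRecording] = {}
    qlog_entries: dict[str, list[QLogEntry]] = {}
    truths: dict[str, LatentMoodTrajectory] = {}
    for si in range(config.n_subjects):
        traj = generate_mood_trajectory(config, si)
        sid = traj.subject_id
        truths[sid] = traj
        entries = []
        for k, (t, period) in enumerate(zip(traj.session_times, traj.periods)):
            latent = float(traj.values[k])
            qrng = _rng(config, 1, si, k)
            scores = generate_qlog_scores(latent, loadings, config.diary_noise_sd, qrng)
            entries.append(
                QLogEntry(subject_id=sid, timestamp=t, period=period, scores=scores)
            )
            erng = _rng(config, 2, si, k)
            recordings[(sid, t)] = generate_eeg_session(
                latent, config, erng, subject_id=sid, session_time=t, period=period
            )
        qlog_entries[sid] = entries
    return Cohort(
        config=config, recordings=recordings, qlog_entries=qlog_entries, truths=truths
    )


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the cohort as plain CSV: eeg/<subject>_<session>.csv,
    qlog/<subject>.csv and truth/<subject>.csv."""
    out = Path(out_dir)
    (out / "eeg").mkdir(parents=True, exist_ok=True)
    (out / "qlog").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for (sid, t), rec in sorted(cohort.recordings.items()):
        tag = t.strftime("%Y%m%dT%H%M")
        df = pd.DataFrame(
            {
                "sample_index": np.arange(rec.n_samples),
                "fp1": rec.samples[0],
                "fp2": rec.samples[1],
            }
        )
        df.to_csv(out / "eeg" / f"{sid}_{tag}.csv", index=False)
    for sid, entries in sorted(cohort.qlog_entries.items()):
        rows = []
        for e in entries:
            row = {"timestamp": e.timestamp.isoformat(), "period": e.period}
            row.update(dict(zip(ITEM_COLUMNS, e.scores.tolist())))
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "qlog" / f"{sid}.csv", index=False)
    for sid, traj in sorted(cohort.truths.items()):
        df = traj.components.copy()
        df["session_time"] = [t.isoformat() for t in traj.session_times]
        df["latent"] = traj.values
        df.to_csv(out / "truth" / f"{sid}.csv", index=False)
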