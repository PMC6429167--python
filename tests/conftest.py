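"""Shared fixtures: small synthetic inputs generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from moodquant.preprocess import EEGRecording, Segment
from moodquant.synthetic import EPOCH, CohortConfig, generate_cohort

FS = 512.0
SEG_LEN = 5120  # 10 s at 512 Hz


def make_recording(samples: np.ndarray, subject="S01", period="morning") -> EEGRecording:
    return EEGRecording(
        subject_id=subject,
        session_time=EPOCH,
        period=period,
        sample_rate_hz=FS,
        channels=("Fp1", "Fp2"),
        samples=samples,
    )


def tone(freq: float, n: int = SEG_LEN, fs: float = FS, amp: float = 10.0) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.fixture(scope="session")
def eeg_segment() -> Segment:
    """A realistic 10-s segment: band sinusoids plus white noise."""
    rng = np.random.default_rng(42)
    sig = sum(tone(f, amp=a) for f, a in [(3, 8), (6, 6), (12, 6), (24, 4), (48, 2)])
    sig = sig + rng.normal(0, 3.0, SEG_LEN)
    return Segment(channel="Fp1", start_index=0, samples=sig, sample_rate_hz=FS)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 4 days, short sessions: cheap but fully structured."""
    config = CohortConfig(
        n_subjects=3,
        n_days=4,
        eeg_duration_s=10.0,
        coupling_strength=3.0,
        diary_noise_sd=2.0,
        seed=7,
    )
    return generate_cohort(config)
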