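"""EEG segmentation, wavelet denoising and subband decomposition.

Raw forehead recordings (Fp1/Fp2 at 512 Hz) are cut into 50%-overlapping
segments.  Each segment is denoised by soft-thresholding the detail
coefficients of an 8-level db5 discrete wavelet transform, then decomposed
into the five classical EEG subbands by single-branch reconstruction of
detail layers D3..D7.  At 512 Hz the dyadic detail layers line up with the
band definitions used throughout the package:

    D3 -> gamma 32-64 Hz, D4 -> beta 16-32 Hz, D5 -> alpha 8-16 Hz,
    D6 -> theta 4-8 Hz,   D7 -> delta 2-4 Hz.

D1, D2 (above 64 Hz) and D8 plus the approximation (below 2 Hz) are kept
as residual branches so the decomposition remains exactly additive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .errors import (
    ConfigurationError,
    DecompositionDepthError,
    EmptyOutputError,
    MoodQuantError,
    SchemaError,
)

logger = logging.getLogger(__name__)

WAVELET = "db5"
DWT_LEVELS = 8
#: pywt boundary mode; periodization keeps the transform orthogonal so that
#: branch energies add up exactly and reconstruction is exact.
DWT_MODE = "periodization"
#: minimum segment length (samples) for a meaningful 8-level decomposition
MIN_DENOISE_LEN = 2560

DEFAULT_SAMPLE_RATE = 512.0
CHANNELS = ("Fp1", "Fp2")

BANDS = ("delta", "theta", "alpha", "beta", "gamma")
#: band -> (low, high) Hz at 512 Hz sampling
BAND_RANGES = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 64.0),
}
#: detail layer -> band at 512 Hz (D3..D7); other layers are residual
LAYER_BAND = {3: "gamma", 4: "beta", 5: "alpha", 6: "theta", 7: "delta"}
BAND_LAYER = {band: layer for layer, band in LAYER_BAND.items()}


@dataclass
class EEGRecording:
    """One subject-session of raw multi-channel EEG in microvolts."""

    subject_id: str
    session_time: datetime
    period: str  # morning | evening
    sample_rate_hz: float
    channels: tuple[str, ...]
    samples: np.ndarray  # (n_channels, n_samples)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise SchemaError("samples must be a (channels x time) matrix")
        if len(set(self.channels)) != len(self.channels):
            raise SchemaError("channel labels must be unique")
        if self.period not in ("morning", "evening"):
            raise SchemaError(f"period must be morning|evening, got {self.period!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.channels.index(label)]
        except ValueError:
            raise SchemaError(f"no channel {label!r} in {self.channels}") from None


@dataclass
class Segment:
    """A half-open window [start, start + L) from one channel."""

    channel: str
    start_index: int
    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.start_index < 0:
            raise SchemaError("start_index must be >= 0")
        if self.samples.size == 0:
            raise SchemaError("segment must be non-empty")


@dataclass
class SubbandSet:
    """Denoised series, the five subband series and the per-layer detail coefficients."""

    denoised: np.ndarray
    delta: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    #: detail coefficients of the denoised signal, layers 1..8
    layer_coefficients: dict[int, np.ndarray]
    #: all reconstructed branches (A8, D1..D8); sums to `denoised`
    branches: dict[str, np.ndarray] = field(default_factory=dict)
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE

    def series(self, name: str) -> np.ndarray:
        if name == "denoised":
            return self.denoised
        if name in BANDS:
            return getattr(self, name)
        raise SchemaError(f"unknown series {name!r}")


def band_of_layer(layer: int) -> str | None:
    """Map a detail layer (1..8) to its EEG band at 512 Hz, or None for residual layers."""
    if not isinstance(layer, (int, np.integer)) or not 1 <= layer <= 8:
        raise MoodQuantError(f"layer must be in 1..8, got {layer!r}")
    return LAYER_BAND.get(int(layer))


def segment(
    recording: EEGRecording, segment_len_s: float = 10.0
) -> list[Segment]:
    """Cut every channel into 50%-overlapping windows of ``segment_len_s`` seconds.

    Windows advance by half a window; a trailing partial window is dropped.
    The number of segments per channel is ``floor((N - L) / (L/2)) + 1``.
    """
    if segment_len_s <= 0:
        raise ConfigurationError("segment_len_s must be positive")
    L = int(round(segment_len_s * recording.sample_rate_hz))
    N = recording.n_samples
    if N < L:
        raise EmptyOutputError(
            f"recording has {N} samples, shorter than one {L}-sample segment"
        )
    hop = L // 2
    out: list[Segment] = []
    for ch_i, ch in enumerate(recording.channels):
        data = recording.samples[ch_i]
        for start in range(0, N - L + 1, hop):
            out.append(
                Segment(
                    channel=ch,
                    start_index=start,
                    samples=data[start : start + L],
                    sample_rate_hz=recording.sample_rate_hz,
                )
            )
    return out


def _mad_sigma(detail: np.ndarray) -> float:
    # robust noise scale from the finest detail layer
    return float(np.median(np.abs(detail)) / 0.6745) if detail.size else 0.0


def denoise(
    seg: Segment | np.ndarray,
    wavelet: str = WAVELET,
    level: int = DWT_LEVELS,
    threshold: float | None = None,
) -> np.ndarray:
    """Soft-threshold wavelet denoising (db5, 8 levels).

    ``threshold=None`` uses the universal threshold sigma*sqrt(2 ln N) with
    sigma estimated as MAD(D1)/0.6745.  ``threshold=0`` reproduces the input
    up to the reconstruction tolerance of the transform.
    """
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    n = x.size
    if n < MIN_DENOISE_LEN:
        raise DecompositionDepthError(
            f"segment length {n} < {MIN_DENOISE_LEN} required for {level}-level {wavelet}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=DWT_MODE, level=level)
    if threshold is None:
        sigma = _mad_sigma(coeffs[-1])  # D1 = finest detail
        threshold = sigma * np.sqrt(2.0 * np.log(n))
    # soft shrinkage; done directly so zero coefficients stay exactly zero
    shrunk = [coeffs[0]] + [
        np.sign(c) * np.maximum(np.abs(c) - threshold, 0.0) for c in coeffs[1:]
    ]
    rec = pywt.waverec(shrunk, wavelet, mode=DWT_MODE)
    return rec[:n]


def _single_branch(
    coeffs: list[np.ndarray], branch: int, wavelet: str, n: int
) -> np.ndarray:
    """Reconstruct one branch (0 = approximation, 1.. = detail slots) alone."""
    iso = [np.zeros_like(c) for c in coeffs]
    iso[branch] = coeffs[branch]
    return pywt.waverec(iso, wavelet, mode=DWT_MODE)[:n]


def decompose_subbands(
    denoised: np.ndarray,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE,
    wavelet: str = WAVELET,
    strict_rate: bool = True,
) -> SubbandSet:
    """8-level db5 decomposition of a denoised series into the five subband series.

    Each subband series is the single-branch inverse transform of one detail
    layer (all other coefficients zeroed), so the subband series plus the
    residual branches sum exactly back to the input.
    """
    x = np.asarray(denoised, dtype=float)
    if strict_rate and sample_rate_hz != DEFAULT_SAMPLE_RATE:
        raise ConfigurationError(
            f"layer<->band mapping is defined at 512 Hz; got {sample_rate_hz} Hz "
            "(pass strict_rate=False only with a recomputed mapping)"
        )
    n = x.size
    if n < MIN_DENOISE_LEN:
        raise DecompositionDepthError(
            f"series length {n} < {MIN_DENOISE_LEN} for 8-level decomposition"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=DWT_MODE, level=DWT_LEVELS)
    # coeffs = [A8, D8, D7, ..., D1]; detail layer j sits at slot (levels+1-j)
    layer_coeffs = {j: coeffs[DWT_LEVELS + 1 - j] for j in range(1, DWT_LEVELS + 1)}
    branches: dict[str, np.ndarray] = {
        "A8": _single_branch(coeffs, 0, wavelet, n)
    }
    for j in range(1, DWT_LEVELS + 1):
        branches[f"D{j}"] = _single_branch(coeffs, DWT_LEVELS + 1 - j, wavelet, n)
    band_series = {band: branches[f"D{layer}"] for layer, band in LAYER_BAND.items()}
    return SubbandSet(
        denoised=x,
        delta=band_series["delta"],
        theta=band_series["theta"],
        alpha=band_series["alpha"],
        beta=band_series["beta"],
        gamma=band_series["gamma"],
        layer_coefficients=layer_coeffs,
        branches=branches,
        sample_rate_hz=sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# readers


def read_eeg_csv(
    path: str | Path,
    subject_id: str,
    session_time: datetime,
    period: str,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE,
) -> EEGRecording:
    """Read a two-channel recording from CSV (columns sample_index, fp1, fp2)."""
    df = pd.read_csv(path)
    required = {"sample_index", "fp1", "fp2"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("sample_index")
    samples = np.vstack([df["fp1"].to_numpy(float), df["fp2"].to_numpy(float)])
    return EEGRecording(
        subject_id=subject_id,
        session_time=session_time,
        period=period,
        sample_rate_hz=sample_rate_hz,
        channels=CHANNELS,
        samples=samples,
    )


def read_eeg_edf(
    path: str | Path,
    subject_id: str,
    session_time: datetime,
    period: str,
) -> EEGRecording:
    """Read Fp1/Fp2 from an EDF file (channel labels matched case-insensitively)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise MoodQuantError("EDF support requires the mne package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    label_map = {name.lower(): name for name in raw.ch_names}
    picks = []
    for want in CHANNELS:
        if want.lower() not in label_map:
            raise SchemaError(f"{path}: channel {want} not found in {raw.ch_names}")
        picks.append(label_map[want.lower()])
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    return EEGRecording(
        subject_id=subject_id,
        session_time=session_time,
        period=period,
        sample_rate_hz=float(raw.info["sfreq"]),
        channels=CHANNELS,
        samples=data,
    )
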