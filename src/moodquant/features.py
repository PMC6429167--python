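"""The 176-dimensional EEG feature vector.

Per channel and per segment, four blocks are extracted from the six analysis
series (denoised signal + delta/theta/alpha/beta/gamma subbands):

* time domain (54): nine descriptive statistics per series — mean, standard
  deviation, min, max, quartiles (p25/median/p75), excess kurtosis, skewness.
* frequency domain (54): eight Welch-spectrum statistics per series
  (absolute power ``*_psd``, relative power, peak/mean/median frequency,
  95% spectral edge, spectral entropy, PSD maximum) plus six cross-band
  power ratios (beta/theta relative and absolute, theta/alpha, alpha/beta,
  (delta+theta)/(alpha+beta), gamma/beta).
* wavelet (56): eleven statistics of the detail coefficients of layers
  D3..D7 of the denoised signal (``denoised_<stat>_CD<layer>``) plus the
  wavelet entropy of the per-layer energy distribution.
* nonlinear (12): C0 complexity and approximate entropy per series.

``original_<stat>_CD<layer>`` names are registered as aliases of the
``denoised_`` features, because the coefficient layers are computed from
the denoised segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import AggregationError, CatalogError, SchemaError
from .preprocess import (
    BAND_RANGES,
    BANDS,
    DEFAULT_SAMPLE_RATE,
    LAYER_BAND,
    Segment,
    SubbandSet,
    band_of_layer,
    decompose_subbands,
    denoise,
)

logger = logging.getLogger(__name__)

SERIES_NAMES = ("denoised",) + BANDS

TIME_STATS = ("mean", "std", "min", "max", "p25", "median", "p75", "kurtosis", "skewness")
FREQ_STATS = (
    "psd",
    "rel_power",
    "peak_freq",
    "mean_freq",
    "median_freq",
    "sef95",
    "spec_entropy",
    "psd_max",
)
RATIO_FEATURES = (
    "beta_theta_rel_ratio",
    "beta_theta_abs_ratio",
    "theta_alpha_ratio",
    "alpha_beta_ratio",
    "slow_fast_ratio",
    "gamma_beta_ratio",
)
WAVELET_STATS = (
    "mean",
    "std",
    "min",
    "max",
    "median",
    "sum",
    "energy",
    "kurtosis",
    "skewness",
    "max_abs",
    "rel_energy",
)
WAVELET_LAYERS = (3, 4, 5, 6, 7)
NONLINEAR_STATS = ("c0", "apen")

BLOCK_SIZES = {"time": 54, "frequency": 54, "wavelet": 56, "nonlinear": 12}
N_FEATURES = 176

# extraction defaults (exposed through ExtractionParams)
WELCH_NPERSEG = 512  # 1 s at 512 Hz -> 1 Hz resolution
C0_THRESHOLD = 5.0
APEN_M = 2
APEN_R_FRAC = 0.2
APEN_MAX_LEN = 1024


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable parameters of the feature extractor."""

    welch_nperseg: int = WELCH_NPERSEG
    c0_threshold: float = C0_THRESHOLD
    apen_m: int = APEN_M
    apen_r_frac: float = APEN_R_FRAC
    #: ApEn is quadratic in series length; it is computed on at most this
    #: many leading samples of each series.
    apen_max_len: int = APEN_MAX_LEN


# ---------------------------------------------------------------------------
# catalog


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    block: str  # time | frequency | wavelet | nonlinear
    source: str  # series name, 'CD<layer>', or 'all-layers'
    description: str


def _series_phrase(series: str) -> str:
    if series == "denoised":
        return "the denoised signal"
    lo, hi = BAND_RANGES[series]
    return f"the {series} subband ({lo:g}-{hi:g} Hz)"


def _build_catalog() -> dict[str, CatalogEntry]:
    cat: dict[str, CatalogEntry] = {}

    time_desc = {
        "mean": "mean amplitude",
        "std": "standard deviation of amplitude",
        "min": "minimum amplitude",
        "max": "maximum amplitude",
        "p25": "25th percentile of amplitude",
        "median": "median amplitude",
        "p75": "75th percentile of amplitude",
        "kurtosis": "excess kurtosis of amplitude",
        "skewness": "skewness of amplitude",
    }
    for series in SERIES_NAMES:
        for stat in TIME_STATS:
            name = f"{series}_{stat}"
            cat[name] = CatalogEntry(
                name, "time", series, f"{time_desc[stat]} of {_series_phrase(series)}"
            )

    freq_desc = {
        "psd": "absolute Welch power spectral density (integrated power)",
        "rel_power": "power relative to the total denoised power",
        "peak_freq": "frequency of the PSD maximum",
        "mean_freq": "power-weighted mean frequency",
        "median_freq": "median frequency (50% spectral power)",
        "sef95": "95% spectral edge frequency",
        "spec_entropy": "Shannon entropy of the normalized PSD",
        "psd_max": "maximum PSD value",
    }
    for series in SERIES_NAMES:
        for stat in FREQ_STATS:
            name = f"{series}_{stat}"
            cat[name] = CatalogEntry(
                name, "frequency", series, f"{freq_desc[stat]} of {_series_phrase(series)}"
            )
    ratio_desc = {
        "beta_theta_rel_ratio": "ratio of beta to theta relative power",
        "beta_theta_abs_ratio": "ratio of beta to theta absolute power",
        "theta_alpha_ratio": "ratio of theta to alpha power",
        "alpha_beta_ratio": "ratio of alpha to beta power",
        "slow_fast_ratio": "ratio of slow (delta+theta) to fast (alpha+beta) power",
        "gamma_beta_ratio": "ratio of gamma to beta power",
    }
    for name in RATIO_FEATURES:
        cat[name] = CatalogEntry(name, "frequency", "cross-band", ratio_desc[name])

    wav_desc = {
        "mean": "mean",
        "std": "standard deviation",
        "min": "minimum",
        "max": "maximum",
        "median": "median",
        "sum": "sum",
        "energy": "energy (sum of squares)",
        "kurtosis": "excess kurtosis",
        "skewness": "skewness",
        "max_abs": "maximum absolute value",
        "rel_energy": "energy share relative to all eight detail layers",
    }
    for layer in WAVELET_LAYERS:
        band = band_of_layer(layer)
        for stat in WAVELET_STATS:
            name = f"denoised_{stat}_CD{layer}"
            cat[name] = CatalogEntry(
                name,
                "wavelet",
                f"CD{layer}",
                f"{wav_desc[stat]} of the layer-{layer} wavelet detail coefficients "
                f"({_series_phrase(band)})",
            )
    cat["wavelet_entropy"] = CatalogEntry(
        "wavelet_entropy",
        "wavelet",
        "all-layers",
        "Shannon entropy of the normalized per-layer detail energies (layers 1-8)",
    )

    nl_desc = {
        "c0": "C0 complexity (fraction of power outside the dominant spectral components)",
        "apen": "approximate entropy (template-match irregularity, m=2)",
    }
    for series in SERIES_NAMES:
        for stat in NONLINEAR_STATS:
            name = f"{series}_{stat}"
            cat[name] = CatalogEntry(
                name, "nonlinear", series, f"{nl_desc[stat]} of {_series_phrase(series)}"
            )
    return cat


CATALOG: dict[str, CatalogEntry] = _build_catalog()
FEATURE_NAMES: tuple[str, ...] = tuple(CATALOG)
assert len(FEATURE_NAMES) == N_FEATURES

#: Table-style aliases: coefficient layers are computed from the denoised
#: segment, but the `original_` spelling is accepted everywhere names are
#: looked up.
ALIASES: dict[str, str] = {
    f"original_{stat}_CD{layer}": f"denoised_{stat}_CD{layer}"
    for layer in WAVELET_LAYERS
    for stat in WAVELET_STATS
}


def resolve_feature_name(name: str) -> str:
    """Resolve a feature name or alias to its canonical catalog name."""
    canonical = ALIASES.get(name, name)
    if canonical not in CATALOG:
        raise CatalogError(f"unknown feature name {name!r}")
    return canonical


def catalog_frame() -> pd.DataFrame:
    """The full catalog as a DataFrame (name, block, source, description)."""
    return pd.DataFrame([vars(e) for e in CATALOG.values()])


# ---------------------------------------------------------------------------
# feature vector container


@dataclass
class FeatureVector:
    """All 176 named features for one channel of one segment or session."""

    subject_id: str
    session_time: datetime | None
    channel: str
    values: dict[str, float]
    level: str = "segment"  # segment | session
    period: str | None = None
    n_segments: int = 1

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise SchemaError(
                f"feature vector must carry the {N_FEATURES} catalog names in order"
            )
        arr = np.fromiter(self.values.values(), dtype=float, count=N_FEATURES)
        if not np.all(np.isfinite(arr)):
            bad = [n for n, v in self.values.items() if not np.isfinite(v)]
            raise SchemaError(f"non-finite features: {bad[:5]}")

    def as_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=float, count=N_FEATURES)

    def __getitem__(self, name: str) -> float:
        return self.values[resolve_feature_name(name)]


# ---------------------------------------------------------------------------
# block extractors


def time_features(series: np.ndarray) -> dict[str, float]:
    """Nine descriptive time-domain statistics of one series."""
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise SchemaError("time features need at least 4 samples")
    std = float(np.std(x))
    if std == 0.0:
        kurt, skew = 0.0, 0.0  # constant series: higher moments defined as 0
    else:
        kurt = float(sp_stats.kurtosis(x, fisher=True, bias=True))
        skew = float(sp_stats.skew(x, bias=True))
    p25, med, p75 = np.percentile(x, [25, 50, 75])
    return {
        "mean": float(np.mean(x)),
        "std": std,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "p25": float(p25),
        "median": float(med),
        "p75": float(p75),
        "kurtosis": kurt,
        "skewness": skew,
    }


def welch_psd(
    series: np.ndarray,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE,
    nperseg: int = WELCH_NPERSEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with a Hamming modified periodogram.

    1-s windows with 50% overlap by default; windows auto-shrink (with a
    warning) for series shorter than one window.  Integrating the returned
    density recovers the series variance (Parseval, within a few percent).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise SchemaError("empty series")
    if x.size < nperseg:
        logger.warning("series length %d < window %d; shrinking window", x.size, nperseg)
        nperseg = x.size
    freqs, psd = sp_signal.welch(
        x,
        fs=sample_rate_hz,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray) -> float:
    return float(np.trapezoid(psd, freqs))


def _spectral_stats(freqs: np.ndarray, psd: np.ndarray) -> dict[str, float]:
    total = _band_power(freqs, psd)
    if total <= 0:
        return {
            "peak_freq": 0.0,
            "mean_freq": 0.0,
            "median_freq": 0.0,
            "sef95": 0.0,
            "spec_entropy": 0.0,
            "psd_max": 0.0,
        }
    p = psd / psd.sum()
    nz = p[p > 0]
    cum = np.cumsum(psd)
    cum = cum / cum[-1]
    return {
        "peak_freq": float(freqs[int(np.argmax(psd))]),
        "mean_freq": float(np.sum(freqs * psd) / np.sum(psd)),
        "median_freq": float(freqs[int(np.searchsorted(cum, 0.5))]),
        "sef95": float(freqs[int(np.searchsorted(cum, 0.95))]),
        "spec_entropy": float(-np.sum(nz * np.log(nz))),
        "psd_max": float(np.max(psd)),
    }


def freq_features(
    subbands: SubbandSet,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE,
    nperseg: int = WELCH_NPERSEG,
) -> dict[str, float]:
    """54 frequency-domain features: 8 Welch statistics per series + 6 band ratios.

    Relative power is taken against the total denoised power over the union
    of the defined bands (2-64 Hz).
    """
    out: dict[str, float] = {}
    abs_power: dict[str, float] = {}
    f_den, p_den = welch_psd(subbands.denoised, sample_rate_hz, nperseg)
    in_band = (f_den >= 2.0) & (f_den <= 64.0)
    total_denoised = _band_power(f_den[in_band], p_den[in_band])
    for series in SERIES_NAMES:
        freqs, psd = welch_psd(subbands.series(series), sample_rate_hz, nperseg)
        power = _band_power(freqs, psd)
        abs_power[series] = power
        if total_denoised > 0:
            rel = power / total_denoised
        else:
            logger.warning("zero total power; relative powers set to 0")
            rel = 0.0
        out[f"{series}_psd"] = power
        out[f"{series}_rel_power"] = rel
        stats = _spectral_stats(freqs, psd)
        for stat, value in stats.items():
            out[f"{series}_{stat}"] = value

    def ratio(num: float, den: float) -> float:
        if den == 0.0:
            logger.warning("zero denominator in band ratio; defined as 0")
            return 0.0
        return num / den

    rel = {s: out[f"{s}_rel_power"] for s in BANDS}
    out["beta_theta_rel_ratio"] = ratio(rel["beta"], rel["theta"])
    out["beta_theta_abs_ratio"] = ratio(abs_power["beta"], abs_power["theta"])
    out["theta_alpha_ratio"] = ratio(abs_power["theta"], abs_power["alpha"])
    out["alpha_beta_ratio"] = ratio(abs_power["alpha"], abs_power["beta"])
    out["slow_fast_ratio"] = ratio(
        abs_power["delta"] + abs_power["theta"], abs_power["alpha"] + abs_power["beta"]
    )
    out["gamma_beta_ratio"] = ratio(abs_power["gamma"], abs_power["beta"])
    return out


def wavelet_entropy(layer_coefficients: dict[int, np.ndarray]) -> float:
    """Shannon entropy of the normalized per-layer detail energies (layers 1..8)."""
    energies = np.array(
        [float(np.sum(np.square(layer_coefficients[j]))) for j in sorted(layer_coefficients)]
    )
    total = energies.sum()
    if total <= 0:
        logger.warning("all-zero wavelet layers; entropy defined as 0")
        return 0.0
    p = energies / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def wavelet_features(subbands: SubbandSet) -> dict[str, float]:
    """56 wavelet features: 11 coefficient statistics for layers D3..D7 + entropy.

    Energy shares are normalized against all eight detail layers, so the
    shares of D3..D7 sum to at most 1.
    """
    missing = [j for j in WAVELET_LAYERS if j not in subbands.layer_coefficients]
    if missing:
        raise SchemaError(f"missing wavelet layers {missing}")
    all_energy = sum(
        float(np.sum(np.square(c))) for c in subbands.layer_coefficients.values()
    )
    out: dict[str, float] = {}
    for layer in WAVELET_LAYERS:
        c = np.asarray(subbands.layer_coefficients[layer], dtype=float)
        std = float(np.std(c))
        if std == 0.0:
            kurt, skew = 0.0, 0.0
        else:
            kurt = float(sp_stats.kurtosis(c, fisher=True, bias=True))
            skew = float(sp_stats.skew(c, bias=True))
        energy = float(np.sum(np.square(c)))
        out[f"denoised_mean_CD{layer}"] = float(np.mean(c))
        out[f"denoised_std_CD{layer}"] = std
        out[f"denoised_min_CD{layer}"] = float(np.min(c))
        out[f"denoised_max_CD{layer}"] = float(np.max(c))
        out[f"denoised_median_CD{layer}"] = float(np.median(c))
        out[f"denoised_sum_CD{layer}"] = float(np.sum(c))
        out[f"denoised_energy_CD{layer}"] = energy
        out[f"denoised_kurtosis_CD{layer}"] = kurt
        out[f"denoised_skewness_CD{layer}"] = skew
        out[f"denoised_max_abs_CD{layer}"] = float(np.max(np.abs(c)))
        out[f"denoised_rel_energy_CD{layer}"] = (
            energy / all_energy if all_energy > 0 else 0.0
        )
    out["wavelet_entropy"] = wavelet_entropy(subbands.layer_coefficients)
    return out


def c0_complexity(series: np.ndarray, spectral_threshold_r: float = C0_THRESHOLD) -> float:
    """C0 complexity: fraction of signal power outside the dominant spectrum.

    Spectral components whose squared magnitude is at most ``r`` times the
    mean squared magnitude are zeroed; the inverse transform of the survivors
    is the regular part, and C0 is the power of the irregular remainder over
    the total power.  0 for a pure periodic signal, approaching 1 for
    broadband noise.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise SchemaError("C0 complexity needs at least 64 samples")
    F = np.fft.fft(x)
    mag2 = np.abs(F) ** 2
    mean_mag2 = mag2.mean()
    if mean_mag2 == 0.0:
        logger.warning("zero-power series; C0 defined as 0")
        return 0.0
    keep = mag2 > spectral_threshold_r * mean_mag2
    regular = np.fft.ifft(np.where(keep, F, 0.0)).real
    resid_power = float(np.sum((x - regular) ** 2))
    total_power = float(np.sum(x**2))
    return resid_power / total_power


def approximate_entropy(
    series: np.ndarray,
    m: int = APEN_M,
    r_frac: float = APEN_R_FRAC,
    max_len: int | None = APEN_MAX_LEN,
) -> float:
    """Approximate entropy ApEn(m, r) with r = r_frac * std(series).

    Standard template-match formulation: Chebyshev distance, self-matches
    included, ApEn = Phi_m - Phi_{m+1}.  Quadratic in series length, so the
    computation is restricted to the first ``max_len`` samples.
    """
    x = np.asarray(series, dtype=float)
    if max_len is not None and x.size > max_len:
        x = x[:max_len]
    n = x.size
    if n < 50:
        raise SchemaError("approximate entropy needs at least 50 samples")
    if m < 1:
        raise SchemaError("m must be >= 1")
    sd = float(np.std(x))
    if sd == 0.0:
        logger.warning("constant series; ApEn defined as 0")
        return 0.0
    r = r_frac * sd

    # Chebyshev template matches as ANDs of the single-sample match matrix:
    # templates (i, j) of length mm match iff B[i+k, j+k] for all k < mm.
    B = np.abs(x[:, None] - x[None, :]) <= r

    def counts_from(W: np.ndarray) -> float:
        n_vec = W.shape[0]
        counts = np.count_nonzero(W, axis=1)
        return float(np.mean(np.log(counts / n_vec)))

    W = B[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        W &= B[k : k + n - m + 1, k : k + n - m + 1]
    phi_m = counts_from(W)
    n_vec1 = n - m
    W1 = W[:n_vec1, :n_vec1] & B[m : m + n_vec1, m : m + n_vec1]
    phi_m1 = counts_from(W1)
    return phi_m - phi_m1


# ---------------------------------------------------------------------------
# per-segment extraction and session aggregation


def extract_segment_features(
    seg: Segment,
    subject_id: str = "",
    session_time: datetime | None = None,
    period: str | None = None,
    params: ExtractionParams = ExtractionParams(),
) -> FeatureVector:
    """Run the full pipeline on one segment: denoise, decompose, all four blocks."""
    den = denoise(seg)
    subbands = decompose_subbands(den, seg.sample_rate_hz)
    values: dict[str, float] = {}
    for series in SERIES_NAMES:
        s = subbands.series(series)
        for stat, v in time_features(s).items():
            values[f"{series}_{stat}"] = v
    values.update(freq_features(subbands, seg.sample_rate_hz, params.welch_nperseg))
    values.update(wavelet_features(subbands))
    for series in SERIES_NAMES:
        s = subbands.series(series)
        values[f"{series}_c0"] = c0_complexity(s, params.c0_threshold)
        values[f"{series}_apen"] = approximate_entropy(
            s, params.apen_m, params.apen_r_frac, params.apen_max_len
        )
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(
        subject_id=subject_id,
        session_time=session_time,
        channel=seg.channel,
        values=ordered,
        level="segment",
        period=period,
    )


def aggregate_session(segment_vectors: list[FeatureVector]) -> FeatureVector:
    """Element-wise mean of segment vectors from one channel of one session."""
    if not segment_vectors:
        raise AggregationError("no segment vectors to aggregate")
    first = segment_vectors[0]
    for v in segment_vectors[1:]:
        if v.channel != first.channel or v.session_time != first.session_time:
            raise AggregationError("segments mix channels or sessions")
    mat = np.vstack([v.as_array() for v in segment_vectors])
    mean = mat.mean(axis=0)
    values = dict(zip(FEATURE_NAMES, mean.tolist()))
    return replace(
        first, values=values, level="session", n_segments=len(segment_vectors)
    )


# ---------------------------------------------------------------------------
# tabular export


def vectors_to_wide(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per subject-session-channel, 176 feature columns in catalog order."""
    rows = []
    for v in vectors:
        row = {
            "subject": v.subject_id,
            "session_time": v.session_time,
            "period": v.period,
            "channel": v.channel,
            "level": v.level,
        }
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows)


def wide_to_vectors(df: pd.DataFrame) -> list[FeatureVector]:
    """Rebuild FeatureVector objects from a wide feature table."""
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"wide table missing feature columns: {missing[:5]}")
    out = []
    for _, row in df.iterrows():
        t = row.get("session_time")
        if isinstance(t, str):
            t = pd.Timestamp(t).to_pydatetime()
        out.append(
            FeatureVector(
                subject_id=str(row["subject"]),
                session_time=t,
                channel=str(row["channel"]),
                values={n: float(row[n]) for n in FEATURE_NAMES},
                level=str(row.get("level", "session")),
                period=row.get("period"),
            )
        )
    return out


def vectors_to_long(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long format: one row per (subject, session, channel, feature)."""
    wide = vectors_to_wide(vectors)
    return wide.melt(
        id_vars=["subject", "session_time", "period", "channel", "level"],
        var_name="feature_name",
        value_name="value",
    )
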