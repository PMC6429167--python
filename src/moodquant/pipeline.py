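"""End-to-end orchestration helpers.

Glue between the stages: segment + extract every recording to session-level
feature vectors, derive per-subject FPC curves from the diaries, pair the
two and evaluate the forest.  The CLI subcommands and the example scripts
are thin wrappers over these functions.
"""

from __future__ import annotations

import logging

from .features import ExtractionParams, FeatureVector, aggregate_session, extract_segment_features
from .model import EvalResult, PairedDataset, build_dataset, lopocv
from .preprocess import EEGRecording, segment
from .qlog import FPCCurve, fpc_curve
from .synthetic import Cohort

logger = logging.getLogger(__name__)


def extract_recording_features(
    recording: EEGRecording,
    segment_len_s: float = 10.0,
    params: ExtractionParams = ExtractionParams(),
) -> list[FeatureVector]:
    """Session-level feature vectors (one per channel) for a recording.

    Each channel is segmented with 50% overlap, every segment yields a
    176-feature vector, and segment vectors are averaged per channel.
    """
    segments = segment(recording, segment_len_s)
    by_channel: dict[str, list] = {}
    for seg in segments:
        by_channel.setdefault(seg.channel, []).append(seg)
    out = []
    for channel, segs in by_channel.items():
        vectors = [
            extract_segment_features(
                s,
                subject_id=recording.subject_id,
                session_time=recording.session_time,
                period=recording.period,
                params=params,
            )
            for s in segs
        ]
        out.append(aggregate_session(vectors))
    return out


def extract_cohort_features(
    cohort: Cohort,
    segment_len_s: float = 10.0,
    params: ExtractionParams = ExtractionParams(),
) -> list[FeatureVector]:
    """Session-level vectors for every recording in a cohort."""
    vectors: list[FeatureVector] = []
    for key in sorted(cohort.recordings):
        vectors.extend(
            extract_recording_features(cohort.recordings[key], segment_len_s, params)
        )
    return vectors


def cohort_fpc_curves(cohort: Cohort) -> dict[str, FPCCurve]:
    """Per-subject FPC curves from the cohort's diaries."""
    return {sid: fpc_curve(entries) for sid, entries in cohort.qlog_entries.items()}


def evaluate_cohort(
    cohort: Cohort,
    ntree: int,
    mtry: int,
    seed: int,
    segment_len_s: float = 10.0,
    channel_mode: str = "concat",
    params: ExtractionParams = ExtractionParams(),
) -> tuple[PairedDataset, EvalResult]:
    """Full pipeline on a synthetic cohort: extract, pair, LOPOCV-evaluate."""
    vectors = extract_cohort_features(cohort, segment_len_s, params)
    curves = cohort_fpc_curves(cohort)
    dataset = build_dataset(vectors, curves, channel_mode=channel_mode)
    result = lopocv(dataset, ntree, mtry, seed)
    return dataset, result
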