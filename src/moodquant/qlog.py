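"""Q-Log diary handling and the first-principal-component (FPC) mood curve.

Each diary entry scores the 40 mood adjectives on a 1-100 slider.  For one
subject the entries form a sessions x 40 matrix; the FPC curve is the
projection of the column-centered matrix onto the leading principal axis.
Items share the 1-100 scale, so columns are centered but not
variance-scaled.  The eigenvector sign is fixed so that the mean loading
over the depression-dejection items is non-negative: a higher FPC value
means a more depressed state, and a declining curve means amelioration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import (
    ClassificationError,
    DegeneratePCAError,
    SchemaError,
    ValidationError,
)
from .items import ITEM_NAMES, N_ITEMS, depression_item_indices

logger = logging.getLogger(__name__)

ITEM_COLUMNS = tuple(f"item_{i + 1:02d}" for i in range(N_ITEMS))
WEEK = timedelta(days=7)


@dataclass
class QLogEntry:
    """One diary entry: 40 integer scores in [1, 100] at one session."""

    subject_id: str
    timestamp: datetime
    period: str  # morning | evening
    scores: np.ndarray  # 40 ints

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (N_ITEMS,):
            raise SchemaError(f"expected {N_ITEMS} scores, got {self.scores.shape}")
        if np.any(self.scores < 1) or np.any(self.scores > 100):
            raise ValidationError(
                f"{self.subject_id} @ {self.timestamp}: scores outside [1, 100]"
            )
        if self.period not in ("morning", "evening"):
            raise SchemaError(f"period must be morning|evening, got {self.period!r}")


@dataclass
class FPCCurve:
    """Per-subject FPC mood values with the unit-norm loading vector."""

    subject_id: str
    session_times: list[datetime]
    values: np.ndarray
    loading_vector: np.ndarray  # 40 reals, |.| = 1
    explained_variance_ratio: float
    periods: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.loading_vector = np.asarray(self.loading_vector, dtype=float)
        if len(self.values) != len(self.session_times):
            raise SchemaError("values and session_times must align")
        if abs(np.linalg.norm(self.loading_vector) - 1.0) > 1e-9:
            raise SchemaError("loading vector must have unit norm")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"session_time": self.session_times, "fpc_value": self.values}
        )
        if self.periods is not None:
            df.insert(1, "period", self.periods)
        return df


def load_qlog(path: str | Path, subject_id: str | None = None) -> list[QLogEntry]:
    """Read one subject's diary CSV (timestamp, period, item_01..item_40).

    Entries are validated (40 items, scores in [1, 100]) and returned in
    chronological order regardless of file order.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    df = pd.read_csv(path)
    missing = [c for c in ("timestamp", "period", *ITEM_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing[:5]}")
    scores = df[list(ITEM_COLUMNS)].to_numpy()
    bad = np.argwhere((scores < 1) | (scores > 100))
    if bad.size:
        rows = sorted(set(int(r) for r, _ in bad))
        raise ValidationError(f"{path}: scores outside [1, 100] in rows {rows[:10]}")
    entries = [
        QLogEntry(
            subject_id=subject_id,
            timestamp=pd.Timestamp(row["timestamp"]).to_pydatetime(),
            period=str(row["period"]),
            scores=scores[i],
        )
        for i, (_, row) in enumerate(df.iterrows())
    ]
    entries.sort(key=lambda e: e.timestamp)
    return entries


def entries_matrix(entries: list[QLogEntry]) -> np.ndarray:
    """Stack one subject's entries into a sessions x 40 score matrix."""
    return np.vstack([e.scores.astype(float) for e in entries])


def fpc_curve(entries: list[QLogEntry]) -> FPCCurve:
    """First-principal-component mood curve of one subject's diary.

    The sessions x 40 matrix is column-centered and projected onto the top
    eigenvector of its covariance.  The FPC values therefore have mean zero;
    the sign is fixed so the mean depression-item loading is >= 0.
    """
    if len(entries) < 3:
        raise SchemaError("FPC needs at least 3 entries")
    entries = sorted(entries, key=lambda e: e.timestamp)
    X = entries_matrix(entries)
    if np.allclose(X, X[0]):
        raise DegeneratePCAError("constant diary matrix has no principal direction")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    loading = pca.components_[0]
    if float(np.mean(loading[depression_item_indices()])) < 0:
        loading = -loading
        scores = -scores
    return FPCCurve(
        subject_id=entries[0].subject_id,
        session_times=[e.timestamp for e in entries],
        values=scores,
        loading_vector=loading,
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
        periods=[e.period for e in entries],
    )


def _week_index(t: datetime, t0: datetime) -> int:
    return int((t - t0) // WEEK)


def diurnal_summary(
    curve: FPCCurve, periods: list[str] | None = None
) -> pd.DataFrame:
    """Per-week morning mean, evening mean and morning-evening FPC difference.

    Weeks are 7 x 24 h blocks from the subject's first session.  A week
    missing either period gets NaN in that cell.
    """
    if periods is None:
        periods = curve.periods
    if periods is None or len(periods) != len(curve.values):
        raise SchemaError("periods must align with curve values")
    t0 = curve.session_times[0]
    df = pd.DataFrame(
        {
            "week": [_week_index(t, t0) + 1 for t in curve.session_times],
            "period": periods,
            "value": curve.values,
        }
    )
    out = []
    for week, grp in df.groupby("week"):
        morning = grp.loc[grp["period"] == "morning", "value"]
        evening = grp.loc[grp["period"] == "evening", "value"]
        m = float(morning.mean()) if len(morning) else np.nan
        e = float(evening.mean()) if len(evening) else np.nan
        out.append(
            {
                "week": int(week),
                "morning_mean": m,
                "evening_mean": e,
                "difference": m - e,
            }
        )
    return pd.DataFrame(out)


def trend_classification(curve: FPCCurve) -> str:
    """Classify the two-week FPC trajectory as declined / rebounded / other.

    A least-squares slope is fitted per week on (session order, value).
    declined: slope1 < 0 and slope2 <= 0; rebounded: slope1 < 0 and
    slope2 > 0; anything else is "other".
    """
    t0 = curve.session_times[0]
    weeks: dict[int, list[tuple[int, float]]] = {}
    for i, (t, v) in enumerate(zip(curve.session_times, curve.values)):
        weeks.setdefault(_week_index(t, t0), []).append((i, float(v)))
    if sorted(weeks) != [0, 1]:
        raise ClassificationError(
            f"need sessions in both weeks, got weeks {sorted(w + 1 for w in weeks)}"
        )
    slopes = []
    for w in (0, 1):
        pts = weeks[w]
        if len(pts) < 2:
            raise ClassificationError(f"week {w + 1} has fewer than 2 sessions")
        xs = np.array([p[0] for p in pts], dtype=float)
        ys = np.array([p[1] for p in pts], dtype=float)
        slope = float(np.polyfit(xs, ys, 1)[0])
        scale = max(float(np.max(np.abs(ys))), 1.0)
        if abs(slope) < 1e-12 * scale:  # numerically flat
            slope = 0.0
        slopes.append(slope)
    s1, s2 = slopes
    if s1 < 0 and s2 <= 0:
        return "declined"
    if s1 < 0 and s2 > 0:
        return "rebounded"
    return "other"


def write_fpc_csv(curve: FPCCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)
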