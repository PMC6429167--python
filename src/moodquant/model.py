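"""Random-forest regression from EEG features to FPC mood values.

The forest is trained per Leave-One-Participant-Out Cross-Validation
(LOPOCV) fold: all sessions of one subject are held out, a forest of
``ntree`` trees (each split drawn from ``mtry`` candidate features) is
grown to full depth on the remaining subjects, and the held-out subject's
predictions are scored by Pearson correlation with the observed FPC values
plus a two-sided t-test p value.  Hyper-parameters are selected on a
(ntree, mtry) grid by maximum mean correlation across folds.

Features are z-scored with statistics fitted on the training partition of
each fold; the standardizer travels with the model, so rule thresholds are
expressed on the standardized scale.

Trees are fitted with scikit-learn and then flattened into plain arrays
(split feature name, threshold, children, leaf value) that this module and
the rule exporter both traverse, keeping prediction and rule application
bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestRegressor

from .errors import (
    AlignmentError,
    ParameterError,
    SchemaError,
    UndefinedCorrelationError,
)
from .features import FEATURE_NAMES, FeatureVector
from .qlog import FPCCurve

logger = logging.getLogger(__name__)

CHANNEL_MODES = ("concat", "fp1", "fp2", "mean")

# hyper-parameter grid: ntree 1..500 step 10, mtry 1..100 step 5
NTREE_GRID = tuple(range(1, 501, 10))  # 1, 11, ..., 491 (50 values)
MTRY_GRID = tuple(range(1, 101, 5))  # 1, 6, ..., 96 (20 values)
#: reduced grid for fast runs; strictly a subset of the full grid cells
REDUCED_NTREE_GRID = (1, 101, 241)
REDUCED_MTRY_GRID = (1, 16, 66)


@dataclass
class Standardizer:
    """Per-feature z-score parameters fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class TreeStruct:
    """A fitted regression tree flattened to parallel arrays.

    ``feature[i] < 0`` marks a leaf; internal nodes send ``x <= threshold``
    left and ``x > threshold`` right.
    """

    feature: np.ndarray  # int, -1 for leaves
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while self.feature[node] >= 0:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.left[node]
            else:
                node = self.right[node]
        return float(self.value[node])


@dataclass
class QuantModel:
    """Trained forest + standardizer; the unit the rule exporter consumes."""

    ntree: int
    mtry: int
    trees: list[TreeStruct]
    standardizer: Standardizer
    feature_names: tuple[str, ...]
    seed: int
    bootstrap: bool = True
    channel_mode: str = "concat"

    def predict(self, rows: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Mean of per-tree leaf values, after standardization."""
        X = self._as_matrix(rows)
        Xs = self.standardizer.transform(X)
        preds = np.array(
            [[t.predict_one(x) for t in self.trees] for x in Xs]
        )
        return preds.mean(axis=1)

    def _as_matrix(self, rows: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(rows, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in rows.columns]
            if missing:
                raise SchemaError(f"rows missing features: {missing[:5]}")
            return rows[list(self.feature_names)].to_numpy(float)
        X = np.atleast_2d(np.asarray(rows, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    # --- JSON round trip -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "ntree": self.ntree,
            "mtry": self.mtry,
            "seed": self.seed,
            "bootstrap": self.bootstrap,
            "channel_mode": self.channel_mode,
            "feature_names": list(self.feature_names),
            "standardizer": {
                "mean": self.standardizer.mean.tolist(),
                "sd": self.standardizer.sd.tolist(),
            },
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QuantModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        trees = [
            TreeStruct(
                feature=np.asarray(t["feature"], dtype=int),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=int),
                right=np.asarray(t["right"], dtype=int),
                value=np.asarray(t["value"], dtype=float),
            )
            for t in doc["trees"]
        ]
        return cls(
            ntree=doc["ntree"],
            mtry=doc["mtry"],
            trees=trees,
            standardizer=Standardizer(
                mean=np.asarray(doc["standardizer"]["mean"], dtype=float),
                sd=np.asarray(doc["standardizer"]["sd"], dtype=float),
            ),
            feature_names=tuple(doc["feature_names"]),
            seed=doc["seed"],
            bootstrap=doc["bootstrap"],
            channel_mode=doc["channel_mode"],
        )


@dataclass
class PairedDataset:
    """Feature rows aligned to FPC values, keyed by (subject, session_time)."""

    X: pd.DataFrame  # one row per session, feature columns
    y: np.ndarray
    subjects: np.ndarray  # subject id per row
    session_times: list[datetime]
    channel_mode: str
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


@dataclass
class EvalResult:
    """Per-fold LOPOCV scores in the shape of the evaluation table."""

    folds: pd.DataFrame  # patient, TrS, TeS, CC, p_value
    mean_cc: float
    sd_cc: float
    mean_p: float
    skipped: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.folds.to_csv(path, index=False)


def build_dataset(
    session_vectors: list[FeatureVector],
    curves: dict[str, FPCCurve],
    channel_mode: str = "concat",
) -> PairedDataset:
    """Align session-level feature vectors with FPC values.

    ``concat`` stacks Fp1 and Fp2 into 352 columns (prefixes ``fp1__`` /
    ``fp2__``); ``fp1``/``fp2`` keep one channel (176 columns); ``mean``
    averages the channels.  Sessions without a matching diary entry (or a
    missing channel) are dropped with a warning count.
    """
    if channel_mode not in CHANNEL_MODES:
        raise ParameterError(f"channel_mode must be one of {CHANNEL_MODES}")
    by_key: dict[tuple[str, datetime], dict[str, FeatureVector]] = {}
    for v in session_vectors:
        by_key.setdefault((v.subject_id, v.session_time), {})[v.channel.lower()] = v

    fpc_lookup: dict[tuple[str, datetime], float] = {}
    for sid, curve in curves.items():
        for t, val in zip(curve.session_times, curve.values):
            fpc_lookup[(sid, t)] = float(val)

    rows, ys, subjects, times = [], [], [], []
    n_dropped = 0
    for key in sorted(by_key, key=lambda k: (k[0], k[1])):
        chans = by_key[key]
        if key not in fpc_lookup:
            n_dropped += 1
            continue
        if channel_mode == "concat":
            if "fp1" not in chans or "fp2" not in chans:
                n_dropped += 1
                continue
            row = {
                f"fp1__{n}": v for n, v in chans["fp1"].values.items()
            }
            row.update({f"fp2__{n}": v for n, v in chans["fp2"].values.items()})
        elif channel_mode in ("fp1", "fp2"):
            if channel_mode not in chans:
                n_dropped += 1
                continue
            row = dict(chans[channel_mode].values)
        else:  # mean
            if "fp1" not in chans or "fp2" not in chans:
                n_dropped += 1
                continue
            a, b = chans["fp1"].as_array(), chans["fp2"].as_array()
            row = dict(zip(FEATURE_NAMES, ((a + b) / 2.0).tolist()))
        rows.append(row)
        ys.append(fpc_lookup[key])
        subjects.append(key[0])
        times.append(key[1])
    if not rows:
        raise AlignmentError("no feature rows could be matched to FPC values")
    if n_dropped:
        logger.warning("dropped %d unmatched sessions", n_dropped)
    return PairedDataset(
        X=pd.DataFrame(rows),
        y=np.asarray(ys, dtype=float),
        subjects=np.asarray(subjects, dtype=object),
        session_times=times,
        channel_mode=channel_mode,
        n_dropped=n_dropped,
    )


def train_rf(
    X: pd.DataFrame,
    y: np.ndarray,
    ntree: int,
    mtry: int,
    seed: int,
    bootstrap: bool = True,
    channel_mode: str = "concat",
) -> QuantModel:
    """Grow ``ntree`` full-depth trees on bootstrap resamples, ``mtry``
    candidate features per split, on z-scored training rows."""
    feature_names = tuple(X.columns)
    n_features = len(feature_names)
    if ntree < 1:
        raise ParameterError("ntree must be >= 1")
    if not 1 <= mtry <= n_features:
        raise ParameterError(f"mtry must be in 1..{n_features}, got {mtry}")
    if len(X) < 5:
        raise ParameterError("need at least 5 training rows")
    standardizer = Standardizer.fit(X.to_numpy(float))
    Xs = standardizer.transform(X.to_numpy(float))
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        bootstrap=bootstrap,
        random_state=int(seed) & 0x7FFFFFFF,
        min_samples_split=2,
        min_samples_leaf=1,
    )
    rf.fit(Xs, np.asarray(y, dtype=float))
    trees = []
    for est in rf.estimators_:
        t = est.tree_
        trees.append(
            TreeStruct(
                feature=t.feature.copy(),
                threshold=t.threshold.copy(),
                left=t.children_left.copy(),
                right=t.children_right.copy(),
                value=t.value[:, 0, 0].copy(),
            )
        )
    return QuantModel(
        ntree=ntree,
        mtry=mtry,
        trees=trees,
        standardizer=standardizer,
        feature_names=feature_names,
        seed=int(seed),
        bootstrap=bootstrap,
        channel_mode=channel_mode,
    )


def predict(model: QuantModel, rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Forest prediction: standardize, then average the trees' leaf values."""
    return model.predict(rows)


def pearson_r_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p value.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(sp_stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def lopocv(
    dataset: PairedDataset,
    ntree: int,
    mtry: int,
    seed: int,
    bootstrap: bool = True,
) -> EvalResult:
    """Leave-One-Participant-Out CV: one fold per subject, sorted by id.

    Subjects with fewer than 3 sessions are skipped with a warning, since
    their fold correlation would be undefined.
    """
    subject_ids = sorted(set(dataset.subjects))
    if len(subject_ids) < 2:
        raise ParameterError("LOPOCV needs at least 2 subjects")
    rows = []
    skipped: list[str] = []
    total = dataset.n_rows
    for sid in subject_ids:
        test_mask = dataset.subjects == sid
        n_test = int(test_mask.sum())
        if n_test < 3:
            logger.warning("skipping subject %s: only %d sessions", sid, n_test)
            skipped.append(sid)
            continue
        X_train = dataset.X.loc[~test_mask]
        y_train = dataset.y[~test_mask]
        X_test = dataset.X.loc[test_mask]
        y_test = dataset.y[test_mask]
        m = train_rf(
            X_train, y_train, ntree, mtry, seed,
            bootstrap=bootstrap, channel_mode=dataset.channel_mode,
        )
        y_pred = m.predict(X_test)
        try:
            r, p = pearson_r_pvalue(y_pred, y_test)
        except UndefinedCorrelationError:
            logger.warning("constant predictions for subject %s; CC set to 0", sid)
            r, p = 0.0, 1.0
        rows.append(
            {
                "patient": sid,
                "TrS": total - n_test,
                "TeS": n_test,
                "CC": r,
                "p_value": p,
            }
        )
    folds = pd.DataFrame(rows)
    return EvalResult(
        folds=folds,
        mean_cc=float(folds["CC"].mean()),
        sd_cc=float(folds["CC"].std(ddof=1)) if len(folds) > 1 else 0.0,
        mean_p=float(folds["p_value"].mean()),
        skipped=skipped,
    )


def grid_search(
    dataset: PairedDataset,
    seed: int,
    ntree_values: tuple[int, ...] | None = None,
    mtry_values: tuple[int, ...] | None = None,
    reduced: bool = False,
    bootstrap: bool = True,
) -> tuple[int, int, pd.DataFrame]:
    """Hyper-parameter grid search by mean LOPOCV correlation.

    The full grid spans ntree 1..491 step 10 and mtry 1..96 step 5; the
    reduced grid is a subset of those cells for fast runs.  The winner is
    the cell with maximum mean CC; ties break by minimum mean p, then
    smaller ntree, then smaller mtry.  The full grid table is returned for
    mesh plotting.
    """
    if ntree_values is None:
        ntree_values = REDUCED_NTREE_GRID if reduced else NTREE_GRID
    if mtry_values is None:
        mtry_values = REDUCED_MTRY_GRID if reduced else MTRY_GRID
    p_feat = len(dataset.feature_names)
    mtry_values = tuple(m for m in mtry_values if m <= p_feat)
    if not mtry_values:
        raise ParameterError("no mtry value fits the feature count")
    records = []
    best = None  # (-mean_cc, mean_p, ntree, mtry)
    for ntree in ntree_values:
        for mtry in mtry_values:
            res = lopocv(dataset, ntree, mtry, seed, bootstrap=bootstrap)
            records.append(
                {
                    "ntree": ntree,
                    "mtry": mtry,
                    "mean_cc": res.mean_cc,
                    "mean_p": res.mean_p,
                }
            )
            key = (-res.mean_cc, res.mean_p, ntree, mtry)
            if best is None or key < best:
                best = key
    grid = pd.DataFrame(records)
    return best[2], best[3], grid
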