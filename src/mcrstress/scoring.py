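"""Standardized performance scores and per-subject performance planes.

Trial features are turned into z-scores against healthy-training reference
statistics, oriented so that higher is always better, combined into one
composite score per difficulty cell, and arranged as a performance plane over
the motor x cognitive grid.

Standardization basis: gait features are referenced to the healthy training
group's baseline (no-challenge) walk; cognitive features to the easiest
cognitive-focused cell (0, 1); obstacle success to the easiest motor-focused
cell (1, 0).  Standardizing against the easiest condition (rather than per
cell) preserves the visible decline of the healthy plane with difficulty.
Sample (n-1) standard deviations are used throughout because the reference
groups are small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ComputationError, CoverageError, DomainError
from .protocol import DifficultyGrid, build_default_grid

GAIT_FEATURES = (
    "step_length_mean_cm",
    "step_length_sd_cm",
    "gyro_amp_midswing",
    "gait_asymmetry_pct",
)
COGNITIVE_FEATURES = ("cognitive_accuracy", "reaction_time_s")
OBSTACLE_FEATURES = ("obstacle_success",)
ALL_FEATURES = GAIT_FEATURES + COGNITIVE_FEATURES + OBSTACLE_FEATURES

#: Sign per feature such that the oriented z-score is higher-is-better.
DEFAULT_ORIENTATION = {
    "cognitive_accuracy": +1,
    "reaction_time_s": -1,
    "obstacle_success": +1,
    "step_length_mean_cm": +1,
    "step_length_sd_cm": -1,
    "gyro_amp_midswing": +1,
    "gait_asymmetry_pct": -1,
}

#: Reference cell per feature family for standardization.
_REFERENCE_CELLS = {
    "gait": (0, 0),
    "cognitive": (0, 1),
    "obstacle": (1, 0),
}


@dataclass(frozen=True)
class BaselineStats:
    """Per-feature reference mean and sample SD from healthy training subjects."""

    mean: dict
    sd: dict

    @property
    def features(self) -> tuple:
        return tuple(self.mean)

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BaselineStats":
        payload = json.loads(text)
        return cls(mean=dict(payload["mean"]), sd=dict(payload["sd"]))


def _reference_records(trials: pd.DataFrame, cell: tuple) -> pd.DataFrame:
    m, c = cell
    return trials[(trials["motor_level"] == m) & (trials["cognitive_level"] == c)]


def fit_baseline_stats(trials: pd.DataFrame, healthy_train_ids,
                       sd_tol: float = 1e-9) -> BaselineStats:
    """Fit reference means/SDs from the healthy training subjects only.

    Raises on an empty reference set and on any zero-variance feature, since
    a degenerate SD would make the z-scores meaningless.
    """
    ids = set(healthy_train_ids)
    subset = trials[trials["subject_id"].isin(ids)]
    if subset.empty:
        raise ComputationError("no reference records: healthy training set is empty")
    families = (
        (GAIT_FEATURES, _REFERENCE_CELLS["gait"]),
        (COGNITIVE_FEATURES, _REFERENCE_CELLS["cognitive"]),
        (OBSTACLE_FEATURES, _REFERENCE_CELLS["obstacle"]),
    )
    mean, sd = {}, {}
    for features, cell in families:
        records = _reference_records(subset, cell)
        for feature in features:
            if feature not in subset.columns:
                continue
            values = records[feature].dropna().to_numpy(dtype=float)
            if values.size == 0:
                raise ComputationError(
                    f"no reference records for feature {feature!r} at cell {cell}"
                )
            feature_sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
            if feature_sd <= sd_tol:
                raise ComputationError(
                    f"zero-variance reference for feature {feature!r}"
                )
            mean[feature] = float(np.mean(values))
            sd[feature] = feature_sd
    return BaselineStats(mean=mean, sd=sd)


def standardize_feature(value: float, feature: str, stats: BaselineStats,
                        orient: dict | None = None) -> float:
    """Oriented z-score: sign * (value - mean) / SD."""
    orient = DEFAULT_ORIENTATION if orient is None else orient
    if feature not in stats.mean:
        raise DomainError(f"unknown feature {feature!r}: not in baseline stats")
    sign = orient.get(feature, +1)
    return sign * (value - stats.mean[feature]) / stats.sd[feature]


def cell_score(oriented_zs, weights=None) -> float:
    """Weighted mean of the available oriented z-scores (equal weights default).

    Missing (NaN) entries are dropped together with their weights; if every
    feature is missing the cell is marked missing (NaN).
    """
    zs = np.asarray(oriented_zs, dtype=float)
    if weights is None:
        w = np.ones_like(zs)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != zs.shape:
            raise DomainError("weights must match the z-score vector")
        if np.any(w < 0):
            raise DomainError("weights must be non-negative")
    keep = np.isfinite(zs)
    if not keep.any() or w[keep].sum() == 0:
        return float("nan")
    return float(np.average(zs[keep], weights=w[keep]))


@dataclass(frozen=True)
class PerformancePlane:
    """Per-subject composite scores over the difficulty grid (NaN = uncovered)."""

    subject_id: str
    scores: np.ndarray
    mask: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.scores.shape

    def is_complete(self) -> bool:
        return bool(self.mask.all())


def _features_for_cell(m: int, c: int) -> tuple:
    if m == 0 and c == 0:
        return GAIT_FEATURES
    features = list(GAIT_FEATURES)
    if c > 0:
        features.extend(COGNITIVE_FEATURES)
    if m > 0:
        features.extend(OBSTACLE_FEATURES)
    return tuple(features)


def _record_score(record, features, stats, orient, weights) -> float:
    zs, ws = [], []
    for feature in features:
        value = record.get(feature, np.nan)
        if pd.isna(value):
            zs.append(np.nan)
        else:
            zs.append(standardize_feature(float(value), feature, stats, orient))
        ws.append(1.0 if weights is None else weights.get(feature, 1.0))
    return cell_score(zs, ws)


def build_plane(subject_trials: pd.DataFrame, stats: BaselineStats,
                orient: dict | None = None, grid: DifficultyGrid | None = None,
                weights: dict | None = None, impute: bool = False) -> PerformancePlane:
    """Build one subject's performance plane from their trial records.

    Each record is scored as the composite of its applicable oriented
    z-scores; repeated cells are averaged at the score level.  The (0, 0)
    cell is scored from the baseline walk's gait features only.  Uncovered
    cells raise :class:`CoverageError` unless nearest-neighbour imputation is
    requested.
    """
    grid = grid or build_default_grid()
    orient = DEFAULT_ORIENTATION if orient is None else orient
    subject_ids = subject_trials["subject_id"].unique()
    if len(subject_ids) != 1:
        raise DomainError("build_plane expects the trials of exactly one subject")
    subject_id = str(subject_ids[0])

    n_m, n_c = grid.shape
    scores = np.full((n_m, n_c), np.nan)
    for (m, c), cell_records in subject_trials.groupby(["motor_level", "cognitive_level"]):
        if not (0 <= m < n_m and 0 <= c < n_c):
            raise DomainError(f"trial cell ({m}, {c}) outside grid {grid.shape}")
        features = _features_for_cell(m, c)
        record_scores = [
            _record_score(record, features, stats, orient, weights)
            for record in cell_records.to_dict(orient="records")
        ]
        record_scores = [s for s in record_scores if np.isfinite(s)]
        if record_scores:
            scores[m, c] = float(np.mean(record_scores))

    mask = np.isfinite(scores)
    if not mask.all():
        missing = [tuple(int(v) for v in idx) for idx in np.argwhere(~mask)]
        if not impute:
            raise CoverageError(
                f"subject {subject_id}: uncovered cells {missing}", cells=missing
            )
        for m, c in missing:
            dist = np.abs(np.arange(n_m)[:, None] - m) + np.abs(np.arange(n_c)[None, :] - c)
            dist = np.where(mask, dist, np.inf)
            nearest = dist.min()
            scores[m, c] = float(np.mean(scores[(dist == nearest) & mask]))
        mask = np.isfinite(scores)
    return PerformancePlane(subject_id=subject_id, scores=scores, mask=mask)


def build_planes(trials: pd.DataFrame, subject_ids, stats: BaselineStats,
                 orient: dict | None = None, grid: DifficultyGrid | None = None,
                 weights: dict | None = None, impute: bool = False) -> dict:
    """Planes for many subjects, keyed by subject id."""
    planes = {}
    for subject_id in subject_ids:
        subject_trials = trials[trials["subject_id"] == subject_id]
        if subject_trials.empty:
            raise DomainError(f"no trial records for subject {subject_id!r}")
        planes[subject_id] = build_plane(subject_trials, stats, orient, grid,
                                         weights, impute)
    return planes


def planes_to_frame(planes: dict) -> pd.DataFrame:
    """Long-format table: subject_id, motor_level, cognitive_level, score."""
    rows = []
    for subject_id, plane in planes.items():
        n_m, n_c = plane.shape
        for m in range(n_m):
            for c in range(n_c):
                if plane.mask[m, c]:
                    rows.append({
                        "subject_id": subject_id,
                        "motor_level": m,
                        "cognitive_level": c,
                        "score": float(plane.scores[m, c]),
                    })
    return pd.DataFrame(rows)
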