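"""Reference plane and the 0-100 motor-cognitive reserve (MCR) index.

The reference plane is the cell-wise median of the healthy training
subjects' performance planes: the normative expectation for a new subject.
A subject's raw index is the mean difference between their plane and the
reference (positive = above healthy norms).  The raw values of the training
cohort fix an affine 0-100 scale whose min/max are retained to score held-out
subjects, which are clipped into [0, 100]; higher values reflect greater
reserve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ComputationError, DomainError
from .scoring import PerformancePlane


@dataclass(frozen=True)
class ReferencePlane:
    """Cell-wise median of healthy training planes."""

    scores: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.scores.shape


@dataclass(frozen=True)
class IndexScaler:
    """Retained min/max raw plane-differences of the training cohort."""

    min_raw: float
    max_raw: float

    def __post_init__(self):
        if not (self.max_raw > self.min_raw):
            raise ComputationError(
                f"degenerate scaler: max_raw ({self.max_raw}) must exceed "
                f"min_raw ({self.min_raw})"
            )


@dataclass(frozen=True)
class MCRResult:
    subject_id: str
    raw_diff: float
    index: float


def build_reference_plane(healthy_train_planes) -> ReferencePlane:
    """Cell-wise median over healthy training planes.

    Standard median: midpoint of the two central values for even n.  Every
    cell must be covered by at least one plane.
    """
    planes = list(healthy_train_planes)
    if not planes:
        raise ComputationError("cannot build a reference plane from zero planes")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise DomainError("all planes must share the grid shape")
    stack = np.stack([np.where(p.mask, p.scores, np.nan) for p in planes])
    covered = np.isfinite(stack).any(axis=0)
    if not covered.all():
        missing = [tuple(int(v) for v in idx) for idx in np.argwhere(~covered)]
        raise ComputationError(f"cells uncovered in every training plane: {missing}")
    return ReferencePlane(scores=np.nanmedian(stack, axis=0))


def raw_index(plane: PerformancePlane, ref: ReferencePlane) -> float:
    """Mean over cells of (plane - reference); above-reference -> positive."""
    if plane.shape != ref.shape:
        raise DomainError(
            f"plane shape {plane.shape} does not match reference {ref.shape}"
        )
    if not plane.is_complete():
        raise ComputationError(
            f"subject {plane.subject_id}: plane has uncovered cells; "
            "score or impute them first"
        )
    return float(np.mean(plane.scores - ref.scores))


def fit_scaler(train_raw_diffs) -> IndexScaler:
    """Retain the training minimum and maximum raw differences."""
    values = np.asarray(list(train_raw_diffs), dtype=float)
    if values.size < 2:
        raise ComputationError("need at least two training values to fit the scaler")
    lo, hi = float(values.min()), float(values.max())
    if not (hi > lo):
        raise ComputationError("degenerate scaler: all training values identical")
    return IndexScaler(min_raw=lo, max_raw=hi)


def scale_index(raw_diff: float, scaler: IndexScaler) -> float:
    """Affine map of the raw difference onto 0-100, clipped for out-of-range values."""
    index = 100.0 * (raw_diff - scaler.min_raw) / (scaler.max_raw - scaler.min_raw)
    return float(np.clip(index, 0.0, 100.0))


def compute_mcr(plane: PerformancePlane, ref: ReferencePlane,
                scaler: IndexScaler) -> MCRResult:
    """Raw plane difference and scaled 0-100 index for one subject."""
    raw = raw_index(plane, ref)
    return MCRResult(subject_id=plane.subject_id, raw_diff=raw,
                     index=scale_index(raw, scaler))


def compute_cohort_indices(planes: dict, ref: ReferencePlane,
                           scaler: IndexScaler) -> pd.DataFrame:
    """Index table for many subjects: subject_id, raw_diff, mcr_index."""
    rows = [compute_mcr(plane, ref, scaler) for plane in planes.values()]
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in rows],
        "raw_diff": [r.raw_diff for r in rows],
        "mcr_index": [r.index for r in rows],
    })


def model_to_json(ref: ReferencePlane, scaler: IndexScaler, seed=None) -> str:
    """Serialize the fitted reference plane + scaler as one model artifact."""
    payload = {
        "grid_shape": list(ref.shape),
        "reference_plane": ref.scores.tolist(),
        "min_raw": scaler.min_raw,
        "max_raw": scaler.max_raw,
        "seed": seed,
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> tuple:
    payload = json.loads(text)
    ref = ReferencePlane(scores=np.asarray(payload["reference_plane"], dtype=float))
    scaler = IndexScaler(min_raw=float(payload["min_raw"]),
                         max_raw=float(payload["max_raw"]))
    return ref, scaler
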