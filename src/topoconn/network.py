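"""Correlation-distance networks from trial-by-ROI band-power matrices.

One subject's resting-state recording is summarised as a matrix of band
power values, one row per trial and one column per region of interest
(ROI).  The weighted brain network is defined on the ROI set by the
correlation distance

    c(x_i, x_j) = 1 - max(r_ij, 0)

where ``r_ij`` is the Pearson correlation of the two ROIs' power values
across trials.  Negative correlations are clipped to zero, so the distance
saturates at 1 for anti- or un-correlated regions and is 0 for perfectly
coupled ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PowerMatrix", "DistanceMatrix", "pearson_distance"]


def _check_labels(labels: Sequence[str], n_cols: int) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) != n_cols:
        raise ValueError(
            f"{len(labels)} ROI labels for {n_cols} columns"
        )
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate ROI labels: {dupes}")
    return labels


@dataclass(frozen=True)
class PowerMatrix:
    """Trial-by-ROI band-power observations for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    band : str
        Frequency-band label, e.g. ``"theta"``; purely descriptive.
    values : ndarray of shape (n_trials, n_rois)
        Finite, nonnegative band-power values in arbitrary units.
    roi_labels : tuple of str
        Column labels, unique, one per ROI.
    """

    subject_id: str
    band: str
    values: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("power values must be a 2-D trials x ROIs array")
        if values.shape[0] < 3:
            raise ValueError(
                f"need at least 3 trials, got {values.shape[0]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("power values must be finite")
        if np.any(values < 0):
            raise ValueError("power values must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "roi_labels", _check_labels(self.roi_labels, values.shape[1])
        )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric ROI-by-ROI correlation-distance matrix with entries in [0, 1]."""

    values: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(values)):
            raise ValueError("distances must be finite")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(values, 0.0)
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "roi_labels", _check_labels(self.roi_labels, values.shape[1])
        )

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def pearson_distance(power: PowerMatrix) -> DistanceMatrix:
    """Correlation-distance matrix ``1 - positive Pearson correlation``.

    Entry (i, j) is ``1 - max(r_ij, 0)`` with ``r_ij`` the Pearson
    correlation of ROI columns i and j across trials.  Negative
    correlations are rectified to zero so all distances lie in [0, 1];
    the diagonal is zero.

    Raises
    ------
    ValueError
        If any ROI column is constant across trials (its correlation is
        undefined), naming the offending ROI.
    """
    x = power.values
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [power.roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant power column(s), correlation undefined: {bad}")
    r = np.corrcoef(x, rowvar=False)
    # numerical fuzz can push |r| marginally past 1
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - np.maximum(r, 0.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, roi_labels=power.roi_labels)
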