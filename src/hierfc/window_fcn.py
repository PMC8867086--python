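"""Sliding-window construction of functional connectivity network sequences.

A window of width ``l_w`` slides over the time axis in steps of ``l_s``;
within each window the pairwise Pearson correlation of the selected ROI
columns yields one symmetric connectivity matrix.  The number of windows is

    K = floor((M − l_w) / l_s) + 1

for a series of M time points; trailing partial windows are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidWindowError, ValidationError
from .io_formats import RoiTimeSeries


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width and step in time points."""

    width: int
    step: int

    def __post_init__(self) -> None:
        if self.step < 1:
            raise InvalidWindowError(f"step must be ≥ 1, got {self.step}")
        if self.width < 2:
            raise InvalidWindowError(f"width must be ≥ 2, got {self.width}")


@dataclass
class FcnSequence:
    """K symmetric correlation matrices from successive windows."""

    matrices: np.ndarray  # shape (K, n, n)
    window_starts: list[int]
    roi_subset: list[int]

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValidationError("FcnSequence expects a (K, n, n) stack")

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def __iter__(self):
        return iter(self.matrices)

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def check_invariants(self, atol: float = 1e-12) -> None:
        for k, w in enumerate(self.matrices):
            if not np.allclose(w, w.T, atol=atol):
                raise ValidationError(f"window {k}: matrix not symmetric")
            if not np.allclose(np.diag(w), 1.0, atol=atol):
                raise ValidationError(f"window {k}: diagonal not 1")
            if np.any(w < -1 - atol) or np.any(w > 1 + atol):
                raise ValidationError(f"window {k}: entries outside [-1, 1]")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0 (with a warning) if either input is constant."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        warnings.warn("zero-variance input to pearson(); correlation set to 0")
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def num_windows(m_time: int, spec: WindowSpec) -> int:
    """K = floor((M − l_w)/l_s) + 1."""
    if spec.width > m_time:
        raise InvalidWindowError(
            f"window width {spec.width} exceeds series length {m_time}"
        )
    return (m_time - spec.width) // spec.step + 1


def _window_correlation(segment: np.ndarray) -> np.ndarray:
    """Correlation matrix of the columns of one window segment.

    Zero-variance columns get zero off-diagonal correlation and unit
    diagonal, keeping downstream model fitting well-posed.
    """
    n = segment.shape[1]
    sd = segment.std(axis=0, ddof=0)
    dead = sd == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance column(s) in a window; "
            "their correlations set to 0"
        )
    safe = np.where(dead, 1.0, sd)
    z = (segment - segment.mean(axis=0)) / safe
    c = (z.T @ z) / segment.shape[0]
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def fcn_sequence(
    ts: RoiTimeSeries, roi_subset: list[int], spec: WindowSpec
) -> FcnSequence:
    """Windowed correlation-network sequence over the given ROI columns.

    Window k covers rows [k·l_s, k·l_s + l_w), 0-based half-open.
    """
    if len(roi_subset) == 0:
        raise ValidationError("roi_subset must be non-empty")
    for i in roi_subset:
        if not 0 <= i < ts.n_roi:
            raise ValidationError(f"ROI index {i} out of range 0..{ts.n_roi - 1}")
    k = num_windows(ts.n_time, spec)
    cols = ts.values[:, list(roi_subset)]
    starts = [i * spec.step for i in range(k)]
    mats = np.stack(
        [_window_correlation(cols[s : s + spec.width]) for s in starts], axis=0
    )
    return FcnSequence(matrices=mats, window_starts=starts, roi_subset=list(roi_subset))


def static_correlation(ts: RoiTimeSeries, roi_subset: list[int] | None = None) -> np.ndarray:
    """Full-series correlation matrix (the single-window limit)."""
    subset = list(range(ts.n_roi)) if roi_subset is None else list(roi_subset)
    seq = fcn_sequence(ts, subset, WindowSpec(width=ts.n_time, step=1))
    return seq.matrices[0]
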