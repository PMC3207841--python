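"""Block-matching ROI tracking of the inner canthi.

The tracker locates a fixed reference block (set on the reference frame, as
the study's operators set it manually) in each subsequent frame by
minimising the mean squared error (MSE) over candidate integer
displacements.  Two searches are provided:

* :func:`cross_search` — the logarithmic cross search used by the pipeline:
  at each step size the x-shaped (diagonal) candidate set is evaluated and
  the search recentres on the best candidate until the centre wins, then
  the step is halved; the final unit step evaluates the full
  8-neighbourhood (the +/x end pattern).  It visits far fewer candidates
  than an exhaustive scan.
* :func:`full_search` — the exhaustive scan over a square radius; the
  global MSE minimiser, kept as the independent oracle.

Both are deterministic: ties are broken by smallest Manhattan displacement,
then row-major order, which favours no motion.  Coordinates are 0-based
(row, col) with half-open ROI extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import ThermalFrameStack


class TrackingFailure(RuntimeError):
    """Raised when no valid candidate placement exists for a search."""


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest: half-open [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")

    def inside(self, frame_shape) -> bool:
        rows, cols = frame_shape[-2], frame_shape[-1]
        return (
            self.top >= 0
            and self.left >= 0
            and self.top + self.height <= rows
            and self.left + self.width <= cols
        )

    def extract(self, frame: np.ndarray) -> np.ndarray:
        if not self.inside(frame.shape):
            raise ValueError(f"{self} not fully inside frame of shape {frame.shape}")
        return frame[self.top : self.top + self.height, self.left : self.left + self.width]

    def shifted(self, d_row: int, d_col: int) -> "ROI":
        return ROI(self.top + d_row, self.left + d_col, self.height, self.width)

    @property
    def center(self) -> tuple:
        return (self.top + self.height / 2.0, self.left + self.width / 2.0)


@dataclass
class SearchResult:
    displacement: tuple  # (d_row, d_col)
    mse: float
    n_evaluated: int


@dataclass
class RegionTrack:
    """Per-frame ROI positions and winning match scores for one region."""

    side: str
    start_frame: int
    positions: np.ndarray  # (n_tracked, 2) of (top, left)
    height: int
    width: int
    scores: np.ndarray  # winning MSE per tracked frame (K^2)
    failed: bool = False
    failure_frame: Optional[int] = None

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def rois(self) -> list:
        return [ROI(int(t), int(l), self.height, self.width) for t, l in self.positions]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(self.start_frame, self.start_frame + len(self)),
                "side": self.side,
                "top": self.positions[:, 0],
                "left": self.positions[:, 1],
                "height": self.height,
                "width": self.width,
                "mse": self.scores,
            }
        )


def mse_score(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Mean over pixels of the squared temperature difference (K^2)."""
    a = np.asarray(block_a, dtype=np.float64)
    b = np.asarray(block_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.mean(d * d))


def _candidate_mse(
    ref_block: np.ndarray, frame: np.ndarray, top: int, left: int
) -> Optional[float]:
    """MSE of the candidate placement, or None if it leaves the frame."""
    h, w = ref_block.shape
    rows, cols = frame.shape
    if top < 0 or left < 0 or top + h > rows or left + w > cols:
        return None
    block = frame[top : top + h, left : left + w]
    d = block - ref_block
    return float(np.mean(d * d))


def _check_sizes(ref_block: np.ndarray, frame: np.ndarray) -> None:
    if ref_block.ndim != 2 or frame.ndim != 2:
        raise ValueError("ref_block and frame must be 2-D arrays")
    if ref_block.shape[0] > frame.shape[0] or ref_block.shape[1] > frame.shape[1]:
        raise ValueError("reference block larger than frame")


def _best_candidate(cands):
    """Deterministic argmin over (mse, (d_row, d_col)) candidate pairs.

    Ties on MSE break by smallest |d_row|+|d_col|, then row-major order.
    """
    return min(cands, key=lambda c: (c[0], abs(c[1][0]) + abs(c[1][1]), c[1]))


def full_search(
    ref_block: np.ndarray,
    frame: np.ndarray,
    origin: tuple,
    radius: int = 8,
) -> SearchResult:
    """Exhaustive scan of all integer displacements within ``radius``.

    ``origin`` is the predicted (top, left) placement of the block. Candidate
    placements that leave the frame are excluded.
    """
    _check_sizes(ref_block, frame)
    top0, left0 = origin
    cands = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            m = _candidate_mse(ref_block, frame, top0 + dr, left0 + dc)
            if m is not None:
                cands.append((m, (dr, dc)))
    if not cands:
        raise TrackingFailure("all candidate placements fall outside the frame")
    m, d = _best_candidate(cands)
    return SearchResult(displacement=d, mse=m, n_evaluated=len(cands))


def cross_search(
    ref_block: np.ndarray,
    frame: np.ndarray,
    origin: tuple,
    max_step: int = 8,
    max_moves: int = 64,
) -> SearchResult:
    """Logarithmic cross search for the best block placement near ``origin``.

    Step sizes halve from ``max_step`` (a power of two) down to 1.  At each
    step the four diagonal (x-shaped) candidates are scored and the search
    recentres on the best until the centre is best; the final unit step uses
    the full 8-neighbourhood.  ``max_moves`` caps the total number of
    recentring moves so the candidate count stays far below an exhaustive
    scan.
    """
    _check_sizes(ref_block, frame)
    if max_step < 1 or (max_step & (max_step - 1)) != 0:
        raise ValueError("max_step must be a power of two >= 1")
    top0, left0 = origin
    d = (0, 0)
    cur = _candidate_mse(ref_block, frame, top0, left0)
    n_eval = 1 if cur is not None else 0
    moves = 0
    step = max_step
    while step >= 1:
        if step > 1:
            neigh = ((-step, -step), (-step, step), (step, -step), (step, step))
        else:
            neigh = (
                (-1, -1), (-1, 0), (-1, 1),
                (0, -1), (0, 1),
                (1, -1), (1, 0), (1, 1),
            )
        while moves < max_moves:
            cands = []
            for a, b in neigh:
                m = _candidate_mse(ref_block, frame, top0 + d[0] + a, left0 + d[1] + b)
                if m is not None:
                    n_eval += 1
                    cands.append((m, (d[0] + a, d[1] + b)))
            if not cands:
                break
            m, best = _best_candidate(cands)
            if cur is None or m < cur:
                cur, d = m, best
                moves += 1
            else:
                break
        step //= 2
    if cur is None:
        raise TrackingFailure("all candidate placements fall outside the frame")
    return SearchResult(displacement=d, mse=cur, n_evaluated=n_eval)


def track_region(
    stack: ThermalFrameStack,
    ref_roi: ROI,
    start_frame: int = 0,
    side: str = "left",
    max_step: int = 8,
    fail_ratio: float = 25.0,
    fail_consecutive: int = 5,
    baseline_frames: int = 15,
) -> RegionTrack:
    """Track a reference region frame-to-frame through the stack.

    The reference block is fixed from the reference frame (no re-templating);
    each frame's search is centred on the previous frame's position.  The
    track is declared failed — the trial unusable — when the winning MSE
    exceeds ``fail_ratio`` times the median winning MSE of the first
    ``baseline_frames`` tracked frames for ``fail_consecutive`` consecutive
    frames, or when no in-frame candidate placement remains.
    """
    if stack.n_frames == 0:
        raise ValueError("empty frame stack")
    if not (0 <= start_frame < stack.n_frames):
        raise ValueError("start_frame outside the stack")
    frames = stack.frames
    if not ref_roi.inside(frames[start_frame].shape):
        raise ValueError("reference ROI not fully inside the frame")
    ref_block = ref_roi.extract(frames[start_frame])

    positions = [(ref_roi.top, ref_roi.left)]
    scores = [0.0]
    failed = False
    failure_frame: Optional[int] = None
    threshold: Optional[float] = None
    n_over = 0

    for i in range(start_frame + 1, stack.n_frames):
        top, left = positions[-1]
        try:
            res = cross_search(ref_block, frames[i], (top, left), max_step=max_step)
        except TrackingFailure:
            failed, failure_frame = True, i
            break
        positions.append((top + res.displacement[0], left + res.displacement[1]))
        scores.append(res.mse)
        n_tracked = i - start_frame
        if n_tracked == baseline_frames:
            # floor guards the noiseless case where the median is exactly 0
            threshold = fail_ratio * max(float(np.median(scores[1:])), 1e-9)
        if threshold is not None and res.mse > threshold:
            n_over += 1
            if n_over >= fail_consecutive:
                failed = True
                failure_frame = i - fail_consecutive + 1
                break
        else:
            n_over = 0

    return RegionTrack(
        side=side,
        start_frame=start_frame,
        positions=np.asarray(positions, dtype=int),
        height=ref_roi.height,
        width=ref_roi.width,
        scores=np.asarray(scores, dtype=float),
        failed=failed,
        failure_frame=failure_frame,
    )
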