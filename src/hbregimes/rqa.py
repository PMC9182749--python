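"""Recurrence quantification analysis of heart-rate series.

A series is time-delay embedded (dimension m, lag tau), and the recurrence
matrix marks pairs of embedded states within a Euclidean radius of each
other.  Determinism (DET) is the fraction of recurrence points lying on
diagonal lines of length >= lmin, a measure of dynamical regularity that
rises with neuromuscular fatigue during sustained exercise.  Line
statistics exclude a Theiler band around the line of identity (default:
only the main diagonal).

Defaults follow the analysis conventions for wrist-worn HR series:
m = 7, tau = 1 sample, radius 5 (absolute, in bpm-embedded space),
lmin = 4.  A percent-of-maximum-distance radius mode is available, as both
conventions are common in the recurrence literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_sessions import UniformSeries

__all__ = [
    "RQAConfig",
    "RQAResult",
    "embed",
    "recurrence_matrix",
    "diagonal_line_lengths",
    "determinism",
    "recurrence_rate",
    "rqa_analyze",
    "section_det",
]


@dataclass
class RQAConfig:
    m: int = 7
    tau: int = 1
    radius: float = 5.0
    lmin: int = 4
    theiler: int = 1
    radius_mode: str = "absolute"  # or "percent" (of the max pair distance)

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("embedding dimension and lag must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")
        if self.radius_mode not in ("absolute", "percent"):
            raise ValueError("radius_mode must be 'absolute' or 'percent'")


@dataclass
class RQAResult:
    n_embedded: int
    matrix: np.ndarray
    rr: float
    det: float
    line_lengths: np.ndarray  # histogram: line_lengths[l] = #lines of length l
    degenerate: bool = False  # no recurrence points off the Theiler band


def embed(series, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: n - (m-1)*tau vectors of dimension m."""
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, float)
    n = x.size
    n_emb = n - (m - 1) * tau
    if n_emb < 1:
        raise ValueError(f"series of {n} samples too short for m={m}, tau={tau}")
    idx = np.arange(n_emb)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def recurrence_matrix(embedded: np.ndarray, radius: float,
                      radius_mode: str = "absolute") -> np.ndarray:
    """Binary symmetric matrix: R[i, j] = 1 iff ||x_i - x_j|| <= radius."""
    embedded = np.atleast_2d(np.asarray(embedded, dtype=float))
    if embedded.shape[0] < 2:
        raise ValueError("need at least 2 embedded vectors")
    d = pdist(embedded)
    if radius_mode == "percent":
        radius = radius / 100.0 * d.max()
    r = squareform(d <= radius).astype(np.uint8)
    np.fill_diagonal(r, 1)
    return r


def diagonal_line_lengths(matrix: np.ndarray, theiler: int = 1) -> np.ndarray:
    """Histogram of diagonal line lengths outside the Theiler band.

    ``out[l]`` counts maximal runs of exactly ``l`` consecutive recurrence
    points along diagonals with offset ``|i - j| >= theiler`` (both
    triangles counted).
    """
    n = matrix.shape[0]
    counts = np.zeros(n + 1, dtype=np.int64)
    for off in range(max(theiler, 1), n):
        diag = np.diagonal(matrix, offset=off)
        if diag.size == 0:
            continue
        padded = np.concatenate(([0], diag, [0]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for length in run_ends - run_starts:
            counts[length] += 2  # symmetric: same runs on offset -off
    if theiler == 0:
        diag = np.diagonal(matrix)
        padded = np.concatenate(([0], diag, [0]))
        d = np.diff(padded.astype(np.int8))
        for length in np.flatnonzero(d == -1) - np.flatnonzero(d == 1):
            counts[length] += 1
    return counts


def determinism(matrix: np.ndarray, lmin: int = 4, theiler: int = 1):
    """DET = sum_{l>=lmin} l*N(l) / sum_{l>=1} l*N(l) over diagonal lines.

    Returns ``(det, line_length_histogram)``.  When the matrix holds no
    recurrence points off the Theiler band the ratio is 0/0; DET is then
    reported as 0.
    """
    counts = diagonal_line_lengths(matrix, theiler=theiler)
    lengths = np.arange(counts.size)
    total = float(np.sum(lengths * counts))
    if total == 0:
        return 0.0, counts
    det = float(np.sum(lengths[lmin:] * counts[lmin:]) / total)
    return det, counts


def recurrence_rate(matrix: np.ndarray, theiler: int = 1) -> float:
    """Fraction of off-Theiler pairs that are recurrent."""
    n = matrix.shape[0]
    i, j = np.triu_indices(n, k=max(theiler, 1))
    pairs = 2 * i.size
    if theiler == 0:
        pairs += n
    if pairs == 0:
        return 0.0
    rec = 2 * int(matrix[i, j].sum())
    if theiler == 0:
        rec += int(np.diagonal(matrix).sum())
    return rec / pairs


def rqa_analyze(series, config: RQAConfig | None = None) -> RQAResult:
    """Embed, build the recurrence matrix, and compute RR and DET."""
    config = config or RQAConfig()
    emb = embed(series, config.m, config.tau)
    matrix = recurrence_matrix(emb, config.radius, config.radius_mode)
    det, counts = determinism(matrix, config.lmin, config.theiler)
    rr = recurrence_rate(matrix, config.theiler)
    degenerate = float(np.sum(np.arange(counts.size) * counts)) == 0
    return RQAResult(n_embedded=emb.shape[0], matrix=matrix, rr=rr, det=det,
                     line_lengths=counts, degenerate=degenerate)


def section_det(hr, config: RQAConfig | None = None) -> dict:
    """DET computed independently on the start/middle/end thirds.

    ``hr`` is a uniform series (or plain array).  A third too short to
    embed is reported as ``None``.
    """
    config = config or RQAConfig()
    x = hr.values if isinstance(hr, UniformSeries) else np.asarray(hr, float)
    n = x.size
    bounds = [0, n // 3, 2 * n // 3, n]
    out = {}
    for name, a, b in zip(("start", "middle", "end"), bounds[:-1], bounds[1:]):
        piece = x[a:b]
        if piece.size - (config.m - 1) * config.tau < 2:
            out[name] = None
            continue
        out[name] = rqa_analyze(piece, config).det
    return out
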