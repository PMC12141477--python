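"""Small quantification formulas used alongside the screen.

Implemented exactly as printed in standard bench protocols:

* RNAscope H-score from per-cell dot counts binned 0 | 1-3 | 4-9 | 10-15 |
  >15, ``H = sum_k k * (% of cells in bin k)`` on a 0-400 scale,
* ChIP-qPCR percent input ``100 * 2**(CT_input - CT_IP)``,
* relative expression by the 2^-ddCt method,
* caliper tumor volume ``V = 0.5 * L * W**2``,
* single-cell migration track statistics (accumulated and Euclidean
  distance, velocity, directionality).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: dots/cell intervals of bins 1..4 (bin 0 is exactly zero dots).
BIN_EDGES = ((1, 3), (4, 9), (10, 15), (16, None))


def bin_dots(dots_per_cell: Sequence[int]) -> np.ndarray:
    """Count cells per H-score bin from per-cell dot counts.

    Bins: 0 dots | 1-3 | 4-9 | 10-15 | >15.  Returns a length-5 integer
    array.  Empty input or negative/non-integer dot counts are errors.
    """
    dots = np.asarray(dots_per_cell)
    if dots.size == 0:
        raise ValueError("need at least one cell")
    if not np.issubdtype(dots.dtype, np.integer):
        as_float = np.asarray(dots_per_cell, dtype=float)
        if np.any(as_float % 1 != 0):
            raise ValueError("dot counts must be integers")
        dots = as_float.astype(np.int64)
    if np.any(dots < 0):
        raise ValueError("dot counts must be non-negative")
    edges = [1, 4, 10, 16]
    idx = np.digitize(dots, edges)
    return np.bincount(idx, minlength=5).astype(np.int64)


def h_score(bins: Sequence[int]) -> float:
    """H-score in [0, 400]: sum over bins k of k times the percent of cells.

    Percentages are kept as exact rationals of the counts, so the result is
    independent of any intermediate rounding.
    """
    counts = [int(c) for c in bins]
    if len(counts) != 5:
        raise ValueError("expected 5 bin counts (bins 0..4)")
    if any(c < 0 for c in counts):
        raise ValueError("bin counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total cell count must be positive")
    score = sum(Fraction(100 * k * c, total) for k, c in enumerate(counts))
    return float(score)


def percent_input(ct_input: float, ct_ip: float,
                  dilution_factor: float = 1.0) -> float:
    """ChIP-qPCR percent input: ``100 * 2**(CT_input - CT_IP)``.

    The plain formula assumes the input aliquot equals the IP chromatin
    amount; if the input was diluted, pass ``dilution_factor`` (> 1) and the
    input CT is first corrected by ``-log2(dilution_factor)``.
    """
    if not (math.isfinite(ct_input) and math.isfinite(ct_ip)):
        raise ValueError("CT values must be finite")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    adjusted_input = ct_input - math.log2(dilution_factor)
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def relative_expression_ddct(ct_target_sample: float, ct_ref_sample: float,
                             ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Fold change by 2^-ddCt with a reference gene and a control condition."""
    for ct in (ct_target_sample, ct_ref_sample, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(ct):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume ``V = 0.5 * L * W**2`` (mm -> mm^3)."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    if width > length:
        logger.warning(
            "width %.3g exceeds length %.3g; computing anyway "
            "(by convention L >= W)", width, length,
        )
    return 0.5 * length * width ** 2


@dataclass(frozen=True)
class Track:
    """A single cell's 2-D migration track sampled at increasing times."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "x", "y"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a track needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")


@dataclass(frozen=True)
class TrackStats:
    accumulated_distance: float
    euclidean_distance: float
    velocity: float
    directionality: float


def track_stats(track: Track) -> TrackStats:
    """Path statistics of one migration track.

    Accumulated distance sums the step lengths; Euclidean distance is the
    start-to-end displacement; velocity is accumulated distance over elapsed
    time (i.e. mean speed along the path); directionality is Euclidean over
    accumulated distance (1 for a straight monotone path, 0 for a closed
    loop or a stationary cell).
    """
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    accumulated = float(steps.sum())
    euclidean = float(np.hypot(track.x[-1] - track.x[0],
                               track.y[-1] - track.y[0]))
    velocity = accumulated / float(track.t[-1] - track.t[0])
    directionality = euclidean / accumulated if accumulated > 0 else 0.0
    return TrackStats(accumulated_distance=accumulated,
                      euclidean_distance=euclidean,
                      velocity=velocity,
                      directionality=directionality)


def read_tracks(path) -> dict[str, Track]:
    """Read tracks from a CSV with columns track_id, t, x, y."""
    tab = pd.read_csv(path)
    missing = {"track_id", "t", "x", "y"} - set(tab.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = {}
    for tid, grp in tab.groupby("track_id", sort=True):
        grp = grp.sort_values("t")
        tracks[str(tid)] = Track(t=grp["t"].to_numpy(),
                                 x=grp["x"].to_numpy(),
                                 y=grp["y"].to_numpy())
    return tracks


def track_stats_table(tracks: dict[str, Track]) -> pd.DataFrame:
    rows = {
        tid: vars(track_stats(tr)) for tid, tr in sorted(tracks.items())
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "track_id"
    return out
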