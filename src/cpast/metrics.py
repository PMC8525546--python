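"""Summary statistics: vertical index, transition-matrix entropy, hit rate.

The vertical index contrasts height-weighted vertical against width-weighted
horizontal saccades,

    Vi = (h * n_vert - w * n_horiz) / (h * n_vert + w * n_horiz),

bounded in [-1, 1], where (h, w) is the bounding box of the gazed region.  The
attention-style phenotype is the Shannon entropy (nats) of the learned
motif-transition matrix, summed over columns; a categorisation run is scored
by its fraction of hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, UndefinedMetricError

__all__ = ["ViResult", "CPASTResult", "vertical_index", "cpast_entropy", "hit_rate", "episode_metrics"]


@dataclass(frozen=True)
class ViResult:
    vi: float
    h: int
    w: int
    n_vertical: int
    n_horizontal: int


@dataclass(frozen=True)
class CPASTResult:
    entropy_total: float
    per_column_entropy: np.ndarray


def vertical_index(h: int, w: int, n_vert: int, n_horiz: int) -> float:
    """(h*n_vert - w*n_horiz) / (h*n_vert + w*n_horiz).

    The denominator uses the horizontal count in its second term (the sum of
    both weighted counts), which bounds the index in [-1, 1]; raises when both
    weighted counts are zero.
    """
    if h < 1 or w < 1:
        raise UndefinedMetricError(f"region dimensions must be >= 1, got h={h}, w={w}")
    if n_vert < 0 or n_horiz < 0:
        raise UndefinedMetricError("saccade counts must be non-negative")
    denom = h * n_vert + w * n_horiz
    if denom == 0:
        raise UndefinedMetricError("vertical index undefined: no vertical or horizontal saccades")
    return (h * n_vert - w * n_horiz) / denom


def cpast_entropy(b2: np.ndarray, tol: float = 1e-9) -> CPASTResult:
    """Shannon entropy (nats, 0*log0 = 0) of each column, and their sum."""
    b2 = np.asarray(b2, dtype=float)
    if (b2 < -tol).any() or np.abs(b2.sum(axis=0) - 1.0).max() > tol:
        raise DegenerateInputError("matrix is not column-stochastic")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(b2 > 0, b2 * np.log(np.where(b2 > 0, b2, 1.0)), 0.0)
    per_col = -terms.sum(axis=0)
    return CPASTResult(entropy_total=float(per_col.sum()), per_column_entropy=per_col)


def hit_rate(trials) -> float:
    """Fraction of trials whose hit flag is set."""
    trials = list(trials)
    if not trials:
        raise DegenerateInputError("hit rate undefined for an empty trial list")
    return sum(bool(t.hit) for t in trials) / len(trials)


def episode_metrics(result) -> dict:
    """Vi, C-PAST entropy and exploration summaries for one foraging episode."""
    vi = vertical_index(
        result.gaze_region_h, result.gaze_region_w, result.n_vertical, result.n_horizontal
    )
    ent = cpast_entropy(result.learned_b2)
    return {
        "complexity": result.complexity,
        "seed": result.seed,
        "vi": vi,
        "h": result.gaze_region_h,
        "w": result.gaze_region_w,
        "n_vertical": result.n_vertical,
        "n_horizontal": result.n_horizontal,
        "n_excluded": result.n_excluded,
        "bbox_area": result.bbox_area,
        "n_distinct_cells": result.n_distinct_cells,
        "cpast_entropy": ent.entropy_total,
        "dirichlet_mass": float(np.asarray(result.b2_counts).sum()),
    }
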