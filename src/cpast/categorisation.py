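"""Experiment-2 driver: cut-out categorisation under a transferred, frozen prior.

The shape space is the four foraging motif families plus an aversive "+"
shape.  Each shape is a 5x5 binary mask; a *cut-out* is the part of a shape
visible through a fixed viewing window (top/bottom/left/right halves, the
middle row/column, or the centre cell).  Two shapes that look identical
through a window yield the same cut-out, so a cut-out's *compatibility set* —
every shape whose restriction to the window equals the visible cells — can
contain several shapes.  Sensing is non-noisy: the likelihood is the exact
compatibility indicator (the epsilon floor lives in the prior embedding, which
keeps every posterior well defined); the transferred motif-transition matrix
supplies the prior that resolves ambiguity.

A trial is: blank display (one prior-propagation step through B2 with no
observation), cut-out presentation, then a decision drawn from the posterior
with a fixed log-penalty on "+" (aversion guarantees a committed choice among
real shapes).  Sampling the decision from the penalised posterior — the
standard policy-posterior action rule — lets the *graded* mass of the
transferred prior show up in performance; a hard argmax rule is available but
makes accuracy discontinuous in the prior.  No learning takes place: the
transferred matrix is frozen.

The predetermined series shows a different shape on every consecutive trial
(uniform no-repeat chain, as in habituation-avoiding stimulus protocols), and
alternates a diagnostic view (a half- or mid-line occlusion that identifies
its shape) with the maximally occluded centre glimpse (compatible with every
shape).  The alternation means the agent's belief re-collapses onto the true
shape before every ambiguous trial, so ambiguous-trial accuracy reads out the
transferred matrix's column mass directly: the probability of resolving the
glimpse correctly is ``(1 - B2[prev, prev])/3`` — agents whose training never
dispersed their transition columns beyond the motifs they saw keep betting on
a repeat that never comes.  The same series object is reused for every agent
in a comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "Cutout",
    "ShapeLibrary",
    "TrialRecord",
    "default_library",
    "generate_cutout_series",
    "embed_b2",
    "run_trial",
    "run_experiment2",
]

PLUS = 4  # index of the aversive "+" shape
N_SHAPES = 5
N_REAL = 4

_SIZE = 5
_MID = _SIZE // 2


def _shape_masks() -> np.ndarray:
    """5x5 masks: horizontal, oblique-down, oblique-up, vertical, plus."""
    masks = np.zeros((N_SHAPES, _SIZE, _SIZE), dtype=np.uint8)
    masks[0, _MID, :] = 1
    masks[1][np.diag_indices(_SIZE)] = 1
    masks[2] = masks[1][::-1]
    masks[3, :, _MID] = 1
    masks[4] = masks[0] | masks[3]
    return masks


_WINDOWS = {
    # half and mid-line occlusions
    "top": [(r, c) for r in (0, 1) for c in range(_SIZE)],
    "bottom": [(r, c) for r in (3, 4) for c in range(_SIZE)],
    "left": [(r, c) for r in range(_SIZE) for c in (0, 1)],
    "right": [(r, c) for r in range(_SIZE) for c in (3, 4)],
    "mid_row": [(_MID, c) for c in range(_SIZE)],
    "mid_col": [(r, _MID) for r in range(_SIZE)],
    # single-cell glimpses: the centre, the four corners, the four edge
    # midpoints.  A glimpse showing nothing (or only the shared centre cell)
    # is compatible with several shapes, which is where the transferred prior
    # has to do the work.
    "center": [(_MID, _MID)],
    "corner_nw": [(0, 0)],
    "corner_ne": [(0, _SIZE - 1)],
    "corner_sw": [(_SIZE - 1, 0)],
    "corner_se": [(_SIZE - 1, _SIZE - 1)],
    "edge_n": [(0, _MID)],
    "edge_s": [(_SIZE - 1, _MID)],
    "edge_w": [(_MID, 0)],
    "edge_e": [(_MID, _SIZE - 1)],
}


@dataclass(frozen=True)
class Cutout:
    """A partial view of a shape: window, visible pigment cells, compatibility set."""

    cutout_id: int
    window: str
    visible: frozenset
    compatible: frozenset  # shape ids whose restriction to the window matches

    @property
    def compatible_real(self) -> frozenset:
        return self.compatible - {PLUS}

    @property
    def is_ambiguous(self) -> bool:
        return len(self.compatible_real) > 1


@dataclass(frozen=True)
class ShapeLibrary:
    """The five shapes and the de-duplicated cut-out catalogue."""

    shapes: np.ndarray
    cutouts: tuple[Cutout, ...]
    names: tuple[str, ...] = ("horizontal", "oblique_down", "oblique_up", "vertical", "plus")

    def cutouts_for(self, shape: int) -> list[Cutout]:
        return [c for c in self.cutouts if shape in c.compatible]


def default_library() -> ShapeLibrary:
    """Build the catalogue by intersecting every shape with every window."""
    masks = _shape_masks()
    seen: dict[tuple[str, frozenset], set[int]] = {}
    for window, cells in _WINDOWS.items():
        for s in range(N_SHAPES):
            visible = frozenset((r, c) for r, c in cells if masks[s, r, c])
            seen.setdefault((window, visible), set()).add(s)
    cutouts = tuple(
        Cutout(i, window, visible, frozenset(compat))
        for i, ((window, visible), compat) in enumerate(sorted(seen.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))))
    )
    lib = ShapeLibrary(shapes=masks, cutouts=cutouts)
    if not any(c.is_ambiguous for c in lib.cutouts):
        raise ConfigurationError("cut-out catalogue contains no ambiguity")
    return lib


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    true_shape: int
    cutout_id: int
    prior: np.ndarray
    posterior: np.ndarray
    decision: int
    hit: bool


def generate_cutout_series(
    library: ShapeLibrary, length: int, seed: int
) -> list[tuple[int, int]]:
    """A predetermined (true_shape, cutout_id) series, deterministic given seed.

    True shapes follow a uniform no-repeat chain over the four real shapes;
    even-indexed trials draw a diagnostic (unambiguous) cut-out uniformly from
    the catalogue, odd-indexed trials present the centre glimpse (see the
    module docstring for why the protocol alternates).  The "+" shape is never
    the true shape.
    """
    if length < 1:
        raise ConfigurationError(f"series length must be >= 1, got {length}")
    if not library.cutouts:
        raise ConfigurationError("empty cut-out catalogue")
    glimpse = [c for c in library.cutouts if len(c.compatible) == N_SHAPES]
    if not glimpse:
        raise ConfigurationError("catalogue lacks a fully ambiguous glimpse cut-out")
    rng = np.random.default_rng(seed)
    series = []
    prev = -1
    for i in range(length):
        options = [s for s in range(N_REAL) if s != prev]
        true_shape = int(options[rng.integers(len(options))])
        if i % 2 == 1:
            cutout = glimpse[0]
        else:
            pool = [c for c in library.cutouts_for(true_shape) if not c.is_ambiguous]
            cutout = pool[rng.integers(len(pool))]
        series.append((true_shape, cutout.cutout_id))
        prev = true_shape
    return series


def embed_b2(b2_motifs: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Embed a 4x4 motif-transition matrix into the 5-shape space.

    The "+" row and column are set to the epsilon floor and columns
    renormalised; "+" is inert (never the true shape, decision-penalised).
    """
    b2_motifs = np.asarray(b2_motifs, dtype=float)
    if b2_motifs.shape != (N_REAL, N_REAL):
        raise ConfigurationError(
            f"transferred matrix must be {N_REAL}x{N_REAL}, got {b2_motifs.shape}"
        )
    out = np.full((N_SHAPES, N_SHAPES), epsilon)
    out[:N_REAL, :N_REAL] = b2_motifs
    return out / out.sum(axis=0)


def run_trial(
    cutout: Cutout,
    prev_belief: np.ndarray,
    b2_shape: np.ndarray,
    library: ShapeLibrary,
    rng: np.random.Generator,
    *,
    true_shape: int,
    trial_index: int = 0,
    plus_penalty: float = -8.0,
    decision_rule: str = "sample",
) -> TrialRecord:
    """One categorisation trial; returns the record and leaves no side effects.

    prior = B2 @ prev_belief (the blank-display step); posterior is the exact
    compatibility indicator times the prior (the prior is strictly positive by
    construction, so the posterior is always well defined).  The decision is
    drawn from the posterior reweighted by ``exp(plus_penalty)`` on "+"
    (``decision_rule="sample"``, default) or is its argmax with ties broken
    uniformly at random (``decision_rule="argmax"``).
    """
    prev_belief = np.asarray(prev_belief, dtype=float)
    if abs(prev_belief.sum() - 1.0) > 1e-9:
        raise DegenerateInputError("carried belief is not normalised")
    prior = b2_shape @ prev_belief
    lik = np.array([1.0 if s in cutout.compatible else 0.0 for s in range(N_SHAPES)])
    posterior = lik * prior
    if posterior.sum() <= 0:
        raise DegenerateInputError("cut-out incompatible with every shape under the prior")
    posterior = posterior / posterior.sum()
    weight = posterior * np.exp(np.where(np.arange(N_SHAPES) == PLUS, plus_penalty, 0.0))
    if decision_rule == "sample":
        decision = int(rng.choice(N_SHAPES, p=weight / weight.sum()))
    elif decision_rule == "argmax":
        ties = np.flatnonzero(weight >= weight.max() - 1e-12 * weight.max())
        decision = int(ties[rng.integers(len(ties))])
    else:
        raise ConfigurationError(f"unknown decision rule {decision_rule!r}")
    return TrialRecord(
        trial_index=trial_index,
        true_shape=true_shape,
        cutout_id=cutout.cutout_id,
        prior=prior,
        posterior=posterior,
        decision=decision,
        hit=decision == true_shape,
    )


def run_experiment2(
    b2_transferred: np.ndarray,
    series: list[tuple[int, int]],
    seed: int,
    *,
    library: ShapeLibrary | None = None,
    epsilon: float = 1e-3,
    plus_penalty: float = -8.0,
    decision_rule: str = "sample",
) -> tuple[list[TrialRecord], float]:
    """Run the full categorisation series under one frozen transferred matrix.

    The first-trial belief is uniform; the belief carried forward is each
    trial's posterior.  Returns the trial records and the hit rate.
    """
    if library is None:
        library = default_library()
    b2_shape = embed_b2(b2_transferred, epsilon)
    frozen = b2_shape.copy()
    by_id = {c.cutout_id: c for c in library.cutouts}
    rng = np.random.default_rng(seed)
    belief = np.full(N_SHAPES, 1.0 / N_SHAPES)
    records = []
    for i, (true_shape, cutout_id) in enumerate(series):
        rec = run_trial(
            by_id[cutout_id],
            belief,
            b2_shape,
            library,
            rng,
            true_shape=true_shape,
            trial_index=i,
            plus_penalty=plus_penalty,
            decision_rule=decision_rule,
        )
        records.append(rec)
        belief = rec.posterior
    assert np.array_equal(b2_shape, frozen)  # no-learning guarantee
    n_hits = sum(r.hit for r in records)
    return records, n_hits / len(records)
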