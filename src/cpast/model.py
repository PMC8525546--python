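"""The agent's two-level generative model and Dirichlet transition learning.

The model is parametrised by

* ``A1`` — level-1 likelihood over {no-pigment, pigment}, rebuilt from the
  remapped :class:`~cpast.remapping.LocalLikelihood` after every saccade;
* ``A2`` — level-2 likelihood mapping each motif to a distribution over grid
  locations (the normalised motif pigment maps);
* ``B1`` — deterministic level-1 transitions: a saccade re-centres the local
  frame, so every action maps onto the centre slot;
* ``B2`` — column-stochastic motif-transition matrix, the only learned object;
  it is the normalisation of a strictly positive Dirichlet count array and its
  learned form constitutes the agent's acquired attention style;
* ``C`` — log-preferences over outcomes (pigment strongly preferred);
* ``D1``/``D2`` — initial state priors (uniform).

Learning touches ``b2_counts`` only: each level-2 inference cycle adds
``rate * outer(q2_now, q2_prev)``, so total count mass grows by exactly
``rate`` per cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .environment import BACKGROUND, N_MOTIFS, VaseStimulus
from .errors import ConfigurationError, DegenerateInputError
from .remapping import NO_PIGMENT, PIGMENT, LocalLikelihood

__all__ = [
    "HierarchicalModel",
    "Policy",
    "init_model",
    "update_dirichlet",
    "normalize_columns",
    "save_transfer",
    "load_transfer",
]

_TOL = 1e-9


def normalize_columns(matrix: np.ndarray) -> np.ndarray:
    """Return the column-stochastic normalisation of a non-negative matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise DegenerateInputError("matrix entries must be non-negative")
    sums = matrix.sum(axis=0)
    if (sums <= 0).any():
        raise DegenerateInputError(f"all-zero column(s) at {np.nonzero(sums <= 0)[0].tolist()}")
    return matrix / sums


def update_dirichlet(
    b2_counts: np.ndarray,
    q2_now: np.ndarray,
    q2_prev: np.ndarray,
    rate: float = 1.0,
) -> np.ndarray:
    """One Dirichlet learning step on the motif-transition counts.

    Adds ``rate * outer(q2_now, q2_prev)`` and returns a new array; the total
    count mass grows by exactly ``rate``.
    """
    if rate <= 0:
        raise ConfigurationError(f"learning rate must be positive, got {rate}")
    q2_now = np.asarray(q2_now, dtype=float)
    q2_prev = np.asarray(q2_prev, dtype=float)
    for name, q in (("q2_now", q2_now), ("q2_prev", q2_prev)):
        if abs(q.sum() - 1.0) > _TOL or (q < 0).any():
            raise DegenerateInputError(f"{name} is not a normalised distribution")
    return np.asarray(b2_counts, dtype=float) + rate * np.outer(q2_now, q2_prev)


@dataclass(frozen=True)
class Policy:
    """A single-step policy: one candidate saccade target."""

    action: int
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.horizon != 1:
            raise ConfigurationError("look-ahead is a single time step; horizon must be 1")


@dataclass
class HierarchicalModel:
    """Parameter set of the two-level agent (see module docstring)."""

    a1: np.ndarray  # (2, 9) outcome x local state, deterministic columns
    a2: np.ndarray  # (n_locations, N_MOTIFS), column-stochastic
    b1: np.ndarray  # (9, 9) deterministic: every column is the centre slot
    b2_counts: np.ndarray  # (N_MOTIFS, N_MOTIFS) strictly positive
    C: np.ndarray  # (2,) log-preferences over [no-pigment, pigment]
    d1: np.ndarray  # (9,) uniform prior over local states
    d2: np.ndarray  # (N_MOTIFS,) uniform prior over motifs
    motif_of: np.ndarray  # flat ground-truth-derived motif membership per location
    epsilon: float = 1e-3
    n_motifs: int = N_MOTIFS
    motifs_present: tuple[int, ...] = field(default_factory=tuple)

    @property
    def b2(self) -> np.ndarray:
        """Column-normalised transition matrix implied by the current counts."""
        return normalize_columns(self.b2_counts)

    def set_a1(self, local: LocalLikelihood) -> None:
        """Rebuild the level-1 likelihood from a remapped local model."""
        self.a1 = local.outcome_probs.T.copy()

    def preference_distribution(self) -> np.ndarray:
        """softmax(C): the desired outcome distribution."""
        e = np.exp(self.C - self.C.max())
        return e / e.sum()


def init_model(
    vase: VaseStimulus,
    *,
    epsilon: float = 1e-3,
    dirichlet_seed: float = 1.0,
    pref_pigment: float = 4.0,
    pref_background: float = -4.0,
    n_motifs: int = N_MOTIFS,
) -> HierarchicalModel:
    """Build a fresh model for one stimulus.

    ``dirichlet_seed`` is the total prior count mass per B2 column (so each
    entry starts at ``seed / n_motifs``); A2 columns are the normalised motif
    pigment maps, with a uniform column standing in for motifs the stimulus
    does not contain (they then only ever contribute the ``epsilon`` floor to
    evidence and predictions).
    """
    if dirichlet_seed <= 0:
        raise ConfigurationError(f"Dirichlet seed must be positive, got {dirichlet_seed}")
    if not 0 < epsilon < 0.5:
        raise ConfigurationError(f"epsilon floor must be in (0, 0.5), got {epsilon}")
    n_loc = vase.grid.n_locations
    a2 = np.empty((n_loc, n_motifs))
    for m in range(n_motifs):
        if m in vase.motifs_present:
            a2[:, m] = vase.motif_pigment_map(m)
        else:
            a2[:, m] = 1.0 / n_loc
    b1 = np.zeros((9, 9))
    b1[4, :] = 1.0  # any saccade re-centres the local frame
    C = np.empty(2)
    C[PIGMENT] = pref_pigment
    C[NO_PIGMENT] = pref_background
    motif_of = vase.motif_of().copy()
    # placeholder A1 (uniform) until the first remap
    a1 = np.full((2, 9), 0.5)
    return HierarchicalModel(
        a1=a1,
        a2=a2,
        b1=b1,
        b2_counts=np.full((n_motifs, n_motifs), dirichlet_seed / n_motifs),
        C=C,
        d1=np.full(9, 1.0 / 9.0),
        d2=np.full(n_motifs, 1.0 / n_motifs),
        motif_of=motif_of,
        epsilon=epsilon,
        n_motifs=n_motifs,
        motifs_present=vase.motifs_present,
    )


def save_transfer(b2_counts: np.ndarray, meta: dict, path_prefix) -> tuple[Path, Path]:
    """Write the learned transition matrix as the transfer artifact.

    Produces ``<prefix>.csv`` (the column-stochastic B2) and
    ``<prefix>.meta.json`` (counts plus provenance: complexity, seed, config
    hash).  This file pair is what the categorisation task consumes.
    """
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".meta.json")
    b2 = normalize_columns(b2_counts)
    np.savetxt(csv_path, b2, fmt="%.17g", delimiter=",")
    payload = dict(meta)
    payload["b2_counts"] = np.asarray(b2_counts, dtype=float).tolist()
    meta_path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
    return csv_path, meta_path


def load_transfer(csv_path) -> tuple[np.ndarray, dict]:
    """Read back a transfer artifact written by :func:`save_transfer`."""
    csv_path = Path(csv_path)
    try:
        b2 = np.loadtxt(csv_path, delimiter=",")
    except ValueError as exc:
        raise ConfigurationError(f"malformed transfer matrix {csv_path}: {exc}") from exc
    if b2.ndim != 2 or b2.shape[0] != b2.shape[1]:
        raise ConfigurationError(f"transfer matrix {csv_path} is not square: shape {b2.shape}")
    if np.abs(b2.sum(axis=0) - 1.0).max() > 1e-6:
        raise ConfigurationError(f"transfer matrix {csv_path} has non-stochastic columns")
    meta_path = csv_path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return b2, meta
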