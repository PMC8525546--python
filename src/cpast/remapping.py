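"""Likelihood remapping: rebuild the local observation model after every move.

The agent never holds a global scene model.  After each saccade the level-1
likelihood is re-read from the 3x3 neighbourhood of the new location, so the
local hidden-state space is always the same nine slots (row-major around the
centre) while their outcome statistics follow the agent around the stimulus.
Off-grid slots are flagged with :data:`OFFGRID` and observe deterministic
no-pigment, so every position on the grid — edges included — has exactly nine
local states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import GridSpec, VaseStimulus

__all__ = ["OFFGRID", "PIGMENT", "NO_PIGMENT", "LocalLikelihood", "neighborhood", "remap_likelihood"]

#: Sentinel index for a 3x3 slot that falls outside the grid.
OFFGRID = -1

#: Outcome coding used throughout the package.
PIGMENT = 1
NO_PIGMENT = 0

#: Row-major offsets of the 3x3 patch; the centre is position 4.
_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]


@dataclass(frozen=True)
class LocalLikelihood:
    """Observation model over the nine local location states at one position.

    ``outcome_probs[k]`` is the distribution ``[P(no-pigment), P(pigment)]``
    for local state ``k``; built from a stimulus it is a deterministic 0/1
    column.
    """

    center: int
    local_states: np.ndarray  # int (9,), grid indices or OFFGRID
    outcome_probs: np.ndarray  # float (9, 2), rows sum to 1

    def __post_init__(self) -> None:
        if self.local_states.shape != (9,) or self.outcome_probs.shape != (9, 2):
            raise ValueError("a local likelihood has exactly 9 local states over 2 outcomes")

    def as_text_grid(self) -> str:
        """3x3 debug rendering: '#' pigment, '.' background, 'x' off-grid."""
        chars = []
        for k in range(9):
            if self.local_states[k] == OFFGRID:
                chars.append("x")
            else:
                chars.append("#" if self.outcome_probs[k, PIGMENT] > 0.5 else ".")
        return "\n".join("".join(chars[i : i + 3]) for i in (0, 3, 6))


def neighborhood(loc: int, grid: GridSpec) -> np.ndarray:
    """The nine location indices of the 3x3 patch centred on ``loc``.

    Row-major order; positions outside the grid are :data:`OFFGRID`.
    """
    row, col = grid.coords(loc)
    out = np.empty(9, dtype=int)
    for k, (dr, dc) in enumerate(_OFFSETS):
        r, c = row + dr, col + dc
        out[k] = grid.index(r, c) if grid.contains(r, c) else OFFGRID
    return out


def remap_likelihood(vase: VaseStimulus, loc: int) -> LocalLikelihood:
    """Read the local observation model from the generative process at ``loc``.

    Pure function of ``(vase, loc)``: in-grid slots get a deterministic column
    on their true pigment outcome, off-grid slots deterministic no-pigment.
    """
    states = neighborhood(loc, vase.grid)
    probs = np.zeros((9, 2))
    for k, s in enumerate(states):
        outcome = NO_PIGMENT if s == OFFGRID else vase.pigment_at(int(s))
        probs[k, outcome] = 1.0
    return LocalLikelihood(center=loc, local_states=states, outcome_probs=probs)
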