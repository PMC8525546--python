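"""Synthetic vase stimuli: the generative process the foraging agent explores.

A stimulus is a binary pigment grid decorated with up to four motif families
whose verticality grows with a *decoration complexity* level in {0, 1, 2, 3}:

* level 0 — horizontal line segments tiled along a central band row;
* level 1 — adds oblique (45°) segments below the band;
* level 2 — adds oblique segments above the band as well;
* level 3 — adds vertical segments below the obliques.

Levels are cumulative: every pigment cell of level ``c`` is also pigmented at
level ``c + 1``.  Locations are indexed row-major, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GridSpec",
    "MotifStencil",
    "VaseStimulus",
    "N_MOTIFS",
    "MOTIF_NAMES",
    "BACKGROUND",
    "build_vase",
    "pigment_at",
    "motif_pigment_map",
    "export_csv",
    "render_png",
]

#: Fixed size of the motif state space at every complexity level.  Experiment 2
#: transfers transition matrices across agents trained at different
#: complexities, which requires a common dimension; motifs that a low-complexity
#: vase lacks simply never occur on it.
N_MOTIFS = 4

MOTIF_NAMES = ("horizontal", "oblique_below", "oblique_above", "vertical")

#: Sentinel motif label for background (pigment-free) cells.
BACKGROUND = -1


@dataclass(frozen=True)
class GridSpec:
    """A rectangular grid of scanning locations, indexed row-major from 0."""

    n_rows: int = 30
    n_cols: int = 30

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError(
                f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols

    def index(self, row: int, col: int) -> int:
        """Row-major location index of ``(row, col)``."""
        if not self.contains(row, col):
            raise IndexError(f"({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def coords(self, loc: int) -> tuple[int, int]:
        """Inverse of :meth:`index`."""
        if not 0 <= loc < self.n_locations:
            raise IndexError(f"location {loc} outside grid of {self.n_locations}")
        return divmod(loc, self.n_cols)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    @property
    def center(self) -> tuple[int, int]:
        return self.n_rows // 2, self.n_cols // 2


@dataclass(frozen=True)
class MotifStencil:
    """One placeable instance of a motif: a small binary mask plus its anchor.

    ``mask`` marks pigment cells (1) inside the stencil's bounding box and
    ``anchor`` is the (row, col) grid offset of the mask's top-left corner.
    """

    motif_id: int
    mask: np.ndarray
    anchor: tuple[int, int]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=np.uint8)
        if mask.sum() == 0:
            raise ConfigurationError(f"motif {self.motif_id} stencil mask has no pigment cell")
        object.__setattr__(self, "mask", mask)

    def cells(self) -> list[tuple[int, int]]:
        """Absolute grid coordinates of the stencil's pigment cells."""
        r0, c0 = self.anchor
        return [(r0 + int(r), c0 + int(c)) for r, c in zip(*np.nonzero(self.mask))]


@dataclass(frozen=True)
class VaseStimulus:
    """The generative process: pigment grid plus ground-truth motif layout."""

    grid: GridSpec
    pigment: np.ndarray  # uint8 (n_rows, n_cols), 1 = pigment
    motif_label: np.ndarray  # int (n_rows, n_cols), BACKGROUND on empty cells
    complexity: int
    stencils: tuple[MotifStencil, ...] = field(default=(), repr=False)

    @property
    def motifs_present(self) -> tuple[int, ...]:
        present = np.unique(self.motif_label)
        return tuple(int(m) for m in present if m != BACKGROUND)

    def pigment_at(self, loc: int) -> int:
        """Outcome at ``loc``: 1 = pigment, 0 = no pigment."""
        row, col = self.grid.coords(loc)
        return int(self.pigment[row, col])

    def motif_pigment_map(self, motif_id: int) -> np.ndarray:
        """Normalised indicator of the motif's cells, flat over locations.

        This is ``P(location | motif)`` — the basis of the level-2 likelihood.
        """
        if motif_id not in self.motifs_present:
            raise KeyError(
                f"motif {motif_id} absent from complexity-{self.complexity} stimulus"
            )
        indicator = (self.motif_label == motif_id).astype(float).ravel()
        return indicator / indicator.sum()

    def motif_of(self) -> np.ndarray:
        """Flat motif label per location (BACKGROUND for empty cells)."""
        return self.motif_label.ravel()


def _layout_stencils(
    complexity: int,
    grid: GridSpec,
    band_row: int | None,
    seg_len: int,
    tile_step: int,
) -> list[MotifStencil]:
    """Stencil placements for one stimulus.

    Geometry (package design choice; only the qualitative description of the
    levels is fixed by the task): segments are ``seg_len`` cells long, tiled
    every ``tile_step`` columns.  Obliques alternate +45°/−45° across tiles but
    belong to a single motif family per side of the band.
    """
    if band_row is None:
        band_row = grid.n_rows // 2 - 1
    stencils: list[MotifStencil] = []
    col_starts = range(0, grid.n_cols - seg_len + 1, tile_step)

    horiz = np.ones((1, seg_len), dtype=np.uint8)
    vert = np.ones((seg_len, 1), dtype=np.uint8)
    diag_down = np.eye(seg_len, dtype=np.uint8)
    diag_up = diag_down[::-1]

    for k, c in enumerate(col_starts):
        stencils.append(MotifStencil(0, horiz, (band_row, c)))
        if complexity >= 1:
            mask = diag_down if k % 2 == 0 else diag_up
            stencils.append(MotifStencil(1, mask, (band_row + 1, c)))
        if complexity >= 2:
            mask = diag_up if k % 2 == 0 else diag_down
            stencils.append(MotifStencil(2, mask, (band_row - seg_len, c)))
        if complexity >= 3:
            stencils.append(MotifStencil(3, vert, (band_row + seg_len + 2, c + seg_len // 2)))
    return stencils


def build_vase(
    complexity: int,
    grid: GridSpec | None = None,
    *,
    band_row: int | None = None,
    seg_len: int = 5,
    tile_step: int = 7,
) -> VaseStimulus:
    """Deterministically construct the stimulus for one complexity level.

    Raises :class:`ConfigurationError`, naming the offending stencil, when the
    grid cannot host the full layout (the default geometry needs at least
    22 rows for complexity 3).
    """
    if complexity not in (0, 1, 2, 3):
        raise ConfigurationError(f"complexity must be in {{0,1,2,3}}, got {complexity}")
    if grid is None:
        grid = GridSpec()
    stencils = _layout_stencils(complexity, grid, band_row, seg_len, tile_step)

    pigment = np.zeros((grid.n_rows, grid.n_cols), dtype=np.uint8)
    motif_label = np.full((grid.n_rows, grid.n_cols), BACKGROUND, dtype=int)
    for st in stencils:
        for r, c in st.cells():
            if not grid.contains(r, c):
                raise ConfigurationError(
                    f"grid {grid.n_rows}x{grid.n_cols} too small for motif "
                    f"{st.motif_id} ({MOTIF_NAMES[st.motif_id]}) stencil anchored at {st.anchor}"
                )
            pigment[r, c] = 1
            motif_label[r, c] = st.motif_id
    return VaseStimulus(grid, pigment, motif_label, complexity, tuple(stencils))


def pigment_at(vase: VaseStimulus, loc: int) -> int:
    """Module-level alias of :meth:`VaseStimulus.pigment_at`."""
    return vase.pigment_at(loc)


def motif_pigment_map(vase: VaseStimulus, motif_id: int) -> np.ndarray:
    """Module-level alias of :meth:`VaseStimulus.motif_pigment_map`."""
    return vase.motif_pigment_map(motif_id)


def export_csv(vase: VaseStimulus, pigment_path, labels_path) -> None:
    """Write the pigment and motif-label matrices as plain CSV."""
    np.savetxt(pigment_path, vase.pigment, fmt="%d", delimiter=",")
    np.savetxt(labels_path, vase.motif_label, fmt="%d", delimiter=",")


def render_png(vase: VaseStimulus, path) -> None:
    """Render the stimulus for visual inspection (motif id as colour)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    shown = np.ma.masked_where(vase.motif_label == BACKGROUND, vase.motif_label)
    ax.imshow(shown, cmap="viridis", vmin=0, vmax=N_MOTIFS - 1, interpolation="nearest")
    ax.set_title(f"complexity {vase.complexity}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
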