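"""Experiment-1 driver: a free-viewing foraging episode over one stimulus.

The agent starts at the grid centre and explores for ``timesteps`` saccades.
Each timestep is move → observe → remap → level-1 inference; after every
fourth timestep one level-2 inference and one Dirichlet update on the
motif-transition counts are performed (the 4:1 cycle ratio), so a default
100-timestep episode performs 25 level-2 updates and grows the Dirichlet mass
by exactly 25 × rate.

All stochasticity (tie-breaking among equal-G candidates) flows through a
single generator seeded from the episode seed, so an episode is fully
reproducible from ``(vase, config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import VaseStimulus
from .errors import ConfigurationError
from .inference import BeliefState, EFEWeights, efe_landscape, infer_level1, infer_level2, select_action
from .model import HierarchicalModel, init_model, normalize_columns, update_dirichlet
from .remapping import remap_likelihood

__all__ = ["Scanpath", "EpisodeResult", "run_episode", "classify_saccade", "gaze_region"]

VERTICAL = "vertical"
HORIZONTAL = "horizontal"
EXCLUDED = "excluded"


def classify_saccade(from_pos: tuple[int, int], to_pos: tuple[int, int]) -> str:
    """Vertical if |Δrow| > |Δcol|, horizontal if |Δcol| > |Δrow|, else excluded.

    Exact diagonals and zero-moves count as neither (the index contrasts only
    vertical against horizontal steps).
    """
    dr = abs(to_pos[0] - from_pos[0])
    dc = abs(to_pos[1] - from_pos[1])
    if dr > dc:
        return VERTICAL
    if dc > dr:
        return HORIZONTAL
    return EXCLUDED


def gaze_region(scanpath: np.ndarray) -> tuple[int, int]:
    """Bounding box (height, width) of the visited cells of a (t, row, col) path."""
    if len(scanpath) == 0:
        raise ConfigurationError("empty scanpath has no gaze region")
    rows = scanpath[:, 1]
    cols = scanpath[:, 2]
    return int(rows.max() - rows.min() + 1), int(cols.max() - cols.min() + 1)


@dataclass
class Scanpath:
    """Gaze positions over one episode, including the starting fixation."""

    positions: np.ndarray  # int (timesteps+1, 3): t, row, col

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)

    def __len__(self) -> int:
        return len(self.positions)

    def saccade_classes(self) -> list[str]:
        return [
            classify_saccade(tuple(self.positions[i, 1:]), tuple(self.positions[i + 1, 1:]))
            for i in range(len(self.positions) - 1)
        ]


@dataclass
class EpisodeResult:
    """Full record of one foraging episode."""

    scanpath: Scanpath
    heatmap: np.ndarray  # per-location visit counts, shape (n_rows, n_cols)
    n_vertical: int
    n_horizontal: int
    gaze_region_h: int
    gaze_region_w: int
    learned_b2: np.ndarray  # column-stochastic
    b2_counts: np.ndarray
    seed: int
    complexity: int
    q2_trace: np.ndarray = field(default=None, repr=False)  # (n_cycles, n_motifs)

    @property
    def n_excluded(self) -> int:
        return (len(self.scanpath) - 1) - self.n_vertical - self.n_horizontal

    @property
    def bbox_area(self) -> int:
        return self.gaze_region_h * self.gaze_region_w

    @property
    def n_distinct_cells(self) -> int:
        return int((self.heatmap > 0).sum())


def run_episode(
    vase: VaseStimulus,
    seed: int,
    *,
    timesteps: int = 100,
    weights: EFEWeights = EFEWeights(),
    epsilon: float = 1e-3,
    dirichlet_seed: float = 1.0,
    dirichlet_rate: float = 1.0,
    pref_pigment: float = 4.0,
    pref_background: float = -4.0,
    max_saccade: int | None = None,
    trace=None,
) -> EpisodeResult:
    """Run one foraging episode; see the module docstring for the loop shape.

    ``max_saccade`` optionally limits candidates to a Chebyshev radius around
    the current position (default: the whole grid is reachable).  ``trace``
    may be a callable receiving one dict per timestep.
    """
    if timesteps < 4:
        raise ConfigurationError(f"timesteps must be >= 4, got {timesteps}")
    rng = np.random.default_rng(seed)
    model = init_model(
        vase,
        epsilon=epsilon,
        dirichlet_seed=dirichlet_seed,
        pref_pigment=pref_pigment,
        pref_background=pref_background,
    )
    grid = vase.grid
    row, col = grid.center
    loc = grid.index(row, col)

    heatmap = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    heatmap[row, col] += 1
    path = [(0, row, col)]
    n_vert = n_horiz = 0

    local = remap_likelihood(vase, loc)
    model.set_a1(local)
    beliefs = BeliefState(
        q1=infer_level1(local, vase.pigment_at(loc), model.d1, epsilon=epsilon),
        q2=model.d2.copy(),
    )
    q2_prev = model.d2.copy()  # posterior of the previous level-2 cycle
    q2_pred = model.b2 @ q2_prev  # belief about the current motif used for action
    evidence: list[tuple[int, int]] = []
    q2_trace = []

    all_locs = np.arange(grid.n_locations)
    rows_flat, cols_flat = np.divmod(all_locs, grid.n_cols)

    for t in range(1, timesteps + 1):
        if max_saccade is None:
            candidates = None
        else:
            reach = np.maximum(np.abs(rows_flat - row), np.abs(cols_flat - col)) <= max_saccade
            candidates = all_locs[reach]
        G = efe_landscape(q2_pred, model, weights, candidates, q2_from=q2_prev)
        new_loc = select_action(G, rng, candidates)
        new_row, new_col = grid.coords(new_loc)

        cls = classify_saccade((row, col), (new_row, new_col))
        n_vert += cls == VERTICAL
        n_horiz += cls == HORIZONTAL
        row, col, loc = new_row, new_col, new_loc
        path.append((t, row, col))
        heatmap[row, col] += 1

        observation = vase.pigment_at(loc)
        local = remap_likelihood(vase, loc)
        model.set_a1(local)
        beliefs.q1 = infer_level1(local, observation, model.d1, epsilon=epsilon)
        evidence.append((loc, observation))
        beliefs.cycle_phase = (beliefs.cycle_phase + 1) % 4

        if trace is not None:
            trace(
                {
                    "t": t,
                    "loc": loc,
                    "observation": observation,
                    "argmax_q2": int(np.argmax(q2_pred)),
                    "G_chosen": float(G.min()),
                }
            )

        if beliefs.cycle_phase == 0:
            q2_now = infer_level2(evidence, model, q2_prev)
            model.b2_counts = update_dirichlet(model.b2_counts, q2_now, q2_prev, dirichlet_rate)
            q2_trace.append(q2_now)
            beliefs.q2 = q2_now
            q2_prev = q2_now
            q2_pred = model.b2 @ q2_prev
            evidence = []

    scan = Scanpath(np.array(path))
    h, w = gaze_region(scan.positions)
    return EpisodeResult(
        scanpath=scan,
        heatmap=heatmap,
        n_vertical=n_vert,
        n_horizontal=n_horiz,
        gaze_region_h=h,
        gaze_region_w=w,
        learned_b2=normalize_columns(model.b2_counts),
        b2_counts=model.b2_counts.copy(),
        seed=seed,
        complexity=vase.complexity,
        q2_trace=np.array(q2_trace) if q2_trace else np.zeros((0, model.n_motifs)),
    )
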