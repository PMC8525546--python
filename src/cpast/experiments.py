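"""Sweep orchestration shared by the CLI, the tests and the acceptance script.

All randomness in a sweep descends from one master seed through
:func:`derive_seed`, which hashes a spawn key with numpy's SeedSequence; runs
are therefore reproducible independently of execution order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categorisation import default_library, generate_cutout_series, run_experiment2
from .config import RunConfig
from .environment import GridSpec, build_vase
from .foraging import EpisodeResult, run_episode
from .metrics import episode_metrics

__all__ = ["derive_seed", "foraging_sweep", "categorisation_sweep", "summarise"]


def derive_seed(master_seed: int, *key: int) -> int:
    """A 31-bit child seed for the given spawn key under the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % 2**31)


def foraging_sweep(config: RunConfig) -> tuple[pd.DataFrame, dict[int, list[EpisodeResult]]]:
    """Run ``n_seeds`` foraging episodes per complexity level.

    Returns the per-episode metrics table and the full episode results keyed
    by complexity (the learned matrices feed the categorisation sweep).
    """
    grid = GridSpec(config.grid_rows, config.grid_cols)
    kwargs = config.episode_kwargs()
    rows, results = [], {}
    for c in config.complexities:
        vase = build_vase(c, grid, band_row=config.band_row)
        results[c] = []
        for i in range(config.n_seeds):
            seed = derive_seed(config.master_seed, 1, c, i)
            res = run_episode(vase, seed, **kwargs)
            results[c].append(res)
            m = episode_metrics(res)
            m["seed_index"] = i
            rows.append(m)
    return pd.DataFrame(rows), results


def categorisation_sweep(
    config: RunConfig, episodes: dict[int, list[EpisodeResult]]
) -> pd.DataFrame:
    """Transfer each learned matrix into ``n_series_seeds`` categorisation runs.

    The same predetermined series (per series seed) is presented to every
    agent, so rows are comparable across training complexities.
    """
    library = default_library()
    rows = []
    for s in range(config.n_series_seeds):
        series = generate_cutout_series(
            library, config.trials, derive_seed(config.master_seed, 2, s)
        )
        for c, results in episodes.items():
            for i, res in enumerate(results):
                _, rate = run_experiment2(
                    res.learned_b2,
                    series,
                    seed=derive_seed(config.master_seed, 3, s, c, i),
                    library=library,
                    epsilon=config.epsilon,
                    plus_penalty=config.plus_penalty,
                    decision_rule=config.decision_rule,
                )
                rows.append(
                    {
                        "complexity": c,
                        "train_seed_index": i,
                        "series_seed_index": s,
                        "hit_rate": rate,
                    }
                )
    return pd.DataFrame(rows)


def summarise(metrics: pd.DataFrame, hit_rates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean and standard deviation of the headline statistics per complexity."""
    agg = metrics.groupby("complexity")[["vi", "cpast_entropy", "bbox_area"]].agg(["mean", "std"])
    agg.columns = ["_".join(col) for col in agg.columns]
    if hit_rates is not None:
        hr = hit_rates.groupby("complexity")["hit_rate"].agg(["mean", "std"])
        hr.columns = ["hit_rate_mean", "hit_rate_std"]
        agg = agg.join(hr)
    return agg.reset_index()
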