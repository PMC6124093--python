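"""Deterministic miniature datasets for tests and examples.

The fixture dataset is intentionally small (8 x 8 lattice, 6 cells, 24 steps,
M = 3) and constructed so that every statistic, including the degenerate
branches, is exercised: one tracked trajectory is replaced by a synthetic
stationary path whose net displacement is zero, which triggers the
tortuosity-degeneracy handling.
"""

from __future__ import annotations

import numpy as np

from .lattice_model import (
    DesignSpec,
    LatticeConfig,
    ModelParams,
    ObservedDataset,
    ReplicateResult,
    Trajectory,
    generate_observed_dataset,
)

__all__ = ["make_fixtures"]


def make_fixtures(seed: int = 0) -> ObservedDataset:
    """A reproducible miniature dataset; same seed, same bytes.

    Replicate 0's first tracked trajectory is overwritten with a synthetic
    stationary path (every recorded position equals the cell's final
    position), guaranteeing a zero-net-displacement tortuosity case.
    """
    config = LatticeConfig(n_rows=8, n_cols=8)
    design = DesignSpec(
        seeded_rows=4,
        n_initial=6,
        duration=1.0,
        record_interval=8,
        n_tracked=3,
        n_replicates=3,
    )
    params = ModelParams(0.4, 0.02)
    dataset = generate_observed_dataset(design, params, config, seed)
    rep0 = dataset.replicates[0]
    t0 = rep0.trajectories[0]
    stationary = Trajectory(
        cell_id=t0.cell_id,
        positions=np.repeat(t0.positions[-1:], len(t0.positions), axis=0),
    )
    patched = ReplicateResult(
        final_state=rep0.final_state,
        trajectories=(stationary,) + rep0.trajectories[1:],
        seed=rep0.seed,
    )
    return ObservedDataset(
        replicates=(patched,) + dataset.replicates[1:],
        params_true=dataset.params_true,
        design=design,
        config=config,
    )
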