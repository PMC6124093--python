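"""Plain-text serialization of datasets, accepted samples and posterior grids.

All coordinates are 0-based ``(x_col, y_row)`` with row 0 at the seeded edge.
CSV/JSON round-trips preserve values to full precision.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .abc_inference import AcceptedSet, PosteriorGrid
from .lattice_model import (
    DesignSpec,
    LatticeConfig,
    LatticeState,
    ModelParams,
    ObservedDataset,
    ReplicateResult,
    Trajectory,
)

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_accepted",
    "read_accepted",
    "write_posterior_grid",
    "read_posterior_grid",
    "write_manifest",
    "finalize_manifest",
]


def write_dataset(dataset: ObservedDataset, out_dir: str | Path) -> None:
    """Write final positions, trajectories and metadata for an M-replicate
    dataset as positions.csv / trajectories.csv / meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = dataset.config
    final_time = dataset.design.duration
    pos_rows = []
    traj_rows = []
    for m, rep in enumerate(dataset.replicates):
        tracked = set(int(t.cell_id) for t in rep.trajectories)
        for cid, (x, y) in enumerate(rep.final_state.cells):
            pos_rows.append(
                (m, final_time, cid, int(x), int(y), int(cid in tracked))
            )
        for t in rep.trajectories:
            for r, (x, y) in enumerate(t.positions):
                traj_rows.append(
                    (m, int(t.cell_id), r * dataset.design.record_interval, int(x), int(y))
                )
    pd.DataFrame(
        pos_rows, columns=["replicate", "time_h", "cell_id", "x_col", "y_row", "tracked"]
    ).to_csv(out / "positions.csv", index=False)
    pd.DataFrame(
        traj_rows, columns=["replicate", "cell_id", "step", "x_col", "y_row"]
    ).to_csv(out / "trajectories.csv", index=False)
    meta = {
        "params_true": asdict(dataset.params_true),
        "design": asdict(dataset.design),
        "config": asdict(config),
        "replicate_seeds": [rep.seed for rep in dataset.replicates],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(in_dir: str | Path) -> ObservedDataset:
    """Inverse of :func:`write_dataset`."""
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    params = ModelParams(**meta["params_true"])
    design = DesignSpec(**meta["design"])
    config = LatticeConfig(**meta["config"])
    positions = pd.read_csv(src / "positions.csv")
    trajectories = pd.read_csv(src / "trajectories.csv")
    replicates = []
    for m, seed in enumerate(meta["replicate_seeds"]):
        pos = positions[positions.replicate == m].sort_values("cell_id")
        cells = pos[["x_col", "y_row"]].to_numpy(dtype=np.int64)
        occupancy = np.zeros((config.n_rows, config.n_cols), dtype=bool)
        occupancy[cells[:, 1], cells[:, 0]] = True
        tracked = pos.loc[pos.tracked == 1, "cell_id"].to_numpy(dtype=np.int64)
        state = LatticeState(
            occupancy=occupancy,
            cells=cells,
            step_index=design.n_steps(config),
            tracked=tracked,
        )
        trajs = []
        sub = trajectories[trajectories.replicate == m]
        for cid in sorted(sub.cell_id.unique()):
            t = sub[sub.cell_id == cid].sort_values("step")
            trajs.append(
                Trajectory(
                    cell_id=int(cid),
                    positions=t[["x_col", "y_row"]].to_numpy(dtype=np.int64),
                )
            )
        replicates.append(
            ReplicateResult(final_state=state, trajectories=tuple(trajs), seed=int(seed))
        )
    return ObservedDataset(
        replicates=tuple(replicates), params_true=params, design=design, config=config
    )


def write_accepted(accepted: AcceptedSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pm": accepted.theta[:, 0],
            "pp": accepted.theta[:, 1],
            "pm_adjusted": accepted.adjusted_theta[:, 0],
            "pp_adjusted": accepted.adjusted_theta[:, 1],
            "combined_distance": accepted.combined,
        }
    )
    for j, sid in enumerate(accepted.statistic_ids):
        df[f"d_{sid}"] = accepted.per_statistic_distance[:, j]
    # default string conversion is the shortest exact representation
    df.to_csv(path, index=False)


def read_accepted(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_posterior_grid(grid: PosteriorGrid, prefix: str | Path) -> None:
    """Grid values as a delimited-text matrix plus a JSON axis sidecar."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".txt"), grid.values, fmt="%.17e")
    axes = {
        "pm_centers": grid.pm_centers.tolist(),
        "pp_centers": grid.pp_centers.tolist(),
    }
    prefix.with_suffix(".axes.json").write_text(json.dumps(axes))


def read_posterior_grid(prefix: str | Path) -> PosteriorGrid:
    prefix = Path(prefix)
    values = np.loadtxt(prefix.with_suffix(".txt"))
    axes = json.loads(prefix.with_suffix(".axes.json").read_text())
    return PosteriorGrid(
        values=values,
        pm_centers=np.array(axes["pm_centers"]),
        pp_centers=np.array(axes["pp_centers"]),
    )


def write_manifest(out_dir: str | Path, config_snapshot: dict, seed: int) -> Path:
    """Record the run configuration before any output is produced."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(
        json.dumps(
            {
                "version": __version__,
                "seed": seed,
                "config": config_snapshot,
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "finished": None,
                "outputs": [],
            },
            indent=2,
        )
    )
    return path


def finalize_manifest(path: str | Path, outputs: list[str]) -> None:
    path = Path(path)
    manifest = json.loads(path.read_text())
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["outputs"] = outputs
    path.write_text(json.dumps(manifest, indent=2))
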