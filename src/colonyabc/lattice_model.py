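"""Stochastic lattice exclusion-process model of cell motility and proliferation.

Cells occupy sites of an ``n_rows x n_cols`` square lattice, at most one cell
per site (volume exclusion).  During each time step of duration ``tau``,
``N(t)`` agents are selected uniformly at random *with replacement* from the
population present at the start of the step.  Each selected agent draws
``r ~ U(0, 1)``:

* ``r <= p_move``          -- attempt a move to one of the four orthogonal
  neighbour sites, chosen uniformly;
* ``p_move < r <= p_move + p_prolif`` -- attempt to place a daughter cell in
  one of the four orthogonal neighbour sites, chosen uniformly;
* otherwise no event.

Attempts onto occupied sites or off the lattice are aborted, which provides a
simple mechanism for contact inhibition.  There is no cell death, so the
population is non-decreasing.  Boundaries are no-flux (events across them
abort); coordinates are 0-based ``(column, row) = (x, y)`` with row 0 at the
seeded edge.

The per-step probabilities relate to the continuum diffusivity and
proliferation rate by ``D = p_move * delta^2 / (4 tau)`` and
``lambda = p_prolif / tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "LatticeConfig",
    "DesignSpec",
    "LatticeState",
    "Trajectory",
    "ReplicateResult",
    "ObservedDataset",
    "initialize_lattice",
    "simulation_step",
    "run_replicate",
    "generate_observed_dataset",
    "continuum_rates",
    "observation_window",
]

_SEED_MAX = 2**31 - 1


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ModelParams:
    """Per-time-step movement and proliferation probabilities."""

    p_move: float
    p_prolif: float

    def __post_init__(self) -> None:
        if self.p_move < 0 or self.p_prolif < 0:
            raise ValueError("probabilities must be non-negative")
        if self.p_move + self.p_prolif > 1.0 + 1e-12:
            raise ValueError(
                f"p_move + p_prolif = {self.p_move + self.p_prolif} exceeds 1"
            )


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry and time discretization.

    Defaults match a 24 x 32 field of view with 18.75 um sites (one cell
    diameter) and one-hour-per-24-steps time resolution.
    """

    n_rows: int = 24
    n_cols: int = 32
    site_length: float = 18.75  # um
    step_duration: float = 1.0 / 24.0  # hours

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if self.site_length <= 0 or self.step_duration <= 0:
            raise ValueError("site_length and step_duration must be positive")


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: initial geometry, duration and replication.

    ``seeded_rows`` controls the interpolation between a growth-to-confluence
    assay (cells spread over all rows) and a scratch assay (cells confined to
    the first few rows).  ``n_initial`` cells are placed uniformly at random
    over distinct sites of the first ``seeded_rows`` rows.
    """

    seeded_rows: int = 24
    n_initial: int = 24
    duration: float = 12.0  # hours
    record_interval: int = 8  # steps between trajectory records
    n_tracked: int = 5
    n_replicates: int = 10

    def n_steps(self, config: LatticeConfig) -> int:
        steps = self.duration / config.step_duration
        n = int(round(steps))
        if abs(steps - n) > 1e-9:
            raise ValueError("duration must be an integer number of steps")
        return n

    def validate(self, config: LatticeConfig) -> None:
        if not 1 <= self.seeded_rows <= config.n_rows:
            raise ValueError("seeded_rows must lie in [1, n_rows]")
        if self.n_initial > self.seeded_rows * config.n_cols:
            raise ValueError(
                f"cannot place {self.n_initial} cells in "
                f"{self.seeded_rows} x {config.n_cols} seeded sites"
            )
        if self.n_tracked > self.n_initial:
            raise ValueError("n_tracked cannot exceed n_initial")
        n = self.n_steps(config)
        if n % self.record_interval != 0:
            raise ValueError("record_interval must divide the step count")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class LatticeState:
    """Occupancy snapshot at one time step.

    ``cells`` is an ``(N, 2)`` integer array of ``(column, row)`` coordinates;
    ``occupancy`` the matching boolean grid; ``tracked`` indexes the founder
    cells whose trajectories are recorded.
    """

    occupancy: np.ndarray  # bool, (n_rows, n_cols)
    cells: np.ndarray  # int, (N, 2) as (col, row)
    step_index: int = 0
    tracked: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        occ_count = int(self.occupancy.sum())
        if occ_count != len(self.cells):
            raise ValueError("occupancy count does not match cell list")
        coords = {(int(x), int(y)) for x, y in self.cells}
        if len(coords) != len(self.cells):
            raise ValueError("duplicate cell coordinates violate exclusion")
        n_rows, n_cols = self.occupancy.shape
        for x, y in self.cells:
            if not (0 <= x < n_cols and 0 <= y < n_rows):
                raise ValueError("cell coordinate out of bounds")
            if not self.occupancy[y, x]:
                raise ValueError("cell list and occupancy grid disagree")


@dataclass(frozen=True)
class Trajectory:
    """Recorded positions of one tracked founder cell (every record_interval steps)."""

    cell_id: int
    positions: np.ndarray  # int, (n_records, 2) as (col, row)


@dataclass(frozen=True)
class ReplicateResult:
    final_state: LatticeState
    trajectories: tuple[Trajectory, ...]
    seed: int


@dataclass(frozen=True)
class ObservedDataset:
    """M replicate simulations standing in for experimental data."""

    replicates: tuple[ReplicateResult, ...]
    params_true: ModelParams
    design: DesignSpec
    config: LatticeConfig

    def __len__(self) -> int:
        return len(self.replicates)


# (dx, dy) for the four orthogonal neighbours
_NBR_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_NBR_DY = np.array([0, 0, 1, -1], dtype=np.int64)


@njit(cache=True)
def _run_steps(occ, xs, ys, n, n_steps, record_interval, tracked, traj, pm, pp, seed):
    """Advance the lattice ``n_steps`` steps in place; record tracked positions.

    ``occ`` holds the cell index at each site (-1 empty); ``xs``/``ys`` have
    capacity for a full lattice.  ``traj`` is ``(n_tracked, n_records, 2)``
    with row 0 already holding the step-0 positions.  Returns the final cell
    count.
    """
    np.random.seed(seed)
    n_rows, n_cols = occ.shape
    rec = 1
    for step in range(n_steps):
        n_start = n
        for _ in range(n_start):
            # uniform integers via scaled floats (the scaling bias is O(2^-53))
            i = int(np.random.random() * n_start)
            r = np.random.random()
            if r <= pm:
                d = int(np.random.random() * 4.0)
                nx = xs[i] + _NBR_DX[d]
                ny = ys[i] + _NBR_DY[d]
                if 0 <= nx < n_cols and 0 <= ny < n_rows and occ[ny, nx] < 0:
                    occ[ys[i], xs[i]] = -1
                    occ[ny, nx] = i
                    xs[i] = nx
                    ys[i] = ny
            elif r <= pm + pp:
                d = int(np.random.random() * 4.0)
                nx = xs[i] + _NBR_DX[d]
                ny = ys[i] + _NBR_DY[d]
                if 0 <= nx < n_cols and 0 <= ny < n_rows and occ[ny, nx] < 0:
                    occ[ny, nx] = n
                    xs[n] = nx
                    ys[n] = ny
                    n += 1
        if record_interval > 0 and (step + 1) % record_interval == 0:
            for t in range(tracked.shape[0]):
                traj[t, rec, 0] = xs[tracked[t]]
                traj[t, rec, 1] = ys[tracked[t]]
            rec += 1
    return n


def _state_to_arrays(state: LatticeState):
    n_rows, n_cols = state.occupancy.shape
    cap = n_rows * n_cols
    occ = np.full((n_rows, n_cols), -1, dtype=np.int64)
    xs = np.zeros(cap, dtype=np.int64)
    ys = np.zeros(cap, dtype=np.int64)
    n = len(state.cells)
    xs[:n] = state.cells[:, 0]
    ys[:n] = state.cells[:, 1]
    occ[ys[:n], xs[:n]] = np.arange(n)
    return occ, xs, ys


def _arrays_to_state(occ, xs, ys, n, step_index, tracked) -> LatticeState:
    cells = np.column_stack([xs[:n], ys[:n]]).astype(np.int64)
    return LatticeState(
        occupancy=occ >= 0,
        cells=cells,
        step_index=step_index,
        tracked=np.asarray(tracked, dtype=np.int64),
    )


def initialize_lattice(
    design: DesignSpec, config: LatticeConfig, rng
) -> LatticeState:
    """Place ``n_initial`` cells uniformly over distinct sites of the first
    ``seeded_rows`` rows and flag ``n_tracked`` of them for trajectory
    recording."""
    design.validate(config)
    rng = _as_rng(rng)
    n_sites = design.seeded_rows * config.n_cols
    flat = rng.choice(n_sites, size=design.n_initial, replace=False)
    rows, cols = np.divmod(flat, config.n_cols)
    cells = np.column_stack([cols, rows]).astype(np.int64)
    occupancy = np.zeros((config.n_rows, config.n_cols), dtype=bool)
    occupancy[rows, cols] = True
    tracked = np.sort(rng.choice(design.n_initial, size=design.n_tracked, replace=False))
    return LatticeState(occupancy=occupancy, cells=cells, step_index=0, tracked=tracked)


def simulation_step(state: LatticeState, params: ModelParams, rng) -> LatticeState:
    """One time step of the exclusion process; returns a new state."""
    rng = _as_rng(rng)
    occ, xs, ys = _state_to_arrays(state)
    n = len(state.cells)
    traj = np.zeros((0, 2, 2), dtype=np.int64)
    seed = int(rng.integers(_SEED_MAX))
    n = _run_steps(
        occ, xs, ys, n, 1, 0, np.empty(0, dtype=np.int64), traj,
        params.p_move, params.p_prolif, seed,
    )
    return _arrays_to_state(occ, xs, ys, n, state.step_index + 1, state.tracked)


def run_replicate(
    design: DesignSpec,
    params: ModelParams,
    config: LatticeConfig,
    rng,
) -> ReplicateResult:
    """Initialize, run ``duration / step_duration`` steps, and record the
    tracked-cell trajectories every ``record_interval`` steps (including
    step 0 and the final step)."""
    rng = _as_rng(rng)
    seed = int(rng.integers(_SEED_MAX))
    return _run_replicate_seeded(design, params, config, seed)


@dataclass(frozen=True)
class _LightReplicate:
    """Internal hot-path replicate: trajectories kept as one array."""

    final_state: LatticeState
    trajectories: np.ndarray  # (n_tracked, n_records, 2)
    seed: int


def _run_replicate_core(
    design: DesignSpec, params: ModelParams, config: LatticeConfig, seed: int
) -> _LightReplicate:
    rng = np.random.default_rng(seed)
    state = initialize_lattice(design, config, rng)
    n_steps = design.n_steps(config)
    n_records = n_steps // design.record_interval + 1
    tracked = state.tracked
    traj = np.zeros((len(tracked), n_records, 2), dtype=np.int64)
    traj[:, 0, :] = state.cells[tracked]
    occ, xs, ys = _state_to_arrays(state)
    kernel_seed = int(rng.integers(_SEED_MAX))
    n = _run_steps(
        occ, xs, ys, len(state.cells), n_steps, design.record_interval,
        tracked, traj, params.p_move, params.p_prolif, kernel_seed,
    )
    final = _arrays_to_state(occ, xs, ys, n, n_steps, tracked)
    return _LightReplicate(final_state=final, trajectories=traj, seed=seed)


def _run_replicate_seeded(
    design: DesignSpec, params: ModelParams, config: LatticeConfig, seed: int
) -> ReplicateResult:
    light = _run_replicate_core(design, params, config, seed)
    tracked = light.final_state.tracked
    trajectories = tuple(
        Trajectory(cell_id=int(tracked[t]), positions=light.trajectories[t].copy())
        for t in range(len(tracked))
    )
    return ReplicateResult(
        final_state=light.final_state, trajectories=trajectories, seed=seed
    )


def generate_observed_dataset(
    design: DesignSpec,
    params: ModelParams,
    config: LatticeConfig | None = None,
    rng=None,
) -> ObservedDataset:
    """M independent replicates with per-replicate seeds spawned from the
    master stream, so the dataset is bit-reproducible from one seed."""
    config = config or LatticeConfig()
    rng = _as_rng(rng)
    seeds = rng.integers(_SEED_MAX, size=design.n_replicates)
    replicates = tuple(
        _run_replicate_seeded(design, params, config, int(s)) for s in seeds
    )
    return ObservedDataset(
        replicates=replicates, params_true=params, design=design, config=config
    )


def continuum_rates(params: ModelParams, config: LatticeConfig) -> tuple[float, float]:
    """Continuum-limit diffusivity D = p_move * delta^2 / (4 tau) in um^2/h and
    proliferation rate lambda = p_prolif / tau in 1/h."""
    d = params.p_move * config.site_length**2 / (4.0 * config.step_duration)
    lam = params.p_prolif / config.step_duration
    return d, lam


def observation_window(
    state: LatticeState, n_rows: int, n_cols: int, row0: int = 0, col0: int = 0
) -> LatticeState:
    """Restrict a state to a rectangular sub-window (used to emulate an imaging
    field of view smaller than the simulated dish).  Tracked flags are dropped;
    trajectory statistics are not defined on a window."""
    occ = state.occupancy[row0 : row0 + n_rows, col0 : col0 + n_cols].copy()
    keep = (
        (state.cells[:, 0] >= col0)
        & (state.cells[:, 0] < col0 + n_cols)
        & (state.cells[:, 1] >= row0)
        & (state.cells[:, 1] < row0 + n_rows)
    )
    cells = state.cells[keep].copy()
    cells[:, 0] -= col0
    cells[:, 1] -= row0
    return LatticeState(occupancy=occ, cells=cells, step_index=state.step_index)
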