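"""Summary statistics for colony-growth experiments.

Thirteen statistics summarize one replicate: eleven are functions of the
final-time cell positions (cell number ``N``, largest 4- and 8-connected
cluster sizes ``kappa4``/``kappa8``, quadrat binning variances ``Q2``, ``Q4``,
``Q8``, the smaller gyration-tensor eigenvalue, and raw / density-normalized
pair-correlation functions in the vertical and full Manhattan metrics), and
two are functions of the five tracked-cell trajectories (mean total Manhattan
displacement and mean tortuosity).

Pair-correlation statistics are length-24 vectors indexed by lattice
separation ``l = 1..24``; all others are scalars.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

from .lattice_model import LatticeState, ReplicateResult

__all__ = [
    "STATISTIC_IDS",
    "CORRELATION_IDS",
    "MAX_LAG",
    "statistic_length",
    "element_index",
    "cell_count",
    "largest_cluster",
    "binning_variance",
    "manhattan_displacement",
    "tortuosity",
    "gyration_min_eigenvalue",
    "pair_correlation",
    "expected_pair_count",
    "normalize_correlation",
    "compute_statistic_set",
    "statistics_to_vector",
]

MAX_LAG = 24

STATISTIC_IDS = (
    "N",
    "kappa4",
    "kappa8",
    "Q2",
    "Q4",
    "Q8",
    "displacement",
    "tortuosity",
    "gyration",
    "Cxy",
    "Cxy_hat",
    "Cy",
    "Cy_hat",
)

CORRELATION_IDS = ("Cxy", "Cxy_hat", "Cy", "Cy_hat")

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def statistic_length(statistic_id: str, max_lag: int = MAX_LAG) -> int:
    """Number of elements L_j of one statistic (24 for pair correlations)."""
    if statistic_id not in STATISTIC_IDS:
        raise KeyError(f"unknown statistic {statistic_id!r}")
    return max_lag if statistic_id in CORRELATION_IDS else 1


def element_index(
    statistic_ids=STATISTIC_IDS, max_lag: int = MAX_LAG
) -> list[tuple[str, int]]:
    """Flattened ``(statistic_id, l)`` layout used by vectorized pipelines."""
    out: list[tuple[str, int]] = []
    for sid in statistic_ids:
        for l in range(1, statistic_length(sid, max_lag) + 1):
            out.append((sid, l))
    return out


def cell_count(state: LatticeState) -> int:
    return len(state.cells)


def largest_cluster(state: LatticeState, connectivity: int = 4) -> int:
    """Size of the largest connected cluster of occupied sites.

    ``connectivity=4`` joins orthogonally adjacent cells only;
    ``connectivity=8`` also joins diagonal neighbours.  Empty lattice -> 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, n_labels = ndimage.label(state.occupancy, structure=structure)
    if n_labels == 0:
        return 0
    counts = np.bincount(labels.ravel())[1:]
    return int(counts.max())


def binning_variance(state: LatticeState, bin_width: int) -> float:
    """Q_k: squared deviation of quadrat counts from the uniform expectation.

    The lattice is tiled by non-overlapping ``k x k`` quadrats (k must divide
    both dimensions); ``Q_k = sum_b (n(b) - N/B_k)^2`` over the ``B_k = RC/k^2``
    quadrats.
    """
    n_rows, n_cols = state.occupancy.shape
    k = bin_width
    if n_rows % k or n_cols % k:
        raise ValueError(f"bin width {k} must divide the {n_rows}x{n_cols} lattice")
    counts = (
        state.occupancy.astype(np.int64)
        .reshape(n_rows // k, k, n_cols // k, k)
        .sum(axis=(1, 3))
    )
    n_bins = counts.size
    expected = len(state.cells) / n_bins
    return float(((counts - expected) ** 2).sum())


def _trajectory_array(trajectories) -> np.ndarray:
    """Stack trajectories into (n_cells, n_records, 2)."""
    if isinstance(trajectories, np.ndarray):
        return trajectories
    return np.stack([t.positions for t in trajectories])


def manhattan_displacement(trajectories) -> float:
    """Mean over tracked cells of the summed L1 distance between consecutive
    recorded positions, in lattice units."""
    pos = _trajectory_array(trajectories)
    if pos.shape[1] < 2:
        raise ValueError("trajectories need at least two recorded positions")
    steps = np.abs(np.diff(pos, axis=1)).sum(axis=(1, 2))
    return float(steps.mean())


def tortuosity(trajectories) -> float:
    """Mean over tracked cells of path length / net L1 displacement.

    A cell that returns exactly to its starting site has an undefined ratio
    and is excluded from the average; if every tracked cell is degenerate the
    statistic is NaN (the replicate carries no tortuosity information).
    """
    pos = _trajectory_array(trajectories)
    path = np.abs(np.diff(pos, axis=1)).sum(axis=(1, 2)).astype(float)
    net = np.abs(pos[:, -1] - pos[:, 0]).sum(axis=1).astype(float)
    ok = net > 0
    if not ok.any():
        return float("nan")
    return float((path[ok] / net[ok]).mean())


def gyration_min_eigenvalue(state: LatticeState, absolute: bool = False) -> float:
    """Smaller eigenvalue of the 2x2 gyration tensor built from pairwise
    coordinate differences with a 1/N^2 normalization over the i<j half-range.

    With signed differences (default) the tensor is positive semidefinite and
    the smaller eigenvalue measures spread along the minor principal axis;
    ``absolute=True`` uses |dx|,|dy| products in the off-diagonal instead, for
    sensitivity checks.  N < 2 -> 0.
    """
    cells = state.cells
    n = len(cells)
    if n < 2:
        return 0.0
    x = cells[:, 0].astype(float)
    y = cells[:, 1].astype(float)
    if absolute:
        dx = np.abs(x[:, None] - x[None, :])
        dy = np.abs(y[:, None] - y[None, :])
        iu = np.triu_indices(n, k=1)
        g11 = float((dx[iu] * dx[iu]).sum())
        g12 = float((dx[iu] * dy[iu]).sum())
        g22 = float((dy[iu] * dy[iu]).sum())
    else:
        # closed form: sum_{i<j} (xi-xj)(yi-yj) = N*sum(xy) - sum(x)*sum(y)
        g11 = n * float((x * x).sum()) - float(x.sum()) ** 2
        g12 = n * float((x * y).sum()) - float(x.sum()) * float(y.sum())
        g22 = n * float((y * y).sum()) - float(y.sum()) ** 2
    g11 /= n * n
    g12 /= n * n
    g22 /= n * n
    # eigenvalues of [[g11, g12], [g12, g22]]
    mean = 0.5 * (g11 + g22)
    half_gap = np.hypot(0.5 * (g11 - g22), g12)
    return float(mean - half_gap)


def pair_correlation(
    state: LatticeState, mode: str, max_lag: int = MAX_LAG
) -> np.ndarray:
    """Counts of unordered cell pairs at each separation ``l = 1..max_lag``.

    ``mode="Y"`` uses the vertical separation |dy| only (informative when the
    initial condition is heterogeneous in y); ``mode="XY"`` uses the full
    Manhattan separation |dx| + |dy|.  Pairs at separation 0 or beyond
    ``max_lag`` are not recorded.
    """
    if mode not in ("Y", "XY"):
        raise ValueError("mode must be 'Y' or 'XY'")
    cells = state.cells
    if len(cells) < 2:
        return np.zeros(max_lag, dtype=float)
    return _pair_counts(
        np.ascontiguousarray(cells[:, 0]),
        np.ascontiguousarray(cells[:, 1]),
        mode == "XY",
        max_lag,
    )


@njit(cache=True)
def _pair_counts(xs, ys, use_xy, max_lag):
    counts = np.zeros(max_lag, dtype=np.float64)
    n = len(xs)
    for i in range(n):
        for j in range(i + 1, n):
            sep = abs(ys[i] - ys[j])
            if use_xy:
                sep += abs(xs[i] - xs[j])
            if 1 <= sep <= max_lag:
                counts[sep - 1] += 1.0
    return counts


def expected_pair_count(l: int, mode: str, n_cells: int, n_rows: int, n_cols: int) -> float:
    """Expected number of cell pairs at separation ``l`` under complete spatial
    randomness of ``n_cells`` cells on the lattice.

    The site-pair count at separation ``l`` is multiplied by
    ``rho * rho_bar = (N / RC) * ((N-1) / (RC-1))``, the probability that both
    sites of a pair are occupied.
    """
    if l < 1:
        raise ValueError("separation must be >= 1")
    r, c = n_rows, n_cols
    rho = n_cells / (c * r)
    rho_bar = (n_cells - 1) / (c * r - 1)
    if mode == "Y":
        # any column for each cell of the pair, rows l apart: C^2 (R - l)
        site_pairs = c * c * max(r - l, 0)
    elif mode == "XY":
        site_pairs = c * max(r - l, 0) + max(c - l, 0) * r
        for j in range(1, l):
            site_pairs += 2 * max(c - j, 0) * max(r - (l - j), 0)
    else:
        raise ValueError("mode must be 'Y' or 'XY'")
    return float(site_pairs) * rho * rho_bar


def normalize_correlation(
    raw: np.ndarray, mode: str, n_cells: int, n_rows: int, n_cols: int
) -> np.ndarray:
    """Elementwise ratio of observed to expected pair counts, Chat(l).

    Elements with zero expected count (separations not realizable on the
    window) are NaN and excluded from downstream distances.
    """
    out = np.full(len(raw), np.nan)
    if n_cells < 2:
        return out
    for i in range(len(raw)):
        q = expected_pair_count(i + 1, mode, n_cells, n_rows, n_cols)
        if q > 0:
            out[i] = raw[i] / q
    return out


def compute_statistic_set(
    replicate: ReplicateResult,
    statistic_ids=STATISTIC_IDS,
    max_lag: int = MAX_LAG,
    gyration_absolute: bool = False,
) -> dict[str, np.ndarray]:
    """All requested statistics for one replicate, as ``{id: values}`` with
    values of length 1 (scalars) or ``max_lag`` (pair correlations)."""
    state = replicate.final_state
    n_rows, n_cols = state.occupancy.shape
    n = len(state.cells)
    out: dict[str, np.ndarray] = {}
    need = set(statistic_ids)
    cxy = cy = None
    if {"Cxy", "Cxy_hat"} & need:
        cxy = pair_correlation(state, "XY", max_lag)
    if {"Cy", "Cy_hat"} & need:
        cy = pair_correlation(state, "Y", max_lag)
    for sid in statistic_ids:
        if sid == "N":
            val = np.array([float(n)])
        elif sid == "kappa4":
            val = np.array([float(largest_cluster(state, 4))])
        elif sid == "kappa8":
            val = np.array([float(largest_cluster(state, 8))])
        elif sid in ("Q2", "Q4", "Q8"):
            val = np.array([binning_variance(state, int(sid[1]))])
        elif sid == "displacement":
            val = np.array([manhattan_displacement(replicate.trajectories)])
        elif sid == "tortuosity":
            val = np.array([tortuosity(replicate.trajectories)])
        elif sid == "gyration":
            val = np.array([gyration_min_eigenvalue(state, gyration_absolute)])
        elif sid == "Cxy":
            val = cxy.copy()
        elif sid == "Cxy_hat":
            val = normalize_correlation(cxy, "XY", n, n_rows, n_cols)
        elif sid == "Cy":
            val = cy.copy()
        elif sid == "Cy_hat":
            val = normalize_correlation(cy, "Y", n, n_rows, n_cols)
        else:
            raise KeyError(f"unknown statistic {sid!r}")
        out[sid] = val
    return out


def statistics_to_vector(
    stats: dict[str, np.ndarray], statistic_ids=STATISTIC_IDS, max_lag: int = MAX_LAG
) -> np.ndarray:
    """Concatenate statistics into the flat element layout of
    :func:`element_index`."""
    return np.concatenate([np.asarray(stats[sid], dtype=float) for sid in statistic_ids])
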