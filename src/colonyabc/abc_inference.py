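"""ABC rejection with MAD-weighted distances, regression adjustment and KDE.

The rejection sampler draws parameters from a uniform prior over
``(p_move, p_prolif)``, simulates M-replicate datasets under the observed
experimental design, averages each summary statistic over replicates, and
accepts the 1% of samples whose weighted distance to the observed averages is
smallest.  Distances standardize each statistic element by its median
absolute deviation (MAD) across the prior-predictive sample and average over
the elements of a statistic, so statistics of different lengths carry equal
weight; the combined distance over several statistics is the sum of squared
per-statistic distances.

Accepted parameters are optionally corrected by local-linear regression
adjustment (ordinary least squares of theta on the summary discrepancies) and
smoothed into a posterior density on a 512 x 512 grid with a Gaussian-kernel
KDE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation

from .lattice_model import (
    DesignSpec,
    LatticeConfig,
    ModelParams,
    ObservedDataset,
    _SEED_MAX,
    _run_replicate_core,
)
from .summary_statistics import (
    MAX_LAG,
    STATISTIC_IDS,
    compute_statistic_set,
    statistic_length,
    statistics_to_vector,
)

__all__ = [
    "PriorSpec",
    "SummaryLayout",
    "AcceptedSet",
    "PosteriorGrid",
    "average_over_replicates",
    "median_absolute_deviation",
    "mad_weights",
    "statistic_distance",
    "combined_distance",
    "prior_predictive_summaries",
    "observed_summaries",
    "distances_from_summaries",
    "abc_rejection",
    "regression_adjustment",
    "kde_posterior",
    "posterior_mode",
    "point_estimate_and_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior over the box ``pm_range x pp_range``.

    The default box (0, 0.99) x (0, 0.01) guarantees p_move + p_prolif <= 1.
    """

    pm_range: tuple[float, float] = (0.0, 0.99)
    pp_range: tuple[float, float] = (0.0, 0.01)

    def __post_init__(self) -> None:
        if self.pm_range[1] <= self.pm_range[0] or self.pp_range[1] <= self.pp_range[0]:
            raise ValueError("prior ranges must be non-empty intervals")
        if self.pm_range[1] + self.pp_range[1] > 1.0 + 1e-12:
            raise ValueError("prior upper corner violates p_move + p_prolif <= 1")

    @property
    def density(self) -> float:
        return 1.0 / (
            (self.pm_range[1] - self.pm_range[0]) * (self.pp_range[1] - self.pp_range[0])
        )

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        pm = rng.uniform(*self.pm_range, size=size)
        pp = rng.uniform(*self.pp_range, size=size)
        return np.column_stack([pm, pp])

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return (
            (theta[:, 0] > self.pm_range[0])
            & (theta[:, 0] < self.pm_range[1])
            & (theta[:, 1] > self.pp_range[0])
            & (theta[:, 1] < self.pp_range[1])
        )


class SummaryLayout:
    """Column layout of a flat summary matrix for an ordered set of statistics."""

    def __init__(self, statistic_ids=STATISTIC_IDS, max_lag: int = MAX_LAG):
        self.statistic_ids = tuple(statistic_ids)
        self.max_lag = max_lag
        self.slices: dict[str, slice] = {}
        start = 0
        for sid in self.statistic_ids:
            n = statistic_length(sid, max_lag)
            self.slices[sid] = slice(start, start + n)
            start += n
        self.n_elements = start

    def columns(self, statistic_ids) -> np.ndarray:
        idx: list[int] = []
        for sid in statistic_ids:
            s = self.slices[sid]
            idx.extend(range(s.start, s.stop))
        return np.array(idx, dtype=np.int64)


@dataclass
class PosteriorGrid:
    """Density over the prior box on a regular grid of cell centers.

    ``values[i, j]`` is the density at ``(pm_centers[i], pp_centers[j])`` in
    units of probability per unit (p_move x p_prolif) area; the midpoint-rule
    integral over the box is 1.
    """

    values: np.ndarray
    pm_centers: np.ndarray
    pp_centers: np.ndarray

    @property
    def cell_area(self) -> float:
        return float(
            (self.pm_centers[1] - self.pm_centers[0])
            * (self.pp_centers[1] - self.pp_centers[0])
        )

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_area)


@dataclass
class AcceptedSet:
    """Accepted 1st-percentile sample of an ABC rejection run."""

    theta: np.ndarray  # (B, 2)
    adjusted_theta: np.ndarray  # (B, 2)
    per_statistic_distance: np.ndarray  # (B, A)
    combined: np.ndarray  # (B,)
    threshold: float
    statistic_ids: tuple[str, ...]
    sigma: np.ndarray  # MAD weights for the used elements
    observed_avg: np.ndarray  # observed averages for the used elements
    summaries: np.ndarray  # (B, n_used) accepted replicate-averaged summaries
    n_prior_samples: int = 0

    def __len__(self) -> int:
        return len(self.theta)


def average_over_replicates(per_replicate_stats: list[dict[str, np.ndarray]]):
    """Elementwise mean over replicates; NaN (degenerate) elements propagate."""
    if not per_replicate_stats:
        raise ValueError("need at least one replicate")
    ids = per_replicate_stats[0].keys()
    return {
        sid: np.mean([s[sid] for s in per_replicate_stats], axis=0) for sid in ids
    }


def median_absolute_deviation(values: np.ndarray) -> float:
    """MAD = median(|X_i - median(X)|), unscaled."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))))


def mad_weights(summaries: np.ndarray, layout: SummaryLayout) -> np.ndarray:
    """Per-element MAD across prior-predictive samples, with flooring.

    Elements whose MAD is zero are floored at the smallest positive MAD among
    that statistic's elements; if every element of a statistic has zero MAD
    the elements are dropped (NaN) and excluded from distances.
    """
    sigma = median_abs_deviation(summaries, axis=0, scale=1.0, nan_policy="omit")
    sigma = np.asarray(sigma, dtype=float)
    for sid in layout.statistic_ids:
        s = layout.slices[sid]
        block = sigma[s]
        positive = block[np.isfinite(block) & (block > 0)]
        zero = np.isfinite(block) & (block == 0)
        if zero.any():
            if positive.size:
                floor = positive.min()
                logger.info("MAD floor applied to %d element(s) of %s", zero.sum(), sid)
                block[zero] = floor
            else:
                logger.warning("statistic %s has zero MAD everywhere; dropped", sid)
                block[zero] = np.nan
        sigma[s] = block
    return sigma


def statistic_distance(
    simulated: np.ndarray, observed: np.ndarray, sigma: np.ndarray
) -> float:
    """Length-averaged squared standardized discrepancy for one statistic.

    Elements with NaN weight are excluded from the average; a NaN simulated
    value (a degenerate statistic) makes the distance infinite so the sample
    is never accepted.
    """
    use = np.isfinite(sigma) & np.isfinite(observed)
    if not use.any():
        raise ValueError("no usable elements: all weights are zero or dropped")
    s = np.asarray(simulated, dtype=float)[use]
    if not np.isfinite(s).all():
        return float("inf")
    z = (s - observed[use]) / sigma[use]
    return float(np.mean(z * z))


def combined_distance(d_values) -> float:
    """Sum of squared per-statistic distances."""
    d = np.asarray(d_values, dtype=float)
    return float(np.sum(d * d))


def _simulate_summary_row(
    theta: np.ndarray,
    design: DesignSpec,
    config: LatticeConfig,
    statistic_ids,
    max_lag: int,
    seed: int,
) -> np.ndarray:
    """Replicate-averaged summary vector for one parameter draw."""
    params = ModelParams(float(theta[0]), float(theta[1]))
    rng = np.random.default_rng(seed)
    seeds = rng.integers(_SEED_MAX, size=design.n_replicates)
    rows = []
    for s in seeds:
        rep = _run_replicate_core(design, params, config, int(s))
        rows.append(
            statistics_to_vector(
                compute_statistic_set(rep, statistic_ids, max_lag), statistic_ids, max_lag
            )
        )
    return np.mean(rows, axis=0)


def prior_predictive_summaries(
    prior: PriorSpec,
    design: DesignSpec,
    config: LatticeConfig,
    statistic_ids,
    n_samples: int,
    rng,
    max_lag: int = MAX_LAG,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_samples`` parameters from the prior and simulate their
    replicate-averaged summaries.  Returns ``(thetas, summaries)``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    thetas = prior.sample(rng, n_samples)
    seeds = rng.integers(_SEED_MAX, size=n_samples)
    layout = SummaryLayout(statistic_ids, max_lag)
    summaries = np.empty((n_samples, layout.n_elements))
    for k in range(n_samples):
        summaries[k] = _simulate_summary_row(
            thetas[k], design, config, statistic_ids, max_lag, int(seeds[k])
        )
    return thetas, summaries


def observed_summaries(
    observed: ObservedDataset, statistic_ids, max_lag: int = MAX_LAG
) -> np.ndarray:
    """Replicate-averaged summary vector of the observed dataset."""
    rows = [
        statistics_to_vector(
            compute_statistic_set(rep, statistic_ids, max_lag), statistic_ids, max_lag
        )
        for rep in observed.replicates
    ]
    return np.mean(rows, axis=0)


def distances_from_summaries(
    summaries: np.ndarray,
    observed_avg: np.ndarray,
    sigma: np.ndarray,
    layout: SummaryLayout,
    statistic_ids,
    convention: str = "squared",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-statistic and combined distances for every row of ``summaries``.

    ``convention="squared"`` keeps the squared-form per-statistic distance;
    ``"sqrt"`` takes its square root before combining (a sensitivity option
    that leaves single-statistic rankings unchanged).
    """
    n = len(summaries)
    a = len(tuple(statistic_ids))
    per_stat = np.empty((n, a))
    for j, sid in enumerate(statistic_ids):
        s = layout.slices[sid]
        for k in range(n):
            per_stat[k, j] = statistic_distance(
                summaries[k, s], observed_avg[s], sigma[s]
            )
    if convention == "sqrt":
        per_stat = np.sqrt(per_stat)
    elif convention != "squared":
        raise ValueError("convention must be 'squared' or 'sqrt'")
    combined = np.sum(per_stat * per_stat, axis=1)
    return per_stat, combined


def _accept_from_distances(
    thetas, summaries, per_stat, combined, acceptance_fraction
) -> tuple[np.ndarray, float]:
    n_accept = math.ceil(acceptance_fraction * len(thetas))
    order = np.argsort(combined, kind="stable")
    idx = order[:n_accept]
    threshold = float(combined[idx[-1]])
    return idx, threshold


def abc_rejection(
    observed: ObservedDataset,
    statistic_ids,
    n_samples: int = 10_000,
    prior: PriorSpec | None = None,
    rng=None,
    acceptance_fraction: float = 0.01,
    adjust: bool = True,
    convention: str = "squared",
    max_lag: int = MAX_LAG,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> AcceptedSet:
    """ABC rejection accepting the smallest-distance percentile of the prior
    sample.

    ``statistic_ids`` selects 1-3 statistics for the distance.  MAD weights
    are estimated from the prior-predictive sample of the same run.
    ``precomputed`` may supply ``(thetas, summaries)`` from
    :func:`prior_predictive_summaries` (for a superset layout equal to
    ``statistic_ids``) to reuse simulations across statistic choices.
    """
    statistic_ids = tuple(statistic_ids)
    if not 1 <= len(statistic_ids) <= 3:
        raise ValueError("choose between 1 and 3 summary statistics")
    prior = prior or PriorSpec()
    layout = SummaryLayout(statistic_ids, max_lag)
    if precomputed is not None:
        thetas, summaries = precomputed
        if summaries.shape[1] != layout.n_elements:
            raise ValueError("precomputed summaries do not match the statistic layout")
    else:
        if n_samples < 100:
            raise ValueError("need at least 100 prior samples for 1% acceptance")
        thetas, summaries = prior_predictive_summaries(
            prior, observed.design, observed.config, statistic_ids, n_samples, rng, max_lag
        )
    obs_avg = observed_summaries(observed, statistic_ids, max_lag)
    sigma = mad_weights(summaries, layout)
    per_stat, combined = distances_from_summaries(
        summaries, obs_avg, sigma, layout, statistic_ids, convention
    )
    idx, threshold = _accept_from_distances(
        thetas, summaries, per_stat, combined, acceptance_fraction
    )
    theta_acc = thetas[idx]
    summ_acc = summaries[idx]
    if adjust:
        adjusted = regression_adjustment(theta_acc, summ_acc, obs_avg, prior)
    else:
        adjusted = theta_acc.copy()
    return AcceptedSet(
        theta=theta_acc,
        adjusted_theta=adjusted,
        per_statistic_distance=per_stat[idx],
        combined=combined[idx],
        threshold=threshold,
        statistic_ids=statistic_ids,
        sigma=sigma,
        observed_avg=obs_avg,
        summaries=summ_acc,
        n_prior_samples=len(thetas),
    )


def regression_adjustment(
    theta: np.ndarray,
    summaries: np.ndarray,
    observed_avg: np.ndarray,
    prior: PriorSpec | None = None,
) -> np.ndarray:
    """Local-linear regression adjustment of accepted parameters.

    Ordinary least squares of each parameter on the summary discrepancies
    ``s - s_obs`` (with intercept); adjusted values are
    ``theta* = theta - (s - s_obs) @ beta_hat``, clipped to the prior box.
    A rank-deficient design leaves the parameters unadjusted.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    ds = np.asarray(summaries, dtype=float) - np.asarray(observed_avg, dtype=float)
    # drop unusable regressors: non-finite or constant across the accepted set
    cols = np.all(np.isfinite(ds), axis=0) & (np.ptp(ds, axis=0) > 0)
    ds = ds[:, cols]
    n, p = ds.shape
    if n <= p + 1:
        logger.warning("too few accepted samples (%d) for %d regressors; skipped", n, p)
        return theta.copy()
    x = np.column_stack([np.ones(n), ds])
    beta, _, rank, _ = np.linalg.lstsq(x, theta, rcond=None)
    if rank < x.shape[1]:
        logger.warning("rank-deficient regression design; adjustment skipped")
        return theta.copy()
    adjusted = theta - ds @ beta[1:]
    if prior is not None:
        lo = np.array([prior.pm_range[0], prior.pp_range[0]])
        hi = np.array([prior.pm_range[1], prior.pp_range[1]])
        n_clip = int(np.sum((adjusted < lo) | (adjusted > hi)))
        if n_clip:
            logger.info("clipped %d adjusted coordinate(s) to the prior box", n_clip)
        adjusted = np.clip(adjusted, lo, hi)
    return adjusted


def _grid_centers(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def kde_posterior(
    theta: np.ndarray,
    prior: PriorSpec | None = None,
    grid_size: int = 512,
    bandwidth_floor: float | None = None,
) -> PosteriorGrid:
    """Gaussian-kernel density of parameter samples on a grid over the prior
    box.

    The two parameters differ by two orders of magnitude in scale, so samples
    are affinely rescaled to the unit square before applying Silverman's
    per-dimension bandwidth, floored at one grid cell (1/grid_size).  Mass
    leaking outside the box is renormalized away, so the midpoint-rule
    integral over the box is exactly 1.
    """
    prior = prior or PriorSpec()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if len(theta) < 2:
        raise ValueError("need at least two samples for a KDE")
    if bandwidth_floor is None:
        bandwidth_floor = 1.0 / grid_size
    lo = np.array([prior.pm_range[0], prior.pp_range[0]])
    hi = np.array([prior.pm_range[1], prior.pp_range[1]])
    u = (theta - lo) / (hi - lo)  # unit-square coordinates
    n = len(u)
    # Silverman's rule per dimension for a bivariate Gaussian kernel
    h = np.std(u, axis=0, ddof=1) * n ** (-1.0 / 6.0)
    h = np.maximum(h, bandwidth_floor)
    centers = _grid_centers(0.0, 1.0, grid_size)
    # separable kernel: density = Ku^T @ Kv summed over samples
    gu = np.exp(-0.5 * ((centers[None, :] - u[:, 0:1]) / h[0]) ** 2)
    gv = np.exp(-0.5 * ((centers[None, :] - u[:, 1:2]) / h[1]) ** 2)
    values = gu.T @ gv  # (grid_pm, grid_pp)
    cell = 1.0 / grid_size
    total = values.sum() * cell * cell
    if total <= 0:
        raise ValueError("degenerate KDE: no mass on the grid")
    values /= total  # unit-square density, renormalized over the box
    # convert to density per original-parameter area
    values = values / ((hi[0] - lo[0]) * (hi[1] - lo[1]))
    return PosteriorGrid(
        values=values,
        pm_centers=_grid_centers(lo[0], hi[0], grid_size),
        pp_centers=_grid_centers(lo[1], hi[1], grid_size),
    )


def posterior_mode(grid: PosteriorGrid) -> tuple[float, float]:
    """Location of the grid argmax, the KDE analogue of an MLE point estimate."""
    i, j = np.unravel_index(np.argmax(grid.values), grid.values.shape)
    return float(grid.pm_centers[i]), float(grid.pp_centers[j])


def point_estimate_and_ci(
    samples: np.ndarray, interval: float = 0.90
) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and empirical central interval (default 5th-95th
    percentiles, linear interpolation) per parameter column."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    alpha = 100.0 * (1.0 - interval) / 2.0
    est = samples.mean(axis=0)
    ci = np.percentile(samples, [alpha, 100.0 - alpha], axis=0).T  # (n_params, 2)
    return est, ci
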