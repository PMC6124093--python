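"""Data-cloning ABC-MCMC for maximum-likelihood estimation.

Data cloning targets the likelihood raised to the K-th power by treating K
independent pseudo-datasets ("clones") as if they were real observations: as
K grows the tempered posterior concentrates on the maximum-likelihood
estimate while remaining samplable by ABC-MCMC.  The chain runs through a
staged schedule: P populations with a decreasing ABC tolerance (K = 1),
followed by Q populations with an increasing clone count at the final
tolerance.  Within a population, proposals are accepted with a Metropolis
ratio of products of per-clone Gaussian ABC kernels
``exp(-d / (2 eps^2))`` built on the same MAD-weighted distances as ABC
rejection (for a single statistic ``d = d_j^2`` exactly).

The MLE is approximated by the mean of the final population; the 5th-95th
percentiles of that population give a (deliberately narrow) credible
interval for comparison with rejection ABC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .abc_inference import (
    AcceptedSet,
    PriorSpec,
    SummaryLayout,
    _simulate_summary_row,
    abc_rejection,
    observed_summaries,
    point_estimate_and_ci,
    regression_adjustment,
    statistic_distance,
)
from .lattice_model import _SEED_MAX, ObservedDataset
from .summary_statistics import MAX_LAG

__all__ = ["DCSchedule", "DCResult", "gaussian_abc_kernel", "run_abc_dc"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DCSchedule:
    """Per-population sample counts, clone counts and tolerances.

    The default scheme has P = 5 tolerance-decreasing populations followed by
    Q = 4 clone-increasing populations:
    r = (1000 x 8, 2000), K = (1,1,1,1,1,1,2,3,4),
    eps = (5, 2, 1, 0.5, 0.25, 0.25, 0.25, 0.25, 0.25).
    """

    n_samples: tuple[int, ...] = (1000,) * 8 + (2000,)
    n_clones: tuple[int, ...] = (1, 1, 1, 1, 1, 1, 2, 3, 4)
    tolerance: tuple[float, ...] = (5.0, 2.0, 1.0, 0.5, 0.25, 0.25, 0.25, 0.25, 0.25)
    n_tolerance_stages: int = 5
    n_clone_stages: int = 4

    def __post_init__(self) -> None:
        p_q = self.n_tolerance_stages + self.n_clone_stages
        if not len(self.n_samples) == len(self.n_clones) == len(self.tolerance) == p_q:
            raise ValueError("schedule arrays must have length P + Q")
        if any(b > a for a, b in zip(self.tolerance, self.tolerance[1:])):
            raise ValueError("tolerances must be non-increasing")
        if any(b < a for a, b in zip(self.n_clones, self.n_clones[1:])):
            raise ValueError("clone counts must be non-decreasing")

    @property
    def n_populations(self) -> int:
        return len(self.n_samples)


@dataclass
class DCResult:
    mle: np.ndarray  # (2,)
    interval: np.ndarray  # (2, 2) rows (lo, hi) per parameter
    final_theta: np.ndarray  # (r_last, 2) raw final population
    final_theta_adjusted: np.ndarray  # regression-adjusted final population
    chain: np.ndarray  # (total, 5): population, iteration, pm, pp, accepted
    acceptance_rates: np.ndarray  # per population


def gaussian_abc_kernel(distance: float, tolerance: float) -> float:
    """Gaussian ABC kernel exp(-d_j^2 / (2 eps^2)) in (0, 1]."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    return float(np.exp(-(distance**2) / (2.0 * tolerance**2)))


def _clone_log_weight(distances: np.ndarray, tolerance: float) -> float:
    """Log product of per-clone kernels; the combined distance plays the role
    of the squared per-statistic distance."""
    return float(-np.sum(distances) / (2.0 * tolerance**2))


def _simulate_clones(theta, observed, layout, statistic_ids, sigma, obs_avg, n_clones, rng):
    """Per-clone combined distances and the clone-averaged summary vector."""
    dists = np.empty(n_clones)
    summ = np.zeros(layout.n_elements)
    for c in range(n_clones):
        row = _simulate_summary_row(
            theta,
            observed.design,
            observed.config,
            layout.statistic_ids,
            layout.max_lag,
            int(rng.integers(_SEED_MAX)),
        )
        d = 0.0
        for sid in statistic_ids:
            s = layout.slices[sid]
            dj = statistic_distance(row[s], obs_avg[s], sigma[s])
            d += dj * dj
        dists[c] = d
        summ += row
    return dists, summ / n_clones


def run_abc_dc(
    observed: ObservedDataset,
    statistic_ids,
    schedule: DCSchedule | None = None,
    prior: PriorSpec | None = None,
    rng=None,
    pilot: AcceptedSet | None = None,
    pilot_samples: int = 1000,
    proposal_scale: tuple[float, float] = (0.02, 0.0002),
    adapt_proposals: bool = True,
    refresh: str = "iteration",
    sigma: np.ndarray | None = None,
    adjust: bool = True,
    max_lag: int = MAX_LAG,
) -> DCResult:
    """Run the staged data-cloning ABC-MCMC and return the MLE approximation.

    The chain is initialized at the smallest-distance accepted sample of a
    pilot ABC rejection run.  The kernel's MAD weights are estimated from the
    *accepted* sample of that rejection run: accepted-level variability sets
    the O(1) distance scale that the tolerance schedule (ending at
    eps = 0.25) presumes, whereas prior-predictive MADs would leave all
    distances far below the final tolerance and the kernel flat.  Pass
    ``pilot`` to reuse an existing rejection run, or ``sigma`` to override
    the weights; otherwise a pilot of ``pilot_samples`` prior draws is
    performed internally.

    ``refresh`` controls the current state's kernel values:
    ``"iteration"`` (default) re-simulates them for every comparison (the
    noisy-MCMC convention), which keeps the chain mobile when the cloned
    kernel product becomes sharp; ``"stage"`` freezes them between iterations
    (pseudo-marginal convention, cheaper but prone to sticking at a lucky
    realization in the clone stages) with one refresh per population
    boundary.  With ``adapt_proposals`` the random-walk scale is re-tuned at
    each boundary to the spread of the previous population, so acceptance
    rates stay usable as the tempered posterior tightens.
    """
    if refresh not in ("iteration", "stage"):
        raise ValueError("refresh must be 'iteration' or 'stage'")
    statistic_ids = tuple(statistic_ids)
    schedule = schedule or DCSchedule()
    prior = prior or PriorSpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    layout = SummaryLayout(statistic_ids, max_lag)

    if pilot is None:
        # keep at least ~20 accepted samples so the accepted-set MADs and the
        # chain's starting point are usable even for small pilots
        fraction = max(0.01, min(1.0, 20.0 / pilot_samples))
        pilot = abc_rejection(
            observed, statistic_ids, n_samples=pilot_samples, prior=prior,
            rng=rng, acceptance_fraction=fraction, adjust=False, max_lag=max_lag,
        )
    elif tuple(pilot.statistic_ids) != statistic_ids:
        raise ValueError("pilot run used different statistics")
    if sigma is None:
        from .abc_inference import mad_weights

        sigma = mad_weights(pilot.summaries, layout)
    obs_avg = observed_summaries(observed, statistic_ids, max_lag)

    theta = pilot.theta[np.argmin(pilot.combined)].astype(float).copy()
    scale = np.asarray(proposal_scale, dtype=float)
    # adaptation bounds: never below 0.1% of the prior width, never above the
    # starting scale
    width = np.array(
        [prior.pm_range[1] - prior.pm_range[0], prior.pp_range[1] - prior.pp_range[0]]
    )
    scale_floor = 1e-3 * width

    chain_rows: list[tuple[int, int, float, float, int]] = []
    acc_rates = np.zeros(schedule.n_populations)
    final_theta = None
    final_summaries = None

    cur_dists = None
    cur_summ = None
    for pop in range(schedule.n_populations):
        eps = schedule.tolerance[pop]
        k_clones = schedule.n_clones[pop]
        r = schedule.n_samples[pop]
        # refresh the retained state's realization for the new stage
        cur_dists, cur_summ = _simulate_clones(
            theta, observed, layout, statistic_ids, sigma, obs_avg, k_clones, rng
        )
        cur_lw = _clone_log_weight(cur_dists, eps)
        n_acc = 0
        is_final = pop == schedule.n_populations - 1
        pop_theta = np.empty((r, 2))
        if is_final:
            final_summaries = np.empty((r, layout.n_elements))
        for it in range(r):
            proposal = theta + rng.normal(0.0, scale)
            accepted = 0
            if prior.contains(proposal)[0]:
                if refresh == "iteration":
                    cur_dists, cur_summ = _simulate_clones(
                        theta, observed, layout, statistic_ids, sigma, obs_avg,
                        k_clones, rng,
                    )
                    cur_lw = _clone_log_weight(cur_dists, eps)
                prop_dists, prop_summ = _simulate_clones(
                    proposal, observed, layout, statistic_ids, sigma, obs_avg,
                    k_clones, rng,
                )
                prop_lw = _clone_log_weight(prop_dists, eps)
                if np.log(rng.uniform()) < prop_lw - cur_lw:
                    theta = proposal
                    cur_dists, cur_summ = prop_dists, prop_summ
                    cur_lw = prop_lw
                    accepted = 1
            n_acc += accepted
            chain_rows.append((pop, it, float(theta[0]), float(theta[1]), accepted))
            pop_theta[it] = theta
            if is_final:
                final_summaries[it] = cur_summ
        acc_rates[pop] = n_acc / r
        if is_final:
            final_theta = pop_theta
        elif adapt_proposals:
            spread = pop_theta.std(axis=0, ddof=1)
            scale = np.clip(spread, scale_floor, np.asarray(proposal_scale, dtype=float))
        logger.info(
            "population %d (eps=%.3g, K=%d): acceptance rate %.3f",
            pop, eps, k_clones, acc_rates[pop],
        )
        if n_acc == 0 and r >= 100:
            raise RuntimeError(
                f"chain stuck: zero acceptances over population {pop} "
                f"(eps={eps}, K={k_clones}); widen the tolerance schedule or "
                "shrink the proposal scale"
            )

    if adjust:
        final_adjusted = regression_adjustment(
            final_theta, final_summaries, obs_avg, prior
        )
    else:
        final_adjusted = final_theta.copy()
    mle, interval = point_estimate_and_ci(final_adjusted)
    return DCResult(
        mle=mle,
        interval=interval,
        final_theta=final_theta,
        final_theta_adjusted=final_adjusted,
        chain=np.array(chain_rows, dtype=float),
        acceptance_rates=acc_rates,
    )
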