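# Methods

## The mechanistic model

`colonyabc` simulates a two-dimensional lattice exclusion process of cell
motility and proliferation. `N(t)` agents occupy distinct sites of an
`R x C` square lattice of site length Δ (default 24 x 32, Δ = 18.75 μm, one
cell diameter). During each step of duration τ (default 1/24 h), `N(t)`
agents are selected uniformly at random *with replacement* from the
population present at the start of the step; daughters born within a step
are not eligible until the next step. A selected agent draws
`r ~ U(0, 1)`: `r ≤ P_m` attempts a move into one of the four orthogonal
neighbour sites chosen uniformly; `P_m < r ≤ P_m + P_p` attempts to place a
daughter there; otherwise nothing happens. Attempts onto occupied sites or
across the boundary abort (no-flux boundaries, volume exclusion). There is
no death, adhesion or directed motion: the model is deliberately the
simplest individual-based description with contact inhibition, and its
continuum limits are the diffusivity `D = P_m Δ²/(4τ)` (527.34 μm²/h at the
defaults) and proliferation rate `λ = P_p/τ` (0.06 /h).

Coordinates are 0-based `(column, row) = (x, y)` with row 0 at the seeded
edge. An experimental *design* consists of: the number of rows into which
the `N(0)` founder cells are seeded uniformly at random (24 rows ≈
growth-to-confluence; 6 rows ≈ scratch assay), the assay duration `T`
(12 h = 288 steps), the number of replicates `M = 10`, and 5 tracked founder
cells whose positions are recorded every 8 steps (20 min), including step 0
— 37 recorded positions, 36 increments. Daughters are never tracked.
`observation_window` can restrict statistics to a sub-grid when the
simulated dish is larger than the imaged field.

### What the generator does and does not emulate

The synthetic "observed" datasets share every protocol feature of the real
assays they stand in for (geometry, duration, replication, tracking
cadence) but none of the imaging artefacts: no segmentation error, no
lattice-mapping distortion of slow-moving cells, no uneven illumination.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model, not robustness to model misspecification.

## Summary statistics

Thirteen statistics summarize a replicate; all but the two trajectory
statistics are functions of the final-time positions.

| statistic | definition | length |
|---|---|---|
| `N` | final cell count | 1 |
| `kappa4`, `kappa8` | largest 4-/8-connected cluster size | 1 |
| `Q2`, `Q4`, `Q8` | `Σ_b (n(b) − N/B_k)²` over non-overlapping k×k quadrats | 1 |
| `displacement` | mean over tracked cells of summed L1 increments between recorded frames | 1 |
| `tortuosity` | mean of path length / net L1 displacement | 1 |
| `gyration` | smaller eigenvalue of the pairwise gyration tensor | 1 |
| `Cy`, `Cxy` | counts of unordered pairs at vertical / Manhattan separation l | 24 |
| `Cy_hat`, `Cxy_hat` | the above normalized by the expected pair count under spatial randomness | 24 |

Numerical conventions, chosen where the definitions leave room:

- **Gyration tensor** uses *signed* coordinate differences with the literal
  `1/N²` half-range normalization, making the tensor positive semidefinite;
  an `absolute=True` variant exists for sensitivity checks (diagonal entries
  agree either way). `N < 2` gives 0.
- **Tortuosity degeneracy**: a tracked cell returning exactly to its start
  has an undefined ratio and is excluded from the average; if all tracked
  cells are degenerate the replicate's value is NaN, which propagates
  through replicate averaging and makes any distance using it infinite — the
  parameter sample is effectively rejected rather than given an arbitrary
  value.
- **Correlation lags** run 1…24 for both modes even though Manhattan
  separations up to R+C−2 exist; pairs beyond lag 24 (and same-row pairs for
  the vertical mode) are simply uncounted. Expected pair counts use
  `q_Y(l) = C²(R−l)ρρ̄` and the three-term Manhattan site-pair closed form,
  with factors clipped at zero so both formulas remain exact pair counts on
  arbitrary windows; lags with zero expectation yield NaN and are excluded
  from distances.
- Cluster size on an empty lattice is 0.

## ABC rejection

K parameter pairs are drawn from the uniform prior on
`(0, 0.99) × (0, 0.01)` (the box keeps `P_m + P_p ≤ 1`). Each draw is
simulated for M replicates under the observed design and every statistic is
averaged over replicates. Distances standardize each element by σ_j(l), the
median absolute deviation of that element **across the K prior-predictive
replicate-averaged samples of the same run** — the only self-contained
choice — and average over the L_j elements of a statistic:
`d_j = (1/L_j) Σ_l ((s̄_j(l) − s̄_j^obs(l))/σ_j(l))²`, combined over the A ≤ 3
chosen statistics as `d = Σ_a d_a²` (a `sqrt` convention switch exists; for
a single statistic the acceptance ranking is unchanged). Elements with zero
MAD are floored at the smallest positive MAD of that statistic, or dropped
if the whole statistic is constant; both events are logged. The smallest
`⌈0.01 K⌉` distances are accepted (default K = 10,000), avoiding an explicit
ε.

**Regression adjustment** fits each parameter by ordinary least squares on
the summary discrepancies `s − s_obs` over the accepted set and moves each
accepted θ along the fitted plane to the observed summary. Non-finite or
constant discrepancy columns are dropped; if fewer accepted samples than
regressors remain, the adjustment is skipped with a warning. Adjusted values
are clipped to the prior box (clips counted in the log).

**KDE posteriors**: the two parameters differ by two orders of magnitude in
scale, so accepted samples are rescaled to the unit square before a
separable Gaussian KDE with per-dimension Silverman bandwidths
(`σ̂ n^{-1/6}`), floored at one grid cell (1/512). The 512 × 512 grid of cell
centers is renormalized over the box (kernel mass leaking outside is
discarded), so the midpoint-rule integral is exactly 1. The "MLE"-style
point estimate of a rejection run is reported as the KDE mode (grid
argmax); the
sample mean and empirical 5–95% percentiles (linear interpolation) are also
computed.

## Data-cloning ABC-MCMC

Data cloning targets `L(D_obs | θ)^K π(θ)`: K independent pseudo-datasets
("clones") are simulated per proposal and their Gaussian ABC kernels
multiplied, so as K grows the tempered posterior concentrates on the MLE.
The staged schedule is r = (1000 × 8, 2000) samples per population,
tolerances ε = (5, 2, 1, 0.5, 0.25) over the first P = 5 populations, then
clones K = (1, 2, 3, 4) over the final Q = 4 populations at ε = 0.25. The
kernel is `exp{−d/(2ε²)}` with the combined distance playing the role of
the squared single-statistic distance (for one statistic this is exactly
`exp{−d_j²/(2ε²)}`). The MLE is the mean of the final 2000-sample
population (after regression adjustment using the stored summary vectors —
a post-hoc placement that leaves the chain's dynamics untouched); the
5–95% percentiles of that population give the deliberately narrow
credible interval.

Choices the staged algorithm leaves open, and how they are resolved here:

- **Kernel scale.** The tolerance schedule bottoming out at ε = 0.25
  presumes distances of order one for acceptable parameters. MADs taken
  over the *prior-predictive* sample leave distances at the truth around
  10⁻³ — the kernel is then flat over most of the prior and the chain never
  concentrates. The DC kernel therefore uses MADs estimated from the
  *accepted* sample of a pilot rejection run (the pilot also supplies the
  chain's starting point: its smallest-distance accepted sample). With this
  scale, accepted-level discrepancies sit at O(ε) and the staged schedule
  behaves as described. An explicit `sigma` argument allows sensitivity
  analysis.
- **Current-state noise.** By default the current state's kernel values are
  re-simulated for every comparison (the noisy-MCMC convention). The
  cheaper pseudo-marginal alternative (`refresh="stage"`), which freezes the
  current realization within a population, sticks at lucky simulation draws
  once the cloned kernel product sharpens (acceptance rates below 1%,
  collapsed final populations) and is kept only as a diagnostic option.
- **Proposals.** Symmetric Gaussian random walk, initial scales
  (0.02, 0.0002) ≈ the accepted-set spread of a pilot run, re-tuned at each
  population boundary to the standard deviation of the previous population,
  clipped to [10⁻³ × prior width, initial scale]. Proposals outside the
  prior box are rejected outright. A population of ≥100 iterations with
  zero acceptances aborts with a diagnostic rather than returning a frozen
  chain.

## Information gain and the design study

Posterior quality is scored by `I_KL(F ∥ G) = ∫ F ln(F/G) dθ` between the
KDE posterior and the uniform prior, computed by the midpoint rule on the
shared 512 × 512 mesh with the `0 ln 0 = 0` convention (non-negative up to
quadrature error ~10⁻¹⁰). The design study repeats, for every (design,
statistic-combination) cell, the full pipeline — fresh observed dataset,
fresh prior-predictive pass, rejection, adjustment, KDE, KL — with
independent seeds, reporting mean ± standard deviation over repetitions.
The K prior-predictive simulations of a design are cached and reused across
all statistic combinations of that repetition; for rejection ABC this is
mathematically identical to resimulating per combination, only the
distances differ.

Posterior predictive checks resample parameters from an accepted set,
simulate one replicate per draw (default 1000), and report each observed
replicate's statistic against the predictive mean and central 95% interval.

## Problem sizes

The reference protocol sizes (M = 10 replicates, 288 steps, the full DC
schedule) are used everywhere. The package's own study sizes keep the accepted set comfortably larger than
the regressor count of the adjustment (the 1% rule accepts K/100 samples
against up to 25 regressors, and ordinary least squares needs n ≫ p: at 50
accepted points the adjusted estimates are visibly biased, at 80–100 they
are stable). Parameter-recovery runs therefore use K = 8,000–10,000 prior
samples, repeated on 2–3 independent datasets with the median estimate
reported, since both the observed dataset and any single point estimate
carry realization-to-realization scatter. The design-comparison orderings
use K = 1500 with 2 repetitions per cell — sizes at which each asserted
ordering is stable under reseeding while a full grid remains a desk-scale
computation. The combinatorial study
(all 13 single statistics, all 78 pairs) is tractable because simulations
are shared across combinations. All randomness flows from a single master
seed through spawned integer sub-seeds, so every table and test is
bit-reproducible.

## Known limitations

- The simulator is the data-generating truth for every experiment here;
  nothing in the tests measures robustness to misspecified motility
  mechanisms (adhesion, pushing, off-lattice movement).
- Accepted-set sizes of ~1% of K leave 15–100 points for the KDE; posterior
  modes carry a few grid cells of Monte-Carlo jitter, and regression
  adjustment is skipped for vector statistics when the accepted set is
  smaller than the regressor count.
- The data-cloning credible intervals are, by construction, not calibrated
  uncertainty statements — they quantify the spread of the tempered
  posterior, which shrinks as clones are added.
- Real-image preprocessing (mapping microscopy frames onto the lattice) is
  out of scope; the CLI consumes datasets in the package's own CSV format.
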