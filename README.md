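# colonyabc

Likelihood-free parameter inference for lattice models of growing cell
colonies, with tools for asking *which experimental design and which summary
statistics make the parameters identifiable*.

Cell-biology assays such as growth-to-confluence and scratch (wound-healing)
experiments are routinely summarized by a handful of statistics — cell
counts, cluster sizes, displacement of tracked cells, spatial correlation
functions. Whether the motility and proliferation rates of a mechanistic
model can be recovered from such summaries depends strongly on the initial
cell geometry and on the statistics chosen. `colonyabc` implements the full
pipeline for studying this question *in silico*:

1. **Simulator** — a 2-D lattice exclusion process: `N(t)` agents on an
   `R x C` grid; each time step of length τ selects `N(t)` agents at random
   with replacement; a selected agent moves to a uniformly chosen orthogonal
   neighbour with probability `P_m` or places a daughter there with
   probability `P_p`; attempts onto occupied or off-lattice sites abort
   (volume exclusion / contact inhibition). The continuum limits are
   `D = P_m Δ² / 4τ` and `λ = P_p / τ`.
2. **Summary statistics** — the 13 statistics used in practice: cell count
   `N(T)`, largest 4-/8-connected cluster κ₄/κ₈, quadrat binning variances
   `Q₂, Q₄, Q₈`, mean Manhattan displacement ‖x‖ and tortuosity Γ of five
   tracked cells, the smaller gyration-tensor eigenvalue λ, and raw /
   density-normalized pair-correlation functions `C_Y, Ĉ_Y, C_XY, Ĉ_XY`
   (lags 1…24).
3. **ABC rejection** — K draws from the uniform prior
   `(P_m, P_p) ∈ (0, 0.99) × (0, 0.01)`, M-replicate simulation, MAD-weighted
   distances `d_j = (1/L_j) Σ_l ((s̄_j(l) − s̄_j^obs(l))/σ_j(l))²` combined as
   `d = Σ_a d_a²`, acceptance of the smallest 1%, local-linear regression
   adjustment, and Gaussian-KDE posteriors on a 512 × 512 grid.
4. **Data-cloning ABC-MCMC** — a staged chain targeting the likelihood
   raised to the K-th power via K independent pseudo-datasets per proposal;
   tolerance decreases (ε = 5, 2, 1, 0.5, 0.25), then clones increase
   (K = 2, 3, 4), concentrating the tempered posterior on the
   maximum-likelihood estimate.
5. **Information gain** — Kullback–Leibler divergence `I_KL(posterior ∥
   prior)` by midpoint quadrature, and a design × statistic study harness
   with posterior predictive checks.

## Worked example

```python
import numpy as np
from colonyabc import (
    DesignSpec, LatticeConfig, ModelParams, generate_observed_dataset,
)
from colonyabc.abc_inference import (
    abc_rejection, kde_posterior, posterior_mode, point_estimate_and_ci,
)

# scratch-assay design: 24 cells seeded over the first 6 of 24 rows,
# 12 h (288 steps), 10 replicates, 5 tracked cells
design = DesignSpec(seeded_rows=6, n_initial=24)
truth = ModelParams(p_move=0.25, p_prolif=0.0025)
observed = generate_observed_dataset(design, truth, LatticeConfig(), rng=2024)

acc = abc_rejection(observed, ("Cxy",), n_samples=5000, rng=1)
mode = posterior_mode(kde_posterior(acc.adjusted_theta))
est, ci = point_estimate_and_ci(acc.adjusted_theta)
print(f"P_m mode {mode[0]:.3f}, 90% CI ({ci[0,0]:.3f}, {ci[0,1]:.3f})")
print(f"P_p mode {mode[1]*100:.3f}e-2, 90% CI ({ci[1,0]*100:.3f}, {ci[1,1]*100:.3f})e-2")
```

prints (exact values vary with the seeds)

```
P_m mode 0.208, 90% CI (0.151, 0.240)
P_p mode 0.259e-2, 90% CI (0.247, 0.280)e-2
```

i.e. from a scratch-assay geometry the two-dimensional pair-correlation
statistic alone recovers *both* the movement probability (truth 0.25) and
the proliferation probability (truth 0.25 × 10⁻²), something no single
statistic achieves for a growth-to-confluence geometry.

The same pipeline is scriptable from the shell:

```
colonyabc simulate --pm 0.25 --pp 0.0025 --rows-seeded 6 --n0 24 --seed 7 --out data/
colonyabc stats data/ --out stats.csv
colonyabc abc-reject data/ --stats Cxy --k 5000 --seed 1 --out run/
colonyabc abc-dc data/ --stats Cxy --seed 1 --out dc/
colonyabc ppc data/ --posterior run/accepted.csv --stat N --out ppc.csv
```

## Layout

- `src/colonyabc/lattice_model.py` — exclusion-process simulator
- `src/colonyabc/summary_statistics.py` — the 13 summary statistics
- `src/colonyabc/abc_inference.py` — distances, rejection, adjustment, KDE
- `src/colonyabc/abc_dc.py` — data-cloning ABC-MCMC
- `src/colonyabc/study.py` — KL information gain, design studies, predictive checks
- `src/colonyabc/config.py`, `io.py`, `fixtures.py`, `cli.py` — plumbing
- `docs/methods.md` — modelling and numerical choices in detail
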