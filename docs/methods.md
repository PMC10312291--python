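# Methods

This note defines the model and every numerical convention the package
uses, in the package's own terms.

## 1. Networks

A patient's brain network is a weighted undirected graph over `n` regions
of interest (ROIs; default atlas size 246). Raw functional couplings are
correlation-like values `r ∈ [−1, 1]` and are mapped linearly onto weights
`w = (r + 1)/2 ∈ [0, 1]` (`rescale_coupling`); self-couplings are zeroed.

**Density thresholding** (`threshold_network`) keeps the
`L = round(θ · n(n−1)/2)` largest links at link-density fraction θ and
keeps their weights (the network is *not* binarized). Ties are broken
deterministically (weight descending, then lexicographic node pair). The
mean degree is κ = 2L/n — at n = 246 and θ = 0.10, κ ≈ 24.5. Thresholding
is idempotent and nested in θ.

**Node-set metrics** (`node_set_metrics`) for a set X: size S = |X|;
out-connectivity E = number of links with exactly one endpoint in X;
betweenness centrality BC (shortest-path, normalized, distance = 1/w);
clustering coefficient c (Onnela weighted form); efficiency F (mean inverse
shortest-path distance). BC, c, F are averaged over X; for X = whole
network only c and F are reported.

## 2. SIR dynamics

Discrete-time stochastic SIR: at each step every infected node i attempts
to infect each susceptible neighbor j independently with probability
`β · w_ij`; every node infected at the *start* of the step recovers with
probability γ (a node cannot recover in the step it is infected).
Outputs per seed set: the per-node probability of ever being infected
`P_IR(i)`, the mean first-infection step (the simulated activation order),
and the epidemic size `IR` = mean fraction of ever-infected nodes.

`run_sir` samples `N_R` independent realizations with an **event-driven
kernel**: on each directed link the step at which transmission succeeds is
`1 + Geometric(β w)`, and the number of attack rounds before the source
recovers is `Geometric(γ)` (≥ 1). Propagating first-infection times
through a time-bucket queue reproduces the synchronous chain's
distribution exactly while touching each link at most once per
realization. Realization substreams derive from a single master seed via
`numpy.random.SeedSequence`, so results are bit-identical given the seed.
Realizations in which some node would have been infected after the step
horizon `T` are counted in `truncated_fraction`.

Two independent implementations guard the kernel: `exact_sir_enumeration`
sums over every stochastic branch of tiny instances (n ≤ 6, T ≤ 6), e.g.
the path A–B–C at β = 0.5, γ = 1 gives P_IR = (1, 1/2, 1/4) and
E[IR] = 7/12; `sir_state_trace` literally steps the chain and exposes
per-step S/I/R counts (conservation: #S + #I + #R = n at every step).

## 3. Pattern comparison

A recorded pattern is the set of sampled (electrode-covered) ROIs, the
subset that activated, and each active ROI's integer activation step. A
simulation is compared through the **total correlation**

```
C = C_w · P_overlap
```

- `C_w`: Pearson correlation between recorded activation steps and
  simulated mean activation times over the ROIs active in *both*, each ROI
  weighted by its `P_IR` (confidently reproduced ROIs count more). Fewer
  than two common ROIs, or zero weighted variance, is flagged degenerate
  and scored `C_w = 0`.
- `P_overlap = N_sampled⁻¹ [ Σ_{i∈active} P_IR(i) + Σ_{i∈inactive} (1 − P_IR(i)) ]`:
  the probability-weighted agreement of the active set over the sampled
  ROIs. It equals 1 exactly when `P_IR` is the indicator of the recorded
  active set.

## 4. Parameter fitting

Free parameters: β, γ (each on the grid 10⁻⁴…10⁻¹, log-spaced by decades)
and θ ∈ {0.025, 0.05, 0.10, 0.20, 0.30}. For each grid point the network
is thresholded, the SIR dynamics is seeded with the patient's resection
area (RA), and C is averaged over `n_fit_iterations` independent blocks
(defaults: T = 1000, N_R = 10⁴, 10 iterations). The fit map stores the
mean and SD of C per point; its argmax gives the patient's parameters.
Because spreading depends on the product of rate and connectivity relative
to recovery, the fit landscape is degenerate along the ridge
**βκ/γ** — the identifiable combination that recovery experiments check.
The population model averages per-patient maps point by point and takes
the overall argmax.

## 5. Seed inference

With global parameters frozen, every ROI is scored as an alternative
single seed by its **seed likelihood** `C_R`: the total correlation when
that ROI seeds the epidemic, with β rescaled by `E_RA / E_R` (out-
connectivity ratio) so the expected initial spreading level matches the
RA-seeded fit. ROIs with no links are excluded. Multi-ROI seeds grow
greedily from the best single seed (`recursive_seed_optimization`, default
up to size 5): each augmentation is scanned at a reduced realization count
and the kept seed re-scored at full count; ties break toward the lower ROI
index after rounding C to 6 decimals.

## 6. Virtual resections

Resecting a node set zeroes all its links but keeps the nodes. The effect
of resecting the RA with the epidemic seeded at a candidate onset zone is
`δ_R = (IR₀ − IR_R)/IR₀`. Since seed nodes stay infected as seeds,
`IR_R ≥ |seed|/n` with equality when the resection isolates the seed; an
empty RA gives `δ_R = 0` exactly. Drivers of `log δ_R` are examined by
pairwise Pearson correlation and bidirectional stepwise OLS (enter at
p < 0.05, remove at p > 0.10, scan order = sorted column names for
determinism, collinear columns dropped with a warning) over 25 covariates:
the model ratio βκ/γ and the S/E/BC/c/F metrics of the RA (baseline), the
seed and the whole network (baseline, post-resection, and their
difference). Non-positive `δ_R` values (sampling noise at tiny effects)
are floored at one tenth of the smallest positive observation before the
log, with a warning.

## 7. Synthetic cohorts

Clinical MEG/SEEG recordings cannot be shared, so validation runs on
synthetic patients with planted ground truth; the generator's defaults are
the study conditions.

- **Connectome:** ROI centroids uniform in a spherical shell of radii
  30–80 mm (pairwise distances ≈ 0–160 mm); weights follow the
  exponential distance rule `w = exp(−α d)` with α = 0.052 mm⁻¹ and
  symmetric log-normal noise (σ = 0.1), clipped to (0, 1].
- **Ground truth:** a spatially contiguous seed of 3 ROIs (1 for
  seed-recovery experiments); generating parameters β* = γ* = 10⁻³,
  θ* = 0.10 — a grid-interior point in the partial-propagation regime, so
  recorded patterns involve some but not all sampled ROIs and both the
  activation order and the extension carry information.
- **Electrodes:** 30–60 sampled ROIs covering the seed and biased toward
  its 40-ROI spatial neighborhood (75% of the extra contacts), as clinical
  electrode placement is.
- **Pattern:** one SIR realization at the true parameters, restricted to
  the sampled ROIs; realizations reaching fewer than 5 sampled ROIs or
  fewer than 2 distinct steps are redrawn.
- **Resection area:** 3–13 ROIs; seizure-free-like ("SF") RAs grow
  contiguously from the seed center and contain the seed; non-seizure-
  free-like ("NSF") RAs are contiguous clusters at moderate distance that
  miss the seed entirely. The default cohort is 11 SF + 4 NSF patients,
  each with an independent connectome.

**Realism and limits.** The generator reproduces the distance-dependent
weight structure, sparse biased sampling, and the SF/NSF asymmetry, but
not hemispheric anatomy, atlas geometry, or measurement artifacts of real
MEG; recovery rates measured on it are upper bounds on clinical
performance and are used only as relative validation of the pipeline.

## 8. Validation experiments and problem sizes

`epispread.experiments` backs both the acceptance tests and
`scripts/acceptance.py`: Monte-Carlo vs enumeration on all small fixtures
(10⁴ realizations, deviations in binomial SEs); closed-form limits
(β = 0 floor, unit-weight wavefront = hop distance, conservation);
fit-statistic identities (machine precision); ridge recovery on 10
patients at N_R = 10³ with 2 fit iterations (success = fitted βκ/γ within
one grid step, i.e. a factor 10, of truth); seed recovery on 20
single-seed patients at N_R = 300 with 3-iteration-averaged maps
(success = argmax is the seed or a direct neighbor; averaging independent
evaluations suppresses the winner's-curse noise of an argmax over
hundreds of candidates at reduced sample sizes); median SF/NSF AUCs over 10 cohort replicates at
N_R = 300; the exact resection floor on the star fixture; and exact
stepwise recovery of a single generative covariate against 2 planted noise
covariates over 100 replicates of 75 observations (with entry threshold
0.05, the expected false-inclusion rate ≈ 1 − 0.95² keeps ≥ 90% exact
recovery statistically comfortable). These sizes keep the full suite
within a desk-scale CPU budget while leaving clear margins to the
thresholds.
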