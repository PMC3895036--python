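# Methods

This note documents the model, its numerical choices, and the design
decisions taken where the design was genuinely open.

## Landscape generator

Landscapes are rectangular blocks of 1-ha hexagonal cells in "odd-r"
horizontal layout (odd rows shifted half a cell right). Because every cell
is 1 ha, area and cell count are interchangeable, and the only geometric
property the model ever consumes is adjacency; any hexagonal tiling with
the same adjacency graph is equivalent. The full-scale landscape is a
180×180 lattice (32,400 cells ≈ an 18×18 km block); tests and the small
preset use 30×30 or 50×50 lattices, which behave identically up to a larger
Monte-Carlo variance of landscape-level statistics.

Partition into landholdings is by region growing: a seed cell is drawn
uniformly from the unassigned cells, a target area is drawn from
Gamma(shape = mean²/var, scale = var/mean) — base parameters mean 20 ha,
variance 100 ha² — rounded to the nearest integer cell count and floored at
one cell, and the patch grows by uniform draws from its unassigned frontier
until it reaches the target or runs out of frontier. Realized areas deviate
from the Gamma (patches get truncated against their neighbors), which is
inherent to any space-filling partition; distributional guarantees are
therefore stated for the *sampler*, not for realized areas. Each
landholding receives one initial understory age, uniform on the integers
{0, …, 70} (the simulator advances age in whole years).

A pool of landscapes (2000 at full scale) is generated once per
configuration and reused across evaluations; pool generation is seeded per
landscape through `numpy` `SeedSequence` spawning, so pools are
reproducible and landscapes mutually independent.

## Dynamics

A regime has 1–5 groups of (interval, proportion); proportions refer to
*counts* of landowners, and each owner is independently assigned a group
with the group probabilities, re-drawn for every replicate landscape.
Interval 100 means the group never clears.

Clearing times per owner:

* At year 0, an owner whose initial age is ≥ the **prescribed** interval
  clears immediately (ties clear; the tie rule is arbitrary but fixed).
* Otherwise the first clearing falls when the understory reaches a
  **sampled** interval: Gamma with mean = prescription and constant shape
  (base 100). If the sampled interval is below the initial age the owner
  also clears at year 0.
* Each subsequent clearing is scheduled one fresh Gamma draw after the
  previous due time. Due times are real-valued; the clearing executes in
  the first integer year ≥ the due time. Keeping the fractional part makes
  the long-run clearing rate exactly 1/m; re-anchoring at integer years
  would bias it to ≈ 1/(m + 0.5).
* A fresh draw per event (rather than one fixed draw per owner) models
  ongoing timing uncertainty; this is a documented assumption.

Within a simulated year, due owners clear (whole landholding, age → 0),
all other cells age one year, and end-of-year summaries are recorded.
Biomass is a deterministic function of age, B(a) = B_max(1 − e^(−ra)) with
B_max = 20,000 kg/ha and r = 0.06 yr⁻¹. The exact curve is configuration:
all six objectives are invariant to B_max (edge contrast and skewness are
shape statistics, fuel load scales linearly, the age-class and cost
objectives never see biomass), so only the saturation time scale matters,
and r = 0.06 puts ~95% of the plateau at age 50, after which variation is
slight.

Implementation uncertainty is alternatively parameterized by the variance
at the 100-year interval ("max variance" V), with shape = 100²/V; V = 100
recovers the base model.

## Objectives

Cost is the mean % of area cleared per year over **all** years; the other
five objectives discard the first 20 years (landscape adaptation burn-in)
and then take their worst year — the maximum for mean fuel load, the
minimum for edge contrast, skewness, and the two age-class areas — so that
single years of extreme fire risk or habitat loss are not averaged away.
Fuel load is the per-hectare mean across cells (not the landscape sum).
Edge contrast is the population variance of |ΔB| over all unordered
adjacent cell pairs, each counted once (pairs within one landholding
contribute zeros and are counted like any other pair). Skewness is the
population moment coefficient g₁, defined as 0 for zero-variance inputs.
Age classes are inclusive on integer ages: mid = {30,…,60}, late = {61,…}.
Population (biased) moments are used throughout; landscape cell counts are
large enough that the bias is negligible, and the choice is fixed.

Internally all six objectives are stored in canonical minimization form
(maximized objectives negated); replicate aggregation is the componentwise
maximum in that form — the worst replicate in every objective.

## Optimizer

Standard elitist NSGA-II over the flat gene vector (k intervals, k
weights): binary tournament by (rank, crowding), SBX crossover with
probability 0.7 and distribution index 5, polynomial mutation per gene with
probability 0.2 and index 10, (μ+λ) survival. The probabilities are the
problem's stated defaults; the distribution indices follow the defaults of
the reference NSGA-II implementation this procedure matches, and both are
configuration. Weights decode to proportions by normalization (uniform
fallback for an all-zero vector), so zero-proportion groups are
representable and group counts below k can emerge during the search.

Each genotype is evaluated once, on `replicates` landscapes drawn from the
pool without replacement (24 at full scale, 12 in sensitivity runs, 4 in
the small preset); survivors keep their evaluated vector (no noisy
re-evaluation), matching standard NSGA-II.

Convergence is monitored with the hypervolume of the cumulative
nondominated archive, computed after the run against a reference point
fixed at the worst value of each objective seen in any generation. With the
fixed reference and one fixed Monte-Carlo sample set per run, the series is
non-decreasing by construction, which makes it a clean convergence
diagnostic even under evaluation noise. Hypervolume is exact (sweep) in
2-D and Monte-Carlo (10⁵ samples at full scale) in higher dimensions, since
exact computation is exponential in the number of objectives; the returned
*frontier* is the rank-1 set of the final population.

## Post-processing

Level-diagram scores: objectives are min–max standardized over the frontier
in canonical form (best = 0) and weighted 6 (cost), 3 (each biodiversity
objective), 2 (each fire objective) inside a Euclidean norm, giving a
worst-case distance of √66. With these weights each *group's* weights sum
to 6 — a third of the total weight each; note that the groups' contributions
to the *squared* distance are not equal (36 vs 18 vs 12), a property of the
stated formula that is implemented as stated.

Restriction scenarios are conjunctions of band, threshold, and quantile
constraints on display-form objectives; quantile thresholds use
linear-interpolation quantiles computed over the input frontier. The five
shipped scenarios: cost bands 5% and 10% (±0.375), fire (each fire
objective in its best 25%), biodiversity (≥9.9% in both age classes), and
compromise (cost ≤ 20%, fuel load ≤ its 60th percentile, edge contrast and
skewness ≥ their 40th percentiles, ≥9% in both age classes).

Interval densities are Gaussian mixtures (sd = bandwidth 5 years) centered
at a regime's intervals and weighted by its proportions, evaluated on the
fixed grid [−12, 115] in steps of 0.1 — three bandwidths beyond the
interval bounds. Kernels are *not* truncated or renormalized at the grid
bounds, so up to ~1.4×10⁻³ of mass can fall outside the grid for intervals
at the bounds; consequently the intersection distance of a regime with
itself is not exactly 0 but below 2×10⁻³. The distance is 1 minus the
trapezoid-rule integral of the pointwise minimum, clipped to [0, 1].
No-management groups enter the density at interval 100.

PCoA is classical scaling: double-center −D²/2, eigendecompose, scale
eigenvectors by √λ over the positive eigenvalues. Negative eigenvalues
(non-Euclidean distances) are dropped from both the coordinates and the
variance-explained denominator.

Compromise-regime re-simulation runs each regime in `n_sims` (default 100)
fresh random landscapes with fresh allocations and reports per-year mean ±
SD of every objective variable and the age-class composition.

## Sensitivity sweeps

Two axes: landholding areas (mean/variance pairs 20/100, 60/900, 100/2500,
140/4900, 200/10000) and implementation uncertainty (max variance 1, 5, 10,
50, 100, 500, 1000). One optimization per level with only the swept
parameter changed; per-level seeds are spawned deterministically from the
base seed, and pools are regenerated per level (the area axis changes the
landholding distribution). Cross-run comparison filters each frontier by a
scenario, pools the solutions, and embeds pairwise density distances with
PCoA; a pooled set with fewer than two solutions or with no positive
embedding axis is reported as degenerate instead of embedded.

## What the generator does and does not emulate

Synthetic landscapes are homogeneous except for ownership and understory
age: no topography, soil, or climate gradients, no spatial autocorrelation
of initial ages, no fire ignition/spread (the three fire objectives are
structural surrogates), and no landowner behavior beyond the Gamma timing
noise. Passing tests therefore demonstrate correctness of the simulation-
optimization machinery and of distribution-level properties, not predictive
accuracy for any real landscape.

## Problem sizes

The default test and demonstration preset ("desk") uses a 30×30 grid,
population 40, 30 generations, 4 replicates, and a pool of 50 landscapes;
the acceptance computations use ten 50×50 landscapes for composition
targets and 10⁵ draws for sampler recovery. These sizes were chosen so the
full suite runs in minutes while leaving the Monte-Carlo error of every
asserted quantity well inside its test tolerance; the "full" preset keeps
the full-scale constants (180×180, 800, 400, 24, pool 2000).

## Known limitations

* Realized landholding areas are only approximately Gamma (truncation
  against neighbors); no correction is applied.
* The six-objective hypervolume is a Monte-Carlo estimate; series values
  carry sampling error of order (volume)/√n_samples, though monotonicity is
  exact for a fixed sample set.
* The archive-based hypervolume series measures frontier quality globally;
  it is not the hypervolume of the current population alone.
* With 5 groups the genotype is 10-dimensional and the small preset's 40
  individuals explore it coarsely; full-scale settings are required for
  frontier compositions to stabilize.
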