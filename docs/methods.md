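# Methods

This note records the statistical procedure multicorr implements, the
conventions and defaults it commits to, what the built-in synthetic data
sources do and do not emulate, and the limitations a user should keep in
mind.

## Windowed correlation surfaces

For an M×N data matrix `D` (rows = observations, columns = variables),
a pair of columns (i, j) and a sorting column s, the surface assigns to
every admissible window

```
Ω = {(α, β) : 0 < β ≤ 1/2,  β ≤ α ≤ 1 − β}
```

the sample correlation of (i, j) over the observations whose
sorting-variable rank falls between the (α−β)-th and (α+β)-th empirical
quantiles.  α is the window center, 2β the included population
fraction; the apex (α, β) = (1/2, 1/2) is the whole sample.

**Rank rule.** Quantile windows are realized by ranks, not by an
interpolated quantile function: rows are stably sorted by s (ties keep
original row order) and the window keeps 1-based ranks p with
`round((α−β)M) ≤ p ≤ round((α+β)M)`, with half-up rounding.  For
distinct sorting values this coincides with the quantile definition,
and it is exactly reproducible — no dependence on any of the many
quantile-interpolation conventions.  Two consequences are tested as
invariants: windows at fixed α are nested in β, and any strictly
increasing relabeling of the sorting variable leaves every window (and
hence every surface cell) unchanged.

**Grid.** An odd resolution R ≤ M (CLI default: largest odd integer
≤ min(M, 99)) induces β ∈ {1/R, …, ⌊R/2⌋/R} and, per β,
α ∈ {β, β+1/R, …, 1−β}.  Stepping β by 1/R cannot land exactly on 1/2
for odd R, so the full-population apex is appended explicitly; the top
of every plot is therefore always the global correlation.  The
admissibility bounds are taken inclusive (α may equal β and 1−β),
since the grid's own endpoints require it.

**Estimates and significance.** Pearson is the default; Spearman is the
same estimate on average-rank-transformed data.  Both are computed via
scipy and carry a two-sided p-value equal to the t-test
`t = r√((n−2)/(1−r²))` with n−2 degrees of freedom (scipy's exact beta
form for Pearson is identical to this t-test; the Spearman p uses the
same t-approximation, the conventional choice — exact permutation nulls
are not implemented).  A window with n < 3 observations or a constant
input yields an estimate flagged `valid=False` rather than an error, so
surface computation proceeds and the cell is simply omitted from plots.
The minimum n of 3 is the smallest size at which the t-test is defined
at all; it is configurable upward, and at such sizes a p-value is a
formality rather than evidence.

**No multiplicity correction.** Cells of one surface are strongly
interdependent (each large window contains its sub-windows), so the
per-cell p-values are *descriptive thresholds*, not calibrated
probabilities of nonzero correlation, and no multiple-testing
correction across cells is applied — a deliberate choice, documented
rather than hidden.  Conclusions should rest on large contiguous
regions, not isolated cells.

**Sorting by an analyzed variable** is refused by default (windowing
would condition on one member of the pair) but can be forced with an
explicit override.

**Outlier candidates.** A single extreme observation can impose a
significant correlation on every window containing it, visible as a
diagonal stripe in the plot.  The detector recomputes the pair's
global correlation leaving out each of the `min(5, M/10)` (at least 1)
lowest- and highest-ranked observations of the sorting variable and
reports those whose omission moves the p-value across the threshold.
It is a screen for influence, not a formal outlier test.

## Gene-network simulator

Two three-species motifs serve as the built-in source of synthetic
"cells", each a chemical-Langevin-style SDE with additive noise:

- activation: `dX/dt = V_x Z^n/(Z^n+K_zx^n) − β_x X`,
  `dY/dt = V_y X^n/(X^n+K_xy^n) − β_y Y`, `dZ/dt = k_z − β_z Z`;
- inhibition: same X and Z equations,
  `dY/dt = α_y + V_y K_xy^n/(X^n+K_xy^n) − β_y Y`.

Both use Hill coefficients n = 2.  The default parameter tables put the
deterministic fixed points at (X*, Y*, Z*) = (1000, 1000, 900) for
activation and ≈ (1406, 935, 1100) for inhibition: displaced by about
+40.6% in X and +22.2% in Z, but not separable once noise is added.
Integration is explicit Euler–Maruyama with Δt = 0.1:
`s ← s + f(s)Δt + σ√Δt·w`, `w ~ N(0, I₃)`, one record per step; the
first 300 records are discarded as burn-in and the rest thinned by 20,
so the default 10300 steps yield 500 approximately independent samples
per model.  With σ = 0 the scheme reduces to explicit Euler on the ODE
(tested against an independent adaptive integrator).

Choices worth knowing:

- **Noise amplitude σ = 10** (expression units/√time, shared by all
  species).  Large enough for clearly spread steady-state clouds,
  small enough that negative excursions are negligible; raising σ
  mostly degrades the mixture demonstration because the Hill
  nonlinearity then also shifts the stationary means.  Excursions below
  zero are *not* clipped by default (the equations as written permit
  them); a floor-at-zero switch exists.
- **Inhibition Y-drift.** The default is the standard repressive Hill
  form `α_y + V_y K^n/(X^n+K^n)`.  A variant without the `K^n`
  numerator (`y_drift_form="printed"`) is selectable; at the default
  parameters its repression term is ~10⁻⁵·V_y, i.e. numerically inert,
  and it produces no X–Y anticorrelation — it exists for comparison
  only.
- **Mixture.** Equal parts of both models (larger sample truncated),
  labels preserved, shuffled by seed.  The package's canonical seed
  derivation is activation = s, inhibition = s+1, shuffle = s+2.

What the simulator emulates: two latent subpopulations with opposite
X–Y regulation whose marginals overlap, the setting the surface plot is
designed for.  What it does not: mRNA count discreteness (no Gillespie
exact simulation), transcriptional bursting, technical dropout, or
cell-size confounders.  Passing tests on this generator demonstrate the
windowing machinery, not robustness to those artifacts.

A note on power at the defaults: the pooled mixture's X–Y correlation
is strongly negative and the low-Z windows are strongly positive, but
the high-Z windows condition on Z within the inhibition cloud, which
removes the Z-mediated share of X's variance and leaves a within-window
anticorrelation of only ρ ≈ −0.2; at ~300-observation windows the
significance call sits near the power boundary and individual seeds can
fail to reach p < 0.05.  Similarly, the activation cascade Z→X→Y
carries a small indirect Z–Y correlation (ρ ≈ +0.09, a structural
property of the cascade, independent of σ): at 500 samples the t-test
flags it in roughly half of replicates, so "no significant Z–Y edge" is
a coin flip, not a stable property of the activation motif at this
sample size.

## qPCR preprocessing

The implemented recipe: (1) drop cells with missing readings, plus any
cells on an explicit user-supplied exclusion list — there is
deliberately no heuristic outlier rule; (2) add a global offset to
every reading (default: the table-wide minimum expression, recomputed
from the input; it can be pinned to a literal to replicate a published
normalization exactly) and divide cell-wise by the housekeeping gene,
whose column becomes 1 and is dropped; (3) no log transformation at any
point — correlations are computed on the normalized linear scale.

Compartment gates: *detected* (raw marker reading above a threshold,
default 0 — non-detects are assumed encoded as zeros; the threshold is
exposed because instruments also encode non-detects as missing) and
*top-k with veto* (the k highest-marker cells among those where a veto
marker is not detected; vetoed cells are replaced by the next eligible
ones; ties at the k-th rank break by stable table order, and the rule
parameters are recorded in the assignment).

The fixture generator produces log-normal expression coupled through a
latent pluripotency-like axis, a near-constant housekeeping column, a
zero-inflated marker (detected preferentially in low-axis cells, as a
differentiation marker would be) with an exact detected count, and a
requested number of rows with missing entries — enough structure to
exercise every preprocessing rule with known bookkeeping, not a
generative model of qPCR chemistry.

## Plots

Markers are filled squares sized to tile the grid at the chosen R.  The
diverging colormap (default `RdBu_r`: blue = negative, red = positive)
is always normalized to [−1, 1] so zero sits at the neutral midpoint;
orientation is configurable since both conventions are in circulation.
Insignificant cells are drawn white (blank space inside the triangle)
rather than dropped, so the extent of non-significance stays visible;
invalid cells are omitted.  The default abscissa is the median sorting
value of each window's subset, which matches how these plots are read
against the data scale but is non-uniform for skewed sorters; a uniform
quantile abscissa is available.  `render` returns the exact marker
table it drew, making plots testable and deterministic.

## Problem sizes and runtime

Defaults are desk-scale: 500 samples per simulated model, surfaces at
R ≤ 99 (≈ 2500 cells), test-suite fixtures at M ≤ 60.  Everything runs
in seconds on one core; the dominant cost is the sequential SDE loop,
O(n_steps) per simulation.

## Known limitations

- Shrinkage correlation estimation for N > M panels and partial
  correlation are not implemented; the package targets small panels.
- Spearman p-values use the t-approximation even at small n.
- Surface p-values are descriptive (see above); no automatic ranking
  or screening of the k(k−1)(k−2)/6 possible surfaces is provided.
- The window rank rule is one defensible convention among several;
  results at very small M can differ from interpolated-quantile
  implementations by one observation per window edge.
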