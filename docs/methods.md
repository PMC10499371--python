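# Methods

## Problem setting

Given a gridded daily pollutant field (cells x days) and per-cell
socioeconomic surfaces, select an ordered list of `k` monitor locations
that (a) capture the field's variability across timescales and (b) can be
steered, by a single coefficient, toward majority-nonwhite or low-income
cells.  The pipeline is: mask and flatten the field, decompose it into a
multiresolution modal library, then greedily pivot on the library rows
with a penalized score.

## Field handling

Cells missing at *any* time step are dropped entirely (the decomposition
needs complete rows; interpolation of gaps is out of scope).  Retained
cells keep a deterministic row-major ordering, `cell_id = row * n_cols +
col` on the unmasked grid, so pivot indices are stable across runs and
survive masking.  Units are metadata only.

## Exact DMD of one window

For snapshots `x_0 .. x_{m-1}` (m >= 3): with `X- = [x_0..x_{m-2}]`,
`X+ = [x_1..x_{m-1}]`, truncated SVD `X- ~ U S V*`, the projected operator
is `A~ = U* X+ V S^-1`; its eigenpairs `(lambda_j, w_j)` give exact modes
`Phi = X+ V S^-1 W`, column-normalized, with each mode's phase rotated so
its largest-magnitude entry is real positive (this makes the library
assembly bit-reproducible).  Continuous frequency is
`f = |Im log lambda| / (2 pi dt)` in cycles/day.

* **Rank rule** — keep singular values `>= 1e-10 * sigma_max`, capped at
  `max_rank = 6` per window.  The cap bounds library growth (1023 nodes at
  the default ladder) and keeps each window's fit parsimonious; it is
  config-exposed.
* **Amplitudes** — `b` solves `Phi b = x_0` by least squares (the standard
  exact-DMD convention).  A whole-window Vandermonde fit
  (`fit_all_snapshots=True`, solved via a Khatri-Rao system) is available;
  it is slower and changes none of the placement logic.
* Zero eigenvalues (nilpotent directions) are discarded with a warning;
  all-zero windows are skipped.

## Multiresolution recursion

Windows follow the dyadic schedule: level 1 = the training window `[0, M)`
(the *last* `M` snapshots of the supplied field), each window floor-splits
in two at the next level, `L` levels in total.  Defaults `M = 4096`,
`L = 10` give 8-day finest windows, 512 of them.  At each node the DMD
runs on the current residual; modes with `f <= rho / (m dt)` (default
`rho = 1`: at most one oscillation per window) form the slow set, their
reconstruction is subtracted over the window, and the recursion descends.
Windows shorter than 3 snapshots store an empty node.  No temporal
subsampling is done at coarse levels by default (a `stride` option exists)
— daily data at these sizes is tractable and results stay exactly
reproducible.

**Caveat (fit, not projection).**  The slow-mode subtraction is a model
fit anchored to each window's first snapshot, not an orthogonal
projection, so the running residual need not shrink at every level —
a coarse window can transiently overfit (e.g., modelling an aligned
transient as a decaying exponential) and hand a larger residual to its
children.  Over the full ladder the residual drops substantially, and the
final residual is attached to the tree root for diagnostics.  A related
consequence: a transient whose onset coincides with a coarse window's
first snapshot can be absorbed above its natural level.  The synthetic
fixtures therefore plant events away from coarse window starts, which is
also the generic position for real episodes.

## Modal library

All retained modes are stacked in deterministic preorder (coarse to fine,
left to right, mode index within node).  A real mode contributes `Re phi`;
each complex-conjugate pair contributes `Re phi` and `Im phi` from the
member with non-negative frequency — information-preserving and
duplicate-free (a `magnitude` representation, one `|phi|` column per mode,
is config-exposed).  Columns are unit-normalized by default so the
penalty coefficient `gamma` acts on O(1) residual norms and its useful
range (0–0.5) is transferable across datasets; `amplitude` weighting
(`|b|`-scaled columns) is available but changes that scale, so a warning
is logged when combined with `gamma > 0`.

## Cost surfaces and the penalty

Race metric: `s = 1 - (non-Hispanic White proportion)`.  Income metric:
`s = 1 - min(income, income_max) / income_max`, with `income_max` a
per-city cap (census top-codes such as $250,000) defaulting to the
observed maximum.  The penalty is low where `s` is high, because the pivot
score *subtracts* `gamma * eta`:

* `step` (default): `eta = 0` where `s >= tau` (default `tau = 0.5`,
  i.e. "majority"), else 1.  Binary penalties make the `gamma` threshold
  behavior easy to reason about but produce score ties, hence the explicit
  tie-break below.
* `linear`: `eta = 1 - s`, a graded alternative.

Both are monotone non-increasing in `s`.  Only per-cell value penalties
are implemented; a spatial-distance notion of "far from target
communities" would require a kernel choice and is deliberately left out.

## Pivot selection

At each step the unselected location maximizing
`l = ||residual column||_2 - gamma * eta_i` is chosen; its residual
direction is orthogonalized against the previously selected set (classical
Gram-Schmidt with one re-orthogonalization pass on the pivot column) and
deflated from all remaining columns; residual norms are recomputed from
the deflated matrix each step.  Ties (common with step penalties) break by
larger residual norm, then smaller `cell_id`, with a 1e-9 relative slack
so floating-point noise cannot flip the documented order.  `gamma = 0`
reproduces classical norm pivoting pivot-for-pivot (cross-checked against
LAPACK's pivoted QR), and the greedy sequence nests: top-k is a prefix of
top-k'.  `k` beyond the library's column count is an error — the library
caps the informative pivots.

A brute-force oracle (`greedy_oracle`) recomputes every residual from
scratch by least-squares projection at every step; it exists for tests
and small instances only.

## Synthetic city

The generator emulates the statistical structure the method assumes:

* background `= mean + urban-core Gaussian bump + seasonal sinusoid +
  linear trend` — defaults 10 ug/m3 mean, +/-3 seasonal, -0.2/yr trend,
  +4 core bump, typical of a decade of urban PM2.5;
* transient events: spatial Gaussians (sigma 1.5–3 cells) held for a
  dyadic duration (8–1024 days), peak enhancements 10–40 ug/m3 — the
  range of haze episodes, inversions, and industrial releases.  Dyadic
  durations mirror the decomposition ladder so level assignment is
  testable;
* iid Gaussian cell-day noise (sigma 2 ug/m3);
* demographics: a segregated nonwhite-metric surface (quadrant, gradient,
  or two-cluster pattern; ~0.9 inside the target region vs ~0.1 outside,
  smoothed), with income anti-correlated with it plus household scatter.

Components are stored separately, so `field = background + events + noise`
holds exactly and each planted event is ground truth.  Not emulated:
advective transport and correlated meteorology, heavy-tailed noise,
spatially correlated measurement error, population density, and any
calibration to a real city.  Passing tests therefore demonstrate that the
algorithm recovers planted structure and responds to the cost constraint
under these idealized conditions — not that a specific real city's optimal
network looks like the synthetic one.

## Default study sizes

The end-to-end fixtures use a 32 x 32 city (1024 cells) observed for 4096
days with six planted events, decomposed at the full 10-level ladder
(~1700 library columns), with networks of up to 250 sensors — large enough
that the equity response and the prefix property are exercised on a
realistically sized library while a full pipeline run stays around a
minute on one CPU.  The two-tone separation fixture is 16 x 16 x 512 days
at 7 levels.

## Numerical choices and degenerate inputs

* SVD via LAPACK `gesdd`; eigen-decomposition of the small projected
  operator only.
* Eigenvalues with `|Im lambda| <= 1e-10 |lambda|` are treated as real;
  frequencies within the slow cutoff get a matching relative slack.
* A pivot whose residual direction is numerically dependent on the
  selected set (norm <= 1e-14) is kept (its score was maximal) but
  contributes no further deflation.
* Odd-length windows floor-split; a window with fewer than 3 snapshots or
  all zeros yields an empty node, logged.
* Non-finite residuals abort the decomposition.

## Known limitations

* Greedy pivoting is near-optimal, not optimal; no combinatorial search.
* `gamma` is user-chosen; the package provides sweeps and summaries, not
  automated selection.
* The step penalty keys on per-cell values only; extreme values of the
  equity metric dominate the optimization (visible in the synthetic
  sweeps as saturation of mean `s` beyond `gamma ~ 0.25`).
* Cells with any missing day are dropped rather than imputed.
* First-snapshot amplitude fitting makes window-boundary-aligned
  transients attributable to coarser levels (see the recursion caveat).
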