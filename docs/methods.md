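# Methods

## The generative model

Case and control locations are drawn from a shared-parent Poisson cluster
(Cox) process on a square observation window with the origin at (0,0):

1. parents ~ homogeneous Poisson with intensity κ (parents per mi²);
2. each parent independently spawns N_case ~ Poisson(λ_case) case children
   and N_control ~ Poisson(λ_control) control children;
3. every child is placed uniformly at random in the disc of radius R around
   its parent (polar sampling with a √U radius, the standard Matérn-cluster
   convention — the model itself says only "within a circle", so uniformity
   on the disc is a modelling choice);
4. children falling outside the observation window are discarded.

Cases and controls share parents, so both types are clustered identically
and the risk of being a case is constant everywhere: the null hypothesis of
the clustering test holds by construction.  Defaults (window side
√3,000,000 ≈ 1732.05 mi, κ = 10⁻⁴, λ_case = λ_control = 50, R = 15 mi)
give E[parents] = 300 and, by the compound-Poisson closed form,

    E[n] = κ|A|(λc + λk) = 30,000,
    sd[n] = √(κ|A|[(λc+λk) + (λc+λk)²]) ≈ 1,740.7,

with a mean case proportion of exactly 0.50 by symmetry.  The per-type mean
of 50 (rather than 100) is deliberate: 100 per type would give E[n] = 60,000,
inconsistent with the 30,000-person cohort the defaults emulate; 50/50
reproduces both the intended mean and the intended dispersion.

**Edge handling.** Parents are drawn on the window dilated by R (side
L + 2R), so every cluster that can reach the window contributes children and
the child process is stationary on the window.  Drawing parents only inside
the window instead would lose ~0.8% of children at this geometry (measured:
mean n ≈ 29,750) and bias every count downward; with dilation E[n] is exact.
This is the same edge policy used by the standard cluster-process simulators.

**What the generator does not emulate.** Real cohort geography: population
density gradients, administrative boundaries, coastlines, non-circular
settlements, spatially varying case ascertainment.  Passing tests show the
*statistical machinery* behaves as designed under a realistic degree of
clustering and sample size — not that any particular real dataset is free of
multiple-testing artefacts.

## K, D and the range grid

Ripley's K is estimated with the border (reduced-sample) edge correction:

    K̂(h) = (|A|/n) · [ Σ_{i: bd(i) > h} #{j ≠ i : d_ij ≤ h} ] / #{i : bd(i) > h}

where bd(i) is the distance from point i to the window boundary and n is the
type's full-window count (λ̂ = n/|A|).  Conventions, fixed so that an O(n²)
double-loop oracle reproduces the estimator exactly:

* closed-ball neighbours (d_ij ≤ h counts);
* strictly interior centres (bd > h; a centre exactly h from the boundary is
  excluded) — both tie sets have probability zero under the continuous
  generator;
* K̂(h) is NaN, never 0, where no centre is eligible, and every consumer of
  a NaN fails loudly rather than silently dropping the range.

D̂(h) = K̂_case(h) − K̂_control(h), each type with its own λ̂.  Ranges are the
equidistant grid h_i = i·(L/4)/r, i = 1…r (from just above 0 up to a quarter
of the window side, the grid convention of the study design); the grid for r
is nested inside the grid for any multiple of r, which is what makes the
shared-dataset monotonicity analysis exact.  Pair counting enumerates the
exact pair set within h_r with a KD-tree; per-range counts come from a
difference-array sweep over the sorted grid, so the per-relabeling cost is
O(#pairs), independent of r, and equals the brute-force count exactly.

## Random labeling and the three decision rules

A permutation null with n_perm relabelings (default 199) is built once per
dataset on a precomputed pair index; only the type masks change per
relabeling.  Under constant risk the observed D vector is exchangeable with
the replicates, so each rule below has exact size conditional on locations
(up to the strict-inequality tie convention, which can only make the test
conservative):

* **pointwise** (the practice under study): per-range critical values are
  the 5th/195th-ranked replicates (general ranks ⌈α/2(n_perm+1)⌉ and its
  mirror); rejection at any range rejects the dataset.  Single-range size is
  2·5/200 = 0.05 exactly.
* **simultaneous**: m_j = max_i |D_j(h_i) − med_i| per replicate, with med_i
  the per-range replicate median (the median is well defined and robust at
  n_perm = 199; centring on the mean is available as an option); the
  critical constant is the ⌈(1−α)(n_perm+1)⌉-th smallest m_j and the band is
  med_i ± c.  The any-range exceedance of this single band has family-wise
  size ≤ α under exchangeability.
* **integrated**: S = Σ_i D(h_i)/sd_i with sd_i the per-range replicate
  standard deviation (ddof = 1; any common scaling of D leaves the ranks of
  S unchanged), the identical sd_i applied to the observed vector and every
  replicate; two-sided Monte Carlo p-value with the +1 "observed counts
  itself" correction: p = (1 + #{|S_rep| ≥ |S_obs|})/(n_perm+1).  The null
  distribution of S is taken from the same replicate set rather than from an
  analytic large-r variance approximation: exchangeability makes the Monte
  Carlo version exact-size, with no large-r assumption and no covariance
  estimation.

An observed value exactly on a critical boundary is not a rejection.

**Degenerate inputs.** A dataset whose D is undefined at some range — no
border-eligible centre of a type in the observed pattern or in any replicate
(the eligible region at h = L/4 is only the inner quarter of the window) —
cannot be tested at that grid and is excluded, with the exclusion count
reported in the denominator.  A dataset where every relabeling yields the
identical D vector (e.g. a single tight cluster, where D depends only on the
fixed type counts) has a zero-variance null: the integrated statistic raises
a degenerate-null error naming the ranges, and the dataset is likewise
excluded.  Both situations are artefacts of small reduced-scale geometries;
at the full scale (~300 clusters) they essentially never occur.

## Study orchestration and seeds

One study condition = n_datasets fresh null datasets tested at the r-range
grid; FWE = rejections/testable datasets, with a Wald 95% interval
p̂ ± 1.959964·√(p̂(1−p̂)/n) clipped to [0,1] (Wald mirrors the original
summary; Wilson is available behind a flag; degenerate intervals at p̂ ∈
{0,1} are returned with a warning).  Defaults: range counts (1, 10, 50,
100), 2,000 datasets per condition, α = 0.05.  Fresh datasets per condition
replicate the original design; `run_nested` instead evaluates all range
counts on the same datasets and labelings by restricting the finest grid's
null to each nested sub-grid, which makes the per-dataset any-range
rejection exactly monotone in r — that mode exists for the monotonicity
analysis and is labelled as such.

All randomness descends from one master seed through `SeedSequence`
spawn keys (condition index → dataset index → generation/permutation
streams), so results are independent of execution order and resumable
(per-dataset rows are streamed to CSV when an output directory is given).
The per-range rejection indicators are summarized by their phi coefficients
(Pearson correlation of binaries); zero-variance columns are reported as
undefined rather than 0.

## Problem sizes used in the shipped analyses

The shipped scripts and the acceptance checks run the Monte Carlo work at a
proportionally reduced geometry — window side and cluster radius scaled
together so E[n] ≈ 600 — with 200–400 datasets and 199 labelings, plus
2,000 full-scale generator draws for the moment checks.  Rescaling leaves
the size of the tests unchanged (the permutation test is exact-size
conditional on locations), but it does change the correlation structure
across ranges, so the desk-scale multi-range FWE values (≈0.15/0.24/0.28 at
r = 10/50/100) are smaller than their full-scale counterparts.  The
full-scale study — 2,000 datasets of ~30,000 points per condition with 199
labelings each, via `kdiff study` with the default config — reproduces the
full inflation curve and is an overnight single-machine run; it is not part
of the default test suite.

## Known limitations

* Only the border edge correction is implemented (no isotropic/translation
  corrections) and only two marks (case/control).
* The Wald interval degenerates at p̂ ∈ {0,1}; use the Wilson option near
  boundaries.
* The Nadaraya-Watson risk surface is illustrative; its Gaussian-kernel
  bandwidth defaults to window side/20 and is a required, logged parameter
  with no data-driven selection.
* The integrated statistic's Monte Carlo null shares replicates with the
  envelope tests; with n_perm = 199 its p-value granularity is 1/200.
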