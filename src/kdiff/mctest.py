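"""Random-labeling Monte Carlo tests for the difference in K functions.

Random labeling permutes the case/control marks over the fixed locations,
holding the counts constant; under the null hypothesis of constant risk the
observed D(h) vector is exchangeable with the permuted replicates, which
makes every test here exact-size by construction (up to the rank convention).

Three decision rules are provided:

* pointwise  — per-range two-sided critical values from ranked replicates
  (defaults: 5th and 195th of 199, a size-0.05 test at each range);
  the multi-range rule rejects if D is outside the band at ANY range, which
  is exactly the practice whose family-wise error this package measures;
* simultaneous — a single global band (per-range replicate median ± a
  max-deviation critical constant) calibrated so the any-range rule has
  family-wise size <= alpha;
* integrated — one statistic S = Σ_i D(h_i)/sd_i pooling all ranges
  (sd_i = per-range replicate standard deviation), with a two-sided
  Monte Carlo p-value over the same replicate set.

Observed values exactly on a critical boundary are NOT rejections (strict
inequalities); ties have probability zero under the continuous generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateNullError, ParameterError, UndefinedEstimateError
from .kstat import CountingIndex, DifferenceEstimate, RangeGrid
from .pointprocess import LabeledPattern

DEFAULT_N_PERM = 199
DEFAULT_ALPHA = 0.05


def random_labeling(marks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the mark vector (counts preserved)."""
    marks = np.asarray(marks)
    if np.unique(marks).size < 2:
        raise ParameterError("random labeling requires both labels to be present")
    return rng.permutation(marks)


@dataclass(frozen=True)
class PermutationNull:
    """Observed D vector plus the n_perm × r matrix of relabeled D vectors."""

    observed: DifferenceEstimate
    replicates: np.ndarray
    n_perm: int
    seed: object = None  # RNG provenance, informational

    @property
    def grid(self) -> RangeGrid:
        return self.observed.grid

    def require_defined(self) -> None:
        """Fail loudly if any D value (observed or replicate) is undefined."""
        bad = np.isnan(self.observed.dhat) | np.isnan(self.replicates).any(axis=0)
        if bad.any():
            idx = np.flatnonzero(bad)
            raise UndefinedEstimateError(
                f"D undefined at range indices {idx.tolist()} "
                "(no border-eligible centres of a type)", range_indices=idx)

    def restrict(self, indices: np.ndarray) -> "PermutationNull":
        """The same null restricted to a nested sub-grid (same labelings)."""
        indices = np.asarray(indices)
        sub = RangeGrid(self.grid.side_length, indices.size)
        obs = DifferenceEstimate(sub, self.observed.dhat[indices])
        return PermutationNull(obs, self.replicates[:, indices], self.n_perm, self.seed)


def permutation_null(pattern: LabeledPattern, grid: RangeGrid, n_perm: int,
                     rng: np.random.Generator, seed=None) -> PermutationNull:
    """Build the random-labeling null: row j of ``replicates`` is D̂ of the
    same locations under the j-th independent relabeling."""
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    pattern.require_testable()
    idx = CountingIndex(pattern.xy, pattern.window, grid)
    is_case = pattern.is_case
    observed = DifferenceEstimate(grid, idx.dhat_for(is_case))
    replicates = np.empty((n_perm, grid.r))
    for j in range(n_perm):
        replicates[j] = idx.dhat_for(rng.permutation(is_case))
    return PermutationNull(observed, replicates, n_perm, seed)


@dataclass(frozen=True)
class Envelope:
    lower: np.ndarray
    upper: np.ndarray
    kind: str  # "pointwise" | "simultaneous"

    def __post_init__(self):
        if np.any(self.lower > self.upper):
            raise ParameterError("envelope lower bound exceeds upper bound")


@dataclass(frozen=True)
class TestOutcome:
    method: str  # "pointwise" | "simultaneous" | "integrated"
    reject_at_range: np.ndarray | None
    reject_any: bool
    p_value: float | None = None
    statistic: float | None = None
    envelope: Envelope | None = None


def default_ranks(n_perm: int, alpha: float) -> tuple[int, int]:
    """Symmetric two-sided ranks: (k, n_perm+1-k) with k = (alpha/2)(n_perm+1).

    For the study defaults n_perm=199, alpha=0.05 this is (5, 195)."""
    k = math.ceil(alpha / 2.0 * (n_perm + 1))
    if k < 1 or n_perm + 1 - k <= k:
        raise ParameterError(f"alpha={alpha} unattainable with n_perm={n_perm}")
    return k, n_perm + 1 - k


def pointwise_envelope(null: PermutationNull, lower_rank: int | None = None,
                       upper_rank: int | None = None,
                       alpha: float = DEFAULT_ALPHA) -> Envelope:
    """Per-range critical values: the lower_rank-th and upper_rank-th smallest
    replicate at each range (defaults 5 and 195 when n_perm = 199)."""
    if lower_rank is None or upper_rank is None:
        lower_rank, upper_rank = default_ranks(null.n_perm, alpha)
    if not (1 <= lower_rank < upper_rank <= null.n_perm):
        raise ParameterError(
            f"ranks must satisfy 1 <= lower < upper <= n_perm, "
            f"got ({lower_rank}, {upper_rank}) with n_perm={null.n_perm}")
    srt = np.sort(null.replicates, axis=0)
    return Envelope(srt[lower_rank - 1], srt[upper_rank - 1], "pointwise")


def simultaneous_envelope(null: PermutationNull, alpha: float = DEFAULT_ALPHA,
                          center: str = "median") -> Envelope:
    """Global max-deviation envelope with family-wise size <= alpha.

    For each replicate j, m_j = max_i |D_j(h_i) − c_i| with c_i the per-range
    replicate median (mean optionally); the critical constant is the
    ceil((1−alpha)(n_perm+1))-th smallest m_j and the band is c_i ± that.
    """
    if null.grid.r < 1:
        raise ParameterError("simultaneous envelope requires at least one range")
    k = math.ceil((1.0 - alpha) * (null.n_perm + 1))
    if k < 1 or k > null.n_perm:
        raise ParameterError(f"alpha={alpha} unattainable with n_perm={null.n_perm}")
    if center == "median":
        c = np.median(null.replicates, axis=0)
    elif center == "mean":
        c = null.replicates.mean(axis=0)
    else:
        raise ParameterError(f"unknown center {center!r}")
    m = np.abs(null.replicates - c).max(axis=1)
    crit = np.sort(m)[k - 1]
    return Envelope(c - crit, c + crit, "simultaneous")


def _envelope_outcome(null: PermutationNull, env: Envelope, method: str) -> TestOutcome:
    d = null.observed.dhat
    flags = (d < env.lower) | (d > env.upper)  # strict: boundary is no rejection
    return TestOutcome(method, flags, bool(flags.any()), envelope=env)


def integrated_statistic(null: PermutationNull, alpha: float = DEFAULT_ALPHA) -> TestOutcome:
    """Standardized-sum statistic over all ranges with a Monte Carlo p-value.

    S = Σ_i D(h_i)/sd_i, the same sd_i (replicate standard deviations) used
    for the observed vector and every replicate; two-sided p includes the
    observed in the reference set: p = (1 + #{|S_rep| >= |S_obs|})/(n_perm+1).
    """
    sd = null.replicates.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateNullError(
            f"replicate D has zero variance at range indices {zero.tolist()}")
    s_obs = float(np.sum(null.observed.dhat / sd))
    s_rep = (null.replicates / sd).sum(axis=1)
    p = (1 + int(np.sum(np.abs(s_rep) >= abs(s_obs)))) / (null.n_perm + 1)
    return TestOutcome("integrated", None, p <= alpha, p_value=p, statistic=s_obs)


def outcome_from_null(null: PermutationNull, method: str,
                      alpha: float = DEFAULT_ALPHA) -> TestOutcome:
    """Apply one of the three decision rules to an existing null."""
    null.require_defined()
    if method == "pointwise":
        return _envelope_outcome(null, pointwise_envelope(null, alpha=alpha), method)
    if method == "simultaneous":
        return _envelope_outcome(null, simultaneous_envelope(null, alpha=alpha), method)
    if method == "integrated":
        return integrated_statistic(null, alpha=alpha)
    raise ParameterError(f"unknown method {method!r}")


def test_dataset(pattern: LabeledPattern, grid: RangeGrid,
                 n_perm: int = DEFAULT_N_PERM, method: str = "pointwise",
                 rng: np.random.Generator | None = None,
                 alpha: float = DEFAULT_ALPHA) -> TestOutcome:
    """Full per-dataset test: build the random-labeling null, apply ``method``."""
    if rng is None:
        rng = np.random.default_rng()
    null = permutation_null(pattern, grid, n_perm, rng)
    return outcome_from_null(null, method, alpha=alpha)


def outcome_table(null: PermutationNull, outcome: TestOutcome,
                  dataset_id=0) -> pd.DataFrame:
    """Per-range test report (the CSV interface)."""
    grid = null.grid
    if outcome.envelope is not None:
        lower, upper = outcome.envelope.lower, outcome.envelope.upper
        flags = outcome.reject_at_range.astype(int)
    else:
        lower = upper = np.full(grid.r, np.nan)
        flags = np.full(grid.r, int(outcome.reject_any))
    df = pd.DataFrame({
        "dataset_id": dataset_id,
        "method": outcome.method,
        "r": grid.r,
        "range_index": np.arange(1, grid.r + 1),
        "h": grid.h,
        "d_obs": null.observed.dhat,
        "lower": lower,
        "upper": upper,
        "reject": flags,
    })
    if outcome.method == "integrated":
        df["statistic"] = outcome.statistic
        df["p_value"] = outcome.p_value
    return df
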