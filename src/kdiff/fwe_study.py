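"""Study orchestration: many simulated null datasets × a set of range counts,
aggregated into family-wise error (FWE) estimates with confidence intervals,
plus the rejection-correlation analysis.

The FWE here is the probability that a dataset generated under constant risk
is (falsely) declared clustered at ANY of the r ranges tested.  Each study
condition draws fresh datasets from its own seed stream (as the original
study did); a shared-dataset nested mode exists for the exact monotonicity
check (adding ranges to a nested grid can only add rejections) and is
labelled as such in its output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import StudyConfig, condition_sequences, dataset_rngs
from .errors import EstimationError, ParameterError
from .kstat import RangeGrid
from .mctest import outcome_from_null, permutation_null
from .pointprocess import (LabeledPattern, PatternSummary, SummaryStats,
                           generate_cox_pattern, pattern_summary,
                           summarize_patterns)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FWEResult:
    r: int
    n_datasets_used: int
    n_rejections: int
    fwe: float
    ci_lower: float
    ci_upper: float


def estimate_fwe(n_rejections: int, n_datasets_used: int,
                 confidence: float = 0.95, r: int = 0,
                 interval: str = "wald") -> FWEResult:
    """Binomial FWE estimate with a normal-approximation (Wald) interval,
    p̂ ± z·sqrt(p̂(1−p̂)/n), clipped to [0, 1]; Wilson available behind a flag.

    A degenerate Wald interval (p̂ of exactly 0 or 1) is returned with a
    warning rather than an error.
    """
    if not (0 <= n_rejections <= n_datasets_used):
        raise ParameterError("need 0 <= n_rejections <= n_datasets_used")
    if n_datasets_used < 1:
        raise ParameterError("n_datasets_used must be >= 1")
    p = n_rejections / n_datasets_used
    z = norm.ppf(0.5 + confidence / 2.0)
    if interval == "wald":
        half = z * np.sqrt(p * (1.0 - p) / n_datasets_used)
        lo, hi = p - half, p + half
        if p in (0.0, 1.0):
            logger.warning("degenerate Wald interval at p̂ = %s (n = %d)",
                           p, n_datasets_used)
    elif interval == "wilson":
        denom = 1.0 + z * z / n_datasets_used
        centre = (p + z * z / (2 * n_datasets_used)) / denom
        half = (z / denom) * np.sqrt(p * (1 - p) / n_datasets_used
                                     + z * z / (4 * n_datasets_used ** 2))
        lo, hi = centre - half, centre + half
    else:
        raise ParameterError(f"unknown interval type {interval!r}")
    return FWEResult(r, n_datasets_used, n_rejections, p,
                     float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def _resume_path(out_dir, r: int) -> Path | None:
    return Path(out_dir) / f"rejections_r{r}.csv" if out_dir is not None else None


def run_condition(config: StudyConfig, r: int, condition_index: int | None = None,
                  out_dir=None) -> tuple[FWEResult, np.ndarray, SummaryStats]:
    """One study condition: ``config.n_datasets`` fresh null datasets, each
    tested at the r-range grid with ``config.n_perm`` random labelings.

    Returns (FWE estimate, per-dataset rejection matrix, generator summary).
    Per-dataset results are appended to ``out_dir/rejections_r{r}.csv`` when
    ``out_dir`` is given, and previously completed datasets are skipped on
    resume.  Datasets failing testability (undefined D anywhere in observed
    or replicates, or fewer than two points of a type) are logged and
    excluded; the denominator reflects completed, testable datasets only.
    """
    if condition_index is None:
        condition_index = (config.range_counts.index(r)
                           if r in config.range_counts else len(config.range_counts))
    grid = RangeGrid(config.sim.side_length, r)
    seqs = condition_sequences(config.master_seed, condition_index, config.n_datasets)

    path = _resume_path(out_dir, r)
    done: dict[int, np.ndarray] = {}
    if path is not None and path.exists():
        prev = pd.read_csv(path)
        for did, g in prev.groupby("dataset_id"):
            done[int(did)] = g.sort_values("range_index")["reject"].to_numpy(int)
        logger.info("resuming condition r=%d: %d datasets already complete", r, len(done))

    rows, summaries = [], []
    n_excluded = 0
    for i, seq in enumerate(seqs):
        gen_rng, perm_rng = dataset_rngs(seq)
        pattern = generate_cox_pattern(config.sim, gen_rng)
        if pattern.n > 0:
            summaries.append(pattern_summary(pattern))
        if i in done:
            rows.append(done[i])
            continue
        try:
            null = permutation_null(pattern, grid, config.n_perm, perm_rng)
            outcome = outcome_from_null(null, config.method, alpha=config.alpha)
        except EstimationError as exc:
            n_excluded += 1
            logger.info("dataset %d excluded (r=%d): %s", i, r, exc)
            continue
        flags = (outcome.reject_at_range.astype(int)
                 if outcome.reject_at_range is not None
                 else np.full(r, int(outcome.reject_any)))
        rows.append(flags)
        if path is not None:
            df = pd.DataFrame({"dataset_id": i,
                               "range_index": np.arange(1, r + 1),
                               "h": grid.h, "reject": flags})
            df.to_csv(path, mode="a", header=not path.exists(), index=False)

    rejections = np.array(rows, dtype=int) if rows else np.zeros((0, r), dtype=int)
    n_used = rejections.shape[0]
    if n_used == 0:
        raise EstimationError("no testable datasets in this condition")
    if n_excluded:
        logger.info("condition r=%d: %d of %d datasets excluded",
                    r, n_excluded, config.n_datasets)
    n_reject = int(rejections.any(axis=1).sum())
    result = estimate_fwe(n_reject, n_used, r=r)
    return result, rejections, summarize_patterns(summaries)


NESTED_CONDITION_KEY = 1_000  # seed spawn key for the shared-dataset mode


def run_nested(config: StudyConfig, range_counts=None,
               ) -> tuple[dict[int, FWEResult], dict[int, np.ndarray], SummaryStats]:
    """Shared-dataset mode: every range count is evaluated on the SAME
    datasets with the SAME permutation stream, by testing at the finest grid
    and restricting the null to each nested sub-grid.

    Because a sub-grid's per-range critical values are identical to the
    corresponding columns of the finest grid's, the per-dataset any-range
    rejection is exactly monotone in r.  This mode exists for that
    monotonicity analysis; the headline study design draws fresh datasets per
    condition (``run_condition``).  All range counts must divide the largest.
    """
    range_counts = sorted(range_counts or config.range_counts)
    r_max = range_counts[-1]
    for r in range_counts:
        if r_max % r != 0:
            raise ParameterError(f"nested mode needs every r to divide {r_max}; got {r}")
    grid = RangeGrid(config.sim.side_length, r_max)
    seqs = condition_sequences(config.master_seed, NESTED_CONDITION_KEY, config.n_datasets)

    per_r_rows: dict[int, list[np.ndarray]] = {r: [] for r in range_counts}
    summaries = []
    n_excluded = 0
    for i, seq in enumerate(seqs):
        gen_rng, perm_rng = dataset_rngs(seq)
        pattern = generate_cox_pattern(config.sim, gen_rng)
        if pattern.n > 0:
            summaries.append(pattern_summary(pattern))
        try:
            null = permutation_null(pattern, grid, config.n_perm, perm_rng)
            null.require_defined()
        except EstimationError as exc:
            n_excluded += 1
            logger.info("dataset %d excluded (nested): %s", i, exc)
            continue
        for r in range_counts:
            sub = null.restrict(grid.subgrid_indices(r))
            outcome = outcome_from_null(sub, config.method, alpha=config.alpha)
            flags = (outcome.reject_at_range.astype(int)
                     if outcome.reject_at_range is not None
                     else np.full(r, int(outcome.reject_any)))
            per_r_rows[r].append(flags)

    if n_excluded:
        logger.info("nested mode: %d of %d datasets excluded", n_excluded, config.n_datasets)
    results, matrices = {}, {}
    for r in range_counts:
        mat = np.array(per_r_rows[r], dtype=int)
        if mat.size == 0:
            raise EstimationError("no testable datasets in nested mode")
        results[r] = estimate_fwe(int(mat.any(axis=1).sum()), mat.shape[0], r=r)
        matrices[r] = mat
    return results, matrices, summarize_patterns(summaries)


def rejection_correlation(rejections: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation (phi coefficient) of the per-range binary
    rejection indicators across datasets; unit diagonal; rows/columns of
    zero-variance indicators are undefined (NaN), never reported as 0."""
    rejections = np.asarray(rejections, dtype=float)
    if rejections.ndim != 2 or rejections.shape[0] < 2:
        raise ParameterError("rejection_correlation needs an (n>=2, r) matrix")
    sd = rejections.std(axis=0)
    ok = sd > 0
    r = rejections.shape[1]
    corr = np.full((r, r), np.nan)
    if ok.any():
        sub = np.corrcoef(rejections[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 1.0)
    return corr


def study_report(results, generator_summary: SummaryStats | None = None) -> pd.DataFrame:
    """Table-shaped summary of the study: one row per range count, ordered by
    r, with the FWE and its confidence interval; generator moments attached
    as DataFrame attrs when available."""
    results = list(results)
    if not results:
        raise ParameterError("study_report requires at least one result")
    df = pd.DataFrame([{
        "r": res.r, "n_used": res.n_datasets_used, "n_reject": res.n_rejections,
        "fwe": res.fwe, "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
    } for res in results]).sort_values("r", ignore_index=True)
    if generator_summary is not None:
        df.attrs["generator_summary"] = generator_summary
    return df
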