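"""Shared-parent Poisson cluster (Cox) process generator for case-control patterns.

The generative model emulates a large epidemiological cohort spread over a
square region: "parent" locations follow a homogeneous Poisson process with
intensity ``kappa`` (parents per mi²); each parent independently spawns a
Poisson number of case children and a Poisson number of control children,
every child placed uniformly at random in a disc of ``cluster_radius``
around its parent.  Case and control counts share parents (hence both are
spatially clustered the same way) but are conditionally independent given
the parents — the null hypothesis of constant risk holds by construction.

Defaults are calibrated so that the expected total sample is 30,000 with
50% cases on a window of 3,000,000 mi² (the area of the continental US):
kappa = 1e-4 (300 expected parents), 50 expected case children and 50
expected control children per parent, cluster radius 15 mi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EstimationError, ParameterError

CASE = "case"
CONTROL = "control"

#: side of a square with the area of the continental US (3,000,000 mi²)
DEFAULT_SIDE = math.sqrt(3_000_000.0)


@dataclass(frozen=True)
class Window:
    """Square observation window with its lower-left corner at the origin."""

    side_length: float

    def __post_init__(self):
        if not (self.side_length > 0):
            raise ParameterError(f"side_length must be positive, got {self.side_length}")

    @property
    def area(self) -> float:
        return self.side_length * self.side_length

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        L = self.side_length
        return (x >= 0) & (x <= L) & (y >= 0) & (y <= L)

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge."""
        L = self.side_length
        return np.minimum(np.minimum(x, L - x), np.minimum(y, L - y))


@dataclass
class LabeledPattern:
    """Planar point locations with case/control marks inside a window."""

    x: np.ndarray
    y: np.ndarray
    mark: np.ndarray  # array of {"case", "control"}
    window: Window

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mark = np.asarray(self.mark, dtype=object)
        if not (self.x.shape == self.y.shape == self.mark.shape):
            raise ParameterError("x, y and mark must have identical length")
        bad = set(np.unique(self.mark)) - {CASE, CONTROL}
        if bad:
            raise ParameterError(f"unknown marks: {sorted(bad)}")
        if self.n > 0 and not self.window.contains(self.x, self.y).all():
            raise ParameterError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def is_case(self) -> np.ndarray:
        return self.mark == CASE

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return self.n - self.n_case

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def require_testable(self, min_per_type: int = 2) -> None:
        if self.n_case < min_per_type or self.n_control < min_per_type:
            raise EstimationError(
                f"testing requires at least {min_per_type} points of each type "
                f"(got {self.n_case} cases, {self.n_control} controls)"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the shared-parent cluster process."""

    side_length: float = DEFAULT_SIDE
    kappa: float = 1e-4            # parents per mi²
    lambda_case: float = 50.0      # mean case children per parent
    lambda_control: float = 50.0   # mean control children per parent
    cluster_radius: float = 15.0   # mi

    def __post_init__(self):
        if not (self.side_length > 0):
            raise ParameterError(f"side_length must be positive, got {self.side_length}")
        if self.kappa < 0:
            raise ParameterError(f"kappa must be nonnegative, got {self.kappa}")
        if self.lambda_case < 0 or self.lambda_control < 0:
            raise ParameterError("child means must be nonnegative")
        if not (self.cluster_radius > 0):
            raise ParameterError(f"cluster_radius must be positive, got {self.cluster_radius}")

    @property
    def window(self) -> Window:
        return Window(self.side_length)

    @property
    def expected_total(self) -> float:
        """E[n] before window clipping: kappa·|A|·(λ_case + λ_control)."""
        return self.kappa * self.window.area * (self.lambda_case + self.lambda_control)

    @property
    def sd_total(self) -> float:
        """sd of the total count before clipping (compound-Poisson closed form)."""
        mu = self.kappa * self.window.area
        lam = self.lambda_case + self.lambda_control
        return math.sqrt(mu * (lam + lam * lam))

    def scaled_to_expected_n(self, target_n: float) -> "SimulationConfig":
        """Shrink/grow the geometry proportionally (side and cluster radius by
        the same factor) so the expected total sample becomes ``target_n``,
        keeping intensities and per-parent means fixed."""
        s = math.sqrt(target_n / self.expected_total)
        return replace(self, side_length=self.side_length * s,
                       cluster_radius=self.cluster_radius * s)


@dataclass(frozen=True)
class PatternSummary:
    n_total: int
    n_case: int
    n_control: int
    prop_case: float


@dataclass(frozen=True)
class SummaryStats:
    """Across-dataset aggregate of pattern summaries (sd is None for one pattern)."""

    n_patterns: int
    mean_n: float
    sd_n: float | None
    mean_prop_case: float
    sd_prop_case: float | None


def generate_parents(window: Window, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson parents: count ~ Poisson(kappa·|A|), uniform locations.

    Returns an (m, 2) coordinate array.
    """
    if kappa < 0:
        raise ParameterError(f"kappa must be nonnegative, got {kappa}")
    m = rng.poisson(kappa * window.area)
    return rng.uniform(0.0, window.side_length, size=(m, 2))


def _uniform_disc(rng: np.random.Generator, centers: np.ndarray, radius: float) -> np.ndarray:
    """One uniform point in the disc of ``radius`` around each center row."""
    k = centers.shape[0]
    r = radius * np.sqrt(rng.uniform(size=k))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=k)
    return centers + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_cox_pattern(config: SimulationConfig, rng: np.random.Generator,
                         return_parents: bool = False) -> LabeledPattern:
    """Draw one case-control pattern from the shared-parent cluster process.

    For each parent, the case-child count ~ Poisson(lambda_case) and the
    control-child count ~ Poisson(lambda_control), independently; children are
    uniform in the disc around their parent; children falling outside the
    observation window are discarded.

    Parents are drawn on the window dilated by ``cluster_radius`` (the
    standard edge handling for cluster-process simulation): every parent
    whose disc intersects the window can contribute, so the child process is
    stationary on the window and E[n] = kappa·|A|·(λ_case + λ_control)
    exactly, with no downward edge bias in the counts.
    """
    window = config.window
    R = config.cluster_radius
    dilated = Window(window.side_length + 2.0 * R)
    parents = generate_parents(dilated, config.kappa, rng) - R  # shift to [-R, L+R]²
    m = parents.shape[0]

    pts = []
    marks = []
    for lam, label in ((config.lambda_case, CASE), (config.lambda_control, CONTROL)):
        counts = rng.poisson(lam, size=m) if m else np.zeros(0, dtype=int)
        centers = np.repeat(parents, counts, axis=0)
        children = _uniform_disc(rng, centers, config.cluster_radius) \
            if centers.shape[0] else np.zeros((0, 2))
        keep = window.contains(children[:, 0], children[:, 1])
        children = children[keep]
        pts.append(children)
        marks.append(np.full(children.shape[0], label, dtype=object))

    xy = np.vstack(pts)
    mark = np.concatenate(marks)
    pattern = LabeledPattern(xy[:, 0], xy[:, 1], mark, window)
    if return_parents:
        return pattern, parents
    return pattern


def pattern_summary(pattern: LabeledPattern) -> PatternSummary:
    n, nc = pattern.n, pattern.n_case
    return PatternSummary(n, nc, n - nc, nc / n if n else float("nan"))


def summarize_patterns(patterns: Iterable[LabeledPattern | PatternSummary]) -> SummaryStats:
    """Sample mean/sd of total size and case proportion across patterns.

    sd is reported as None (absent, not zero) for a single pattern.
    """
    summaries = [p if isinstance(p, PatternSummary) else pattern_summary(p)
                 for p in patterns]
    if not summaries:
        raise ParameterError("summarize_patterns requires at least one pattern")
    n_tot = np.array([s.n_total for s in summaries], dtype=float)
    prop = np.array([s.prop_case for s in summaries], dtype=float)
    k = len(summaries)
    return SummaryStats(
        n_patterns=k,
        mean_n=float(n_tot.mean()),
        sd_n=float(n_tot.std(ddof=1)) if k > 1 else None,
        mean_prop_case=float(prop.mean()),
        sd_prop_case=float(prop.std(ddof=1)) if k > 1 else None,
    )


def nadaraya_watson_risk(pattern: LabeledPattern, bandwidth: float,
                         grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel smoothed case risk at each query point.

    risk(u) = Σ_cases w(u, x_i) / Σ_all w(u, x_i), w = exp(-d²/(2b²)).
    Query points where the total kernel mass underflows to zero get NaN
    (undefined, never silently zero).  ``grid`` is an (m, 2) array.
    """
    if not (bandwidth > 0):
        raise ParameterError(f"bandwidth must be positive, got {bandwidth}")
    if pattern.n == 0:
        raise ParameterError("nadaraya_watson_risk requires a non-empty pattern")
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    d2 = cdist(grid, pattern.xy, "sqeuclidean")
    w = np.exp(-d2 / (2.0 * bandwidth * bandwidth))
    total = w.sum(axis=1)
    case_mass = w[:, pattern.is_case].sum(axis=1)
    risk = np.full(grid.shape[0], np.nan)
    ok = total > 0
    risk[ok] = case_mass[ok] / total[ok]
    return risk


def square_grid(window: Window, n_per_side: int) -> np.ndarray:
    """Regular n×n lattice of query points spanning the window interior."""
    g = np.linspace(0.0, window.side_length, n_per_side)
    gx, gy = np.meshgrid(g, g)
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# pattern CSV interface: header x,y,mark; one row per point

def write_pattern_csv(pattern: LabeledPattern, path) -> None:
    pd.DataFrame({"x": pattern.x, "y": pattern.y, "mark": pattern.mark}) \
        .to_csv(path, index=False)


def read_pattern_csv(path, window: Window) -> LabeledPattern:
    """Read a pattern CSV, validating marks and window containment."""
    df = pd.read_csv(path)
    missing = {"x", "y", "mark"} - set(df.columns)
    if missing:
        raise ParameterError(f"pattern CSV missing columns: {sorted(missing)}")
    return LabeledPattern(df["x"].to_numpy(float), df["y"].to_numpy(float),
                          df["mark"].to_numpy(object), window)
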