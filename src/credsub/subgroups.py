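"""Credible subgroups: personalised treatment effects over a covariate
grid, simultaneous credible bands, and the D / S\\D / S-complement
trichotomy with its posterior bracketing guarantee.

Effects are benefit-positive: on the log-odds scale the effect at a
predictive point z is the negated treatment-control log-odds contrast
``-(z' gamma)``, so a positive value means reduced event odds under
treatment.  The band multiplier is the empirical quantile of the
per-draw sup of pointwise-standardized deviations, which makes the pair
(D, S) bracket the true benefiting set with posterior probability at
least the chosen level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CONTINUOUS_COVARIATES
from .design import StandardizationParams
from .model import PosteriorDraws

logger = logging.getLogger(__name__)

#: Pointwise posterior sd treated as zero-width (exact zero: every draw
#: at the point is bitwise identical, so the effect there is certain).
SD_FLOOR = 0.0

#: Axis iteration order of factorial grids (row-major raveling).
GRID_AXIS_ORDER = ("sf36_gh", "age", "sex", "hba1c")

#: Column of each axis in the 5-vector (1, GH, age, sex, HbA1c).
_POINT_COLUMN = {"sf36_gh": 1, "age": 2, "sex": 3, "hba1c": 4}

DEFAULT_LEVEL_GRID = np.round(np.arange(0.001, 1.0, 0.001), 3)


# ---------------------------------------------------------------------------
# covariate grid


@dataclass(frozen=True)
class CovariateGrid:
    """Evaluation points of the predictive covariate space.

    ``points`` is (m, 5): leading 1, then standardized GH, age, sex and
    HbA1c.  Factorial grids built by :func:`make_grid` additionally
    carry per-axis values (``axis_std``/``axis_raw``, ordered as
    :data:`GRID_AXIS_ORDER`) enabling fast nearest-point lookup.
    """

    points: np.ndarray
    raw: pd.DataFrame | None = None
    axis_std: dict | None = None
    axis_raw: dict | None = None

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 5 or p.shape[0] < 1:
            raise ValueError("points must be a nonempty (m, 5) array")
        if not np.all(p[:, 0] == 1.0):
            raise ValueError("first component of every grid point must be 1")
        if not np.isin(p[:, 3], (0.0, 1.0)).all():
            raise ValueError("sex component must be 0 or 1")
        object.__setattr__(self, "points", p)

    @property
    def m(self) -> int:
        return self.points.shape[0]

    @property
    def is_factorial(self) -> bool:
        return self.axis_std is not None

    @property
    def shape(self) -> tuple:
        if not self.is_factorial:
            raise ValueError("grid is not factorial")
        return tuple(len(self.axis_std[a]) for a in GRID_AXIS_ORDER)


def make_grid(
    std: StandardizationParams,
    ranges: dict,
    resolution: int = 20,
) -> CovariateGrid:
    """Full factorial grid over the covariate space.

    Parameters
    ----------
    std : StandardizationParams
        Scale of the fitted model; grid points are stored standardized.
    ranges : dict
        Raw (low, high) interval per continuous covariate
        (``sf36_gh``, ``age``, ``hba1c``).
    resolution : int
        Number of equally spaced raw values per continuous axis; the
        sex axis always contributes {0, 1}, so m = 2 * resolution**3.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if not ranges:
        raise ValueError("ranges must be nonempty")
    unknown = set(ranges) - set(CONTINUOUS_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariate name(s): {sorted(unknown)}")
    missing = set(CONTINUOUS_COVARIATES) - set(ranges)
    if missing:
        raise ValueError(f"ranges missing for: {sorted(missing)}")

    axis_raw, axis_std = {}, {}
    for name in CONTINUOUS_COVARIATES:
        lo, hi = float(ranges[name][0]), float(ranges[name][1])
        if lo == hi:
            raise ValueError(f"range endpoints for {name!r} are equal")
        if lo > hi:
            lo, hi = hi, lo
        axis_raw[name] = np.linspace(lo, hi, resolution)
        axis_std[name] = std.transform(name, axis_raw[name])
    axis_raw["sex"] = np.array([0.0, 1.0])
    axis_std["sex"] = np.array([0.0, 1.0])

    mesh = np.meshgrid(*(axis_std[a] for a in GRID_AXIS_ORDER), indexing="ij")
    m = mesh[0].size
    points = np.empty((m, 5))
    points[:, 0] = 1.0
    for name, grid_vals in zip(GRID_AXIS_ORDER, mesh):
        points[:, _POINT_COLUMN[name]] = grid_vals.ravel()

    mesh_raw = np.meshgrid(*(axis_raw[a] for a in GRID_AXIS_ORDER), indexing="ij")
    raw = pd.DataFrame(
        {name: vals.ravel() for name, vals in zip(GRID_AXIS_ORDER, mesh_raw)}
    )
    return CovariateGrid(points=points, raw=raw, axis_std=axis_std, axis_raw=axis_raw)


def default_ranges(cohort: pd.DataFrame, lower_pct: float = 1.0, upper_pct: float = 99.0) -> dict:
    """Per-covariate raw ranges from cohort percentiles (default 1st-99th)."""
    return {
        name: tuple(np.percentile(cohort[name].dropna(), [lower_pct, upper_pct]))
        for name in CONTINUOUS_COVARIATES
    }


# ---------------------------------------------------------------------------
# personalised treatment effect draws


class PTEDraws:
    """Per-draw benefit-positive personalised treatment effects on a grid.

    Concrete subclasses expose draws in row blocks so that bands over
    large grids (m >= 50,000) never require the full draws x m array in
    memory.  ``values`` materializes the full array and is intended for
    small problems and tests.
    """

    scale: str
    threshold: float
    grid: CovariateGrid | None

    @property
    def n_draws(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def m(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def block(self, start: int, stop: int) -> np.ndarray:
        """(stop-start, m) array of effects for draws [start, stop)."""
        raise NotImplementedError

    def iter_blocks(self, block_size: int = 512):
        for start in range(0, self.n_draws, block_size):
            yield self.block(start, min(start + block_size, self.n_draws))

    @property
    def values(self) -> np.ndarray:
        return self.block(0, self.n_draws)

    @staticmethod
    def from_values(
        values, scale: str = "log-odds", threshold: float = 0.0, grid=None
    ) -> "PTEDraws":
        """Wrap an explicit (draws, m) effect table (toy/test entry point)."""
        return _ArrayPTE(np.asarray(values, dtype=float), scale, threshold, grid)


class _ArrayPTE(PTEDraws):
    def __init__(self, values, scale, threshold, grid):
        if values.ndim != 2:
            raise ValueError("values must be 2-d (draws x points)")
        if not np.isfinite(values).all():
            raise ValueError("effect draws must be finite")
        self._values = values
        self.scale = scale
        self.threshold = float(threshold)
        self.grid = grid

    @property
    def n_draws(self):
        return self._values.shape[0]

    @property
    def m(self):
        return self._values.shape[1]

    def block(self, start, stop):
        return self._values[start:stop]


class _LogOddsPTE(PTEDraws):
    """Delta(z) = -(z' gamma) per draw; linear in the coefficients."""

    def __init__(self, gamma, grid, threshold):
        self._gamma = gamma
        self.grid = grid
        self.scale = "log-odds"
        self.threshold = float(threshold)

    @property
    def n_draws(self):
        return self._gamma.shape[0]

    @property
    def m(self):
        return self.grid.m

    def block(self, start, stop):
        return -(self._gamma[start:stop] @ self.grid.points.T)

    def shifted(self, delta0: float) -> "_LogOddsPTE":
        """Copy with ``delta0`` added to every treatment-main-effect draw."""
        gamma = self._gamma.copy()
        gamma[:, 0] += delta0
        return _LogOddsPTE(gamma, self.grid, self.threshold)


class _RiskDiffPTE(PTEDraws):
    """Delta(z) = logit^-1(x'beta) - logit^-1(x'beta + z'gamma), x = z."""

    def __init__(self, beta, gamma, grid, threshold):
        self._beta = beta
        self._gamma = gamma
        self.grid = grid
        self.scale = "risk-difference"
        self.threshold = float(threshold)

    @property
    def n_draws(self):
        return self._beta.shape[0]

    @property
    def m(self):
        return self.grid.m

    def block(self, start, stop):
        xb = self._beta[start:stop] @ self.grid.points.T
        zg = self._gamma[start:stop] @ self.grid.points.T
        return expit(xb) - expit(xb + zg)


def compute_pte(
    draws: PosteriorDraws,
    grid: CovariateGrid,
    scale: str = "log-odds",
    threshold: float = 0.0,
) -> PTEDraws:
    """Personalised treatment effect draws over ``grid``.

    ``scale="log-odds"`` gives the negated log-odds contrast
    ``-(z' gamma)``, the package's primary scale (positive = benefit);
    ``scale="risk-difference"`` gives the benefit-positive event
    probability difference with the prognostic vector taken equal to the
    predictive one.
    """
    if scale == "log-odds":
        return _LogOddsPTE(draws.gamma.copy(), grid, threshold)
    if scale == "risk-difference":
        return _RiskDiffPTE(draws.beta.copy(), draws.gamma.copy(), grid, threshold)
    raise ValueError(f"unknown effect scale {scale!r}")


# ---------------------------------------------------------------------------
# simultaneous band


@dataclass(frozen=True)
class SimultaneousBand:
    """Pointwise mean/sd plus a simultaneous multiplier.

    The band is mean +/- multiplier * sd, except at floored points
    (pointwise sd of exactly zero) where lower = upper = mean.
    """

    mean: np.ndarray
    sd: np.ndarray
    multiplier: float
    level: float
    floored: np.ndarray
    grid: CovariateGrid | None = None

    @property
    def m(self) -> int:
        return self.mean.shape[0]

    @property
    def lower(self) -> np.ndarray:
        out = self.mean - self.multiplier * self.sd
        out[self.floored] = self.mean[self.floored]
        return out

    @property
    def upper(self) -> np.ndarray:
        out = self.mean + self.multiplier * self.sd
        out[self.floored] = self.mean[self.floored]
        return out


def _pointwise_stats(pte: PTEDraws, block_size: int):
    # two-pass: exact same algebra as a naive per-draw enumeration loop
    k = pte.n_draws
    total = np.zeros(pte.m)
    for blk in pte.iter_blocks(block_size):
        for row in blk:
            total += row
    mean = total / k
    sumsq = np.zeros(pte.m)
    for blk in pte.iter_blocks(block_size):
        for row in blk:
            dev = row - mean
            sumsq += dev * dev
    return mean, np.sqrt(sumsq / max(k - 1, 1))


def _sup_deviations(pte: PTEDraws, mean, sd, valid, block_size):
    w = np.empty(pte.n_draws)
    if not valid.any():
        w[:] = 0.0
        return w
    mean_v, sd_v = mean[valid], sd[valid]
    pos = 0
    for blk in pte.iter_blocks(block_size):
        dev = np.abs(blk[:, valid] - mean_v) / sd_v
        w[pos : pos + blk.shape[0]] = dev.max(axis=1)
        pos += blk.shape[0]
    return w


def simultaneous_band(
    pte: PTEDraws, level: float, block_size: int = 512
) -> SimultaneousBand:
    """Two-sided simultaneous credible band at ``level``.

    The multiplier c is the empirical ``level`` quantile (inverted-CDF
    convention) of the per-draw sup over grid points of
    |Delta - mean| / sd; zero-sd points (all draws identical there) collapse
    to zero width and are excluded from the sup.  Draws are processed in
    blocks, so memory stays O(block_size * m).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if pte.n_draws < 2:
        raise ValueError("need at least 2 draws")
    mean, sd = _pointwise_stats(pte, block_size)
    valid = sd > SD_FLOOR
    w = _sup_deviations(pte, mean, sd, valid, block_size)
    c = float(np.quantile(w, level, method="inverted_cdf"))
    return SimultaneousBand(
        mean=mean, sd=sd, multiplier=c, level=level, floored=~valid, grid=pte.grid
    )


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class CredibleSubgroupPair:
    """Exclusive (D) and inclusive (S) subgroup masks over a grid.

    D contains only points credibly above the threshold; S contains all
    points not credibly at or below it.  D is always a subset of S and
    the regions D, S\\D and S-complement partition the grid.
    """

    D: np.ndarray
    S: np.ndarray
    level: float
    threshold: float
    grid: CovariateGrid | None = None

    def __post_init__(self):
        if self.D.shape != self.S.shape:
            raise ValueError("D and S masks must share shape")
        if np.any(self.D & ~self.S):
            raise ValueError("D must be a subset of S")

    @property
    def uncertainty(self) -> np.ndarray:
        """S \\ D mask."""
        return self.S & ~self.D

    @property
    def S_complement(self) -> np.ndarray:
        return ~self.S

    def region_labels(self) -> np.ndarray:
        """Per-point label in {"D", "S\\D", "Sc"}."""
        out = np.full(self.D.shape, "S\\D", dtype=object)
        out[self.D] = "D"
        out[self.S_complement] = "Sc"
        return out


def classify(band: SimultaneousBand, threshold: float = 0.0) -> CredibleSubgroupPair:
    """Trichotomize the grid: D where the lower surface exceeds the
    threshold, S where the upper surface does.

    Comparisons are made in the standardized domain --
    ``(mean - threshold)/sd > c`` rather than ``mean - c*sd > threshold``
    -- which is algebraically identical but keeps the posterior
    bracketing guarantee exact in floating point (rounding is monotone
    under division by the same positive sd used for the sup statistic).
    """
    delta = float(threshold)
    c = band.multiplier
    valid = ~band.floored
    with np.errstate(divide="ignore", invalid="ignore"):
        t_d = (band.mean - delta) / band.sd
        t_sc = (delta - band.mean) / band.sd
    D = np.where(valid, t_d > c, band.mean > delta)
    S = np.where(valid, t_sc < c, band.mean > delta)
    return CredibleSubgroupPair(
        D=D, S=S, level=band.level, threshold=delta, grid=band.grid
    )


def bracket_probability(
    pte: PTEDraws, pair: CredibleSubgroupPair, block_size: int = 512
) -> float:
    """Monte-Carlo estimate over draws of P(D subset of B subset of S).

    For each draw the event holds when every point of D has effect above
    the pair's threshold and no point outside S does.  This is the
    defining property of the pair and serves as its oracle.
    """
    if pair.D.shape[0] != pte.m:
        raise ValueError("pair and effect draws use different grids")
    delta = pair.threshold
    d_idx = np.flatnonzero(pair.D)
    sc_idx = np.flatnonzero(pair.S_complement)
    hits = 0
    for blk in pte.iter_blocks(block_size):
        ok = np.ones(blk.shape[0], dtype=bool)
        if d_idx.size:
            ok &= (blk[:, d_idx] > delta).all(axis=1)
        if sc_idx.size:
            ok &= (blk[:, sc_idx] <= delta).all(axis=1)
        hits += int(ok.sum())
    return hits / pte.n_draws


# ---------------------------------------------------------------------------
# maximum credible level


@dataclass(frozen=True)
class MaxLevelSurface:
    """Signed maximum credible level per grid point.

    Positive values: the largest level (within the level grid) at which
    the point enters D.  Negative values: minus the largest level at
    which it enters the S-complement.  Zero: the point enters neither at
    any level in the grid.
    """

    values: np.ndarray
    level_grid: np.ndarray
    threshold: float
    grid: CovariateGrid | None = None


def max_credible_level(
    pte: PTEDraws,
    threshold: float = 0.0,
    level_grid: np.ndarray | None = None,
    block_size: int = 512,
) -> MaxLevelSurface:
    """Invert the classification over a grid of credible levels.

    Consistent with :func:`classify` at every level in ``level_grid``:
    a point's signed value is >= L exactly when it belongs to D at level
    L (and symmetrically for the S-complement with negated values).
    """
    if level_grid is None:
        level_grid = DEFAULT_LEVEL_GRID
    levels = np.asarray(level_grid, dtype=float)
    if levels.size == 0:
        raise ValueError("level grid is empty")
    if np.any((levels <= 0.0) | (levels >= 1.0)):
        raise ValueError("levels must lie in (0, 1)")
    levels = np.sort(levels)

    mean, sd = _pointwise_stats(pte, block_size)
    valid = sd > SD_FLOOR
    w = _sup_deviations(pte, mean, sd, valid, block_size)
    c_levels = np.quantile(w, levels, method="inverted_cdf")

    # D at level L  <=>  c(L) <  (mean - delta) / sd   (strict lower bound)
    # Sc at level L <=>  c(L) <= (delta - mean) / sd
    delta = float(threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_d = np.where(valid, (mean - delta) / sd, np.where(mean > delta, np.inf, -np.inf))
        t_sc = np.where(valid, (delta - mean) / sd, np.where(mean <= delta, np.inf, -np.inf))
    n_d = np.searchsorted(c_levels, t_d, side="left")
    n_sc = np.searchsorted(c_levels, t_sc, side="right")

    values = np.zeros(pte.m)
    has_d = n_d > 0
    values[has_d] = levels[n_d[has_d] - 1]
    neg = ~has_d & (n_sc > 0)
    values[neg] = -levels[n_sc[neg] - 1]
    return MaxLevelSurface(
        values=values, level_grid=levels, threshold=delta, grid=pte.grid
    )


# ---------------------------------------------------------------------------
# applying a pair to subjects


def _nearest_axis_index(axis_values: np.ndarray, x: np.ndarray) -> np.ndarray:
    order = np.argsort(axis_values)
    sorted_vals = axis_values[order]
    pos = np.searchsorted(sorted_vals, x)
    pos = np.clip(pos, 1, len(sorted_vals) - 1)
    left = sorted_vals[pos - 1]
    right = sorted_vals[pos]
    idx_sorted = np.where(np.abs(x - left) <= np.abs(right - x), pos - 1, pos)
    return order[idx_sorted]


def nearest_grid_indices(
    grid: CovariateGrid, cohort: pd.DataFrame, std: StandardizationParams
) -> np.ndarray:
    """Nearest grid point per subject in the standardized space.

    The sex axis is matched exactly; subjects outside a continuous axis
    range are assigned to the boundary value (with a logged warning).
    Requires a factorial grid.
    """
    if not grid.is_factorial:
        raise ValueError("nearest-point lookup requires a factorial grid")
    n_out_of_range = 0
    axis_idx = {}
    for name in CONTINUOUS_COVARIATES:
        raw = cohort[name].to_numpy(dtype=float)
        lo, hi = grid.axis_raw[name].min(), grid.axis_raw[name].max()
        n_out_of_range += int(((raw < lo) | (raw > hi)).sum())
        axis_idx[name] = _nearest_axis_index(grid.axis_std[name], std.transform(name, raw))
    axis_idx["sex"] = cohort["sex"].to_numpy(dtype=float).astype(int)
    if n_out_of_range:
        logger.warning(
            "%d subject covariate values fall outside the grid ranges; "
            "assigned to boundary points",
            n_out_of_range,
        )
    shape = grid.shape
    flat = np.zeros(len(cohort), dtype=int)
    for name, size in zip(GRID_AXIS_ORDER, shape):
        flat = flat * size + axis_idx[name]
    return flat


def apply_to_cohort(
    pair: CredibleSubgroupPair,
    cohort: pd.DataFrame,
    std: StandardizationParams,
    grid: CovariateGrid | None = None,
) -> dict:
    """Share of subjects whose covariate profile falls in D, S\\D and Sc.

    Each subject is mapped to its nearest grid point (exact on sex) and
    inherits that point's region.  Returns a dict with keys
    ``"D"``, ``"S\\D"`` and ``"Sc"``; the fractions sum to 1.
    """
    grid = grid if grid is not None else pair.grid
    if grid is None:
        raise ValueError("pair carries no grid; pass one explicitly")
    if cohort[["age", "sex", "sf36_gh", "hba1c"]].isna().any().any():
        raise ValueError("cohort must be complete-case")
    idx = nearest_grid_indices(grid, cohort, std)
    labels = pair.region_labels()[idx]
    n = len(cohort)
    return {
        "D": float((labels == "D").sum() / n),
        "S\\D": float((labels == "S\\D").sum() / n),
        "Sc": float((labels == "Sc").sum() / n),
    }


def classification_table(
    grid: CovariateGrid,
    band: SimultaneousBand,
    pair: CredibleSubgroupPair,
    surface: MaxLevelSurface | None = None,
) -> pd.DataFrame:
    """Machine-readable export of a grid classification.

    One row per grid point: raw covariate values (factorial grids),
    standardized values, posterior mean effect, band surfaces, region
    label and (optionally) the signed maximum credible level.
    """
    out = pd.DataFrame()
    if grid.raw is not None:
        for name in GRID_AXIS_ORDER:
            out[f"{name}_raw"] = grid.raw[name].to_numpy()
    for name, col in _POINT_COLUMN.items():
        out[f"{name}_std"] = grid.points[:, col]
    out["mean_effect"] = band.mean
    out["lower"] = band.lower
    out["upper"] = band.upper
    out["region"] = pair.region_labels()
    if surface is not None:
        out["max_credible_level"] = surface.values
    return out
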