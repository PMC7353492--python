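"""Joint likelihood confidence regions for (k_ref, E_a).

The joint (1−α) region is the set of parameter pairs whose sum of
squared errors does not exceed

    SSE_min · (1 + p/(n−p) · F(p, n−p, 1−α)),

the F-based contour of the likelihood surface.  Unlike per-parameter
intervals it captures the strong correlation between k_ref and E_a, and
it is the filter applied to Monte Carlo parameter draws downstream.
Membership tests use exact SSE evaluation; the boundary polygon is only
for inspection/plotting and is extracted by marching squares on an SSE
grid with automatic box expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage import measure

from .errors import InvalidInputError
from .units import GAS_CONSTANT
from .fitting import FitResult, IsothermalDataset, _predictions
from .kinetics import ArrheniusParameters

__all__ = [
    "JointConfidenceRegion",
    "RegionBoundary",
    "sse_at",
    "joint_threshold",
    "in_region",
    "region_boundary",
    "filter_pairs",
]


def sse_at(params: ArrheniusParameters, dataset: IsothermalDataset) -> float:
    """Sum of squared retention residuals of the integrated model."""
    predicted = _predictions(np.array([params.k_ref, params.E_a]), dataset, params.T_ref)
    r = dataset.retention - predicted
    return float(r @ r)


def joint_threshold(sse_min: float, n: int, p: int, alpha: float) -> float:
    """F-based SSE bound of the joint (1−alpha) likelihood region."""
    if n <= p or p < 1:
        raise InvalidInputError(f"need n > p ≥ 1, got n={n}, p={p}")
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    fq = stats.f.ppf(1.0 - alpha, p, n - p)
    return sse_min * (1.0 + (p / (n - p)) * fq)


@dataclass(frozen=True)
class JointConfidenceRegion:
    """SSE threshold plus the dataset over which membership is evaluated."""

    sse_min: float
    threshold: float
    alpha: float
    n: int
    p: int
    dataset: IsothermalDataset
    T_ref: float

    @classmethod
    def from_fit(cls, fit: FitResult, dataset: IsothermalDataset, alpha: float = 0.05) -> "JointConfidenceRegion":
        sse_min = sse_at(fit.parameters, dataset)
        return cls(
            sse_min=sse_min,
            threshold=joint_threshold(sse_min, dataset.n, fit.p, alpha),
            alpha=alpha,
            n=dataset.n,
            p=fit.p,
            dataset=dataset,
            T_ref=fit.parameters.T_ref,
        )

    def contains(self, k_ref: float, E_a: float) -> bool:
        if k_ref <= 0:
            return False
        return sse_at(ArrheniusParameters(k_ref, E_a, self.T_ref), self.dataset) <= self.threshold

    def sse_grid(self, k_ref_values: np.ndarray, E_a_values: np.ndarray) -> np.ndarray:
        """SSE evaluated on the outer grid (len(E_a) rows × len(k_ref) cols)."""
        x = 1.0 / self.dataset.temperature_K - 1.0 / self.T_ref
        t = self.dataset.time_days
        obs = self.dataset.retention
        # (nE, nk, nobs) would be large; loop over rows instead
        out = np.empty((E_a_values.size, k_ref_values.size))
        for i, Ea in enumerate(E_a_values):
            A = np.exp(-(Ea / GAS_CONSTANT) * x)
            pred = np.exp(-np.outer(k_ref_values, A * t))  # (nk, nobs)
            out[i] = ((obs - pred) ** 2).sum(axis=1)
        return out


def in_region(candidate: ArrheniusParameters, region: JointConfidenceRegion) -> bool:
    """Exact SSE membership test against the region threshold."""
    if candidate.T_ref != region.T_ref:
        raise InvalidInputError("candidate must share T_ref with the fitted region")
    return sse_at(candidate, region.dataset) <= region.threshold


@dataclass(frozen=True)
class RegionBoundary:
    """Ordered boundary points of a joint region in the (k_ref, E_a) plane."""

    k_ref: np.ndarray
    E_a: np.ndarray
    threshold: float
    unbounded_within_search_box: bool
    contour_found: bool

    @property
    def polygon_area(self) -> float:
        """Shoelace area of the boundary polygon (0 if no contour)."""
        if not self.contour_found or self.k_ref.size < 3:
            return 0.0
        x, y = self.k_ref, self.E_a
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def region_boundary(
    fit: FitResult,
    dataset: IsothermalDataset,
    alpha: float = 0.05,
    grid: int = 201,
    max_expansions: int = 4,
) -> RegionBoundary:
    """Extract the SSE = threshold contour around the least-squares optimum.

    Scans a rectangular grid spanning the estimate ± 5 asymptotic SEs per
    parameter, extracting the iso-SSE contour by marching squares.  If the
    contour touches the box edge the box is doubled (up to
    ``max_expansions`` times), after which the boundary is flagged as
    unbounded within the search box — likelihood regions of nonlinear
    models can genuinely be unbounded.
    """
    region = JointConfidenceRegion.from_fit(fit, dataset, alpha)
    k_hat, E_hat = fit.parameters.k_ref, fit.parameters.E_a
    se_k, se_E = fit.standard_errors
    half_k, half_E = 5.0 * se_k, 5.0 * se_E

    for expansion in range(max_expansions + 1):
        k_vals = np.linspace(max(k_hat - half_k, 1e-12), k_hat + half_k, grid)
        E_vals = np.linspace(E_hat - half_E, E_hat + half_E, grid)
        sse = region.sse_grid(k_vals, E_vals)
        contours = measure.find_contours(sse, region.threshold)
        if not contours:
            half_k *= 2.0
            half_E *= 2.0
            continue
        # keep the contour enclosing (or nearest to) the optimum
        contour = max(contours, key=len)
        touches_edge = bool(
            np.any(contour <= 0.0) or np.any(contour >= grid - 1.0)
        )
        if touches_edge and expansion < max_expansions:
            half_k *= 2.0
            half_E *= 2.0
            continue
        rows, cols = contour[:, 0], contour[:, 1]
        E_pts = np.interp(rows, np.arange(grid), E_vals)
        k_pts = np.interp(cols, np.arange(grid), k_vals)
        return RegionBoundary(
            k_ref=k_pts,
            E_a=E_pts,
            threshold=region.threshold,
            unbounded_within_search_box=touches_edge,
            contour_found=True,
        )

    return RegionBoundary(
        k_ref=np.empty(0),
        E_a=np.empty(0),
        threshold=region.threshold,
        unbounded_within_search_box=True,
        contour_found=False,
    )


def filter_pairs(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    region: JointConfidenceRegion,
) -> tuple[np.ndarray, np.ndarray]:
    """Order-preserving subsequence of (k_ref, E_a) pairs inside the region.

    Returns (retained_pairs, mask); the retained count is mask.sum().
    Membership uses exact SSE evaluation, vectorized over candidates.
    """
    arr = np.atleast_2d(np.asarray(pairs, dtype=float))
    if arr.shape[1] != 2:
        raise InvalidInputError("pairs must have shape (m, 2) as (k_ref, E_a)")
    x = 1.0 / region.dataset.temperature_K - 1.0 / region.T_ref
    t = region.dataset.time_days
    obs = region.dataset.retention
    k = arr[:, 0][:, None]
    Ea = arr[:, 1][:, None]
    pred = np.exp(-k * np.exp(-(Ea / GAS_CONSTANT) * x[None, :]) * t[None, :])
    sse = ((obs[None, :] - pred) ** 2).sum(axis=1)
    mask = (sse <= region.threshold) & (arr[:, 0] > 0)
    return arr[mask], mask
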