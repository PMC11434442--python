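"""Correlation-threshold selection by random-matrix-theory spacing statistics.

For each candidate cutoff the thresholded correlation matrix is
eigendecomposed, the eigenvalue spectrum is unfolded through a smoothed
empirical CDF, and the nearest-neighbour spacing distribution is compared
against the Poisson (exponential) and Wigner-Dyson (GOE surmise) densities.
The selected threshold is the smallest candidate at which spacings fit
Poisson better than GOE and keep doing so for the next two grid points —
the transition point where genuine modular signal separates from the bulk
of a random matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from rhizonet.correlation import CorrelationSet
from rhizonet.errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.50, 0.90 + 1e-9, 0.01), 2)
DEFAULT_FALLBACK = 0.70

_N_BINS = 30
_SPACING_MAX = 3.0


@dataclass(frozen=True)
class ThresholdScan:
    """Scan table plus the selected threshold."""

    scan: pd.DataFrame  # columns: threshold, dist_poisson, dist_goe, poisson_better
    selected: float
    fallback_used: bool

    def write_tsv(self, path) -> None:
        self.scan.to_csv(path, sep="\t", index=False)


def _unfold_spacings(eigenvalues: np.ndarray) -> np.ndarray | None:
    """Nearest-neighbour spacings after empirical-CDF unfolding.

    The CDF is smoothed by a monotone cubic (PCHIP) through a coarse subset
    of the distinct eigenvalues so that local fluctuations — the object of
    interest — are not absorbed into the unfolding. Returns None when the
    spectrum is too degenerate to unfold (treated as trivially Poisson).
    """
    ev = np.sort(eigenvalues)
    n = ev.size
    uniq, counts = np.unique(np.round(ev, 10), return_counts=True)
    if uniq.size < 4:
        return None
    cdf = np.cumsum(counts) / n
    # coarse knots: ~20 evenly spaced distinct eigenvalues
    step = max(1, uniq.size // 20)
    knots = np.unique(np.concatenate([uniq[::step], uniq[-1:]]))
    knot_cdf = np.interp(knots, uniq, cdf)
    # enforce strict monotonicity for the interpolator
    keep = np.concatenate([[True], np.diff(knots) > 1e-12])
    knots, knot_cdf = knots[keep], knot_cdf[keep]
    if knots.size < 3:
        return None
    smooth_cdf = PchipInterpolator(knots, knot_cdf)
    unfolded = n * np.asarray(smooth_cdf(ev))
    spacings = np.diff(unfolded)
    spacings = spacings[np.isfinite(spacings)]
    spacings = np.clip(spacings, 0.0, None)
    mean = spacings.mean() if spacings.size else 0.0
    if mean <= 0:
        return None
    return spacings / mean


def _chi2_distance(spacings: np.ndarray, density) -> float:
    """Chi-square distance between the spacing histogram and a model density."""
    counts, edges = np.histogram(spacings, bins=_N_BINS, range=(0.0, _SPACING_MAX))
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    expected = density(centers) * width * spacings.size
    expected = np.clip(expected, 1e-9, None)
    return float(np.sum((counts - expected) ** 2 / expected))


def _poisson_density(s: np.ndarray) -> np.ndarray:
    return np.exp(-s)


def _goe_density(s: np.ndarray) -> np.ndarray:
    return (np.pi * s / 2.0) * np.exp(-np.pi * s * s / 4.0)


def scan_thresholds(cset: CorrelationSet, grid: np.ndarray) -> pd.DataFrame:
    """Spacing-distribution fit statistics for every candidate threshold."""
    rho = cset.rho_matrix().to_numpy()
    rows = []
    for s in grid:
        mat = np.where(np.abs(rho) >= s, rho, 0.0)
        np.fill_diagonal(mat, 1.0)
        ev = np.linalg.eigvalsh(mat)
        spacings = _unfold_spacings(ev)
        if spacings is None or spacings.size < 10:
            # degenerate spectrum: no level repulsion left, trivially Poisson
            rows.append((s, 0.0, np.inf, True))
            continue
        d_p = _chi2_distance(spacings, _poisson_density)
        d_g = _chi2_distance(spacings, _goe_density)
        rows.append((s, d_p, d_g, d_p < d_g))
    return pd.DataFrame(
        rows, columns=["threshold", "dist_poisson", "dist_goe", "poisson_better"]
    )


def optimize_threshold(
    cset: CorrelationSet,
    grid: np.ndarray | None = None,
    fallback: float = DEFAULT_FALLBACK,
    min_taxa: int = 30,
) -> ThresholdScan:
    """Select the edge-inclusion cutoff for |rho|.

    Picks the smallest grid value whose spacing distribution fits Poisson
    better than GOE, with the fit stable for the next two grid points. A
    single-point grid is returned as-is. If no candidate qualifies the
    configured fallback is used with a warning.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("threshold grid must be strictly increasing")
    if grid.size == 1:
        scan = scan_thresholds(cset, grid)
        return ThresholdScan(scan=scan, selected=float(grid[0]), fallback_used=False)
    if len(cset.taxa) < min_taxa:
        raise InsufficientDataError(
            f"need >= {min_taxa} taxa for eigenvalue statistics, got {len(cset.taxa)}"
        )

    scan = scan_thresholds(cset, grid)
    flags = scan["poisson_better"].to_numpy()
    selected = None
    for i in range(len(grid) - 2):
        if flags[i] and flags[i + 1] and flags[i + 2]:
            selected = float(grid[i])
            break
    fallback_used = selected is None
    if fallback_used:
        warnings.warn(
            f"threshold scan did not converge; falling back to {fallback}",
            stacklevel=2,
        )
        selected = float(fallback)
    logger.info("optimize_threshold: selected %.3f (fallback=%s)", selected, fallback_used)
    return ThresholdScan(scan=scan, selected=selected, fallback_used=fallback_used)
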