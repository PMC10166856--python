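"""Binned 1D profiles and loess smoothing of spot-level features.

Given each spot's scaled axis position in [0, 1] and any per-spot feature
value (normalized gene expression, raw counts, module scores, cell-type
proportions), the profile is built in two steps:

1. bin the axis into ``n_bins`` equal intervals and record, per non-empty
   bin, the mean axis position ``x_i`` and mean feature value ``y_i``;
2. fit a loess curve (locally weighted polynomial regression with tri-cube
   weights) of ``y_i`` on ``x_i`` and evaluate it on an even grid.

Bin ``i`` covers ``[(i-1)/n_bins, i/n_bins)`` for ``i = 1..n_bins-1``; the
last bin is right-closed so a position of exactly 1 is binned. Empty bins
are omitted (an average over an empty set is undefined).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyModule,
    InvalidBinCount,
    NoSpots,
    OutOfRange,
    TooFewBins,
)
from .types import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 50
DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2


@dataclass
class BinnedProfile:
    """Per-bin means of axis position and feature value."""

    n_bins: int
    bin_index: np.ndarray      # non-empty bin indices, 1-based, increasing
    x: np.ndarray              # mean axis position per non-empty bin
    y: np.ndarray              # mean feature value per non-empty bin
    occupancy: np.ndarray      # spot count per non-empty bin
    feature_name: str = "feature"
    n_dropped: int = 0         # spots without a defined feature value


@dataclass
class SmoothedProfile:
    """Loess fit of a binned profile on an even axis grid."""

    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int
    se: np.ndarray | None = None


def assign_bins(scaled_positions: dict[str, float], n_bins: int) -> dict[str, int]:
    """Map each spot to its axis bin (1-based).

    Positions must lie in [0, 1]; the value 1 falls in bin ``n_bins``
    (right-closed last bin), every other position p in bin
    ``floor(p * n_bins) + 1``.
    """
    if n_bins < 1:
        raise InvalidBinCount(f"n_bins must be >= 1, got {n_bins}")
    out: dict[str, int] = {}
    for spot, p in scaled_positions.items():
        if not (0.0 <= p <= 1.0):
            raise OutOfRange(f"position {p!r} of spot {spot!r} outside [0, 1]")
        out[spot] = min(int(np.floor(p * n_bins)) + 1, n_bins)
    return out


def bin_profile(
    scaled_positions: dict[str, float],
    feature: dict[str, float],
    n_bins: int = DEFAULT_N_BINS,
    feature_name: str = "feature",
) -> BinnedProfile:
    """Average the feature within axis bins.

    Spots present in ``scaled_positions`` but missing from ``feature`` (or
    carrying a NaN) are dropped with a logged count. Raises
    :class:`NoSpots` if nothing remains.
    """
    bins = assign_bins(scaled_positions, n_bins)
    kept_ids = [
        s for s in scaled_positions
        if s in feature and np.isfinite(feature[s])
    ]
    n_dropped = len(scaled_positions) - len(kept_ids)
    if n_dropped:
        logger.info(
            "bin_profile(%s): dropped %d of %d spots without a feature value",
            feature_name, n_dropped, len(scaled_positions),
        )
    if not kept_ids:
        raise NoSpots(f"no spot has a defined value for {feature_name!r}")

    by_bin: dict[int, list[str]] = {}
    for s in kept_ids:
        by_bin.setdefault(bins[s], []).append(s)
    idx = np.array(sorted(by_bin), dtype=int)
    x = np.array([np.mean([scaled_positions[s] for s in by_bin[i]]) for i in idx])
    y = np.array([np.mean([feature[s] for s in by_bin[i]]) for i in idx])
    occ = np.array([len(by_bin[i]) for i in idx], dtype=int)
    return BinnedProfile(
        n_bins=n_bins, bin_index=idx, x=x, y=y, occupancy=occ,
        feature_name=feature_name, n_dropped=n_dropped,
    )


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> np.ndarray:
    """Locally weighted polynomial regression with tri-cube weights.

    At each evaluation point the ``ceil(span * n)`` nearest data points
    (at least ``degree + 1``) form the local window; weights are
    ``(1 - (d/dmax)^3)^3`` with ``dmax`` the largest distance in the
    window, and a weighted degree-``degree`` polynomial is fitted and
    evaluated at the point. This is the direct-surface, non-robust loess
    of the classical local-regression literature.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < degree + 1:
        raise TooFewBins(
            f"loess degree {degree} needs >= {degree + 1} points, got {n}"
        )
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    fitted = np.empty(len(eval_x))
    for j, x0 in enumerate(np.asarray(eval_x, float)):
        d = np.abs(x - x0)
        window = np.argsort(d, kind="stable")[:k]
        dmax = d[window].max()
        if dmax == 0.0:
            fitted[j] = y[window].mean()
            continue
        w = (1.0 - (d[window] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        if w.sum() == 0.0:  # all window points at dmax
            w = np.ones_like(w)
        # centred design for conditioning
        xc = x[window] - x0
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[window] * sw, rcond=None)
        fitted[j] = coef[0]
    return fitted


def smooth_profile(
    profile: BinnedProfile,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    n_grid: int = 100,
) -> SmoothedProfile:
    """Loess-smooth a binned profile over an even grid on [min x, max x]."""
    if len(profile.x) < degree + 1:
        raise TooFewBins(
            f"{len(profile.x)} non-empty bins cannot support degree {degree}"
        )
    grid = np.linspace(profile.x.min(), profile.x.max(), n_grid)
    fitted = loess_fit(profile.x, profile.y, grid, span=span, degree=degree)
    return SmoothedProfile(grid=grid, fitted=fitted, span=span, degree=degree)


def normalize_counts(matrix: FeatureMatrix) -> FeatureMatrix:
    """Median-library-size normalization followed by log1p.

    Each spot's counts are scaled so its library size equals the median
    library size of the sample, then log1p-transformed. Returns a matrix
    of kind ``normalized``; pre-normalized input is passed through.
    """
    if matrix.kind == "normalized":
        return matrix
    libs = matrix.row_sums()
    if np.any(libs == 0):
        raise NoSpots("cannot normalize: some observations have zero counts")
    target = float(np.median(libs))
    dense = matrix.dense()
    scaled = dense * (target / libs)[:, None]
    return FeatureMatrix(
        obs_ids=matrix.obs_ids,
        var_ids=matrix.var_ids,
        values=np.log1p(scaled),
        kind="normalized",
        gene_annotations=matrix.gene_annotations,
    )


def score_module(
    matrix: FeatureMatrix,
    gene_set: list[str],
    module_name: str = "module",
) -> dict[str, float]:
    """Per-observation gene-module score: mean normalized expression.

    Duplicate gene names in the set count once. Genes absent from the
    matrix are dropped with a warning listing them; an entirely absent
    module raises :class:`EmptyModule`.
    """
    wanted = list(dict.fromkeys(gene_set))  # de-duplicate, keep order
    present = [g for g in wanted if g in set(matrix.var_ids)]
    missing = [g for g in wanted if g not in set(matrix.var_ids)]
    if not present:
        raise EmptyModule(
            f"no gene of module {module_name!r} is present in the matrix "
            f"(looked for {wanted[:10]}...)"
        )
    if missing:
        warnings.warn(
            f"module {module_name!r}: {len(missing)} gene(s) absent from the "
            f"matrix and ignored: {missing}",
            stacklevel=2,
        )
    cols = np.stack([matrix.column(g) for g in present], axis=1)
    scores = cols.mean(axis=1)
    return {str(s): float(v) for s, v in zip(matrix.obs_ids, scores)}
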