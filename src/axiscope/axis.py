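"""Dorsal-ventral axis estimation and 1D projection of spot coordinates.

The dorsal-ventral (DV) axis of a spinal-cord cross-section is estimated
from manual region annotations: for a random subsample of dorsal spots,
each spot's *DV-difference vector* points to its nearest ventral subsample
spot; the unit-normalized average of these vectors is the axis direction
``a``. Every spot ``s`` with coordinates ``u_s`` is then assigned the
scalar orthogonal-projection coefficient ``u_s . a``, and the coefficients
are min-max scaled over the whole sample so that 0 marks the dorsal-most
and 1 the ventral-most extreme. The scaled position is the 1D coordinate
used by the profiling module.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConstantProjection, DegenerateAxis, EmptyRegion
from .random import substream
from .types import SpotMap

DEFAULT_CAP_DORSAL = 200
DEFAULT_CAP_VENTRAL = 100


@dataclass
class AxisEstimate:
    """The estimated DV axis and the per-spot axis positions.

    ``raw_projection`` holds the scalar projection coefficient ``u_s . a``
    (with ``|a| = 1`` this carries the same information as the projected
    2-vector); ``scaled_projection`` is its min-max rescaling to [0, 1]
    over all spots of the sample, annotated or not.
    """

    axis: np.ndarray                       # unit 2-vector, dorsal -> ventral
    dv_vectors: np.ndarray                 # (|D'|, 2) difference vectors
    mean_dv: np.ndarray                    # average difference vector
    subsample_d: list[str]
    subsample_v: list[str]
    raw_projection: dict[str, float] = field(default_factory=dict)
    scaled_projection: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    flipped: bool = False

    def positions(self, spot_ids) -> np.ndarray:
        """Scaled axis positions for the given ids, in order."""
        return np.array([self.scaled_projection[s] for s in spot_ids])


def subsample_regions(
    spotmap: SpotMap,
    cap_d: int = DEFAULT_CAP_DORSAL,
    cap_v: int = DEFAULT_CAP_VENTRAL,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Draw the dorsal and ventral subsamples D' and V'.

    Uniform sampling without replacement of sizes ``min(|D|, cap_d)`` and
    ``min(|V|, cap_v)``; deterministic given the seed. Raises
    :class:`EmptyRegion` if either annotation set is empty, since the axis
    is undefined without both poles.
    """
    if cap_d < 1 or cap_v < 1:
        raise ValueError("caps must be positive")
    dorsal = spotmap.dorsal_ids
    ventral = spotmap.ventral_ids
    if len(dorsal) == 0 or len(ventral) == 0:
        raise EmptyRegion(
            f"need >=1 dorsal and >=1 ventral spot; "
            f"got |D|={len(dorsal)}, |V|={len(ventral)}"
        )
    rng = substream(seed, "axis-subsample")
    sub_d = rng.choice(dorsal, size=min(len(dorsal), cap_d), replace=False)
    sub_v = rng.choice(ventral, size=min(len(ventral), cap_v), replace=False)
    return [str(s) for s in sub_d], [str(s) for s in sub_v]


def compute_axis_vector(
    spotmap: SpotMap,
    subsample_d: list[str],
    subsample_v: list[str],
) -> AxisEstimate:
    """Estimate the axis direction from the region subsamples.

    For each dorsal subsample spot ``d_s``, the nearest ventral subsample
    spot ``v_k`` (Euclidean distance; ties broken by lexicographically
    smallest spot_id) defines a difference vector ``delta_s = v_k - d_s``.
    The axis is the unit-normalized mean of the ``delta_s`` and therefore
    points from dorsal toward ventral.
    """
    if len(subsample_d) == 0 or len(subsample_v) == 0:
        raise EmptyRegion("both subsamples must be non-empty")
    d_xy = spotmap.coords_of(subsample_d)
    # sort ventral candidates by id so that among equidistant neighbours the
    # smallest spot_id wins deterministically
    v_order = sorted(range(len(subsample_v)), key=lambda i: subsample_v[i])
    v_ids = [subsample_v[i] for i in v_order]
    v_xy = spotmap.coords_of(v_ids)

    # all-pairs distances: subsamples are capped (200 x 100 by default), so a
    # full scan is cheap. Distances within a relative 1e-9 of the minimum are
    # treated as tied and the smallest spot_id wins (candidates are id-sorted,
    # argmax returns the first tied column); the tolerance keeps the tie-break
    # stable under rigid transforms of the coordinates, where exact ties (e.g.
    # on a lattice) pick up machine-precision noise
    d2 = cdist(d_xy, v_xy, metric="sqeuclidean")
    d2min = d2.min(axis=1, keepdims=True)
    tied = d2 <= d2min * (1.0 + 1e-9) + 1e-30
    nearest = np.argmax(tied, axis=1)
    deltas = v_xy[nearest] - d_xy
    mean_dv = deltas.mean(axis=0)
    norm = float(np.linalg.norm(mean_dv))
    if norm == 0.0:
        raise DegenerateAxis(
            "difference vectors cancel (|mean delta| = 0); "
            f"|D'|={len(subsample_d)}, |V'|={len(subsample_v)}, "
            f"mean dorsal coord={d_xy.mean(axis=0)}, "
            f"mean ventral coord={v_xy.mean(axis=0)}"
        )
    return AxisEstimate(
        axis=mean_dv / norm,
        dv_vectors=deltas,
        mean_dv=mean_dv,
        subsample_d=list(subsample_d),
        subsample_v=list(subsample_v),
    )


def project_and_scale(spotmap: SpotMap, est: AxisEstimate) -> AxisEstimate:
    """Populate raw and min-max-scaled axis positions for every spot.

    Scaling uses all spots of the sample, not only the annotated ones, so
    the scaled position attains exactly 0 (dorsal-most extreme) and exactly
    1 (ventral-most extreme). Raises :class:`ConstantProjection` when all
    spots project to one point.
    """
    if abs(np.linalg.norm(est.axis) - 1.0) > 1e-9:
        raise ValueError("axis must have unit norm")
    raw = spotmap.coords @ est.axis
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise ConstantProjection(
            f"all {len(spotmap)} spots project to {lo}; axis={est.axis}"
        )
    scaled = (raw - lo) / (hi - lo)
    est.raw_projection = {str(s): float(r) for s, r in zip(spotmap.spot_ids, raw)}
    est.scaled_projection = {str(s): float(p) for s, p in zip(spotmap.spot_ids, scaled)}
    return est


def estimate_axis(
    spotmap: SpotMap,
    cap_d: int = DEFAULT_CAP_DORSAL,
    cap_v: int = DEFAULT_CAP_VENTRAL,
    seed: int = 0,
    flip: bool = False,
) -> AxisEstimate:
    """Full axis pipeline: subsample, estimate direction, project, scale.

    ``flip=True`` reverses the reported orientation (position p becomes
    1 - p and the stored axis vector is negated) for callers who prefer
    0 = ventral.
    """
    sub_d, sub_v = subsample_regions(spotmap, cap_d=cap_d, cap_v=cap_v, seed=seed)
    est = compute_axis_vector(spotmap, sub_d, sub_v)
    est.seed = seed
    est = project_and_scale(spotmap, est)
    if flip:
        est.axis = -est.axis
        est.raw_projection = {s: -r for s, r in est.raw_projection.items()}
        est.scaled_projection = {s: 1.0 - p for s, p in est.scaled_projection.items()}
        est.flipped = True
    return est
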