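"""Shared data containers: the spot table and the observation x gene matrix.

A :class:`SpotMap` is the geometric substrate of the analysis — spot
identifiers, 2D coordinates and the manual dorsal/ventral annotation that
defines the axis. A :class:`FeatureMatrix` is any observations x features
numeric matrix (raw counts, normalized expression, or deconvolution
proportions) aligned to a SpotMap by identifier.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import DuplicateSpotId, NegativeCount, NonNumericCoordinate

REGIONS = ("dorsal", "ventral", "unassigned")
MATRIX_KINDS = ("counts", "normalized", "proportions")

#: tolerance on row sums for kind="proportions"
PROPORTION_TOL = 1e-6


@dataclass
class SpotMap:
    """Spot identifiers, 2D Cartesian coordinates and region annotations.

    Coordinates are taken as-is (arbitrary length units, mathematical y-up
    convention); the axis method is invariant to the choice as long as the
    annotations are consistent with it.
    """

    spot_ids: np.ndarray          # unique strings, shape (n,)
    coords: np.ndarray            # float, shape (n, 2)
    region: np.ndarray            # strings in REGIONS, shape (n,)
    sample_id: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        n = len(self.spot_ids)
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be (n, 2); got {self.coords.shape} for n={n}")
        if len(self.region) != n:
            raise ValueError("region length does not match spot_ids")
        uniq, counts = np.unique(self.spot_ids.astype(str), return_counts=True)
        if len(uniq) != n:
            dups = uniq[counts > 1][:5].tolist()
            raise DuplicateSpotId(f"duplicate spot_id values: {dups}")
        if not np.all(np.isfinite(self.coords)):
            bad = np.where(~np.isfinite(self.coords).all(axis=1))[0]
            raise NonNumericCoordinate(
                f"non-finite coordinates at rows {bad[:5].tolist()}"
            )
        unknown = set(np.unique(self.region)) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
        if self.sample_id is None:
            self.sample_id = np.asarray(["sample_0"] * n, dtype=object)
        else:
            self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=object)

    def __len__(self) -> int:
        return len(self.spot_ids)

    @property
    def dorsal_ids(self) -> np.ndarray:
        return self.spot_ids[self.region == "dorsal"]

    @property
    def ventral_ids(self) -> np.ndarray:
        return self.spot_ids[self.region == "ventral"]

    def coords_of(self, ids) -> np.ndarray:
        """Coordinates of the given spot ids, in the given order."""
        index = {s: i for i, s in enumerate(self.spot_ids)}
        rows = [index[s] for s in ids]
        return self.coords[rows]

    def subset(self, mask) -> "SpotMap":
        return SpotMap(
            spot_ids=self.spot_ids[mask],
            coords=self.coords[mask],
            region=self.region[mask],
            sample_id=self.sample_id[mask],
            age=None if self.age is None else self.age[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "spot_id": self.spot_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "region": self.region,
                "sample_id": self.sample_id,
            }
        )
        if self.age is not None:
            df["age"] = self.age
        return df


@dataclass
class FeatureMatrix:
    """Observations x features matrix with identifiers attached.

    ``values`` may be a dense ndarray or any scipy sparse matrix; rows are
    observations (cells or spots), columns are features (genes or cell
    types). ``kind`` declares the scale of the values and is preserved by
    subsetting.
    """

    obs_ids: np.ndarray
    var_ids: np.ndarray
    values: "np.ndarray | sparse.spmatrix"
    kind: str = "counts"
    gene_annotations: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.obs_ids = np.asarray(self.obs_ids, dtype=object)
        self.var_ids = np.asarray(self.var_ids, dtype=object)
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"kind must be one of {MATRIX_KINDS}")
        if not sparse.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.obs_ids), len(self.var_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.obs_ids)} obs x {len(self.var_ids)} vars"
            )
        if self.min() < 0:
            if self.kind == "counts":
                raise NegativeCount("count matrix contains negative entries")
            raise ValueError("matrix contains negative entries")
        if self.kind == "proportions":
            rs = self.row_sums()
            if np.any(np.abs(rs - 1.0) > PROPORTION_TOL):
                bad = int(np.argmax(np.abs(rs - 1.0)))
                raise ValueError(
                    f"proportion rows must sum to 1 +/- {PROPORTION_TOL}; "
                    f"row {bad} sums to {rs[bad]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def min(self) -> float:
        if sparse.issparse(self.values):
            if self.values.nnz == 0:
                return 0.0
            return float(min(self.values.data.min(), 0.0))
        return float(self.values.min()) if self.values.size else 0.0

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def detected_per_obs(self) -> np.ndarray:
        """Number of features with a strictly positive value, per row."""
        if sparse.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=1)).ravel()
        return (self.values > 0).sum(axis=1)

    def detected_per_var(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray((self.values > 0).sum(axis=0)).ravel()
        return (self.values > 0).sum(axis=0)

    def column(self, var_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.var_ids == var_id)
        if len(idx) == 0:
            raise KeyError(var_id)
        col = self.values[:, idx[0]]
        if sparse.issparse(col):
            return np.asarray(col.todense()).ravel()
        return np.asarray(col).ravel()

    def subset(self, obs_mask=None, var_mask=None) -> "FeatureMatrix":
        obs_mask = np.ones(len(self.obs_ids), bool) if obs_mask is None else obs_mask
        var_mask = np.ones(len(self.var_ids), bool) if var_mask is None else var_mask
        vals = self.values
        if sparse.issparse(vals):
            vals = vals.tocsr()[obs_mask][:, var_mask]
        else:
            vals = vals[np.ix_(np.flatnonzero(obs_mask), np.flatnonzero(var_mask))]
        ann = self.gene_annotations
        if ann is not None:
            kept = set(self.var_ids[var_mask])
            ann = {g: b for g, b in ann.items() if g in kept}
        return replace(
            self,
            obs_ids=self.obs_ids[obs_mask],
            var_ids=self.var_ids[var_mask],
            values=vals,
            gene_annotations=ann,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.obs_ids, columns=self.var_ids)
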