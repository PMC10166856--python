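"""Readers and writers for the interchange formats.

Plain-text formats only: delimited spot tables and proportion tables,
MatrixMarket sparse matrices with gene/barcode name files, dense delimited
matrices, plain-text gene sets (one symbol per line) and JSON sidecars for
axis estimates, QC reports and co-localization graphs.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .axis import AxisEstimate
from .coloc import ColocGraph
from .errors import DimensionMismatch, MissingColumn, NonNumericCoordinate
from .profiling import BinnedProfile, SmoothedProfile
from .types import REGIONS, FeatureMatrix, SpotMap

logger = logging.getLogger(__name__)

_REQUIRED_SPOT_COLUMNS = ("spot_id", "x", "y", "region")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_spot_table(path: str | Path) -> SpotMap:
    """Parse a delimited spot table into a :class:`SpotMap`.

    Requires header columns spot_id, x, y, region (sample_id and age are
    optional). Region strings are normalized case-insensitively; values
    other than dorsal/ventral map to unassigned with a warning count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"spot_id": str})
    missing = [c for c in _REQUIRED_SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumn(f"{path}: missing required column(s) {missing}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((coerced.isna()).idxmax())
            raise NonNumericCoordinate(
                f"{path}: non-numeric {col!r} at data row {row} "
                f"(value {df[col].iloc[row]!r})"
            )
        df[col] = coerced
    region = df["region"].astype(str).str.strip().str.lower()
    known = region.isin(REGIONS)
    n_unknown = int((~known).sum())
    if n_unknown:
        warnings.warn(
            f"{path}: {n_unknown} region value(s) not dorsal/ventral/unassigned; "
            "mapped to unassigned",
            stacklevel=2,
        )
        region = region.where(known, "unassigned")
    return SpotMap(
        spot_ids=df["spot_id"].to_numpy(dtype=object),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        region=region.to_numpy(dtype=object),
        sample_id=(
            df["sample_id"].astype(str).to_numpy(dtype=object)
            if "sample_id" in df.columns else None
        ),
        age=(
            df["age"].astype(str).to_numpy(dtype=object)
            if "age" in df.columns else None
        ),
    )


def write_spot_table(spotmap: SpotMap, path: str | Path) -> None:
    path = Path(path)
    spotmap.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_matrix(
    path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    kind: str = "counts",
    orientation: str = "auto",
) -> FeatureMatrix:
    """Read a MatrixMarket triplet or a dense delimited matrix.

    For ``.mtx`` input, ``genes_path``/``barcodes_path`` default to
    ``genes.tsv`` / ``barcodes.tsv`` next to the matrix. Orientation
    (obs x genes vs genes x obs) is auto-detected from the name-file
    lengths; pass ``orientation='obs_by_var'`` or ``'var_by_obs'`` to
    override. Dense input is obs x genes with the header row carrying
    gene names and the first column observation ids.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = sio.mmread(path).tocsr()
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        genes = [l.split("\t")[0] for l in _read_lines(genes_path)]
        barcodes = [l.split("\t")[0] for l in _read_lines(barcodes_path)]
        n_rows, n_cols = mat.shape
        if orientation == "obs_by_var":
            pass
        elif orientation == "var_by_obs":
            mat = mat.T.tocsr()
        else:  # auto: rows must match barcodes or genes unambiguously
            if n_rows == len(barcodes) and n_cols == len(genes):
                pass
            elif n_rows == len(genes) and n_cols == len(barcodes):
                mat = mat.T.tocsr()
            else:
                raise DimensionMismatch(
                    f"{path}: matrix is {n_rows}x{n_cols} but name files have "
                    f"{len(barcodes)} barcodes and {len(genes)} genes"
                )
        if mat.shape != (len(barcodes), len(genes)):
            raise DimensionMismatch(
                f"{path}: resolved orientation {mat.shape} does not match "
                f"{len(barcodes)} barcodes x {len(genes)} genes"
            )
        return FeatureMatrix(
            obs_ids=np.array(barcodes, dtype=object),
            var_ids=np.array(genes, dtype=object),
            values=mat,
            kind=kind,
        )
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return FeatureMatrix(
        obs_ids=df.index.astype(str).to_numpy(dtype=object),
        var_ids=df.columns.astype(str).to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        kind=kind,
    )


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write MatrixMarket (with genes.tsv/barcodes.tsv) or dense CSV/TSV."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        vals = matrix.values
        if not sparse.issparse(vals):
            vals = sparse.coo_matrix(vals)
        sio.mmwrite(str(path), vals)
        (path.parent / "genes.tsv").write_text(
            "\n".join(str(g) for g in matrix.var_ids) + "\n"
        )
        (path.parent / "barcodes.tsv").write_text(
            "\n".join(str(b) for b in matrix.obs_ids) + "\n"
        )
    else:
        matrix.to_frame().to_csv(path, sep=_sep_for(path), index_label="obs_id")


def _read_lines(path: Path) -> list[str]:
    return [l for l in path.read_text().splitlines() if l.strip()]


def read_gene_set(path: str | Path) -> list[str]:
    """Plain-text gene set: one symbol per line, '#' comments allowed."""
    return [
        l.strip() for l in _read_lines(Path(path)) if not l.lstrip().startswith("#")
    ]


def read_gene_annotations(path: str | Path) -> dict[str, str]:
    """Two-column delimited text: gene_id, biotype."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#")
    if df.shape[1] < 2:
        raise MissingColumn(f"{path}: expected two columns (gene_id, biotype)")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def write_axis_estimate(est: AxisEstimate, prefix: str | Path) -> None:
    """Per-spot projections as CSV plus a JSON sidecar with the axis."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "spot_id": list(est.raw_projection),
            "raw_projection": list(est.raw_projection.values()),
            "scaled_projection": [
                est.scaled_projection[s] for s in est.raw_projection
            ],
        }
    ).to_csv(f"{prefix}.projections.csv", index=False)
    sidecar = {
        "axis": [float(v) for v in est.axis],
        "mean_dv": [float(v) for v in est.mean_dv],
        "n_subsample_d": len(est.subsample_d),
        "n_subsample_v": len(est.subsample_v),
        "subsample_d": est.subsample_d,
        "subsample_v": est.subsample_v,
        "seed": est.seed,
        "flipped": est.flipped,
    }
    Path(f"{prefix}.axis.json").write_text(json.dumps(sidecar, indent=2))


def read_axis_positions(path: str | Path) -> dict[str, float]:
    """Scaled positions from a `.projections.csv` written by this package."""
    df = pd.read_csv(path, dtype={"spot_id": str})
    for col in ("spot_id", "scaled_projection"):
        if col not in df.columns:
            raise MissingColumn(f"{path}: missing column {col!r}")
    return dict(zip(df["spot_id"], df["scaled_projection"].astype(float)))


def write_profile(
    profile: BinnedProfile,
    smoothed: SmoothedProfile | None,
    prefix: str | Path,
) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "bin": profile.bin_index,
            "x": profile.x,
            "y": profile.y,
            "n": profile.occupancy,
        }
    ).to_csv(f"{prefix}.profile.csv", index=False)
    if smoothed is not None:
        df = pd.DataFrame({"grid": smoothed.grid, "fitted": smoothed.fitted})
        if smoothed.se is not None:
            df["se"] = smoothed.se
        df.to_csv(f"{prefix}.smoothed.csv", index=False)


def write_coloc_graph(graph: ColocGraph, prefix: str | Path) -> None:
    """JSON graph plus a circos-style edge list (a, b, r, major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.coloc.json").write_text(json.dumps(graph.to_dict(), indent=2))
    pd.DataFrame(
        [
            {"a": e.pair[0], "b": e.pair[1], "r": e.r, "major": e.major}
            for e in graph.edges
        ]
    ).to_csv(f"{prefix}.edges.csv", index=False)


def write_truth(truth, out_dir: str | Path) -> None:
    """Spot table, truth file and parameter manifest for one section."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spot_table(truth.spotmap, out / "spots.csv")
    pd.DataFrame(
        {
            "spot_id": list(truth.true_dv),
            "true_dv": list(truth.true_dv.values()),
        }
    ).to_csv(out / "truth.csv", index=False)
    manifest = {
        "seed": truth.seed,
        "params": truth.params,
        "genes": [
            {
                "name": s.name, "baseline": s.baseline, "effect": s.effect,
                "dispersion": s.dispersion, "center": s.center,
                "width": s.width, "steepness": s.steepness,
                "age_multipliers": s.age_multipliers,
            }
            for s in truth.gene_specs
        ],
        "archetypes": [
            {
                "name": a.name, "kernel": a.kernel, "center": a.center,
                "width": a.width, "weight": a.weight,
            }
            for a in truth.archetypes
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
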