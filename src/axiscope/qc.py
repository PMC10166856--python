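"""Quality-control filters for single-cell and spatial count matrices.

The single-cell filter keeps protein-coding and lincRNA genes, removes
cells with fewer than 500 detected genes or more than 25% mitochondrial
counts, then removes genes detected in fewer than 15 surviving cells. The
spatial filter removes blacklisted gene families (hemoglobin, MALAT1,
mitochondrial, ribosomal protein genes), spots with fewer than 500
detected genes, and genes detected in fewer than 5 surviving spots.

Thresholds are strict as stated: "fewer than 500" means < 500, so a
boundary observation with exactly 500 detected genes survives; "over 25%"
means > 25%, so exactly 25% mitochondrial survives. Rule order is
gene-identity filters first, then observations, then gene-support — the
support counts depend on which observations survive. The mitochondrial
fraction is computed on the counts as loaded, before any biotype
enrichment, so dropping MT genes from the gene universe does not change
which cells the fraction removes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyResult, MissingAnnotations
from .types import FeatureMatrix

DEFAULT_BIOTYPES = ("protein_coding", "lincRNA")
DEFAULT_MITO_PREFIX = "MT-"

#: gene-symbol patterns removed from spatial matrices, by reason code
DEFAULT_BLACKLIST = {
    "hemoglobin": r"^HB[ABDEGMQZ]\d*$",
    "malat1": r"^MALAT1$",
    "mitochondrial": r"^MT-",
    "ribosomal": r"^RP[SL]",
}


@dataclass
class QCReport:
    """Bookkeeping of a QC pass: what was removed, and why."""

    n_obs_in: int
    n_genes_in: int
    n_obs_out: int = 0
    n_genes_out: int = 0
    removed_obs: dict[str, str] = field(default_factory=dict)    # id -> reason
    removed_genes: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_obs_in": self.n_obs_in,
            "n_genes_in": self.n_genes_in,
            "n_obs_out": self.n_obs_out,
            "n_genes_out": self.n_genes_out,
            "removed_obs": self.removed_obs,
            "removed_genes": self.removed_genes,
            "thresholds": self.thresholds,
        }


def _finalize(matrix, obs_mask, gene_mask, report) -> tuple[FeatureMatrix, QCReport]:
    if not obs_mask.any() or not gene_mask.any():
        raise EmptyResult(
            f"QC removed everything: {int(obs_mask.sum())} obs and "
            f"{int(gene_mask.sum())} genes survive"
        )
    out = matrix.subset(obs_mask, gene_mask)
    report.n_obs_out = int(obs_mask.sum())
    report.n_genes_out = int(gene_mask.sum())
    return out, report


def qc_single_cell(
    matrix: FeatureMatrix,
    min_genes: int = 500,
    min_cells: int = 15,
    max_mito_pct: float = 25.0,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    biotypes: tuple[str, ...] | None = DEFAULT_BIOTYPES,
) -> tuple[FeatureMatrix, QCReport]:
    """Filter a cells x genes count matrix.

    ``biotypes=None`` skips the biotype enrichment (useful when no
    annotation is available); otherwise ``matrix.gene_annotations`` must
    map every gene to a biotype string.
    """
    if matrix.kind != "counts":
        raise ValueError("single-cell QC operates on raw counts")
    report = QCReport(
        n_obs_in=len(matrix.obs_ids),
        n_genes_in=len(matrix.var_ids),
        thresholds={
            "min_genes": min_genes,
            "min_cells": min_cells,
            "max_mito_pct": max_mito_pct,
            "mito_prefix": mito_prefix,
            "biotypes": list(biotypes) if biotypes else None,
        },
    )
    genes = matrix.var_ids.astype(str)
    gene_mask = np.ones(len(genes), bool)

    # mitochondrial fraction on the pre-enrichment counts
    mito_cols = np.array([g.startswith(mito_prefix) for g in genes])
    totals = matrix.row_sums()
    mito_counts = (
        matrix.subset(var_mask=mito_cols).row_sums()
        if mito_cols.any() else np.zeros(len(totals))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)

    # rule 1: biotype enrichment
    if biotypes is not None:
        if matrix.gene_annotations is None:
            raise MissingAnnotations(
                "biotype enrichment requested but gene_annotations is None"
            )
        allowed = set(biotypes)
        keep = np.array(
            [matrix.gene_annotations.get(g) in allowed for g in genes]
        )
        for g in genes[~keep]:
            report.removed_genes[g] = "biotype"
        gene_mask &= keep

    # rule 2: cells with fewer than min_genes detected genes (within the
    # enriched gene universe)
    detected = matrix.subset(var_mask=gene_mask).detected_per_obs()
    obs_mask = detected >= min_genes
    for c in matrix.obs_ids[~obs_mask]:
        report.removed_obs[str(c)] = "min_genes"

    # rule 3: cells with over max_mito_pct mitochondrial counts
    mito_fail = obs_mask & (mito_pct > max_mito_pct)
    for c in matrix.obs_ids[mito_fail]:
        report.removed_obs[str(c)] = "max_mito_pct"
    obs_mask &= ~mito_fail

    # rule 4: genes detected in fewer than min_cells surviving cells
    support = matrix.subset(obs_mask=obs_mask).detected_per_var()
    weak = gene_mask & (support < min_cells)
    for g in genes[weak]:
        report.removed_genes[g] = "min_cells"
    gene_mask &= ~weak

    return _finalize(matrix, obs_mask, gene_mask, report)


def qc_spatial(
    matrix: FeatureMatrix,
    min_genes_per_spot: int = 500,
    min_spots: int = 5,
    blacklist: dict[str, str] | None = None,
) -> tuple[FeatureMatrix, QCReport]:
    """Filter a spots x genes count matrix.

    ``blacklist`` maps a reason code to a gene-symbol regular expression;
    the default covers hemoglobin genes, MALAT1, mitochondrial genes and
    ribosomal protein genes, the families the source protocol removes
    from tissue sections.
    """
    if matrix.kind != "counts":
        raise ValueError("spatial QC operates on raw counts")
    if blacklist is None:
        blacklist = DEFAULT_BLACKLIST
    report = QCReport(
        n_obs_in=len(matrix.obs_ids),
        n_genes_in=len(matrix.var_ids),
        thresholds={
            "min_genes_per_spot": min_genes_per_spot,
            "min_spots": min_spots,
            "blacklist": dict(blacklist),
        },
    )
    genes = matrix.var_ids.astype(str)
    gene_mask = np.ones(len(genes), bool)

    # rule 1: blacklist by symbol pattern (first matching rule is the reason)
    compiled = [(reason, re.compile(pat)) for reason, pat in blacklist.items()]
    for i, g in enumerate(genes):
        for reason, rx in compiled:
            if rx.search(g):
                report.removed_genes[g] = reason
                gene_mask[i] = False
                break

    # rule 2: spots with fewer than min_genes_per_spot detected genes
    detected = matrix.subset(var_mask=gene_mask).detected_per_obs()
    obs_mask = detected >= min_genes_per_spot
    for s in matrix.obs_ids[~obs_mask]:
        report.removed_obs[str(s)] = "min_genes_per_spot"

    # rule 3: genes detected in fewer than min_spots surviving spots
    support = matrix.subset(obs_mask=obs_mask).detected_per_var()
    weak = gene_mask & (support < min_spots)
    for g in genes[weak]:
        report.removed_genes[g] = "min_spots"
    gene_mask &= ~weak

    return _finalize(matrix, obs_mask, gene_mask, report)
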