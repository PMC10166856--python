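"""End-to-end pipeline: simulate -> qc -> axis -> profiles -> coloc.

Each stage writes format-valid artifacts plus the resolved configuration
and a log into the output directory, so a run is fully reproducible from
its own outputs.
"""
from __future__ import annotations

import logging
from pathlib import Path

from . import io as aio
from .axis import estimate_axis
from .coloc import colocalization_graph
from .config import resolve_config, write_resolved
from .profiling import bin_profile, normalize_counts, smooth_profile
from .qc import qc_spatial
from .simulate import make_section, simulate_expression, simulate_proportions

logger = logging.getLogger(__name__)


def run_pipeline(
    config_path=None,
    overrides: dict | None = None,
) -> dict:
    """Run the full synthetic pipeline under one resolved config.

    Returns a dict of the in-memory artifacts (truth, matrices, axis
    estimate, profiles, coloc graph); everything is also written under
    ``run.out``.
    """
    cfg = resolve_config(config_path, overrides)
    out = Path(cfg["run"]["out"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg["run"]["log_level"])
    write_resolved(cfg, out)
    seed = int(cfg["run"]["seed"])

    sim = cfg["simulate"]
    truth = make_section(
        n_spots=int(sim["n_spots"]),
        ellipse_a=float(sim["ellipse_a"]),
        ellipse_b=float(sim["ellipse_b"]),
        dorsal_frac=float(sim["dorsal_frac"]),
        ventral_frac=float(sim["ventral_frac"]),
        rotation_deg=float(sim["rotation_deg"]),
        seed=seed,
        age=sim["age"],
    )
    counts = simulate_expression(
        truth,
        library_size_mean=float(sim["library_size_mean"]),
        library_size_cv=float(sim["library_size_cv"]),
        seed=seed,
    )
    proportions = simulate_proportions(
        truth, noise_conc=float(sim["noise_conc"]), seed=seed
    )
    aio.write_truth(truth, out)
    aio.write_matrix(counts, out / "counts.csv")
    aio.write_matrix(proportions, out / "proportions.csv")
    logger.info("simulate: %d spots, %d genes, %d cell types",
                len(truth.spotmap), len(counts.var_ids), len(proportions.var_ids))

    # spatial QC on the synthetic panel: the bundled panel has few genes, so
    # the spot threshold is scaled to the panel size (threshold 500 applies
    # to transcriptome-wide matrices)
    qc_cfg = cfg["qc"]
    min_genes = min(int(qc_cfg["min_genes"]), max(1, len(counts.var_ids) // 2))
    filtered, report = qc_spatial(
        counts,
        min_genes_per_spot=min_genes,
        min_spots=int(qc_cfg["min_support"] or 5),
    )
    import json as _json
    (out / "qc_report.json").write_text(_json.dumps(report.to_dict(), indent=2))
    logger.info("qc: spots %d -> %d, genes %d -> %d",
                report.n_obs_in, report.n_obs_out,
                report.n_genes_in, report.n_genes_out)

    est = estimate_axis(
        truth.spotmap,
        cap_d=int(cfg["axis"]["cap_d"]),
        cap_v=int(cfg["axis"]["cap_v"]),
        seed=seed,
        flip=bool(cfg["axis"]["flip"]),
    )
    aio.write_axis_estimate(est, out / "axis")
    logger.info("axis: a=%s from %d dorsal / %d ventral subsample spots",
                est.axis, len(est.subsample_d), len(est.subsample_v))

    normalized = normalize_counts(filtered)
    prof_cfg = cfg["profile"]
    features = list(prof_cfg["features"]) or [str(g) for g in normalized.var_ids[:4]]
    positions = {
        str(s): est.scaled_projection[str(s)] for s in normalized.obs_ids
    }
    profiles = {}
    for gene in features:
        feature = dict(zip((str(s) for s in normalized.obs_ids),
                           normalized.column(gene)))
        prof = bin_profile(
            positions, feature, n_bins=int(prof_cfg["n_bins"]), feature_name=gene
        )
        smooth = smooth_profile(
            prof,
            span=float(prof_cfg["span"]),
            degree=int(prof_cfg["degree"]),
            n_grid=int(prof_cfg["n_grid"]),
        )
        aio.write_profile(prof, smooth, out / f"profile_{gene}")
        profiles[gene] = (prof, smooth)
    logger.info("profile: %d features, %d bins occupied (first feature)",
                len(profiles), len(next(iter(profiles.values()))[0].x))

    coloc_cfg = cfg["coloc"]
    graph = colocalization_graph(
        proportions,
        method=str(coloc_cfg["method"]),
        major_rule=str(coloc_cfg["major_rule"]),
        r_min=float(coloc_cfg["r_min"]),
        top_k=int(coloc_cfg["top_k"]),
        min_variance=float(coloc_cfg["min_variance"]),
    )
    aio.write_coloc_graph(graph, out / "coloc")
    logger.info("coloc: %d edges, %d flagged major",
                len(graph.edges), len(graph.major_edges()))

    return {
        "config": cfg,
        "truth": truth,
        "counts": counts,
        "qc": (filtered, report),
        "axis": est,
        "profiles": profiles,
        "proportions": proportions,
        "coloc": graph,
    }
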