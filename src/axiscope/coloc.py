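"""Cell-type co-localization from spot-level deconvolution proportions.

Deconvolution (e.g. stereoscope) assigns every spot a composition vector
over cell types. Two cell types co-localize when their proportions rise
and fall together across spots; the statistic here is the Pearson (or
Spearman) correlation of the two proportion vectors. The result is a
graph: nodes are cell types weighted by mean proportion, edges carry the
correlation, and an edge is flagged a *major connection* either by a
threshold on r or by membership in the top-k edges.

Because each row sums to 1, correlations are constrained: with exactly
two variable types the closure forces r = -1. Types with (numerically)
constant proportion have no defined correlation and are excluded from
edges but reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DegenerateInput
from .types import FeatureMatrix

DEFAULT_R_MIN = 0.3
DEFAULT_TOP_K = 10
DEFAULT_MIN_VARIANCE = 1e-12


@dataclass
class ColocEdge:
    pair: tuple[str, str]   # lexicographically ordered
    r: float
    major: bool


@dataclass
class ColocGraph:
    nodes: dict[str, float]                 # cell type -> mean proportion
    edges: list[ColocEdge]
    n_spots: int
    method: str
    major_rule: str
    r_min: float | None = None
    top_k: int | None = None
    excluded: list[str] = field(default_factory=list)   # constant types

    def edge(self, a: str, b: str) -> ColocEdge:
        key = tuple(sorted((a, b)))
        for e in self.edges:
            if e.pair == key:
                return e
        raise KeyError(key)

    def major_edges(self) -> list[ColocEdge]:
        return [e for e in self.edges if e.major]

    def to_dict(self) -> dict:
        return {
            "n_spots": self.n_spots,
            "method": self.method,
            "major_rule": self.major_rule,
            "r_min": self.r_min,
            "top_k": self.top_k,
            "nodes": self.nodes,
            "excluded": self.excluded,
            "edges": [
                {"a": e.pair[0], "b": e.pair[1], "r": e.r, "major": e.major}
                for e in self.edges
            ],
        }


def colocalization_graph(
    proportions: FeatureMatrix,
    method: str = "pearson",
    major_rule: str = "threshold",
    r_min: float = DEFAULT_R_MIN,
    top_k: int = DEFAULT_TOP_K,
    min_variance: float = DEFAULT_MIN_VARIANCE,
) -> ColocGraph:
    """Build the co-localization graph of one section (or age group).

    Requires >= 3 spots and >= 2 cell types whose proportions actually
    vary across spots.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if major_rule not in ("threshold", "top_k"):
        raise ValueError("major_rule must be 'threshold' or 'top_k'")
    if proportions.kind != "proportions":
        raise ValueError("colocalization operates on a proportions matrix")
    values = proportions.dense()
    n_spots, n_types = values.shape
    if n_spots < 3:
        raise DegenerateInput(f"need >= 3 spots, got {n_spots}")

    types = [str(t) for t in proportions.var_ids]
    variances = values.var(axis=0)
    variable = variances >= min_variance
    excluded = [t for t, v in zip(types, variable) if not v]
    if variable.sum() < 2:
        raise DegenerateInput(
            f"need >= 2 cell types with variance >= {min_variance}; "
            f"only {int(variable.sum())} vary (excluded: {excluded})"
        )

    nodes = {t: float(values[:, j].mean()) for j, t in enumerate(types)}
    edges: list[ColocEdge] = []
    for j, k in combinations(np.flatnonzero(variable), 2):
        a, b = values[:, j], values[:, k]
        if method == "pearson":
            r = float(stats.pearsonr(a, b).statistic)
        else:
            r = float(stats.spearmanr(a, b).statistic)
        pair = tuple(sorted((types[j], types[k])))
        edges.append(ColocEdge(pair=pair, r=r, major=False))

    if major_rule == "threshold":
        for e in edges:
            e.major = e.r >= r_min
    else:
        ranked = sorted(edges, key=lambda e: e.r, reverse=True)
        for e in ranked[:top_k]:
            e.major = True

    edges.sort(key=lambda e: e.pair)
    return ColocGraph(
        nodes=nodes,
        edges=edges,
        n_spots=n_spots,
        method=method,
        major_rule=major_rule,
        r_min=r_min if major_rule == "threshold" else None,
        top_k=top_k if major_rule == "top_k" else None,
        excluded=excluded,
    )


def colocalization_by_group(
    proportions: FeatureMatrix,
    groups: dict[str, str],
    **kwargs,
) -> dict[str, ColocGraph]:
    """One graph per group label (sample or age), never pooled.

    ``groups`` maps spot id to its label; spots missing from the mapping
    are ignored.
    """
    out: dict[str, ColocGraph] = {}
    labels = np.array([groups.get(str(s)) for s in proportions.obs_ids], dtype=object)
    for label in sorted({l for l in labels if l is not None}):
        sub = proportions.subset(obs_mask=(labels == label))
        out[str(label)] = colocalization_graph(sub, **kwargs)
    return out
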