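"""Synthetic Visium-like spinal-cord sections with known DV structure.

A section is a triangular-lattice point cloud clipped to an ellipse — the
hex packing of the emulated capture array — with a hidden true
dorsal-ventral coordinate ``true_dv`` in [0, 1] (0 = dorsal pole) defined
along the ellipse's b-axis before any rotation, so ground truth is
invariant to the rotation used in robustness tests. The dorsal-most and
ventral-most quantiles of ``true_dv`` receive region labels, emulating
manual annotation.

Gene counts are negative binomial: the expected count of gene g in spot s
is ``baseline_g * effect_g(true_dv_s) * size_factor_s`` with gene-wise
dispersion and log-normal spot size factors. Effect shapes cover the
patterns seen on real sections: monotone (logistic or linear) morphogen
gradients, gaussian-banded progenitor domains, and uniform housekeeping
genes; optional per-age multipliers emulate temporal decline of signaling
modules. Cell-type proportions are Dirichlet draws around spatial kernel
archetypes (dorsal / central / ventral / uniform), emulating the output
of a deconvolution tool.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidConcentration,
    InvalidFraction,
    InvalidSpec,
    TooFewSpots,
)
from .random import substream
from .types import FeatureMatrix, SpotMap

EFFECTS = ("constant", "logistic_increasing", "logistic_decreasing",
           "gaussian_band", "linear")
KERNELS = ("dorsal", "central", "ventral", "uniform")

DEFAULT_N_SPOTS = 2000
DEFAULT_ELLIPSE_A = 1.0
DEFAULT_ELLIPSE_B = 1.5
DEFAULT_DORSAL_FRAC = 0.2
DEFAULT_VENTRAL_FRAC = 0.2
DEFAULT_LIBRARY_CV = 0.3
DEFAULT_DISPERSION = 2.0
DEFAULT_NOISE_CONC = 50.0

#: floor on effect/kernel values, keeps NB means and Dirichlet alphas positive
EFFECT_FLOOR = 0.05
KERNEL_FLOOR = 0.02


@dataclass
class GeneSpec:
    """Generative recipe for one gene.

    ``baseline`` is the expected count at full effect; ``dispersion`` the
    negative-binomial size (smaller = more overdispersed);
    ``age_multipliers`` optionally scales the baseline per age label.
    """

    name: str
    baseline: float
    effect: str = "constant"
    dispersion: float = DEFAULT_DISPERSION
    center: float = 0.5      # logistic midpoint or band center on true_dv
    width: float = 0.1       # gaussian band sd
    steepness: float = 10.0  # logistic slope
    age_multipliers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.dispersion <= 0:
            raise InvalidSpec(
                f"gene {self.name!r}: baseline must be >= 0 and dispersion > 0"
            )
        if self.effect not in EFFECTS:
            raise InvalidSpec(f"gene {self.name!r}: unknown effect {self.effect!r}")

    def effect_at(self, t: np.ndarray) -> np.ndarray:
        """Multiplicative effect of the true DV coordinate, in [floor, 1]."""
        t = np.asarray(t, float)
        lo = EFFECT_FLOOR
        if self.effect == "constant":
            return np.ones_like(t)
        if self.effect == "logistic_increasing":
            s = 1.0 / (1.0 + np.exp(-self.steepness * (t - self.center)))
        elif self.effect == "logistic_decreasing":
            s = 1.0 / (1.0 + np.exp(self.steepness * (t - self.center)))
        elif self.effect == "gaussian_band":
            s = np.exp(-0.5 * ((t - self.center) / self.width) ** 2)
        else:  # linear
            s = t
        return lo + (1.0 - lo) * s


@dataclass
class ProportionArchetype:
    """Spatial kernel of one cell type over the true DV coordinate."""

    name: str
    kernel: str = "uniform"
    center: float | None = None   # overrides the kernel's canonical center
    width: float = 0.2
    weight: float = 1.0           # relative abundance

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise InvalidSpec(f"archetype {self.name!r}: unknown kernel {self.kernel!r}")
        if self.weight <= 0 or self.width <= 0:
            raise InvalidSpec(f"archetype {self.name!r}: weight and width must be > 0")

    def kernel_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if self.kernel == "uniform":
            base = np.ones_like(t)
        else:
            center = self.center
            if center is None:
                center = {"dorsal": 0.0, "central": 0.5, "ventral": 1.0}[self.kernel]
            base = np.exp(-0.5 * ((t - center) / self.width) ** 2)
        return self.weight * (KERNEL_FLOOR + (1.0 - KERNEL_FLOOR) * base)


@dataclass
class SectionTruth:
    """A generated section plus everything needed to simulate data on it."""

    spotmap: SpotMap
    true_dv: dict[str, float]
    gene_specs: list[GeneSpec] = field(default_factory=list)
    archetypes: list[ProportionArchetype] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def true_dv_array(self) -> np.ndarray:
        return np.array([self.true_dv[str(s)] for s in self.spotmap.spot_ids])


def default_gene_specs() -> list[GeneSpec]:
    """The bundled gene panel.

    Dorsal-high (PAX3, MSX1, WNT1/WNT3A), ventral-high (OLIG2, SHH, GLI1),
    banded progenitor domains (FOXN4, NKX6-1), and uniform housekeeping
    (ACTB, SOX2, HES1, NOTCH1). The WNT/SHH/NOTCH genes carry decreasing
    per-age multipliers to emulate the temporal decline of the patterning
    pathways.
    """
    decline = {"W5": 1.0, "W8": 0.5, "W12": 0.25}
    return [
        GeneSpec("PAX3", 30, "logistic_decreasing", center=0.35),
        GeneSpec("MSX1", 25, "logistic_decreasing", center=0.25, steepness=12),
        GeneSpec("OLIG2", 30, "logistic_increasing", center=0.65),
        GeneSpec("SHH", 20, "logistic_increasing", center=0.85, steepness=15,
                 age_multipliers=decline),
        GeneSpec("GLI1", 15, "logistic_increasing", center=0.75,
                 age_multipliers=decline),
        GeneSpec("WNT1", 15, "logistic_decreasing", center=0.15, steepness=15,
                 age_multipliers=decline),
        GeneSpec("WNT3A", 12, "logistic_decreasing", center=0.2,
                 age_multipliers=decline),
        GeneSpec("FOXN4", 20, "gaussian_band", center=0.5, width=0.08),
        GeneSpec("NKX6-1", 20, "gaussian_band", center=0.75, width=0.1),
        GeneSpec("HES1", 25, "constant", age_multipliers=decline),
        GeneSpec("NOTCH1", 18, "constant", age_multipliers=decline),
        GeneSpec("ACTB", 60, "constant"),
        GeneSpec("SOX2", 40, "constant"),
        GeneSpec("DVLIN", 20, "linear"),
    ]


def default_archetypes() -> list[ProportionArchetype]:
    """Five cell-type archetypes: dorsal ASC, central NPC and EPC, ventral
    OPC, uniform neurons."""
    return [
        ProportionArchetype("ASC", "dorsal", width=0.2, weight=1.0),
        ProportionArchetype("NPC", "central", width=0.35, weight=1.5),
        ProportionArchetype("EPC", "central", width=0.12, weight=0.8),
        ProportionArchetype("OPC", "ventral", width=0.2, weight=1.0),
        ProportionArchetype("Neuron", "uniform", weight=1.2),
    ]


def _triangular_lattice(ellipse_a: float, ellipse_b: float, n_target: int) -> np.ndarray:
    """Triangular-lattice points inside the ellipse, at least n_target of them."""
    area = math.pi * ellipse_a * ellipse_b
    # per-point cell area of a triangular lattice with spacing s is s^2*sqrt(3)/2
    spacing = math.sqrt(2.0 * area / (math.sqrt(3.0) * n_target))
    for _ in range(40):
        dy = spacing * math.sqrt(3.0) / 2.0
        ys = np.arange(-ellipse_b, ellipse_b + dy, dy)
        pts = []
        for row, y in enumerate(ys):
            offset = 0.5 * spacing if row % 2 else 0.0
            xs = np.arange(-ellipse_a - spacing, ellipse_a + spacing, spacing) + offset
            keep = (xs / ellipse_a) ** 2 + (y / ellipse_b) ** 2 <= 1.0
            pts.extend((x, y) for x in xs[keep])
        if len(pts) >= n_target:
            return np.array(pts)
        spacing *= 0.93
    raise TooFewSpots(
        f"could not place {n_target} lattice points in ellipse "
        f"a={ellipse_a}, b={ellipse_b}"
    )


def make_section(
    n_spots: int = DEFAULT_N_SPOTS,
    ellipse_a: float = DEFAULT_ELLIPSE_A,
    ellipse_b: float = DEFAULT_ELLIPSE_B,
    dorsal_frac: float = DEFAULT_DORSAL_FRAC,
    ventral_frac: float = DEFAULT_VENTRAL_FRAC,
    rotation_deg: float = 0.0,
    seed: int = 0,
    sample_id: str = "synthetic",
    age: str | None = None,
    gene_specs: list[GeneSpec] | None = None,
    archetypes: list[ProportionArchetype] | None = None,
) -> SectionTruth:
    """Generate one annotated section with known true DV coordinates.

    The dorsal pole sits at the +b end of the ellipse before rotation;
    ``true_dv`` runs 0 (dorsal) to 1 (ventral) and is min-max scaled over
    the realized spots. The lowest ``dorsal_frac`` quantile of ``true_dv``
    is labeled dorsal, the highest ``ventral_frac`` quantile ventral, the
    rest unassigned.
    """
    if n_spots < 10:
        raise TooFewSpots(f"n_spots must be >= 10, got {n_spots}")
    if ellipse_a <= 0 or ellipse_b <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    if not (0.0 < dorsal_frac + ventral_frac < 1.0) or dorsal_frac <= 0 or ventral_frac <= 0:
        raise InvalidFraction(
            f"need 0 < dorsal_frac + ventral_frac < 1 with both positive; "
            f"got {dorsal_frac} + {ventral_frac}"
        )
    rng = substream(seed, "section-geometry")
    pts = _triangular_lattice(ellipse_a, ellipse_b, n_spots)
    if len(pts) > n_spots:
        pts = pts[rng.choice(len(pts), size=n_spots, replace=False)]
    pts = pts[np.lexsort((pts[:, 0], pts[:, 1]))]  # stable id order

    # true DV along the b-axis (y), dorsal at +b, before rotation
    y = pts[:, 1]
    t = (y.max() - y) / (y.max() - y.min())

    order = np.argsort(t, kind="stable")
    n_d = int(round(dorsal_frac * n_spots))
    n_v = int(round(ventral_frac * n_spots))
    region = np.array(["unassigned"] * n_spots, dtype=object)
    region[order[:n_d]] = "dorsal"
    region[order[n_spots - n_v:]] = "ventral"

    theta = math.radians(rotation_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    coords = pts @ rot.T

    ids = np.array([f"spot_{i:05d}" for i in range(n_spots)], dtype=object)
    spotmap = SpotMap(
        spot_ids=ids,
        coords=coords,
        region=region,
        sample_id=np.array([sample_id] * n_spots, dtype=object),
        age=None if age is None else np.array([age] * n_spots, dtype=object),
    )
    return SectionTruth(
        spotmap=spotmap,
        true_dv={str(s): float(v) for s, v in zip(ids, t)},
        gene_specs=gene_specs if gene_specs is not None else default_gene_specs(),
        archetypes=archetypes if archetypes is not None else default_archetypes(),
        seed=seed,
        params={
            "n_spots": n_spots, "ellipse_a": ellipse_a, "ellipse_b": ellipse_b,
            "dorsal_frac": dorsal_frac, "ventral_frac": ventral_frac,
            "rotation_deg": rotation_deg, "sample_id": sample_id, "age": age,
        },
    )


def simulate_expression(
    truth: SectionTruth,
    library_size_mean: float = 1.0,
    library_size_cv: float = DEFAULT_LIBRARY_CV,
    seed: int = 0,
    age: str | None = None,
) -> FeatureMatrix:
    """Draw a spots x genes negative-binomial count matrix.

    Spot size factors are log-normal with the given mean and coefficient
    of variation; ``age`` (defaulting to the section's own label) selects
    each gene's age multiplier where one is defined.
    """
    if not truth.gene_specs:
        raise InvalidSpec("truth carries no gene specs")
    if library_size_mean <= 0 or library_size_cv < 0:
        raise InvalidSpec("library size mean must be > 0 and CV >= 0")
    rng = substream(seed, "expression")
    t = truth.true_dv_array()
    n = len(t)
    if library_size_cv > 0:
        sigma2 = math.log1p(library_size_cv ** 2)
        mu = math.log(library_size_mean) - sigma2 / 2.0
        size_factors = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    else:
        size_factors = np.full(n, library_size_mean)

    if age is None and truth.spotmap.age is not None:
        age = str(truth.spotmap.age[0])

    counts = np.empty((n, len(truth.gene_specs)), dtype=float)
    for j, spec in enumerate(truth.gene_specs):
        mult = 1.0
        if spec.age_multipliers and age is not None:
            mult = spec.age_multipliers.get(age, 1.0)
        mean = spec.baseline * mult * spec.effect_at(t) * size_factors
        p = spec.dispersion / (spec.dispersion + mean)
        counts[:, j] = rng.negative_binomial(spec.dispersion, p)
    return FeatureMatrix(
        obs_ids=truth.spotmap.spot_ids.copy(),
        var_ids=np.array([s.name for s in truth.gene_specs], dtype=object),
        values=counts,
        kind="counts",
    )


def simulate_proportions(
    truth: SectionTruth,
    noise_conc: float = DEFAULT_NOISE_CONC,
    seed: int = 0,
) -> FeatureMatrix:
    """Draw a spots x cell-types proportion matrix.

    Expected proportions are the archetype kernels normalized to sum to 1
    per spot; the observed row is Dirichlet with parameter
    ``noise_conc * expected``, so larger concentrations mean less noise
    and the expectation is recovered in the limit.
    """
    if not truth.archetypes:
        raise InvalidSpec("truth carries no proportion archetypes")
    if noise_conc <= 0:
        raise InvalidConcentration(f"noise_conc must be > 0, got {noise_conc}")
    rng = substream(seed, "proportions")
    t = truth.true_dv_array()
    kernels = np.stack([a.kernel_at(t) for a in truth.archetypes], axis=1)
    expected = kernels / kernels.sum(axis=1, keepdims=True)
    # vectorized Dirichlet via normalized gammas
    gammas = rng.gamma(shape=noise_conc * expected)
    rows = gammas / gammas.sum(axis=1, keepdims=True)
    return FeatureMatrix(
        obs_ids=truth.spotmap.spot_ids.copy(),
        var_ids=np.array([a.name for a in truth.archetypes], dtype=object),
        values=rows,
        kind="proportions",
    )


def expected_proportions(truth: SectionTruth) -> FeatureMatrix:
    """Noise-free archetype proportions (the Dirichlet means)."""
    t = truth.true_dv_array()
    kernels = np.stack([a.kernel_at(t) for a in truth.archetypes], axis=1)
    expected = kernels / kernels.sum(axis=1, keepdims=True)
    return FeatureMatrix(
        obs_ids=truth.spotmap.spot_ids.copy(),
        var_ids=np.array([a.name for a in truth.archetypes], dtype=object),
        values=expected,
        kind="proportions",
    )


def make_age_series(
    ages: list[str],
    n_spots: int = DEFAULT_N_SPOTS,
    seed: int = 0,
    **section_kwargs,
) -> dict[str, tuple[SectionTruth, FeatureMatrix]]:
    """One section + count matrix per age label.

    Each age gets its own geometry seed and expression draw; genes with
    ``age_multipliers`` change their baseline across the series, emulating
    temporal regulation of, e.g., the patterning pathways.
    """
    out: dict[str, tuple[SectionTruth, FeatureMatrix]] = {}
    for i, age_label in enumerate(ages):
        truth = make_section(
            n_spots=n_spots, seed=seed + i, sample_id=f"section_{age_label}",
            age=age_label, **section_kwargs,
        )
        counts = simulate_expression(truth, seed=seed + i, age=age_label)
        out[age_label] = (truth, counts)
    return out
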