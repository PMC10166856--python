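# Methods

## The axis model

The package treats a tissue section as a 2D point cloud of capture spots
with a latent 1D anatomical coordinate. The dorsal–ventral axis is not
fitted to expression data; it is derived purely from the manual region
annotation, which mirrors how an anatomist would define it: the direction
you travel to get from dorsal tissue to the nearest ventral tissue.

Concretely, for random subsamples *D′* (≤ cap_d = 200 dorsal spots) and
*V′* (≤ cap_v = 100 ventral spots), each dorsal spot contributes the
vector to its nearest ventral subsample spot, and the axis *a* is the
unit-normalized mean of these difference vectors. Every spot's position is
the scalar projection u_s · a, min–max scaled over **all** spots of the
sample so the reported coordinate always spans exactly [0, 1] with
0 = dorsal-most extreme. Consequences of this construction:

- the estimate is invariant to translation exactly and to rotation up to
  floating point, because the difference vectors co-rotate with the
  coordinates;
- it is robust to the *shape* of the annotated regions but not to
  mislabeled poles — the annotation is trusted input;
- scaling over all spots (not only annotated ones) means adding or
  removing unannotated spots at the extremes changes everyone's scaled
  position. That is intentional: the coordinate is relative to the
  section, not absolute.

Averaging runs over the dorsal subsample (each dorsal spot contributes one
difference vector); the caps bound the nearest-neighbour search and
equalize the influence of sections with very different region sizes. The
subsample is drawn once per section with a caller seed and reused for
every feature, so all profiles of a section share one axis.

Nearest-neighbour ties are broken toward the smallest spot id, with
distances within a relative 1e-9 treated as tied. The tolerance matters on
lattice-like geometries (Visium arrays, the synthetic generator): there a
dorsal spot can be exactly equidistant to two ventral spots, and without
the tolerance a rigid rotation flips such ties through machine-precision
noise, moving the estimated axis by far more than rounding error.

Degenerate inputs raise typed errors rather than returning silently: an
empty dorsal or ventral set (axis undefined), difference vectors that
cancel to zero (e.g. ventral tissue symmetrically surrounding dorsal), and
an all-equal projection (min–max scaling undefined).

## Binning and smoothing

Scaled positions are cut into `n_bins` equal intervals, indexed 1..n_bins;
interior bins are right-open and the last bin right-closed so that a
position of exactly 1 is binned. Per non-empty bin the profile records the
mean position x_i, mean feature value y_i and occupancy; empty bins are
omitted rather than interpolated, since a mean over an empty set is
undefined and interpolation would invent data. Default `n_bins` = 50,
giving a few tens of spots per bin on a typical few-thousand-spot section;
it is exposed everywhere.

The smoother is classical loess: at each evaluation point the
`ceil(span·n)` nearest bins get tri-cube weights
(1 − (d/d_max)³)³ and a weighted polynomial of degree 1 or 2 is fitted and
evaluated. Defaults span = 0.75, degree = 2, the common defaults of
statistical plotting software. The implementation is the direct
(non-robust) surface; it reproduces constants exactly and straight lines
to numerical precision, and the test suite pins it against two independent
implementations: statsmodels' lowess for degree 1 and R's `loess` for
degree 2 (compared at the data points, where R's evaluation is exact —
away from them R interposes its own approximation layer).

Feature normalization, when requested, is counts scaled per spot to the
median library size then log1p — the minimal, assumption-light transform.
Gene-module scores are plain means of normalized expression over the
present module genes (duplicates dropped, absent genes warned about); no
control-gene background subtraction is applied, keeping the estimator
transparent at the cost of a library-size-correlated baseline, which the
normalization mitigates.

## QC filters

Thresholds are applied strictly as stated: "fewer than 500" keeps exactly
500, "over 25 %" keeps exactly 25 %. The fixed rule order is gene-identity
filters (biotype enrichment or name-pattern blacklist) → observation
filters → gene-support filters, because a gene's support count depends on
which observations survive. The mitochondrial fraction is computed on the
counts as loaded, before biotype enrichment, so the set of removed cells
does not depend on whether MT genes remain in the gene universe.
Mitochondrial genes are recognized by the human "MT-" symbol prefix and
the spatial blacklist by symbol regular expressions (HB gene families,
MALAT1, MT-*, RPS*/RPL*); both are configurable since symbol dialects vary.

## Co-localization

The statistic is the Pearson (optionally Spearman) correlation of two cell
types' proportion vectors across spots. Because proportions are
compositional (rows sum to 1), correlations are negatively biased — with
exactly two varying types the closure constraint forces r = −1 — so edge
weights should be compared within a graph, not across panels with
different type counts. "Major connections" are flagged either by a
threshold (default r ≥ 0.3) or as the top-k edges; both rules are exposed
because the choice is a presentation convention, not an estimand. Types
with numerically constant proportions have no defined correlation and are
excluded from edges but reported. Graphs are computed per sample and per
age label, never pooled, since developmental stages differ precisely in
this structure.

## The synthetic generator

The generator emulates the geometry and noise of a Visium-like section
well enough to exercise every pipeline stage against known truth:

- **Geometry:** triangular lattice (the platform's hex packing) clipped to
  an ellipse (default semi-axes a = 1.0, b = 1.5 — a DV-elongated
  cross-section), subsampled to exactly `n_spots` (default 2,000, a
  typical section scale). The true DV coordinate is the min–max-scaled
  position along the b-axis **before** rotation, so ground truth is
  invariant to the rotation used in robustness tests. The lowest and
  highest 20 % of true DV are labeled dorsal and ventral, emulating
  conservative manual annotation of the poles.
- **Counts:** negative binomial with mean
  baseline_g · effect_g(true_dv) · size_factor_s, gene-wise dispersion
  (default size 2.0, typical spot-level overdispersion) and log-normal
  size factors (mean 1, CV 0.3, the order of spot-to-spot library-size
  spread). Effects cover logistic gradients (morphogen-like), gaussian
  bands (progenitor domains), linear ramps and constants; the bundled
  panel names familiar markers (PAX3/MSX1 dorsal, OLIG2/SHH ventral,
  FOXN4/NKX6-1 banded, ACTB/SOX2 uniform) purely as mnemonic labels for
  those shapes. Per-age baseline multipliers on the signaling genes
  (1.0 → 0.5 → 0.25 across W5/W8/W12) emulate the temporal decline of
  patterning-pathway activity.
- **Proportions:** five cell-type archetypes with gaussian kernels over
  true DV (dorsal astrocyte-like, central progenitor and ependymal,
  ventral OPC-like, uniform neuronal); observed rows are Dirichlet draws
  around the normalized kernels with concentration 50 — visibly noisy but
  spatially structured, like deconvolution output.

What the generator does **not** emulate: gene–gene correlation beyond the
shared DV dependence, segmentation/annotation errors, spatial
autocorrelation of technical noise, platform-specific artifacts (edge
effects, permeabilization gradients), or realistic transcriptome-wide gene
counts. Passing tests therefore demonstrate correctness of the
computations and recoverability under the stated generative model, not
performance on real tissue.

All randomness derives from a single integer seed through named,
crc32-keyed substreams (geometry, subsampling, expression, proportions),
so stages are independently reproducible and adding a stage never shifts
another's draws.

## Numerical and design choices

- Bin indices 1..n_bins with a right-closed last bin: equal printed edges,
  full coverage of [0, 1], no perpetually empty bin.
- The stored axis position is the scalar coefficient u_s · a; with a unit
  axis it carries the same information as the projected 2-vector and is
  what binning needs.
- Orientation is reported 0 = dorsal; `flip` (CLI `--flip`) negates the
  axis and maps p → 1 − p for the opposite convention.
- Coordinates are used as-is — no image-style y flip, no unit conversion;
  the method is invariant to these choices when annotations are
  consistent.
- Duplicate coordinates are allowed (distinct spots may coincide);
  duplicate spot ids are not.
- Loess local systems are solved by least squares on a design centred at
  the evaluation point, for conditioning; windows that collapse to a
  single location fall back to the weighted mean.
- Problem sizes in the test and acceptance runs (2,000-spot sections for
  recovery, 500–600-spot sections for multi-seed sweeps, 10 seeds, 50
  oracle instances) were chosen as the smallest sizes at which the
  Monte-Carlo statements they check are stable.

## Known limitations

- The axis is a straight line; strongly curved sections would need an
  arc-length coordinate, which is out of scope.
- Min–max scaling is sensitive to single extreme spots (e.g. a detached
  debris spot defines an endpoint); QC should precede projection.
- The co-localization statistic inherits compositional bias; a
  log-ratio-based variant would remove it at the cost of interpretability
  of the node weights.
- Module scores are unweighted means; highly expressed genes dominate.
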