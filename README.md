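# axiscope

Quantification of gene expression and cell-type composition along the
dorsal–ventral (DV) axis of spatial-transcriptomics sections, built for
developing spinal-cord cross-sections but applicable to any tissue with two
annotated anatomical poles.

Spatial platforms such as Visium measure expression at fixed capture spots
in a 2D section, but the biology of the neural tube is organized along a 1D
anatomical axis: morphogen gradients (SHH ventrally, WNT/BMP dorsally) and
the progenitor domains they pattern vary with DV position, not with raw
array coordinates. `axiscope` casts the 2D data into that 1D representation
and profiles any spot-level feature along it.

## The method

Spots are manually annotated as dorsal (set *D*), ventral (*V*) or
unassigned. From random subsamples *D′*, *V′* of size min(|D|, 200) and
min(|V|, 100):

1. **Axis direction.** For each dorsal spot *d_s* ∈ *D′*, the DV-difference
   vector δ_s = v_k − d_s points to its nearest ventral spot
   v_k = argmin‖d_s − v_k‖, v_k ∈ *V′*. The axis is the unit-normalized
   mean, a = δ̄ / ‖δ̄‖, pointing dorsal → ventral.
2. **Projection.** Each spot with coordinates u_s gets the scalar
   orthogonal-projection coefficient p_s = u_s · a, min–max scaled over the
   sample to [0, 1] (0 = dorsal-most, 1 = ventral-most extreme).
3. **Profiling.** Positions are cut into n_bins equal bins
   (bin *i* = [(i−1)/n_bins, i/n_bins), last bin right-closed); per
   non-empty bin the mean position x_i and mean feature value y_i are
   recorded, and the curve y = f(x) is estimated by loess (tri-cube
   locally weighted polynomial regression, default span 0.75, degree 2).

The feature can be normalized gene expression, a gene-module score (mean
normalized expression of a gene set), or deconvolution cell-type
proportions. The package also ships the standard count-matrix QC filters
(biotype enrichment; cells < 500 detected genes, > 25 % mitochondrial,
genes in < 15 cells; spatial hemoglobin/MALAT1/mito/ribosomal blacklist,
spots < 500 genes, genes in < 5 spots), a cell-type co-localization graph
(correlation of proportion vectors across spots, with "major connection"
flagging), and a synthetic section generator — a triangular-lattice
elliptical section with known true DV coordinates, negative-binomial
counts and Dirichlet proportion noise — so the whole pipeline is testable
without any external download.

## Worked example

```python
import axiscope as ax
from scipy.stats import spearmanr

truth = ax.make_section(n_spots=2000, seed=7)        # synthetic section
est = ax.estimate_axis(truth.spotmap, seed=7)        # DV axis + positions
rho = spearmanr(truth.true_dv_array(),
                est.positions([str(s) for s in truth.spotmap.spot_ids])).statistic

norm = ax.normalize_counts(ax.simulate_expression(truth, seed=7))
pos = {str(s): est.scaled_projection[str(s)] for s in norm.obs_ids}
obs = [str(s) for s in norm.obs_ids]
prof = ax.bin_profile(pos, dict(zip(obs, norm.column("OLIG2"))), n_bins=50)
sm = ax.smooth_profile(prof)
```

prints (via the accompanying report lines):

```
axis direction (dorsal->ventral): (+0.0174, -0.9998)
Spearman(true DV, scaled projection) = 0.9999
OLIG2 profile: 50 occupied bins, y[first]=0.676, y[last]=3.146
loess fit at grid ends: 0.761 -> 2.973
coloc: 10 edges, major: EPC-NPC (r=0.34)
```

The estimated axis points almost exactly down the section's long axis; the
scaled positions recover the simulated DV coordinate (ρ = 0.9999); the
ventral marker OLIG2 rises from 0.68 to 3.15 (log-normalized counts)
between the dorsal-most and ventral-most bins; and the co-localization
graph flags the ependymal/progenitor pair, whose kernels overlap centrally,
as the one major connection.

The same stages are available from the shell:

```bash
axiscope simulate --n-spots 2000 --seed 7 --out section/
axiscope estimate-axis --spots section/spots.csv --seed 7 --out section/axis
axiscope profile --matrix section/counts.csv --axis section/axis.projections.csv \
                 --features OLIG2,PAX3 --n-bins 50 --out section/prof
axiscope coloc --proportions section/proportions.csv --out section/coloc
axiscope run --seed 7 --out section/full       # everything under one config
```

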