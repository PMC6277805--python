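# Methods

`motorgraph` analyzes reorganization of a 20-region executive motor network
from paired (pre/post intervention) resting-state fMRI ROI time series. This
note documents the models, conventions, and numerical choices the package
commits to, and what its synthetic-data tests do and do not demonstrate.

## Network construction

**Nodes.** The packaged atlas defines 20 motor-network ROIs (bilateral M1,
SMA, dorsal premotor, superior parietal lobule, thalamus, basal ganglia,
superior and anterior-inferior cerebellum, dentate nucleus; plus left ventral
premotor and right postcentral gyrus) as 5 mm diameter spheres around MNI
coordinates. Atlas row order defines node order everywhere. The voxelizer
labels a voxel by closed-ball membership of its *center*
(‖center − ROI center‖ ≤ radius), the simplest reproducible rule; the voxel
grid is a parameter because acquisition grids differ (the packaged ROIs are
disjoint at 5 mm on 2 mm and 3.5 mm grids).

**Edges.** For each session, connectivity is the absolute Fisher z of the
Pearson correlation between ROI signals: `z_ij = |atanh(r_ij)|`. The
absolute value reflects that the analysis concerns coupling magnitude, not
sign; since atanh is odd, applying it before or after the transform is
equivalent. `r` is clipped to ±(1 − 1e−7) before atanh so numerically
identical signals cannot produce infinities.

**Thresholding.** A proportional threshold at density *s* keeps
`E = max(N−1, round(s·N(N−1)/2))` edges (round half-up, so 0.42·190 → 80).
To guarantee connectedness the maximum spanning tree (Prim's algorithm) is
retained as a backbone and the remaining `E − (N−1)` slots are filled with
the strongest non-tree edges. All ordering ties break by (weight descending,
i ascending, j ascending), making graphs bit-reproducible and nested across
densities. Weights are the z values themselves; there is no binarization.
The default fixed density for regional analyses is 0.42, the density at
which every subject's suprathreshold (z > 1.96) edges survive in the cohort
this pipeline emulates; the CLI can instead recompute the cohort minimum
significant-edge fraction (`--density auto`).

## Graph measures

With `W_ij` the edge weight, `S_i` node strength, and `K_i` binary degree:

- **Clustering (segregation).**
  `C_i = (1 / (S_i (K_i − 1))) Σ_{(j,k)} (W_ij + W_ik)`, summing over
  neighbor pairs (j, k) of i that are themselves connected — the Barrat
  normalization, which the printed denominator `S_i(K_i − 1)` implies. The
  alternative reading (all neighbor pairs, closed or not) would make
  `C_i ≡ 1` identically and is therefore rejected. An Onnela
  (geometric-mean) variant is exposed as `clustering_variant="onnela"` for
  sensitivity analyses; it never changes the default. `C_i = 0` when
  `K_i ≤ 1`. Network clustering C is the nodewise mean.
- **Path length (integration).** Traversal cost of an edge is `1/W_ij`
  (strong coupling = short functional distance, the Brain Connectivity
  Toolbox convention); `l_i` is the mean Dijkstra cost from i to all other
  nodes, and L the nodewise mean. Connectedness is guaranteed by the MST
  backbone, so L is always finite.
- **Degree centrality.** The binary count of suprathreshold edges at a node.
- **Betweenness centrality.** `BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` over
  unordered pairs on the same 1/weight shortest paths, then rescaled by the
  nodewise mean BC so values are comparable across graphs of different size
  and density (mean-normalized BC averages 1 whenever any BC is nonzero; a
  graph with no intermediated pairs maps to all zeros).

Scale invariances (C, DC, BC unchanged and L halved under doubling of all
weights) and agreement with exhaustive path-enumeration oracles on small
random graphs are enforced by the test suite.

## Statistics

All pre/post comparisons use the **exact two-sided Wilcoxon signed-rank
test**: differences post − pre, zeros dropped (Wilcoxon's original
convention), midranks for tied absolute differences, and the exact null
distribution of the positive-rank sum obtained by generating-function
convolution over the doubled midranks — identical to enumerating all 2^n
sign assignments, conditional on the observed tie pattern. The two-sided p
is `min(1, 2·min(lower tail, upper tail))` with the point mass counted in
both tails. Beyond 25 effective pairs (far above this design's n = 13) a
tie-corrected normal approximation is used with a warning. On the packaged
clinical table the test reproduces the published exact values: seven
positive untied ARAT differences give p = 2/2⁷ = 0.0156, and thirteen
uniformly negative 9-HPT differences give p = 2/2¹³ ≈ 0.0002.

Multiple comparisons are corrected per family with Benjamini–Hochberg FDR:
betweenness tests across the 20 regions, degree tests across the 20 regions,
and behavior correlations each form one family; the global sweep is adjusted
within measure across the density grid. A result is *significant* if
q < α = 0.05 and a *trend* if its raw p < 0.07 without surviving FDR.
Brain–behavior association is the Pearson correlation of per-subject metric
changes with ARAT/9-HPT changes (two-sided p from the t distribution,
n − 2 df, pairwise deletion of missing scores; ≥ 3 complete pairs required).

## Synthetic cohorts

The generator emulates the *output* of resting-state preprocessing, not the
scanner: per subject and session it draws T = 230 time points (ten minutes
at TR 2.6 s) of multivariate Gaussian signal over the 20 ROIs with a
block-structured target correlation — 0.45 within functional communities
(ipsilesional cortical, contralesional cortical, bilateral subcortical,
bilateral cerebellar), 0.10 between — then applies AR(1) smoothing
(coefficient 0.3, stationary initialization) to mimic the autocorrelation
of bandpassed BOLD, and adds white observation noise (SD 0.2; ROI-mean
signals average out most thermal noise, so residual noise is small relative
to the neural signal whose stationary SD is ≈ 1.05). Because all columns
share the AR coefficient, smoothing preserves the cross-correlation targets
exactly; only the white noise attenuates them (by ≈ 3.5% at the defaults).

Reorganization is injected by adding Δr to designated edges of the post
session's target; a non-positive-definite target is repaired by eigenvalue
flooring and rescaling to unit diagonal (logged). Behavioral change scores
couple linearly to each subject's *realized* mean Δr on the effect edges:
ARAT gains +slope·strength, 9-HPT −slope·strength (improvement is faster),
plus Gaussian noise; defaults (slope 20, noise SD 2) land in the range of
published chronic-stroke change scores. Everything derives from one seed.

**What passing tests show.** Calibration (null cohorts reject at ≈ 5%),
power (an all-edge Δr = +0.25 increase at ipsilesional M1 is flagged at
least as a trend in ≥ 80% of replicates), and direction (raising
within-community coupling raises clustering over the mid-density band) are
properties of this Gaussian block world. Real BOLD has non-Gaussian tails,
motion and physiological artifacts, spatially varying noise, and no clean
community structure; the tests validate the *pipeline's* statistical
behavior, not fMRI realism. One structural consequence of the block design:
within-community pairs are only 41/190 = 21.6% of edges, so below ≈ 0.22
density both sessions retain the same all-within-community topology and the
clustering change is pinned near zero; the injected clustering increase
emerges from ≈ 0.24 density upward, which is why the direction check
summarizes the 0.12–0.36 band by its median.

## Numerical choices and degenerate inputs

- Correlation clipping 1e−7 before atanh; graphs reject non-positive
  weights; MST edges of weight 0 (possible only for an all-zero matrix) are
  floored at the smallest positive float so path costs stay finite.
- Round-half-up edge counts; the edge budget never drops below N−1.
- All differences zero in a paired pipeline test → reported as p = 1 with a
  warning (the bare statistical function raises instead, since there the
  caller should know the test is undefined).
- Mean-zero betweenness → all normalized values 0; K ≤ 1 → C_i = 0.
- FDR accepts p = 0.0 (floating underflow of perfect fits).
- PD repair floor 1e−6 on eigenvalues; the spec of a cohort fails fast at
  construction if its targets leave (−1, 1) or cannot be repaired.

## Problem sizes

Default analyses use the study-scale design throughout: 13 subjects, 230
time points, 20 ROIs, density grid 0.05–0.50 (step 0.01) with regional
tests at 0.42. Simulation-based checks use 20–100 replicates at this scale,
which resolves the tested rates well inside their acceptance bands.

## Known limitations

- No hemodynamic forward model, motion/lesion simulation, or preprocessing:
  the package starts at denoised ROI time series.
- The exact test's discreteness at n ≤ 13 means achievable significance
  levels are quantized; calibration checks account for this.
- Group-median matrices are descriptive only; all inference is
  within-subject.
- Crossover/control phases and intermediate time points are out of scope;
  the analysis is strictly pre vs post.
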