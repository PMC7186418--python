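# Methods

## Data model

Input is a censored Ct matrix: per cell and gene assay, either a cycle
threshold in (0, 40] or a sentinel (999) for a reaction that never crossed
threshold. Analysis operates on LOD-referenced expression

    Et = max(0, LOD − Ct),   LOD default 24 cycles,

in log2 units (one PCR cycle ≈ one transcript doubling). The source study
fed "Ct values" to its tSNE tool but displayed "gene expression"; the two
are consistent only up to a monotone affine map, and since every downstream
stage here is distance-based, the choice only rescales geometry. We
therefore fix the minimal LOD-referenced transform above and expose the LOD
in config. Cells flagged as doublets/debris never enter matrices; a QC
filter drops cells with fewer than `min_detected` (default 1) detected
genes.

## Synthetic cohort generator

The real cohort is not deposited, so the generator emulates the study
design: 1107 cells split 207/169/265/261/205 over littermate control,
surgical control, and post-pneumonectomy days 1/3/7; a 96-assay panel; 73
bulk samples over 8 sorted cell-types sharing an 18-gene overlap panel.

Per cell, a latent population (K = 6) is drawn from its group's composition
vector; per gene, detection is Bernoulli(detect_prob), and a detected
reaction yields Ct = LOD − N(mean_et, sd_et) clamped to (0, 40]. Bulk
replicates are the source population's mean program on the overlap genes
plus N(0, 0.5²) log2 noise (no dropout: bulk averages thousands of cells).
Draw order is fixed and all draws come from one seeded PCG64 stream, so
output is bit-reproducible.

Defaults encode the study's two printed frequency claims: the emergent
population (the analogue of the study's post-PNX cluster) has frequency
0.005 in both control groups and (0.24, 0.30, 0.27) on days 1/3/7 — the
paper prints only the 27% mean, so the split is our choice and is
configurable. Surgical controls share the littermate composition (the study
found them indistinguishable). The remaining mass is split over the other
five populations in fixed proportions (0.30/0.22/0.18/0.17/0.13). No effect
sizes are published, so separability is our calibration: each population
over-expresses a 13-gene signature block (3 overlap genes + 10 panel genes)
by 7 log2 units over a baseline of 2, with sd_et = 1 and detection 0.95 on
signature vs 0.5 on background genes. Panel names use the ~35 symbols the
study prints, padded to 96 with placeholder assays (`Syn01`…).

What the generator does **not** emulate: continuous gradations between cell
states (populations are well-separated Gaussians), expression-dependent
dropout, within-population covariance structure, batch/chip effects, and
the "under-clustered" subpopulations the study reports inside its Cluster 1.
Passing recovery tests therefore show the pipeline is correct under the
stated mixture model, not that real alveolar-duct data are this clean.

## tSNE

Conditional affinities use a Gaussian kernel on Euclidean distances over all
genes; the per-cell precision is found by binary search until the row's
Shannon perplexity matches the target within 1e-6 in log-perplexity
(bounded at 200 steps; non-convergence raises with the row index).
Symmetrization is p_ij = (p(j|i)+p(i|j))/(2n). The map minimizes KL(P‖Q)
with the Student-t (1 df) kernel.

Run parameters default to the study's published settings: 2000 iterations,
perplexity 10, theta 0.5. The optimization schedule is the canonical one
(learning rate 200 with adaptive gains in [0.01, ∞), early exaggeration 12
for 250 iterations, momentum 0.5 → 0.8 at iteration 250, random N(0, 1e-4²)
init; PCA init available). The momentum buffer and gains are reset when the
exaggeration phase ends, as reference implementations do — carrying the
exaggerated-phase momentum measurably degrades final KL. P is floored at
1e-12; duplicate input rows are jittered by 1e-8 before bandwidth
calibration to avoid degenerate searches. KL against the *unexaggerated* P
is recorded every 50 iterations.

Two gradient engines: exact O(n²) (theta = 0; the reference path — a
1100-cell cohort is desk-scale) and Barnes-Hut (theta > 0), which
approximates the repulsive term with an adaptive quadtree opened at
cell-diameter/distance < theta; attraction stays exact since P is dense at
this scale. Points within 1e-10, or beyond depth 52, merge into one leaf.
tSNE converges to different local minima from different starts — on small
fixtures two exact runs differing only in seed overlap ~0.67 in 10-NN sets —
so `restarts` (default 1) runs independent optimizations and keeps the
lowest-KL map, the standard recommendation when layout quality matters.

## Clustering

Ward-linkage agglomerative clustering on Euclidean distances, cut at k = 6
(the study's stated constraint). The study does not state the criterion or
the space; we cluster in Et gene space by default (marker-space clustering,
as SPADE does; the 2-D embedding is for display), with
`space: embedding` exposed. Labels are renumbered 1..k by decreasing size
(ties by first occurrence); centroids are within-cluster mean Et.
Density-dependent downsampling (SPADE's device for 10⁵⁺-cell cytometry
runs) is available but off by default at this n: local density is the
neighbor count within a kernel radius, and cells are kept with probability
min(1, c/density) with c bisected so the expected kept count matches the
target fraction — rare cells are kept with probability 1. Held-out cells
join the nearest centroid.

The emergent cluster of a frequency table is identified as the cluster
maximizing (mean post-PNX fraction − mean control fraction).

## Bulk projection

Both data sets are restricted to the overlap genes (default: the 18 printed
symbols; the study elsewhere says "36 overlapping genes" without listing
them, so the set is configurable), z-scored per gene within each data set
(absorbing platform scale and location), and compared by Pearson
correlation across genes — "similarity" is otherwise unspecified in the
source, and correlation is the scale-free choice a cross-platform
comparison demands. Genes constant in either data set are dropped from both
(≥3 must remain); cells constant across the overlap genes get similarity 0
rather than NaN so column indices keep cohort alignment. Each bulk sample
projects onto the map at its m most similar cells (default m = 20; the
study shows several dots per bulk population but prints no count), ties
broken by cell order. Because bulk populations may straddle clusters,
identity is reported as a distribution over cluster labels per cell-type
plus its mode (ties to the smaller label). Heatmap row/column orders come
from average-linkage clustering on correlation distance.

## Statistics

Cluster frequencies are per-group fractions (groups conserve cell counts
exactly). Marker ranking uses one-vs-rest differences of mean Et — Et is
log2-scale, so the difference *is* a log2 fold-change (ΔΔCt convention) —
sorted descending with alphabetical tie-break, top 10 kept. Pre/post
comparisons pool days 1+3+7 against littermate controls (surgical controls
excluded by default, configurable — their placement is unstated in the
source); per gene, Welch's unequal-variance t-test with Satterthwaite df,
two-sided p, stars at p < 0.05/0.01/0.001. Two zero-variance samples with
equal means give t = 0, p = 1 by convention. No multiple-testing correction
is applied to the stars (matching the per-gene display convention); a
Benjamini–Hochberg q-value column is emitted additionally as a clearly
separate extension. log10 display values are computed as log10(Et+1) at
export only; all inference runs on Et. Gene overlays are per-gene min-max
scaled to [0, 1]; constant genes map to zero.

## Pipeline

Stages run in dependency order (simulate → load/transform → embed → cluster
→ project → stats) from a validated YAML config; unknown keys are rejected
and every constraint violation names its key before any compute. One global
seed fans out to per-stage seeds by stable hashing of the stage name, so
toggling a stage leaves the others' random streams untouched. Every emitted
file is checksummed (SHA-256) into `manifest.json`; identical config + seed
reproduces identical checksums. CSV floats are written at 6 significant
digits for byte-stable output.

## Problem sizes

Verification runs use proportionally scaled cohorts (largest-remainder
rounding of the group sizes): 400 cells × 10 seeds for the full-pipeline
frequency checks, 250–300 cells × 20 seeds for clustering and projection
recovery, and the full 1107-cell design for design-conformance and
cluster-count checks — chosen so the whole suite runs on a laptop in about
a minute while keeping every per-group expectation identical to the
full-size design.

## Known limitations

- The LOD transform, clustering criterion/space, similarity measure, m, and
  the 18-vs-36 overlap set are all decisions the source leaves open; each is
  exposed in config and defaulted as argued above.
- The Barnes-Hut engine approximates only the repulsive term; its layouts
  differ from exact-gradient layouts at the fine-neighborhood level, within
  the run-to-run variability of the optimizer itself.
- Recovery guarantees are conditional on the generator's separability
  defaults; heavily overlapping populations will degrade clustering and
  projection recovery, and no claim is made about them.
- Ct-calling (baseline correction, thresholding) is assumed done upstream by
  instrument software; files carry already-called Ct values.
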