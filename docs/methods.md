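# Methods

## Overview

`sbnfuse` operates on undirected, nonnegative weighted networks over a
fixed parcellation. One scan yields nine networks (one per weighting
strategy); the package fuses them, filters the fusion topologically, and
evaluates reliability and subject discriminability across a
subjects × scans design. This note documents the models, the defaults and
why, and what the synthetic generator does and does not emulate.

## Synthetic cohort model

Each subject carries a latent network on a native-space geometry; each
scan is a noisy realization of it.

**Geometry.** A template parcellation samples centroids uniformly in a
brain-sized box (≈140 × 177 × 123 mm) and log-normal gray-matter voxel
counts (median 400 voxels, σ = 0.5 log units). Each subject displaces the
template centroids by N(0, 2.5 mm) per axis — so inter-centroid Euclidean
distances genuinely differ across individuals — and each scan adds a
residual N(0, 0.5 mm) jitter (head position / registration error).

**Latent subject network.** Connection probability and mean streamline
count decay exponentially with centroid distance (length scale 40 mm),
modulated by a subject-specific planted partition (6 modules;
within-module boost ×2) and a subject-specific per-edge log-normal jitter
(σ = 0.6; this is the fingerprint signal). Mean counts scale from 80 at
zero distance. Per-edge tract metrics are drawn once per subject:
FA ~ N(0.45, 0.12) clipped to [0.05, 0.95]; MD ~ N(8×10⁻⁴, 0.8×10⁻⁴) mm²/s;
RD = MD × U(0.55, 0.9); mean streamline length = chord × U(1.1, 1.6) + 2 mm;
a white-matter offset ~ Exp(25 mm) determines how much of each tract's
length counts as contiguous white matter.

**Scan realization.** Counts are negative-binomial (dispersion r = 100,
variance m + m²/100) around log-normally fluctuating scan means
(σ = `scan_noise`). Relative count noise therefore grows as tracts get
weaker — the test-retest signature of streamline tractography — and
tracts whose draw is zero are absent from that scan. Each scan also gains
spurious false-positive tracts (expected 8% of the true tract count),
weak (1–2 streamlines) and traversing little white matter
(U(0.05, 6) mm), making them the natural target of both the 0–6 mm
length-threshold sweep and topological filtering. FA/MD/RD get scan-level
Gaussian noise (`metric_noise`, default 0.02). Setting `scan_noise = 0`
produces bit-identical repeat scans (counts = rounded latent means, no
dropout, no spurious tracts) — a deliberate degenerate case for testing.

**Defaults.** `CohortParams()` is a moderate-noise regime
(`scan_noise = 0.15`); `LOW_NOISE` (`between_subject_scale = 0.8`,
`scan_noise = 0.05`, `metric_noise = 0.01`) is the well-separated regime
in which k-NN subject recognition is expected to be perfect. The default
design mirrors the test-retest setting the package targets: 5 subjects ×
5 scans × 90 ROIs.

**What the generator does *not* emulate.** No diffusion physics,
tractography geometry, or anatomical atlas structure; no hemispheric
symmetry; weak-edge unreliability is parametric, not mechanistic. A green
end-to-end test establishes that the pipeline recovers planted
subject structure under the stated noise model — not that it would do so
on real scans.

## Nine weighting strategies

NSTR sums streamline counts per ROI pair; PSTR divides by the
upper-triangle total (so its upper triangle sums to 1); TV sums tract
volumes; SD = 2/(gᵢ+gⱼ) × NSTR with g the gray-matter voxel counts;
ED is the dense centroid-distance matrix (computed per scan, in native
space); FA/MD/RD/ATL are streamline-count-weighted means over the records
of a pair. Count-weighting is the natural aggregation when several
bundles connect one pair; MD, RD and ED are used as-is (no inversion),
so "weight" means the measured quantity, not necessarily connection
strength — the fusion treats all nine symmetrically. Length filtering
discards records whose contiguous white-matter length is below the
threshold; the conventional sweep is 0–6 mm in 0.5 mm steps (13 values).

## Graph diffusion distance

With L = D − W, the kernel exp(−tL) is the heat/diffusion propagator;
d(t) = ‖exp(−tL₁) − exp(−tL₂)‖²_F vanishes at t → 0 and (for matching
component structure) at t → ∞, so the distance is the interior maximum
over t. The search evaluates 100 log-spaced points on
[10⁻³, 10³] / λ_max(L₁, L₂) — scaling by the largest Laplacian eigenvalue
makes the window unit-free — then refines with bounded Brent
maximization around the grid argmax. Numerical choices: symmetric `eigh`,
eigenvalues clipped at 0 from below, identical inputs short-circuit to
distance 0. Disconnected graphs are allowed (the kernel remains
well-defined).

Because the nine strategies live on incommensurate scales (mm, counts,
mm³, unitless), matrices are max-normalized to [0, 1] before the distance
by default (`normalization="max"`; `strength` and `none` are available
and recorded in outputs).

## Fusion

Fusion weights are the normalized row sums of the 9 × 9 dissimilarity
matrix — a strategy more dissimilar from the rest weighs *more*. This is
implemented exactly as specified even though an inverse convention is
also defensible; `integration_weights(..., mode="inverse")` exposes it.
The integrated network is Σₖ lₖ · Wₖ/max(Wₖ). A fully degenerate
dissimilarity matrix (all strategies identical) falls back to uniform
weights with a warning. Weights are computed independently per scan.

## OMST topological filtering

Edges are ranked by distance 1/w (strongest = shortest); Kruskal with
deterministic (distance, i, j) tie-breaking extracts a minimum spanning
forest, then repeats on the remaining edges until none are left. The
kept network is the cumulative prefix of rounds maximizing
J = GE − Cost, with Cost = selected weight / total weight and GE the
weighted global efficiency of the selected subgraph on
**max-normalized** weights. Normalizing inside GE makes J scale-invariant
(Cost already is) and keeps GE in [0, 1]; without it, J would depend on
the physical units of the weights. Ties in J prefer fewer rounds. The
filtered output keeps the original weights on surviving edges. Round 1
is a spanning tree, so the filtered network is connected whenever the
input is.

## Network metrics

All path metrics use distance = 1/w (the same convention as the MST
step). Efficiency contributions of unreachable pairs are 0; local
efficiency of a node is the global efficiency of its neighbor-induced
subgraph (0 for < 2 neighbors); characteristic path length,
eccentricity, radius and diameter are computed on the largest connected
component with a warning when the graph is disconnected (filtered
networks are connected by construction). Network-level eccentricity is
reported as the mean of node eccentricities.

## Evaluation

* **ICC**: Shrout–Fleiss from one-way/two-way ANOVA mean squares;
  ICC(1,1) is the default (repeat scans are indistinguishable sessions),
  (2,1) and (3,1) selectable. An all-constant table raises rather than
  returning 0/0.
* **Wilcoxon rank-sum**: exact enumeration when the combined sample has
  ≤ 12 untied values, tie-corrected normal approximation otherwise.
* **k-NN recognition**: leave-one-out, k = 4 by default; majority subject
  among the k nearest scans, ties broken by smaller summed distance then
  subject order — deterministic by construction. Note the chance level of
  this design is (scans−1)/(m−1), slightly *below* 1/subjects, because
  the held-out scan's own subject has one fewer candidate.
* **QCI**: equalized ratio of mean summed between-subject to
  within-subject distances. The numerator runs over all scan pairs of
  every subject pair, the denominator over unordered within-subject scan
  pairs, and the prefactor (scans(scans−1)/2)/scans² makes a constant
  matrix score exactly 1. Scale-invariant by construction.
* **MDS**: classical Torgerson double-centering with the top eigenpairs;
  negative eigenvalues (non-Euclidean distances) are truncated at zero.

## Lesion schemes

`zero_half` removes the strongest ⌊m/2⌋ incident edges of a node (ties by
neighbor index; a seeded random split is available), `diminish_half`
halves all incident edges, `combined` does both. Node influence is the
diffusion distance between original and lesioned network, normalized to
sum 1 over nodes. Cluster-wise attacks restrict the scheme to edges
within rich-club hubs, within the remainder, or between the two. The
rich-club rule (hubs = strength > mean + 1 SD; rich-club hubs = hubs
above the median within-hub strength) is a documented stand-in for an
under-specified construct and is configurable; modularity clustering uses
greedy weighted modularity maximization.

## Known limitations

* The fused "integrated" network inherits the dense ED background, so its
  density is ~100%; interpretation rests on the OMST-filtered variant.
* On this synthetic world, dense integrated networks separate subjects
  *more* sharply (higher QCI) than their OMST-filtered versions: the
  planted fingerprint lives on every edge, so filtering discards signal
  and adds tree-selection variability. On real scans, where dense
  comparisons are dominated by within-subject noise, filtering is
  expected to help instead; the package asserts this behaviour in its
  acceptance suite and reports it honestly as failing in the synthetic
  regime.
* Exhaustive OMST is O(rounds × E log E); fine to ~200 nodes, not tuned
  beyond that.
* No confidence intervals on ICC; no NIfTI/TRK input — the package starts
  at the tract-table / matrix level.
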