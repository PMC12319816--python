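# Methods

## The chance-connectivity model

Streamline endpoints inside a target structure arise from a mixture of true
anatomical connection and noise in the imaging and tracking process. The
pipeline's identifying assumption is that at least one subregion receives no
true input, so the least-connected subregion's counts are noise alone. Two
further assumptions follow from treating those counts as i.i.d. Poisson:
voxels are exchangeable (no spatial autocorrelation is modeled) and the
noise rate is homogeneous within the reference region. Under them the MLE of
the rate is the sample mean λ̂, and the significance rule "count strictly
greater than the critical count c, where c is the smallest integer with
P(X > c) < α" is a one-sided exact Poisson test. Because the statistic is
discrete, the achieved level is below α (at λ = 0.15, α = 0.05 the achieved
level is P(X > 1) ≈ 0.010); every type-I-error check in the test suite
therefore tests `≤ α + 3 SE`, not equality.

Two critical counts are computed: one from a simulated null sample (the
authoritative one, since a finite random draw is what the original pipeline
thresholds against) and one from the closed-form Poisson tail (the oracle).
They disagree only when the empirical tail mass near α fluctuates across
the boundary; at 100,000 draws that happens in well under 1% of seeds
(asserted in the suite).

λ is fitted on counts pooled across subjects and hemispheres of the single
cohort-level reference region; a per-hemisphere fit is available but one
shared null matches how the downstream proportions are interpreted.
Reference selection pools the same way (voxel-count-weighted mean) and
breaks ties lexicographically with a warning.

## Co-clustering and its sham null

The feature matrix has one row per subregion and one column per (subject,
hemisphere) — 8 × 50 in the reference design; hemispheres enter as separate
observations by default (an averaging mode exists) because left and right
connectivity are counted separately upstream. k-means with k = 2 and squared
Euclidean distance is run `n_init` times (default 1000); co-clustering
probability with the reference is the fraction of runs sharing its cluster.
k-means is implemented in-package — Lloyd alternation seeded at two distinct
random rows, assignment ties to the lower-index center, empty clusters
reseeded at the point farthest from the surviving center, convergence when
assignments stop changing (cap 300 iterations) — so that every tie-break is
specified and results are bit-reproducible from a master seed. A vectorized
multi-initialization path is used internally and is asserted identical to
the per-seed path. The statistic is invariant to common positive affine
transforms of the features, which the suite checks.

The sham condition: each permutation samples a row's worth of observations
(without replacement by default) from the pool of all entries, and that
pseudo-region's co-clustering probability with the reference forms the null.
The wording of the procedure leaves open which matrix the sham is evaluated
in; here the sham row replaces one uniformly chosen non-reference row,
keeping the matrix the same size as the real analysis (an `append` mode adds
it as a ninth row instead). One null distribution serves all regions;
per-region p-values are the plain fraction of sham values ≥ the observed
probability (a (r+1)/(n+1)-smoothed option exists). Each sham evaluation
uses `n_init_sham` initializations (default: same as `n_init`; the analysis
drivers use 100 against 1000 real initializations, trading a noisier null
for a ~10× cheaper permutation loop — the null is an average over
permutations, so this mainly widens it slightly and is conservative for the
saturated probabilities of interest).

## Overlap and density profiling

Dice is computed on binary masks sharing one grid. The `collapse2d` mode
projects both masks along the third array axis (column-wise any()) before
the overlap, reproducing a legacy behavior in which volumes were flattened
on load; it can only merge voxels, so collapsed Dice ≥ volumetric Dice is
typical and overlap can appear where none exists in 3D (demonstrated by a
constructed pair in the tests). `volume3d` is recommended for new work.
Empty∩empty is defined as 0 with a warning, keeping downstream rankings
stable.

Density profiling sums map values within each atlas region and divides by
the recorded number of seeding attempts; sums over regions plus background
conserve the map total to 1e-9 relative. Group comparisons are paired per
subject; Wilcoxon signed-rank is the default, with paired t available
because both appear in practice for this design. BH-FDR goes through
statsmodels and is checked against the definitional step-up oracle.
"Present" means normalized density strictly greater than 0 (configurable);
"1 streamline per participant" thresholds the across-subject mean map at 1
(equivalently the sum map at n — both modes exist and are asserted equal).
The upper-5th-percentile threshold uses the nearest-rank convention on each
map's non-zero values and retains strictly-greater voxels, so 100 distinct
non-zero values yield exactly 5 retained.

## The phantom generator

The generator emulates the study design the statistics assume: 8 named
subregions × 2 hemispheres × 25 subjects on a 24³ grid, 200 voxels per
region, per-voxel endpoint counts Poisson at a per-region rate, and paired
per-subject density maps over a 12-region synthetic atlas (150 voxels each,
Gaussian noise sd 2 around group means of 5, rectified at zero, 100,000
seeding attempts). Three presets fix the scenarios the analyses use:
`two_group` (four regions at rate 1.5, four at chance rate 0.15 — rates
chosen to reproduce the qualitative two-group structure, since per-region
empirical rates are not published), `null_uniform` (all regions at 0.15),
and `graded` (monotone rates). Regions are contiguous segments of a snake
traversal of the grid — connected, exactly sized, disjoint — because only
label identity enters any statistic; geometry is not anatomically
meaningful. Between-subject endpoint variability is a multiplicative
mean-one gamma factor on the rate (variance d², giving negative-binomial
margins with var/mean = 1 + λd²); the default d = 0 keeps counts exactly
Poisson, matching the fitted model. Density maps optionally share a
mean-one per-subject factor across groups (`subject_density_dispersion`) to
induce within-subject pairing; "truncated at zero" is implemented as
rectification (negatives set to 0), which at the default mean/sd ratio of
2.5 censors ~0.6% of draws.

What the phantom does *not* emulate: spatial autocorrelation of endpoints,
anatomical ROI shapes, registration error, or any dependence between the
endpoint and density channels. Passing tests therefore certify the
statistical machinery under its own assumptions, not robustness to violations
of them on real data.

All randomness descends from a single integer seed via independent
`SeedSequence` streams keyed by stable CRC tags, so identical (spec, seed)
pairs are byte-identical regardless of process or platform.

## Problem sizes and numerical choices

The analysis drivers and test suite run the reference design (8 × 2 × 25,
200 voxels/region) throughout; null calibration uses 100 replicate phantoms
at 100 initializations and 100 permutations, and the simulated Poisson null
uses 100,000 draws (20,000 inside the replicate loop, where only the
critical count — stable far from the α boundary — is consumed). Exact
oracles (2-partition enumeration, 2ⁿ signed-rank enumeration, definitional
BH) are kept at n ≤ 20 where enumeration is exact and instant.

## Known limitations

- The reference-region rate is estimated from the minimum-mean region, a
  selection that biases λ̂ slightly downward; with ≥10⁴ pooled voxels the
  bias is far smaller than the gap between consecutive critical counts and
  never moved a threshold in testing.
- Sham p-values inherit the resolution 1/n_perm; with n_perm = 1 they are
  degenerate {0, 1} by construction.
- The 2D-collapse Dice is reported for fidelity, not endorsed.
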