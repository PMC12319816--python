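# amyconn

Statistical machinery for classifying brain subregions by their structural
connectivity with a tractography seed, built for the question of which
amygdala subregions receive direct input from the human olfactory bulb.
Diffusion-MRI tractography produces, per subject, a 3D map of streamline
*endpoints* inside the amygdala and whole-brain *streamline density* maps;
`amyconn` provides the downstream statistics:

1. **Poisson chance-connectivity null.** Some amygdala subregions are known
   not to receive olfactory-bulb fibers, so the subregion with the fewest
   endpoints approximates pure noise. Its per-voxel endpoint counts are
   fitted with a Poisson law (λ̂ = sample mean); a 100,000-draw simulated
   null from Poisson(λ̂) gives the critical count *c* — the smallest integer
   such that P(X > c) < α. A voxel with more than *c* endpoints is
   significantly connected. At chance rates near λ = 0.2 and α = 0.05,
   *c* = 1: more than one endpoint per voxel is unlikely under noise.
2. **Repeated 2-means co-clustering with a sham permutation.** Each
   subregion becomes a feature row of per-(subject, hemisphere) proportions
   of significant voxels. k-means (k = 2, squared Euclidean distance) is run
   1000 times from random initializations; a region's *co-clustering
   probability* is the fraction of runs in which it shares the reference
   (chance) region's cluster. A sham pseudo-region — observations resampled
   from the pool of all regions — is clustered the same way 1000 times to
   build a permutation null, giving each region a p-value.
3. **Dice colocalization** between the chance-thresholded group endpoint map
   and each subregion ROI, 2·|A∩B| / (|A|+|B|), in plain 3D and in a
   2D-collapse mode that reproduces a quirk of the original MATLAB pipeline
   (volumes flattened along the third axis before overlap).
4. **Whole-brain density profiling**: per-atlas-region density sums
   normalized by seeding attempts, paired Wilcoxon signed-rank (or paired t)
   tests between seed groups with Benjamini–Hochberg FDR control,
   presence-in-≥50%-of-subjects summaries, and unique-vs-shared voxel
   partitions at per-participant or upper-5th-percentile thresholds.

Because cohort dMRI data of this kind are not generally shareable, the
package ships a **phantom generator** (`amyconn.phantom`) that simulates
the full study design — 8 subregions × 2 hemispheres × 25 subjects with
Poisson endpoint counts (optionally overdispersed across subjects) and
paired density maps over a synthetic atlas — so every stage is testable
end to end.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a phantom
cohort (four subregions at endpoint rate 1.5, four at chance rate 0.15,
25 subjects × 2 hemispheres):

```
python analysis/01_simulate_phantom.py
python analysis/02_endpoint_null_and_profiles.py
python analysis/03_cluster_subregions.py
```

`02_endpoint_null_and_profiles.py` prints:

```
reference (least-connected) region: BMA
fitted chance rate lambda = 0.1473 endpoints/voxel
critical count = 1 (closed form 1); voxels with > 1 endpoint(s) are significant at alpha 0.05
mean proportion of significant voxels per region:
MeA   0.451
CeA   0.445
PAC   0.445
ACo   0.442
BLA   0.012
PCo   0.012
LA    0.011
BMA   0.010
```

The four elevated-rate regions carry ~44% significant voxels, the four
chance-rate regions ~1% (P(X > 1) ≈ 0.010 at λ = 0.15 — the test is
conservative because counts are discrete). `03_cluster_subregions.py` then
reports that the three non-reference chance-rate regions co-cluster with the
reference in 100% of 1000 runs and are the only regions significant against
the sham null:

```
region  cocluster_probability  p_value  significant
   MeA                  0.000    1.000        False
   ...
    LA                  1.000    0.029         True
   BLA                  1.000    0.029         True
   PCo                  1.000    0.029         True
regions significantly co-clustered with BMA: ['LA', 'BLA', 'PCo']
```

`04_endpoint_overlap.py` and `05_connectome_profiles.py` continue with the
Dice colocalization table and the whole-brain group comparison (which
recovers exactly the atlas regions given a true simulated effect).

A CLI mirrors the scripts for use on real NIfTI inputs:
`amyconn simulate | endpoints | cluster | dice | profile --help`.

## Layout

- `src/amyconn/` — library: `phantom`, `volumes`, `endpoints`, `clustering`,
  `overlap`, `profiles`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — pytest suite (unit, property, and end-to-end statistical checks)
- `docs/methods.md` — model assumptions, parameter choices, limitations
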