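# roqa — 3D round-object quantification for µCT and confocal volumes

`roqa` segments, measures and statistically compares populations of bright,
roundish particles — typically labeled cell nuclei — in 3D grayscale
volumes such as tube-source X-ray microtomography (µCT) reconstructions or
confocal stacks. It is aimed at researchers quantifying cell populations
inside thick constructs (tissue-engineering scaffolds, organ-on-chip
devices) where optical sectioning cannot reach and where a single scan
yields thousands of objects.

## Method

The pipeline turns a grayscale volume into per-nucleus shape statistics in
five stages:

1. **Adaptive segmentation.** The volume is white top-hat transformed
   (WTH: `v − opening(v)`), which extracts bright features smaller than the
   structuring element independently of the varying local background, then
   thresholded (both band limits inclusive). Holes are filled, particles
   touching the field-of-view faces are removed (*border kill*), and a
   physical volume sieve drops sub-resolution debris. Connectivity is 26
   throughout. The WTH threshold can be tuned automatically against caliper
   axis measurements of reference nuclei taken from a higher-resolution
   image (`roqa tune`).
2. **Shape quantification.** Each voxel particle is meshed (marching cubes
   at the 0.5 iso-level of its padded mask) and an ellipsoid is fitted to
   the mesh vertices by algebraic linear least squares on the general
   quadric. With ordered semi-axes a ≥ b ≥ c the pipeline reports

   - flatness `c/b`, elongation `b/a`, anisotropy `1 − c/a`,
   - sphericity `π^(1/3) (6V)^(2/3) / A` from the mesh volume and area,
   - diameters `2a, 2b, 2c`, voxel volume, and mean signal intensity.

3. **Quality screening.** The *ellipsoid-to-voxels volume ratio*
   `(4/3)πabc / V_voxels` is ≈ 1 for well-segmented round objects; fits
   outside the 0.8–1.2 band (and non-ellipsoidal "hyperboloid" fits) are
   rejected as anomalies — most are fused aggregates of proximate nuclei.
4. **In silico disintegration.** Rejected aggregates are reprocessed:
   unsharp masking re-sharpens the blurred interfaces, H-maxima (regional
   maxima with dynamic ≥ h) mark one core per nucleus, and marker-based
   watershed flooding of the inverted intensity cuts the aggregate along
   the watershed lines into daughter particles, which are re-sieved and
   re-quantified.
5. **Group statistics.** Two groups are compared per measure with medians,
   semi-interquartile ranges (SIQR = (Q3−Q1)/2) and the two-sided
   Wilcoxon–Mann–Whitney test; a difference counts as *well resolved* only
   when |Δmedian| exceeds the average SIQR, guarding against the tiny p
   values that large samples produce even for overlapping distributions.

A synthetic phantom generator (`roqa simulate`) renders voxelized rotated
ellipsoids with dome-shaped intensity profiles, background, blur, noise and
optional fused pairs, together with analytic ground-truth tables, so every
stage is testable without any raw scan data. Small imaging-geometry
helpers compute the focal-spot penumbra `f·ODD/SOD` and the Nyquist minimum
resolvable spacing `2 × voxel`.

## Worked example

```sh
$ roqa simulate --seed 42 --n-nuclei 8 --shape 128 128 128 \
      --fused-pair-fraction 0.25 --out scene
wrote scene.tif and scene_truth.csv (8 nuclei)

$ roqa run scene.tif --preset phantom --spacing 1.1 1.1 1.1 --out out
accepted 8, rejected 2 particles
```

The bookkeeping table (`out/bookkeeping.csv`) shows the particle flow: the
8 simulated nuclei segment into 6 particles (two fused pairs each merge
into one aggregate), the two aggregates fail the quality screen — one with
an out-of-band ratio, one as a hyperboloid fit — and watershed
disintegration recovers 2 daughters from each, for 8 accepted records:

```
labeled,6
after_sieve,6
quantified,6
fit_invalid,1
ratio_accepted,4
ratio_rejected,1
disintegration_parents_in,2
disintegration_daughters_cut,4
disintegration_daughters_accepted,4
```

Comparing a control arm against a "cytoskeleton-relaxed" arm (flatness
distributions 0.45 vs 0.70, 60 nuclei per group through the full pipeline):

```
$ roqa compare control.csv treated.csv --measures flatness,elongation,sphericity
   measure  median_a  median_b  median_difference  average_siqr      p_value  well_resolved
  flatness  0.456587  0.712813           0.256226      0.055579 4.643389e-20           True
elongation  0.812969  0.779351          -0.033618      0.043293 1.234445e-01          False
sphericity  0.787790  0.874965           0.087175      0.022954 1.165605e-19           True
```

Flatness and sphericity shift strongly toward rounder nuclei and are well
resolved (|Δmedian| > average SIQR); elongation, which was not varied,
stays statistically indistinguishable.

```sh
$ roqa geometry penumbra --focal-spot 7 --sod 60 --odd 15
1.7500 µm
```

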