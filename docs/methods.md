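# Methods

## The assay being modelled

Artificial axons (AAs) are vertical hydrogel micropillars (~8 μm diameter,
~20 μm tall, 20 μm center-to-center spacing) printed into 96-well plates and
seeded with oligodendrocyte progenitor cells. After dosing with candidate
pro-myelinating compounds, wells are imaged by confocal microscopy in three
channels — pillars (rhodamine), myelin membrane (MBP immunostain), nuclei
(DAPI) — as z-stacks of 10 slices at a 2 μm step, 9 fields of view (FOV) per
well, 3 replicate wells per condition. The analytic task is to turn those
stacks into a per-compound dose–response readout of *3D myelin wrapping*.

## Wrapping quantification

For each z-slice, the pillar and myelin channels are binarized. Each
detected pillar contributes a 1-px **inner outline** (the region minus its
erosion by a 3×3 structuring element), a discretization of its
circumference. The **overlap mask** assigns 255 to outline pixels that are
myelin-positive and 0 to outline pixels without myelin; the **wrap
fraction** of the slice is the 255-count over the outline size, i.e. the
fraction of the circumference covered by myelin.

Per-slice fractions are aggregated along z. Maximal runs of consecutive
slices with wrap fraction strictly above 0.8 form **ensheathed segments**;
a segment of *n* slices has physical length *n* × z-step (so three slices at
2 μm ⇔ 6 μm; the convention is count × step, not (count−1) × step). A
pillar is **fully wrapped** when some segment is at least 6 μm long — i.e.
at least three qualifying consecutive slices at the default geometry.
Slices in which the pillar mask is undetected break contiguity: the
circumference is unmeasurable there, and assuming continuation would inflate
segment lengths.

Each pillar is also assigned one exclusive **wrapping-extent category** by
its maximum per-slice fraction, with bins [0, 0.2], (0.2, 0.5], (0.5, 0.8],
(0.8, 1.0]. (An alternative convention assigns a pillar to every category
that any of its slices visits; the exclusive max-based binning is used
because it makes per-condition category percentages sum to 100%.)

The field-level **wrapping index** is the number of fully wrapped pillars
divided by the number of nuclei in the FOV, which normalizes away local
cell-density variation. A FOV with zero nuclei has an undefined index; it is
flagged invalid and excluded from condition averages. Pillars touching the
field border are excluded outright — their circumference is not fully
observable, which would bias wrap fractions downward.

## Segmentation choices

* **Thresholding.** Default Otsu. The axon channel is thresholded per slice
  (pillars appear in every slice, so each slice histogram is bimodal). The
  myelin and nuclei channels default to a single *global* Otsu threshold
  over the whole channel: these channels can contain signal-free slices, and
  per-slice Otsu on a unimodal noise histogram splits the noise itself,
  flooding the slice with false foreground. All three methods
  (`otsu_per_slice`, `otsu_global`, `fixed`) are available per channel. A
  constant-intensity slice under Otsu falls back to an all-background mask
  with a logged warning.
* **Pillar detection.** 8-connected components per slice, linked across z by
  XY centroid proximity (tolerance ≈ pillar radius, default 6 px). Pillars
  are vertical by construction, so this is exact without general 3D
  tracking. Components outside an area window are discarded.
* **Nuclei.** Counted as connected components on the maximum-intensity
  projection of the nuclei masks (the count is therefore invariant to slice
  order), with a minimum-area filter and an optional distance-transform
  watershed for merged blobs.

## Sheath-length analysis

Sheath length — the axial extent of one ensheathed segment — is pooled over
all segments of all non-border pillars at a condition (a pillar with several
discrete sheaths contributes several lengths). Summaries use boxplot
conventions: quartiles by linear interpolation between order statistics,
whiskers at Q1 − 1.5·IQR and Q3 + 1.5·IQR, values outside reported as
outliers. Histograms of lengths ≥ 6 μm use a 2 μm default bin width, one
z-step, because lengths are quantized at that resolution. The wrapping index
can be recomputed under any minimum-segment-length threshold (default
comparisons: 6 μm vs 10 μm); it is monotone non-increasing in the threshold.

## Dose–response model

Condition responses (wrapping index, or MBP-positive area for the 2D
differentiation assay) are averaged over all FOVs pooled across replicate
wells (3 × 9 = 27 at the full design), with SEM over FOVs. Each compound's
series is fitted by unweighted least squares with the four-parameter
logistic

    R(c) = bottom + (top − bottom) / (1 + (EC50 / c)^hill)

parameterized in log10(EC50), with EC50 bounded to [c_min/100, c_max·100],
hill in [10⁻³, 20], and initialization bottom = min mean, top = max mean,
EC50 = geometric mean of tested concentrations, hill = 1. Weighting is
unnecessary because FOV counts are balanced by design. A flat series (zero
observed range) is degenerate and reported as non-converged.

* **Cytotoxicity exclusion.** Concentrations at and above the lowest dose
  whose mean nuclei count falls below 50% of the vehicle mean are excluded
  from the fit (the fraction is configurable). Exclusion never re-admits
  higher doses.
* **EC50 / plateau rule.** EC50 is *undetermined* when the fit fails, when
  the response is still rising at the highest included dose (maximum mean at
  the top dose and fitted top exceeding it by > 20%), or when the fitted
  EC50 is at or beyond the highest included concentration.
* **Efficacy** is the maximum *observed* included condition mean — taken
  from the raw data, never from the fitted top — with the SEM of that peak
  condition. **Relative efficacy** divides by the reference compound's
  efficacy (T3 by convention), exactly 1 for the reference; its SEM uses
  first-order ratio propagation. No vehicle baseline subtraction is applied:
  the index is reported directly, with the vehicle carried as a
  concentration-0 row.
* **Ranking.** Compounds sort by efficacy descending; adjacent compounds are
  tied when a two-group one-way ANOVA on their FOV-level peak-dose responses
  gives p ≥ 0.05 (for two groups this is identical to the two-sided t-test,
  F = t²). Tie groups take competition ranks. No multiplicity correction is
  applied by default (pairwise tests mirror the assay's reporting style); a
  Bonferroni-corrected alpha can be passed instead.

## Synthetic data generator

Because the assay's raw stacks are not publicly deposited, the generator
renders fields with exactly known ground truth at the study geometry:
0.65 μm/px sampling (a typical 20× air-objective digitization — the true
sampling is not published, so this is a configurable default), 512×512
default FOV, 10 slices at 2 μm, 8 μm pillar discs on a 20 μm square grid
(the lattice type is not published; square is the simplest layout matching
the printed spacing). Myelin is drawn as an annular arc concentric with each
pillar whose angular extent equals the requested per-slice coverage, with a
seeded random start angle (azimuthal position is not reported and results
must not depend on it). Nuclei are disjoint discs in a single designated
slice, counted on the projection. Noise is additive Gaussian on a constant
background — the simplest model that stresses thresholding; Poisson shot
noise is noted as future work.

Rendered arc coverage differs from the requested angular fraction only by
outline rasterization (empirically ≤ 0.05 on the ~40 px outlines at default
geometry). Test fixtures therefore draw true coverages at least 0.1 away
from the 0.8 classification threshold, so noiseless analysis must recover
full-wrap labels exactly; values near the threshold would make labels
sensitive to sub-pixel rasterization, which is a property of any pixel-level
pipeline, not of this implementation.

Simulated plates map each condition's true 4PL response to a per-pillar
Bernoulli probability of full wrapping such that the *expected* wrapping
index equals the true response; FOV-to-FOV variability then arises naturally
from binomial sampling rather than from an ad-hoc noise term. Optional
per-condition nuclei multipliers emulate cytotoxic cell loss at high doses.

What the generator does **not** emulate: optics (PSF, bleaching), cell-body
and process morphology, myelin deposited off-pillar, partial-height pillars,
and uneven illumination. Passing the recovery tests therefore shows the
analysis is exact on geometry-faithful inputs, not that it is robust to all
real-microscopy artifacts.

## Problem sizes used in the test suite

Unit tests run on 128×128 fields (16 pillars); the end-to-end screen test
uses 2 compounds × 9 concentrations × 3 wells × 3 FOV at 256×256 px
(64 pillars/FOV, 171 stacks), a deliberate scale-down of the full design
(9 FOV/well, 512×512) that preserves the statistical structure: pooled-FOV
averaging, binomial FOV noise, and a 9-point 3× dilution series from 10 μM.
The 4PL noise-recovery test applies replicate noise of 10% of the top
response at n = 27 replicates per concentration — the full design's FOV
count — and fits the condition means, since that is where noise enters the
real assay.

## Known limitations

* Wrap fractions are pixel-level; very small pillar radii (< ~4 px) make the
  outline too coarse for the 0.8 threshold to be meaningful.
* Axon linking assumes vertical pillars; tilted or drifting structures would
  need true 3D tracking.
* The cytotoxicity rule (50% of vehicle nuclei) is this package's default;
  the original study excluded cytotoxic doses without publishing a rule.
* EC50s from 9-point series with free hill are ill-determined when the true
  EC50 sits near the edges of the tested range; the plateau rule reports
  such cases as undetermined rather than extrapolating.
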