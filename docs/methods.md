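# Methods

This note documents the models and measurement procedures implemented in
`nichescape`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Coordinate and unit conventions

Images are `channel × row × col` arrays with 0-based indices, origin at
the top-left corner; x runs along columns, y along rows.  Pixel `(r, c)`
has its centre at `((c + 0.5)s, (r + 0.5)s)` µm for pixel size `s`.  All
physical quantities are µm (distances), µm² (areas) or percent.  An image
without a resolvable pixel size is rejected: every downstream measure is
physical.

## Vessel segmentation and the distance field

Endothelial signal (CD31-like channel) is thresholded (Otsu by default; a
fixed threshold is available for reproducing observer-set values) and
connected components are kept only if they are at least `min_area_um2`
(default 20 µm²) and have a second-moment-ellipse major/minor axis ratio
of at least `min_elongation` (default 2.5).  This renders "elongated
structures, distinct from punctate background" as a single auditable
statistic: round debris and antibody speckle fail the elongation test,
capillary profiles pass.  The distance field is the exact Euclidean
distance transform of the mask complement (`scipy.ndimage`), pixel centre
to pixel centre, scaled to µm; it is 0 on vessel pixels and undefined
(flagged, +inf) for an empty mask.  Per-cell distance is the field value
at the pixel containing the centroid; no sub-pixel interpolation is done
because the half-pixel quantisation (≤ 0.35 µm at 0.5 µm/px) is far below
the µm-scale effects of interest and unbiased on average.

Region metrics assign a pixel to a subregion polygon if its centre lies
inside or on the boundary (boundary-inclusive; ties between adjacent
regions go to the first-listed region).  Percent area is
`100·|mask ∧ region| / |region|`; overlap fraction is
`100·|num ∧ den ∧ region| / |den ∧ region|`, undefined where the
denominator is empty.

## The systematic random null and the association index

Sample stations are placed along the SGZ midline at a fixed arc-length
spacing (default 100 µm) starting from a seeded uniform offset in
`[0, spacing)`; the random start avoids phase-locking artifacts between
the station grid and any periodic structure.  Each station snaps to the
nearest Hoechst+ nucleus inside the band (within half the spacing);
duplicates are used once, stations with no eligible nucleus are skipped
with a warning.  The association index of phenotype `p` in animal `a` is
`mean distance of p-cells − mean distance of null nuclei`, pooling all of
the animal's sections for both terms.  Negative values mean preferential
vessel association.  Analysis is strictly hierarchical: cells → animal
means → group tests; cell-level mixed models are out of scope.

## Statistics

Two groups: Welch t (unequal variances), two-sided.  More groups: one-way
ANOVA; two crossed factors (e.g. treatment × experiment block): two-way
ANOVA with interaction, the main effect of the first factor being the
headline test.  Post hoc pairwise comparisons are Welch t tests with
Holm–Šídák adjustment.  α = 0.05.  Degenerate input with identical values
in both groups returns statistic 0 and p = 1 rather than NaN.  The type-I
rate of the two-group path is verified by simulation (1,000 null cohorts)
in the test suite.

## Puncta counting

Spots are local intensity maxima above a threshold (Otsu on the puncta
channel by default) with a minimum peak separation (default 2 px),
assigned to the labeled nucleus containing them; maxima outside all nuclei
are reported separately.  Counting is 2D; spots merged below the minimum
separation count once — a documented undercount shared by target and
reference phenotypes, so percent differences are only weakly affected.
The percent difference uses an explicit reference phenotype:
`100·(mean_ref − mean_target)/mean_ref` per animal, summarised as
mean ± SEM over animals.

## Assay metrics

Scratch ingression is `1 − area(t)/area(0)` per well, each scratch
normalised to its own 0 h area; 0 is no closure, 1 complete closure.
Negative values (widening) are reported and flagged, never clamped.
Image-based area measurement takes the largest below-threshold connected
component as the cell-free region.  Nucleus counting is threshold →
connected components → size filter (≥ 20 µm² by default); touching nuclei
merge and undercount, a property shared by pre- and post-detachment images
of the same well.  Retention is `100·post/pre` per well (pre- and
post-images are assumed registered by acquisition position — an input
contract, no registration is attempted).  The treatment effect is the
per-pair percent reduction `100·(1 − retention_treated/retention_vehicle)`
over adjacent well pairs, tested across experiment blocks by two-way
ANOVA.

## The synthetic niche generator

The generator emulates the *statistical structure* of the measurements,
not microscopy physics.  One section comprises:

- **Midline and regions.** A gentle sinusoid spanning the frame (default
  192 × 800 µm at 0.5 µm/px), amplitude capped so the curvature radius
  exceeds the outermost region offset (offset band polygons stay simple).
  Subregions are offset bands: SGZ = ±10 µm around the midline ("two cell
  body widths"), GCL and ML above, hilus below.
- **Vasculature.** Capillaries are smooth splines roughly parallel to the
  midline: lanes evenly spaced across a ±25 µm corridor (lane count set by
  `vessel_density_um_per_um2`, default 0.05 µm/µm²), each with per-animal
  offset jitter (σ = 2 µm), a smooth transverse meander (σ = 3 µm per
  60 µm control point), and exponential present/absent runs (35% gap
  fraction, 60 µm scale) reflecting that a single optical plane catches a
  capillary bed discontinuously.  Centrelines are dilated to the tube
  radius (2.5 µm).  This architecture is stereotyped across animals —
  matching the consistency of the SGZ plexus — which keeps the per-animal
  random-baseline distance stable (SD ≈ 1.6 µm per section) while still
  spanning a 0–20 µm distance range with a ~4–5 µm baseline and a CD31
  area fraction of ~6–7%, plausible against DG percent-area measurements.
- **Cells and nuclei.** Random nuclei (30 per 100 µm of midline) and
  phenotype cells share one transverse law: uniform along the arc, normal
  across the band (σ = halfwidth/2, truncated), so the random-nucleus
  baseline and the cell candidate pool are exchangeable by construction
  and a zero offset produces zero association.  Astrocytes are placed in
  a hilar strip instead.  A phenotype with target offset Δ is drawn from a
  large candidate pool by exponential tilting: weights `exp(λ·d)` with λ
  solved (Brent) so the weighted mean distance equals baseline + Δ.  The
  offset is thus a property of the *mean*, not a per-cell constraint,
  which is how the source measurements are reported.  Targets slightly
  beyond a section's achievable range (possible when an animal-level
  deviate meets a vessel-rich section) are clamped to the range edge with
  a warning; targets more than 1 µm outside raise.
- **Cohorts.** Each animal receives its group's offsets plus an
  independent normal deviate (default σ = 0.8 µm, drawn per animal and
  phenotype) and contributes `n_sections` (default 4) independent
  sections, mirroring section-series sampling per mouse.  With the
  default cell numbers (15–20 per phenotype per section) the per-animal
  SD of mean distance is ≈ 1.0–1.3 µm, making simulated group SEMs the
  same order as those printed for the in-vivo cohorts.  All seeds derive
  from one master seed via `numpy.random.SeedSequence` spawning; identical
  config + seed gives bit-identical arrays and tables.
- **Rendering.** Channels are foreground/background intensity maps
  (vessel mask, stamped nucleus disks) smoothed with a σ = 1 px Gaussian,
  plus additive read noise and intensity-proportional shot noise.  There
  is no PSF model, no z-dimension, no autofluorescence, no illumination
  gradient.
- **Puncta, scratch, attachment.** Puncta images draw Poisson counts per
  nucleus and place spots on the pixel grid with a Chebyshev minimum
  separation (conservative for detectors with square suppression
  footprints); overcrowded nuclei warn and record possible merges.
  Scratch areas follow a linear closure `A(t) = A0·max(0, 1 − rate·t)`
  with multiplicative log-normal noise (CV 3%); truth stores the noiseless
  trajectory.  Attachment wells seed `Poisson(n)` nuclei on a jittered
  grid (guaranteed separation, so automated counts are exact) and retain
  a binomial draw at the treatment's retention fraction, re-imaged at the
  same positions.

**What passing tests show — and do not.**  Recovery tests demonstrate
that the measurement chain is unbiased and correctly calibrated *given*
images whose segmentation is easy and whose annotations are correct.  They
do not validate performance under real-microscopy nuisances (uneven
illumination, autofluorescence, anisotropic PSF, section warping,
imperfect marker thresholds); on real data the segmentation and threshold
parameters are the user's responsibility.

## Problem sizes

The default validation cohorts are 8 vs 8 and 10 vs 12 animals with 4
sections each at 192 × 800 µm per section; RNAscope validation uses 4
animals × 120 nuclei; attachment validation uses 3 experiments × 3–4 well
pairs × ~1,000 cells/well.  These sizes put every simulated SEM at or
below the scale of the effects being recovered while keeping a full run in
the order of a minute.

## Known limitations

2D only (planar sections); no vessel centreline/graph extraction or
tubeness filtering; morphology flags (radial process, bipolar, primary
dendrite) are inputs, never inferred from pixels; no mixed-effects models;
scratch closure is linear rather than mechanistically modelled; the
generator's marker calls are noiseless booleans.
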