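# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `choroidmap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

Volumes are indexed `[z, x, y]` = [axial sample, A-line, B-scan]. Axial
index 0 is the zero-delay line; depth increases with z. The axial sample
pitch is specified in air (`axial_spacing_air_um`, default 10 µm ≈ the
system's axial resolution in air); geometric distances inside tissue
divide by the tissue group index (default 1.38). This tissue index is
distinct from the whole-eye group index n = 1.3375 used by the
axial-length formula: the former converts the axial sampling pitch to
geometric µm inside retina/choroid, the latter scales a whole-eye
optical path. In the raw scanner frame x increases temporally for right
eyes (OD) and nasally for left eyes (OS); laterality normalisation
(mirroring so "nasal" points toward the optic disc) happens in thickness
mapping, never in I/O. Derived tables are in mm relative to the fovea.

## Synthetic eye model

The generator emulates a 10 × 5 mm posterior-pole raster centred near
the fovea. Per eye it draws, from a seeded generator:

- nine per-sector CT targets from configurable normals (clamped at a
  20 µm floor), defaults from published group statistics for low /
  moderate / high myopia; superior/inferior sectors, for which no group
  statistics are published, default to the mean of the same-ring nasal
  and temporal entries;
- axial length from the group's normal (means 24.619 / 25.413 /
  25.983 mm, SDs 0.016 / 0.022 / 0.021 mm);
- refractive error uniform within the group's range (no within-group
  distribution is published; uniform is assumed);
- geometry: RPE bowl depth 850–950 µm with curvature 3–5 µm/mm² and
  tilt ≤ 8 µm/mm, retina 280–320 µm, foveal pit 100–140 µm deep with
  0.35–0.45 mm Gaussian radius, pit centre jittered ±0.15 mm;
- a per-B-scan axial motion trace, iid uniform integers in ±4 px with
  the first entry 0.

**CT field.** The field is a smooth blend of nine per-sector plateaus:
erf transitions in radius and polar angle (radial transitions at 0.68
and 2.30 mm with 0.12 / 0.15 mm widths, angular transitions of 16° at
the 45° diagonals). The plateau parameters are solved from a 9 × 9
linear system so that the drawn targets are the field's **exact sector
means** over the scan area; sectors whose in-scan support is too small
to condition the system (the superior/inferior outer sectors of a
10 × 5 mm raster, diagonal weight < 0.55) are pinned to their targets.
Both radial transitions are placed inside the large inner-ring sectors
so the fovea disk and the outer ring — including the 5-mm profile bins —
sit on-plateau; consequently the field at the pit centre equals the
drawn Fovea value, and the nasal 5-mm ring bin is an unbiased probe of
the drawn nasal-outer value. An earlier design interpolated the nine
targets with radial basis functions at sector centroids; it was dropped
because the interpolant's sector means deviated from the targets by up
to ~10 µm, consuming most of the recovery tolerance. The CSI surface is
placed at the drawn CT distance along the local RPE normal (fixed-point
solve for the normal's foot point).

**Rendering.** Each A-line's reflectivity is a sum of erf-smoothed
plateaus — vitreous 0, retina 0.25, RPE band 1.0 (25 µm thick, ending
at the outer RPE), choroid 0.08, scleral band 0.45 (250 µm) — so every
boundary the segmenter looks for is a step edge at exactly the truth
position. Amplitude is attenuated as 2^(−depth/3 mm) (6 dB sensitivity
roll-off at 3 mm), multiplied by unit-mean exponential speckle (fully
developed speckle; the intensity statistics, not the interferogram, are
modelled), and offset by a 0.02 noise floor. Motion is applied as an
integer roll per B-scan with vacated rows at the noise floor. There is
no k-space/spectrometer simulation, no transverse motion, and no blink
artifacts.

**What passing recovery tests show.** The generator's boundaries are
clean step edges with analytically known positions; real choroids have
vessel shadowing, heterogeneous texture and a far less distinct CSI.
Recovery of the configured group statistics therefore validates the
pipeline's geometry, statistics and noise robustness — not clinical
segmentation accuracy on pathological scans.

## Motion correction

Laterally averaged axial profiles of adjacent B-scans are registered by
normalized cross-correlation over ±`max_shift` (default 8 px), with
parabolic subpixel refinement of the correlation peak (ties resolve to
the smaller |lag|; a perfect integer-lag match is not "refined").
Each pairwise estimate is quantised to the nearest integer before
chaining into the cumulative trace (referenced to B-scan 0): saccadic
motion displaces B-scans by whole pixels, while the anatomical depth
trend between neighbouring B-scans (tilt + bowl curvature at the default
78 µm B-scan pitch) stays below half a pixel, so quantisation separates
motion from anatomy instead of flattening the eye. Correction applies
the negated integer trace as a roll (no interpolation blur); vacated
rows take the volume's noise-floor median; raw subpixel steps are kept
for audit. Consequences: injected integer traces are recovered exactly
on speckle-free renders, and the pass is idempotent.

## Segmentation

`segment_surface` is a dynamic-programming minimum-cost path through a
per-polarity cost image (−∂I/∂z for dark-to-bright, +∂I/∂z for
bright-to-dark, −I for ridge; centered differences, one-sided at the
borders) under a per-column step bound, with parabolic subpixel
refinement of the cost. It is exactly optimal — verified against
exhaustive path enumeration on small images.

`segment_volume` finds, per B-scan: the bright RPE band by ridge search;
the outer RPE edge (bright-to-dark) just below it; the ILM
(dark-to-bright) above it; and the CSI (dark-to-bright into the scleral
reflectivity) in a band 10–600 µm below the outer RPE. Column validity
requires the expected bright/dark contrast (12% of the volume's p99–p50
intensity range) across the detected edge; B-scans under 50% joint
validity are wholly invalidated; a 3 × 3 median pass and the
ILM ≤ RPE ≤ CSI ordering are applied per surface.

Processing adapts to the measured speckle contrast (local std/mean in
bright tissue; > 0.2 ⇒ speckled): speckled volumes get lateral
pre-smoothing σ = (1, 2) px, DP step bound 3 and the median pass;
near-noiseless volumes get σ = (1, 0.8), step bound 6, no median, and a
per-column refinement on a depth-only-smoothed image that removes the
lateral drag of smoothing where surfaces bend. One deterministic code
path; the adaptation exists because strong lateral smoothing is what
makes speckled edge statistics stable, yet the same smoothing is the
dominant error source on clean data. Manual correction is out of scope;
an `overrides` hook accepts externally supplied surfaces instead.

The dual-analysis rule compares the CT maps of two segmentation
configurations (the second uses σ = (1.5, 2.25) and a 5 × 5 median) on
map means; eyes with fractional discrepancy > 0.15 are excluded before
any statistic. A per-pixel variant is available by flag.

## Thickness mapping

CT is measured along the unit normal of the Gaussian-smoothed
(σ = 0.2 mm) RPE surface: a ray marches from each RPE point in 0.25-px
steps, the bilinearly interpolated CSI surface is tested for a sign
change, and the crossing is linearly interpolated; cells with no
crossing within 1000 µm, or whose ray exits the grid or samples invalid
CSI, are NaN. For parallel planes tilted by θ this yields exactly the
vertical separation × cos θ (asserted analytically in the tests).

The fovea is the maximum of the σ = 0.25 mm-smoothed ILM depth within
the central 60% of the scan, refined by a centre of mass over the
deepest 5% of pit pixels; a smoothed depth range under 5 µm raises an
explicit no-pit error (manual centre advised). Sectors use half-open
radial bins (Fovea r < 0.5; inner 0.5–2.5; outer 2.5–5 mm) and 45°
diagonal boundaries with ties assigned to the horizontal quadrants — a
deterministic partition of the 10-mm disk whose area-weighted sector
means conserve the disk mean to 1e-6 relative. Sectors with < 25% valid
in-scan area are flagged missing. The ring profile averages 90°
horizontal wedges in 1-mm annuli out to ±5 mm (bin 0 = the fovea disk);
by construction bins ±1 cover 0 ≤ r < 1 and therefore overlap the
central disk — the bins need not partition. Note the superior/inferior
outer sectors of a 10 × 5 mm raster are mostly outside the scan; their
reported means describe only the in-scan sliver.

## Axial length

Peak detection takes the strongest local maximum above 5× the median
amplitude in the retinal window (first 40% of samples — the corneal line
sits ~4 mm into a ~6 mm window) as the foveal RPE peak, the strongest
beyond it as the cornea, each parabolically refined. The dominant
(RPE) peak is used as the retinal reference, consistent with defining
the length to the RPE. Reported IOL is rounded to 3 decimals only at
presentation. The RM1/RM2 hardware calibration is represented solely by
the ΔL_ref constant.

## Cohort statistics

Groups: low |D| ≤ 3, moderate 3 < |D| < 6, high |D| ≥ 6 (hyperopic
input is rejected). Tables report mean and sample STD (n−1); empty
cells are missing, never zero. The t-test is the classical
pooled-variance two-sample Student's t with df = n_a + n_b − 2
(Welch by flag); zero pooled variance degenerates to (0, 1) for equal
means and (±∞, 0) otherwise. No multiple-testing correction is applied
(none is used in the source statistics). Reduction rates divide the
difference of adjacent group means by a 3 D span — the span between
group midpoints, inferred from the published rates (31.28 =
(273.85 − 180)/3; 13.49 = (180 − 139.54)/3). The analogous
moderate→high axial-length rate computes to (25.983 − 25.413)/3 =
0.190 mm/D; the previously reported 0.137 mm/D is not reproducible from
the stated group means and the formula value is reported instead. A
published moderate-TIM SD appears both as 27.28 and 27.78; the
tabulated 27.78 is used.

## Problem sizes and tolerances

Default volumes are 256 axial × 256 A-lines × 64 B-scans (the full
512 × 256 raster is available by configuration); cohort recovery runs
use 20 low-myopia and 10 moderate-myopia eyes, matching the study
design, and complete in a few minutes on one CPU. Recovery tests accept
cohort means within 2 standard errors of the configured group
parameters for the three headline cells, and within a Bonferroni-sound
3 SE simultaneous band when all 15 published group × sector cells are
checked at once (15 simultaneous 2 SE tests would fail by chance with
probability ≈ 0.5). Surface-recovery tolerances: ≤ 1 axial px
(speckle-free, max over 10 seeds), < 2 axial px mean absolute error
(default speckle). All randomness flows through explicit integer seeds.

## Known limitations

- Speckle is multiplicative-exponential on intensity; no spatial
  speckle correlation, vessel shadows or layer texture.
- Maximum-gradient edge localisation under multiplicative noise has a
  small residual bias toward the bright side (≈ 0.5–1 px on the RPE
  edge); it largely cancels in the CT difference (net ≈ +2–3 µm, well
  inside the recovery tolerances).
- No lateral magnification correction by axial length; lateral
  positions assume the nominal scan extent.
- The 15% dual-analysis rule compares two automated configurations, not
  two human graders; with deterministic segmentation it rarely excludes.
- Ring-profile bins at ±5 mm can be clipped by the scan edge for eyes
  with a laterally jittered fovea; empty bins are flagged, not zeroed.
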