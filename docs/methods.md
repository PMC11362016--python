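# Methods

`thymoquant` re-implements, as a tested library, the quantification
machinery used to measure age-related structural change in the thymus:
volumetric segmentation of thymic regions, nuclear-spot classification and
cross-lobe cell-count estimation, the single-cell quality-control and
signature procedures, and injury-recovery statistics.  Every stage can be
exercised on seeded synthetic data with known ground truth; this note
records the models, the defaults, and the choices made where the design
was genuinely open.

## Coordinate and unit conventions

Volumes are indexed `(z, y, x)`; spacing is the per-axis voxel pitch in
micrometres, and the physical coordinate of voxel `(i, j, k)` is
`(i·sz, j·sy, k·sx)` (0-based, grid registered at voxel centres).  Two
spacing presets mirror the instruments used in this field: light-sheet
`(4.9, 0.915, 0.915)` μm and confocal `(2.0, 0.22, 0.22)` μm.  Signed
distances are negative inside a surface, so the classification rules
"distance ≤ 0" (inside or on the medullary/HD surface) and
"distance ≥ −25 μm" (within 25 μm inside the section edge) read literally.

## The lobe phantom

The image phantom emulates a two-channel nuclear-reporter scan of one
thymic lobe:

* an ellipsoidal lobe (default semi-axes 135 × 105 × 105 μm — a
  scaled-down lobe that fits a 64 × 256 × 256 grid at light-sheet
  spacing);
* five medullary blobs (radius 28 μm) placed deep enough that blob plus
  shell clear the surface by 20 μm; blobs may merge, as real medullary
  islands do;
* peri-medullary high-density (HD) shells, thickness 30 μm, covering a
  configurable fraction of each blob's boundary as a randomly oriented
  spherical-cap sector (`hd_fraction`, the fraction of medullary boundary
  coated; 0 reproduces the young-thymus limit with no HD at all);
* nuclei placed by an inhomogeneous hard-sphere Poisson process (minimum
  centre-to-centre distance 2 × nuclear radius, default radius 2 μm) and
  rendered as Gaussian spots (PSF σ = (3, 2, 2) μm by default), then
  corrupted with `Poisson(scale·I)/scale` noise plus additive Gaussian
  noise (σ = 2 intensity units against a single-nucleus peak of 100).

All nucleus populations — the GFP-labelled subsets, the rendered
tdTomato subset, an invisible space-filling remainder standing in for
the unlabelled cells that pack real tissue (`packing_density`, default
8.5 × 10⁻³ μm⁻³), and an unlabelled exterior ring surrounding the lobe —
are placed in a single hard-sphere pass, so populations compete for
space across every boundary.  Without the filler, per-region rejection
sampling crowds nuclei against region surfaces (a random-sequential-
adsorption edge artefact, ~15–20% interior depletion for the HD shells);
without the exterior ring, the vacuum outside the organ enriches the
outermost cortical layer the same way.  With both, realized densities
are uniform to within counting noise, which is what makes densities
measured in region interiors transferable between samples.

Default densities are free parameters of the generator — the source
protocol reports none — chosen once to be biologically plausible and to
respect the qualitative ordering the imaging shows (compacted HD ≫
medulla ≫ sparse cortex): cortex 1.2 × 10⁻⁴, medulla 3.5 × 10⁻³, HD
8 × 10⁻³ nuclei·μm⁻³, with a ubiquitous tdTomato background of
5 × 10⁻⁴ μm⁻³ everywhere except HD regions, which are devoid of tdTomato
nuclei.  The HD value sits at ~70% of the random-sequential-adsorption
jamming limit for 4-μm hard spheres (≈1.1 × 10⁻² μm⁻³), which the
generator treats as a hard error if exceeded.

One property of the generator matters for interpretation: the rendered
intensity of a region fluctuates with the local nucleus count inside the
smoothing kernel, so segmentation boundary placement carries an
irreducible wander of ±2–3 μm at the default densities; the segmentation
accuracy expectations below were set with that limit in mind.

What the phantom does **not** emulate: depth-dependent attenuation,
spectral bleed-through, optical aberrations, nucleus shape and size
variation, or autofluorescence.  A pipeline that passes on phantoms is
validated for its geometry and statistics, not for instrument artefacts.

## Region segmentation

`segment_dense_region` implements the published pipeline order exactly:
channel summation, per-slice 2D median filter (radius 2 px), 3D Gaussian
in physical units (default σ = 5 μm, divided by the per-axis spacing),
per-slice min–max normalization with a fractional threshold, closing,
small-component removal (default 10⁴ μm³), and restriction to a parent
mask.  Because the original thresholds were set interactively from
fluorescence intensity and are unrecoverable, the threshold is exposed
three ways: a per-slice min–max fraction (default 0.5, the literal
reading), a per-volume min–max fraction, and an automatic Otsu threshold
(optionally gated on class separation).  Slices whose min equals max — or
whose dynamic range is below 5% of the volume's — contribute no
foreground, avoiding the 0/0 of a degenerate normalization and the
fabrication of foreground from stretched noise in empty slices.

The end-to-end convenience path (`segment_phantom_regions`) automates
the "set thresholds from the histogram" step:

1. the lobe comes from the tdTomato channel (σ = 5 μm smoothing, Otsu,
   15-μm closing, hole filling, largest connected component);
2. a rough dense compartment (>30% of the within-lobe 99.5th-percentile
   intensity) is eroded in-plane to leave plateau cores, and the core
   intensities are split in two by an Otsu threshold;
3. HD regions are accepted only when the upper class is genuinely
   brighter (class-mean ratio ≥ 1.45): on aged-type whole-lobe phantoms
   the ratio is ≈1.6–1.7, on young-type ≈1.36, so the gate cleanly
   returns an empty HD mask for the young case — the pipeline
   *discovers* the absence of HD rather than being told.  The gate is
   calibrated for whole-lobe images; small high-resolution sections have
   broader intensity fluctuations and the gate margin there is narrow;
4. boundary thresholds interpolate between plateau medians at 0.37
   (cortex→medulla) and 0.22 (medulla→HD) of the transition.  The
   factors sit below the naive half-way point because Gaussian smoothing
   biases the half-level surface of a convex object inward by ≈σ²/R and
   the morphological clean-up (closing 4 μm, in-plane opening 4 μm)
   erodes slightly; the values were calibrated on phantoms so that the
   recovered volumes are approximately unbiased;
5. the blur bleed-through surrounding bright HD regions is subtracted
   before the medullary threshold using a Gaussian forward model of the
   HD mask (its plateau excess convolved with the effective kernel),
   which removes the spurious thin "halo" ring that would otherwise be
   segmented as medulla around each HD cap.

This automated path applies no median prefilter: the physical-units
Gaussian provides the denoising, and a pixel-radius median would erase
nuclei that are sub-pixel at fine sampling.  The literal fixed pipeline
(median → Gaussian → per-slice min–max → threshold → closing → component
filter) remains available verbatim through ``segment_dense_region``.

Cortex is always the lobe minus medulla and HD, so
`cortex + medulla + hd = lobe` holds exactly on integer voxel counts.
Where medulla and HD masks overlap, HD wins: compaction is the stricter
criterion.

## Nuclear spots and the distance rules

Detection is scale-normalized Laplacian-of-Gaussian filtering at
σ = diameter/(2√3) in physical units (anisotropy corrected per axis),
local maxima above a score threshold, and per-axis parabolic sub-voxel
refinement.  This replaces the proprietary spot detector of the original
protocol with a standard, parameter-light detector honouring the same
contract (centres + scores).  On phantoms with the default confocal-type
settings (4-μm nuclei, PSF (1.2, 0.8, 0.8) μm) recall and precision
exceed 0.97 per region, including inside HD shells.

Signed distances are computed from a pair of anisotropic Euclidean
distance transforms (outside minus inside), interpolated linearly at the
sub-voxel nucleus centres; an empty mask yields +∞.  Classification
applies the rules with fixed precedence — medullary/HD when the distance
to the medullary *or* HD surface is ≤ 0 μm, then subcapsular when the
distance to the section edge is ≥ −25 μm, remainder cortical — so every
nucleus receives exactly one label.  "Section edge" means the lateral
boundary only: edge distance is computed slice-wise in (y, x), because in
a 200-μm section every nucleus is within 25 μm of a cut face, and
counting cut faces would label the whole section subcapsular.  Whether
the original analysis included cut faces is not stated; this is the only
reading under which the rule is non-degenerate.  When individual
attribution of the combined medullary/HD label is needed, the region
whose surface the nucleus is deepest inside wins, ties to HD.

## Paired-lobe counts

Whole-lobe subset counts multiply densities from one sample (sectioned,
high-resolution) by region volumes from the other (whole-lobe) — the
published left-lobe/right-lobe design.  The estimator is a pure product,
`count_B = density_A × volume_B`, and is exact for exact inputs; the
reported relative error is the sum of the input relative errors when
supplied.

Two refinements make the estimator approximately unbiased on phantoms:

* *Core densities*: density is an intensive quantity, so it is measured
  in high-confidence interiors.  Sections are segmented with an inflated
  medullary mask (level 0.30, so missed dense islands cannot leak
  30-fold denser nuclei into the cortical count) and a tight HD mask
  (level 0.45 — with uniform truth densities any mask inside a region
  measures its density correctly, so the tight mask trades coverage for
  purity).  Medullary and cortical densities come from 3-μm-eroded
  cores; the medullary core excludes an 8-μm dilation of HD, and the
  cortical core excludes an 8-μm dilation of all dense tissue plus a
  4-μm-eroded lobe interior (the segmented lobe boundary is uncertain
  by a blur length).  Counts and volumes are pooled over several
  sections before dividing, mirroring density estimation from multiple
  slices.
* *Partial-volume compensation*: at light-sheet resolution the
  segmented HD shell loses its outer skin and z-caps to partial-volume
  dilution while overshooting slightly into medulla, so the
  extrapolation volume uses a 3-μm outward-only dilation of the HD
  mask (the medullary side stays fixed), with cortex taken as the
  remainder of the lobe.

Because the estimator scales a count by a volume *ratio*
(`V_B/V_A`), systematic segmentation bias that is common to both samples
cancels to first order; what remains is the seed-to-seed scatter of the
two segmentations and of the Poisson counts.  The cortical estimate is
the noise-limited one: at 1.2 × 10⁻⁴ nuclei·μm⁻³ the exclusion-filtered
section cores contain only one–two hundred countable nuclei, so its
standard error is ~7–10% — of the same order as the 10% recovery target
the tests check.

## Expression procedures

*QC rule.*  Three negative indicators: low total counts, gene count
≤ 1,000, mitochondrial fraction ≥ 0.2.  A cell is low quality when more
than one indicator fires.  "Low total counts" has no published numeric
threshold; the default is the 5th percentile of the per-sample library
sizes, a deliberately mild choice since the rule only acts jointly with
the other indicators.  Ribosomal fraction is computed and reported but is
not an indicator.  Cluster-level exclusion drops clusters with >50%
flagged cells or >50% of cells expressing a contaminant gene — the 50%
defaults are explicit reconstructions, the original criterion being
qualitative.  Doublet exclusion is accepted as an input flag column.

*Normalization.*  Counts per cell are scaled to a library size of 10,000
and log-transformed with a pseudo-count of 1 (natural log).  The
transform satisfies `Σ_g (exp(v) − 1) = 10,000` per cell exactly, which
the tests verify to 10⁻⁶ relative.

*Marker ranking.*  One-vs-rest Wilcoxon rank-sum per gene with the
tie-corrected normal approximation; the z-score's sign is the direction;
p-values are two-sided and BH-adjusted across genes within each
comparison (not pooled across subsets); no fold-change filter.  The
tie-corrected variance equals the exact permutation variance, so the
z-score matches the exact enumeration moments for small groups — the
test suite verifies this against brute-force enumeration and against an
independent implementation of the same ranking.

*Signatures and scoring.*  A subset signature is its top-N (default 20;
10 and 30 are other published uses) FDR ≤ 0.05 up-regulated genes by
descending z, ties broken by gene name.  A cell's score is the mean
expression of the signature minus the mean of a control set drawn from
expression-matched bins (genes ranked by mean expression into 25
equal-size bins, 50 controls per signature gene, union semantics,
seeded).  For any fixed reference the score reduces to a two-mean
difference, which the tests check to 10⁻⁹.  Cells and spots map to the
argmax-score subset; exact ties are left unassigned and the top-minus-
runner-up margin is reported.

*Scaled frequency change.*  The per-subset change `f_aged − f_young` is
divided by the maximum absolute change within the compartment, giving
values in [−1, 1].  The original figure's scaling is not defined
anywhere in the text; this max-|Δ| normalization is a reconstruction and
the output column is named `scaled_change_reconstructed` to say so.

*EMT axis.*  Cells are ordered by descending *Cdh1* expression; E and M
scores are means over the supplied epithelial and mesenchymal sets; the
quadrant class uses detection thresholds (default: expressed vs not) on
*Cdh1* and *Vim*, so a partial-EMT state (anchor low, *Vim* high)
occupies the E−M+ quadrant.

## Injury-recovery statistics

The synthetic time-course has baseline abundance at day 0, a linear drop
to `baseline × (1 − depth)` at the nadir (day 1) and exponential return
toward baseline at an age-dependent rate, sampled at days 0, 1, 4, 7 with
10 replicates and multiplicative noise (CV 0.1) — aged kinetics deplete
deeper and recover slower.

Recovery fraction is `100 × mean(day t) / mean(age-matched day 0)`.  AUC
is the trapezoid over replicate means at the observed days (non-uniform
spacing handled natively); the aging index is the aged/young AUC ratio
per subset.  The point estimate uses replicate means (not per-replicate
AUCs, which the source does not distinguish); uncertainty comes from a
replicate-level percentile bootstrap (default 2,000 resamples, seeded),
resampling replicates within each (subset, age, day) cell.  Whether the
original AUCs used absolute counts or normalized abundances is not
stated; the functions accept either, since the index is invariant to any
common rescaling of both age groups.

## Problem sizes and test design

Unit tests run on a 40 × 112 × 112 phantom (one coated blob) and
200–1,000-cell expression matrices; the acceptance suite uses the full
256 × 256 × 64 aged/young phantoms, a confocal-type section phantom of
96 × 224 × 224 voxels for the paired-count design, 500 null simulations
for the type-I check and 100 seeded runs for bootstrap coverage.  These
sizes keep the full suite within tens of minutes on one CPU while leaving
the Monte-Carlo standard errors well below the tolerances being checked.

## Known limitations

* The segmentation calibration (level factors, bleed model) is tuned to
  the phantom's contrast regime; real images with different
  density ratios may need the exposed parameters adjusted.
* Medullary Dice saturates near 0.83 at the default densities — the
  nucleus-sampling noise limit discussed above — so small systematic
  volume biases (±10–15%) remain at the boundary-wander scale.
* The rank-sum p-values are normal approximations; for groups of a few
  cells an exact test would differ (the z-scores themselves are exact in
  the permutation-moment sense).
* The bootstrap CI for the aging index is percentile-based and can
  undercover slightly for very small replicate counts.
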