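# Methods

This note documents the models, procedure constants and numerical choices
behind the package, and what the synthetic benchmarks do and do not
establish about real data.

## Image model and 8-bit normalization

All quantification operates on 8-bit copies of the acquisitions. The
mapping is a fixed linear display range per channel: values at or below
`low` map to 0, at or above `high` to 255, in between to
`round(255·(v−low)/(high−low))` with round-half-up. Rounding is pinned
because peak areas (sums of 8-bit samples) depend on it. The display range
is an explicit configuration value; by default it is frozen from the
per-channel (min, max) of the first image of a batch and reused unchanged
for every other image, so intensities are comparable across conditions. The
mapping is assumed linear; if the original acquisition used a non-linear
lookup table, absolute peak areas shift but the overlap *ratios* that drive
positivity calls are much less affected.

Pixel coordinates are 0-based and refer to pixel centres.

## Spot detection

The detector computes the scale-normalized negated LoG response
`R = −σ²·(G_σ ∗ ∇²) I` with `σ = d/(2√2)` for estimated object diameter
`d` — the standard blob-detection convention under which a Gaussian blob of
sd `σ_b` responds maximally when `d = 2√2·σ_b`, with peak response equal to
half the blob amplitude. The truncated discrete kernel's small nonzero sum
is subtracted so a constant image yields exactly zero response. Borders are
reflected.

Detections are strict 8-neighbourhood local maxima above the quality
threshold, greedily suppressed within `d/2` (Euclidean, higher quality
wins, ties broken by (y, x) order for determinism). A detection is flagged
as a possible unresolved doublet when its connected supra-half-maximum
response support exceeds 1.5× the single-spot expectation (≈ 3.96 σ² px for
a matched Gaussian); flagged detections are reported, never automatically
split, because resolving touching vesicles is a human judgment. Counts are
reported with and without flags.

The default quality thresholds (4 for 10-px CD63-like objects, 12 for 6-px
EEA1-like objects) are instrument-scale values tied to the original
acquisition software's normalization and are not meaningful on other
intensity scales. Synthetic analyses therefore calibrate a threshold from
the noise floor: the 99.9th percentile of the *local-maximum* responses of
an object-free image rendered with the batch noise model, times a 2×
margin. The percentile is taken over maxima rather than over all response
pixels because thresholding maxima against a pixelwise percentile leaves
tens of noise maxima per 512² field, while matched vesicle responses sit
>50× above the noise floor — the margin costs no sensitivity and drives
expected false detections per image well below one.

z-stacks are detected per plane; detections on adjacent planes closer than
the suppression radius in xy are merged transitively before counting.

## Line-profile colocalization

A profile of `L` samples (40 for marker scoring, 50 for contact sites) is
taken at 1-px steps along a line centred on the vesicle, bilinearly
interpolated; samples falling outside the image are recorded as missing and
can never join a peak. The default line direction is the local intensity
principal axis (second-moment eigenvector in a 17-px window); fixed-angle
and toward-reference modes are available, the latter used for contact
profiles. For isotropic puncta the axis is arbitrary, and all peak
statistics are invariant to direction reversal.

A *signal peak* is a maximal run of samples strictly above the cutoff
(default 100 of 255); a run sitting exactly at the cutoff is not a signal.
Peak area is the raw sum of sample intensities over the run (the simpler
reading of "peak area"; area-above-cutoff is available by flag). The
vesicle peak is the run containing the profile midpoint, else the nearest
run (ties: larger area, then smaller start). The marker peak is the
marker-channel run with maximal support overlap with the vesicle peak. The
overlap area is the sum of the pointwise two-channel minimum over the
intersection of the two supports — the area under both curves — and the
call is positive iff overlap > 0.5 × marker peak area, strictly, so a share
of exactly one half is negative. Support-length overlap is available by
flag. Reporter quantification returns the area and maximum of the reporter
peak overlapping the vesicle peak (zero when none overlaps).

The percentage of marker-positive vesicles is 100 × positives / total; an
empty call set is reported as missing, not zero.

## Contact sites and regions

For each vesicle the 50-px profile is directed toward the nearest
mitochondria-mask pixel (Euclidean, ties to the smallest (y, x); a vesicle
inside the mask gets distance 0 and the inward boundary normal). A contact
is called when a vesicle-channel signal run intersects a
mitochondria-channel signal run; a strict mode additionally requires both
channels above threshold at the same sample.

The default signal threshold is mean + 3·sd of the channel intensities
outside all detected objects. A 2·sd cut was considered and rejected: by
construction it passes ≈2.3% of background samples regardless of noise
level, which over the ~15-sample support of a vesicle peak produces
profile-level false-contact rates well above 10%; at 3·sd the per-sample
rate is 0.13% and the realized false-positive rate on synthetic scenes is
≈0. The multiplier and a fixed cutoff-100 alternative are both config
options, and every run echoes the values used.

The perinuclear region is the disk of twice the nuclear diameter centred on
the nucleus centroid, intersected with the cell mask; the peripheral region
is the remaining cell area (an exact pixelwise partition). For non-circular
nuclei, "nuclear diameter" is the equivalent-area circle diameter
`2√(area/π)`. Contacts are localized at the vesicle anchor for region
assignment. Points exactly on the disk boundary are perinuclear (≤).

For EM annotation tables the rule is: gap < mean vesicle radius of the
image, where gap is the boundary-to-boundary distance (centre distance
minus both radii; negative when boundaries overlap — always a contact).
Boundary-to-boundary is used because the rule compares a distance with a
radius; centre-to-centre would double-count object size.

## Localization rendering

Localization tables carry nm coordinates. XYZ export divides by a
configurable scale factor (default 13.46 nm per output unit; the legacy
integer factor 15 is also supported — the two conventions assume different
source units, so the factor used is written into the XYZ comment line) and
prints uranium pseudo-atoms with three decimals.

Density maps sum isotropic 3D Gaussians of σ = sigma_factor × resolution
(defaults 1.5 × 1.4 output units), each normalized to unit integral —
mass-weighting is deliberately off, so the volume integral equals the
localization count. The grid covers the bounding box plus a 4σ margin;
every kernel is evaluated over the whole grid, so the only mass loss is the
tail beyond the margin (≪1%). Grids with voxel spacing above σ are refused
(default voxel 2.0 units ≈ 27 nm, about half the rendered resolution).

Dust filtering keeps a point iff another point lies strictly within the
dust radius, 60 nm by default (1.5 voxels at the ~40 nm voxel spacing of
the original volume rendering — a coarser grid than the density map's,
which is why the radius is stored in nm rather than voxels). One-pass mode
judges connectivity on the input set and is idempotent (removing an
isolated point never orphans a kept one, since kept points witness each
other); an iterative mode runs to fixpoint, and a voxel-component mode
removes small connected components for closer parity with volume-renderer
behaviour.

## Statistics

Group summaries are mean ± s.d. (ddof = 1). "Student's t-test" is read
literally as the pooled-variance test with df = n₁ + n₂ − 2, two-sided;
Welch's correction is available by flag and the choice is echoed into the
report. Zero pooled variance returns t = 0, p = 1 for equal means and a
flagged degenerate infinite t otherwise. Pearson's r is computed on the raw
(pre-8-bit) images over an optional mask; z-stacks are max-projected by
default (single-plane by flag); constant channels report a missing value.

## Synthetic scenes

The generator emulates one confocal field per cell on a 512×512 grid at
0.1 µm/px: an elliptical nucleus (14 µm equivalent diameter, 0.75 aspect),
a cell ellipse filling most of the field, ~10 random-walk mitochondrial
filaments, and vesicles of diameter 1.0 ± 0.15 µm rendered as isotropic
Gaussian spots of sd = diameter/(2√2) (a ring mode exists for larger
hollow vesicles). 45% of vesicles carry a marker punctum (sd 1.5 px),
displaced 2 px from the vesicle centre to mimic markers confined to
discrete membrane subdomains — this deliberately stresses the overlap rule
rather than handing it perfectly concentric peaks. Contacting vesicles
(30% by default) are placed 1–4 px from a filament centre line;
non-contacting ones at least 30 px away, so truth labels are unambiguous
with a 50-px profile. Centre-to-centre spacing is at least 2× the vesicle
diameter by default; a crowded setting below that exercises the
merged-detection flag. All channels are blurred with a Gaussian PSF
(σ = 1 px), then Poisson photon noise and Gaussian read noise
(sd 30 counts) are added over a 300-count background; peak amplitudes
(~10⁴ counts) give the high signal-to-noise of well-stained fixed-cell
confocal data. Intensity distributions are assumptions (no reference
values exist for them) and are fully configurable.

Geometry sampling and rendering draw from independent streams of one
per-scene seeded generator, so truth-table statistics can be checked over
hundreds of seeds without rendering pixels, and every scene is
deterministic given its seed.

Because spots are rendered with sd = d/(2√2), their intrinsic FWHM is
0.833·d; the rendering self-consistency check therefore compares the fitted
spot width against the model prediction √((d/(2√2))² + σ_psf²) rather than
against d itself.

What passing synthetic benchmarks shows: the detector, the overlap rule,
the contact logic and the statistics are implemented correctly and recover
known truth under realistic noise. What it does not show: robustness to
uneven illumination, autofluorescence, varying vesicle morphology, crowded
or overlapping organelles, or segmentation errors in real micrographs —
none of which the generator simulates (no Gibson–Lanni PSF, no 3D
astigmatism, no intraluminal substructure).

## Problem sizes and determinism

The shipped benchmarks use 20 cells × 50 vesicles per condition for
fraction recovery, six 512² scenes for contact recovery, 10 for detector
precision/recall, and 10⁴ random profiles plus an exhaustive three-level
enumeration for classifier-oracle equivalence — sizes at which the binomial
sampling error of the recovered fraction (≈1.6 points at n = 1000) is well
inside the ±5-point acceptance band. All randomness flows from explicit
seeds; full pipeline runs are byte-deterministic, and every CSV the
pipeline emits is sufficient to recompute the summary numbers it reports.

## Known limitations

- Quality values are not comparable to thresholds from other software's
  intensity normalization; recalibrate per instrument or batch.
- The 8-bit cutoff of 100 presumes display ranges that put real signal
  well above ~40% of saturation; dim channels need their range, not the
  cutoff, adjusted.
- Merged vesicles are flagged, not resolved; counts are reported both ways.
- The density map's unit-integral kernels differ from atomic-mass-weighted
  volume renderers by a constant factor per localization.
- Region assignment uses the vesicle anchor only; a contact whose
  mitochondrion lies across the perinuclear boundary is assigned by the
  vesicle side alone.
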