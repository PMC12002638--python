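# Methods

`nanospine` quantifies the nanoscale organization of excitatory synapses
from multi-channel confocal/STED image stacks, and ships a synthetic-scene
generator that renders ground-truth scenes through the same imaging model,
so that every stage of the analysis can be validated by parameter recovery.
This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic validation does and does not show.

## The analysis pipeline

**Confocal puncta co-clustering (`puncta`).** Each confocal channel is
max-projected; the projection is binarized at the full-frame mean + k·SD
(default k = 2, sample SD, strict `>`); puncta are 8-connected components
of 3–100 pixels; cross-channel co-clusters require *more than one* shared
pixel (i.e., ≥ 2). Densities are reported per 10 µm of dendrite, with a
warning below 50 µm. The frame statistics deliberately include all
structure in the field: on dense tissue images this is what anchors the
threshold.

**3D nanocluster segmentation (`cluster3d`).** STED stacks are smoothed
in-plane with a 0.8-pixel Gaussian, then segmented by local maxima plus
thresholds: (1) global threshold T_g = frame mean + 2·SD; (2) seeds are
voxels above T_g that are strict maxima within an ellipsoidal neighborhood
of 5 pixels laterally and 2 axially, ties broken toward the lower linear
index; (3) each seed grows over 26-connected voxels brighter than
max(T_g, L_s), where the per-seed level L_s = peak·exp(−sd²/2) is a Gaussian
evaluated sd = 1.5 standard deviations from its peak (≈ 0.325·peak), within
20 pixels of the seed laterally (scaled by dx/dz axially, so the constraint
is near-isotropic in physical units); voxels reachable from several seeds go
to the seed whose flood front reaches them first on descending intensity
(marker watershed on inverted intensity); (4) objects outside 3–20,000
voxels are discarded. The per-seed level formula and the contested-voxel
rule are this package's interpretation of an unpublished plugin internal;
both are configurable, and the property suite checks the implementation
against an independent brute-force realization of the same rules.
Nanocluster (NC) centers are intensity-weighted centroids — more robust than
geometric centers on a coarse (150 nm) axial grid. Volume is voxel count ×
voxel volume. Trans-synaptic pairs are cross-channel NC pairs sharing ≥ 1
voxel; each pair carries its center-to-center distance and an orientation
class (A if the lateral offset component ≥ the axial one, else B).

**Per-spine analysis (`spines`).** Spine masks come from generator truth, a
provided label image, or mean + 2·SD thresholding of the morphology channel
(the last merges touching structures and is only a fallback). The head ROI
defaults to the full mask; the manual head/neck split used on real data has
no automatic equivalent. PSD-95 NCs are assigned to a spine only when every
voxel center lies inside the head ROI (evaluated by nearest-voxel lookup of
physical coordinates against the morphology-grid mask — intensity data are
never resampled); Bassoon NCs associate on ≥ 1 voxel-center overlap or a
centroid within 0.2 µm of the ROI. Discrete NCs must additionally exceed
the ROI-local mean + 1.5·SD level (`identify_spine_ncs` implements the full
ROI-local re-segmentation; the pipeline applies the equivalent peak-level
check to the globally segmented NCs, whose geometry stays authoritative).
A *nanomodule* is an assigned PSD-95 NC with ≥ 1 aligned Bassoon partner;
counting is keyed on PSD-95, so one Bassoon shared by two PSD-95 NCs counts
twice, and a Bassoon NC may associate with two adjacent spines. Spines with
zero recovered nanomodules are excluded from single/multiple denominators
and reported separately. Input classification: a VGluT punctum "contacts" a
spine when it overlaps the z-projected mask by more than one pixel; VGluT2
only → TC, VGluT1 only → CC; dual contact is resolved by which marker
colocalizes with the spine's aligned nanomodules, then by the larger total
overlap (exact ties fall to CC, deterministically); no contact →
unclassified.

**Profiles and calibration (`profiles`).** Cluster size is the FWHM of a
Gaussian + offset least-squares fit to a line profile (linear
interpolation, default step = pixel size) along the cluster's principal
intensity axis; a fit is flagged and excluded when it fails to converge or
peaks at the profile boundary. Fitting was preferred over half-max crossing
because it is stable at 5–10 photons/pixel; a crossing estimate can be
derived from the returned fit if needed. Two-point resolvability uses a
two-Gaussian (shared width) fit selected against the single-Gaussian model
by AICc, with a short multi-start over plausible splittings (barely
resolved doublets have a shallow likelihood valley); the Rayleigh dip is
the percentage drop of the fitted midpoint below the mean fitted peak.
At a 50 nm separation with a 50 nm PSF roughly half of noisy profiles
come out unimodal — that is the physics of the diffraction edge, and those
profiles are reported unresolved rather than forced.

Axially spaced bead pairs are a special case: at a 150 nm z-step, a 90 nm
separation is below the per-pair information limit at any realistic photon
count (the least-squares cost is flat over ~±30 nm even at 100 peak
photons). All rulers on a slide share one designed spacing, so the package
estimates that common spacing by a matched-filter profile likelihood pooled
over pairs: for each candidate separation, each pair's best score
(amplitude in closed form, pair center scanned over a local z-grid, lateral
profile fixed at the known PSF widths) is summed, and the pooled argmax is
the calibration estimate. The per-pair constrained fit
(`axial_pair_separation`) remains available for finer grids or very bright
data and is exact on noiseless input.

**Statistics (`report`).** Size-scaling relations are ordinary least
squares (slope ± SE, R²). Slope comparison between groups is the
homogeneity-of-slopes test: the t-test of the group-by-x interaction term in
a pooled linear model (the standard ANCOVA slope test; sums-of-squares type
does not matter for this single-interaction design). Distribution
comparisons use the two-sample Kolmogorov–Smirnov test. Fraction tables
report % TC/CC, % single vs multiple nanomodules per class, and the full
count distribution, always with denominators.

## The synthetic-scene generator

Scenes place dendritic spines on a jittered lattice (spherical head of
0.3–1.4 µm diameter plus a 100 nm-radius neck and a shaft stub in the
morphology channel), separated by ≥ 0.5 µm. Study conditions are the
defaults:

| parameter | default | rationale |
|---|---|---|
| P(TC) | 68/507 ≈ 13.4% | basal-dendrite identity proportions |
| count pmf, CC basal | (308, 107, 20, 4)/439 | per-category spine counts |
| count pmf, TC basal | (0.68, 0.28, 0.04, 0) | stated single/multiple split |
| cleft offset | 140 nm | trans-synaptic PSD-95↔Bassoon distance |
| cleft axis mix | 0.5 | both XY- and Z-aligned pairs occur |
| NC size | 150 ± 25 nm (clipped 100–200) | reported NC size range |
| spine volume | 0.05 + 0.36·count µm³, ×lognormal (σ_log 0.25, unit mean) | inverse of the ~2.8 NCs/µm³ scaling slope |
| STED grid | 20 nm XY / 150 nm z | acquisition settings |
| confocal grid | 100 nm XY / 300 nm z | acquisition settings |
| STED PSF | 50 nm lateral / 130 nm axial FWHM | lateral: nano-ruler calibration; axial: see below |
| confocal PSF | 250 / 600 nm | diffraction-limited 1.4 NA |
| STED photons | 8 peak / 0.05 background | photon-counting regime, 5–10 per pixel; near-zero background after lifetime cleanup |
| ruler photons | 100 peak | bright calibration slides |
| neuropil synapses | 2.0 µm⁻², 60% trans-synaptically paired | dense tissue fields |

Each nanomodule contributes one PSD-95 emitter placed inside the head (with
lateral/axial margins of 200/280 nm and pairwise separations ≥ 300 nm so
that distinct modules remain individually resolvable and thresholded PSD-95
sets stay entirely inside the discretized head mask, consistent with the
assignment rule) and one Bassoon emitter offset by the cleft distance along
a purely lateral (random azimuth) or purely axial direction per the axis
mix. A VGluT1 or VGluT2 bouton abuts the head opposite the neck. Emitters
are isotropic Gaussians convolved per axis in quadrature with a separable
Gaussian PSF, scaled so the expected peak equals the photon budget,
background added, then Poisson-sampled — photon-counting detection, no read
noise. All randomness flows from one seed; identical (config, seed) gives
bit-identical truth and renders.

**Neuropil.** Frames also contain non-spine synapse units (paired or
single NCs, ≥ 350 nm apart, ≥ 250 nm clear of spine heads). These are not
decoration: the mean + 2·SD frame threshold is only meaningful when real
structure dominates the frame statistics, as it does in tissue. Without
them the threshold sits on bare noise and fragments emitter tails into
spurious small clusters. Paired neuropil synapses share the configured
cleft offset and legitimately enter pooled distance statistics.

**The axial PSF default (130 nm FWHM)** is the one optics parameter with no
stated value. A 90 nm *bead separability* figure is sometimes read as the
axial FWHM, but 3D STED with 20% of depletion power in the z-donut
typically achieves 120–200 nm axial FWHM, and with a 90 nm axial FWHM the
thresholded voxel sets of purely axial 140 nm pairs routinely occupy
single, disjoint z-planes at 150 nm sampling — making the ≥ 1-voxel overlap
rule unsatisfiable for a large fraction of real-by-construction synapses.
130 nm is the package default; it is a documented modeling choice, not a
reported instrument value.

**Spine head sizes** follow the volume model rather than a hard 1 µm cap:
the ~0.36 µm³-per-module increment puts 4-module spines near 1.5 µm³
(head diameter ≈ 1.4 µm), consistent with the largest mushroom spines.

**Exact composition mode.** `SceneConfig(exact_fractions=True)` realizes
class and count compositions exactly (largest remainder) instead of i.i.d.
draws. The recovery experiments use it because the printed compositions
(68 TC of 507; the basal count distribution) are the study condition
itself; it isolates pipeline error from multinomial sampling noise.

## What the validation shows — and what it does not

Passing recovery tests show that the pipeline returns the generator's
parameters through the full imaging chain: PSF blurring, anisotropic
sampling, Poisson noise, dense neuropil context, thresholding and
segmentation. They do not certify performance on real tissue, where spine
masks are drawn and assigned by an experimenter, PSDs are curved disks
rather than Gaussian blobs, labeling is incomplete and background removal
imperfect. Known estimator limits, measured on synthetic data and asserted
at those levels in the property suite:

- voxel-centroid pair distances carry a +1–4% quantization/Jensen bias on
  the 150 nm axial grid (the 140 nm recovery lands within ±10 nm
  regardless);
- a ~5–10% nanomodule miss rate (mostly axial pairs at unfavorable
  z-phases) inflates the recovered volume-per-module regression slope by
  ~10% through errors-in-variables, while leaving the single-vs-multiple
  fractions nearly unbiased (misses on single-module spines drop the spine
  from the denominator rather than shifting it between categories);
- classification accuracy is ≥ 95% at the default noise and 100% in the
  noiseless limit, with < 5% dual-labeled spines under well-separated
  scenes.

## Numerical choices and degenerate inputs

Thresholds use strict `>` with the sample SD (ddof = 1), so constant images
yield empty masks rather than errors. Maxima ties break toward the lower
linear index; contested watershed voxels resolve by flood order with FIFO
age on exact ties — segmentation is fully deterministic. Coordinates are
0-based (z, y, x) voxel indices and physical nm everywhere else; volumes in
µm³; intervals half-open. Gaussian rendering windows extend ±4.5σ
(truncation < 10⁻⁴ of an emitter's photons); an emitter whose effective
FWHM falls below half the voxel pitch on any axis is rejected as
unresolvable on that grid. Nearest-neighbor queries use a k-d tree and are
asymmetric (A→B) by design. Empty inputs: no seeds → empty NC list; no
assigned NCs → null (not zero) volume metrics; empty channel B → 0% aligned.

## Problem sizes

The recovery experiments process spine populations in batches of ~50 spines
per ~15 × 15 × 2.1 µm field (≈ 6–9 M STED voxels per channel), a size at
which a full generate–render–segment–count cycle takes a few seconds per
batch on one core: 500-spine runs complete in about a minute and the whole
recovery suite in a few minutes. These batch sizes are package choices made
for convenient iteration; all statistics pool across batches with seeds
spawned from one master seed.
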