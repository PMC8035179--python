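# Methods

`salispect` implements a two-timepoint quantitative salivary-gland
SPECT/CT analysis: a pre-stimulation SPECT/CT pair at 20 min
post-injection of Tc-99m pertechnetate, a sialagogue stimulus, and a
post-stimulation SPECT at 40 min reconstructed in the 20-min CT frame.
Per gland (right/left parotid, right/left submandibular) the pipeline
reports the VOI volume, the percent injected dose

    %ID(t) = 100 * A_gland(t) / A_ref(t),

and the percent excretion fraction

    %EF = 100 * (%ID_20 - %ID_40) / %ID_20,

where `A_gland` is the activity summed over the gland VOI
(concentration x voxel volume) and `A_ref` is the administered activity,
by default decay-corrected to the acquisition time with the Tc-99m
physical half-life of 6.0058 h.  Decay correction is a toggle; with it
on, %ID reflects tracer biology and %EF is not inflated by the ~4%
physical decay between the two timepoints.  Activities are carried in Bq
internally and reported in MBq; %ID is linear in the SPECT voxel values
and inversely proportional to the injected activity.

## Synthetic phantom population

No patient data ship with the package; every stage is validated on
synthetic head-and-neck phantoms (`salispect.phantom`).  Defaults define
the study population and are not tuned per experiment:

| parameter | default | note |
| --- | --- | --- |
| grid | 112 x 80 x 48 voxels at 2 x 2 x 3 mm | neck field of view |
| parotid volume | 23.43 +/- 10.42 mL | per gland, truncated normal |
| submandibular volume | 11.57 +/- 4.48 mL | per gland |
| parotid %ID (20 min) | 0.36 +/- 0.11 % | per gland |
| submandibular %ID (20 min) | 0.17 +/- 0.09 % | per gland |
| parotid %EF | 61.41 +/- 9.04 % | per gland |
| submandibular %EF | 45.22 +/- 16.14 % | per gland |
| injected activity | 555 MBq | |
| PSF FWHM | 10 mm | isotropic Gaussian system blur |
| count scale | 5.6e-4 counts/Bq | ~3% relative noise on a parotid VOI sum |
| HU: parotid / submandibular / soft tissue / bone | 15 / 55 / 40 / 700 | noise SD 15 HU |
| misalignment range | +/-6 mm, +/-5 deg per axis | 40-min SPECT vs CT frame |

Glands are ellipsoids with jittered axis ratios and positions, placed
laterally symmetric inside a body ellipsoid with a spinal bone column;
a thyroid and an oral cavity carry realistic confounding activity
(1.5% and 0.2-0.5% ID).  The diffuse soft-tissue background holds 2% ID
and is excluded from gland interiors (gland tissue displaces it).

**Programmed %ID semantics.** The reference ranges that define the
phantom kinetics are themselves VOI measurements on resolution-limited
SPECT.  The generator therefore defines the programmed %ID as the value
a truth-VOI measurement recovers from the blurred pre-noise activity
map: after applying the PSF, each gland's pre-blur concentration is
scaled linearly so that the truth-VOI sum (including spill-in from
background, thyroid and mouth) equals programmed %ID x administered
activity exactly.  Noiseless recovery error is then limited only by
inter-gland spill (<0.1%).  The alternative convention — programming the
*total* gland activity — would make truth-VOI recovery of a 23-mL gland
under a 10-mm PSF biased low by 25-30% (surface-layer spill-out), which
is not the quantity the reference ranges describe.

A rare-draw guard floors the 40-min %ID at 0.01% (capping %EF for joint
draws of minimal uptake and maximal excretion) so the post-stimulation
signal stays above the background-spill floor; this affects on the
order of 1% of gland draws.

**Poisson noise.** Expected counts are concentration x voxel volume x
count scale; the default count scale yields ~3% relative noise on a
parotid VOI sum (about 1100 counts per parotid; measured 2.9%),
emulating a 1-min acquisition.  Fainter quantities then carry
correspondingly more counting noise — measured relative sigmas are
~5% for parotid 40-min %ID and submandibular 20-min %ID, and ~18% for
submandibular %EF (a difference ratio of two noisy small numbers).
This is a property of the programmed acquisition, not of the estimator:
the VOI arithmetic is unbiased, and on noiseless phantoms every
per-gland quantity recovers within 2% (in practice <0.1%).  The test
suite asserts the noiseless bound strictly and documents the per-gland
noisy recovery rate at this calibration; tightening the noisy bound
would require quietening the acquisition, which would no longer match
the calibrated 1-min count level.

**Rater simulation.** Manual contouring is emulated per gland by keeping
every 2nd (or 3rd) occupied axial slice, perturbing each kept contour by
a one-voxel dilation or erosion (probability `rater_jitter_prob`, drawn
per slice), and reconstructing skipped slices by linear interpolation of
per-slice signed distance maps — the shape-based interpolation used by
clinical contouring software.  The jitter probability was calibrated
once, to its maximum of 1.0, which puts the mean simulated inter-rater
gland DSC at ~0.85-0.90 on default phantoms — the lowest the
single-voxel contour model reaches, slightly above the 0.77-0.84 band
reported for human experts (who disagree by more than one voxel) and
comfortably within [0.70, 0.95].  Because the SPECT is
blurred, boundary voxels carry less activity than core voxels, so rater
disagreement perturbs %ID less than VOI volume — reproducing the
empirical pattern that %ID is the more reproducible parameter.

What the phantoms do *not* model: anatomical gland shapes, CT artifacts,
attenuation/scatter physics, projection-domain SPECT formation, or
inter-structure HU texture.  Passing tests demonstrate the pipeline's
arithmetic, recovery and learning behaviour under controlled conditions,
not clinical segmentation difficulty; clinical DSC levels for CT gland
segmentation are substantially harder to reach than phantom levels.

## Preprocessing

The network operates on a fixed matrix (clinical default 256 x 128 x 64
as x-y-z; the tested desk-scale target is 96 x 64 x 32).  The soft-tissue
band is the contouring display window, level 40 width 400 HU, i.e.
[-160, 240].  The z window is the contiguous run of slices maximising the
summed per-slice soft-tissue voxel count (ties broken toward the profile
centroid — the selection rule among contiguous windows was an open
choice and is recorded in the plan file); x/y windows are centred on the
bounding box of the axial maximum-intensity projection of the soft-tissue
mask, clipped or symmetrically padded to the target.  Padding uses
-1000 HU for CT and 0 for SPECT/labels; the plan is serialisable and
invertible (uncrop).  Network input intensities are the soft-tissue
window mapped linearly to [0, 1].

## Segmentation network

A 3D U-Net (encoder-decoder, two 3x3x3 convolutions per level,
channel doubling, average-pool downsampling, nearest-neighbour
upsampling with concatenating skips, 1x1x1 five-class head) is trained
end-to-end with a soft multi-class Dice loss (background included) and
Adam with a cosine learning-rate decay.  Implementation is a compact
CPU network: im2col convolutions over BLAS in float32 with hand-written
backprop, gradient-checked against float64 finite differences.  Because
the four gland classes encode laterality while convolutions are
translation-equivariant — and the phantom anatomy is laterally symmetric
— three normalized voxel-coordinate channels are appended to the input
by default.  A combined Dice + cross-entropy loss is available but is
not the default; on this task the dense CE term prolongs the initial
all-background phase.

Two conditioning choices matter for training speed on this anatomy.
First, the [0, 1] window-normalized CT is standardized to
``(x - 0.5) / 0.15`` before entering the network: the 15-HU
submandibular-vs-soft-tissue contrast is only ~4% of the display window,
and rescaling it to order 0.25 shortens the phase in which the faint
classes produce no gradient signal.  Second, the per-class Dice weights
are adapted each epoch to the inverse of the running soft Dice
(normalized), because with fixed weights one gland class reliably
converges last and is then squeezed out by the already-confident
classes; inverse-Dice reweighting keeps all four glands learning.

Desk-scale defaults (3 levels, 4 base channels, grid 96 x 64 x 32,
12 epochs at batch size 1, learning rate 3e-2) are the tested
configuration; clinical-scale settings remain expressible through the
same config.  Post-processing takes the per-voxel argmax and keeps, per
foreground class, only the largest 6-connected component above a minimum
size.  Training is bit-reproducible from the config seed on a fixed
BLAS.

## Misregistration correction

The 40-min SPECT is registered rigidly to the 20-min SPECT (which shares
the CT frame) — same-modality similarity is far better conditioned than
SPECT-to-CT.  The estimator maximises normalized cross-correlation of
6-mm-smoothed volumes over a mean-pooled pyramid (factors 4, 2, 2) using
Powell's bounded direction-set method per level, then polishes the three
translations with golden-section line searches at full resolution.
Plain axis-aligned coordinate descent was tried first and stalls on the
strongly coupled rotation-translation parameters; Powell's rotating
direction set resolves this while remaining derivative-free and
deterministic.  Rotations are extrinsic x-y-z about the volume centre;
transforms serialise to JSON, and a manual-transform entry path exists
alongside the estimator.

## Agreement statistics

DSC, MAPE (denominator: the reference/manual measurement), squared
Pearson correlation, Bland-Altman bias with bias +/- 1.96 SD limits of
agreement, the classical paired t test, and the intraclass correlation
of a two-way model.  The ICC variant is pinned to two-way random,
single measure, absolute agreement (McGraw & Wong ICC(A,1)) with the
F-based Satterthwaite confidence interval; the variant and CI method are
recorded in the result object.  A both-empty-mask DSC is reported
missing rather than 1.0 so resected glands do not inflate averages.
R^2 is Pearson's r squared (identical to simple-regression R^2).

## Dose accounting

Tracer effective dose = injected activity x 0.013 mSv/MBq
(pertechnetate, adult); CT effective dose = DLP x 0.0031 mSv per
mGy.cm (head region).  Both coefficients are config constants, not
hard-coded truths.  With the protocol's 555 MBq and a 60.31 mGy.cm CT
session this gives 7.22 and 0.19 mSv; a one-CT protocol totals 7.41 mSv
against 7.59 mSv for two CT sessions.  Reported totals follow clinical
printing convention: components rounded half-up at two decimals, then
summed.

## Numerical choices and degenerate inputs

* Tie-breaks: crop z-window ties resolve toward the soft-tissue
  centroid; connected-component ties keep the first largest label.
* %EF with a non-positive 20-min %ID raises and is reported missing,
  never 0.
* A constant ratings table is a degenerate input for the ICC; a paired t
  test with zero difference-variance likewise raises.
* SPECT voxels are clipped at 0 after interpolation; CT pads are
  -1000 HU.
* Registration and resampling conserve in-field total activity to
  within 1% (linear interpolation).
* All stochastic components (phantoms, training, fold assignment)
  derive from explicit integer seeds; reruns are bit-stable.

## Problem sizes used in validation

Validation experiments are sized for a single CPU: quantification
recovery uses 50 noisy single-study seeds; registration recovery 20
phantoms; crop checks 100 phantoms; rater reproducibility 10 cohorts of
8 studies; network training 40 training and 10 validation phantoms on a
96 x 64 x 32 grid with a 3-level, 4-channel network.  The clinical-scale
matrix and channel counts remain available through configuration but are
not exercised by the test suite.

## Known limitations

* Ellipsoid anatomy makes the segmentation task easier than clinical CT;
  phantom DSC levels should not be read as clinical performance.
* The registration similarity assumes the 20- and 40-min tracer
  distributions are structurally similar; gross redistribution (e.g.
  complete washout) would degrade it.
* Absolute SPECT calibration (counts to Bq/mL) is a configuration
  constant; reproducing a vendor calibration chain is out of scope.
* The network file format stores raw float32 parameters; portability
  across BLAS builds preserves values but retraining bit-identity is
  only guaranteed on a fixed build.
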