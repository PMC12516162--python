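# Methods

## Pipeline model and assumptions

The package assumes its four input contrasts (T1w, FLAIR, EPI magnitude,
EPI phase) are already bias-corrected, rigidly co-registered to the EPI
space, skull-stripped, and (for phase) unwrapped; the only intensity step
performed here is per-contrast z-normalization.  Normalization statistics
are computed over the brain mask only and outside-mask voxels are zeroed, so
patch extraction near the brain edge pads with zeros that are
distributionally neutral for z-scored data.  (Whether mask-based or
whole-volume statistics are the "right" convention is genuinely open; the
mask-based choice is self-consistent with the padding convention and is what
the phantom experiments use.)

The three pipeline stages — liberal voxel-wise proposal, peak-based confluent
splitting, attention-masked patch classification — are deliberately
decoupled: the proposal stage may be replaced by any externally supplied
probability map (`segment_subject(..., prob_map=...)`), since the in-repo
logistic voxel classifier is a simplified stand-in for a full voxel-wise
lesion segmenter.  Its feature set (raw intensities, Gaussian-smoothed
intensities at σ = 1 and 2 voxels, a T1×FLAIR coupling term, per-contrast
gradient magnitudes) is documented, not canonical; perfect voxel-wise
segmentation is not its job — capturing essentially every true lesion at the
0.05 threshold is.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| proposal threshold | 0.05 | probability | liberal: sensitive, not specific |
| min component size | 3 | voxels | drops single-voxel noise; unstated upstream, configurable |
| split smoothing σ | 1 | voxel | stabilizes peak detection on noisy maps |
| peak merge radius | 3 | mm | centers closer than a small lesion radius are one lesion |
| patch size | 24³ | voxels | large enough to show a lesion with context |
| masking factors | ×0 / ×2 / ×0.1 | — | zero outside-target EPIm, emphasize interior, dim competitors |
| reconstruction upweight | 4 | — | prioritizes candidate voxels and the low-SNR EPI channels |
| oversampling | 3 per positive label | — | true lesions/PRLs/CVS each sampled 3× more than false positives; additive across labels (a lesion+PRL+CVS candidate has weight 9), the simplest consistent reading |
| epochs | 50 pretrain + 100 joint | — | full-scale defaults in `TrainConfig` |
| optimizer | Adam, lr 0.001, minibatch 64 | — | full-scale defaults |
| rotation range | ±15° per axis | degrees | unstated upstream; small angles keep rim/vein geometry intact |
| rescale / log-gamma | [0.66, 1.5] / [−0.5, 0.5] | — | augmentation ranges |
| operating thresholds | 0.789 / 0.106 / 0.212 | probability | lesion / PRL / CVS defaults (Youden-J-derived operating points) |

Gamma correction is defined on z-scored data by shifting to [0, 1] within the
brain mask, applying the gamma, inverting the shift, and re-z-scoring — a
convention this package fixes explicitly because gamma is otherwise undefined
for negative intensities.  Pretraining reconstructs the *masked* patch
(target = masked input), keeping pretraining and joint training inputs
identical.  Augmentation draws fresh transforms every epoch.  Inference
patch centers are uniform over candidate voxels, and inference patches are
masked exactly as in training.

## Label handling

Candidate labels come from gold-standard coordinates: a candidate containing
a PRL coordinate is PRL-positive; a candidate containing no coordinate is a
false positive — unless the subject's lesion coordinates are incomplete, in
which case its status is *missing*, not negative.  "Unsure" CVS confers
lesion-positive but CVS-missing status (open convention; fixed here).
Missing/unsure statuses weight the corresponding BCE component to 0, which
produces exactly zero gradient, so unknown truth never moves a parameter.
"Unsure" candidates keep sampling weight 1 (they are not oversampled as
positives).

## The numpy network engine

No GPU framework is used: the encoder/decoder/predictor, Adam, and both loss
functions run on a small reverse-mode autodiff engine written for this
package (`rimvein.autodiff`).  Convolutions are evaluated as im2col GEMMs
with reused scratch buffers, batch chunking, and a cache-blocked backward
scatter; loss scalars are accumulated in float64 (so closed-form checks hold
to 1e-9) while the network path stays float32.  Backward dismantles the
graph as it sweeps, so activation memory is released progressively; a
forward graph can be backpropagated once.  Gradients of every operation are
finite-difference checked in the test suite.  The printed channel list
"4, 64, 128, 512, 2048" is read as input 4 with layer outputs
[64, 128, 512, 2048, 2048]; the flat 2048-unit latent is obtained by global
average pooling of the final 3³ grid, and the decoder mirrors the encoder
with nearest-neighbour ×2 upsampling — all config-expressible if another
consistent reading is preferred.  The lesion node is not gradient-detached
before concatenation, so the PRL/CVS losses can shape the lesion pathway.

## What the phantom emulates — and what it does not

The generator reproduces the *signatures* the classifier must exploit:
FLAIR-hyperintense/T1-hypointense ellipsoidal lesions; a 1-voxel hypointense
rim shell on phase for PRLs (shell = 6-neighbourhood surface, the same
convention the attention mask uses); 1-voxel-wide hypointense vein lines on
magnitude through the center of CVS lesions and ≥2 voxels off-center for a
fraction (default 0.3) of non-CVS lesions; confluent pairs sharing a
6-connected boundary; FLAIR-bright "mimic" foci with only partial T1
hypointensity, which the liberal proposal keeps but the patch classifier
must reject; free background vein lines; Gaussian noise inside the mask; and
subject-level label missingness with "unsure" CVS codes.  Rim and vein
contrast magnitudes are free parameters (default −2.0 on the raw intensity
scale, i.e. strong relative to noise σ = 0.1) — they are not calibrated to
any real acquisition.  The phantom has no anatomy, bias fields, registration
error, partial-volume effects, or realistic vein topology; passing the
end-to-end tests therefore shows that the pipeline's machinery (proposal,
splitting, masking, dependency-aware training, missingness weighting,
ensembling, scoring) recovers known truth under its stated assumptions — not
that any particular performance level transfers to clinical data.

## Desk-scale problem sizes

The full-scale configuration (width_scale = 1, 50 + 100 epochs, dozens of
subjects) is expressed by the defaults but is not what the test suite runs.
The end-to-end tests and `scripts/acceptance.py` use the package's
desk-scale conditions: 48³ phantoms with 6 lesions (2 PRL, 2 CVS, one
confluent pair), 8 training + 5 held-out subjects, width_scale = 1/16
(channels 4→8→32→128→128), 3 pretraining + 10 joint epochs, 25 patches per
subject per epoch, minibatch 16, and the full 25-patch inference ensemble.
At these sizes one training run plus held-out evaluation takes several
minutes on a single CPU core and reaches candidate-level AUROCs near 1.0 on
held-out phantoms; the determinism check uses an even smaller configuration
(width 1/64, 3 subjects).  Unit tests use 40³ phantoms and width 1/64.
`scripts/acceptance.py` additionally draws each subject's lesion count
uniformly in [4, 8] — lesion burden varies across people, and a constant
count would make the subject-level score/count correlation degenerate.

## Numerical conventions and degenerate cases

Plateau maxima collapse to the lexicographically smallest coordinate; a
component whose every voxel fails the negative-semi-definite Hessian check
falls back to its global maximum, so every component yields ≥1 center.
Nearest-center distance ties go to the lower center index; global candidate
ids follow raster order of peaks.  Empty segmentations, empty candidate
lists (percentage scores become `None`, never 0), and single-class ROC
inputs (an error) are all defined behaviours.  All randomness flows through
explicit seeded `numpy` generators — phantom streams are derived as
`[seed, k]` child seeds — so the full pipeline is bit-reproducible on one
platform.

## Known limitations

Training is CPU-bound and memory-bandwidth-limited; the engine implements
only the operations this architecture needs.  Max-pool gradients follow the
first-index tie convention.  The voxel classifier's background downsampling
(10:1) inflates its probabilities by design; its maps are calibrated for
ranking and liberal thresholding, not as posterior probabilities.
Cross-validation utilities provide subject-level folds, but the acceptance
experiment uses a single train/held-out split for runtime.
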