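# Methods

This note documents the models, procedures and numerical choices behind
`rimpipe`, a pipeline for classifying multiple-sclerosis (MS) lesions as
paramagnetic-rim-positive (rim+) or rim-negative (rim−) from co-registered
multimodal 3D MRI.

## Problem setting

Chronic active MS lesions carry a rim of iron-laden microglia/macrophages
at their edge, visible on susceptibility-based MRI (unwrapped phase and
T2\*-magnitude of a 3D-EPI acquisition) as a thin rim of shifted signal,
while FLAIR provides lesion-versus-white-matter contrast for detection.
The pipeline takes co-registered phase, T2\* and FLAIR volumes plus a
binary lesion segmentation, extracts one candidate per 6-connected
component, classifies a fixed-size patch around each candidate with a
3D CNN, and aggregates to lesion- and patient-level statistics.
Registration, phase unwrapping, lesion segmentation and anatomical
parcellation are upstream of this package: it consumes their outputs.

## Candidate extraction and exclusion rules

Candidates are maximal 6-connected components (face adjacency only) of
the lesion mask, ordered by first voxel in a raster scan so extraction is
deterministic. A candidate is rim+ if any voxel overlaps the rim+
annotation mask. Exclusions run in a fixed order so the per-rule report
is reproducible (the order is a package choice; the rules themselves are
standard):

1. `too_small` — volume < 12.3 mm³ (such small lesions would always be
   called rim−);
2. `too_big` — more than 10,000 voxels (the whole rim can no longer fit
   in the patch);
3. `artefact` — the candidate's patch window intersects a user-supplied
   artefact mask ("near air artefact" is operationalised as window
   intersection, since the original criterion was visual);
4. `rim_contaminated` — a rim− candidate whose window contains more than
   900 voxels of *other* rim+ lesions (so that rim− patches do not show
   rim+ structure).

A note on the 900-voxel threshold: the conventional phrasing equates it
with 410.5 mm³, which matches no isotropic voxel size in the 0.65–0.67 mm
range (0.65³ × 900 ≈ 247 mm³). The implementation uses the voxel count,
which is the operational quantity.

Splitting of confluent rim+ lesions is an input contract: callers supply
masks in which a technician (or the phantom ground truth) has already
separated them.

## Patches

Patches are cubes of 28 voxels per edge (default), centred on the
half-up-rounded, unweighted centre of mass of the candidate's voxels.
Overhang beyond the volume is zero-filled, then each modality is
independently min–max normalised to [−1, 1]; a constant window maps to
all zeros (the midpoint — a neutral value). Normalisation is per patch
and per modality; whether to normalise before or after cropping was an
open choice and per-patch was selected for locality and simplicity.

## Augmentation

Offline (before training): every rim+ patch is rotated by 90°, 180° and
270° about each of the three array axes — axis-aligned rotations are pure
permutations, so no interpolation occurs — giving the original plus nine
variants (a tenfold increase of the minority class). Then three
elastically deformed versions of *every* patch (both classes) quadruple
the set while preserving the class ratio. The elastic family is a coarse
4³ grid of uniform random displacement vectors, clipped to a maximum norm
(default 2 voxels) and trilinearly upsampled; since linear interpolation
is a convex combination, the displacement bound is preserved everywhere.
The deformation family and amplitude are package choices (mild enough to
preserve rim topology); no canonical parameters exist.

Online (each time a patch is fed to the network): one of 4 flips
{none, X, Y, Z} followed by one of 27 translations (−2/0/+2 voxels per
axis), uniform over the 108-element transform space, with zero-fill of
vacated voxels. Transform tags are recorded on every patch, which makes
repeated variants detectable.

## Network architectures

Both networks are VGG-style stacks of three blocks, each block two 3×3×3
'same' convolutions (batch-norm after each convolution, then tanh)
followed by 2×2×2 max-pooling; with 28³ inputs the spatial trace is
28 → 14 → 7 → 3 (floor division on odd extents).

The bimodal network runs two parallel branches (main modality: phase;
secondary: FLAIR or T2\*). Early fusion: the secondary branch's block-1
output is channel-concatenated onto the main branch's block-1 output
before the main branch's block 2 (so the main branch sees low-level
multimodal features); the secondary branch continues on its own stream.
Late fusion: both final feature blocks are flattened, concatenated and
fed to a fully connected cascade (defaults 256 → 64 → 2) ending in a
softmax. "Merging" is realised as channel concatenation rather than
addition — the standard VGG-style choice. Filter counts (32/64/128) and
head widths are configurable defaults; canonical values are not fixed by
the architecture description. The unimodal baseline is a single branch
connected to the same head.

The engine is a self-contained NumPy implementation (im2col + GEMM
convolutions, analytic backward passes, Adam, Xavier initialisation);
its gradients are verified against numerical differentiation in the test
suite. Convolution biases are retained for completeness although batch
normalisation makes their gradient exactly zero. With zero input and
fresh batch-norm statistics the symmetric initialisation yields class
probabilities of exactly 0.5.

## Training protocol

Folds are patient-grouped (all lesions of a patient share a fold) and
per-site stratified: within each site, patients sorted by rim+ count
descending are greedily assigned to the least-loaded fold (rim+ load,
then rim− load, then fold index; ties pre-shuffled by seed). The greedy
longest-processing-time heuristic is a package choice — it keeps per-fold
class counts within one patient's load of optimal, which the tests check
against exhaustive enumeration on small instances.

Optimisation is Adam (batch 32, softmax cross-entropy) with a
learning-rate ladder of 1.0e−4, 5.0e−5, 2.5e−5, 1.0e−5. An epoch counts
as an improvement only when its validation loss is strictly below the
best seen so far; the first epoch establishes the baseline. After three
consecutive non-improving epochs the next rate engages; a decay past the
last rate stops training (so a never-improving run stops after
4 × patience epochs). A 3-fold patient-grouped inner cross-validation
can convert the adaptive schedule into fixed per-rate epoch budgets
(averaged, rounded half-up, minimum 1) for retraining on the full outer
training set without a validation split. Ensemble inference (e.g. for an
inter-site scenario) averages per-model rim+ probabilities.

## Evaluation

Per-fold ROC and PR curves are step-interpolated (piecewise constant)
onto a fixed 1001-point abscissa grid and averaged pointwise; the number
of grid points is a package choice. The reported AUC is the mean of the
per-fold AUCs, not the AUC of the averaged curve (the pooled AUC is also
logged for diagnostics). Correlated AUCs are compared with the DeLong
test (midrank components, two-sided normal reference; p = 1 for zero
variance with equal AUCs). Paired decisions use the McNemar test with
continuity correction, (|b−c|−1)²/(b+c) against χ²₁, with p = 1 when
b + c = 0. The operating point is the smallest threshold whose empirical
specificity reaches the target (default 95%); a lesion is called rim+
iff its score ≥ threshold. Metrics with zero denominators are reported
as absent, never as zero. A patient is "chronic active" iff its rim+
lesion count reaches a threshold (sweep 1–6, headline ≥ 4).

Region assignment dilates the cortex mask by 2 mm and the ventricle mask
by 3 mm (spherical element, radius `round(mm / spacing)` voxels).
Precedence is periventricular (any overlap) → juxtacortical (≥ 50% of
lesion volume in dilated cortex) → deep gray / brainstem / cerebellum
(≥ 50%) → deep white matter. Periventricular-first precedence is the
package's reading of exclusive category reporting: the any-overlap rule
is stated as the exception, so it is applied first.

## Synthetic phantom

The phantom emulates, on 96³ grids at 0.65 mm isotropic spacing, exactly
the features the classifier uses: ellipsoidal lesions (random semi-axes
2–4 mm, random orientation) hyperintense on the FLAIR-like channel; for
rim+ lesions a closed one-erosion shell that is hypointense on the
phase-like channel (sign configurable) and attenuated on the T2\*-like
channel; rim-shaped phase rings with no FLAIR counterpart as artefacts;
optional confluent lesion pairs with both identities recorded; additive
Gaussian noise; and a multiplicative second-order polynomial bias field
on the magnitude-like channels (phase, being a phase map, receives no
bias field). Rim+ lesions are regenerated until their rasterised volume
clears 12.3 mm³, so the size filter never removes one. Region masks are
schematic (central ventricle blob, cortical shell, deep-gray nucleus).

What the phantom does *not* model: MR physics (no Bloch equations or
k-space), anatomy, partial-volume effects, rims of varying
completeness/contrast, or inter-scanner intensity differences. Passing
the recovery experiment therefore shows that the pipeline's machinery is
correct and can extract a rim signal it is pointed at — not that the
network reaches any particular accuracy on patient data.

## Reference recovery experiment (problem sizes)

The standard synthetic experiment uses 24 patients across two sites with
3 rim+ and 10 rim− lesions each (~312 lesions, 25% rim+), noise SD 2.0
on intensities of order 100 and a 10% bias field; patch size 16 (spatial
trace 16 → 8 → 4 → 2), reduced filters 8/16/32 with a 64/16 head, batch
32, four epochs at the first ladder rate, online augmentation on; 4-fold
patient-grouped CV; three seeds, medians reported. These sizes are the
package's desktop-scale reference configuration; the full-size network
and 28³ patches are available through the same interfaces. Under these
conditions the bimodal phase+FLAIR model reaches a mean test ROC-AUC
near 1.0, while the FLAIR-only baseline stays near chance — by
construction, the phantom's FLAIR channel carries no class information —
reproducing the expected ordering of modality configurations.

## Known limitations

* The phantom's rim is geometrically clean; real rims are open, faint or
  confounded by veins and cortical folds.
* The NumPy engine is single-threaded and CPU-bound; it is sized for the
  reference experiment, not for full-scale training runs.
* `run_pipeline` reruns are bit-reproducible on one machine; across BLAS
  builds, floating-point reduction order may differ in the last ulp.
* Automatic splitting of confluent lesions is out of scope (input
  contract), as is every upstream preprocessing step.
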