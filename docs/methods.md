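# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. Units are micrometres (µm) and minutes unless
stated; voxel arrays are `(z, y, x)` with the voxel-centre convention
(`position = (index + 0.5) * voxel_size`), and all public APIs speak µm.

## Coordinate and axial conventions

Spindle axes and kinetochore-pair directions are *axial* quantities: a
direction and its negation are the same object. Averages therefore go
through the orientation scatter matrix `S = Σ wᵢ vᵢ vᵢᵀ`; the mean axis is
the eigenvector of the largest eigenvalue. If the two leading eigenvalues
agree within 1e−9 (after weight normalisation) there is no unique axis and
the code raises rather than silently picking one. The metaphase plate is
the plane through the intensity-weighted chromosome mass centre (Gaussian
blur, default σ = 0.5 µm, then global Otsu; all above-threshold voxels
contribute, weighted by blurred intensity) with the spindle axis as its
normal. Registration between sequential stacks is translation-only (the
drift observed in this kind of acquisition is translational); it uses
phase cross-correlation with subvoxel upsampling and reports a normalised
correlation as a confidence score.

## The synthetic oocyte-scene generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

**Karyotype.** Porcine: 19 bivalents, 6 acrocentric (a large and a small
size group) and 13 metacentric; the acrocentric TALE labels all 6
acrocentrics, the metacentric TALE 6 of the 13 metacentrics. Human mode:
23 bivalents, 5 acrocentric, reusing the porcine geometry (arm-length
detail is not modelled).

**Congression (metaphase I).** Each bivalent centre follows an
Ornstein–Uhlenbeck relaxation along the spindle axis, started at
stationarity (relaxation time 8 min, stationary SD 0.25 µm, frame interval
4 min). The acrocentric stationary mean is solved numerically (closed-form
folded-normal mean, Brent root find) so that the stationary mean plate
*distance* of acrocentrics exceeds metacentrics by exactly the configured
offset (default 1.0 µm). Homologous kinetochores co-move at a fixed
inter-homologue separation (Normal(2.0, 0.15) µm) along a pair axis tilted
~5° from the spindle axis; transverse positions jitter around a plate
lattice (2.2 µm spacing).

**Anaphase.** Missegregation is drawn per chromosome with class
probabilities 0.08 (acrocentric) and 0.01 (metacentric), split 1/3
misalignment : 2/3 lagging. Total mild/severe lagging rates are exact
class parameters — defaults 0.12/0.06 (acro) and 0.03/0.01 (meta), i.e.
4× and 6× acro:meta risk ratios; the absolute levels are the package's
choice, as only the ratios are published. Chromosome masses separate at
0.5 µm/min and already show a small (3.2 µm) inter-mass gap at the onset
frame, matching the described phenomenology that a gap is visible at
onset. Laggards sit in the central zone until 12 min (mild) or 20 min
(severe) after onset and clear afterwards; severely lagging or misaligned
chromosomes that missegregate place both homologues on one side.

**Metaphase II.** One dyad per chromosome (or per supplied fate list);
sister kinetochores face opposite poles at class-conditional
interkinetochore distances: Normal(1.09, 0.18) µm acro-labelled,
Normal(0.96, 0.13) metacentric, Normal(0.97, 0.11) meta-labelled (clipped
at 0.4 µm). Cohesin level per dyad is the class ratio (acro/meta default
0.8 — a free parameter, since only significance, not a ratio, is
published) with 10% lognormal jitter.

**Telomeres.** Acrocentric pairs are masked with probability 0.20
(porcine) or 0.38 (human); presets 0.26/0.14 stand in for the early/late
metaphase distinction, which is not image-derived here. Masked telomeres
sit 0.35 µm poleward (outward along the pair axis) of their kinetochore,
exposed ones 0.35 µm toward the bivalent centre, both with 0.05 µm
isotropic noise; metacentric telomeres are placed a chromosome-arm length
(≥ 1.3 µm) perpendicular to the pair axis, so they are never proximal.

**Trim-Away separation kinetics.** Separation time is
`scale · cohesin · W` with `W ~ Weibull(shape)`, shape 4 and scale 20 min
by default, i.e. the hazard decreases steeply and monotonically with
cohesin level. A memoryless (exponential) hazard proportional to
1/cohesin cannot make the low-cohesin class separate first often enough:
by min-stability of Weibull scale mixtures, P(first separator is
acrocentric) = 6 r^k / (6 r^k + 13) for cohesin ratio r and shape k, which
at r = 0.5 is 48% for k = 1 but 89% for k = 4. The shape is the package's
kinetic choice; no kinetic model is published.

**Mad1 and attachment labels.** Mad1 positivity is drawn independently per
kinetochore at 29%; kinetochore–microtubule attachment categories are
ground-truth annotations drawn from class-conditional tables (≈50/34/16%
acro, 70/14/16% meta for end-on / lateral-merotelic / unattached) and are
never inferred from rendered images.

**Rendering.** Default confocal-like geometry: voxels 0.32 × 0.1 × 0.1 µm,
image 48 × 168 × 168, PSF σ (0.35, 0.13, 0.13) µm. Objects are rendered as
Gaussians with the PSF folded into their widths (for Gaussian objects this
is exactly equivalent to convolution): kinetochores/TALE/telomere spots at
PSF scale, chromosome bodies as size-scaled ellipsoids chosen so the total
Otsu-thresholded chromatin volume of an MI scene falls mid-range of
150–800 µm³ (≈ 450 µm³), Mad1 blobs at σ (1.0, 0.5, 0.5) µm, and
pericentromeric cohesin as a blob whose axial FWHM equals the sister IKD —
so a fixed-radius cylinder between sisters samples the same relative
profile for every pair and the measured class ratio is unbiased. Noise is
Poisson (gain 200 photons/unit) plus Gaussian read noise (σ 0.01).
Everything is a pure function of `(config, seed)`; rendered channels are
bit-exact reproducible.

**What the simulator does not emulate.** Spindle mechanics, k-fibres,
optical aberrations, photobleaching, background structure from cytoplasm,
and segmentation-resistant chromosome clumping. Passing round-trip tests
therefore demonstrates the *analysis* is correct under controlled
conditions, not that it is robust to every real-imaging artefact.

## Joint tracking MILP

Variables: binary pair selections `x_p`, binary links `y_pq` between pairs
of adjacent frames, continuous per-frame slack `s_f`. Objective:
`Σ c_p x_p + Σ m_pq y_pq + penalty Σ s_f` with the pair and motion costs
given in the README. Constraints: (i) a detection joins ≤ 1 selected pair;
(ii) per frame, selected pairs + slack = 19 (the slack is charged 100 per
missing pair — at least 10× any plausible per-pair cost, making shortfall
strictly a last resort while remaining soft); (iii) links imply their
endpoints and every selected pair has exactly one successor/predecessor
where a neighbouring frame exists, so tracks span the solved window;
(iv) pairwise exclusion between candidate pairs whose 3D segments come
closer than 0.4 µm; (v) every detection within 1.5 µm of a selected
kinetochore; (vi) every Otsu component of the DNA signal (≥10 voxels)
within its equivalent radius + 2 µm of a selected pair midpoint. Candidate
pairs require inter-homologue distance ≤ 3 µm; links require each
kinetochore step ≤ 1.5 µm under the better of the two endpoint
correspondences. Defaults: w_motion 1 µm⁻², w_signal 1, w_signal_var 0.1,
w_angle 0.5, w_angle_dist 0.1 µm⁻¹ (the last three deliberately small).

The solver is HiGHS via `scipy.optimize.milp` with a 1e−6 relative gap;
ties are broken deterministically by a 1e−9·index perturbation of pair
costs. The spindle axis is initialised as the minimum-variance principal
axis of the per-frame-centred detection cloud (the plate normal), then
re-estimated from the selected pairs and the solve repeated until the
pairing is stable (max 5 iterations). Long series are solved in
overlapping batches (default 100 frames, 2-frame overlap) and stitched by
mutual-nearest pair matching in the first shared frame; double-counted
overlap terms are subtracted from the summed objective. An exhaustive
oracle with the same objective (guarded to ≤ 4 pairs × ≤ 3 frames)
certifies MILP optimality in the tests.

Track continuity is enforced as hard link-consistency constraints rather
than emerging from link costs alone; whether the original design
hard-constrained continuity is not stated, and this choice is the
package's own.

## Segmentation and multicut

Preprocessing interpolates z linearly to cubic voxels, Gaussian-smooths
(0.25 µm) and subtracts a constant 10th-percentile background. The
threshold scan tries k = 1…8 multilevel-Otsu levels, each candidate level
alone, highest first, and keeps the first foreground inside the target
volume range — a fixed scan order making "at least one threshold works"
deterministic. Cleanup fills 3D holes and removes 26-connected fragments
of ≤ 20 voxels ("at or below": a 21-voxel fragment survives).
Oversegmentation is watershed on the negated smoothed (0.3 µm) Euclidean
distance transform seeded at its regional maxima. Contact areas are
counted over face-adjacent voxel pairs (6-connectivity) × face area.
The multicut ILP minimises total cut area over binary edge variables with
lazily generated cycle-consistency and seed-separation path inequalities
(re-solved until the cut is consistent with a partition separating all
seeds); fragments holding several seeds are first split by geodesic
nearest-seed regions (anisotropy-aware minimum-cost paths). Seedless
clusters are merged to the nearest seed by centroid distance, ties to the
lowest seed id.

## Quantification conventions

TALE labelling: a kinetochore within 2.0 µm (inclusive) of a shifted TALE
centroid is labelled; strictly farther is not. Kinetochore orientation:
leading eigenvector of the region's second-moment tensor, |dot| with the
spindle axis; tied eigenvalues are flagged as degenerate. Telomere
masking reduces the visual "front surface" criterion to the sign of the
telomere centroid's displacement from the sister-pair centroid along the
poleward direction; zero displacement classifies as exposed. ROI
intensities average voxels whose centres fall inside the cylinder
(radius 0.5 µm between sisters) or sphere (radius 1.0 µm), subtract a
background estimate, and are normalised per cell to the mean over that
cell's ROIs. The Mad1 quality filter defaults to background median + 3
robust SD on the Mad1 channel itself (an ambiguity in the described
568-channel assignment was resolved in favour of the Mad1 channel);
a kinetochore is positive if a surviving 1.73/3.47 µm-scale spot lies
within 1 µm. Lagging uses exactly the two probe frames nearest 12 and
20 min after onset — a chromosome absent at +12 but central at +20 is
severe. Anaphase onset is the first frame whose axial DNA profile
(0.4 µm bins) drops below 50% of both flanking maxima over ≥ 0.8 µm.

## Statistics

Fisher's exact test is two-sided by the probability-mass method (summing
hypergeometric tables no more probable than the observed one) — stated
because two-sided conventions differ. The t-test is unpaired, two-tailed,
pooled-variance; zero pooled variance with equal means returns p = 1 and
with unequal means is an error. The Wilcoxon rank-sum test enumerates all
rank assignments exactly (midranks for ties) up to 10 per group and
otherwise uses the normal approximation with continuity and tie
correction; rank-sum (not signed-rank) is used because the compared
kinetochore populations are independent. No multiple-comparison
adjustment is applied anywhere.

## Problem sizes and determinism

The bundled validation suite runs, on one CPU: optimiser-oracle
equivalence on 100 tracking instances and 100 multicut graphs; perfect
pairing/purity recovery on a noise-free 19-bivalent × 60-frame series
(solved in two overlapping batches and stitched); parameter recovery on
cohorts of ≥ 5,000 chromosomes per class (≥ 10,000 pairs for the masking
fraction) generated scene by scene, with rendered-measurement round trips
at 40 scenes for Mad1 and 40 eggs for the IKD means; and 10,000 null
tables for the Fisher type-I-error check. These sizes keep the full suite
to a few minutes while leaving Monte-Carlo tolerances (2× the sampling SE)
meaningful. Every stochastic component draws from
`numpy.random.default_rng` seeded from the scene config, so all outputs —
including rendered volumes — are bit-exact under a repeated seed.

## Known limitations

Tracking assumes tracks span the solved window; a detection missing in a
middle frame ends its track and costs a missing-pair penalty rather than
bridging the gap. The chromatin-component coverage constraint uses
component centroids and equivalent radii, not exact distance transforms.
Attachment-type classification from images is out of scope (simulator
ground truth only), as are rotational registration, deconvolution, and
trainable pixel classification.
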