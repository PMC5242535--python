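# Methods

This note documents the models implemented in `neuropheno`, the defaults
and why they were chosen, and what the synthetic validation does and does
not demonstrate.

## The synthetic study

The generator emulates a longitudinal phenotyping study of homozygous
HdhQ150 knock-in mice against wild-type (WT) littermates: 2 genotypes ×
2 sexes with `n_per_cell` animals per cell, imaged at seven ages
(8, 15, 23, 36, 52, 70, 94 weeks) and tested behaviourally at the same
ages. All inputs to the analysis stages come from this generator, so
every estimate can be checked against known ground truth.

### Brain phantom

Anatomy is a set of analytic ellipsoids on a 64×96×64 grid (axis order
z, y, x) at 0.5 × 0.15625 × 0.15625 mm — the in-plane resolution and
slice thickness of a 128×128, 20 mm field-of-view in vivo protocol.
Regions: a whole-brain envelope, cortex, striatum, hippocampus, corpus
callosum, ventricles (all inside the envelope, mutually disjoint), and a
cheek-muscle block outside the brain that serves as the relaxometry
control. Each region's semi-axes are scaled isotropically so the analytic
ellipsoid volume `4/3·π·abc` matches the trajectory target at the
requested age; region centre offsets scale with the whole-brain linear
scale so relative geometry is preserved as the brain grows or shrinks.
Voxels are labelled by centre-point inclusion, which keeps the voxel-count
volume within a surface-shell bound of the analytic target; per-subject
sub-voxel position shifts act like random grid offsets and make the
cohort-mean volume quasi-unbiased.

Absolute region volumes are not published for this model, so the defaults
(whole brain ≈ 470 mm³, cortex ≈ 85, hippocampus ≈ 22, striatum ≈ 21,
corpus callosum ≈ 10, ventricles ≈ 4 at the WT plateau) are
order-of-magnitude plausible for adult mouse and otherwise arbitrary;
every downstream check is about *relative* change, which the phantom
controls exactly.

### Volume trajectories

Each region × genotype follows a three-phase curve: a normalised logistic
rise from the 8-week volume to a plateau (WT plateau at 36 weeks, when WT
brain growth stops), a flat segment, and — for disease-affected regions
in HdhQ150 — a linear decline from a region-specific onset such that the
94-week volume is `plateau·(1 − decline_fraction)`. This is the simplest
family that reproduces "slower growth, growth arrest, progressive
atrophy". Defaults: striatum plateaus at 15 weeks and declines from 23
weeks by 27%; cortex and hippocampus plateau at 23 weeks and decline from
52 weeks by 12% and 21%; corpus callosum declines from 15 weeks by 10%;
whole brain declines slowly (6%) from 23 weeks. The HdhQ150 cortical
plateau is set 12.5% below WT so the compounded final-age WT gap is ≈23%.
WT regions never decline. Females carry a global 0.92 volume factor;
disease fractions are sex-independent.

Per-subject biology is a log-normal allometric factor (CV 3%) constant
across ages — so each subject's *percent* change is exactly the
configured one — plus per-observation log-normal measurement jitter
(CV 1%) and scanner-session drop-out (missingness 5%).

### MR signal

Voxel signal follows the mono-exponential decay `S0(r)·exp(−TE/T2(r))`
of the voxel's region, with the default 8-echo train at TE = 10…80 ms.
Tissue defaults give a white:grey first-echo ratio of ≈1.25 and Gaussian
noise with first-echo grey-matter SNR ≈ 5 (switchable to Rician). At that
SNR the late echoes sit near the noise floor; the T2 fit's validity mask
exists precisely to flag such voxels.

### Behaviour

Each measure (locomotor distance, grip strength, rotarod latency, T-maze
percent correct, odour discrimination, social interaction) has a linear
WT age curve per sex and a disease deficit that ramps linearly from a
36-week onset (the motor "clinical horizon"; 30 weeks for rotarod) to its
final-age value: locomotion 34% (M) / 39% (F), grip 25%, rotarod 30%,
and — deliberately — zero for the cognitive/social measures, mirroring
the dissociation between motor and cognitive phenotypes. Noise: per
subject-measure ability factor (CV 6%), per-observation noise (CV 5%),
5% missingness, and 1% outliers injected at ±4 within-cell SD so the
Grubbs screen has true positives.

### Histology

Section stacks carry exact object lists: neuron somata (disks, darkness
180) and inclusion blobs in two classes — dense nuclear (darkness 200)
and diffuse (darkness 150) — in sections of known thickness (18 µm).
Rendered pixel values use the transmitted-light convention
`value = 255 − darkness`, so stained pixels are *low*; rendering is
noise-free by default so annotations equal the painted masks exactly.

## Analysis stages

### Relaxometry

`fit_t2_map` solves the log-linear least-squares problem per voxel (exact
on noiseless data); an optional Gauss–Newton refinement in the signal
domain is provided for noisy data. Voxels with any non-positive echo or a
fitted T2 outside (1, 2000) ms are flagged invalid, never silently
zeroed; ROI means use valid voxels only and report the exclusion count.
The validity window is our choice (it excludes background and divergent
fits). Protocol arithmetic: in-plane resolution = FOV/matrix (reported to
the nearest µm), nominal scan time = TR × phase-encode steps × averages —
reproducing 156 µm/21 min (in vivo) and 100 µm/≈3.5 h (ex vivo).

### Volumetry

Volumes are voxel count × voxel volume (phantom labels are exact). The
"peak" age for peak-to-final declines is the argmax of the group-mean
trajectory, not a fixed age, because regions peak at different ages per
genotype. Missing ages are never interpolated; summaries use available
data. Sexes are pooled by default with a flag to split.

### Registration

Linear registration optimises SSD (after dividing each image by its
foreground standard deviation — the zero background must stay at zero so
border fill is intensity-neutral) with Powell's method over a Gaussian
pyramid; 6 dof = rotations + translations, 9 dof adds per-axis log
scales. The text's "uniform scaling" reading of 9 dof is internally
inconsistent (9 parameters need 3 scales); a 7-dof uniform-scale variant
is available for sensitivity analysis. The population template iterates
register-resample-average and re-centres through the inverse of the mean
transform so it cannot drift toward a subject.

The fluid solver is a greedy compositional flow: force
`(fixed − warped)·∇warped`, velocity = Gaussian-regularised force
(σ_fluid, default 2 voxels; 1.5 in the TBM examples), step scaled so the
largest update is ≤ 0.4 voxel, compositional update of the displacement,
step-halving backtracking so SSD is monotone over accepted steps, and
classic regridding (reset the source to the current warp) when the
minimum Jacobian falls below 0.5. This standard approximation of a
full Navier–Stokes solver preserves the contract that matters here —
large diffeomorphic deformations with positive Jacobians — at a small
fraction of the cost. All operators are dimension-generic; 2-D mode is a
first-class citizen used for fast end-to-end studies. Jacobians are
`det(I + ∇u)` by central differences (one-sided at boundaries).

### TBM statistics

Welch's unequal-variance t is computed per masked voxel (zero-variance
voxels are flagged and set to 0). Significance is non-parametric: group
labels are permuted at the subject level (optionally within sex strata),
and the |t| values of *all* permutations at *all* voxels are pooled into
one null — the pooling argument that makes the required null size
`ceil(n_voxels/q)` (840,000 at 42,000 voxels, q = 0.05) reachable with
~100 label shuffles rather than 840,000. p-values carry the plus-one
correction so they are never zero; when fewer distinct label splits exist
than requested permutations the splits are enumerated exhaustively.
Benjamini–Hochberg at q produces the significance mask; directional maps
are reported as signed t with two-sided q. Jacobians are analysed
untransformed ("apparent volume difference"); log-J is available behind a
flag.

### Stereology

`V = ΣP·(a/p)·d` and `N = ΣQ⁻/(ssf·asf·tsf)` with the study's design
constants: 50 µm sections with a 450 µm gap (period 500 µm, hence
ssf = 1/10 — the fraction itself is our inference from thickness and
gap), 65×35 µm frames on 200×200 (cortex) or 400×400 µm (striatum) grids,
18 µm measured thickness, 0.5 µm guard zones, 17 µm dissector. The
Cavalieri point-grid spacing is not published; synthetic validations use
60 µm grids and document that choice. The CE is Gundersen–Jensen with
smoothness m = 1, noise = ΣP and systematic variance
`(3(A − noise) − 4B + C)/240` floored at zero (a negative estimate means
the systematic component is indistinguishable from point noise; constant
count sequences of modest counts therefore give the pure Poisson CE).
Sampling simulators count a neuron when its unique point falls in a frame
(half-open bounds — the point-rule analogue of the unbiased counting
frame) and its depth lies inside the dissector; over random grid/section
offsets both estimators are unbiased, which the tests verify.

### Histology quantification

The printed threshold scale (0 = full transmission, 255 = none) would
make the nuclear threshold (90) admit *more* pixels than the total
threshold (130), contradicting nuclear ⊆ total. We therefore adopt the
transmitted-light orientation — stained pixels are low, a threshold
admits pixels ≤ it — which restores the subset relation; the literal
orientation remains available behind a flag and raises an error when it
breaks the subset relation on a calibration image. The FOV is the whole
section by default with a tiling option for fixed-size non-overlapping
fields. Cortical thickness drops n (default 10) vertical lines between
the callosal and pial boundary polylines, excludes lines that fail to
span both (with a warning), and averages over consecutive sections.

### Cohort statistics

Grubbs' two-sided test uses `G = max|x − mean|/sd` against the critical
value `((n−1)/√n)·√(t²/(n−2+t²))`, `t = t_{1−α/(2n), n−2}`; the screen is
applied once per genotype × sex × age × measure cell, flagging at most
the single most extreme value (iterative mode behind a flag). Age enters
the factorial ANOVA as a between-subject categorical factor — the same
workaround a repeated-measures design with missing sessions forces — and
the fit uses sum-to-zero coding with Type III sums of squares (equal to
the classical decomposition on balanced data; a constant response returns
all-zero F by convention). Correlation matrices are pairwise-complete
Pearson with the Bonferroni gate α/C(k,2) (0.0033 for 6 measures, 0.0024
for 7); post-hocs are pairwise Welch t with p × m capped at 1.

## Validation design and problem sizes

- Effect-size recovery runs 3 seeds × 10 animals per cell × 7 ages on the
  full 64×96×64 grid (≈5 s total) and checks recovered declines/deficits
  within ±3 percentage points of the configured values.
- The end-to-end TBM check runs in 2-D (64×64, 10 subjects per group,
  100 permutations): a planted 20% regional loss must be recovered with
  Dice > 0.5 between the significant-atrophy mask and the planted region.
- FDR calibration (any-discovery rate over 200 null repeats ≤ q plus
  binomial error) exercises the statistical stage on smooth spatially
  correlated null Jacobian maps rather than thousands of fresh fluid
  registrations; the registration stage's own behaviour under planted
  effects is covered by the Dice check, and this split keeps the
  calibration honest about what it measures.
- Estimator-level checks freeze hand evaluations (Welch t, Grubbs G,
  Gundersen CE, Cavalieri/fractionator products) and brute-force oracles
  (exhaustive 2-vs-2 permutation enumeration, dense T2 grid search,
  textbook balanced ANOVA decomposition).

## What passing does not show

The phantoms are analytic ellipsoids with piecewise-smooth trajectories:
they contain no partial-volume mixing, susceptibility or motion
artefacts, no anatomical variability beyond global scale and position,
and no spatially varying coil sensitivity. Behavioural noise is
log-normal and independent across sessions. Registration results on these
phantoms therefore bound the method's behaviour on clean, well-contrasted
data; they say nothing about robustness to real-scanner artefacts.
CAG-repeat variation, husbandry covariates and video-based behavioural
scoring are out of scope; behavioural values enter as tables.

## Known limitations

- The fluid solver is greedy (no momentum/FFT solve); very large
  deformations rely on regridding and the multi-resolution pyramid.
- The log-linear T2 fit is noise-biased at low SNR; the Gauss–Newton
  refinement mitigates but does not remove the Rician floor bias.
- Repeated-measures ANOVA assumes sphericity (no Greenhouse–Geisser
  correction); mixed-effects longitudinal models are out of scope.
- The Gundersen CE is implemented only for smoothness class m = 1.
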