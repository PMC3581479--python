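# Methods

`ratconn` re-implements, as a tested library, a multimodal MRI analysis of
two rat genotype groups: resting-state functional connectivity with
weighted graph metrics, pharmacological-MRI (phMRI) modelling of a
cocaine-induced BOLD response, and diffusion-tensor tractography
connectomes. Because the original animal data are not public, every stage
is exercised against a synthetic-study generator with known ground truth;
this note records the models, the defaults and why, and what the
synthetic checks do and do not establish.

## Synthetic study generator (`ratconn.simulate`, `atlas`, `scheme`)

**Atlas.** `make_atlas` places 23 bilaterally mirrored gray-matter box
ROIs (the corticolimbic parcellation: PFC (dm/vm), Ins, FC, OFC (v/d),
NAc, CPu, GP, Amy, Tha, Hip (d/v), SN, DRN, VTA, ViC, AuC, TeC, PtC, MC,
SmC, RsC) plus 4 midline white-matter ROIs (genu CC, body CC, anterior
commissure, internal capsule) on a configurable grid (default 48x48x24 at
0.5 mm). Placement is lattice-deterministic; left/right homolog pairing
is exact by construction. Boxes rather than anatomical shapes: the
analyses under test depend only on label geometry, homology and voxel
counts, not on anatomical realism.

**Resting BOLD.** Region signals are white Gaussian noise passed through
the same zero-phase spectral band-pass used in analysis (0.01–0.1 Hz at
TR = 0.5 s, 1200 frames), standardized, and colored by the symmetric
matrix square root of the target correlation matrix, so the population
inter-regional correlation equals the target exactly and the spectrum
matches the analysis band. The voxel volume broadcasts each region's
signal into its labels and adds independent voxel noise (SD 0.5 relative
to the unit-variance signals), a global band-limited component (0.3), six
random-walk motion traces (0.2, coupled into the volume through their
sum), and a linear drift (0.3); all additive nuisance time courses are
returned so that ideal preprocessing is well defined. With the spectral
band-pass the sampling SD of a single-run correlation estimate at 1200
frames is about 0.09 (about 108 independent low-frequency samples), which
sets what "recovery" can mean for one run; recovery tests therefore
average FC over simulation seeds.

**phMRI.** Each subject x ROI series (in %BOLD; 20 baseline + 80
post-injection frames, 0.5 min apart) is
`lam * g(t - t_inj; alpha, beta)` plus covariate offsets plus stationary
discrete AR(1) noise (`Corr = phi^|dt|`, frame units). Subject x ROI
log-parameters are drawn around group-level means with log-SD 0.3 (CV
~31%, in the range of the printed between-subject tables). Default group
means: shape 2.0, rate 0.6/min, scale 12 %BOLD*min for the reference
group — peak ~2.7 %BOLD at ~1.7 min post-injection, peak/AUC ~0.22/min,
matching the printed peak-to-AUC regime — and a 40% scale inflation for
the "knockout-style" group. Noise SD 0.5 %BOLD per frame, phi = 0.4 by
default (0.3 in the recovery tests). Physiological covariates
(PaCO2 before; MABP before and at peak) are drawn from plausible mmHg
distributions with small linear effects, and a configurable fraction is
set missing to exercise group-mean imputation.

**Diffusion.** `make_scheme` spreads 50 unit directions (b = 1250 s/mm^2,
2 leading b0 volumes) by antipodal electrostatic repulsion from a seeded
random start. Phantoms assign prolate tensors (closed-form eigenvalues
for a requested FA at MD = 0.7e-3 mm^2/s) to voxels within a radius of a
bundle centerline, aligned with the local tangent; background is
near-isotropic below the FA = 0.2 seeding threshold. Crossing-fiber
voxels keep the first-listed bundle's tensor — a documented single-tensor
limitation that matches the analysis model. The forward DWI signal is
`S = s0 exp(-b g^T D g)` with optional Rician noise (SNR = s0/sigma).

## Resting-state pipeline (`ratconn.bold`)

Preprocessing follows the published order: Gaussian spatial smoothing
(FWHM 1.0 mm, sigma = FWHM/2.3548), per-voxel linear detrend, OLS
nuisance regression (intercept + global mean + 6 motion traces + linear
trend; collinear columns dropped with a warning; the global-mean column
can be excluded via `include=` since global-signal regression is debated),
then the band-pass. The band-pass is a zero-phase spectral (FFT-mask)
filter: unit passband gain, complete stopband rejection, DC removed — the
convention of standard resting-state band-pass tools and the
minimum-variance choice for correlation estimation. Order matters
(nuisance regression before filtering can reintroduce stopband energy
into neither — the residual projection happens on unfiltered data, as
published).

FC is Fisher z' = atanh(r) with |r| clipped at 1 - 1e-7 so degenerate
(perfectly correlated) synthetic inputs never abort a batch; diagonals
and constant series are NaN. Homologous averaging: intra-hemispheric
value(A,B) = mean{z(A_L,B_L), z(A_R,B_R)}, inter-hemispheric value =
mean{z(A_L,B_R), z(A_R,B_L)}, homotopic value(A,A) = z(A_L,A_R). ROIs
spanning fewer than 2 voxels are excluded, mirroring the exclusion of
regions too small to identify at acquisition resolution.

## Brain graphs (`ratconn.graph`)

Graphs are weighted and undirected; self-connections always removed and
negative weights dropped by default (as published), with no thresholding
of positive weights. Clustering is the Onnela coefficient (weights
normalized by the maximum; degree-<2 nodes contribute 0). Path length
maps weight w to length 1/w — the standard choice for correlation-like
weights; the source analysis does not state its mapping, so this is a
documented package decision. Unreachable pairs are excluded from the mean
and their fraction reported (disconnection is likewise unaddressed in the
source). Normalization divides by the mean metric over surrogate networks
with the same nodes whose edge weights are randomly permuted; the default
permutes weights across the existing edge slots (density and topology
preserved), `surrogate="full-rewire"` additionally randomizes edge
positions. For an equal-weight complete graph both normalized metrics are
exactly 1 by permutation invariance. Whether ordered or unordered pairs
are averaged is immaterial for symmetric graphs.

## phMRI response (`ratconn.phmri`)

The response is a scaled gamma density
`f(t) = lam * beta^alpha t^(alpha-1) e^(-beta t) / Gamma(alpha)`, so the
area under the curve ("total activation") equals `lam` exactly and the
peak is at `(alpha-1)/beta` with amplitude
`lam * beta (alpha-1)^(alpha-1) e^(1-alpha) / Gamma(alpha)`. The density
form was chosen precisely because it makes AUC = lam an identity.

**Subject-level fits** are nonlinear least squares of
`offset + f(t - t_inj)` with method-of-moments starts; they seed the
hierarchical priors.

**Hierarchical Bayesian model.** Subject x ROI parameters are modeled on
the log scale with normal group-level distributions (per-group means,
shared SDs) — positivity enforced by the link, since the source does not
state a truncation. Priors: group-level means normal, centered on the
median of the subject-level fits with SD = 10x their interquartile range
(floored at 1); group-level SDs half-normal(1) on the log-parameter
scale; noise SD half-normal(2x the median subject-fit residual SD). The
likelihood models stationary AR(1) noise on the frame grid with a
logit-normal prior on the lag-1 correlation — matching both the generator
and the GLS analysis model; with a white-noise likelihood the fits showed
a small systematic scale/rate trade-off bias under autocorrelated noise.
The hierarchy is sampled in its non-centered form (subject log-parameters
= group mean + group SD x a standard-normal offset, with the offsets as
the sampled variables): the centered form mixes poorly along the
shape/rate/scale ridge and, initialized at the scale-biased least-squares
fits, produced visibly biased group-level posteriors at realistic noise.
ROIs share no parameters, so the model factorizes exactly and is sampled
per ROI with an affine-invariant ensemble sampler (differential-evolution
moves, 2*ndim+2 walkers, 50% burn-in, internal RNG seeded for
bit-reproducible runs), initialized at the subject-level fits. Convergence is gated at split-R-hat < 1.1 computed over four walker
subgroups, each split in half; violations flag (not silently discard) the
result. Group-difference summaries pool per-ROI difference draws; the
across-ROI average of the group-level mean is exposed as a per-draw
average over the independent per-ROI chains. Group-level means are
reported on the natural scale as exp(mu) (the group median). At the
default noise level the posterior retains a small (~3%) scale bias from
the nonlinearity of the fit — visible only when pooling many ROIs, and
documented rather than tuned away.

**GLS with continuous-time AR(1).** Error correlation `phi^|t_i - t_j|`
with phi estimated by profile maximum likelihood on [0, 1); the
regression is solved on the exactly whitened system (first-observation
scaling included in the log-determinant). `normalize=True` z-scores the
response and non-constant predictors, matching the normalized-coefficient
reporting convention. Near-unit-root estimates warn.

**Voxel design matrix**: a representative gamma-variate curve fitted to
the grand-mean time course, the 6 motion traces, and the first 3 left
singular vectors of the per-subject mean responses minus the
representative curve (orthonormal by construction; reduced with a warning
when subjects are fewer). First-level voxel fits reuse the per-subject
phi estimated from the subject's mean series — one noise process per
acquisition — so thousands of voxels can be whitened with a single
profile-likelihood search. Second level: OLS of the response coefficients
on group plus covariates (group-mean imputed), yielding the group t-map.

**Mixed model**: REML linear mixed model of per-ROI summaries (AUC or
peak) on group plus covariates with a random intercept per subject; a
numerically zero random-effect variance collapses to OLS and is flagged.

## DTI (`ratconn.dti`)

Tensor fit: log-linear least squares of `ln S` on the 6 tensor elements
plus ln S0; non-positive signals clamped to epsilon and flagged; negative
eigenvalues clamped to zero with a per-voxel flag (this affects FA in
noisy regimes). FA and MD from eigenvalues in the standard closed form.

Tractography integrates the principal eigenvector of the trilinearly
interpolated tensor (interpolate components, then decompose)
bidirectionally from 10 uniform random seeds per voxel with FA > 0.2,
with sign continuity, 0.1 mm steps (small relative to the 0.25 mm grid so
the 35 degree per-step cap approximates a curvature limit), terminating
on FA <= 0.2, turns > 35 degrees, or volume exit. Seed placement within
the voxel is uniform (the referenced implementation does not state its
distribution). Streamlines are stored in mm world coordinates
(axis-aligned, index*voxel_size) and serialized as JSON-lines.

Connectome: a streamline joins ROI pair (A,B) iff its endpoint voxels are
labeled A and B (no dilation) and its arc length is >= 1.0 mm (excluding
trivial neighbor connections); the edge weight is the mean FA over all
points of all contributing streamlines (pooled; a per-streamline-mean
variant is togglable). White-matter ROI statistics use two-sample t-tests
with BH-FDR and pooled-SD Cohen's d.

## Inference utilities (`ratconn.stats`)

Two-sample tests use pooled variance (Student), consistent with
`d = t*sqrt(1/n1 + 1/n2)` reproducing the printed effect sizes; the
`d = 2t/sqrt(df)` convention is provided separately, and neither is
declared canonical. BH-FDR is the step-up procedure with enforced
monotonicity. Cluster-extent thresholds simulate smoothed, re-standardized
Gaussian noise volumes, threshold at the one-sided voxel p, and take the
(1-alpha) quantile of the maximum cluster size (6-connectivity);
AlphaSim internals are not replicated — the contract is the Monte-Carlo
quantile definition. Covariate imputation replaces missing values with
within-group means and rejects groups with no observed value.

## Problem sizes in the shipped checks

Chosen to make the statistical contracts testable at interactive cost:
FC recovery uses a 4-pair atlas on a 24x24x12 grid, 1200 frames, 20 (test)
or 10 (acceptance script) seeds; hierarchical recovery uses 10+10
subjects x 21 ROIs with 1500 ensemble steps, and null-difference CI
calibration 20 replicate studies of 6+6 subjects x 1 ROI at 2000 steps;
tractography phantoms use a 40x24x12 grid at 0.25 mm with ~160 bundle
voxels; type-I calibration uses 2000 null replicates at n = 12 vs 15.

## What the synthetic checks do not show

The generator reproduces the statistical structure of the study, not the
physics or physiology: no k-space/artifact simulation, no registration
error, no slice timing, no cardiorespiratory noise, no HARDI multi-fiber
geometry (crossings are single-tensor by construction), box-shaped ROIs,
and linear covariate effects. Passing recovery tests therefore
demonstrates correctness of the estimators under their assumed models at
realistic noise, not robustness to the real data's violations of those
assumptions. Parameter-recovery margins quoted above (e.g. the ~3%
high-noise scale bias) are properties of this noise regime.
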