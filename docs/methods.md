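# Methods

`fcdmap` computes voxel-wise functional connectivity density (FCD) maps
from resting-state BOLD volumes and decomposes them by hemisphere. This
note records the model, the parameters that matter, what the phantom
generator does and does not emulate, and the numerical and design choices
a maintainer would want to know about.

## The connectivity model

All voxels inside a gray-matter mask (N of them) are treated as nodes of
a graph. Two voxels i and j are connected when the Pearson correlation of
their cleaned time series exceeds a threshold:

    S_ij = 1  if  r_ij > θ   (θ = 0.6 by default, strict inequality)

Negative correlations never connect — the condition is one-sided. Three
degree maps follow for every voxel i:

    gFCD_i = Σ_{j≠i} S_ij                      (global degree)
    cFCD_i = Σ_{j≠i} h_ij S_ij                 (contralateral degree)
    iFCD_i = gFCD_i − cFCD_i                   (ipsilateral degree)

where h_ij = 1 exactly when i and j lie in *opposite* hemispheres.
Hemisphere membership comes from the sign of the world x coordinate under
the NIfTI affine (RAS: x < 0 left). Voxels with |x| < 1e−6 mm are
*midline*: they belong to neither hemisphere, so h = 0 for every pair
touching one — a midline voxel's degree is entirely ipsilateral. The
normalized maps divide all three raw counts by the subject's mask-mean
global count, so the mask mean of normalized gFCD is exactly 1 and the
g = c + i identity survives normalization.

The mask-mean in the denominator runs over gray-matter voxels only (the
same mask that defines N); where a handful of masked voxels have constant
series (common at mask edges in real data) they are dropped from the
working mask with a logged warning and receive 0 in every map.

### Blockwise computation

The N×N correlation matrix is never materialized. Series are centered and
scaled to unit norm once; correlations are then inner products, evaluated
over upper-triangular block pairs with each supra-threshold pair credited
to both endpoints. The counts are identical to an exhaustive double loop
over pairs and invariant to the block size (both properties are tested,
against an `np.corrcoef` pair loop and across block sizes). Differences
could arise only if a correlation sat within float round-off of θ, which
has probability ~0 for continuous data.

## Temporal preprocessing

Per masked voxel, in this fixed order:

1. **Linear detrend** — OLS residual on {intercept, ramp}; removes the
   slow scanner drift and the mean. (Correlation is mean-invariant, so
   removing the intercept is harmless and keeps the nulls simple.)
2. **Nuisance regression** — OLS residual on {intercept} ∪ regressors
   (motion, WM, CSF, global signal). Rank-deficient designs are rejected
   with the collinear columns named.
3. **Band-pass 0.01–0.08 Hz** — an ideal (rectangular) filter in the
   discrete Fourier domain with *inclusive* band edges; DC is removed.
   The ideal realization was chosen because it is exactly idempotent and
   testable bit-exactly against direct DFT-bin zeroing. Note that an
   ideal filter fully suppresses a stop-band sinusoid only when the tone
   sits on a DFT bin; off-bin tones leak a few percent through spectral
   smearing, as any finite-length realization does.

Optional Gaussian smoothing (default 8 mm FWHM when enabled,
σ = FWHM/(2√(2 ln 2)) per axis converted to voxels via the affine,
reflective boundaries) runs *before* the temporal stages, mirroring the
convention of spatially smoothing during spatial preprocessing and
cleaning afterwards; the literature is not explicit on this order and it
is recorded here as a convention, not a derived fact. All temporal stages
are linear projections or ideal filters, hence non-expansive: per-voxel
energy can only decrease (a tested invariant). No motion
scrubbing/censoring is performed.

## Group statistics

Voxel-wise comparison fits, at every masked voxel, an OLS model of the
FCD value on {intercept, group, age, sex}, with group coded control = 0,
case = 1 (negative t ⇒ lower in cases) and sex as a binary indicator.
The group coefficient's t statistic with df = n − p and a two-tailed p is
the test; with covariates removed it reduces exactly to the classical
pooled-variance two-sample t (tested to 1e−10). Voxels where the design
fits exactly (residuals at round-off) are reported as t = 0, p = 1 when
the group coefficient is also null — identical maps — and t = ±inf,
p = 0 when it is not (perfectly separated groups, which saturated
phantoms can produce).

Multiplicity is controlled per measure by Benjamini–Hochberg over the
masked voxels at q = 0.05, then a cluster-extent filter: connected
components of the significance mask under 18-neighbor connectivity with
fewer than 20 voxels are discarded. 18-connectivity and per-measure FDR
are conventions of the standard neuroimaging tooling; the overlap map
(counting in how many of the three measures a voxel is significant) is
where the measures are compared. Cluster peaks are the member voxels of
maximum |t|, reported in world mm.

Severity analysis: per subject, the mean (or max) of a chosen FCD map
over each surviving cluster of *decreased* connectivity; then the
partial Pearson correlation between that regional summary and the
clinical score, controlling age and sex — both variables residualized on
{intercept, age, sex}, ρ = Pearson of residuals, df = n − 2 − k
(so n = 221 complete cases with two covariates gives df = 217),
p two-tailed from t = ρ√(df/(1 − ρ²)), BH-corrected across the regions
tested. Pearson-on-residuals was chosen over a rank-based variant; rows
with any missing value are dropped per test, with n and df reported.

## The phantom generator

A phantom is a rectangular grid (2 mm voxels, centered affine: an
odd-width grid has a true midline plane, an even-width grid two equal
hemispheres) with latent networks. A member voxel of network k with
coupling weight w has

    x_v(t) = √w · z_k(t) + √(1−w) · ε_v(t),

z_k and ε_v independent unit-variance white noise, so the expected
pairwise correlation between members is exactly w — the closed form that
makes expected degrees computable by hand (e.g. 15+15 mirrored voxels at
w = 0.8 ≫ θ: each member sees ≈15 contralateral and ≈14 ipsilateral
partners; a unilateral network has cFCD ≈ 0). *Homotopic* networks are a
left-hemisphere seed plus its exact mirror image sharing one latent
signal — the synthetic analogue of bilateral resting-state networks.
Off-network voxels are pure noise. Optional nuisance signals (default: 6
motion-like + WM + CSF + global columns, amplitude 0 so the table exists
but the data stay clean unless contamination is requested) are added
uniformly to all voxels; an AR(1) switch exists for the latent/noise
processes but defaults off, keeping correlation nulls exact. A baseline
of 100 gives the data a BOLD-like offset; correlations are unaffected.

Cohorts add: group labels (cases multiply each network's coupling by its
`group_effect`), ages uniform on [8, 30] years, sex male with probability
0.85 (so covariate adjustment is genuinely exercised), a per-subject,
per-network coupling multiplier drawn uniformly from a configurable
range (default (0.6, 1.0)), and a clinical score
α + β·m + σ·e tied to the multiplier m of a designated network
(defaults α = 10, β = −20, σ = 10, i.e. |β|/σ = 2: severity rises as
regional coupling falls). Everything is reproducible bit-for-bit from
one seed, with per-subject volumes regenerated on demand from spawned
child seeds rather than held in memory.

**Study designs.** Two canned phantoms define the recovery experiments:

- *Group study* (16³ grid, T = 200, TR = 2 s): an "affected" homotopic
  network of 3×3×3 voxels per hemisphere whose coupling is halved in
  cases, a same-sized "stable" homotopic network common to both groups,
  and a unilateral network. The affected network is 27 voxels per side
  because a component must reach the 20-voxel cluster minimum to be
  detectable at all. The stable network keeps every subject's mean
  global degree — the normalization denominator — well away from zero;
  without it, weakly-coupled case subjects can have *no* connections,
  making normalized maps ill-defined.
- *Severity study* (10³ grid, T = 200): an "affected" homotopic network
  (2³ per side) with multiplier ~ U(0.1, 1.0) driving the score, and a
  stable network with multiplier ~ U(0.8, 1.0). The wide spread on the
  affected network is the point: the association between regional FCD
  and score lives entirely in inter-subject coupling variability, and a
  spread of U(0.1, 1.0) puts the expected score–summary correlation
  near −0.4 at n = 60 (a power calculation done when the design was
  fixed), where detection at BH-corrected p < 0.05 is reliable across
  seeds.

**What the phantoms do not emulate:** hemodynamic response shapes,
physiological noise spectra, spatial autocorrelation of real BOLD noise,
scanner artifacts, multi-site heterogeneity, realistic gray-matter
geometry, or registration error. Passing recovery tests therefore shows
the *pipeline machinery* is correct and sensitive under the stated
generative model — not that real-data effect sizes or false-positive
rates will match.

## Problem sizes and runtime

The recovery experiments repeat 30+30-subject cohorts over independent
seeds: 10 effect + 10 null seeds in the test suite, 5 + 5 in the
acceptance script; one 16³ cohort takes ~12 s single-threaded, dominated
by the blockwise correlation pass (O(N²T), ~0.4 s per subject at
N = 4096, T = 200). Recovery is reported as a rate over seeds (≥ 8/10
detection, ≤ 1/10 null false-cluster seeds in the tests) because any
single cohort is a random draw.

## Degenerate inputs and tie-breaks

- Zero-variance series: an error (naming the voxel) at the degree-kernel
  level; dropped from the working mask with a warning at the
  subject-map level.
- mean gFCD = 0 (no connections anywhere): an error advising a
  threshold/data check — normalization is undefined.
- c > g anywhere is an internal-consistency error (cannot happen through
  the public path).
- Cluster peak ties (equal |t|) resolve to the first member in C-order
  of `np.argwhere`; deterministic.
- Constant covariates (e.g. a single-sex cohort) are dropped from the
  GLM design with a warning, adjusting df accordingly.
- BH on an empty p-vector returns empty; a single p value is returned
  unchanged.

## Known limitations

- The ideal band-pass has infinite impulse response in time; for very
  short series its implicit periodicity assumption matters more.
- The GLM assumes homoscedastic Gaussian residuals voxel-wise; normalized
  FCD counts are discrete and right-skewed at low degree, so small-n
  inferences on near-empty maps are approximate.
- Cluster inference is extent-thresholding only (no permutation or
  random-field correction).
- Hemisphere assignment trusts the affine's RAS orientation; data in
  LAS or oblique orientations must be reoriented first.
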