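# Methods

## Generative model and what the synthetic cohorts emulate

Each subject's component timecourses are drawn from a K-state hidden Markov
model with multivariate Gaussian emissions: state-specific mean activation
patterns over C channels and one covariance matrix shared across states.
State mean maps are random orthonormal C-vectors (unit norm, pairwise
centered correlation ≤ 0.3 for C ≥ 4), standing in for independent-component
spatial modes.  The shared covariance defaults to isotropic with noise SD
0.5 per channel, giving a Mahalanobis separation of about 2.8 between state
means — states are individually discriminable from single volumes only
imperfectly, so temporal structure matters to the fit, as in real data.

Group structure is planted in the transition matrices.  The base matrix has
stay-probability 0.8 (mean state lifetime 5 volumes ≈ 10 s at TR 2 s, in
the range reported for fMRI brain states) and uniform off-diagonal mass.
Patients' rows are exponentially tilted toward a designated executive state
set and away from a subcortical state set, with the tilt solved by root
finding so the stationary executive mass rises by exactly the configured
`occupancy_shift` (default 0.1); rows stay stochastic for any attainable
shift.  Each subject's matrix is then perturbed by a Dirichlet draw
(concentration 600 × row) for mild between-subject heterogeneity.  These
two values were calibrated once so that the full pipeline detects the
group difference at n = 24 vs 22 with high power, which is the regime the
pipeline is intended to validate; they are config-exposed, not asserted as
empirical truth.

Severity (a PSPRS-like score, patients only; location 34.9, scale 14) is a
linear function of the patient's true executive-minus-subcortical occupancy
contrast plus Gaussian noise, with the planted correlation equal to
`severity_loading` (default 0.6).  Since the discriminating occupancy
component is oriented so patients score more negative, the within-patient
severity correlation is negative by construction — the sign structure the
pipeline must recover.  A subcortical-volume proxy loads (default 0.3) on
subcortical-state occupancy; the frontal-thickness proxy carries no planted
loading.  Ages are N(68, 8) and sex Bernoulli(0.5).

Motion realism: one latent per-subject motion level (lognormal, σ = 0.5)
scales a six-parameter random-walk trace with occasional spikes, and the
same level injects FD-coupled artifacts into the timecourses (2 signal
units per mm FD, random channel weights).  This makes the four QC indices
co-vary as they do in practice, so the any-metric 1-SD exclusion rule
removes roughly 20–35% of subjects rather than half.  A model-mismatch mode
(AR(1) noise or per-state covariance scaling) exists for robustness checks.

What the generator does **not** emulate: hemodynamic response shapes,
spatial structure (there are no voxels, only component channels),
physiological noise spectra, scanner drift, or clinical phenotype subtypes.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the assumed model family — not that effects of this
size exist in any particular patient cohort.

## HMM fitting

Maximum-likelihood EM (Baum–Welch) rather than variational Bayes:
deterministic given the seed, oracle-checkable against exhaustive path
enumeration, and sufficient for occupancy/switching metrics.  Details:

- **Initialization**: k-means on pooled volumes for state means; sample
  covariance of the pooled data; transition matrix with 0.9 diagonal;
  uniform initial distribution.  Multiple restarts (default 3) with
  different k-means seeds; the best final log-likelihood wins.
- **Numerics**: the forward–backward recursions use per-frame scaling with
  a per-frame log-shift of the emission densities, which is exactly
  equivalent to log-space and cannot underflow on finite input.  When all
  subjects share a series length, the recursion is vectorized across
  subjects (the time loop runs once for the whole cohort).  The
  log-likelihood is checked non-decreasing every iteration (1e-8 relative
  slack); convergence at relative change < 1e-6 or 500 iterations.
- **Shared covariance**: the M-step pools responsibility-weighted scatter
  across all states, plus a ridge of 1e-6 · trace/C on the diagonal.
- **Empty states**: a state whose total responsibility falls below 1 is
  re-seeded at a random frame (logged) rather than aborting.
- **Chains per subject**: all subjects share transition matrix and
  emissions; each subject's chain restarts at their boundary with the
  model's initial distribution.
- **Metrics**: fractional occupancy from soft posteriors (gamma) by
  default, switching rate from the Viterbi path; both choices are
  config-exposed since either convention is defensible.
- **State matching** across fits: Hungarian assignment on Dice coefficients
  of mean maps binarized at |activation| > 0.5 SD (threshold
  config-exposed).  Dice on absolute-value maps is sign-blind, so a
  signed-correlation mode exists and is what the parameter-recovery
  checks use.

## Multiscale entropy

Sample entropy is −ln(A/B) with template pairs counted over i < j, both
template sets drawn from the first T − m positions (so the length-m and
length-(m+1) counts are comparable), Chebyshev distance, self-matches
excluded.  Defaults m = 1, r = 0.35.  The tolerance is fixed in units of
the standardized original series and not recomputed per scale, preserving
the signature that distinguishes white noise (entropy falls with scale)
from 1/f-like signals (entropy sustained); per-scale renormalization is
available by flag.  Coarse-graining is non-overlapping window means; the
number of scales defaults to 4 for T ≥ 300 and 3 otherwise, and the series
must leave at least 10 usable points at the coarsest scale.  Zero-match
(undefined) entropies propagate as NaN and are excluded from channel
averages with a logged count; the across-scale sum is taken per channel
first, then averaged over channels.

## Wavelet connectomes and graph topology

The MODWT is computed by the circular pyramid algorithm with Daubechies
filters rescaled by 1/√2 per level (filter coefficients from PyWavelets);
under periodic boundary the detail/smooth variances partition the series
variance exactly, which the tests verify.  The default filter is the
shortest standard Daubechies (length 4), maximizing usable coefficients at
T = 200; the first (2^j − 1)(L − 1) + 1 boundary-affected coefficients are
dropped before correlating.  The level-j band spans fs/2^(j+1)–fs/2^j Hz;
at TR 2 s, level 2 gives 0.0625–0.125 Hz (the formulaic band; the filter's
finite roll-off means neighboring bands leak, more so for short filters).

Edges are ranked by signed correlation (most positive first; an
absolute-value mode exists) and exactly round(density · R(R−1)/2) edges are
retained, ties broken by node index and logged.  Clustering coefficient and
characteristic path length are computed on the binarized graph (networkx),
path length over reachable pairs only with the excluded fraction logged.
Normalization divides by the mean over an ensemble of degree-preserving
double-edge-swap rewirings (default 1000 per the field convention; 100 in
the benchmarks here, which the calibration checks show is ample for ratio
estimates).  Swap-exhausted graphs (e.g. a triangle) are returned unchanged
with a warning.  Weighted degree is computed on the density-retained
weighted matrix (a full-matrix mode exists).

## Permutation statistics

The GLM contrast test uses Freedman–Lane: residuals of the nuisance-only
model are permuted, the full model is refit, and the FWE-corrected p comes
from the permutation distribution of the maximum |t| over all outcomes and
contrasts in the call (the family is whatever one call contains, made
explicit by the caller).  The observed data count as one permutation, so
the smallest attainable p is 1/(n_perm + 1).  Degenerate (zero-variance)
outcomes are flagged NaN and dropped from the family.  Sign-flipping
schemes are not implemented.

FO PCA runs on the column correlation matrix (occupancy components have
unequal variances; correlation avoids dominance), pooled across groups,
retaining eigenvalues > 1; each loading vector is oriented so its
largest-magnitude entry is positive, and the group-discriminating component
is subsequently re-oriented so the case group scores below controls.
Demographic t-tests are pooled-variance (a Welch mode exists) and the 2×2
χ² uses no continuity correction — both choices verified to reproduce the
published cohort tables from their summary statistics.  Two-sided p-values
throughout.

## Quality control

FD is the sum of absolute translation differences plus 50 mm times the sum
of absolute rotation differences; DVARS the RMS across channels of the
volume-to-volume difference.  Spike percentage is threshold exceedance
(FD > 0.5 mm or signal change above 3× the channel's median absolute
successive difference), summarized per subject as the maximum and median
over channels — an approximation to voxelwise spike maps, config-exposed.
The exclusion rule is one-sided (mean + 1 SD, sample SD with n−1), since
all four indices are worse-when-larger; thresholds come from the supplied
cohort by default, with an external reference table accepted.  The motion
covariate is the within-subject mean of the four z-scored indices and is
affine-invariant to any single metric's units.

## Problem sizes used in the benchmarks

The replicate studies run at desk scale, chosen once: group-effect
replicates use 22 + 24 subjects, 12 channels, 305 volumes, 4 states, 500
permutations, 100 seeds; parameter recovery uses 20 subjects × 300 volumes
(plus one 3000-volume series for transition recovery); calibration uses
500 null replicates of n = 40 with 5 outcomes and 1000 permutations; graph
benchmarks use 100-graph null ensembles.  Fewer states and channels than a
full 30-component, 8-state analysis keeps a hundred replicate fits cheap
while preserving every structural feature of the problem (compositional
FO, state matching, nuisance covariates, max-statistic FWE).

## Known limitations

- EM with k-means restarts can still find local optima; the recovery tests
  bound the practical consequence at the benchmark scale, not in general.
- The Gaussian shared-covariance emission model matches the generator by
  design (the mismatch modes probe robustness but are not exhaustive).
- Permutation exchangeability is assumed across all subjects; no
  block/within-group permutation schemes are implemented.
- Graph metrics are implemented for binary (plus retained-weight degree)
  undirected graphs only; negative-weight graph theory is out of scope.
- The spike-percentage definition is a stated approximation; absolute
  values of the QC indices are not comparable to scanner-derived ones,
  only their between-subject ordering matters here.
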