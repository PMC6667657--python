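# Methods

This note documents the models, numerical choices and limitations of
the package, in the spirit of a statistical-software methods appendix.

## Study design being emulated

A small open-label longitudinal cohort (~12 subjects) imaged at rest at
three sessions — pre-intervention, post-intervention (8 weeks), and an
8-week follow-up — with the Tinnitus Functional Index (TFI) collected
at each session. Analyses relate within-subject *changes* between
consecutive sessions (network measures vs TFI), compare group community
structure between sessions, and regress voxelwise seed connectivity on
TFI longitudinally. Subject-level data for such studies are typically
available only on request, so the package ships generators for every
input, with ground truth recorded alongside.

## Synthetic data

**ROI panels.** Each subject-session matrix is drawn from a zero-mean
Gaussian whose correlation is block-structured: `rho_within` inside
each planted community, `rho_between` across, unit variances. Session
effects add a shift to the within-block correlation — the default
trajectory (0, −0.10, −0.02 for pre/post/follow-up) emulates a
segregation dip after the intervention that largely rebounds at
follow-up. A per-subject-session jitter of the within-block correlation
(SD 0.04 by default) creates genuine between-subject spread in graph
measures; without it, all between-subject variance would be sampling
noise. An optional AR(1) coefficient imposes temporal autocorrelation
with the same stationary covariance (off by default: independent
samples keep null calibrations interpretable). Default scale mirrors
the emulated study: 12 subjects, 3 sessions, 90 ROIs, 300 time points
at TR = 2 s.

**Clinical scores.** Pre-session TFI is drawn at mean 50.92, SD 15.57
(the emulated cohort's moments; per-subject values are not public, so
only the marginals are matched). Between-session score changes are
coupled to supplied per-subject network changes by a Gaussian
construction on standardized deltas, z_score = ρ·z_net + √(1−ρ²)·ε, so
the *population* correlation of the deltas is ρ (default 0.7); the
mean change is −15.5 pre→post and 0 afterwards, SD 10, echoing the
observed severity drop that then holds. Coupling operates on deltas,
not raw scores, because the downstream analyses are delta–delta
correlations.

**SBM fixtures and voxel data.** Subject networks for community-model
tests are independent Bernoulli draws from a planted partition (p_in
within blocks, p_out across). Voxel datasets place a spherical seed
region sharing a latent time course and a disjoint target region whose
correlation with the seed is base_rho + effect_beta·(TFI − mean TFI),
clipped to ±0.95; everywhere else is independent Gaussian noise. With
effect_beta = 0 the score is globally uninformative — an exact null
for GEE calibration. No hemodynamics, motion or scanner artifacts are
simulated; passing tests show the *statistics* behave as designed, not
that the pipeline is robust to real-data artifacts.

## Denoising

Nuisance regression (ordinary least squares on [intercept |
confounds], dropping exactly collinear columns with a warning) runs
*before* filtering so confound fits cannot reintroduce out-of-band
energy. The band-pass is a second-order Butterworth applied
forward-backward (zero phase) over 0.008–0.08 Hz, the canonical
resting-state band; its squared magnitude response retains ≥ 99% of a
mid-band sinusoid and passes ≤ 2% at 2.5× the upper edge. A Butterworth
band is not a brick wall, so denoising is deliberately *not* claimed to
be idempotent: a second pass attenuates band-edge content further
(nuisance regression alone is exactly idempotent).

## Networks

Edges are the E = round(d·n(n−1)/2) largest-|r| pairs; ties at the cut
are broken by descending |r| then lexicographic (i, j), which makes
edge sets nested across densities and runs reproducible. Negative
correlations enter by absolute value — anticorrelated ROI pairs become
edges, which matters when interpreting "connectivity". The density
grid {0.05, 0.10, 0.15, 0.20, 0.25} covers the sparse regime used for
static analysis; dynamic analysis fixes width 20 TRs (40 s), step
1 TR, density 0.10. A 300-point scan yields 281 windows; the package
exposes `n_discard_initial` for acquisitions that drop initial volumes
(e.g. 304 collected, 299 analysed → 280 windows) but defaults to 0
rather than guessing any particular scanner's discard rule.

## Graph measures

Modularity uses the Newman–Girvan quality and seeded Louvain with 20
restarts keeping the best Q (window-wise dynamic metrics default to 1
restart — a 20-fold cost saving where each of ~10⁴ windows would
otherwise be optimised repeatedly; the trade-off is a slightly noisier
dynamic Q course). Efficiency conventions: unreachable pairs
contribute 0, keeping E ∈ [0, 1]; local clustering of degree-<2 nodes
is 0 and *included* in the global mean, which depresses C_glob on very
sparse graphs — a convention choice, applied consistently. An
exhaustive-partition maximiser (restricted-growth-string enumeration,
vectorised Q over all partitions; ≤ 10 nodes) serves as an independent
oracle: best-of-20 Louvain attains the exact maximum on ~94% of random
8-node graphs, and never exceeds it.

## Random-effects SBM via Co-OSNTF

Objective: Σ_s‖A_s − H_s S_s H_sᵀ‖²_F + λΣ_s‖H_sH_sᵀ − HHᵀ‖²_F +
μ(Σ_s‖H_sᵀH_s − I‖²_F + ‖HᵀH − I‖²_F), all factors nonnegative.
λ and μ are specified on a loss-normalized scale (each penalty rescaled
by the data-fit term at initialization) so λ = μ = 1 are balanced
defaults regardless of graph size or density. Optimisation uses
multiplicative updates with a damping exponent of ½ — symmetric
tri-factorizations overshoot at the full Newton-like step — plus
backtracking (halve the exponent, up to 5 times) so the recorded
objective trace is non-increasing by construction; if no step is
accepted the fit stops and flags non-convergence. Initialization takes
the positive and negative parts of the leading eigenvectors of the mean
adjacency as separate candidate columns and keeps the k largest-norm
ones (folding signs by |·| merges communities and noticeably hurts
recovery); 20 random restarts perturb this base, keeping the best final
objective. Tolerance: relative objective change < 1e-6. The community
count k is the rounded-half-up median of per-graph Louvain counts.

**Session comparison.** The null is within-subject exchangeability of
session labels: each subject's pre/post networks are swapped or not,
and both group models are refitted per pattern (exact enumeration of
the 2^n patterns when ≤ 1024, otherwise sampled with the add-one
p-value). Observed and permuted statistics use identical fit settings —
a requirement of exchangeability, not a shortcut. The permutation
statistic is the continuous projection distance
‖H_AH_Aᵀ − H_BH_Bᵀ‖²_F/(2k) rather than 1 − ARI of the hard
memberships: the Rand-based distance pins at its ceiling whenever the
two structures share nothing, so near-pure permutation patterns tie
with the observed value and the test loses all power exactly where the
effect is strongest; the projection distance degrades continuously
with mixing (both distances are reported; 1 − ARI remains the
descriptive measure). Node-level changes are scored after optimal
community matching (Hungarian assignment on the membership confusion
matrix) as a hard change indicator plus the norm of the matched,
row-normalised basis-row difference, tested against the same sign-flip
null with Benjamini–Hochberg control.

## Longitudinal statistics

Paired t on complete pairs (listwise deletion); delta–delta Pearson
correlation with a parametric p and a subject-permutation p (≥ 9999
sampled shuffles, two-sided on |r|), Spearman available; Holm for FWER
across the 5-density grid (uniformly dominates Bonferroni at the same
guarantee) and Benjamini–Hochberg for nodal FDR; Welch t for nodal
group comparisons; OLS with intercept for ΔTFI on (ΔQ, ΔE_glob,
ΔC_glob), warning on condition numbers above 1e8. Consecutive-session
deltas (pre→post, post→follow-up) are pooled by default; the
normalized change (later − earlier)/|earlier| is guarded for
|earlier| < 1e-8. KDE summaries use a Gaussian kernel with Silverman
bandwidth on a 256-point grid spanning the data ± 3 bandwidths;
constant series are reported as degenerate point masses.

## Seed-to-voxel and MAGEE

Seed masks are unions of spheres in mm space (voxel centres within the
radius) and/or label masks, with one averaged seed time course. The
GEE is linear with exchangeable working correlation: moment estimation
of the common intra-subject correlation alternating with GLS updates
(closed-form V⁻¹ for exchangeable blocks), sandwich variance; it is
vectorised across voxels sharing one design, and agrees with
statsmodels' GEE to ~1e-6 relative on the same data (asserted in
tests). With one observation per subject it reduces exactly to OLS.

MAGEE smoothing runs one pass per radius in the schedule {1,…,5}
voxels: weights are a Gaussian spatial kernel (scale r/2) times a
similarity kernel exp(−(βᵢ−βⱼ)²/2h²) with h the robust SD
(1.4826·MAD) of the current β map, and the variance map is averaged
with identical weights. Consequences worth knowing: a spatially
constant β map is an exact fixed point; a spike a few robust SDs above
the field shrinks monotonically; a spike far beyond the similarity
bandwidth is *preserved* — that is the adaptivity. The exact schedule
and kernels of the original multi-scale adaptive GEE are not public;
these are documented defaults, not a reconstruction. W = β̂²/var̂ is
referred to χ²(1); under the null the pre-smoothing Wald quantiles
track χ²(1) with QQ slope ≈ 1, and the realised rejection rate at
α = 0.05 with 50 subjects is ~0.07–0.08 (small-sample sandwich
inflation; no small-sample correction is applied).

**Cluster inference.** Session contrasts use voxelwise paired t,
cluster formation at a height threshold (default p < 1e-5 to match the
emulated study's reporting; extent 100), 18-connectivity by default
(6/26 configurable), cluster *mass* (sum of |t|) as the statistic, and
a max-mass sign-flip permutation null — exact enumeration when
2^n ≤ 1024. Permutation inference replaces random-field-theory
correction deliberately: it is exact at small n and implementable
without parametric smoothness assumptions. Calibration is checked at a
cluster-forming height of p = 0.01; at p < 1e-5 with 10 subjects
essentially no null voxel ever crosses the threshold, so a
false-positive-rate check there would be vacuous (the procedure's
validity does not depend on the height).

## Pipeline

Stages run in dependency order from one JSON config; every stage
derives its RNG seed from the root seed and a stable stage name
(CRC32), so toggling one stage never perturbs another, and identical
config + seed gives byte-identical output tables (SHA-256 recorded in
the run report). Clinical scores are generated *after* graph metrics
because the generator couples ΔTFI to each subject's measured
Δmodularity. Session labels form the closed ordered vocabulary
pre < post < followup. The default voxel stage runs on a small 12³
grid — large enough to exercise seed maps, MAGEE and cluster
extraction end-to-end while keeping a full run to minutes.

Problem sizes used in tests and the acceptance script (oracle
agreement over 100 graphs, 20 recovery seeds, 300–500 calibration
replicates, 25–50 voxel simulations, 100–200 cluster-FWER simulations)
were chosen so each study estimates its rate with a standard error
comfortably inside the asserted band.

## Known limitations

- Gaussian, stationary, artifact-free synthetic data: conclusions
  about robustness to motion, physiological noise or hemodynamic
  variability are out of reach by design.
- The Co-OSNTF objective is non-convex; restarts mitigate but do not
  eliminate local optima, and the permutation test inherits whatever
  fit noise remains (identical settings for observed and null keep the
  test valid regardless).
- Weighted graphs, partial correlations, and Bayesian SBM posteriors
  are out of scope; the sandwich variance is uncorrected for small
  samples.
- The normalized-change definition and the exact inferential procedure
  behind the emulated study's community-comparison p-values are not
  public; the ones here are the package's own documented choices.
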