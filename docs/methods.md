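# Methods

This package implements an individualized structural covariance network
(IDSCN) analysis of regional cortical thickness for a two-group
(smoker vs healthy-control) cross-sectional design, together with the
nonparametric statistics used to compare the resulting network properties,
and a synthetic cohort generator that provides a tunable ground truth for
the whole chain.

## Normative z-scoring of regional thickness

Inputs are per-subject mean cortical gray-matter thickness (mm) for the 34
Desikan–Killiany regions. Each region is residualized by ordinary least
squares on an intercept plus age (years), sex (0/1), education (years) and
the subject's global mean cortical thickness. The regression is fitted on
healthy controls only and its coefficients are applied to all subjects — the
normative-model convention, so that a smoker's residual expresses deviation
from the *healthy* covariate norm. A configuration flag (`fit_group=None`)
fits on the pooled sample instead. Residuals are standardized per region by
the control-group mean and sample standard deviation (denominator n − 1):

    z_k(i) = (res_k(i) − mean_HC(i)) / sd_HC(i)

Control columns therefore have mean 0 and SD 1 by construction; this is
asserted to 1e-8 in the tests. Z-scores are invariant to any positive affine
transform applied uniformly to the raw thickness because the intercept and
the global-mean covariate absorb it.

## Individualized networks

For subject k, the edge weight between regions i and j is a similarity
("joint variation") of the two deviations,

    w_ij = exp(−(z_i − z_j)² / (2c²)),    c = 1 by default,

which lies in (0, 1], equals 1 iff the deviations coincide, and depends only
on the pairwise difference (adding a constant to every z changes nothing).
Two alternative kernels (Laplacian `exp(−d/c)`, inverse `1/(1+d/c)`) are
available; all are strictly decreasing in |z_i − z_j|, and since the
downstream analysis only uses the *ranking* of weights, the kernel and scale
choice cannot change any binarized-network result.

Each weighted matrix is thresholded to a fixed edge density K: the
m = round(K·n(n−1)/2) largest off-diagonal weights (round half away from
zero) become edges of an undirected, unweighted graph. Ties are broken by
ascending (i, j) index, which makes thresholding deterministic and the edge
sets nested across densities. All graph analysis is performed on these
binary graphs; weighted variants are out of scope.

## Graph measures

On each binary network we compute: mean nodal clustering
(c_i = 2t_i/(k_i(k_i−1)), 0 for degree < 2); global efficiency (mean inverse
hop distance, disconnected pairs contribute 0); characteristic path length
(mean geodesic within the largest connected component); Newman modularity Q
maximized by a greedy multilevel (Louvain-type) heuristic with 20 seeded
restarts under random node permutations, best Q kept (the heuristic never
exceeds, and on ≤8-node graphs virtually always attains, the
exhaustive-partition optimum — tested); largest-component fraction; and
small-worldness

    σ = (C / ⟨C_null⟩) / (L / ⟨L_null⟩)

against an ensemble of degree-preserving double-edge-swap rewirings
(10 attempted swaps per edge; connectivity not enforced; graphs admitting no
valid swap are used unchanged with a warning). Nodal centralities are
betweenness (unnormalized geodesic counts, each unordered pair once),
eigenvector (leading adjacency eigenvector, computed per connected component
so the Perron–Frobenius vector is well defined on disconnected graphs,
nonnegative, unit Euclidean norm) and closeness ((s−1)/Σd within a
component of size s; isolated nodes 0). Path-based measures deliberately use
within-component conventions because disconnection is expected — and
screened for — at low density.

## Density screening and selection

For every density in the grid (default 0.05–0.30, step 0.01, 26 values) each
network is screened by three strict criteria: largest component > 80% of
nodes, Q > 0.3, σ > 1. A density qualifies when more than 50% of the
networks pass all three. The retained range is the maximal contiguous run of
qualifying densities (ties resolved toward lower density) and the analysis
density K* is the mean of the retained grid values rounded half away from
zero to 2 decimals, together with the fraction of networks passing all
criteria at K*.

During screening, σ uses 10 rewired nulls per network (26 densities × all
subjects); at the selected density σ is recomputed with 100 nulls for the
group comparison. A screening-only convention handles the degenerate case of
an entirely triangle-free null ensemble at very low density: σ is taken as
+∞ when the observed network has clustering and 0 otherwise (the library
function itself raises, per its contract); these densities are discarded by
the connectedness screen regardless.

## Group statistics

All comparisons are rank-based: two-sided Mann–Whitney U (exact enumeration
for tie-free samples with both n ≤ 20, otherwise the normal approximation
with tie and continuity correction), reported both as U and as the rank-sum
W of the first group, with Benjamini–Hochberg FDR adjustment *within
declared families*: the 4 global metrics at K*; each centrality type across
the 34 regions as its own family (centralities are first averaged across the
retained density range per subject); the 4 metabolites; and the correlation
set. Effect sizes are Cliff's delta with a 95% CI from Cliff's consistent
variance estimator and a normal critical value, truncated to [−1, 1]
(coverage ≈ 0.95 verified by simulation at the calibrated settings).
Metabolites additionally get per-group boxplot outlier screening
(quartiles by linear interpolation, 1.5·IQR whiskers, closed interval)
before testing — network metrics are not trimmed — and tNAA gets a
two-group ANCOVA with age as covariate (type-III F on the group term).
Exploratory brain–behavior associations use partial Spearman correlations:
tied-rank transform of x, y and the covariates (age, sex, education, global
mean thickness), least-squares residualization of the ranked x and y, then
Pearson correlation of residuals with p from the t approximation on
n − 2 − #covariates degrees of freedom; with no covariates this reduces
exactly to ordinary Spearman.

## Synthetic cohort generator

The generator is first-class, tested code that defines the study conditions
for every downstream test. Thickness follows a module-factor linear model:

    t_kr = μ_r + β_age(age_k − 40) + β_sex s_k + b_k
           + λ_{g(k)} u_{m(r),k} + ε_kr − thinning·1[g(k)=SM]

with region means μ_r ~ U(2, 3) mm drawn once per run; module factors
u_{m,k} ~ N(0,1) shared by all regions of module m (default 4 modules of
9/9/8/8 regions); loadings λ_HC = 1.2, λ_SM = 0.6 so the smoker group's
modular covariance is attenuated; subject offsets b_k ~ N(0, 0.1²);
residual noise ε ~ N(0, 0.3²); β_age = −0.005 mm/yr; β_sex = +0.02 mm
(female); diffuse smoker thinning 0.02 mm. Ages are N(40,13²) (HC) and
N(48,12²) (SM) truncated to the 21–65 eligibility window; P(female) =
0.45/0.51; education N(14, 2.5²) years truncated to [8, 20] for both groups
(education has no generative effect on thickness; it enters only as a
covariate). Subjects drawing a non-positive thickness anywhere are redrawn
(latent factors and noise only), failing loudly after 100 rounds.

Metabolites are Gaussian per group: tNAA at the calibrated group
medians/IQR-derived scales — HC 17.8 (1.92/1.349), SM 16.7 (2.27/1.349)
i.u. — giving an analytic Cliff's delta of
2Φ(1.1/√(1.423² + 1.683²)) − 1 ≈ 0.38 for the group shift; Glu 8.7 (1.1),
GSH 1.6 (0.35) and GABA 2.4 (0.5) i.u. carry no group effect and serve as
built-in negative controls. Behavioral scores come from Gaussians truncated
to instrument ranges with per-group location/scale; smoker-only instruments
(FTND, QSU) are missing for controls by design.

What the generator does *not* emulate: spatial autocorrelation between
neighboring regions, non-Gaussian or heteroscedastic thickness noise,
scanner/site effects, hemispheric asymmetry, real covariate–thickness
nonlinearity, or any image-level process. Passing tests therefore
demonstrate correctness and calibration of the analysis chain under the
stated generative model, not sensitivity on real morphometric data.

## Numerical and reproducibility choices

- One pipeline seed fans out through `numpy.random.SeedSequence` to
  per-stage and per-network child seeds, so identically configured runs are
  byte-identical (manifest checksums compare equal) and stages can be rerun
  in isolation.
- Edge-count rounding and the K* rounding are both half-away-from-zero,
  stated explicitly to avoid banker's-rounding drift.
- Tie-breaks: thresholding by ascending (i, j); density-run selection toward
  lower K; eigenvector component ties toward the first component.
- The eigenvector solver uses a dense symmetric eigendecomposition per
  component (n = 34), not power iteration.
- Degenerate inputs fail loudly with named offenders: constant covariates,
  rank-deficient designs, zero reference SDs, edgeless graphs, fully tied
  samples (p = 1 with a warning), densities that keep zero edges.

## Known limitations

- Under the default generator, binarized networks at admissible densities
  retain nearly all within-module pairs for both groups (within-module
  z-differences contain only noise, the shared factor cancels), so both
  groups sit near the union-of-cliques regime and the modularity group
  difference, while consistently in the expected direction, is a small
  effect (median gap ≈ 0.02–0.04 in Q): per-density Mann–Whitney power at
  n = 51/group is around 0.5, not high. The effect-direction property is
  robust; high-powered detection of the modular attenuation would require a
  stronger loading contrast than the default study conditions.
- The density screening at default scale passes in the upper part of the
  grid (≈0.24–0.30); where the majority rule first holds depends on cohort
  noise, so the selected density is itself a random quantity across seeds.
- σ is a Monte-Carlo estimate; with 10 screening nulls its sampling error is
  visible near the σ = 1 boundary, which is why the comparison at K* uses
  100 nulls.
- Problem sizes used by the test suite: the oracle suites use 200 random
  graphs of ≤7–8 nodes; parameter-recovery and null-calibration run 25
  simulated cohorts each at full study scale over the retained range;
  the end-to-end check runs the complete 102-subject, 26-density analysis
  twice. These sizes are the package's chosen trade-off between statistical
  resolution and suite runtime.
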