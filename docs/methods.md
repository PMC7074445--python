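# Methods

## Procrustes superimposition

Shapes are k = 19 two-dimensional landmark configurations. The preshape step
centers each configuration on its centroid and scales to unit centroid size
(root summed squared landmark deviation); the generalized Procrustes
iteration then (1) initializes the consensus as the first preshape,
(2) rotates every shape onto the consensus with the closed-form proper
rotation (reflections are never admitted — all wings are right forewings,
so a reflected fit would be biologically meaningless), (3) recomputes the
consensus as the per-landmark mean rescaled to unit size, and repeats until
the consensus RMS displacement falls below `tol = 1e-10` or 100 iterations.
On wing-scale data convergence takes 3–5 iterations and the residual
criterion is effectively exact. Within a caste, all wings enter one joint
superimposition and colony means are computed afterwards, not per-colony.

Distances are *partial* Procrustes distances — the residual root sum of
squares between unit-size, centered, optimally rotated configurations — the
convention under which site-level wing differentiation is conventionally
reported. No projection to tangent space is applied before averaging or
covariance computation: at the shape distances involved here (≲ 0.07) the
chordal/tangent discrepancy is O(d³) and negligible relative to sampling
noise. Degenerate inputs (all landmarks coincident) raise; a rank-deficient
cross-covariance in the rotation step warns and returns the smallest-angle
SVD branch.

## CVA and its rank handling

Procrustes coordinates lose 4 degrees of freedom (2 translation, 1 scale,
1 rotation), so colony-mean shape variables are first projected onto
leading principal components — enough to explain 99.9 % of variance by
default, and never more than min(rank, n − g) so the pooled within-group
covariance stays positive definite. Canonical axes solve the generalized
eigenproblem `B v = λ W v` (between- vs pooled within-group covariance,
scipy `eigh`); eigenvalues are invariant to invertible linear maps of the
variables, which the tests verify numerically, and the axes agree with
eigen-solver LDA up to normalization.

## Spatial features

The sPCA input for morphometrics is not the raw coordinate matrix but the
Euclidean distances between *proximal* landmark pairs of each colony mean —
pairs adjacent along the wing venation. The venation of the stylized
19-landmark wing gives 24 default pairs (`wing_features.DEFAULT_PAIRS`),
shipped as an editable table because the biologically "correct" pair set is
a digitizing-protocol choice, not something the method fixes. Features are
computed on GPA-aligned (unit centroid size) means, so they measure shape;
they are centered but not standardized before the sPCA — the distances
share units and comparable scales, and leaving them unstandardized
preserves the variance weighting of the eigen-analysis (a configuration
choice, exposed to the user rather than baked in).

## Connectivity, Moran's I, sPCA

Connectivity is a K-nearest-neighbour graph (default k = 5) on great-circle
distances, symmetrized (an edge in either direction is kept) and
row-normalized. Exact ties — duplicate coordinates — are broken by node
index with a warning, never silently jittered. Moran's index is

    I(x) = (n / ΣW) · Σᵢⱼ Wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)² .

The Moran eigenbasis diagonalizes the doubly centered symmetrized weights
on the orthogonal complement of the constant vector, built through an
explicit Helmert basis so orthogonality to 1 is exact, not approximate.
Each basis vector's I equals n·λ/ΣW, an identity the tests check to 1e-10;
the extreme attainable I values for a network are the corresponding
extremes of λ, which for row-normalized KNN graphs bracket the nominal
[−1, 1] range.

sPCA diagonalizes `H = Xcᵀ(L + Lᵀ)Xc / 2n`. Because scores s = Xc·v have
zero mean, the identity λ = var(s)·I(s) is exact per axis; the test suite
asserts it to 1e-8 together with the trace identity Σλ = tr(H) and a
Rayleigh-quotient bound on the leading eigenvalue. Zero-variance feature
columns are dropped with a warning.

## The max(t) structure test

For each Moran eigenvector uⱼ, t-raw(j) is the mean over feature columns of
the squared Pearson correlation with uⱼ (columns are centered and unit-
normalized internally; since uⱼ ⊥ 1 and ‖uⱼ‖ = 1, the correlation is a
plain dot product). The profile is smoothed by a 3-point moving average
over eigenvectors adjacent in eigenvalue order (edge-truncated; window
configurable — 3 is the established convention for this statistic), and
max(t) is the maximum over the positive-I eigenvectors (global test) or
negative-I ones (local test). The null distribution jointly permutes the
rows of the feature matrix; `p = (1 + b)/(1 + B)`, so B = 9,999 attains
p = 10⁻⁴ exactly and B = 10,000 (the headline setting) approximately. The
permutation seed is a required argument everywhere — there is no implicit
global randomness. Global and local tests run off one shared set of
permutations (`structure_test_pair`) since both statistics are functionals
of the same permuted profiles.

Score maps use inverse-distance-weighted interpolation (power 2) on a
regular latitude/longitude grid, exact at sample locations and masked
outside the samples' convex hull. No kriging or cartography is attempted.

## Haploid F_ST

Site allele frequencies are means of non-missing haploid calls. Pairwise
F_ST uses a Hudson-type estimator adapted to haploid counts, combined as a
ratio of averages: per locus, numerator `(p₁−p₂)² − p₁(1−p₁)/(n₁−1) −
p₂(1−p₂)/(n₂−1)`, denominator `p₁(1−p₂) + p₂(1−p₁)`; loci with fewer than
two calls in either site are excluded pairwise. The estimator needs no
ploidy-specific variance components, which is exactly right for drone
(haploid) genotypes. Values are clamped to [0, 1] for the distance matrix,
with raw values returned alongside. Simulation tests confirm bias < 0.01 at
n = 200 haploid samples and 100 loci.

## Concordance conventions

sPCA axes are sign-arbitrary: score comparisons report the signed r and the
sign-aligned |r| with the flip recorded. Distance-matrix correlations use
lower-triangle entries with the plain parametric p (the convention of the
analyses being mirrored) *and* an optional Mantel permutation p, because
triangle entries are not independent; both are printed when requested.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: 23 sites on three north–south
transects (8 Atlantic at lon −8.5°, 9 Central at −5.0°, 6 Mediterranean at
−1.5°, latitudes 37.2–43.0°), 10 apiaries × 3 colonies per site (apiary
jitter SD 0.08°, colony jitter 0.01°), 5 wings per colony per caste, and
383 haploid loci genotyped in one drone per colony. A latent variable per
colony, `q = logistic(3·t)` with t the min–max-scaled projection of its
coordinates on a bearing-45° (northeast–southwest) axis, drives everything:

- **wing shape**: colony mean = template + (q − ½)·β·d + colony effect,
  with d a fixed unit-norm deformation axis (distal stretch, dorsoventral
  compression, orthogonalized against pure scaling) and β = 0.08 Procrustes
  units across the full cline; wings add wing-level (SD 0.004/coordinate)
  and digitizing (SD 0.001) noise on top of the colony effect (SD 0.002),
  then a random rotation/scale/translation into pixel-like units.
- **genotypes**: per-locus Bernoulli with logit = α_l + γ_l (q − ½),
  baseline frequencies uniform on (0.2, 0.8), |γ_l| = 3 with random sign.
- **missing landmarks**: independent per-landmark drops at 0.003 (drones)
  vs 0.0002 (workers), chosen to reproduce the observed wing-level loss
  (~6 % of drone wings vs ~0.4 % of worker wings discarded), reflecting the
  haploid expression of venation anomalies in drones.

Effect sizes are not identifiable from published summaries in feature
units; β and γ were fixed once, during design calibration, at the weakest
values that put desk-scale runs (92 colonies) robustly in the qualitative
regime the method is meant to exhibit — global structure detected, no local
structure, cross-marker sPC1 agreement ≈ 0.9. At the full 690-colony design
these defaults yield observed global max(t) ≈ 0.016 and minimum site-pair
Procrustes distances ≈ 0.0036, the right order of magnitude for real wing
data, though the maximum distances (~0.07) and the leading Moran's I
(~0.92) exceed what noisy field data show: the generator has no
beekeeper-mediated gene flow, no measurement-protocol drift, no
linkage between loci, and its cline is perfectly monotone. Passing tests
therefore demonstrate that the pipeline recovers structure *of this kind*
when present and stays at nominal size when absent — not that any
particular field dataset will behave as cleanly.

All randomness flows from the single config seed; identical seeds yield
bit-identical TPS output and genotype matrices.

## Problem sizes used by the test suite and acceptance script

The calibration study (type-I error) uses 500 pure-noise datasets at
n = 100, p = 10, k = 5, 199 permutations. The power/recovery study uses 100
replicates of a reduced design — all 23 sites but 2 apiaries × 2 colonies,
3 wings/colony, 100 loci, 499 permutations — with every effect size, noise
SD and rate at its shipped default; this is the package's standard
replicate design for distributional claims. `scripts/acceptance.py` runs
one full-design dataset (690 colonies per caste, 383 loci) with 9,999
permutations per structure test.

## Known limitations

- Missing landmarks are filtered, never imputed; a colony losing every wing
  drops out of the morphometric side (handled, but reduces n).
- The KNN graph ignores coastline/topography; connectivity is purely
  geometric.
- CVA p-values are not provided (no permutation test on canonical roots).
- The sPCA treats SNP calls by mean-imputing missing values per locus;
  under high missingness a dedicated imputation step would be preferable.
- Great-circle distances assume a spherical Earth (radius 6371.0088 km).
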