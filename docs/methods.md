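# Methods

## Superimposition and shape distances

Configurations are p named 3D landmarks in mm (X right–left, Y
posterior–anterior, Z superior–inferior). Centroid size is
CS = √Σᵢ‖xᵢ − x̄‖². Generalized Procrustes analysis centres each
configuration, scales it to unit CS, and iteratively rotates it onto the
consensus with the orthogonal least-squares solution restricted to proper
rotations (det = +1): allowing reflections would collapse genuine
left–right anatomical differences. The consensus is the coordinate-wise
mean re-normalized to unit CS during iteration; the reported `mean_shape`
is the plain coordinate-wise mean of the aligned records. Iteration stops
when the consensus moves less than 1e-10 in chord distance (at most 100
rounds; non-convergence raises with the objective trace attached). The
first record's orientation seeds the consensus, which makes output
deterministic. The full-GPA objective Σᵢ‖Xᵢ − m‖² is non-increasing under
both the rotation and the consensus-update steps, and the implementation
records it per iteration so tests can assert monotonicity.

Shape distances are full-Procrustes chord distances on the aligned
coordinates. No tangent-space projection is applied: at the small shape
distances of within-population facial data the chord is an excellent
approximation of the Riemannian distance, and projecting would change the
reported numbers far below their printed precision. (Whether to project is
left as an explicit non-default because published analyses are often
ambiguous about it.)

## Absolute error (ODEV / AVEDEV)

All replicas of one individual are digitized on the same image volume, so
absolute error is computed on *raw* coordinates, never on superimposed
ones — superimposition is a least-squares convention that spreads error
across landmarks and would corrupt a per-landmark error measure. For each
(individual, landmark), the across-operator mean position is the
reference; ODEV is each operator's Euclidean deviation from it, AVEDEV the
mean of the k ODEVs. Exact consequences used as test oracles: the mean of
the operator ODEVs equals AVEDEV; for k = 2 both ODEVs equal half the
inter-operator distance; ODEV is invariant to a rigid motion applied
jointly to all of an individual's replicas but not to per-replica motions.
Profiles report per-landmark mean AVEDEV with 2.5th/97.5th percentiles
using linear interpolation between order statistics; with n = 20 the
percentile convention materially affects the tails, so it is recorded in
the output metadata. The bone/soft contrast is
(mean bone AVEDEV − mean soft AVEDEV)/mean soft AVEDEV.

## Variance partitioning

Size analyses are classical univariate ANOVAs on CS. Shape analyses sum
squares jointly over all Procrustes coordinates and multiply classical
degrees of freedom by the shape-space dimension 3p − 7 (3p coordinates
minus 3 translations, 3 rotations, 1 scale); a 20-individual, 3-replicate
design therefore has individual/error df of 722/1520, 437/920 and 152/320
for 15, 10 and 5 landmarks. F = MSamong/MSwithin is referred to the F
distribution on the inflated df (Goodall-style); a seeded permutation P is
available as an alternative. For the repeatability design the permutation
scheme shuffles records freely across individuals: permuting replicas
*within* individuals would leave every sum of squares unchanged in a
one-way individual-vs-error design, so the free scheme is the only one
with a non-degenerate null (verified: its p-values are uniform under pure
noise).

Effect sizes: R² = 100·SSeffect/SStotal. The ICC is computed from the
ANOVA mean squares as (MSamong − MSwithin)/(MSamong + MSwithin). This
symmetric form — rather than the classical one-way k-replicate form
(MSamong − MSwithin)/(MSamong + (k−1)·MSwithin), available via
`variant="one_way"` — is the default because it is the form under which
published repeatability tables of this design reproduce exactly from their
printed mean squares; the test suite pins all six reference rows at
2-decimal rounding. For k = 3 the symmetric form converges to
k·σ²b/(k·σ²b + 2σ²w) rather than the classical σ²b/(σ²b + σ²w); both
variants are Monte-Carlo-tested against their expectations.

The operator-bias partition is a one-way grouping ANOVA (operator as the
grouping factor); its group R² approximates the share of variance due to
systematic operator differences, with null expectation (g − 1)/(n − 1)
under exchangeability. The large-sample analysis is a *sequential*
(Type I) decomposition with sex entered before operator — operator SS is
the increment over the sex-only model, so its R² is controlled for sex.
Factors are crossed, not nested (every operator may measure both sexes);
empty sex×operator cells warn but do not abort. The balanced robustness
check draws a seeded per-cell subsample (without replacement) and re-runs
the hierarchical ANOVA, re-superimposing for shape.

## Concordance diagnostics

Size agreement: pairwise Pearson correlations of CS over the individuals
shared by each operator pair, plus their mean. Shape agreement: Pearson
correlation of the strictly-lower triangles of the per-operator Procrustes
distance matrices; no Mantel test by default (the correlation is purely
descriptive and cannot expose biases), though a seeded Mantel P is behind
a flag. UPGMA is implemented directly (size-weighted average linkage,
merge height = half the average distance) so that ties in the minimum
distance break deterministically by lexicographic leaf-label order;
scipy's average-linkage is the independent oracle in tests, and trees
serialize to newick via scikit-bio. Cluster counts on the phenogram:
a *triplet* is an individual whose k replicas form an exclusive clade; a
*pair-or-better* has some two replicas as an exclusive 2-leaf clade (the
testable reading of "nearest neighbours on the tree"). The relative range
of variation is max/min of the distances to the mean shape; the trimmed
variant removes ⌈2.5%⌉ of the distances from each tail (the statistic uses
both extremes, so trimming is symmetric), and the convention is stored in
the output.

## Shape PCA

Covariance (never correlation) PCA of the flattened aligned coordinates —
the universal convention for Procrustes data, where all variables share a
scale. At most min(n − 1, 3p − 7) components are retained; the discarded
eigenvalues are curvature residuals several orders of magnitude below the
leading ones. Eigenvector signs are fixed by making each component's
largest-magnitude loading positive so score plots reproduce across runs.

## Synthetic generator

The generator emulates the two study designs the pipeline expects, with
defaults fixed once as the study conditions:

* **Replica design**: 20 individuals × 3 operators (60 records), one sex —
  a deliberately homogeneous sample.
* **Study design**: 906 individuals, each digitized by one operator, with
  the unbalanced sex-by-operator cells F/M = 102/61, 106/163, 252/222.

Each record = individual true configuration + operator bias field +
digitizing noise. True configurations are a bilaterally symmetric template
face (CS 230 mm) plus isotropic Gaussian per-coordinate individual
deviations, rescaled to an individual CS drawn from N(230, 6²) mm (plus
+14 mm for males — size dimorphism ≫ shape dimorphism). Male mean shape
adds a fixed masculinization field (unit per-coordinate RMS, default
magnitude 0.5 mm replica / 0.75 mm study). Digitizing noise is isotropic
Gaussian per coordinate with SD 0.924 mm on bone and 0.56 mm on soft
tissue (ratio 1.65: on MRI, soft-tissue points are easier to locate than
cortical bone, which yields little signal and distorts nearby tissue).

Operator bias is a fixed field per operator: OP1 is the reference (zero),
OP2 and OP3 displace the low-contrast bone landmarks (porion, zygion,
orbitale, sella, glabella) and the nasal points, each in its own
direction. The crafted fields are projected to be centroid-size-neutral
for the all/bone/nose subsets (to first order at the template) and an
explicit nasal-size misjudgment (OP2 −0.3 mm, OP3 +1.2 mm of nose CS) is
added back along the nose-size gradient. This reproduces the empirical
signature that motivates the pipeline: operator bias nearly invisible in
full-face and bone size, clearly visible in nasal size, and substantial in
shape everywhere. Field magnitudes, noise SDs and individual variances
were calibrated once so the defaults land in the published regime (shape
error R² ≈ 30% all/bone vs ≈ 17% nose; size error ≈ 1–2% all/bone vs
≈ 16% nose; operator shape R² ≈ 15–20% replica; study-sample sex R² ≈
55% size vs ≈ 1% shape) and then frozen. The study design uses a larger
individual shape SD (2.4 vs 1.5 mm) because the mixed-sex population is
more heterogeneous than the single-sex replica sample.

Ground truth: the generator returns the true configurations, the bias
fields, and brute-force designed variance shares (individual / sex /
operator / noise) computed in unit-CS shape units, ignoring the
second-order effect of the Procrustes rotations. Parameter-recovery tests
require the operator-grouping shape R² to match the designed operator
share within ±0.05 averaged over 20 seeds.

What the generator does **not** emulate: non-Gaussian or heavy-tailed
digitizing error, intra-operator replication, landmark-specific individual
variances (so the empirical pattern that *nasal* shape varies relatively
more among real individuals — and with it the study-sample reversal where
nasal sex R² exceeds nasal operator R² — is not reproduced), correlated
errors between neighbouring landmarks, and any image-level effects.
Passing recovery tests therefore shows the estimators are correct under
the stated model, not that real MRI digitizing error follows it.

## Numerical and interface conventions

* Coordinates are always mm; CSV/Morphologika writers emit shortest exact
  float representations, so write→read→write is byte-stable and lossless.
* The long CSV (one row per individual/operator/replicate/landmark) is the
  canonical format; the Morphologika reader supports the
  individuals/landmarks/dimensions/names/rawpoints blocks and warns on
  others. Record metadata rides in the name line as `ind|op|sex|rep`.
* All randomness flows from explicit integer seeds; identical inputs give
  byte-identical JSON reports. Human-readable output rounds to whole
  percents and 2-decimal ICC/r, while the JSON always carries unrounded
  values.
* Degenerate inputs fail loudly: zero-CS configurations, unbalanced
  repeatability designs, missing operators, zero distances in range
  statistics, non-symmetric distance matrices.

## Problem sizes used in the shipped analyses

The analysis drivers and test suite run the replica design at its natural
size (60 records) and the study design at n = 906 (drivers, selected
tests) or a proportionally scaled n = 228 / n = 114 (property tests that
repeat over many seeds), sizes chosen so the whole suite completes in
seconds while keeping every statistic in its asymptotic regime.
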