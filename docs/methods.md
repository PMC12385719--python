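# Methods

This note documents the statistical procedures `germeval` implements,
the synthetic-panel model behind its default configuration, and the
numerical and design choices a maintainer should know about.

## The trait panel

The fixed registry holds 34 traits in canonical order: crude protein
and crude oil (% of kernel dry weight), 16 amino acids (% of kernel dry
weight), 8 fatty acids (% of total fatty acids: C14:0, C16:0, C16:1,
C18:0, C18:1, C18:2, C18:3, C20:0), three fiber-yield components (boll
weight BW in g per 20 bolls, lint percentage LP %, seed index SI as
100-seed weight in g) and five fiber-quality components (length FL mm,
uniformity FU %, strength FS cN/tex, micronaire FM, elongation FE %).
Amino acids are expressed per kernel dry weight (the convention under
which glutamic acid ≈ 8.2% of the kernel), not per unit protein.

Each trait carries a desirability flag (`higher_better`,
`lower_better`, `neutral`) used *only* to orient principal components:
protein, amino acids, unsaturated fatty acids, oil and the fiber
yield/quality traits are `higher_better`; the four saturated fatty
acids are `lower_better`; micronaire — whose optimum is a mid-range
band — is `neutral`.

## Descriptive profiling

Per trait: mean, SD (n−1 denominator — these are sample statistics on a
germplasm sample), CV = 100·SD/mean, min/max, and a Shapiro–Wilk
normality screen at α = 0.05. The screen is advisory and never gates
any stage: the downstream ANOVA and PCA are applied regardless, as is
conventional for panels of this size. CV is undefined (reported as a
null marker) when the mean is zero. Histogram binning for report plots
uses the Freedman–Diaconis rule.

## Group comparison

One-way ANOVA per trait across origin groups (6 levels) or breeding
periods (4 levels), F = MS_between/MS_within with (k−1, N−k) df. The
degenerate case of zero variance everywhere is defined as F = 0, p = 1.
Post hoc pairwise comparisons use Tukey's HSD via the studentized-range
distribution with the Tukey–Kramer correction, which the unbalanced
origin groups (40/95/28/58/15/23) require. Pairwise significance is
summarized as a compact letter display computed with the
insert-and-absorb algorithm: start with one letter covering all levels;
for each significantly different pair, split every letter column
containing both; absorb columns that became subsets. The construction
guarantees exactly that two levels share a letter iff they are not
significantly different, and letters are assigned in descending order
of group mean, so the display is deterministic.

No multiple-testing correction is applied across the 26 nutritional
traits (or the 561 correlation pairs): the per-trait significance
counts are intentionally raw, matching standard practice in germplasm
characterization reports, and the type-I cost is made explicit by the
calibration tests.

## Correlation analysis

Pairwise Pearson r over all 34 traits; two-sided p from the exact
transform t = r·√((n−2)/(1−r²)) with n−2 df (appropriate at n ≈ 259;
no permutation needed). Stars follow the display convention ** p<0.01,
* p<0.05. The cross-family report lists all pairs between two trait
families sorted by |r| descending, ties broken by registry order.

## Composite scoring (PCA-FMF)

Traits are standardized to zero mean/unit SD; the sample correlation
matrix is eigendecomposed (so Σλ = 34 and contribution rates are
CRᵢ = λᵢ/34). Components with λ > 1 are retained (strict inequality;
the threshold is a flag). Weights Wᵢ = λᵢ/Σλ_retained; note CR could
equally be defined relative to retained variance — the normalization
cancels, so the ambiguity is harmless. Retained component scores are
min–max normalized to memberships Uᵢ ∈ [0, 1] (exact 0/1 endpoints per
component), and F = ΣUᵢWᵢ. Ranking is by F descending with ties broken
by accession id; the elite count is ⌈proportion·n⌉ — the ceiling rule
is what makes "top 5% of 259" come out to 13 rather than 12.

**Sign convention.** Eigenvectors are defined up to sign, and F is not
sign-invariant (flipping a component maps U to 1−U). Each loading
column is therefore flipped, if necessary, so that the sum of its
loadings on `higher_better` traits minus the sum on `lower_better`
traits is non-negative; if that signed sum is numerically zero (e.g.
no desirability information), the entry of largest magnitude is made
positive. On the calibrated panel this orients PC1 toward high
protein/amino acids and away from oil — the agronomically meaningful
direction — and makes F deterministic and invariant to positive affine
rescaling of any trait. A regression test pins the convention.

**Degenerate inputs.** Constant traits are rejected by name before
standardization (constancy is detected via zero range, not a floating
SD threshold). A retained component with zero score range raises
unless the caller opts into mapping it to a constant membership 0.5.
If no eigenvalue exceeds the threshold the error advises overriding
it; with a single trait (λ = 1 exactly) this is unavoidable under the
strict rule.

## Clustering

Agglomerative clustering of accessions on the standardized 34-trait
matrix with Euclidean distance and Ward linkage (defaults k = 4);
average and complete linkage are available. Ward/Euclidean is the
conventional choice for trait heatmaps and produces compact groups;
the merge-height monotonicity of Ward dendrograms is asserted in
tests. Cluster labels are canonicalized (descending size, ties by
smallest member id) so identities are stable across row orders and
runs. Cophenetic distances are retained for audit, a silhouette report
is available, the dendrogram exports as newick, and per-cluster trait
profiling reuses the ANOVA + letter-display machinery (singleton
clusters are surfaced as errors by name).

## The synthetic panel generator

The generator emulates the statistical structure of a 259-accession
upland cotton reference panel — it is the package's test bed and
benchmark, not a simulator of any assay's error process.

**Marginals.** Each trait is Gaussian with the reference mean and
CV (SD = mean·CV/100). Pinned means include protein 44.00%, oil
32.46% (sum 76.46%), glutamic acid 8.19%, arginine 5.02%, aspartic
acid 3.60%, C18:2 55.92% of total fatty acids, and fatty-acid family
sums SFA 26.73% / UFA 73.12%. Pinned CV extremes include the
amino-acid span 7.79–13.07% (arginine highest), the fatty-acid span
3.42–26.37% (C18:2 26.37, C14:0 13.74) and the fiber span 1.46% (FU)
to 13.34% (BW). Values not individually published (minor amino-acid
and fatty-acid means, fiber means) are set once to values typical of
cottonseed and upland cotton fiber and constrained by the published
family sums; they are declared in one table in `synthetic.py`.

**Fatty-acid labeling.** The reference conditions print the second
most abundant fatty acid as palmitoleic (C16:1) at 22.88%, which is
biologically implausible for cottonseed and arithmetically
inconsistent with the same source's family sums (UFA 73.12%) and its
statement that C16:0 + C18:1 + C18:2 = 95.21% of total fatty acids.
The default configuration adopts the self-consistent reading —
palmitic (C16:0) = 22.88% — and exposes
`fatty_acid_labeling="as_printed"` for the literal labeling, under
which the UFA family sums to ≈95% instead. The conflict is surfaced,
not silently fixed.

**Correlation structure.** The published targets pin only a handful of
cells: corr(protein, oil) = −0.947, protein × each amino acid in
0.57–0.85, protein–LP 0.47, oil–SI 0.44, protein–C18:2 0.26,
protein–C18:3 0.25. The remaining cells are completed by a
deterministic five-factor latent model (protein axis; a common
amino-acid factor; oil's residual axis, on which SI also loads just
enough to pin oil–SI = 0.44; a fatty-acid axis giving the ±0.3
SFA/UFA block pattern; a fiber-quality factor). The completion
reproduces every pinned cell exactly and is positive semidefinite by
construction, so the PSD repair step is a no-op for the default
target. Protein–amino-acid correlations are spread deterministically
by amino-acid abundance (most abundant 0.85, methionine lowest at
0.60, echoing its weaker metabolic coupling). An explicit
`repair_correlation` (eigenvalue clipping at 1e−8 followed by diagonal
rescaling, which preserves PSD) remains available for user-supplied
targets that are not jointly consistent; the maximum entry
displacement is logged so pinned values can be audited.

**Group effects.** Additive origin and period mean shifts reproduce
the reported patterns: NIR highest protein (+1.65 → 45.65%) and lowest
oil (−1.71 → 30.75%), FOR highest oil (+3.12 → 35.58%) and highest
C16:0/SFA; protein, amino acids and C18:2 rising across breeding
periods while oil and C16:0 fall. Amino-acid shifts shadow protein
proportionally to abundance. Each shift vector is balanced to a
size-weighted zero so panel-wide means stay at their configured
values. Seed index additionally tracks oil across groups (ratio 0.09),
which keeps the panel-wide oil–SI correlation at its configured 0.44
despite the between-group variance the oil shifts add. Periods are
assigned independently of origin with fixed (default uniform)
proportions via largest-remainder counts and a seeded shuffle.

**Sampling and determinism.** Draws are z ~ N(0, I) transformed by
the eigenfactor of the (repaired) correlation matrix — the eigenfactor
is preferred to Cholesky for robustness at near-singular targets.
All randomness derives from one master seed through
`numpy.random.SeedSequence` spawning, so identical config + seed gives
byte-identical CSV output. Percentage traits are clipped to [0, 100]
with clip counts recorded in the ground-truth sidecar (at the default
configuration clipping touches only the far C18:2 tail, a few draws
per 5000). Every generated table ships with a `GroundTruth` record —
config, the correlation matrix actually sampled from, realized group
shifts, clip counts — so recovery tests never have to re-derive the
truth.

**What the generator does not emulate.** Assay-specific measurement
error (Kjeldahl vs chromatography), compositional closure of the
fatty-acid simplex (the 8 proportions are modelled as correlated
Gaussians and not renormalized to 100, which preserves the published
pairwise correlations at the cost of exact closure), origin × period
dependence, and any genetic/pedigree structure. Tests passing on
synthetic panels therefore validate the statistical machinery and its
calibration, not the biology of any particular panel.

## Problem sizes and tolerances in the test suite

Calibration checks run on a single 5000-accession draw (means within
±0.5, family sums within ±0.8–1.0, protein–oil r within ±0.02 —
comfortable against Monte-Carlo error at that size, e.g. SE(mean
protein) ≈ 0.05). The all-pairs correlation-recovery check uses
n = 20000: with 561 pairs the extreme deviation at n = 5000 is
expected near 0.04–0.05 even when every pair is unbiased, so the
±0.03 blanket bound is only meaningful at the larger size; the pinned
pairs are additionally checked at ±0.03 at n = 5000. Statistical
calibration uses 200 null simulations (type-I rate asserted within a
~3σ binomial band of α) and five seeded replicates for power and
planted-structure recovery. Oracle equivalence compares the full
scoring chain against an independently coded SVD-based implementation
at 1e−8 on every F value; analytic identities (2×2 eigenvalues 1 ± r,
ΣW = 1, exact membership endpoints, trace Σλ = p, affine invariance of
F) are asserted at 1e−8–1e−12.

## Known limitations

- The composite score inherits PCA's linearity; strongly nonlinear
  trait relationships would be folded into minor components and mostly
  ignored by the Kaiser rule.
- The elite set depends on the panel itself (memberships are min–max
  normalized within-panel), so F values are not comparable across
  panels — only ranks within one panel are meaningful.
- The compact letter display is minimal in the insert–absorb sense but
  not guaranteed to use the globally minimal number of letters for
  every pathological significance pattern (the sharing relation is
  always exact, which is the property that matters and the one tested).
- No mixed models or genotype × environment analysis: the panel model
  is single-location, single-season by design.
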