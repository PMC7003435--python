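# Methods

This note documents the models, algorithmic choices and numerical details
behind `connectosync`, and what the synthetic-data experiments do and do not
establish about real data.

## Reach probability and the binary structural connectome

A tract is represented by a non-negative 3-D grid of probabilistic-tractography
path counts on the same voxel grid as an integer label volume (0 background,
1 white matter, higher labels grey-matter ROIs). For each ROI the *boundary
mask* is the set of ROI voxels with at least one face-adjacent (6-connectivity;
26 available) white-matter voxel — one voxel deep, so within-ROI streamline
propagation cannot inflate connectivity. The tract's support is trimmed to
white matter plus all boundary masks, each voxel is normalized by the total
trimmed count (mass normalization: the per-voxel values form a probability
distribution over the trimmed support), and the reach probability toward an
ROI is the mean normalized value over its boundary mask, zero-count voxels
included. An empty mask yields 0; a tract with no trimmed mass is an error
naming the tract.

**Connection threshold.** Fixed mode binarizes at a supplied cutoff (0.002
is the shipped default for full-scale reproduction). ECDF-reflection mode
finds the elbow of the reach-probability ECDF: both axes are normalized to
[0, 1], the chord runs from the origin — anchoring the zero-probability
mass — to the largest value, and the cutoff is the non-zero value with the
largest |ECDF − chord| distance (ties to the smaller value). Anchoring at
the origin is deliberate: when the non-zero values form a single cluster
well separated from zero (a clean planted connectome), the elbow lands at
the bottom edge of the cluster and the planted set is recovered exactly;
when small-scale leakage coexists with genuine connections
(extreme-value-like data), the elbow lands at the shoulder between the
scales. A Gumbel fit (location, scale) of the non-zero entries is reported
as a distributional diagnostic, never used for thresholding.

**Region-pair classes.** Expression regions map to atlas ROIs via a
region-map table (many-to-one allowed). A pair is *tract-bound* if some
connected tract reaches ROIs of both regions, *AD-tract-bound* if such a
tract is in the disease-associated list (default: the four tracts whose
diagnosis associations replicated across cohorts — L-CAB, L-ILF, L-SLFT,
L-SLFP), else *not-bound*. Classification is symmetric and idempotent; the
three classes partition all pairs.

## Diffusion-measure associations

Each (tract, measure) column — volume, length, AxD, RD, MD, FA — is fit by
ordinary least squares on diagnosis severity plus age, sex and total brain
volume. Diagnosis is coded CN=0 < MCI=1 < Dementia=2 and treated as a
numeric severity covariate so a single effect size beta is reported per
measure (a two-dummy categorical variant would report two and is not the
default). Observations more than 3.5 SD from the raw measure mean are
removed once, before the fit, within cohort; values at exactly 3.5 SD are
kept. p-values are Benjamini–Hochberg adjusted over all tract x measure
tests within one cohort (statsmodels `multipletests`; a brute-force step-up
oracle guards it in the tests). Replication requires q below the cutoff in
both cohorts *and* concordant beta signs. The covariate screen reports
−log10 p from single-covariate fits before and after residualizing the
measure on age/sex/TBV.

## Tissue-to-tissue correlation

Expression is residualized per region on age, sex, post-mortem interval,
pH, ethnicity and Braak stage (categoricals dummy-coded; rank-deficient
designs are absorbed by the pseudo-inverse with a warning). For every
unordered region pair, all cross-region gene pairs are scored by Spearman
correlation (average ranks for ties) on shared subjects, computed blockwise
on standardized rank matrices so memory scales with one gene block, not all
pairs. Significance uses the t approximation
`t = rho * sqrt(df / (1 - rho^2))` with `df = n - 2 - k`, where `k` is the
number of degrees of freedom the covariate residualization consumed (design
rank minus intercept; `k = 0` for raw input, recovering the textbook
`n - 2`). The df reduction follows the partial-correlation convention; at
n = 40 with six covariates the unadjusted formula is measurably
anticonservative (empirical null about 3x the nominal rate at alpha 1e-3),
while the adjusted null stays within three binomial SDs. An exact
permutation p is infeasible at thresholds like 1e-8, which is why the t
approximation is used at all; it is a declared approximation, not a claim
about the original study's unstated method. Constant genes are skipped and
counted.

**Top-decile enrichment.** Region pairs are ranked by significant-pair
count, ties broken by lexicographic pair id; the top `ceil(0.1 N)` pairs
(14 of 136 at full scale) are crossed with a binding class in a one-sided
(greater) Fisher exact test. One-sided is the default because enrichment is
the stated direction; a two-sided flag exists.

## Bipartite modules (Barber modularity, LPAb+)

Significant TTC pairs of one region pair form a binary bipartite graph.
Barber modularity compares within-module edges to the degree-preserving
bipartite null, `Q_B = (1/m) sum_ij (A_ij - k_i d_j / m) delta(c_i, c_j)`.
LPAb+ maximizes it in two stages. Stage 1 initializes every node with a
unique label and sweeps nodes in a seeded random order; a bottom node
evaluates each neighbouring label L by `(#neighbours in L) - k_i D_L / m`
(D_L = top-side degree sum of L; symmetric for top nodes) and adopts the
best strictly-improving label, ties to the smallest label id. Convergence
is a full sweep with zero changes, capped at 100 sweeps. Stage 2 greedily
merges module pairs sharing at least one edge while any merge increases
Q_B — the gain for merging (a, b) is
`[E_cross(a,b) - (K_a D_b + K_b D_a)/m] / m` — best gain first, ties to the
smallest pair. Five restarts (child seeds `[seed, restart]`) keep the best
labeling, ties to the earliest restart. Accepted moves never decrease Q_B,
and on graphs of up to nine nodes the result matches the exhaustive maximum
over all set partitions. Modules with strictly more than the interaction
cutoff (1000 at full scale; configurable for desk scale) are kept and their
genes pooled per side, deduplicated.

A single dense planted block is a degenerate case: complete bipartite
graphs have maximal Q_B = 0, so label propagation has no gradient and the
graph stays unclustered. Synthetic configurations exercising the module
path therefore plant at least two blocks per region pair.

## Pathway layer

Over-representation is a one-sided Fisher exact test of a pooled gene list
against each pathway over a fixed background of all human genes (20,996 by
default). Eight Drosophila-specific catalog entries are filtered at GMT
load. BH-FDR runs across pathways within one gene list (per region-pair
side) by default — the usual per-list over-representation family — with a
global-family switch because the original choice is ambiguous. Calls at
q < 0.05 are binarized. A pathway-to-pair association counts once even when
both sides hit; per (pair, pathway) the synchronization type is *symmetric*
(both sides), *asymmetric* (one) or *none*. The category-fraction test
crosses enriched-pathway membership with category membership (one-sided
Fisher) over the whole catalog.

**Pathway interactions.** Per region pair, side-1 and side-2 binary calls
are crossed into a pathway x pathway adjacency and symmetrized by
element-wise max (region-pair orientation is arbitrary); the diagonal marks
both-side association, and symmetrization is idempotent. Per binding class,
cell-wise presence counts against the not-bound reference form 2x2 tables
tested by Pearson chi-square without continuity correction (Yates variant
available), computed by the closed form
`n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))` vectorized over all cells and
cross-checked against scipy's contingency test; degenerate margins give
p = 1, as do cells with no interaction in either group. Cells below nominal
p < 0.05 become graph edges; degree counts incident edges with self-loops
contributing one, since a diagonal cell is a meaningful
symmetric-synchronization signal. Ward clustering of the −log10 matrices is
an optional report whose memberships are configuration-dependent and never
asserted. The symmetric-synchronization test builds, per pathway and class,
the 2x2 table (pair in class vs reference) x (pathway symmetric in pair)
with a one-sided Fisher p.

## Blood gene-set association

Probe-level expression collapses to gene level by mean-max: the probe with
the highest mean across subjects represents the gene verbatim, ties to the
smallest probe id. Each gene is tested against a diffusion measure in a
linear model with sex, age, RIN and plate; the plate term is fixed-effect
dummies rather than the random intercept a mixed model would use — with a
handful of plates the two are practically indistinguishable for the
expression coefficient, and fixed effects keep the permutation scheme
exact. The per-gene statistic is the Wald chi-square `(beta/SE)^2`,
computed by Frisch–Waugh–Lovell residualization (`t^2` with
`df = n - rank(design) - 1`), capped at 1e12 when the fit is numerically
degenerate, and verified against statsmodels in the tests. The gene-set
statistic is the plain sum over set genes — invariant to gene order,
monotone in each component. The null permutes whole subject columns of the
expression matrix against the fixed measure and covariates, preserving
inter-gene correlation (which the sum statistic is sensitive to);
per-gene independent shuffles would destroy it and overstate significance.
`p = (1 + #{perm >= obs}) / (1 + n_perm)` (add-one convention) is never
zero and respects the `1/(1+n_perm)` floor. Full-scale runs use 100,000
permutations; the test suite and acceptance script use 199–999. Fewer than
100 permutations are refused.

## Synthetic data: what it emulates, and what it does not

One master seed fans out to per-dataset child generators through
`numpy.random.default_rng([seed, stream])` (PCG64; stream indices 1–4 for
tracts, expression, phenotypes, blood), so datasets are independently
reproducible and regenerating one never shifts another. Planted truth is
written to a separate `truth.json`; no pipeline stage reads it. Generated
matrices contain no missing values.

- **Volumes.** A white-matter slab below a plane of 2x2x2 ROI blocks — every
  ROI touches white matter with a 2x2 boundary sheet. Planted (tract, roi,
  fraction) triples deposit that fraction of the tract's integer path mass
  evenly over the ROI's boundary mask; a configurable leak rate scatters
  mass multinomially over unplanted boundaries (exactly zero at leak 0);
  the remainder falls on white matter. No MR physics, scanner effects or
  tractography geometry are simulated.
- **Expression.** Genes are unit-variance Gaussian with a shared linear
  covariate confounder; planted synchronized blocks load sqrt(rho) on a
  block latent factor so every cross-region block pair correlates at rho
  before the covariate term. Gaussian margins are an assumption of
  convenience — the original microarray intensity distributions are not
  modeled — so calibration results speak to the procedure, not to platform
  artefacts. Because one factor drives a whole block, block-level recovery
  fractions fluctuate together across seeds; power statements are made for
  the correlation screen on the planted matrices.
- **Phenotypes.** An ADNI3-like cohort (defaults: 499 subjects,
  CN/MCI/Dementia 347/118/34, age 73.8 +- 8.4) with measures
  `beta * severity + covariate effects + N(0, sd)`.
- **Blood.** Gene latents with probe-level noisy copies at distinct offsets
  (so mean-max is exercised), sex/age/RIN/plate covariates, and an optional
  planted effect of the standardized target-set mean on one designated
  measure. Defaults mirror the full-scale study's 102 subjects and 49-gene
  target set.

## Problem sizes and tolerances

The suite runs at desk scale by design: null calibrations use 200–400
replicates (binomial 95% CI around 0.05), the TTC null uses 200 x 200 genes
at n = 40, bipartite recovery uses three 30 x 30 blocks (within-density
0.3, between 0.01) over 50 seeds scored by normalized mutual information,
and permutation tests use 199–999 permutations. Floating-point comparisons
use relative tolerances of 1e-8 to 1e-12 against oracles that are exact
summations. Fisher p-values on fixed-margin tables are discrete and
super-uniform; calibration under label permutation is therefore asserted
one-sidedly (no anti-conservatism) rather than by two-sided uniformity,
which a discrete conservative test cannot satisfy.

## Known limitations

- The t approximation for Spearman p-values at 1e-8 thresholds is an
  extreme-tail extrapolation; at n in the 30–50 range its accuracy there is
  unverifiable by permutation and is taken as a convention.
- Full transcriptome scale (20k x 20k gene pairs per region pair) is a
  documented cluster-mode contract of the blocked implementation, not a
  test-suite requirement.
- The ECDF elbow is a geometric rule; on data without scale separation the
  fixed cutoff mode should be preferred.
- Mixed-effects site/plate modeling and longitudinal designs are out of
  scope.
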