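# Methods

This note documents the statistical models, conventions and design
choices behind popflow, in the order the pipeline applies them.

## Synthetic cohorts

The generator exists because chip cohorts of labelled regional groups
are rarely deposited; it produces data under the simplest model in which
every downstream statistic has a known expectation.

**Drift.** Population allele frequencies follow the Balding–Nichols
model: an ancestral frequency `p` is drawn uniformly on [0.05, 0.95]
(bounded away from 0/1 so that ancestral monomorphism never occurs —
within-population fixation must come from drift, which is exactly what
the drift statistic measures), and population *i* draws
`p_i ~ Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i)`.  This gives
`E[p_i] = p` and `Var(p_i) = F_i·p(1−p)`, so Weir–Cockerham θ estimates
`F_i` directly and the monomorphic fraction is monotone in `F_i`.

**LD blocks.** Within a block of `block_length` consecutive markers
(default 50) every haplotype is copied from a founder pool (default 4);
blocks are drawn independently, so cross-block R² is at the sampling
floor.  Founders are built as a *two-core mixture*: two core haplotypes
are drawn site-wise from the population frequencies, founders alternate
between the cores, and each founder site is flipped with a small
mutation rate (default 0.01).  This construction is deliberate:
independent Bernoulli founders would give mean within-block R² of about
`1/(pool − 1)` (≈ 0.33 at pool 4), which no 0.7 threshold could separate
from background, whereas the two-core pool keeps most segregating pairs
at R² ≈ 1 while the mutation rate injects realistic haplotype diversity.
The trade-off is that a small pool quantises within-population allele
frequencies, so block-structured populations are used for LD/hotspot
analyses while frequency-based calibrations (Fst, drift, RSM) use
`founder_haplotypes_per_block=None`, which draws haplotypes site-wise at
linkage equilibrium.  The `analysis/` scripts mirror this split the way
the underlying study design does: hotspots are flagged on a separate
dense reference panel, then removed from the cohort by position.

**Planted regional markers** set one population's frequency to
`p + shift` at chosen markers (a zero shift is a no-op).  **Admixed
individuals** draw each of their two haplotypes from a source
population's pool according to per-individual ancestry proportions;
locus-level ancestry tracts are not modelled, which is sufficient for
distance/embedding behaviour but not for tract-length statistics.
**Missingness** is i.i.d. per call; the default rate 0.013 reproduces a
98.7% genotype call rate.  Every operation is a pure function of
`(inputs, seed)`; seeds are combined with per-stage tags through
`numpy.random.SeedSequence`.

Default cohort: 5 populations × 16 diploids, 2 000 markers, drift graded
0.30/0.20/0.16/0.12/0.02 — a desk-scale analogue of a worldwide panel
whose groups range from strongly bottlenecked to nearly panmictic.

What the generator does *not* emulate: coalescent genealogies and
recombination maps, mutation, selection, real LD decay (blocks are
rectangular), and site-frequency spectra; a pass on synthetic data shows
the statistics behave correctly under their own model assumptions, not
that a particular real cohort satisfies those assumptions.

## Two-locus EM and R²

For unphased biallelic genotypes the 3×3 genotype table determines all
haplotype counts except the double-heterozygote cell, which is split in
the E-step between *AB/ab* and *Ab/aB* proportionally to the current
`f_AB·f_ab` vs `f_Ab·f_aB`; the M-step renormalises.  Iteration stops
when the largest frequency change is below `tol` (default 1e-8) or at
`max_iter` (default 1000; non-convergence flags the result and returns
the last iterate).  The likelihood is non-decreasing per iteration.

Initialisation matters: at linkage equilibrium `f_AB·f_ab = f_Ab·f_aB`
holds identically, so the LE point is an exact fixed point whenever the
first M-step lands back on it — for tables dominated by double
heterozygotes it is a saddle and single-start EM can be ~20 log-units
below the maximum.  The estimator therefore also starts EM near each end
of the Fréchet interval of `f_AB` (the marginal allele frequencies are
sufficient statistics and stay fixed across iterations) and returns the
best-likelihood solution.  On random tables this matches a 0.001-step
grid search over the `f_AB` profile to within 1e-6 log-units.

`R² = D²/(p_A(1−p_A)p_B(1−p_B))` with `D = f_AB − p_A·p_B`; undefined
(NaN) when either locus is monomorphic, and undefined values never
propagate into hotspot decisions.

## Hotspot flagging

For each focal marker and reference population, R² is computed against
every flanking marker within `flank` positions (default 25) on the same
chromosome, on samples with complete calls at both loci (pairwise
deletion); the statistic is the arithmetic mean of the defined values
(focal-vs-flank pairs only — this yields a per-marker statistic and is
O(flank) per marker, whereas all-pairs-in-window would be O(flank²) and
yield a window, not marker, statistic).  A marker is flagged when at
least one population's defined mean falls below the threshold (default
0.7).  Ground-truth evaluation on simulated blocks: a planted boundary
counts as detected if any flagged marker lies within `flank` of it, and
the false-positive rate is the flagged fraction among markers farther
than `flank` from every boundary — markers inside the boundary zone
legitimately see the boundary through their window and are counted in
neither denominator.  At the default design (pool 4, block 50, 200
diploids) boundary sensitivity is 1.0 and FPR a few percent, driven by
founder-mutation singleton markers.

## Call-rate experiments

`GCR_i = N_gt/(N_gt + N_ng + N_ig)`.  Degradation inserts
`N_ig = round(total·(1 − target)) − N_ng` no-calls (floored at 0)
uniformly at random among each sample's called positions, never touching
natural no-calls, so missingness is monotone and stepwise degradation
equals direct degradation in per-sample counts.  Marker QC drops markers
with call rate strictly below the cutoff (a marker exactly at the cutoff
is retained); samples are never dropped.

## Regional specific markers

Frequencies come from genotype counts, `p = (2n_11 + n_12)/2(n_11 +
n_12 + n_22)`, pooled counts giving `p̄`.  The deviation variance is
`var_i = (p_i − p̄)²` and `z_i = (var_i − μ)/σ` with μ, σ the mean and
*denominator-K* standard deviation of the variances across populations
at that marker (populations with no called samples are excluded; markers
with fewer than three defined populations are unusable; σ = 0 gives all
z = 0 and no selection).  Defined z-scores sum to zero, and selection is
invariant under allele relabelling and sample-size scaling.

A hard consequence of standardising within K values (Samuelson's
inequality): no |z| can exceed `√(K−1)`.  The default threshold 4.0 is
therefore only attainable with K ≥ 18 populations — consistent with a
24-group design (bound ≈ 4.8), and the planted-marker tests demonstrate
≥ 90% recovery at 24 groups.  With 10 groups the bound is 3.0 and the
4.0 threshold selects nothing, which the test suite records explicitly.
On panels whose groups drift at very different rates, genuine drift
outliers in the high-F groups dominate σ and mask moderate planted
shifts elsewhere; this is the method working as designed (it looks for
*any* population-specific deviation), not an implementation artefact.

Thinning scans each chromosome in position order and keeps the first
marker of every maximal run of selected markers whose consecutive gaps
are ≤ 500 kb; unsorted input is an error, never silently sorted.

## Distances, MDS, PCA

IBS sharing at a locus is `2 − |d_a − d_b|` for dosages, i.e. het–het
pairs share 2 (genotype-identity convention; the allele-matching
alternative would give 1).  Distance = 1 − shared/(2·loci), over
pairwise-complete loci; under this convention the allele-sharing
distance coincides with the IBS distance for biallelic SNPs and the
metric label records intent.  A pair with no jointly called loci is an
error listing the pairs.

Classical MDS double-centres the squared distances, `B = −½JD²J`, and
scales the top-k eigenvectors by √eigenvalue; negative eigenvalues
(non-Euclidean inputs) zero their axes with a logged warning rather than
erroring.  PCA codes genotypes 0/1/2, centres by `2p̂`, scales by
`√(p̂(1−p̂))`, mean-imputes missing entries (0 after centring), and
excludes overall-monomorphic markers.  Both embeddings fix axis signs so
the largest-magnitude loading is positive, making outputs bitwise
reproducible.

## Neighbor joining

Saitou–Nei agglomeration with the Studier–Keppler criterion
`Q(i,j) = (N−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`; ties in the minimum
break by lexicographic order of the joined labels, so topology is a pure
function of the input.  Limb lengths use the standard formulas; negative
lengths are clamped to zero with the original value logged (clamping can
be disabled).  On additive matrices the tree reproduces the input
distances exactly (verified to 1e-9 up to 12 taxa).  Trees are written
as Newick with labels quoted when they contain reserved characters;
population-level trees from mean inter-group distances are available
alongside individual-level trees.

## Fst and drift

Weir–Cockerham variance components a (among populations), b (among
individuals within populations) and c (within individuals, from observed
heterozygosity) are computed per marker from genotype counts;
`θ = a/(a+b+c)` per marker and the multi-locus mean is the ratio of sums
`Σa/Σ(a+b+c)`.  Markers missing an entire population or monomorphic
overall are skipped and logged.  Grouped tables report each group
against the pooled complement at every nesting level, on that level's
samples only (a single group has an empty complement and is an error).
θ is a method-of-moments estimator, not the posterior drift parameter of
an admixture F-model, so absolute values from other software will differ
even on identical data; orderings are comparable.

The drift score counts, per population, markers monomorphic within the
population among markers polymorphic in the pooled sample; populations
rank descending by fraction.  The count is sample-size biased (smaller
samples fix more markers by chance), so a >20% size spread logs a
warning and `rarefy=True` subsamples every population to the minimum
size with a seeded generator.

## Pipeline

Stage order is fixed — load/simulate, marker QC, optional RH filter,
optional RSM restriction or 500 kb spacing, optional call-rate grid,
then per-variant distances/MDS/PCA/NJ/Fst/drift — with hotspot filtering
always preceding distance computation.  The JSON manifest records per
stage the parameters, seed, sample/marker counts and a content digest;
re-running with the same config and seed reproduces all numeric outputs
bitwise.

On call-rate robustness: with pairwise deletion, the within-population
embedding spread scales like the reciprocal square root of the jointly
called locus count, so degrading from 98.7% to 85% call rate (joint
factor 0.85² ≈ 0.72, plus the 80% marker cutoff) predicts a ~19%
decline in the between/within separation ratio before any sampling
variance.  Observed declines on the default cohort are 20–35%; the map's
cluster structure itself remains intact (all groups separated), which is
the qualitative robustness the filtering aims for.

## Problem sizes

Test and acceptance runs use desk-scale designs chosen to keep every
Monte-Carlo band comfortable: 200 random tables for the EM oracle, 2 000
markers / 200 diploids for hotspot recovery, 5 000 unlinked markers ×
100 diploids × 2 populations for Fst recovery (±0.02 band), 5 000
markers for drift monotonicity, and the 5-population default cohort for
pipeline checks.
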