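# Methods

## The BEP model

The simulator grows a tumor as a cellular automaton on a 2D square lattice
(one cell per point). Each cell carries a binary genome **g** of
`n_genes` loci; the first `n_drivers` are driver genes. Per unit time step
every cell dies with probability `death_prob` (q₀) and, if it survives,
divides with probability

    p = min(1, p0 · 10^(f·k)),      k = number of mutated drivers.

The cap at 1 is our addition: p is a probability and the formula exceeds 1
for k·f ≳ 3.75 at the defaults. Before a division the parent genome is
mutated — each wild-type locus switches on independently with probability
`mutation_rate` (r) — and the daughter receives a copy, so parent and
daughter both carry the newly acquired mutations (the procedure mutates
"before the cell division"; which of the two cells keeps the new mutations
is otherwise ambiguous, and both-carry is the literal reading). There is
no back-mutation, no migration, no fitness cost, no 3D growth.

Default parameters are the study conditions: n = 300 genes, p₀ = 0.001,
q₀ = 10⁻⁷, c₀ = 10 initial cells packed at minimal Euclidean radius around
the lattice center, growth until the population exceeds c_max = 10⁶ or
t_max = 5·10⁶ steps. The three evolutionary parameters default to the
ABC-fitted setting r = 0.01, d = 6, f = 0.8. The lattice side is not
specified by the model; we default to 2048 for c_max = 10⁶ (area margin
≈ 4×) and use 200 for the scaled 10⁴-cell configuration.

### Spatial dynamics

A step is three phases: (1) death and division marks are drawn
simultaneously from the pre-step state; (2) dead cells are removed;
(3) marked survivors divide in outward-square-spiral order from the
lattice center — implemented as ordering by (Chebyshev ring, angle), with
each ring's traversal direction flipped with probability 1/2 per step to
preserve spatial symmetry. A daughter goes to a uniformly chosen empty
Moore neighbor if one exists; otherwise each of the 8 directions is drawn
with probability ∝ 1/lᵢ, where lᵢ is the run of consecutive occupied
points before the nearest empty point, and the run is shifted outward by
one point. A direction whose run reaches the lattice boundary without an
empty point is ineligible; if all 8 are ineligible the division is
skipped. One global PRNG stream (NumPy PCG64, explicit seed) drives the
whole run; the spiral fixes the draw order, so runs are bit-reproducible.
Cell identifiers are never reused, which keeps the full genealogy
addressable for lineage tests.

Because q₀ ≈ 0 there is no cell turnover: the tumor is a frozen spatial
mosaic of its growth history, and "selective sweeps" happen only by
differential expansion, not replacement. Lineages that happen to collect
drivers in few divisions take off fastest, so trunks are short relative to
the post-takeoff mutation load — which is why per-sample (rather than
profile-union) summary statistics are the ones that match multiregional
data (below).

## In-silico multiregional sequencing

25 square windows (31×31 points) are centered on a 5×5 grid at offsets
{0, ±s, ±2s} about the lattice center with s = (L−w)//4 — evenly spread,
pairwise disjoint for L ≥ 5w, and symmetric under 90° rotation about the
pattern centroid. A window is eligible when at least half its points are
occupied (≥ 481 of 961). s windows are drawn uniformly from the eligible
set; per window and gene the VAF is the mutated-cell fraction among
occupied points (the simulated genome is haploid and purity is 1, so VAF =
cancer cell fraction), and VAFs not exceeding 0.3 (inclusive) are floored
to 0, emulating the detection limit of bulk multiregional sequencing.
Sequencing noise itself (read sampling, error rates) is deliberately not
modeled. Scaled test runs keep the 31×31 window wherever the lattice
allows the full 5×5 grid (200 ≥ 155); the window side is a parameter for
smaller worlds.

## Summary statistics and the ABC fit

For a profile matrix (genes × samples, zeros below the floor):

* φ = mean over samples of (founder-row count) / (rows non-zero in that
  sample);
* θ = mean over samples of (rows non-zero **only** in that sample) /
  (rows non-zero in that sample).

Both are *per-sample proportions averaged over samples*. The defining
text is ambiguous between this and a profile-union denominator; we chose
the per-sample form because it is the one consistent with the fitted
model: at r = 0.01, d = 6, f = 0.8 the simulated per-sample φ centers on
≈ 0.72 (the observed value), whereas the union denominator yields ≈ 0.4
and *decreases* with tumor size, which would make the published fit
impossible. An empty sample column contributes 0 to both statistics.

Observed values are estimated per case: cases with exactly s = 5 samples
directly, larger cases as the average over 10 uniform 5-sample subsets;
mean and SD (ddof = 1) are then taken across cases. The ABC grid is
d ∈ 1..10 × f ∈ 0.1..1.0 (step 0.1) × r ∈ {10⁻⁴, 3·10⁻⁴, 10⁻³, 3·10⁻³,
10⁻²} = 500 settings; each setting's score is the fraction of replicate
simulations whose (φ, θ) both fall within one SD (closed interval) of the
observed means. Replicates whose profile is all-zero or that cannot
supply s eligible windows count as rejected.

## Mutation profiles, trees, colors, spectra

Real-data profiles are built per case by rescue-and-filter: keep variants
called somewhere whose depth is ≥ 10 in *every* sample (absence is then
trustworthy), mark presence where VAF > 0.05 (strict), drop variants
present nowhere. Founder = present in all samples; unique = exactly one;
shared = the rest. Heat-map row order: founder by chromosomal position,
shared by average-linkage hierarchical clustering of VAF vectors, unique
by sample then descending VAF.

Sample trees are built by greedy binary-character compatibility:
characters (presence patterns) are processed by descending sharing count
(ties: lexicographic pattern), a pattern is admitted as a clade iff
compatible (nested/disjoint) with all admitted clades, and rejected
characters are charged to the minimal admitted cover (counting the extra
origins as homoplasy). The trunk above the root carries the founder
characters. The procedure is deterministic, and on conflict-free matrices
it reproduces the unique perfect phylogeny (validated against exhaustive
scoring of all rooted binary topologies for ≤ 6 leaves). Unresolved
regions may differ from trees produced by general parsimony software.
Branch bipartitions — {leaves under a branch} vs {the rest} for every
branch below the first branching point, complementary duplicates merged —
feed the copy-number and methylation callers.

Sample colors: project each sample's VAF vector on the first three
principal components, min–max scale each component to 0–255
(numerically degenerate components fall back to 128), emit RGB. Mutation
spectra collapse substitutions to the pyrimidine strand; the 6-class mode
splits C>A/C>G/C>T by 3′-G (CpG) context, and the 96-channel mode bins by
both flanking bases.

## Cancer cell fraction

For a mutation in m of n reads at allele-specific copy number (q_a, q_b)
and purity α, the expected allele fraction of a mutation on p copies in a
fraction c of cancer cells is f = αcp / (2(1−α) + α(q_a+q_b)), clipped to
[0, 1]. (The source prints the expression without the division sign; the
quotient is the only reading with f ≤ 1 and matches the cited approach.)
The posterior over a 100-point grid c ∈ [0.01, 1] (both endpoints
included) is ∝ Binom(m | n, f)·P(p | q_a, q_b) with a uniform prior on c;
P(p) enumerates all single-allele configurations (1..q_a on allele a,
1..q_b on b) as equally probable. CCF is the posterior median, defined as
the smallest grid point whose cumulative mass reaches 0.5. CCF > 0.8
(strict) is clonal; samples with purity ≤ 0.6 are not evaluated. Note the
estimator's precision is bounded by binomial noise: at depth 2000 the
sampling SD of the implied CCF is ≈ 0.02–0.03, i.e. 2–3 grid steps.

## Copy-number calls

Segmented LRR tables are median-centered per sample (plain median of
segment values) and averaged per predefined region with segment-length
weights; regions without coverage in some sample are excluded with a
warning. Founder call: one shared sign with |LRR| > 0.06 in all samples
and |LRR| > 0.12 in at least one (the sign-consistency requirement is
ours — a direction must be assignable). Progressor call (on regions not
already called founder): the signed group-mean difference with maximal
absolute value over the tree bipartitions, called when |ΔLRR| > 0.06,
direction from the sign of the altered (larger-|mean|) side. A focal call
inside an arm-level call of the same category is discarded. The
recurrent-region list is a user input; a toy region set ships with the
fixture generator.

## Methylation calls and variance

Δβ = tumor β − matched-normal β per probe. Founder hyper: Δβ > 0.3 in all
samples of the case; founder hypo: Δβ < −0.3 (the printed hypo threshold
lacks the sign; the symmetric reading is the only sensible one).
Progressor: Δ′β = max-|difference| of group-mean Δβ over bipartitions;
the threshold θ is the smallest value on the grid 0.05..0.60 (step 0.01)
whose permutation-estimated FDR — mean permuted exceedance count over the
observed count, default 100 permutations — is ≤ 0.1; calls split
hyper/hypo by the sign of the sample-mean Δβ. With very lopsided
bipartitions (n−1 vs 1) and strong effects the permutation null is
contaminated by the effect itself and the estimated FDR plateaus above
the target, so no calls are made; this is a property of the
label-permutation design, not of the implementation, and it is why the
synthetic fixtures plant progressor events on balanced splits of 8
samples per case.

Variance analysis decomposes each probe's total sum of squares across all
samples into within-case and between-case parts, SS_T = SS_w + SS_b
(identity asserted to 1e-9 relative tolerance). SS_w measures intratumor
and SS_b intertumor variance — the formulas' standard meaning; a prose
sentence in the source transposes the two labels and we follow the
formulas. Category enrichment among the top-N highest-variance probes is
(category fraction in top N) / (category fraction overall).

## Synthetic fixtures

The generators emulate the *shapes* of multiregional data, not its
noise structure: mutation profiles plant founder/shared/unique variants
on a chosen topology with base VAFs 0.3/0.2/0.1 and truncated-Gaussian
noise kept above the presence threshold; CN fixtures emit one segment per
region per sample plus quiet chromosomes (keeping the per-sample median
at 0) with Gaussian segment noise; β fixtures combine case-level baseline
offsets (intertumor clustering) with planted founder (whole-case) and
progressor (half-case clade) events of ±0.4 on a matched-normal baseline
drawn in [0.4, 0.6] so hypo events stay within [0, 1]. All generators are
deterministic given the seed, and truth tables round-trip through the
package's readers. Passing recovery tests on these fixtures demonstrates
the callers' logic at the published thresholds; it does not certify
performance on array-specific artifacts (probe cross-reactivity,
normalization drift) or sequencing noise, which the generators do not
model.

## Problem sizes and numerical choices

The test-suite and the scaled reproductions run the simulator at
c_max = 10⁴ on a 200-side lattice (a run takes a few seconds), pooling 20
runs for the VAF-ordering/driver-enrichment patterns and 10 replicates
per setting for the ABC gradient; the full-scale configuration
(c_max = 10⁶, lattice 2048) is the library default for real use. Window
eligibility uses 2·occupied ≥ window-size to mean "at least half".
Tie-breaks everywhere are deterministic (documented in the relevant
functions); probabilities are capped/clipped where formulas can leave
[0, 1]; degenerate inputs (all-zero profiles, zero-variance color
profiles, empty sample columns) have defined behaviors rather than
exceptions wherever a neutral value exists.

## Known limitations

* The simulator stores every cell ever created (for lineage queries);
  full-scale runs with high mutation rates are memory-heavy (≈ 0.3 GB per
  10⁶ cells at n = 300).
* The greedy tree builder guarantees optimality only on conflict-free
  character matrices.
* The permutation-FDR threshold search returns no calls when the null is
  saturated (see above) and can make occasional lucky calls on pure-null
  data when the observed exceedance count at a high threshold is tiny.
* CCF precision is depth-limited; clonal/subclonal classification near
  the 0.8 boundary inherits that noise.
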