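# Methods

This note records the models, rules and numerical choices behind each
`viropop` module, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Coordinates and units

All intervals are 0-based half-open internally and in emitted BED; tables
that print positions are 1-based and labelled. Percent identity is a
fraction in [0, 1] everywhere inside the library; BLAST tabular input
(percent, 1-based inclusive, possibly reverse-strand) is normalised on
read. PAF input is consumed as-is (already 0-based half-open). N bases are
legal in sequences; identity is taken from the alignment records, never
recomputed by realignment.

## Dereplication into viral populations

Two contigs belong to one species-rank population when they share
**ANI ≥ 0.95 over ≥ 0.85 of the shorter contig's length**. ANI between a
pair is the match-weighted mean over all their alignment blocks
(Σ matches / Σ aligned length), which is robust to split alignments;
coverage is the length of the union of the shorter contig's alignment
intervals divided by its length. The coverage denominator is deliberately
the *shorter* contig (ClusterGenomes behaviour): a short fragment fully
contained in a longer genome should dereplicate into it.

Clustering is **greedy longest-first**, not single-linkage: contigs are
sorted by length descending (ties broken lexicographically by id for
determinism); each still-unassigned contig seeds a population and absorbs
every unassigned shorter contig that passes the test *against the seed*.
Consequences worth knowing: the output always partitions the input, the
representative is always the longest member, and chains (A–B pass, B–C
pass, A–C fail) do **not** merge transitively — C remains a singleton. A
brute-force reimplementation of the same rule serves as the equivalence
oracle in the test suite.

Breakage analysis takes the union of member-alignment footprints on a
representative and counts every maximal uncovered run — terminal runs
included — as one breakage. Counting terminal runs means
`pct_aligned = 100` iff `n_breakages = 0`, a conservation check the demo
asserts. Members shorter than `min_member_len` (default 1000 bp, the
conventional cut-off for surveying all short-read contigs) are ignored.

## Abundance, presence and normalisation

*tpmean* is the mean per-base depth after excluding positions strictly
below the 5th or strictly above the 95th percentile of the per-position
depth distribution. Percentiles are **nearest-rank** on the sorted depth
vector (the ceil(q·n)-th smallest value) and the exclusion is strict, so a
constant track returns the constant and a single-position track returns its
depth. Percentiles are computed per contig per sample, not pooled.

Breadth (horizontal coverage) is the fraction of positions with depth ≥ 1
from filtered mappings (reads kept iff aligned length ≥ 90% of read length
AND identity ≥ 95%, both inclusive). A population with breadth < 0.70 in a
sample is assigned abundance exactly 0 — the false-positive guard — and
otherwise contributes its tpmean scaled by 1e6 / total reads in the sample
(per-million-reads normalisation; the unit is recorded in the matrix
metadata). The isolate-genome screen reports presence at both the standard
70% and a relaxed 40% breadth cut-off alongside RPKM
(`reads / (len/1e3) / (total/1e6)`). Read subsampling to a fixed budget
(default 5 million) is a uniform draw without replacement, deterministic
under the seed and order-preserving, so presence calls are comparable
across datasets of different depths.

## Hypervariable regions

A hypervariable region is a maximal run of positions with depth **strictly
below 20% of the whole-contig median** (strict, from "less than"), **≥ 600
bp** long, **containing at least one exactly-zero position**. The three
criteria are conjunctive; the zero-zone requirement is what separates
strain-variable loci from merely poorly covered stretches. The median is
taken over all contig positions including the dip itself — with dips a
small fraction of contig length this is stable — and a zero-median contig
is an error (it should have failed the presence rule upstream). Top-N
selection of abundant contigs and the mapping-filter thresholds are CLI
parameters, not hard-coded.

## Host prediction

Evidence tiers are additive per (virus, MAG) pair, each kind contributing
its best tier only (no double counting across multiple hits of one kind):

| kind | tiers |
|---|---|
| prophage BLAST | 4: ≥ 98% id ∧ ≥ 90% cov; 3: ≥ 90% ∧ ≥ 75%; 2: ≥ 90% ∧ ≥ 50%; 1: ≥ 90% ∧ ≥ 30% |
| tRNA match | 3: 100% id; 2: ≥ 95%; 1: ≥ 90% |
| WIsH | 2.5: p ≤ 1e-10; 2: p ≤ 1e-5 |

All thresholds are inclusive. A combined score ≥ 3 assigns a putative host;
pairs scoring 0 are omitted. The BLAST coverage denominator is whatever the
upstream evidence table used — the library consumes it as given. MAG
quality is `completeness − 2 × contamination`, with a hard gate at
completeness ≥ 70% and contamination ≤ 10%.

## Microdiversity (π)

A contig enters the analysis only when breadth ≥ 0.70 and mean depth ≥ 10X.
SNV sites are retained when QUAL > 30 (strict), and some non-reference
allele has frequency > 1% (strict) with ≥ 4 supporting reads; the frequency
filter is evaluated on the raw counts, before subsampling, matching the
order in which the filters are defined. Each retained locus with depth ≥ 10
is subsampled to exactly 10 reads by a multivariate hypergeometric draw
(without replacement); shallower loci are excluded.

Per-site diversity is the unbiased sample heterozygosity
`π_s = n/(n−1) · (1 − Σ_a p_a²)` with n the subsampled depth and p_a the
subsampled allele fractions. This equals the fraction of mismatching read
pairs among the n(n−1)/2 pairs at the locus (for {A:5, C:5} at n = 10:
25/45 ≈ 0.556), which the tests verify by direct pair enumeration. Contig
π averages π_s over the *covered length* — positions with pre-subsampling
depth ≥ 10, the π-evaluable sites — so monomorphic covered positions
contribute zero and π lands on the per-site scale (deep-virome surveys
report values around 1e-4). Averaging over all covered sites rather than
SNV loci only is a deliberate choice; the alternative inflates π for
sparse-SNV contigs.

A statistical property to be aware of: because the estimator is unbiased
for the diversity of the read pool, its *expectation* over binomial read
sampling at true allele frequency f is `2f(1−f)` — the n/(n−1) factor
cancels in expectation and does not reappear as a multiplicative bias. The
parameter-recovery tests assert exactly this.

Group comparisons: the bootstrap draws 100 π values with replacement per
replicate, 1000 replicates, reporting the mean of replicate means and the
2.5/97.5 percentile interval. The permutation test pools both groups,
shuffles labels and re-splits at the original sizes; the statistic is the
difference of group means and the two-sided p-value carries the +1/+1
correction, `p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (n_perm + 1)`, so p is never
0 and the test is exact under exchangeability.

## Community ecology

Abundances are cube-root transformed (a compromise between untransformed
and presence/absence that tempers dominance of abundant populations) before
Bray–Curtis dissimilarity `Σ|u−v| / Σ(u+v)`. A pair of all-zero samples is
defined to have distance 0, with a warning. PCoA is the Gower
double-centring `B = −½ J D² J` followed by eigendecomposition; axes come
from positive eigenvalues only (scaled eigenvectors), negative eigenvalues
(Bray–Curtis is semi-metric) are reported in the spectrum, and percent
explained is taken over the positive-eigenvalue sum. PERMANOVA uses the
standard one-way pseudo-F
`F = ((SS_T − SS_W)/(g−1)) / (SS_W/(n−g))` with squared distances, a
label-shuffle null and the +1/+1 p-value — at 999 permutations the smallest
attainable p is exactly 0.001, which is what a maximally separated
configuration reports. F is invariant to global rescaling of the distances,
so p is too. SIMPER averages the per-taxon contribution
`|u_i − v_i| / Σ_k(u_k + v_k)` over all between-group sample pairs and
normalises to fractions of the mean dissimilarity (summing to 1); ties in
the ranking break by taxon id. Group centroids are unweighted means of
member coordinates over all retained ordination axes. The prevalence
bootstrap resamples the per-population sample-occurrence counts 10,000
times and brackets the median with the 2.5/97.5 percentile interval.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline consumes,
not sequencing reality. Populations are point-mutated copies of unrelated
random seed sequences: the representative is the seed itself; members are
truncated by up to 5% (so "longest = representative" is well defined) and
mutated to the configured identity (default 0.97), with two thirds of each
member's mutations drawn from a population-shared polymorphic set and one
third private. The shared set keeps member–member identity near
`1 − ⅔(1−id)` (≈ 0.98 at 0.97), mirroring co-circulating strains that share
derived alleles, and guarantees that any configured identity ≥ 0.95 yields
one cluster under the 95/85 rule. Decoy contigs at 0.90 identity probe the
rejection side. Because members differ from the seed only by substitutions,
the true alignment is the identity mapping and alignment records (and hence
ANI) are computed exactly from the sequences — no aligner, no heuristics.

Coverage tracks are Poisson around a per-contig mean drawn from
`mean_depth_range` (default 20–80X, a realistic range for abundant virome
populations). Engineered dips are Poisson around the dip floor, capped well
below 20% of the mean; zero-floor dips contain forced zeros, positive-floor
dips are clamped to depth ≥ 1 so they exercise the zero-zone rejection
path. SNV loci have binomial alternative counts at fixed depth (default
50X) and QUAL 50. Abundance matrices are log-normal with multiplicative
sample noise and a `2**effect_size` fold-change on the first
`n_effect_taxa` populations in the second sample group; `effect_size = 0`
is the exchangeable null. Defaults (8 populations × 3 contigs, 12 samples
in two groups of 6) keep the full demo under a few seconds while leaving
every decision rule non-trivially exercised.

Not emulated: read-level sequences (FASTQ), sequencing-error profiles,
indels and rearrangements within populations, assembly artefacts,
compositional correlations between populations, and depth covariation
between samples. Passing tests therefore demonstrate correctness of the
decision rules and estimators under their stated models, not robustness to
upstream artefacts such as misassembly or mapping bias.

## Numerical choices and degenerate inputs

- Seeding: every stochastic routine takes a seed or Generator;
  simulation streams derive from one seed via fixed per-component child
  keys, so regenerating one component never perturbs another.
- Permutation/bootstrap p-values and intervals use the +1/+1 correction and
  percentile method respectively; constant inputs give degenerate
  (zero-width) intervals rather than errors.
- Empty alignment sets give (ANI, coverage) = (0, 0), not an error; an
  unmapped contig has breadth 0 and is zeroed by the presence rule.
- PCoA drops eigenvalues below a relative tolerance of 1e-10 of the largest
  magnitude to avoid numerical-noise axes.
- PERMANOVA raises on a zero within-group sum of squares (identical points)
  and on trivial groupings (one group, or all-singleton groups).

## Limitations

- The clustering stage consumes alignments; it does not produce them. Real
  datasets need an external all-vs-all aligner upstream, and the
  greedy result depends on the completeness of the supplied pair set.
- BAM files are not read; depth, mapping summaries and SNVs arrive as text
  exports. Mapping-filter semantics of different upstream tools are assumed
  equivalent at the ≥ 90%-length / ≥ 95%-identity level.
- WIsH model building, BLAST and tRNA scanning are upstream; only their
  tabular outputs are scored.
- π values are comparable only between datasets processed with identical
  filters and the same subsample target, since the covered-length
  denominator and the 10X subsample are part of the definition.
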