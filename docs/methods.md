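# Methods

## Reference model

The reference is a set of ABO alleles, each with per-exon nucleotide
sequences (exons 6 and 7 in the standard assays) and phenotype metadata.
Allele names follow the dbRBC convention: an optional `ABO*` prefix, a
subgroup token (`A1`, `Ax`, `B1`, `O`, ...), then up to three numeric name
fields separated by dots.  The blood group is the leading letter of the
subgroup token; for O alleles the serological subgroup (O1, O2, O48, ...)
derives from the second name field.  Curation drops alleles that cannot be
typed or interpreted — missing exon 6/7 sequence, truncated exon 7, unknown
or uncertain phenotype — applying the exclusion predicates in a fixed order
and recording the first matching reason.  The "uncertain phenotype"
predicate is carried as an explicit metadata flag rather than derived from
sequence content.

Amplicons are coordinate windows within exons (1-based inclusive in config
files, 0-based half-open internally); overlapping windows on one exon are
allowed, as in the three-amplicon assay (exon 6, 192 bp; exon 7a, 460 bp;
exon 7b, 328 bp).  The two-amplicon assay (exon 6 plus the central 507 bp of
exon 7) is a second window configuration, not separate code.

Per amplicon, alleles with identical window sequences form an Exon Allele
Group (EAG); EAGs partition the retained alleles.  Alleles identical over
*all* windows merge into allele groups named after their lexicographically
smallest member with a trailing `*`.  Adding an amplicon can only refine
this partition, never coarsen it (tested as a property).

## Genotype calling

Raw reads are collapsed per amplicon into distinct sequences with counts.  A
sequence is retained when supported by at least `min_fraction` (default
0.25) of the **modal** sequence count.  The threshold is deliberately
relative to the most abundant sequence rather than to the amplicon read
total: with exact-identity collapsing, each error-bearing read is an almost
surely unique variant, so the one or two true haplotype sequences dominate
the per-sequence count table even when — at realistic window lengths and
error rates — error-free reads are a minority of all reads.  This is the
standard minor-versus-major rule for diploid amplicon assays.  Samples with
fewer than `min_depth` (default 50) reads at any amplicon fail as
`FAIL_LOW_READS`; more than two surviving sequences at an amplicon, or EAG
member sets that cannot be joined into two haplotypes, fail as
`FAIL_NO_INTERSECTION` (the status enum has no dedicated third-sequence
value; the human-readable `reason` field distinguishes the two situations).

Matching is exact and full-length per window.  A non-matching sequence
becomes a novel-allele candidate annotated with the minimal-Hamming-distance
reference allele(s) and the differing positions; indel-containing reads fail
the length check and route the same way.

Calling enumerates every way to distribute the observed sequences onto two
haplotype chains (homozygous amplicons contribute their sequence to both
chains), intersects EAG memberships along each chain, and keeps pairings
with two non-empty candidate sets; unordered duplicates are removed.  Each
surviving pairing is a *phasing alternative*.  Resolution is the highest
level — full, third field, second field, allele group, subgroup, blood
group — at which every alternative's candidate sets project to a single
label and all alternatives agree on the same unordered label pair.
Phenotype follows A/B codominance with O recessive, and is reported as
undetermined when alternatives disagree on the carried blood groups.

## Hardy-Weinberg disambiguation

Under HWE with allele-group frequencies θ, an unordered genotype (i, j) has
probability `2·θi·θj` (i ≠ j) or `θi²`.  A slot whose candidates span
several allele groups takes the sum of their frequencies (candidate sets are
always unions of whole groups).  The relative likelihood of two alternatives
is the ratio of these probabilities; the factor 2 cancels only when both
alternatives are heterozygous, which is stated explicitly because the
published census happens to exhibit only het/het cases.  `resolve_call`
discards an alternative when the best alternative is at least
`ratio_threshold` times more probable.  The default threshold of 1,000 sits
between the published decision points — ratios near 6,000 were acted on,
617 was considered uncomfortably low — and is exposed as a CLI flag.  Ties
are never discarded, and an alternative whose candidates lack a frequency
cannot be scored and is always kept.  Ratios are reported both raw and
integer-rounded; all comparisons use raw values.

The ambiguity census enumerates all unordered allele-group genotypes, maps
each to its observed per-amplicon sequence multiset, and reports every
multiset explained by more than one genotype, ordered by HWE-expected case
frequency (the sum of constituent genotype probabilities).  Published case
frequencies are *observed* cohort values and do not exactly equal the
HWE-expected `2pq` recomputed from the published frequency table; the census
reports the expected value and makes no attempt to match that column.  The
companion error-rate helper, case frequency divided by relative likelihood,
is an order-of-magnitude tool only (for the OB1/OA1 case the published
inputs give one error in roughly 24 million samples).

## Frequency estimation

Samples are tallied by ambiguity category (distinct EAG composition).
Categories partition genotype space; zero-count categories are kept so the
partition stays explicit.  The likelihood is multinomial over categories
with `P(c) = Σ_{(i,j) ∈ G(c)} P_HWE(i,j | θ)`.

* **EM**: E-step splits each category count over G(c) proportionally to
  current genotype probabilities and onto allele copies; M-step sets
  `θ = copies / 2N`.  The log-likelihood is asserted non-decreasing each
  iteration; convergence at relative change ≤ 1e-10, cap 10,000 iterations.
  A category observed with zero probability restarts the chain from uniform
  θ with a warning (unreachable from the uniform start, kept defensively).
* **Gibbs**: data augmentation with exact conjugate updates — latent
  genotypes for ambiguous categories are multinomial draws proportional to
  HWE probabilities, then `θ ~ Dirichlet(α + copies)`.  Symmetric prior
  α = 1 (uniform on the simplex); no thinning; defaults 10,000 burn-in +
  10,000 retained sweeps; posterior mean and SD accumulated by Welford's
  method; a fixed seed reproduces the chain bit-for-bit.  Unambiguous
  categories contribute fixed copy counts computed once, so sweep cost
  scales with the number of *ambiguous* categories, which is small.

Hierarchical summaries sum allele/allele-group values into subgroup totals
and subgroup totals into blood-group totals; the bundled published table is
internally consistent under these sums to ≤ 0.002 percentage points (A1,
B1 and the A total are exact).

## Synthetic data

The generator's defaults are the study conditions of the German survey this
package is modeled on: an allele census of 108 A, 68 B and 73 O alleles,
113,367 samples, ~1,000 reads per amplicon, and the published 82-entry
frequency spectrum (renormalized to a simplex) as the default θ.  The
per-base substitution error rate defaults to 0.001, a typical
quality-filtered short-read figure; the model is substitution-only, since
exact-length matching routes indels to novel-candidate handling by design.

Sequences are random but seed-deterministic: one base sequence per exon,
with each requested EAG class mutating two dedicated positions inside its
amplicon's *exclusive* zone (window positions covered by no other amplicon).
Consequences, by construction: requested collision structures are realized
exactly; distinct window sequences differ at ≥ 2 positions, so a single
read error never converts one reference sequence into another; and collision
classes on different amplicons never interact, which keeps arbitrary
per-amplicon partitions feasible.  The cross-amplicon phasing trap is
expressed as shared exon 6 plus crossed exon-7a/7b sharing over four
alleles, which yields exactly two phasing alternatives for the affected
genotypes.

What the generator does **not** emulate: real ABO sequence content and
real linkage between variant sites, platform-specific error profiles,
indels, chimeras and index hopping, or depth variation across amplicons.
Passing tests therefore demonstrate the correctness of the matching,
enumeration and estimation machinery under controlled sharing structures —
not robustness to every artifact of production sequencing data.

For estimator validation at large N, populations can be drawn directly at
category resolution (one multinomial over category probabilities), which is
statistically identical to simulating reads for every sample and genotyping
them, and is the path used for the 50,000-sample recovery and the
200-replicate coverage checks (run at 2,000 + 2,000 sweeps).  Full
read-level validation runs at 1,000 samples.

## Numerical and design choices

* Simplex conservation is enforced to 1e-9 at every EM iteration and Gibbs
  draw (exact by construction of both updates).
* Deterministic tie-breaks throughout: amplicons sorted by id, alternatives
  sorted by candidate sets, group identifiers by lexicographic minimum.
* `project_novel_rate` uses the unrounded confirmation rate for projection
  and rounds only for presentation (rate to 0.1%, projected count to the
  nearest integer, population rate to two decimals); the output carries a
  caveat flag because the replicated subset is assumed representative.
* The reference bundle is frozen JSON keyed by a content hash so genotype
  calls are traceable to a database version.

## Known limitations

* Exon 6/7 coverage cannot separate alleles differing only elsewhere; weak
  subgroup phenotypes inside cross-subgroup allele groups are inherently
  unresolvable at this assay footprint.
* HWE is assumed both for disambiguation and estimation; strong departures
  (stratification, consanguinity) would bias both.
* The frequency prior is uninformative; with very rare groups and small N
  the posterior mean is pulled toward uniform by α = 1.
* Exact matching treats any indel or primer-site variant as a novel
  candidate rather than attempting alignment.
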