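# Methods

## Coordinate system and variant model

All positions are 1-based coordinates on the bovine mitochondrial
reference (BRS numbering, 16,338 bp, circular). Variant extraction uses
a global pairwise alignment (match +1, mismatch −1, gap open −5, gap
extend −2; Biopython's `PairwiseAligner`). Near-identical mitogenomes
make the result insensitive to the exact scores, but they are fixed for
reproducibility. Circularity is recorded on the reference but alignment
is linear from position 1, matching how complete mitogenomes are
deposited. Aligned mismatches become substitutions at the reference
coordinate; gap runs become insertions anchored to the preceding
reference base (printed `16201.1A`) or deletions, so positions
downstream of an indel keep reference numbering. Columns involving an N
are recorded as ambiguous sites and never emitted as variants. Queries
whose length deviates more than 5% from the reference, or whose
alignment identity falls below 90%, are rejected as non-homologous.

The package cannot ship the real reference sequence, so a deterministic
synthetic stand-in of the same length is generated from a fixed seed.
Only the coordinate system matters to every algorithm here; the one
exception is the transversion motif at 14523, whose reference base is
pinned to A so the explicit-allele change stays valid. On a shortened
genome (used to keep alignment tests fast) all diagnostic positions are
remapped proportionally.

Alignment recovery is exact for well-separated variants whose indels sit
outside homopolymer context; an indel inside a homopolymer run has
several co-optimal placements, and the aligner's choice, while
deterministic, need not match the planted coordinate. The round-trip
tests therefore plant indels only at unambiguous sites, which is also
the only regime in which "the" coordinate of an indel is well defined.

## Haplogroup classification

A haplogroup tree is a single-rooted hierarchy; each node carries a
motif of diagnostic sites (`Ts` = transition relative to the reference
base, explicit `A>T` changes for transversions, `+X` for insertion
alleles). All markers are weighted equally, including hypervariable
control-region sites. The score of a node is the number of motif
variants matched along its root-to-node path. Candidate nodes are the
root plus every node with at least one matched marker of its own; this
encodes reversion tolerance — a missing marker on the path is treated as
a back-mutation only when the node itself (or, transitively, a deeper
candidate) supplies direct evidence, otherwise the sample stays at the
last supported ancestor. The winner is the deepest best-scoring
candidate; ties between sibling branches fall back to matched evidence
strictly below the branching point, and an unresolved tie assigns the
common ancestor with both branches reported as conflicts. Matched,
missing (reversion) and conflicting markers are all part of the
returned assignment, so every call is auditable.

The bundled T1 tree encodes the published diagnostics: T1
(16050/16113/16255 Ts), T1b (7542 Ts), T1c (16122 Ts), T1b1 (16022 Ts)
and a T1b1 subclade defined by the 14523 A>T transversion. The defining
mutations of T1a, T1d, T1e and T1f are not restated in the source
material, so their config slots ship as clearly marked placeholders;
the engine is correct for any user-supplied tree, and real-data work
should substitute the published motifs.

Frequency tables roll assignments deeper than the subhaplogroup level
up to their depth-2 ancestor (T1b1 and its subclade count as T1b), while
samples on shallower internal nodes (a basal T1 lineage) count for that
node itself. Percentages are rounded half-up to one decimal and raw
counts are always reported alongside, because at n = 35 one sample is
2.857% — a value that rounding conventions render as either 2.9% or
3.0%; counts keep such artifacts visible.

## Population statistics

Nucleotide diversity π is the mean, over all unordered sequence pairs,
of pairwise differences divided by the sites usable for that pair
(pairwise deletion: columns with a gap or N in either member are
excluded; a `site_mask` supports complete deletion when preferred). The
default standard error is Nei's (1987) approximation
`V(π) = (n+1)/(3(n−1)L)·π + 2(n²+n+3)/(9n(n−1))·π²`, which accounts for
both site and sequence sampling; a nonparametric bootstrap over
sequences (1,000 replicates) is available. The published "±" values for
the real herds do not name their estimator, which is one of the reasons
they are treated as external-data checks (below).

Pairwise F_ST defaults to Hudson's `1 − H_w/H_b`, with `H_w` the mean
within-population pairwise difference (averaged over the two
populations) and `H_b` the mean between-population pairwise difference.
`H_b = H_w = 0` (identical monomorphic populations) is defined as
F_ST = 0. Slightly negative estimates are legitimate sampling behaviour
and are reported both raw and clamped to zero. The alternative
`phi_st` is a two-population distance-based AMOVA, with raw pairwise
difference counts playing the role of squared Euclidean distances (the
convention of distance-based AMOVA on sequence data).

Significance uses a label permutation test: the p-value is the
proportion of permuted datasets with F_ST at least the observed value,
with the (k+1)/(n+1) correction so p is never exactly zero. Permutations
are split into equal batches (defaults: 10,000 permutations, 10 batches,
seed 1009) and the standard deviation of per-batch p estimates is
reported as `p ± sd`, mirroring the convention of permutation software.
Everything is reproducible from the seed. Under a true null (a
panmictic pool split at random) the acceptance suite verifies the
rejection rate at p ≤ 0.05 stays in the 1–10% band over 200 simulated
datasets.

The founder-gradient report runs π per population and all pairwise
F_ST values over populations in their declared chain order and reports
two booleans: π monotonically non-increasing along the chain, and F_ST
to the chain head monotonically non-decreasing — the joint signature of
serial founder events.

### External-data checks

The published statistics for the real herds (π of 0.00075/0.00082/
0.00094 for the southern African, Ethiopian and Egyptian samples; F_ST
of 0.463, 0.437 and 0.035 with the 0.035 non-significant at
p = 0.07207 ± 0.029) cannot be recomputed here: they require the
original GenBank mitogenome sets plus the comparative genomes, and the
estimator behind the printed values is unnamed. They are recorded in
`popgen.EXTERNAL_REFERENCE_CHECKS` with a ±0.05 absolute tolerance and
surfaced in every run manifest as checks to perform once the external
data are available — never asserted against synthetic inputs.

## Median-joining networks

Characters are the segregating substitution columns plus indel
presence/absence coded as a substitution-like character (a shared
insertion with two alleles therefore separates its carriers), equally
weighted. Identical state vectors are condensed into haplotypes whose
id is the first-seen sample id, with multiplicities and per-population
counts.

The network construction iterates: (1) build the ε-relaxed minimum
spanning network — an edge (u,v) is kept iff `d(u,v) ≤ minimax(u,v) + ε`
where minimax is the bottleneck weight of the u–v path in a minimum
spanning tree, so ε = 0 yields exactly the union of all MSTs; (2) for
every linked pair and every neighbour of its endpoints, form the
per-character majority consensus of the triplet and add it as a median
(Steiner) vector when it strictly shortens the triplet's spanning cost;
(3) repeat until no median is added (a cap of 20 rounds raises a
diagnostic rather than looping); finally prune median vectors of
degree < 3 and rebuild. Ties in the consensus (three distinct states)
keep the state of the lexicographically smallest node id, and node
ordering is sorted everywhere, so output is deterministic and invariant
to input order up to relabelling.

A note on "contains the MST": once a median vector links two sampled
haplotypes through shorter steps, the direct edge between them is
legitimately dropped — that is the point of median vectors. The
guaranteed property, asserted in tests, is the bottleneck sense: every
brute-force MST edge (u,v,w) is realized by a u–v path whose every step
weighs at most w.

Exports: GML (via networkx, with multiplicity, median flag, serialized
population counts and the state vector per node), a TSV edge list with
a sibling node table, and a NEXUS-style network block.

## Synthetic data

### The herd fixture

Thirty-five variant profiles encode the published per-sample
descriptions: every sample carries 16050, 16113 and the 16201 insertion
(allele G in samples 6/10/15, A otherwise); samples 6/7/8 lack 16255
but carry 7542 (reversions); samples 16/27/40 lack 7542 and are T1c,
T1d and basal T1 respectively; samples 4/24/26/32 carry both the T1b
and T1c markers plus the 14523 A>T transversion; sample 28 is the one
T1b member outside T1b1; everyone else carries the generic T1b1 path.
Sample ids are 1–34 plus 40, matching the ids quoted in the source
descriptions (which number 35 animals while citing a 34-accession
range; the package never assumes a count when loading data). Private
transitions at fixed positions in the 15900–16300 control-region window
make condensation non-trivial — their placement is invented, since the
per-sample descriptions do not enumerate private variants, and is
labelled as such. The T1d defining site is taken from the config
placeholder.

### The founder-chain simulator

A haploid Wright–Fisher model (mtDNA is maternally inherited,
effectively haploid; non-overlapping generations) over a chain of
populations. The chain head is seeded at the stated subhaplogroup
frequencies (defaults follow the published North African column: T1a
26.9%, T1b 26.9%, T1c 38.5%, T1d 3.8%, T1f 3.9%), each founder
additionally carrying Poisson(10) private substitutions so the source
population holds realistic standing variation (head π ≈ 1e-3,
pairwise differences of order 20 — the same order as real complete
mitogenomes). Each subsequent population is founded by 10 individuals
drawn without replacement, held at that size for one generation, then
expanded to the effective size. Mutations arrive as a Poisson process
(default 1e-7 per site per generation) and are transition-biased with
Ts:Tv odds of 20:1 (mammalian-mtDNA-like; all but one of the classical
diagnostics are transitions). A mutation back to the reference base
removes the variant, so reversions arise naturally.

Default sizes: three populations, effective size 1,000 each, 100
generations between steps, final samples of 26/170/35 echoing the
comparative datasets. The bottleneck is deliberately held for a single
generation: pilot runs showed that holding 10 founders for several
generations routinely fixes the population, flattening the very
gradient the simulator exists to produce, whereas the single-generation
bottleneck (loss ≈ 10% expected heterozygosity per founder event, plus
the drift differential accumulated downstream) yields a strictly
decreasing π along the chain in ~84% of seeds. The residual variance is
the coalescent variance of a single non-recombining locus and no
parameter choice removes it, which is why the gradient test asserts a
≥ 70% majority over 50 fixed seeds rather than certainty. The
simulator's `effective_sizes`, `bottleneck_generations` and
`founder_private_mutations` are explicit parameters because a
Wright–Fisher chain is undefined without a population size and a
bottleneck cannot erode diversity a source population does not have.

What the simulator does *not* emulate: selection, recombination (absent
in mtDNA anyway), heteroplasmy, sequencing error, and indel mutation
during evolution (the fixture, not the simulator, exercises indel
handling). Passing gradient tests therefore show the statistics behave
correctly under the stated demographic model, not that the historical
inference about real herds is correct.

## Problem sizes in the test suite

Tests run the full pipeline at reduced scale so the suite stays fast:
alignment round-trips use a 2,000 bp synthetic genome (alignment cost is
quadratic in length; the variant logic is length-independent),
permutation-calibration simulations use 2,000 bp genomes with 16-sample
pools and 200 permutations each, and the 50-seed gradient check runs
the simulator at its full defaults. The acceptance script's headline
quantity is computed on the complete 35-sample fixture at full genome
length.
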