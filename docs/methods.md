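# Methods

This note documents the models, defaults, numerical choices and
limitations behind `polyphase`. Everything quantitative stated here is
computed by the test suite or the analysis drivers; nothing is asserted
that the code does not reproduce.

## The synthetic polyploid generator

The generator emulates the statistical structure of a three-lineage
allopolyploid grass genome so that every downstream stage can be validated
against ground truth at desk scale.

**Substitution model.** Sites mutate independently; a mutated site takes
one of the three alternative bases uniformly. Under this kernel the
probability that a site differs after a branch with per-site substitution
probability b satisfies q = 1 − (4/3)p with q multiplicative along a path
(the discrete analogue of Jukes–Cantor). Requested pairwise divergences
d(X,Y) are therefore realized *exactly in expectation* by solving
ln q_X + ln q_Y = ln(1 − 4·d(X,Y)/3) for per-lineage branch probabilities
on a star tree (least squares; infeasible maps — an implied negative
branch — are rejected, as is any divergence ≥ 0.75, the saturation point).
Indels are off by default (`indel_rate=0`); a simple 1–3 bp indel process
is available at the ancestral stage only.

**Default divergences.** A–B 3%, A–C = B–C 12%, haplotype copies within an
ancestry 0.5% pairwise (each copy mutated at b = 0.25% from its ancestral
chromosome). The intra-ancestry haplotype divergence is a free parameter
with no published value; 0.5% was chosen once as typical of heterozygous
outcrossing grasses and is not revisited. Base chromosome number x = 6,
default base length 100 kb (desk-scale stand-in for chromosomes three
orders of magnitude larger); the default composition is the aneuploid
octoploid 2A/4B/2C on base chromosomes 1–4 and 3A/3B/2C on 5–6
(14A + 22B + 12C = 48).

**Repeat families.** An LTR retrotransposon copy descends from a
per-family master element; at insertion its two LTRs are identical, after
which internal region and both LTRs mutate independently at
μ·T (μ default 1.3×10⁻⁸ subs/site/year, a common grass rate; T drawn per
copy from a truncated normal in Myr). The expected LTR pair divergence of
a copy of age T is 2μT up to the quadratic multiple-hit term. The default
fixture carries one A-specific and one B-specific Gypsy-like family and a
shared A+B Copia-like family with young ages (0.8–1 Myr) plus a C-specific
family at 3 Myr — the "A and B share recent transpositional history, C is
older and independent" configuration.

Lineage-specific repeat families are not decoration: different base
chromosomes are unrelated sequences, so genome-wide repeats are the *only*
k-mer signal that ties chromosomes of the same ancestry together. A
repeat-free genome is structurally unphaseable by k-mer clustering (the
test suite demonstrates the degradation), which mirrors the real
situation, where subgenome-diagnostic k-mers are overwhelmingly
repeat-derived.

**Markers.** Single-copy markers are planted by overwriting a window
(coordinates stay put under the substitution-only model) exactly once on
every haplotype copy of the marker's home base chromosome, with
haplotype-level mutations; positions avoid repeat elements and other
markers. Truth copy number of a marker therefore equals the copy count of
its base chromosome (8 everywhere in the default fixture).

**Reads.** Paired-end FR fragments with normal insert sizes, uniform
starts, per-base substitution errors (default 0.2%), and expected pair
count per chromosome equal to length × coverage_per_copy / (2·read
length), so read dosage tracks chromosome dosage. "An accession sequenced
at 20×" means 20× sample depth: per-copy coverage 20/ploidy.

**Determinism.** Every operation takes a seed and uses an isolated
`numpy.random.Generator`; fixed seed ⇒ byte-identical output.

## Subgenome phasing

Canonical k-mers (lexicographic minimum of k-mer and reverse complement,
odd k, default 15) are counted per chromosome and normalized to
occurrences per Mb. A k-mer is *differential* for a clustering iff its
highest cluster-mean count ≥ fold_q × the second highest (default 2) and
≥ min_count (default 2 per Mb). Phasing alternates k-means over the
differential submatrix (10 seeded restarts) with recomputation of the
differential set, starting from the 10,000 highest-variance k-mers among
those present in ≥ 20% of chromosomes (the presence filter biases the
seed clustering toward genome-wide ancestry signal rather than k-mers
private to one homologous group), until the induced partition stabilizes
or `max_iter` is reached (then `converged=False` is reported with the last
labels). For clustering, ordination (2-component PCA) and the
average-linkage dendrogram on Jaccard distances of presence/absence, the
differential set is capped at the 50,000 highest-enrichment k-mers to
bound the dense submatrix; the full set is returned. Cluster letters are
assigned by first appearance over lexicographically sorted chromosome
ids, so labels are deterministic but arbitrary; all comparisons use the
induced partition.

On the default fixture (48 × 100 kb) the recovered partition matches the
true ancestries with adjusted Rand index 1.0 in a few seconds.

## Ploidy from marker multiplicity

Markers are located with an internal aligner: exact k-mer seeds (default
k = 15) on a sorted forward-strand index, clustered by (target, strand,
diagonal), then verified by edlib infix alignment of the full marker
against the local window. A locus counts when the seed cluster covers
≥ min_coverage (0.9) of the marker and the edit-distance identity is
≥ min_identity (0.9); hits overlapping ≥ 50% are merged into one locus.
The modal copy number (ties broken toward the larger value) times the base
number gives the chromosome estimate. The engine matches an exhaustive
substring oracle exactly when markers are planted error-free.

## Synteny scaffolding

Alignments (internal seed aligner, or any external PAF) are chained
greedily per (query, target, strand) in query order while query and target
gaps stay within `max_gap` (default 100 kb); chains with fewer than
`min_chain_len` aligned bases (default 10 kb) are discarded. The
one-to-one link filter drops every chain whose query occurs in more than
one chain, then every chain whose target interval overlaps another
retained chain's — an automated formalization of what is usually manual
dotplot curation; it is idempotent. Retained contigs are placed whole on
their single target, ordered by chain midpoint, oriented by chain strand
(ties between orientations resolve to "+"), and separated by 100 bp
scaffold gaps in an AGP v2.1 plan (0-based half-open in memory, 1-based
inclusive on disk). No contig may appear twice in a plan (asserted on
every build).

Against a reference containing near-identical homologous copies, the
aligner keeps only alignments scoring ≥ 0.95 × the query's best
(minimap2 `-p`-style). A contig is an exact substring of its source but
shares only ~0.995²¹ ≈ 90% of 21-mers with a homolog at 0.5% divergence,
so the filter separates source from homologs with a wide margin; this is
what makes unique-link filtering usable on a polyploid, where staged
alignment plus manual curation is the usual workaround. The full
round trip (fragment → align → chain → filter → anchor → apply AGP)
reconstructs all 48 fixture chromosomes exactly outside gap runs for
contigs ≥ 12 kb.

The fused-reference builder concatenates chromosome groups (default 100 bp
N junction) to mimic a relative whose karyotype differs by known fusions;
the liftover table maps old → new coordinates exactly and bijectively.

## Composition inference

Each read pair is assigned to the chromosome sharing the most canonical
k-mers (default k = 21) summed over both mates; pairs scoring below
`min_shared` (default 10) are unassigned. Ties for the top are broken by a
seeded deterministic pseudo-random draw by default, the behaviour of a
"top best" competitive aligner. This is deliberate: ties occur whenever a
read's window is identical to *any* homolog, so discarding tied pairs
removes proportionally more reads from higher-dosage subgenomes (4 B
copies per base chromosome tie more often than 2 A copies) and would bias
the observed shares away from chromosome dosage — the very signal being
measured. The strict variant (`tie_policy="unassigned"`) is available for
ambiguity filtering where dosage is not the target.

Observed per-subgenome percentages (half-up rounding, matching printed
tables) are fitted with nonnegative integers summing to N by
largest-remainder apportionment, then verified L2-optimal by ±1 local
search between subgenome pairs; the fit equals a brute-force minimum-L2
search over all compositions and inverts the expected-proportion map for
every 3-part composition with N ≤ 48. Formulas divide counts by x when all
are divisible (AABBBB), otherwise use aneuploid notation (14A 22B 12C);
ratios divide by the smallest nonzero count with two-decimal trimming
(1A:2B).

## LTR dating and enrichment

p-distance between a copy's two LTRs (equal lengths site-by-site,
otherwise unit-cost global alignment first, gap columns excluded) is
Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3) (domain p < 0.75; a
Kimura two-parameter correction is available via `model="k2p"`), and
converted to age T = d/(2μ). μ defaults to 1.3×10⁻⁸ subs/site/year and is
overridable; absolute ages are only as good as μ, so cross-subgenome
*orderings* are the robust statistic. Family enrichment per subgenome uses
the hypergeometric tail with population = all elements and successes =
elements on the subgenome — exactly the label-permutation null, which the
tests confirm against 10,000 permutations — with Benjamini–Hochberg
adjustment at α = 0.05 across family × subgenome tests.

## What the fixtures do and do not show

The generator reproduces the features these methods rely on: calibrated
inter-ancestry divergence, haplotype polymorphism, ancestry-specific
repeat structure with age signal, dosage-proportional read sampling, and
exact ground truth. It does not model recombination, gene structure,
centromeres/telomeres, GC or mapping bias, long-read error profiles, or
RNA-seq expression effects (allelic expression ratios add noise that the
uniform-coverage fixtures cannot exhibit). Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
conditions at ~3–6 Mb scale, not performance on a multi-Gb assembly; the
problem sizes used by the tests (30–100 kb base chromosomes, 20× accession
depth, 18 markers, ~180 LTR elements) are the package's chosen desk-scale
study conditions.

## Known limitations

- The seed aligner has no gapped extension; it is adequate for
  substitution-dominated synthetic data and short markers, and external
  PAF input is the intended path for real assemblies.
- Competitive assignment scores raw shared k-mers without mapping-quality
  modelling; very repetitive references inflate scores equally across
  homologs (handled by the tie rule) but can mask low-complexity signal.
- No uncertainty is attached to composition calls beyond the L2 residual.
- Manual curation of scaffold links may use evidence beyond the
  automated one-to-one rule; the rule is a formalization, not a claim of
  equivalence.
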