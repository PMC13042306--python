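# Methods

## Overview

taxsieve assigns taxonomic labels to metagenomic contigs or reads with a
two-stage hybrid design. A fast, alignment-free screening stage ranks
reference genomes by how much of each reference is contained in the query
set; an adaptive selection step keeps a small, sample-scaled candidate set;
and an alignment-based classification stage turns per-candidate coverage
into a weighted lowest-common-ancestor (LCA) call with a rank-consensus
confidence score. A CAMI-style evaluation layer and a fully seeded
synthetic-community generator make every stage testable offline.

## Containment screening

Each reference genome is condensed to a bottom-s MinHash sketch: the s
smallest 64-bit hash values of its distinct canonical k-mers (canonical =
lexicographic minimum of a k-mer and its reverse complement, so screening
is strand-agnostic). The containment of reference A in query set B is
estimated as

    c_k(A, B) = |S(A) ∩ π(B)| / |S(A)|

where S(A) is the sketch and π(B) the *full* distinct k-mer hash set of the
pooled query sequences — the query side is never sketched, so the estimate
is unbiased for the sketched fraction. The estimator's error scales as
sqrt(1/s): s = 1,000 (the default) gives ≈ 0.032, s = 5,000 ≈ 0.014.

Hashing is a seeded 64-bit MurmurHash3-style finalizer applied to the 2-bit
packing of the canonical k-mer (A=0, C=1, G=2, T=3, so numeric order equals
lexicographic order). The seed participates in the hash, and sketches built
under different (k, seed) pairs are incomparable by construction — mixing
them raises an error. k-mers containing any non-ACGT base are skipped, not
substituted. k is limited to 31 (64-bit packing); defaults are k = 21,
s = 1,000, seed = 42.

A guideline for choosing k given a genome size n and an acceptable random
k-mer collision probability q is k = ceil(log_|Σ|(n(1−q)/q)); e.g. a 5 Mb
genome at q = 0.01 gives k = 15, a 3 Gb genome gives k = 20. The result is
rounded up so the collision bound is met, never exceeded.

Each screen hit carries a binomial upper-tail p-value: P(X ≥ shared) with
X ~ Binomial(s, r) and r = 1 − (1 − |Σ|^−k)^m for a query of m distinct
k-mers — the chance of the observed sketch overlap if query and reference
shared no true sequence. It is monotone non-increasing in the shared count
and computed stably with log1p/expm1 for large m.

## Adaptive candidate selection

Screening thresholds are walked down from 0.90 containment in 0.02 steps
(an exact grid in integer hundredths, avoiding float drift) until the
number of qualifying references reaches a sample-scaled target of
round-half-up(3.25 × n_queries), never below 5, or until a hard floor of
0.70. Hits below the floor are treated as noise and never returned. When a
species map is available (derived from assembly-summary files), candidates
are deduplicated to one reference per species — highest containment wins,
ties break to the smaller accession — *before* counting, so the target caps
species-unique candidates rather than redundant assemblies. Assembly
accessions are matched through their 9-digit base (GCF_000169215.1 →
"000169215") so version bumps and RefSeq/GenBank prefix differences never
break the join.

## Weighted LCA classification

Alignments are consumed as PAF records. Per (query, reference) pair,
coverage is the size of the union of aligned query intervals divided by
query length; overlaps merge rather than sum, keeping coverage in [0, 1].
An alignment is an *exact match* only when it spans the whole query with no
mismatch or gap (n_matches = block_len = query span = query length).

If a query has an exact hit, that reference's full lineage is assigned
directly with confidence 1.0. Otherwise each supporting reference gets

    weight = coverage × abundance

with abundance the reference's share of all alignment records in the
dataset (record frequency; a distinct-query frequency variant would be a
one-line change, record frequency is the default because it is the simplest
reading of "frequency in the dataset"). Walking the rank ladder
superkingdom → phylum → class → order → family → genus → species → strain,
the weights accumulate onto each reference lineage's taxon at that rank;
the heaviest taxon that descends from the previously chosen parent wins
(preventing chimeric lineages), and its share of the total rank weight is
the consensus fraction. The descent stops at the deepest rank whose
fraction is ≥ min_support (default 0.5, compared with ≥ so an exactly split
rank still reports). Confidence is the product of the recorded fractions
over the *reported* ranks only — unreported deeper ranks do not deflate it.
Weight ties break to the smaller TaxID; all outputs are invariant to
alignment record order. Queries with no alignments are reported
unclassified, not errors.

This stopping rule is what produces back-off under incomplete references:
when a species' references are missing and its contigs align across several
congeneric references, no single species reaches min_support, the descent
halts at genus, and the classifier reports the (correct) genus rather than
a confidently wrong sister species.

## Evaluation layer

Profiles map TaxID → relative abundance per rank; per-rank sums may be
below 1 because mass from shallow classifications stays unassigned.
Metrics follow CAMI conventions: presence/absence precision, recall, F1 at
a 0.1% abundance threshold (empty predicted-positive sets report precision
0 with an explicit flag); L1 total variation Σ|p−q| without the ½ factor,
so L1 = 2 × Bray–Curtis for normalized profiles, with the scale (fraction
vs percentage points) an explicit argument; Bray–Curtis Σ|p−q|/Σ(p+q);
Pearson correlation over the zero-filled taxon union; and contig-level
accuracy as the fraction of truth contigs whose prediction, projected to a
rank, equals the truth at that rank (unclassified counts as incorrect).
"Kingdom" is treated as an alias of superkingdom throughout. The pairwise
metric functions accept either Profile objects or bare taxon → abundance
mappings, so published abundance tables can be scored directly.

## Synthetic data

The generator emulates the structure of a benchmark dataset without any
download: a rank-complete taxonomy over up to three domains (genera dealt
round-robin across superkingdoms, paired into families under
per-domain phylum/class/order chains), one random genome per species
(default 25–35 kb — scaled-down stand-ins for real genomes that keep the
whole pipeline in seconds), contigs that tile each genome completely
(default 2–5 kb), a count-basis truth profile consistent with those
contigs, and a contig → TaxID truth map. The default community shape
includes one four-species genus because sister-species confusion is the
dominant failure mode the classifier must handle. Reads are deterministic
250 bp windows over contigs with a final partial window kept iff ≥ 125 bp.

Divergence is modelled per base: each position independently suffers an
event with probability `rate`; an event is a substitution (probability
`sub_fraction`, default 0.9) to a uniformly chosen different base, else an
insertion or deletion (equally likely) with geometric length of mean 3
("short indels"). `rate` counts events per base *before* indel expansion,
so sweeps at different rates are comparable.

Because genomes are i.i.d. random strings, congeneric species share no
sequence; relatedness is emulated at the alignment layer instead. The
synthetic PAF generator supports: `perfect` (one full-length exact record
per contig to its source reference), `partial` (random 50–90% coverage at
sub-unit identity, so the exact path never fires), an optional `bleed_prob`
that adds off-target records to genus mates, and — always — contigs whose
source reference is absent bleed to *every* remaining same-genus reference
with coverage drawn U(0.4, 0.6) at 92% identity, emulating an aligner
falling back to near relatives. The U(0.4, 0.6) range is chosen so that
with three or more retained genus mates of similar abundance no single
wrong species can reach a 0.5 consensus fraction, which is the database
regime (several congeneric references present) in which real back-off is
observed. Ablation experiments therefore use a balanced community (equal
genome lengths, equal contig counts per genome) so reference abundances do
not tip that balance.

What the generator does **not** emulate: sequencing error profiles and
quality scores, real inter-genome homology and conserved regions, repeat
structure, GC bias, chimeric contigs, and assembly artifacts. Passing
tests therefore demonstrate the correctness of the screening, selection,
classification, and scoring machinery under controlled conditions — not
field accuracy on real metagenomes, which depends on reference databases
and aligner behaviour outside this package.

## Experiment protocols

* **Parameter recovery** — default 10-taxon community, complete
  references, perfect alignments: every contig should recover its true
  species TaxID at confidence 1.0 and the species-rank profile should match
  truth (Bray–Curtis < 0.02; the tiny slack absorbs the k-mers lost at
  contig boundaries during screening).
* **Mutation sweep** — rates {0, 10, 20, 30}% with fixed per-contig seeds.
  Species-rank presence F1 must be non-increasing in rate. Under uniform
  per-base divergence the screening floor dominates: at 10% divergence the
  expected containment of a k = 15 sketch is 0.9^15 ≈ 0.21, far below the
  0.70 floor, so the candidate set empties and F1 drops to 0 beyond the
  clean point. This is the honest behaviour of a containment floor under
  uniformly diverged queries; real communities, where divergence
  concentrates in parts of the genome, degrade more gradually.
* **Reference ablation** — remove floor(level × n) of a species'
  reference sequences (level ∈ {0, 0.25, 0.5, 0.75, 1.0}), re-sketch,
  re-select, re-classify with unchanged parameters. At full ablation the
  affected contigs must land at genus or coarser (or unclassified), never
  on a wrong species with confidence 1.0.
* **Reads vs contigs** — the same community classified from contigs and
  from 250 bp windowed reads must agree at genus rank for ≥ 95% of reads on
  clean input.

Problem sizes (10 genomes × ~30 kb, ~80–100 contigs) are the package's
test-scale defaults; every generator parameter is exposed, so larger
studies are a matter of arguments, not code.

## Numerical and interface choices

* Threshold and min_support comparisons carry a 1e-9 / 1e-12 slack so
  grid-exact cases (containment 0.79 vs threshold 0.79, fraction 0.5 vs
  min_support 0.5) behave as the ≥ rules intend.
* The sketch store is a documented JSON container (params + ref_id +
  sorted hashes); it is deliberately not compatible with any external
  binary sketch format.
* PAF is the alignment interchange; a minimap2 invocation hook
  (presets asm10 for contigs, sr for reads) is provided as configuration
  but the tested surface consumes PAF files.
* No mapping-quality filter is applied by default; all alignments of a
  query contribute weight (multi-mapping is resolved by the consensus
  itself, not by best-hit filtering).
* All randomness flows through explicit integer seeds; there is no global
  random state anywhere in the package.

## Known limitations

Species-level resolution inside four-species genera relies on the
min_support back-off rather than sequence-level discrimination, mirroring
the sister-species ambiguity of real classifiers. The binomial screening
p-value treats k-mers as independent draws, which overstates significance
for repetitive queries. The per-base mutation model has no
transition/transversion bias. Strain-level calls require strain nodes in
the taxonomy; the generator emits none by default.
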