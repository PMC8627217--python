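# Methods

`icemob` analyses the conjugative mobilome of rhizobial genomes: it finds
the machinery that moves DNA between cells (relaxases, type IV secretion
systems, coupling proteins), delineates the chromosomal elements that carry
it (ICEs and IMEs) from the short direct repeats their integrases create,
classifies every element and plasmid, partitions element gene content into
a conserved backbone and variable cargo, and quantifies sequence exchange
between elements without alignment. This note records the model behind each
step, the tunable parameters and their defaults, what the synthetic-data
generator does and does not emulate, and the numerical choices a maintainer
would want to know.

## The integration model and att-based delineation

Site-specific integrases recombine a short identical "core" sequence shared
by the attachment sites attP (on the circular element) and attB (on the
chromosome, usually overlapping the 3' end of a tRNA gene or of guaA, radC
or dusA). Integration duplicates the core: the integrated element is
flanked by attL and attR carrying identical copies. Delineation inverts
this: around each anchor's strand-aware 3' end the two candidate cores (the
window ending at the 3' end and the window starting at it) are searched for
a second exact occurrence within ±`max_span`, the match is extended
maximally in both directions, and a pair is retained only when the enclosed
interval contains at least one mobility-gene seed (relaxase, conjugation
cluster or integrase locus). When several pairs satisfy the constraints for
one anchor the longest core wins, then the most enclosed seeds, then the
shortest span.

Parameters: `min_core` 15 bp (exact match; a 1-mismatch budget exists but
is off by default), `max_span` 900 kb — chosen to exceed the largest
monopartite element fragment reported for this genus (~767 kb) with margin.

Conventions, fixed by the splice oracle in the test-suite rather than
assumed: an element fragment runs from attL start to attR end with both
cores included; the excised circle spans attL start to attR start, so it
carries exactly one core copy (its attP) and circle length = fragment
length − core length. Excision leaves a single core (the restored attB) per
former pair. Re-integration of the circle at that attB reproduces the
original replicon byte-for-byte; this conservation is asserted on hundreds
of randomized cases.

### Tripartite elements

Some symbiosis ICEs exist as three separated chromosomal regions (α, β, γ)
that recombine through three att pairs into one circular transfer form.
Each fragment then carries cores of two *different* pairs at its ends, and
the pairs interleave on the chromosome. The resolver takes all pairs whose
spans mutually interleave (exactly one endpoint of one inside the span of
the other), sorts the six core occurrences, keeps the inter-core intervals
that contain mobility seeds as fragments, labels each fragment with its
flanking pair identities, and chains fragments into a cycle (the right
family of one fragment must equal the left family of the next). A single
three-cycle yields the circle: fragments concatenated in join order with
each shared core collapsed to one copy, so circle length = Σ fragment
lengths − 3 × core length. Roles α/β/γ are assigned by decreasing size.
Anything that is not a single three-cycle — including the two-pair pattern
left when one att pair is undetectable — is rejected as unresolvable;
known elements are monopartite or tripartite, so two-fragment resolutions
are treated as evidence of a missed pair, not as a new element class.

Published fragment sizes for the largest tripartite element sum to 8 bp
more than the stated total, implying an unstated core-accounting
convention; our convention is the one the splice oracle verifies, and we
make no attempt to reproduce that 8-bp discrepancy.

## Homology engine

All similarity calls go through one panel-search primitive: best local
alignment (BLOSUM62, gap open −11 / extend −1 for proteins; +1/−1 with gap
−2 for nucleotide) with identity defined as identities divided by aligned
columns, gaps included — the definition that matches common BLAST usage.
Defaults for protein role calls: identity ≥ 30%, query coverage ≥ 0.6
(configurable); the published nucleotide rule for trbB/traA searches (50%
pairwise identity) is applied over the aligned region with coverage ≥ 0.5.
A shared-k-mer prefilter (k = 4 amino acids, one shared word) skips
hopeless pairs in large inputs; inputs under 80 sequences are aligned
all-vs-all, so the permissive 25% clustering preset is exact where it is
exercised.

Relaxase (MOB) family typing follows the published decision rule: hits at
bit score ≥ 33 qualify; amongst competing families the best full-sequence
e-value wins, then score, then exemplar id. Input can be panel hits or an
hmmscan-style tabular file produced externally — the package does not
re-implement profile-HMM scoring. Conjugation clusters group colocated
role hits (gap ≤ 10 kb, configurable; the source analyses never state a
colocation distance): ≥ 6 of the 9 trb roles → trb-type T4SS, ≥ 6 vir roles
→ vir-type, traA + traC divergently oriented → Ti-plasmid-like traACD locus
(traD optional, an adjacent RDF gene is noted), a lone coupling protein →
T4CP_only.

The bundled reference panel is synthetic: exemplar proteins are generated
deterministically from a fixed seed and back-translated, so the repository
ships no third-party sequence data, and the panel file format
(`exemplar_id|role_label` FASTA) accepts real exemplar sets unchanged. Two
roles alias the same sequence deliberately: the ICE backbone relaxase rlxS
is a MOB_P1-family protein, and the Ti-type TraA is itself the MOB_F
relaxase — one locus legitimately answers both questions.

## Element classification

Ordered rules, applied to the per-element evidence bundle: integrated +
att + integrase + relaxase + T4SS → ICE; the same without a T4SS (traACD
or a lone MOB gene) → IME; plasmid replicon + relaxase + T4SS →
conjugative plasmid; plasmid + relaxase and/or T4CP without T4SS →
mobilizable plasmid; otherwise unclassified. Chromosomal regions with
mobility genes, repABC replication genes and *no* att pair are flagged as
likely assembly-joined plasmid sequence and excluded from ICE/IME counts;
att evidence always wins over repABC. Four att-less ICEs in the source
dataset motivate keeping att-less candidates as elements when repABC is
absent.

The symbiosis flag (ICESym) requires complete nodABC and nodIJ plus at
least one nif and one fix gene. The published inventory states the outcome
of this judgement, not the criterion; the rule is configurable.

QS-locus profiling re-scans the nucleotide neighbourhood of quorum-sensing
protein hits against each QS exemplar, which also recovers unannotated
remnants. Matches need ≥ 72% nucleotide identity over ≥ 60 bp — random
sequence supports short local matches up to the mid-60s, genuine diverged
copies sit near 90%. Status per copy: exemplar coverage < 40% → remnant;
net frameshifting indel (coordinate-range difference not divisible by 3) →
pseudogene/frameshift; internal stop in the exemplar frame →
pseudogene/premature stop; coverage < 80% → pseudogene/truncation;
otherwise intact. The length thresholds are package choices — the source
narrative describes the calls, not the cutoffs.

Redundancy: elements sharing identical cluster content after removing IS
(transposase) clusters collapse into one group represented by the longest
member; SNP-level divergence is invisible at cluster level by design.

Regulatory motifs (nod boxes) use a position-weight matrix built from
aligned equal-length training sequences with +0.5 pseudocounts; the scan
threshold defaults to the minimum training-sequence self-score, so every
training instance is recovered by construction.

## Pangenome, backbone and mobilome accounting

One clustering engine with two presets replaces the two external tools
commonly used for this task: greedy single linkage over reciprocal-best
local-alignment hits between units, with any passing within-unit hit as a
paralog edge (paralogs are not split), at 40% identity (backbone work) or
25% (accessory counting), coverage ≥ 0.5. Clustering is deterministic and
input-order invariant. Backbone clusters are those present in ≥ 95% of
non-redundant trb-carrying elements — the threshold absorbs sporadic
deletions — with the single-copy subset flagged for concatenated-alignment
export. Core-size sweeps re-threshold one cached alignment table. A caveat
the property tests encode: at very permissive thresholds (~20%) spurious
local-alignment links can merge distinct families, so the core count is
monotone in the threshold only above that zone.

Mobilome accounting assigns each cluster mobile/non-mobile by an
any-member rule and reports the mobile fraction of the pangenome and its
split across ICEs (with the ICESym share within ICEs), IMEs, plasmids and
phages. Gene-content trees are neighbor-joining on presence/absence
Hamming distances (exact on additive matrices; verified for 4 and 5 taxa).
Trait association is a plain two-sided Fisher exact test with Bonferroni
correction — deliberately *not* a population-structure-aware method — with
support for excluding units (e.g. a duplicated element) from the cohort.

ANI is fragment-based: 1020-bp query fragments are placed in the subject
by sampled 16-mer seeding, scored by edit distance on the candidate
window, kept when ≥ 80% identical and reciprocally consistent, and
averaged. When fewer than 5% of fragments align the genomes share no
meaningful backbone — perhaps only a transferred island — and ANI is
reported as undefined rather than as that island's identity. Genomes join
one genospecies under single linkage at ANI ≥ 95.0
(the boundary value joins). On simulated pairs ANI tracks 100 − divergence
to well within a point.

## Alignment-free recombination detection

For each ordered element pair the per-position match-length profile —
the longest exact substring starting at each query position that occurs
anywhere in the subject or its reverse complement — is computed by
streaming the reversed query through a suffix automaton of the reversed
subject plus its complement strand (linear time; equal to the brute-force
scan on thousands of random cases). Non-overlapping 1000-bp windows whose
mean match length is improbable under an i.i.d. subject null at α = 0.05
merge into homologous segments.

The analytic null treats per-position lengths as draws from the tail law
P(X ≥ L) ≈ min(1, 2m·q^L) (q = Σ base-frequency², both strands of an
m-bp subject) and tests window means by normal approximation with an
effective sample size of window/(1 + mean), because one long match covers
correlated positions. This deliberately conservative choice keeps the
realized false-positive window rate at or below α (measured ≈ 0 on
i.i.d. sequences); a seeded permutation null (shuffled subject) is
available as a cross-check. Directed edges weighted by additive segment
length form the flux network; masking backbone-gene intervals reproduces
the published contrast in which most inter-element connectivity collapses
to genuine cargo exchange once conserved-backbone homology is excluded.
Note that elements sharing recognisably similar (~80% identity) backbones
do produce segments — that is the behaviour the mask exists to subtract,
not a false positive. Chimaeric loci are painted by windowed best-donor
identity (1000-bp windows, 500-bp step) with lexicographic, flagged
tie-breaks.

## The synthetic-data generator

The generator builds genomes in which every downstream claim has planted
truth: i.i.d. background at configurable GC (default 0.62, typical for
these soil bacteria), shared chromosomal core families (default 30 at 5%
nucleotide divergence) plus per-genome accessory genes, tRNA and
protein-gene anchors, elements integrated by literally duplicating the
attB core into attL/attR (so boundary truth is exact by construction),
cargo genes as exemplar copies mutated to a target nucleotide divergence
(substitutions uniform over sites, in-frame stops avoided, start/stop
codons preserved; realized divergence is recorded), pseudogenization as
1-bp frameshifts, planted internal stops, 60% truncations or 100-bp 3'
remnants, IS copies, repABC-no-att artifact regions, plasmid replicons,
and inter-element transplants into dedicated cargo "pad" regions with an
exact event registry. Bases flanking planted cores are patched so the
maximal repeat equals the planted core; otherwise chance 1-bp extensions
would rotate the recovered circle and make bp-exact boundary comparison
ill-posed. Everything derives from one seed; identical seeds give
byte-identical output.

The default benchmark is five ~2-Mb single-chromosome genomes carrying 4
monopartite ICEs (2 of them ICESyms), 1 tripartite ICESym with fragments
interleaved as α–γ–β on the chromosome, 2 traACD IMEs, 1 conjugative and
1 mobilizable plasmid, 1 artifact region, QS duplications with one
frameshift pseudogene and a traR1 remnant, and 2 recombination events
(5 kb and 4 kb). Element sizes are tens of kilobases — deliberately
smaller than the 65–854 kb range reported for real elements — so the
full pipeline and its tests run in minutes on one CPU; nothing in the
method depends on absolute element size except `max_span`, which is kept
at its real-data default.

What the generator does not emulate — and hence what green tests do not
certify about real data: phylogenetically correlated divergence (mutations
are i.i.d.; real backbone divergence is tree-structured), codon bias and
selection, IS-mediated rearrangement, tandem element arrays at one anchor,
degraded or partial att sites (cores are exact copies), assembly errors
other than the joined-plasmid artifact, and real profile-HMM score
distributions (the panel is synthetic). Results on real genomes therefore
depend on annotation quality and on supplying real exemplar panels/HMM
tables; the decision logic, coordinate arithmetic, and statistics are what
the synthetic truth certifies.

## Numerical and degenerate-input choices

Ties everywhere break deterministically (score, then lexicographic id).
Empty protein sets, anchor-less genomes and element-less networks return
empty results rather than erroring; degenerate traits (one class) and
training sets of unequal length are errors. Coverage is measured on the
query for panel calls and as the pairwise minimum for clustering.
Per-element evidence uses only features fully contained in element
fragments. The evaluation module counts a boundary as recovered only at
bp-exact attL/attR agreement. Problem sizes used by the shipped analyses:
the five-genome benchmark above; 20 mini-genomes for the backbone
prevalence check; 80-kb pairs for ANI recovery; 100–10,000-bp pairs for
profile oracles; 200 × 3 windows for null calibration.
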