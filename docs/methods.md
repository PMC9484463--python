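# Methods

## Model

A regulation is a directed miRNA → transcript relation.  Its state in one
genome is decided by two independent complementarity scorers; requiring
both to agree before calling a regulation present (the "intersection"
rule) suppresses single-scorer artifacts.  Per ecotype, the four detection
booleans (scorer A/B × reference/ecotype genome) collapse to one fate
symbol via the set identities

    Lost   = (T_ref ∩ P_ref) − (T_eco ∪ P_eco)
    Gained = (T_eco ∩ P_eco) − (T_ref ∪ P_ref)
    Kept   = (T_ref ∩ P_ref) ∩ (T_eco ∩ P_eco)

with T and P the pair sets of the two scorers.  The full decision table
(`classify_pair_in_ecotype`) is:

| ref A | ref B | eco A | eco B | fate |
|-------|-------|-------|-------|------|
| ✓ | ✓ | ✓ | ✓ | k |
| ✓ | ✓ | one of the two | | o |
| ✓ | ✓ | ✗ | ✗ | l |
| ✗ | ✗ | ✓ | ✓ | g |
| ✗ | ✗ | one of the two | | o |
| ✗ | ✗ | ✗ | ✗ | n |
| one of the two | | any detection | | o |
| one of the two | | ✗ | ✗ | n |

The symbols `o` (single-scorer ambiguity in the decisive genome) and `n`
(absent) make the score's denominator well-defined for regulations that
exist only in part of the panel; without an explicit absence symbol, a
gained regulation would have no state in the ecotypes where it is not
predicted.  When the reference call itself is ambiguous (one scorer), no
settled fate exists: any ecotype evidence yields `o`, none yields `n`.
Such regulations never anchor a fate profile (profiles exist only for
reference-intersection or gained regulations).

General fate: a reference regulation is `K` when never lost, `KL` when
both kept and lost occur, `L` when lost wherever a settled call exists;
a non-reference regulation gained somewhere is `G`.  Ambiguous `o`
symbols are tolerated inside `K` — ambiguity is not evidence of loss.

## Duplex scoring

Both scorers are position-weighted penalty schemes over gapless
antiparallel duplexes: Watson–Crick 0, G:U wobble 0.5, mismatch 1.0,
with a 5′ core multiplier (scheme A: core 2–13 ×2.0, cutoff 4.0 — the
classic plant-miRNA weighting; scheme B: core 2–17 ×1.5, cutoff 2.5 — a
stricter, longer-core variant).  Ties at the cutoff are accepted.  Gapless
windows keep the scorer exactly equivalent to brute-force window
enumeration, which the tests exploit; bulged sites and free-energy terms
are out of scope.  Users with genuine external predictions can load them
through the pair-table adapter (`parse_external_pairs`) — downstream logic
consumes only pair-level existence.

## The coreg score

For two regulations toward the same target, over the ecotypes where all
three sequences are available (no indel),

    coreg = (|EcoK| + |EcoL| + |EcoG| + |EcoN|) / |Eco|

counting ecotypes where both fates are k, l, g, or n.  Joint (o,o) never
counts — coincident ambiguity is not a fate match.  Guards: `KL/KL`
requires a co-occurring loss (EcoL ≠ ∅), else 0; `G/G` requires a
co-occurring gain (EcoG ≠ ∅), else 0.  Counting joint absence is what
makes a pair of regulations gained together in a small cluster (say 22 of
1,131 ecotypes) score 1.0 rather than 22/1131 ≈ 0.02; the EcoG guard
simultaneously rejects pairs gained in disjoint ecotype sets.  Because
this reading is not forced by the score's bare definition, the "literal"
mode (no EcoN term, no G/G guard) is selectable (`coreg_mode`); "extended"
is the default.  Mixed general-fate motifs (K/G, KL/G) can never exhibit
per-ecotype fate equality and are excluded from typing.

Motif types: ss = K/K, sd = K/KL, dd = KL/KL or G/G.  Edge (crosstalk)
type: the motif type of a strict majority of the edge's surviving motifs,
capitalized; otherwise unclassified.  The motif filter removes scores
strictly below the threshold (default 0.85, chosen in practice via the
threshold sweep, not auto-detected); a score exactly at the threshold
survives.

## Randomization statistics

Enrichment cells compare an observed edge count with its distribution
over randomized networks: Z = (X_obs − mean)/SD, sample SD (ddof = 1,
matching R's `sd`), two-sided normal p (both over- and
under-representation are reported; one-sided available by flag), BH
adjustment jointly across all cells of one matrix.  Degenerate cells
(SD = 0) report z = NaN and p = 1 rather than an infinite Z —
conservative.  Three nulls: label (fate) shuffling over fixed topology,
node-identity permutation (preserves degree sequence and label multiset),
and per-stratum uniform edge sampling.  The number of replicates defaults
to 1,000 and is configurable.

The climate test measures whether an ecotype group experiences similar
climate: the group SD of a bioclimatic variable is compared with uniform
same-size ecotype samples; p is the fraction of permutations with a
*strictly smaller* SD, so p = 0 is a legal outcome (no pseudocount).  The
stress test reports the fraction of edges whose endpoints share ≥ 1
annotated stress type against uniform same-size pair samples from the
all-pairs universe; the universe defaults to the network's nodes since
the alternative (all annotated miRNAs) is not dictated by the method —
callers can pass their own.

Expression preprocessing averages replicates per sample, log2-transforms,
treats zero abundance as missing (presence/absence semantics), and drops
miRNAs quantified in fewer than 6 samples.  Pairwise Pearson correlations
use the samples where both profiles are present (≥ 3 required).

Topology: unnormalized shortest-path betweenness with fractional counting
over equally short paths (the standard convention, made explicit because
GUI tools vary).  Hubs/bottlenecks/bridges are the descending top
ceil(0.15·N) of degree / node betweenness / edge betweenness, extended
through value ties so that equal values receive equal status.

## Synthetic panels

The generator's defaults are the package's study conditions: 100
ecotypes, 30 miRNAs (21 nt), 60 transcripts (240 nt), 10 planted
cooperative pairs (mixed SS/SD/DD, fate agreement 1.0) and 10 discordant
pairs (agreement 0.3), two shared targets per pair, dynamic clusters of
10 ecotypes, 30 singleton SNPs and 5 indels confined to decoy transcripts
so the planted truth stays exact.  Expression tables use 30 samples × 2
replicates with pair correlation 0.9 for cooperative pairs; climate
tables draw cluster members at SD 0.1 against a background SD of 10.

A single SNP cannot destroy a perfect duplex under scheme A (max per-SNP
penalty 2.0 < cutoff 4.0), so planted sites sit just under both cutoffs:
loss sites carry wobbles at miRNA positions 3, 8 and 15 (A = 2.5,
B = 2.25) and one core SNP at position 10 pushes them to 4.5/3.75; gain
sites carry wobbles at 5 and 15 plus a 3′ mismatch (A = 2.5, B = 2.5)
and the reference holds an additional core mismatch (4.5/4.0) that the
cluster SNP reverts.  All sums are exact binary fractions, so cutoff
comparisons are float-safe.

Two named fixtures reproduce canonical worked examples: a single miRNA
pair sharing 18 targets (2 static–static, 16 co-lost dynamic–dynamic
motifs ⇒ crosstalk type DD at fractions 11 %/89 %), and a 7-member
homologous family whose shared binding site gains one target in the same
22-ecotype cluster through a single 3′UTR-style SNP.

What the generator does *not* emulate: linkage disequilibrium and
demographic structure among ecotypes, realistic site/flank base
composition, bulged duplexes, expression heteroskedasticity, and spatial
autocorrelation of climate beyond block clusters.  Passing tests
demonstrate the machinery recovers the structure it assumes — not that
real panels satisfy those assumptions.

## Numerical and design choices

* Coordinates are 1-based inclusive within each sequence; chromosome →
  transcript liftover is the caller's responsibility.
* Heterozygous genotypes count as carriers (selfing species; presence of
  the alternate allele is the signal).  Multi-allelic VCF rows are split
  into biallelic records before the singleton filter; singletons
  (exactly one carrier) are removed by default.
* Any carried indel discards that (sequence, ecotype) pair — indels in
  mature miRNAs or coding sequence are treated as inactivating.
* miRNAs live in RNA alphabet, transcripts in DNA; the comparison layer
  maps U↔T, and VCF alleles are accepted in DNA letters.
* Per-ecotype scans are memoized on sequence content, so an ecotype run
  re-scans only mutant-type sequences.
* Statistical problem sizes in the test suite (200 simulated matrices at
  400 replicates, 200 climate fixtures, 1,000 random profile pairs) were
  chosen to bound Monte-Carlo noise well below the tested tolerances
  while keeping the suite fast.

## Known limitations

* The two built-in schemes are not re-implementations of any external
  predictor; only the intersection semantics carry over.  Absolute site
  counts will differ from published genome-scale figures.
* The `o`-fate convention for scorer disagreement in the reference genome
  is one defensible reading; alternatives (treating any disagreement as
  missing) would shrink fate universes slightly.
* Normal-tail p-values on permutation counts inherit the usual
  discreteness error of normal-approximation Z-tests; calibration is
  verified at the
  5 % level in the suite, but extreme tails should not be over-read.
* The pipeline holds the panel in memory; it is sized for hundreds of
  ecotypes × thousands of sequences, not for whole-genome scans.
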