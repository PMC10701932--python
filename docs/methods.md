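# Methods

This note documents the models, conventions and design choices behind
`cystra`, in the order the pipeline uses them.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion from GFF3
and tRNAscan-SE 2.0 tabular output (both 1-based inclusive, the latter
with begin > end encoding the minus strand) happens only in
`cystra.io`. Minus-strand gene sequences are reported 5'→3' in
transcription orientation. Genes whose sequence contains N are flagged
and excluded from identity statistics. The tRNAscan-SE note vocabulary
for pseudogenes varies across versions, so the note-to-category map is
a parser argument (default: any note containing "pseudo"); a companion
set of high-confidence gene ids (as produced by a EukHighConfidenceFilter
run) overrides note-based confidence when supplied.

## Alignment and the identity statistic

Every comparison runs through one global aligner with affine gap
penalties: match +5, mismatch −4, gap open 10, gap extend 0.5, end
gaps free — the defaults of the classic `needle` implementation of
Needleman–Wunsch. A gap of length k costs `open + k·extend`. Percent
identity is `100 · identities / columns` with gap columns in the
denominator, i.e. the "Identity" figure needle prints; values quoted as
ranges are rounded to integers. The scorer is Biopython's
`PairwiseAligner` (C implementation) behind the package's own scoring
and statistic definitions; the test suite pins it against an exhaustive
alignment enumerator and an independently written plain DP on small
inputs. One consequence of free end gaps worth noting: for two
sequences with nothing in common the optimum is the fully staggered
alignment (score 0, zero identities), not the mismatch-saturated
gapless one.

Read assignment uses the same substitution/gap costs in local
(Smith–Waterman) mode. At tRNA scale exact local DP is affordable and
deterministic, so no seeded heuristic is used.

## Cluster detection

Clusters are maximal runs of tRNA genes on one sequence with adjacent
gaps ≤ `max_gap` (default 1 kbp, the conventional cutoff for "regions
containing only tRNA genes"). Strand is ignored for membership;
`same_isotype` optionally breaks runs at isotype changes. Pseudogenes
are excluded from membership but attached as flanking features within
`max_gap` of an edge, because the conserved upstream pseudogene is part
of the biology being tracked, not of the cluster proper. Overlapping
genes yield negative spacers and a flag rather than an error — real
annotations contain such cases (e.g. a cluster overlapping an intron in
antisense).

Orientation for two-gene clusters: by ascending coordinate, strands
(−,+) mean the transcription starts face each other (head-to-head),
(+,−) is tail-to-tail, uniform strands are head-to-tail, anything else
is mixed.

## Unit decomposition

Units are anchored at gene starts (unit i = `[start_i, start_{i+1})`),
not at spacer midpoints: the anchor is observable in every accession
and makes unit i's spacer the one downstream of gene i. The last unit
extends by the rounded median of the earlier unit lengths, clipped to
the region end (and flagged when clipped). A region whose genes sit
mostly on the minus strand is reverse-complemented first; an even
strand split requires an explicit orientation.

## Grouping and structural events

Corresponding units across accessions are grouped by neighbor joining
(Saitou–Nei: join the pair minimizing Q, standard two-point branch
lengths, negative lengths clamped to zero, ties broken on the smallest
node pair in creation order) on p-distances `d = 1 − identity/100`.
Branches longer than 0.03 are cut and connected leaves form groups,
tying grouping to the 97%-identity convention. The distance function is
a parameter: the package default is the alignment-derived p-distance
rather than a model-based distance (e.g. composite-likelihood), since
at these divergences the two are nearly affine and the grouping cut is
what matters. Flank inclusion is likewise a flag (off for units).

Structural events are called from the global alignment of whole
cluster regions against the reference accession (default: the most
units, ties lexicographic — the longest cluster defines the full unit
complement). Internal gap runs ≥ 50 bp are events; a run within 20% of
k × (median unit length) is a whole-unit gain/loss of k units (its
position snapped to the nearest unit boundary before deciding which
units are affected, since similarity between adjacent units lets an
optimal alignment slide a whole-unit gap off the true junction), and a
smaller run is a partial deletion of exactly the gap length. Calling
events on regions rather than on matched unit pairs is what makes a
deletion that removes a gene (so that decomposition sees one unit
fewer) still come out at its true size.

## Variant analysis

Exact deduplication first; then greedy centroid clustering in the
fixed order (length descending, sequence, id), each sequence joining
the best centroid at ≥ threshold fractional identity
(matches/columns), else seeding a new centroid. With threshold 1.0
this reproduces the deduplication partition exactly. Stem assessment
aligns the variant to a reference tRNA and transfers the reference's
cloverleaf pairing map (7 acceptor, 4 D, 5 anticodon, 5 T-stem pairs)
through the alignment; a transferred pair is a mispair unless
Watson–Crick or G·U wobble (wobble pairs are structurally tolerated in
tRNA stems), and a stem position falling in a gap sets that stem's
indel flag instead of counting.

## Expression quantification

Stage order: collapse to unique reads → TMM factors → 55–110 nt length
filter → contamination filter → assignment → library comparison. TMM
factors are computed from the collapsed unique-read matrix (scaling
belongs to the library, not to the assigned subset) and applied to
assigned counts as counts-per-million over effective library sizes.
The TMM implementation follows the canonical algorithm exactly:
reference library by upper-quartile/library-size ratio closest to the
mean, rows zero in either library dropped, M and A doubly trimmed (30%
of M tails, 5% of A tails, tie ranks averaged), factor =
2^(inverse-asymptotic-variance weighted mean M), factors rescaled to
geometric mean 1. The tests pin it to reference values computed once
with edgeR's `calcNormFactors` on five toy matrices (1e-6).

Each locus carries two references: mature (gene body + the
post-transcriptional 3'-CCA) and precursor (genomic sequence with 30 nt
leader and trailer, no CCA). The CCA/flank asymmetry is what makes
flank-bearing reads locus-specific. A read's locus score is the larger
of its two local-alignment scores; it is gene-assigned iff exactly one
locus attains the maximum, rescued at variant level when all tied loci
share one mature variant, discarded as multi-mapped otherwise, and left
unassigned below a minimum score of 60 (non-specific fragments). Read
accounting (gene-assigned + variant-only + multimapped + unassigned =
input) holds exactly and is asserted in the pipeline report.

The contamination screen is pluggable. The package ships a
sequence-set matcher (best local alignment ≥ 65% identity over ≥ 20
columns against a reference set) mirroring a permissive BLAST screen,
and a documented command adapter for running the screen externally with
word size 6 / 65% identity / no dust masking; the matcher must answer
for every read — failures abort rather than silently keep.

Library comparison flags per variant: undetected (zero in both
normalized libraries), ambiguous (zero in exactly one), charged
(deacylated > control: aminoacylated tRNA survives the periodate-style
selection that the deacylated library removes), low (detected but
below the 10th percentile of detected totals).

## Synthetic data

The panel generator emulates the study conditions: a 420 bp ancestral
unit (72 nt cloverleaf-consistent tRNA-Cys-GCA-like gene + random
spacer at 36% GC, *A. thaliana*-like), six group templates diverged
from it, accessions carrying 4–6 units (the first n groups, so
accessions are collinear with the longest cluster and differ by whole
units at the downstream end, as tandem gain/loss produces), identical
500 bp flanks with the cluster-spanning primer pair planted in them, a
conserved upstream pseudogene (3 shared substitutions, anticodon loop
intact, ~1% per-accession drift → pairwise identity ≥ ~95%), one
CTAG[TC] motif per unit spacer, and one accession with a 167 bp
deletion spanning a unit junction (95 bp of one unit's tail + the next
unit's 72 nt gene).

Divergence has two scales: `group_divergence` (default 0.06 per group
vs the ancestor → between-group unit identity in the high-80s/low-90s
percent) and `within_divergence` (default 0.01, a unit vs its group
template → within-group identity ≥ ~97%). A single rate cannot serve
both roles: groups must separate decisively at the 0.03 tree cut while
copies of one group stay together. Substitution-only mutation keeps
unit lengths exact, so whole-unit gaps are exact multiples of 420 bp —
real data would add small indels and make event sizes approximate.

The read simulator draws per-gene read counts multinomially from an
expression vector (default: two silent singleton variants among 13
variants over 16 genes, emulating transcriptionally silenced
cluster-internal genes); mature reads are the CCA-tailed reference with
0–5 nt 3' truncation, precursor reads extend 5–30 nt into one genomic
flank, sequencing errors are i.i.d. substitutions (default 1%), and
contaminants (default 10%) are random sequences. The deacylated
library up-weights charged genes (default: alternating genes at factor
2). What the simulator does not model: modification-induced RT stops
and misincorporations, ligation bias, indel sequencing errors, adapter
read-through — so passing tests demonstrate correctness of the
computational pipeline, not robustness to every artefact of real
tRNA-seq libraries.

All randomness flows from one top-level seed through named child
streams (numpy `SeedSequence` spawn keys); the same seed gives
byte-identical genomes, reads, truth tables and pipeline reports.

## Problem sizes and numerical choices

Default study sizes: five accessions of 4–6 units (~2.7–3.7 kbp
regions), 16 loci / 13 variants, 20 000 reads per library for the
expression analyses (6 000 in the demo pipeline), chosen so the full
synthetic study and its tests run in minutes on one core while keeping
multinomial noise well below the effects being measured. Distance
matrices must be symmetric to 1e-9 (asymmetry is an input error, not
noise to average away); alignment score ties in read assignment are
resolved with a 1e-6 score tolerance; TMM follows its reference
implementation into the degenerate corners (empty trimmed set → factor
1). The 3-substitution pseudogene and the 167/95/72 bp deletion
arithmetic are fixed constants of the generator, not tunables.

## Known limitations

- Event calling assumes conserved flanks anchor the region alignment;
  accessions with rearranged flanks would need explicit synteny
  handling upstream.
- Greedy 97% clustering of 72 nt genes sits near its resolution limit:
  two substitutions keep a pair together (97.2%), three split it
  (95.8%), so borderline within-group pairs can split groups.
- The NJ tree-cut grouping is exact on the synthetic conditions but,
  like any fixed-threshold cut, fragile when between-group divergence
  approaches the cut.
- "Cumulative" scoring of a read against a locus reduces to the single
  best local alignment here; with full-length DP there is only one
  optimal score per reference, so no HSP summation arises.
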