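# Methods

## Coordinate model

GTF is 1-based inclusive on disk and the internal model keeps that
convention throughout; an intron between exons `[.., e]` and `[s, ..]` is
`[e+1, s-1]`. Exons listed out of order are sorted; exactly adjacent exons
(gap 0) are always merged with a warning, because a zero-length intron is
meaningless; overlapping exons are merged (`on_malformed="repair"`, the
default) or the transcript is dropped (`"drop"`). Records other than
`transcript`/`exon` are counted in the parse summary but not modelled. Raw
attribute text (and the score/frame columns) is preserved per record, so
unmodified records round-trip byte-identically — useful when filtering an
assembler's GTF whose attributes downstream tools still need.

Abundance is read from the first attribute present among
`cov, FPKM, TPM, RPKM` (covering StringTie- and Scallop-style outputs) and
biotype from `transcript_biotype, transcript_type` (Ensembl vs GENCODE
dialects); both lists are configurable because assemblers and annotation
providers disagree on attribute names.

## Structural sets and identity

Boundaries are intron endpoints, not exon endpoints; the two conventions
give identical Jaccard values when applied uniformly (the exon-end of one
element is the intron-end ± 1 of the same element), and tests pin the
intron-endpoint convention. Transcript start/end positions are never
boundaries. Identity of boundaries, junctions and chains includes
chromosome *and* strand; a strand of `"."` only matches `"."`. Every
set-valued operation takes an `ignore_strand` switch for sensitivity
analysis, which collapses strands to `"."` before comparison.

A boundary shared by two introns counts once (set semantics). Single-exon
transcripts stay in the model — evaluation needs them for the 80%-overlap
rule — but contribute nothing to B/J/C.

## Intron-retention classification

The coverage gate `p(r)/p(t) ≥ cr` is **inclusive**, so the default
`cr = 0.5` flags a reference with exactly half the candidate's abundance —
an exclusive reading would make the documented default dead at its own
boundary. Edge conventions, each logged or unit-tested: a candidate with
zero or unknown abundance is gated by any positive-abundance reference
(the ratio is treated as unbounded); if *no* transcript carries abundance
the gate passes everything and the classifier degrades to pure geometry
(warned once).

"First/last exon" is genomic (leftmost/rightmost), not 5'→3': criteria 1
and 2 are then exact mirror images and classification is strand-symmetric.

The partial criteria require the terminal exon's inner endpoint to fall
*strictly* inside the reference intron (`a < start ≤ b` for criterion 1,
`a ≤ end < b` for criterion 2). If the terminal exon covers the whole
intron, that is entire retention (criterion 3, closed containment
`x ≤ a ∧ y ≥ b`) — keeping "partial" and "entire" disjoint per reference
intron, which is what makes the `-po`/`-wo` switches well-defined.

The length-ratio numerator is the *overlap* between terminal exon and
intron (`b − start + 1`, mirrored for criterion 2), not the full exon
length: this keeps `lr ∈ [0, 1]` and makes flagging antitone in `lr`.
Classification is single-pass — references may themselves be flagged; no
iterative removal is performed. Candidate references are restricted to
span-overlapping transcripts on the compatible strand via an interval
index; a non-overlapping reference cannot satisfy any criterion, so this
is a pure optimisation (asserted against the O(n²) oracle). Single-exon
candidates are eligible (their one exon is both first and last);
single-exon references are not (no introns).

## Similarity

Annotation-level Jaccard uses all multi-exon transcripts; no gene pairing
is involved. When both sets are empty the value is reported as undefined
(`None`), never 0 or 1. Gene pairing follows the structural rule — two
multi-exon genes pair iff their boundary sets intersect — so every pair
has boundary Jaccard > 0 by construction; one gene may pair with several.
Distribution quartiles use the nearest-rank rule on raw per-pair values
(value at rank `⌈p/100·n⌉`), with histograms binned on [0, 1].

## Evaluation

Multi-exon matching is exact chain identity via a hash index on
(chromosome, strand, junction tuple). The single-exon "significant
overlap (80%)" rule is implemented *reciprocally* (≥ 80% of both lengths);
the stricter reading is the default and a one-directional variant is a
flag. `n_matching` counts matched assembled transcripts (two assembled
transcripts matching the same reference chain both count), mirroring the
precision numerator.

Adjusted precision removes one transcript per step from the higher-recall
assembly, in ascending abundance with unknown abundance sorting lowest and
ties broken lexicographically by transcript id, until the matching counts
agree; equal counts short-circuit with the raw precisions. Removal cannot
change other transcripts' match status, so the trace only decrements
counters.

Intersection/union composite annotations use "=" semantics: a query
transcript is in the intersection iff it matches the reference (chain
identity, or the single-exon rule); the union is the reference plus
unmatched query transcripts, with id collisions suffixed.

## Synthetic data

The toy annotation pair encodes two loci whose distinct-element counts are
10/12 boundaries, 5/8 junctions and 2/6 chains, hitting the three target
ratios (5/6, 5/8, 1/3) exactly; literal set sizes 6/8/3 for the three
unions are geometrically unrealizable (a chain of k junctions needs 2k
distinct boundary positions, which bounds the junction union below 8 on
six positions), so the ratios — not the counts — are the fixture's
contract. The toy assembly plants one event per criterion against a
five-exon reference, with all abundance ratios at 0.6 and both partial
overlaps at ~51% of their intron, so `cr` above 0.6 or `lr` above 0.51
suppress the respective calls.

The seeded simulators are constructive: gene windows 100 kb apart make
cross-gene structure impossible, and expected values are computed from the
raw emitted coordinates with plain set arithmetic, independent of the
model code under test. The annotation-pair generator realises per-level
sharing targets by assigning windows to four motifs (identical gene;
junction-shared/chain-split; boundary-shared/junction-split; private);
targets must satisfy chain ≤ junction ≤ boundary or validation fails. The
retention generator plants each event by template geometry (terminal exon
placed midway into the retained intron; merged exon for entire retention)
so that exactly the requested criterion fires, and realises
`p(r)/p(t) = ratio` with `p(t) = 20`. Identical seeds give byte-identical
GTF output.

What the simulators do **not** emulate: realistic expression distributions,
soft-clipped/noisy exon boundaries, multi-chromosome genomes, overlapping
gene loci, and annotation-scale set sizes. Passing tests therefore
demonstrate correctness of the set algebra, classification geometry and
bookkeeping — not performance claims about real annotation releases, which
require the external checks below.

## Problem sizes and tolerances

Randomized cross-validation runs 100 assemblies of 10–200 transcripts for
the retention classifier (exact agreement with the O(n²) oracle required),
25–30 annotation pairs/assemblies for the similarity and matching oracles,
and seeded planted-retention fixtures with 15–50 transcripts. All equality
assertions on Jaccard values are exact (identical integer divisions);
nothing is compared with loose tolerances except hand-derived overlap
ratios (`pytest.approx` at default relative tolerance).

`scripts/external_checks.py` applies the annotation-level Jaccard and
gene-pairing pipeline to real downloaded releases; it streams two GTFs and
an optional two-column gene-pair catalog and prints the three Jaccard
levels and the catalog recovery fraction. It is not part of the default
suite because the inputs are multi-gigabyte downloads.

## Known limitations

* Abundance-blind assemblies fall back to geometry-only gating, which
  over-flags relative to the abundance-aware definition.
* Only "=" class-code semantics are implemented; other transcript
  class codes (contained, intron-compatible, …) are out of scope.
* The per-gene Jaccard distribution reports nearest-rank percentiles;
  other interpolation rules will differ slightly on small pair sets.
* GFF3 input is not supported (GTF only, optionally gzipped).
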