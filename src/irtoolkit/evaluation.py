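"""Assembly-vs-annotation evaluation.

Matching follows the transcript-level rule used by GffCompare: an assembled
multi-exon transcript matches when its intron chain is coordinate-identical
to that of an annotated transcript; an assembled single-exon transcript
matches when it overlaps an annotated single-exon transcript significantly
(80% reciprocally by default).  From the per-transcript verdicts come the
two summary metrics: the number of matching transcripts (a recall proxy)
and precision (matching / assembled).

When two assemblies disagree in opposite directions on the two metrics,
their *adjusted precisions* break the tie: the higher-recall assembly has
its lowest-abundance transcripts removed one at a time until its matching
count equals the other's, and the precision at that point is compared.

Also here: biotype stratification of matches, union/intersection composite
references built by exact chain matching ("=" class-code semantics), and
precision/recall sweeps over the intron-retention thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import Annotation, Transcript
from .retention import IRParams, params_with, partition

__all__ = [
    "MatchRow",
    "MatchReport",
    "AdjustedPrecision",
    "SweepPoint",
    "match",
    "adjusted_precision",
    "stratify_by_biotype",
    "annotation_intersection",
    "annotation_union",
    "threshold_sweep",
]


@dataclass(frozen=True)
class MatchRow:
    """Match status of one assembled transcript."""

    transcript_id: str
    matched: bool
    matched_reference_id: str | None = None
    match_type: str | None = None  # "chain" or "single_exon"


@dataclass
class MatchReport:
    """Per-transcript match rows plus the two summary metrics."""

    rows: list[MatchRow]
    n_assembled: int

    @property
    def n_matching(self) -> int:
        return sum(1 for r in self.rows if r.matched)

    @property
    def precision(self) -> float:
        if self.n_assembled == 0:
            return 0.0
        return self.n_matching / self.n_assembled

    @property
    def matched_ids(self) -> set[str]:
        return {r.transcript_id for r in self.rows if r.matched}

    def row(self, transcript_id: str) -> MatchRow:
        for r in self.rows:
            if r.transcript_id == transcript_id:
                return r
        raise KeyError(transcript_id)


def _reciprocal_overlap(t: Transcript, r: Transcript) -> tuple[int, int, int]:
    (ts, te), (rs, re_) = t.span, r.span
    ov = min(te, re_) - max(ts, rs) + 1
    return max(ov, 0), te - ts + 1, re_ - rs + 1


def _match_single_exon(
    t: Transcript,
    reference: Annotation,
    min_overlap: float,
    reciprocal: bool,
) -> str | None:
    lo, hi = t.span
    best: str | None = None
    for r in reference.overlapping(t.chrom, t.strand, lo, hi):
        if r.is_multi_exon or r.strand != t.strand:
            continue
        ov, lt, lr_ = _reciprocal_overlap(t, r)
        ok = ov >= min_overlap * lt and (not reciprocal or ov >= min_overlap * lr_)
        if ok and (best is None or r.transcript_id < best):
            best = r.transcript_id
    return best


def match(
    assembly: Annotation,
    reference: Annotation,
    single_exon_overlap: float = 0.8,
    reciprocal: bool = True,
) -> MatchReport:
    """Match every assembled transcript against the reference annotation.

    Multi-exon transcripts match by exact intron-chain identity (same
    chromosome, strand, and junction coordinates).  Single-exon transcripts
    match a single-exon reference transcript by >= ``single_exon_overlap``
    of each transcript's length (set ``reciprocal=False`` for the
    one-directional variant).  Two assembled transcripts matching the same
    reference both count; ties among candidate references break to the
    lexicographically smallest id.
    """
    chain_idx = reference.chain_index
    rows: list[MatchRow] = []
    for t in assembly:
        if t.is_multi_exon:
            hits = chain_idx.get(t.chain(), [])
            if hits:
                rows.append(MatchRow(t.transcript_id, True, min(hits), "chain"))
            else:
                rows.append(MatchRow(t.transcript_id, False))
        else:
            ref_id = _match_single_exon(t, reference, single_exon_overlap, reciprocal)
            if ref_id is not None:
                rows.append(MatchRow(t.transcript_id, True, ref_id, "single_exon"))
            else:
                rows.append(MatchRow(t.transcript_id, False))
    return MatchReport(rows=rows, n_assembled=len(assembly))


@dataclass
class AdjustedPrecision:
    """Outcome of the adjusted-precision comparison.

    ``adjusted`` is the higher-recall assembly's precision after the
    removal trace; ``other`` is the lower-recall assembly's raw precision.
    ``removed`` lists removed transcript ids in removal order (empty when
    matching counts were already equal).
    """

    adjusted_assembly: str | None
    adjusted: float
    other: float
    removed: list[str] = field(default_factory=list)
    n_matching_final: int = 0


def adjusted_precision(
    report_a: MatchReport,
    assembly_a: Annotation,
    report_b: MatchReport,
    assembly_b: Annotation,
) -> AdjustedPrecision:
    """Equalise matching counts by abundance-ordered removal, then compare.

    The assembly with the larger matching count loses its lowest-abundance
    transcripts one at a time (unknown abundance sorts lowest; ties break
    lexicographically by transcript id) until the counts agree.  Both match
    reports must have been computed against the same reference.
    """
    na, nb = report_a.n_matching, report_b.n_matching
    if na == nb:
        return AdjustedPrecision(
            adjusted_assembly=None,
            adjusted=report_a.precision,
            other=report_b.precision,
            n_matching_final=na,
        )
    if na > nb:
        high_rep, high_ann, target, other_prec = report_a, assembly_a, nb, report_b.precision
    else:
        high_rep, high_ann, target, other_prec = report_b, assembly_b, na, report_a.precision

    matched = high_rep.matched_ids
    order = sorted(
        high_ann,
        key=lambda t: (
            t.abundance if t.abundance is not None else float("-inf"),
            t.transcript_id,
        ),
    )
    n_matching = high_rep.n_matching
    n_assembled = high_rep.n_assembled
    removed: list[str] = []
    for t in order:
        if n_matching <= target:
            break
        removed.append(t.transcript_id)
        n_assembled -= 1
        if t.transcript_id in matched:
            n_matching -= 1
    adjusted = n_matching / n_assembled if n_assembled else 0.0
    return AdjustedPrecision(
        adjusted_assembly=high_ann.name,
        adjusted=adjusted,
        other=other_prec,
        removed=removed,
        n_matching_final=n_matching,
    )


def stratify_by_biotype(report: MatchReport, reference: Annotation) -> Counter:
    """Count matched assembled transcripts per matched-reference biotype.

    Each matched transcript contributes one to the biotype bucket of the
    reference transcript it matched; unmatched transcripts contribute
    nowhere, so bucket totals sum to ``n_matching``.  An empty biotype
    string buckets under ``""``.
    """
    counts: Counter = Counter()
    for row in report.rows:
        if row.matched and row.matched_reference_id is not None:
            counts[reference[row.matched_reference_id].biotype] += 1
    return counts


def _fresh_id(tid: str, taken: set[str]) -> str:
    if tid not in taken:
        return tid
    i = 1
    while f"{tid}.{i}" in taken:
        i += 1
    return f"{tid}.{i}"


def annotation_intersection(
    reference: Annotation, query: Annotation, single_exon_overlap: float = 0.8
) -> Annotation:
    """Query transcripts whose structure matches the reference exactly.

    "=" class-code semantics: multi-exon transcripts by exact intron-chain
    identity, single-exon transcripts by the significant-overlap rule.
    """
    rep = match(query, reference, single_exon_overlap)
    matched = rep.matched_ids
    return Annotation(
        f"intersection({reference.name},{query.name})",
        (t for t in query if t.transcript_id in matched),
    )


def annotation_union(
    reference: Annotation, query: Annotation, single_exon_overlap: float = 0.8
) -> Annotation:
    """All reference transcripts plus query transcripts not matching them.

    Query transcript ids colliding with reference ids get a numeric suffix
    so the combined annotation keeps ids unique.
    """
    rep = match(query, reference, single_exon_overlap)
    matched = rep.matched_ids
    out = Annotation(f"union({reference.name},{query.name})", reference)
    taken = {t.transcript_id for t in reference}
    for t in query:
        if t.transcript_id in matched:
            continue
        tid = _fresh_id(t.transcript_id, taken)
        taken.add(tid)
        if tid != t.transcript_id:
            t = Transcript(
                transcript_id=tid,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                exons=t.exons,
                abundance=t.abundance,
                biotype=t.biotype,
                source=t.source,
            )
        out.add(t)
    return out


@dataclass(frozen=True)
class SweepPoint:
    """One point of a threshold sweep: filter at ``threshold``, then match."""

    threshold: float
    precision: float
    n_matching: int
    n_kept: int
    n_flagged: int


def threshold_sweep(
    assembly: Annotation,
    reference: Annotation,
    params_base: IRParams,
    vary: str,
    grid: list[float],
    single_exon_overlap: float = 0.8,
) -> list[SweepPoint]:
    """Precision/recall of the filtered assembly across a threshold grid.

    ``vary`` is ``"lr"`` (length ratio) or ``"cr"`` (coverage ratio); each
    grid value replaces that field of ``params_base``, the assembly is
    partitioned, and the kept part is matched against the reference.
    """
    if vary not in ("lr", "cr"):
        raise ValueError("vary must be 'lr' or 'cr'")
    fieldname = "length_ratio" if vary == "lr" else "coverage_ratio"
    points: list[SweepPoint] = []
    for value in grid:
        params = params_with(params_base, **{fieldname: value})
        ir, kept = partition(assembly, params)
        rep = match(kept, reference, single_exon_overlap)
        points.append(
            SweepPoint(
                threshold=value,
                precision=rep.precision,
                n_matching=rep.n_matching,
                n_kept=len(kept),
                n_flagged=len(ir),
            )
        )
    return points
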