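"""Intron-retention detection within a transcript assembly.

A transcript ``t`` is flagged as carrying (partial or entire) intron
retention when some *other* transcript ``r`` of the same assembly, with
sufficiently high relative abundance ``p(r)/p(t)``, exhibits one of three
geometric relations to ``t``:

1. **criterion 1** (partial, left end): the genomically first exon of ``t``
   starts inside an intron of ``r`` and extends into the exon that follows
   that intron;
2. **criterion 2** (partial, right end): the mirror image — the genomically
   last exon of ``t`` ends inside an intron of ``r`` and starts inside the
   exon that precedes it;
3. **criterion 3** (entire): some exon of ``t`` fully contains an intron of
   ``r``.

Two thresholds tune the call: the **coverage ratio** ``cr`` (default 0.5)
gates every criterion on ``p(r)/p(t) >= cr``; the **length ratio** ``lr``
(default 0) additionally requires, for criteria 1-2, that the terminal exon
overlap at least ``lr`` of the retained intron's length.  Raising either
threshold can only shrink the flagged set.

Conventions (documented because the verbal definitions are ambiguous at the
edges):

* the coverage gate is inclusive (``>=``), so at the default ``cr = 0.5`` a
  reference with exactly half of ``t``'s abundance still gates;
* "first/last exon" is genomic (leftmost/rightmost), making criteria 1 and 2
  exact mirror images and the classifier strand-symmetric;
* the terminal exon's inner endpoint must fall *strictly* inside the intron:
  a terminal exon that covers the whole intron is criterion 3's territory,
  keeping "partial" and "entire" disjoint per reference intron;
* the length-ratio numerator is the overlap between the terminal exon and
  the intron, so ``lr`` lives in [0, 1] and gating is monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .model import Annotation, Transcript

__all__ = ["IRParams", "Evidence", "IRCall", "coverage_gate",
           "criterion1", "criterion2", "criterion3", "classify", "partition"]

logger = logging.getLogger(__name__)
_warned_abundance_blind = False


@dataclass(frozen=True)
class IRParams:
    """Thresholds and criterion switches for intron-retention calls.

    ``partial_enabled`` covers criteria 1-2 (turned off by the ``-po``
    option, which keeps entire-retention only); ``entire_enabled`` covers
    criterion 3 (turned off by ``-wo``).  At least one group must stay on.
    """

    coverage_ratio: float = 0.5
    length_ratio: float = 0.0
    partial_enabled: bool = True
    entire_enabled: bool = True
    ignore_strand: bool = False

    def __post_init__(self) -> None:
        if self.coverage_ratio < 0:
            raise ValueError("coverage_ratio must be >= 0")
        if not 0.0 <= self.length_ratio <= 1.0:
            raise ValueError("length_ratio must be in [0, 1]")
        if not (self.partial_enabled or self.entire_enabled):
            raise ValueError("at least one of partial/entire criteria must be enabled")


@dataclass(frozen=True)
class Evidence:
    """One (criterion, reference) pair that fired for a transcript."""

    criterion: int
    reference_id: str
    abundance_ratio: float | None
    overlap_ratio: float | None = None  # criteria 1-2 only


@dataclass
class IRCall:
    """Verdict for one transcript: which criteria fired, against whom."""

    transcript_id: str
    flagged: bool
    fired_criteria: frozenset[int] = frozenset()
    evidence: list[Evidence] = field(default_factory=list)


def coverage_gate(t: Transcript, r: Transcript, cr: float) -> bool:
    """True when ``p(r)/p(t) >= cr`` under the documented edge conventions.

    If ``p(t)`` is zero or unknown the ratio is treated as unbounded, so any
    positive ``p(r)`` gates.  If both abundances are unknown the gate passes
    (abundance-blind fallback, logged once).
    """
    global _warned_abundance_blind
    pt, pr = t.abundance, r.abundance
    if pt is not None and pt < 0 or pr is not None and pr < 0:
        raise ValueError("negative abundance")
    if pt is None and pr is None:
        if not _warned_abundance_blind:
            logger.warning("no abundances available; coverage gate passes all pairs")
            _warned_abundance_blind = True
        return True
    if pt is None or pt == 0:
        return pr is None or pr > 0
    if pr is None:
        return True
    return pr / pt >= cr


def _strand_compatible(t: Transcript, r: Transcript, ignore_strand: bool) -> bool:
    return ignore_strand or t.strand == r.strand


def criterion1(t: Transcript, r: Transcript, lr: float = 0.0) -> tuple[bool, float]:
    """Partial retention at the genomically left end of ``t``.

    The first exon of ``t`` starts strictly inside an intron ``[a, b]`` of
    ``r`` and extends past ``b`` into the following exon of ``r``.  Returns
    ``(fired, overlap_ratio)`` where ``overlap_ratio = (b - start + 1) /
    (b - a + 1)`` for the best (largest-ratio) qualifying intron, or 0.0.
    """
    if t.chrom != r.chrom:
        return False, 0.0
    s, e = t.exons[0]
    best = 0.0
    fired = False
    for a, b in r.introns():
        if a < s <= b and e > b:
            ratio = (b - s + 1) / (b - a + 1)
            if ratio >= lr:
                fired = True
                best = max(best, ratio)
    return fired, best


def criterion2(t: Transcript, r: Transcript, lr: float = 0.0) -> tuple[bool, float]:
    """Partial retention at the genomically right end of ``t`` (mirror of
    :func:`criterion1`): the last exon of ``t`` ends strictly inside an
    intron ``[a, b]`` of ``r`` and starts before ``a``."""
    if t.chrom != r.chrom:
        return False, 0.0
    s, e = t.exons[-1]
    best = 0.0
    fired = False
    for a, b in r.introns():
        if a <= e < b and s < a:
            ratio = (e - a + 1) / (b - a + 1)
            if ratio >= lr:
                fired = True
                best = max(best, ratio)
    return fired, best


def criterion3(t: Transcript, r: Transcript) -> bool:
    """Entire retention: some exon of ``t`` fully contains (closed
    containment) some intron of ``r``."""
    if t.chrom != r.chrom:
        return False
    introns = r.introns()
    for x, y in t.exons:
        for a, b in introns:
            if x <= a and y >= b:
                return True
    return False


def _abundance_ratio(t: Transcript, r: Transcript) -> float | None:
    if t.abundance is None or r.abundance is None or t.abundance == 0:
        return None
    return r.abundance / t.abundance


def classify(t: Transcript, assembly: Annotation, params: IRParams = IRParams()) -> IRCall:
    """Classify one transcript of ``assembly`` against all candidate
    references.

    Candidates are the other transcripts on the same chromosome and
    (unless ``ignore_strand``) strand whose genomic span overlaps ``t``'s;
    a non-overlapping reference cannot satisfy any criterion, so the
    restriction loses nothing.  Evidence records every (criterion,
    reference) pair that fired; the verdict is independent of iteration
    order.
    """
    lo, hi = t.span
    evidence: list[Evidence] = []
    fired: set[int] = set()
    for r in assembly.overlapping(t.chrom, t.strand, lo, hi, params.ignore_strand):
        if r.transcript_id == t.transcript_id:
            continue
        if not _strand_compatible(t, r, params.ignore_strand):
            continue
        if not r.is_multi_exon:
            continue
        if not coverage_gate(t, r, params.coverage_ratio):
            continue
        ratio = _abundance_ratio(t, r)
        if params.partial_enabled:
            ok1, ov1 = criterion1(t, r, params.length_ratio)
            if ok1:
                fired.add(1)
                evidence.append(Evidence(1, r.transcript_id, ratio, ov1))
            ok2, ov2 = criterion2(t, r, params.length_ratio)
            if ok2:
                fired.add(2)
                evidence.append(Evidence(2, r.transcript_id, ratio, ov2))
        if params.entire_enabled and criterion3(t, r):
            fired.add(3)
            evidence.append(Evidence(3, r.transcript_id, ratio))
    evidence.sort(key=lambda e: (e.criterion, e.reference_id))
    return IRCall(
        transcript_id=t.transcript_id,
        flagged=bool(fired),
        fired_criteria=frozenset(fired),
        evidence=evidence,
    )


def classify_all(assembly: Annotation, params: IRParams = IRParams()) -> dict[str, IRCall]:
    """Classify every transcript of the assembly.  Single-pass: references
    may themselves be flagged; no iterative removal is performed."""
    return {t.transcript_id: classify(t, assembly, params) for t in assembly}


def partition(
    assembly: Annotation, params: IRParams = IRParams()
) -> tuple[Annotation, Annotation]:
    """Split the assembly into ``(ir, kept)``: flagged transcripts and the
    rest.  The two parts are disjoint and jointly exhaust the assembly."""
    calls = classify_all(assembly, params)
    ir = Annotation(f"{assembly.name}.intron-retention")
    kept = Annotation(f"{assembly.name}.filtered")
    for t in assembly:
        (ir if calls[t.transcript_id].flagged else kept).add(t)
    return ir, kept


def params_with(params: IRParams, **overrides) -> IRParams:
    """A copy of ``params`` with the given fields replaced."""
    return replace(params, **overrides)
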