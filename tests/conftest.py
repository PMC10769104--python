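"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every quantity directly from exon coordinate lists
with plain Python set arithmetic and all-pairs scans — no interval indexes,
no model-layer derivations — so they stay independent of the code paths
they check.
"""

from __future__ import annotations

import random

import pytest

from irtoolkit.model import Annotation, Transcript
from irtoolkit.fixtures import make_fig8_fixture, make_fig9_fixture


@pytest.fixture
def fig8():
    return make_fig8_fixture()


@pytest.fixture
def fig9():
    return make_fig9_fixture()


# --------------------------------------------------------------------------
# brute-force set constructors


def raw_introns(exons) -> list[tuple[int, int]]:
    return [(b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(exons, exons[1:])]


def raw_sets(transcripts):
    """(boundaries, junctions, chains) by direct enumeration over exons."""
    B, J, C = set(), set(), set()
    for t in transcripts:
        ii = raw_introns(t.exons)
        if not ii:
            continue
        C.add((t.chrom, t.strand, tuple(ii)))
        for a, b in ii:
            J.add((t.chrom, t.strand, a, b))
            B.add((t.chrom, t.strand, a))
            B.add((t.chrom, t.strand, b))
    return B, J, C


def raw_jaccard(tx1, tx2, level):
    i = {"boundary": 0, "junction": 1, "intron_chain": 2}[level]
    s1, s2 = raw_sets(tx1)[i], raw_sets(tx2)[i]
    union = s1 | s2
    return None if not union else len(s1 & s2) / len(union)


# --------------------------------------------------------------------------
# brute-force intron-retention classifier (O(n^2), definition-literal)


def oracle_gate(t, r, cr):
    pt, pr = t.abundance, r.abundance
    if pt is None and pr is None:
        return True
    if pt is None or pt == 0:
        return pr is None or pr > 0
    if pr is None:
        return True
    return pr / pt >= cr


def oracle_criteria(t, r, lr):
    """Criteria fired by candidate t against reference r, from first
    principles: terminal-exon-in-intron for 1/2 (strict interiority, ratio
    gated by lr), closed containment for 3."""
    fired = set()
    introns = raw_introns(r.exons)
    if introns:
        s, e = t.exons[0]
        for a, b in introns:
            if a < s <= b and e > b and (b - s + 1) / (b - a + 1) >= lr:
                fired.add(1)
        s, e = t.exons[-1]
        for a, b in introns:
            if a <= e < b and s < a and (e - a + 1) / (b - a + 1) >= lr:
                fired.add(2)
        for x, y in t.exons:
            for a, b in introns:
                if x <= a and y >= b:
                    fired.add(3)
    return fired


def oracle_classify(t, transcripts, cr=0.5, lr=0.0, partial=True, entire=True,
                    ignore_strand=False):
    """All-pairs verdict for one transcript: the set of criteria that fire
    against any admissible reference."""
    fired = set()
    for r in transcripts:
        if r.transcript_id == t.transcript_id or r.chrom != t.chrom:
            continue
        if not ignore_strand and r.strand != t.strand:
            continue
        if len(r.exons) < 2 or not oracle_gate(t, r, cr):
            continue
        got = oracle_criteria(t, r, lr)
        if not partial:
            got -= {1, 2}
        if not entire:
            got -= {3}
        fired |= got
    return fired


def oracle_match(assembly_tx, reference_tx, min_overlap=0.8):
    """All-pairs matcher: exact chain identity for multi-exon, reciprocal
    span overlap for single-exon.  Returns {tid: matched_bool}."""
    out = {}
    for t in assembly_tx:
        matched = False
        for r in reference_tx:
            if t.chrom != r.chrom or t.strand != r.strand:
                continue
            if len(t.exons) >= 2:
                if raw_introns(t.exons) == raw_introns(r.exons) and len(r.exons) >= 2:
                    matched = True
            else:
                if len(r.exons) >= 2:
                    continue
                (ts, te), (rs, re_) = t.exons[0], r.exons[0]
                ov = min(te, re_) - max(ts, rs) + 1
                if ov >= min_overlap * (te - ts + 1) and ov >= min_overlap * (re_ - rs + 1):
                    matched = True
            if matched:
                break
        out[t.transcript_id] = matched
    return out


# --------------------------------------------------------------------------
# randomized annotation builder


def random_assembly(
    rng: random.Random,
    n_transcripts: int,
    n_loci: int = 5,
    grid_step: int = 25,
    with_abundance: bool = True,
    strands=("+", "-"),
    single_exon_fraction: float = 0.1,
    name: str = "rand",
) -> Annotation:
    """Random transcripts clustered on shared loci so structures collide.

    Exon endpoints come from a per-locus coordinate grid, which makes
    shared boundaries, overlapping spans, and retention-like geometries
    common — the regime the classifiers must get right.
    """
    transcripts = []
    for i in range(n_transcripts):
        locus = rng.randrange(n_loci)
        offset = 1000 + locus * 50_000
        strand = strands[locus % len(strands)] if len(strands) > 1 else strands[0]
        if rng.random() < single_exon_fraction:
            k = 1
        else:
            k = rng.randint(2, 6)
        points = sorted(rng.sample(range(offset, offset + 8000, grid_step), 2 * k))
        exons = tuple((points[j], points[j + 1] - 1) for j in range(0, 2 * k, 2))
        abundance = None
        if with_abundance:
            roll = rng.random()
            abundance = 0.0 if roll < 0.05 else round(rng.uniform(0.1, 20), 3)
        transcripts.append(
            Transcript(
                transcript_id=f"{name}.t{i}",
                gene_id=f"{name}.g{locus}",
                chrom="chr1",
                strand=strand,
                exons=exons,
                abundance=abundance,
                biotype=rng.choice(
                    ["protein_coding", "retained_intron", "lncRNA", ""]
                ),
            )
        )
    return Annotation(name, transcripts)
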