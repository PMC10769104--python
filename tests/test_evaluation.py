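"""Matching, precision, adjusted precision, biotypes, composite references,
threshold sweeps."""

import random

import pytest

from irtoolkit.model import Annotation, Transcript
from irtoolkit.evaluation import (
    adjusted_precision,
    annotation_intersection,
    annotation_union,
    match,
    stratify_by_biotype,
    threshold_sweep,
)
from irtoolkit.retention import IRParams, partition

from conftest import oracle_match, random_assembly


def tx(exons, tid, gid="g", strand="+", abundance=None, biotype=""):
    return Transcript(tid, gid, "chr1", strand, tuple(exons),
                      abundance=abundance, biotype=biotype)


def _ten_transcript_reference():
    txs = []
    for i in range(8):
        base = 10_000 * (i + 1)
        txs.append(tx([(base, base + 99), (base + 200, base + 299), (base + 400, base + 499)],
                      f"ref{i}", f"rg{i}", biotype="protein_coding" if i % 2 else "retained_intron"))
    # two single-exon transcripts
    txs.append(tx([(200_000, 200_999)], "ref8", "rg8", biotype="lncRNA"))
    txs.append(tx([(300_000, 300_499)], "ref9", "rg9", biotype="lncRNA"))
    return Annotation("reference", txs)


def _clone(ann, name):
    return Annotation(
        name,
        [
            Transcript(f"asm.{t.transcript_id}", t.gene_id, t.chrom, t.strand,
                       t.exons, abundance=1.0, biotype="")
            for t in ann
        ],
    )


def test_identity_assembly_has_precision_one():
    ref = _ten_transcript_reference()
    rep = match(_clone(ref, "asm"), ref)
    assert rep.n_assembled == 10
    assert rep.n_matching == 10
    assert rep.precision == 1.0
    assert all(r.matched for r in rep.rows)


def test_one_bp_junction_shift_breaks_the_match():
    ref = Annotation("ref", [tx([(100, 200), (301, 400)], "r0")])
    shifted = Annotation("asm", [tx([(100, 201), (301, 400)], "a0")])
    assert match(shifted, ref).n_matching == 0
    exact = Annotation("asm2", [tx([(100, 200), (301, 400)], "a1")])
    assert match(exact, ref).n_matching == 1


def test_chain_match_ignores_transcript_ends():
    ref = Annotation("ref", [tx([(100, 200), (301, 400)], "r0")])
    asm = Annotation("asm", [tx([(150, 200), (301, 450)], "a0")])
    rep = match(asm, ref)
    assert rep.n_matching == 1
    assert rep.rows[0].match_type == "chain"
    assert rep.rows[0].matched_reference_id == "r0"


def test_single_exon_reciprocal_overlap_rule():
    ref = Annotation("ref", [tx([(1000, 1999)], "r0")])  # length 1000
    hit = Annotation("a", [tx([(1100, 1999)], "a0")])  # overlap 900: 90% both ways
    assert match(hit, ref).n_matching == 1
    # 80% of the assembled transcript but only 50% of the reference
    short = Annotation("b", [tx([(1500, 1999)], "b0")])
    assert match(short, ref).n_matching == 0
    assert match(short, ref, reciprocal=False).n_matching == 1
    # multi-exon never matches single-exon
    multi = Annotation("c", [tx([(1000, 1400), (1501, 1999)], "c0")])
    assert match(multi, ref).n_matching == 0


def test_match_equals_all_pairs_oracle_on_random_fixtures():
    rng = random.Random(31)
    for trial in range(30):
        ref = random_assembly(rng, rng.randint(5, 60), n_loci=3, name="R")
        # assembly: a mix of exact copies (renamed) and fresh random transcripts
        copies = [
            Transcript(f"cp{i}", t.gene_id, t.chrom, t.strand, t.exons, abundance=1.0)
            for i, t in enumerate(ref.transcripts[:: max(1, trial % 4)][:20])
        ]
        noise = random_assembly(rng, rng.randint(5, 40), n_loci=3, name=f"N{trial}")
        asm = Annotation("asm", copies + noise.transcripts)
        rep = match(asm, ref)
        expected = oracle_match(asm.transcripts, ref.transcripts)
        got = {r.transcript_id: r.matched for r in rep.rows}
        assert got == expected


# --------------------------------------------------------------------------
# adjusted precision


def _assembly_for_adjustment():
    """A: 6 matching / 10 assembled; B: 5 matching / 8 assembled.

    A's two lowest-abundance transcripts are one unmatched (0.5) and one
    matched (1.0); removing both leaves 5 matching / 8 -> 0.625.
    """
    ref = _ten_transcript_reference()
    a_txs = []
    for i in range(6):  # matching copies of ref0..ref5
        r = ref[f"ref{i}"]
        a_txs.append(Transcript(f"A.m{i}", r.gene_id, r.chrom, r.strand, r.exons,
                                abundance=1.0 if i == 0 else 5.0 + i))
    for i in range(4):  # unmatched
        base = 900_000 + 10_000 * i
        a_txs.append(tx([(base, base + 99), (base + 200, base + 299)], f"A.u{i}",
                        abundance=0.5 if i == 0 else 7.0 + i))
    A = Annotation("A", a_txs)

    b_txs = []
    for i in range(5):
        r = ref[f"ref{i}"]
        b_txs.append(Transcript(f"B.m{i}", r.gene_id, r.chrom, r.strand, r.exons,
                                abundance=4.0))
    for i in range(3):
        base = 700_000 + 10_000 * i
        b_txs.append(tx([(base, base + 99), (base + 200, base + 299)], f"B.u{i}",
                        abundance=4.0))
    B = Annotation("B", b_txs)
    return ref, A, B


def test_adjusted_precision_hand_simulated_trace():
    ref, A, B = _assembly_for_adjustment()
    rep_a, rep_b = match(A, ref), match(B, ref)
    assert (rep_a.n_matching, rep_a.n_assembled) == (6, 10)
    assert (rep_b.n_matching, rep_b.n_assembled) == (5, 8)
    adj = adjusted_precision(rep_a, A, rep_b, B)
    assert adj.adjusted_assembly == "A"
    assert adj.removed == ["A.u0", "A.m0"]  # lowest abundance first
    assert adj.n_matching_final == rep_b.n_matching
    assert adj.adjusted == pytest.approx(5 / 8)
    assert adj.other == pytest.approx(5 / 8)


def test_equal_matching_counts_need_no_adjustment():
    ref, A, _ = _assembly_for_adjustment()
    rep = match(A, ref)
    adj = adjusted_precision(rep, A, rep, A)
    assert adj.adjusted_assembly is None
    assert adj.adjusted == rep.precision and adj.other == rep.precision
    assert adj.removed == []


def test_adjustment_ties_broken_by_transcript_id():
    ref = _ten_transcript_reference()
    # all abundances tied: removal order must be lexicographic
    A = Annotation("A", [
        Transcript(f"A.t{i}", "g", "chr1", "+", ref[f"ref{i}"].exons, abundance=2.0)
        for i in range(4)
    ])
    B = Annotation("B", [
        Transcript("B.t0", "g", "chr1", "+", ref["ref0"].exons, abundance=2.0)
    ])
    adj1 = adjusted_precision(match(A, ref), A, match(B, ref), B)
    adj2 = adjusted_precision(match(A, ref), A, match(B, ref), B)
    assert adj1.removed == adj2.removed == ["A.t0", "A.t1", "A.t2"]
    assert adj1.n_matching_final == 1


def test_adjustment_never_touches_lower_recall_side():
    ref, A, B = _assembly_for_adjustment()
    adj = adjusted_precision(match(A, ref), A, match(B, ref), B)
    assert all(tid.startswith("A.") for tid in adj.removed)


# --------------------------------------------------------------------------
# biotype stratification


def test_biotype_buckets_sum_to_n_matching():
    rng = random.Random(77)
    ref = _ten_transcript_reference()
    for trial in range(5):
        noise = random_assembly(rng, 20, name=f"n{trial}")
        asm = Annotation("asm", _clone(ref, "x").transcripts + noise.transcripts)
        rep = match(asm, ref)
        counts = stratify_by_biotype(rep, ref)
        assert sum(counts.values()) == rep.n_matching


def test_biotype_single_bucket_and_empty():
    ref = Annotation("ref", [tx([(100, 200), (301, 400)], "r0", biotype="retained_intron")])
    asm = Annotation("asm", [tx([(100, 200), (301, 400)], "a0")])
    assert dict(stratify_by_biotype(match(asm, ref), ref)) == {"retained_intron": 1}
    empty = Annotation("asm2", [tx([(900, 950), (1001, 1100)], "z0")])
    assert dict(stratify_by_biotype(match(empty, ref), ref)) == {}


# --------------------------------------------------------------------------
# union / intersection composite annotations


def test_identity_intersection_and_union():
    ref = _ten_transcript_reference()
    query = _clone(ref, "query")
    inter = annotation_intersection(ref, query)
    assert len(inter) == len(query)
    union = annotation_union(ref, query)
    assert {t.transcript_id for t in union} == {t.transcript_id for t in ref}


def test_disjoint_intersection_and_union():
    ref = Annotation("ref", [tx([(100, 200), (301, 400)], "r0")])
    query = Annotation("q", [tx([(10_100, 10_200), (10_301, 10_400)], "q0")])
    assert len(annotation_intersection(ref, query)) == 0
    union = annotation_union(ref, query)
    assert len(union) == 2
    assert {t.transcript_id for t in union} == {"r0", "q0"}


def test_half_overlapping_sizes_match_brute_force():
    rng = random.Random(8)
    for trial in range(10):
        ref = random_assembly(rng, 30, n_loci=2, name="R")
        shared = [
            Transcript(f"s{i}", t.gene_id, t.chrom, t.strand, t.exons)
            for i, t in enumerate(ref.transcripts[:15])
        ]
        private = random_assembly(rng, 15, n_loci=2, name=f"P{trial}")
        query = Annotation("Q", shared + private.transcripts)
        expected = oracle_match(query.transcripts, ref.transcripts)
        n_match = sum(expected.values())
        assert len(annotation_intersection(ref, query)) == n_match
        assert len(annotation_union(ref, query)) == len(ref) + len(query) - n_match


def test_union_renames_colliding_ids():
    e = [(100, 200), (301, 400)]
    ref = Annotation("ref", [tx(e, "same_id")])
    query = Annotation("q", [tx([(9000, 9100), (9201, 9300)], "same_id")])
    union = annotation_union(ref, query)
    assert len(union) == 2
    assert "same_id" in union and "same_id.1" in union


# --------------------------------------------------------------------------
# threshold sweeps


def test_single_point_sweep_equals_direct_run(fig9):
    ref = Annotation("ref", list(fig9))
    pts = threshold_sweep(fig9, ref, IRParams(), "cr", [0.5])
    _, kept = partition(fig9, IRParams())
    rep = match(kept, ref)
    assert pts[0].precision == rep.precision
    assert pts[0].n_matching == rep.n_matching
    assert pts[0].n_kept == len(kept)


def test_cr_sweep_monotone_on_planted_fixture(fig9):
    ref = Annotation("ref", list(fig9))
    grid = [0.0, 0.3, 0.5, 0.8, 2.0]
    pts = threshold_sweep(fig9, ref, IRParams(), "cr", grid)
    kept_sizes = [p.n_kept for p in pts]
    assert kept_sizes == sorted(kept_sizes)  # flagged set shrinks as cr rises
    matches = [p.n_matching for p in pts]
    assert matches == sorted(matches)


def test_lr_one_with_partial_only_flags_only_full_overlaps(fig9):
    pts = threshold_sweep(
        fig9,
        Annotation("ref", list(fig9)),
        IRParams(entire_enabled=False),
        "lr",
        [1.0],
    )
    # nothing in the fixture overlaps an intron completely with a terminal exon
    assert pts[0].n_flagged == 0
    assert pts[0].n_kept == 4


def test_filtering_never_increases_match_counts():
    rng = random.Random(55)
    ref = random_assembly(rng, 40, name="ref")
    asm = random_assembly(rng, 60, name="asm")
    rep_full = match(asm, ref)
    _, kept = partition(asm, IRParams())
    rep_kept = match(kept, ref)
    assert rep_kept.n_matching <= rep_full.n_matching
    assert len(kept) <= len(asm)


def test_bad_vary_rejected(fig9):
    with pytest.raises(ValueError):
        threshold_sweep(fig9, fig9, IRParams(), "xx", [0.1])
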