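"""Deterministic synthetic annotations and assemblies.

Everything in this package is testable without downloading real annotation
releases: this module builds

* two small worked-example fixtures — an annotation pair whose three-level
  Jaccard similarities are exactly 5/6 (boundary), 5/8 (junction) and 1/3
  (intron chain), and a four-transcript assembly in which one transcript
  triggers each intron-retention criterion against a shared high-abundance
  reference;
* seeded simulators for annotation pairs with known per-level Jaccard
  (:func:`simulate_annotation_pair`) and for assemblies with geometrically
  planted intron-retention events carrying exact truth labels
  (:func:`simulate_assembly_with_ir`).

Construction is the oracle: the generators compute the expected Jaccard
values and truth labels from the raw coordinates they emit, with plain set
arithmetic, independent of the model code under test.  Genes are placed in
disjoint coordinate windows so no cross-gene structure arises by accident.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction

from .model import Annotation, Transcript

__all__ = [
    "SimSpec",
    "make_fig8_fixture",
    "make_fig9_fixture",
    "simulate_annotation_pair",
    "simulate_assembly_with_ir",
]

_WINDOW = 100_000


def transcript_from_introns(
    transcript_id: str,
    gene_id: str,
    introns: list[tuple[int, int]],
    pad: int = 50,
    chrom: str = "chr1",
    strand: str = "+",
    abundance: float | None = None,
    biotype: str = "",
) -> Transcript:
    """Build a transcript whose intron list is exactly ``introns``.

    Terminal exons extend ``pad`` bases beyond the outermost introns;
    internal exons fill the gaps between consecutive introns.
    """
    if not introns:
        raise ValueError("need at least one intron; use Transcript directly for single-exon")
    introns = sorted(introns)
    exons = [(introns[0][0] - pad, introns[0][0] - 1)]
    for (_, b1), (a2, _) in zip(introns, introns[1:]):
        exons.append((b1 + 1, a2 - 1))
    exons.append((introns[-1][1] + 1, introns[-1][1] + pad))
    return Transcript(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        abundance=abundance,
        biotype=biotype,
    )


def make_fig8_fixture() -> tuple[Annotation, Annotation]:
    """Two toy annotations with Jaccard 5/6, 5/8, 1/3 at the boundary,
    junction, and intron-chain level.

    Two gene loci.  At the first locus the annotations disagree on one
    acceptor of the last junction of one transcript; at the second they
    agree on a two-junction transcript but disagree on the second isoform
    (retained middle exon vs truncated form).  Counting distinct elements:
    boundaries 10 shared / 12 total, junctions 5/8, chains 2/6.
    """
    g1 = [
        transcript_from_introns("T1.A", "T1G1", [(70, 250), (610, 730), (820, 910)]),
        transcript_from_introns("T1.B", "T1G1", [(430, 730)]),
    ]
    g2 = [
        transcript_from_introns("T1.C", "T1G2", [(2580, 2610), (2790, 2850)]),
        transcript_from_introns("T1.D", "T1G2", [(2580, 2850)]),
    ]
    h1 = [
        transcript_from_introns("T2.A", "T2G1", [(70, 250), (610, 730), (790, 910)]),
        transcript_from_introns("T2.B", "T2G1", [(430, 730)]),
    ]
    h2 = [
        transcript_from_introns("T2.C", "T2G2", [(2580, 2610), (2790, 2850)]),
        transcript_from_introns("T2.D", "T2G2", [(2580, 2610)]),
    ]
    return Annotation("toy-T1", g1 + g2), Annotation("toy-T2", h1 + h2)


def make_fig9_fixture() -> Annotation:
    """A four-transcript assembly: one per intron-retention criterion.

    ``t1`` is the high-abundance reference (5 exons, 4 introns).  ``t2``'s
    first exon starts inside t1's second intron and runs into the next
    exon (criterion 1); ``t3``'s last exon runs into t1's fourth intron
    (criterion 2); ``t4``'s second exon fully covers t1's second intron
    (criterion 3).  All abundance ratios against t1 are 0.6, above the
    default coverage-ratio threshold.  Both partial overlaps cover ~51% of
    their intron, so a length-ratio threshold of 0.6 suppresses them.
    """

    def mk(tid: str, exons, cov: float) -> Transcript:
        return Transcript(
            transcript_id=tid,
            gene_id="fig9g",
            chrom="chr1",
            strand="+",
            exons=tuple(exons),
            abundance=cov,
        )

    t1 = mk("t1", [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)], 10.0)
    t2 = mk("t2", [(450, 600), (700, 800), (900, 1000)], 6.0)
    t3 = mk("t3", [(100, 200), (300, 400), (500, 600), (700, 850)], 6.0)
    t4 = mk("t4", [(100, 200), (300, 550), (700, 800)], 6.0)
    return Annotation("toy-assembly", [t1, t2, t3, t4])


@dataclass
class SimSpec:
    """Parameters for the seeded simulators.

    ``fraction_shared`` maps level name to the target fraction of gene
    windows shared at that level between the generated pair; sharing at a
    finer level implies sharing at the coarser ones, so the fractions must
    satisfy chain <= junction <= boundary.  ``ir_plant`` lists intron
    retention events to plant, each a ``(criterion, abundance_ratio)``
    pair with ``abundance_ratio = p(reference)/p(candidate)``.
    """

    seed: int = 0
    n_genes: int = 10
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (50, 300)
    intron_length: tuple[int, int] = (60, 500)
    fraction_shared: dict[str, float] = field(
        default_factory=lambda: {"boundary": 0.6, "junction": 0.5, "intron_chain": 0.3}
    )
    ir_plant: list[tuple[int, float]] = field(default_factory=list)

    def validate(self) -> None:
        for lo, hi in (
            self.transcripts_per_gene,
            self.exons_per_transcript,
            self.exon_length,
            self.intron_length,
        ):
            if lo < 1 or hi < lo:
                raise ValueError(f"bad range ({lo}, {hi})")
        if self.exon_length[0] < 2 or self.intron_length[0] < 4:
            raise ValueError("exon length must be >= 2 and intron length >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        fb = self.fraction_shared.get("boundary", 0.0)
        fj = self.fraction_shared.get("junction", 0.0)
        fc = self.fraction_shared.get("intron_chain", 0.0)
        for f in (fb, fj, fc):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if not fc <= fj <= fb:
            raise ValueError(
                "infeasible sharing targets: need intron_chain <= junction <= boundary"
            )
        for crit, ratio in self.ir_plant:
            if crit not in (1, 2, 3):
                raise ValueError(f"unknown criterion {crit}")
            if ratio < 0:
                raise ValueError("abundance_ratio must be >= 0")

    @classmethod
    def from_json(cls, path: str) -> "SimSpec":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("transcripts_per_gene", "exons_per_transcript", "exon_length", "intron_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "ir_plant" in raw:
            raw["ir_plant"] = [tuple(ev) for ev in raw["ir_plant"]]
        spec = cls(**raw)
        spec.validate()
        return spec


def _random_chain(
    rng: random.Random, spec: SimSpec, offset: int, n_introns: int | None = None
) -> list[tuple[int, int]]:
    """A random intron list inside the window starting at ``offset``."""
    if n_introns is None:
        n_introns = rng.randint(*spec.exons_per_transcript) - 1
    n_introns = max(1, n_introns)
    pos = offset + rng.randint(*spec.exon_length)
    introns = []
    for _ in range(n_introns):
        a = pos + 1
        b = a + rng.randint(*spec.intron_length) - 1
        introns.append((a, b))
        pos = b + rng.randint(*spec.exon_length)
    return introns


def _raw_sets(chains: list[tuple[tuple[int, int], ...]]):
    B: set[int] = set()
    J: set[tuple[int, int]] = set()
    C: set[tuple[tuple[int, int], ...]] = set()
    for ch in chains:
        C.add(tuple(ch))
        for a, b in ch:
            J.add((a, b))
            B.update((a, b))
    return B, J, C


def simulate_annotation_pair(
    spec: SimSpec,
) -> tuple[Annotation, Annotation, dict[str, float]]:
    """A seeded annotation pair with exactly known per-level Jaccard.

    Gene windows are assigned to four motifs according to
    ``fraction_shared``: *identical* (same transcripts both sides — shared
    at every level), *junction-shared* (same junction set, different chain
    partition), *boundary-shared* (two junctions on one side vs one
    spanning junction on the other, sharing the outer boundaries only),
    and *private* (one side only, alternating).  The returned ``truth``
    maps each level to the Jaccard value implied by the emitted raw
    coordinates, computed with plain set arithmetic.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    n = spec.n_genes
    fb = spec.fraction_shared.get("boundary", 0.0)
    fj = spec.fraction_shared.get("junction", 0.0)
    fc = spec.fraction_shared.get("intron_chain", 0.0)
    n_ident = round(fc * n)
    n_junc = round(fj * n) - n_ident
    n_bound = round(fb * n) - n_ident - n_junc
    motifs = (
        ["identical"] * n_ident
        + ["junction"] * n_junc
        + ["boundary"] * n_bound
        + ["private"] * (n - n_ident - n_junc - n_bound)
    )

    tx1: list[Transcript] = []
    tx2: list[Transcript] = []
    chains1: list[tuple[tuple[int, int], ...]] = []
    chains2: list[tuple[tuple[int, int], ...]] = []

    def emit(side: int, gid: str, tid: str, introns: list[tuple[int, int]]) -> None:
        t = transcript_from_introns(tid, gid, introns, pad=rng.randint(*spec.exon_length))
        (tx1 if side == 1 else tx2).append(t)
        (chains1 if side == 1 else chains2).append(tuple(sorted(introns)))

    for w, motif in enumerate(motifs):
        offset = (w + 1) * _WINDOW
        gid1, gid2 = f"simg{w}.a", f"simg{w}.b"
        if motif == "identical":
            m = rng.randint(*spec.transcripts_per_gene)
            for k in range(m):
                introns = _random_chain(rng, spec, offset)
                emit(1, gid1, f"sim{w}.t{k}.a", introns)
                emit(2, gid2, f"sim{w}.t{k}.b", introns)
        elif motif == "junction":
            introns = _random_chain(rng, spec, offset, n_introns=max(
                2, rng.randint(*spec.exons_per_transcript) - 1))
            emit(1, gid1, f"sim{w}.t0.a", introns)
            emit(2, gid2, f"sim{w}.t0.b", introns[:-1])
            emit(2, gid2, f"sim{w}.t1.b", introns[-1:])
        elif motif == "boundary":
            introns = _random_chain(rng, spec, offset, n_introns=2)
            emit(1, gid1, f"sim{w}.t0.a", introns)
            emit(2, gid2, f"sim{w}.t0.b", [(introns[0][0], introns[1][1])])
        else:  # private
            side = 1 if w % 2 == 0 else 2
            m = rng.randint(*spec.transcripts_per_gene)
            for k in range(m):
                introns = _random_chain(rng, spec, offset)
                emit(side, gid1 if side == 1 else gid2, f"sim{w}.t{k}", introns)

    B1, J1, C1 = _raw_sets(chains1)
    B2, J2, C2 = _raw_sets(chains2)

    def jac(a: set, b: set) -> float:
        u = a | b
        return len(a & b) / len(u) if u else float("nan")

    truth = {
        "boundary": jac(B1, B2),
        "junction": jac(J1, J2),
        "intron_chain": jac(C1, C2),
    }
    return Annotation("sim-T1", tx1), Annotation("sim-T2", tx2), truth


def _plant_event(
    rng: random.Random, spec: SimSpec, offset: int, idx: int, criterion: int, ratio: float
) -> tuple[list[Transcript], dict]:
    """One reference + one candidate in a private window.

    The reference has five exons; the candidate's geometry satisfies
    exactly the requested criterion against it (terminal exon midway into
    the retained intron for criteria 1-2, full containment for 3), and the
    abundances realise ``p(reference)/p(candidate) = ratio``.
    """
    # five exons e0..e4, four introns I0..I3
    bounds: list[tuple[int, int]] = []
    pos = offset
    exons: list[tuple[int, int]] = []
    for _ in range(5):
        a = pos + 1
        b = a + rng.randint(*spec.exon_length) - 1
        exons.append((a, b))
        pos = b + rng.randint(*spec.intron_length)
    introns = [(b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(exons, exons[1:])]

    p_t = 20.0
    p_r = round(ratio * p_t, 6)
    rid, tid = f"plant{idx}.ref", f"plant{idx}.t"
    gid = f"plantg{idx}"

    if criterion == 1:
        a, b = introns[1]
        s = a + (b - a + 1) // 2  # strictly inside the intron
        cand_exons = [(s, exons[2][1])] + exons[3:]
    elif criterion == 2:
        a, b = introns[2]
        e = a + (b - a + 1) // 2 - 1
        e = max(a, min(e, b - 1))  # a <= e < b
        cand_exons = exons[:2] + [(exons[2][0], e)]
    else:  # criterion 3: exon spanning e1..e2 covers intron I1
        cand_exons = [exons[0], (exons[1][0], exons[2][1])] + exons[3:]

    ref = Transcript(rid, gid, "chr1", "+", tuple(exons), abundance=p_r)
    cand = Transcript(tid, gid, "chr1", "+", tuple(cand_exons), abundance=p_t)
    truth = {
        "criterion": criterion,
        "ratio": ratio,
        "reference": rid,
    }
    return [ref, cand], truth


def simulate_assembly_with_ir(
    spec: SimSpec,
) -> tuple[Annotation, dict[str, dict | None]]:
    """A seeded assembly with geometrically planted intron-retention events.

    Each ``(criterion, ratio)`` entry of ``spec.ir_plant`` produces, in its
    own window, a five-exon reference and a candidate transcript satisfying
    exactly that criterion, with ``p(reference)/p(candidate) = ratio``.
    ``spec.n_genes`` additional clean one-transcript genes are emitted as
    decoys.  The truth map assigns each planted candidate its event record
    and every other transcript ``None`` (not retained); recovery at a
    coverage-ratio threshold ``cr`` is expected exactly for events with
    ``ratio >= cr``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    transcripts: list[Transcript] = []
    truth: dict[str, dict | None] = {}

    for i, (crit, ratio) in enumerate(spec.ir_plant):
        offset = (i + 1) * _WINDOW
        txs, ev = _plant_event(rng, spec, offset, i, crit, ratio)
        transcripts.extend(txs)
        truth[txs[0].transcript_id] = None
        truth[txs[1].transcript_id] = ev

    base = (len(spec.ir_plant) + 1) * _WINDOW
    for w in range(spec.n_genes):
        offset = base + (w + 1) * _WINDOW
        introns = _random_chain(rng, spec, offset)
        t = transcript_from_introns(
            f"decoy{w}.t0",
            f"decoyg{w}",
            introns,
            pad=rng.randint(*spec.exon_length),
            abundance=round(rng.uniform(1, 50), 3),
        )
        transcripts.append(t)
        truth[t.transcript_id] = None

    return Annotation("sim-assembly", transcripts), truth


FIG8_EXPECTED = {
    "boundary": Fraction(5, 6),
    "junction": Fraction(5, 8),
    "intron_chain": Fraction(1, 3),
}
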