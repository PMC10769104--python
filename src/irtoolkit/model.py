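"""Core domain model for transcript annotations.

A transcript is an ordered run of exons on one chromosome strand; the gaps
between consecutive exons are its introns.  Three derived structures drive
everything else in this package:

* **boundaries** ``B(t)`` — the genomic coordinates where an exon meets an
  intron (splice-site positions, i.e. the endpoints of the introns);
* **junctions** ``J(t)`` — the introns themselves, each expressed as its
  pair of boundary coordinates;
* **intron chain** ``C(t)`` — the ordered tuple of all junctions of a
  multi-exon transcript.  Two transcripts "match" structurally exactly when
  their chains are coordinate-identical.

Transcript start/end positions are *not* boundaries: only splice-adjacent
positions count.  Single-exon transcripts are kept in the model (the
assembly-evaluation code needs them) but contribute nothing to B/J/C.

All coordinates are 1-based inclusive, matching GTF on disk.  An intron
between exons ``[.., e]`` and ``[s, ..]`` is ``[e + 1, s - 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from intervaltree import IntervalTree

__all__ = [
    "Boundary",
    "Junction",
    "IntronChain",
    "Transcript",
    "Gene",
    "Annotation",
    "boundary_set",
    "junction_set",
    "chain_set",
]


class Boundary(NamedTuple):
    """A splice-site coordinate: an endpoint of some intron."""

    chrom: str
    strand: str
    pos: int


class Junction(NamedTuple):
    """An intron expressed as its pair of boundary coordinates (inclusive)."""

    chrom: str
    strand: str
    start: int
    end: int


class IntronChain(NamedTuple):
    """The full ordered junction tuple of a multi-exon transcript."""

    chrom: str
    strand: str
    junctions: tuple[Junction, ...]


def _stranded(strand: str, ignore_strand: bool) -> str:
    return "." if ignore_strand else strand


@dataclass
class Transcript:
    """One transcript: sorted exons plus identity, abundance and biotype.

    ``abundance`` is the assembler-predicted expression level (``None`` when
    the source annotation carries none); ``biotype`` is the functional
    category tag (empty when absent).  ``attributes`` preserves the raw GTF
    attribute text of the transcript record so unmodified records round-trip
    byte-identically; ``exon_attributes`` does the same per exon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    abundance: float | None = None
    biotype: str = ""
    source: str = "irtoolkit"
    attributes: str | None = None
    exon_attributes: tuple[str, ...] | None = None
    score: str = "."
    frame: str = "."
    exon_scores: tuple[str, ...] | None = None
    exon_frames: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.exons = tuple((int(a), int(b)) for a, b in self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        for a, b in self.exons:
            if a < 1 or b < a:
                raise ValueError(
                    f"transcript {self.transcript_id}: malformed exon [{a},{b}]"
                )
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 - b1 < 2:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons not separated "
                    f"by >=1 bp gap near position {b1}"
                )
        if self.abundance is not None and self.abundance < 0:
            raise ValueError(
                f"transcript {self.transcript_id}: negative abundance {self.abundance}"
            )

    # -- derived structure ------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def introns(self) -> tuple[tuple[int, int], ...]:
        """The k-1 gaps between the k exons, as 1-based inclusive intervals."""
        return tuple(
            (b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        )

    def junctions(self, ignore_strand: bool = False) -> frozenset[Junction]:
        s = _stranded(self.strand, ignore_strand)
        return frozenset(Junction(self.chrom, s, a, b) for a, b in self.introns())

    def boundaries(self, ignore_strand: bool = False) -> frozenset[Boundary]:
        s = _stranded(self.strand, ignore_strand)
        return frozenset(
            Boundary(self.chrom, s, p) for a, b in self.introns() for p in (a, b)
        )

    def chain(self, ignore_strand: bool = False) -> IntronChain | None:
        """The intron chain; ``None`` for single-exon transcripts."""
        if not self.is_multi_exon:
            return None
        s = _stranded(self.strand, ignore_strand)
        return IntronChain(
            self.chrom,
            s,
            tuple(Junction(self.chrom, s, a, b) for a, b in self.introns()),
        )


@dataclass
class Gene:
    """A set of transcripts sharing one gene id.

    The gene-level B/J/C sets are unions over member transcripts; only
    multi-exon transcripts contribute.
    """

    gene_id: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} has gene_id {t.gene_id!r}, "
                    f"expected {self.gene_id!r}"
                )

    @property
    def is_multi_exon(self) -> bool:
        """True when at least one member transcript is multi-exon."""
        return any(t.is_multi_exon for t in self.transcripts)

    def boundaries(self, ignore_strand: bool = False) -> frozenset[Boundary]:
        out: set[Boundary] = set()
        for t in self.transcripts:
            out |= t.boundaries(ignore_strand)
        return frozenset(out)

    def junctions(self, ignore_strand: bool = False) -> frozenset[Junction]:
        out: set[Junction] = set()
        for t in self.transcripts:
            out |= t.junctions(ignore_strand)
        return frozenset(out)

    def chains(self, ignore_strand: bool = False) -> frozenset[IntronChain]:
        return frozenset(
            c for t in self.transcripts if (c := t.chain(ignore_strand)) is not None
        )


class Annotation:
    """A named collection of genes/transcripts with lookup indexes.

    Indexes (built lazily, invalidated on mutation):

    * ``chain_index`` — intron chain -> transcript ids (exact structural
      lookup, the basis of chain matching);
    * per ``(chrom, strand)`` interval trees over transcript spans, for
      overlap queries.
    """

    def __init__(self, name: str, transcripts: Iterable[Transcript] = ()) -> None:
        self.name = name
        self._transcripts: dict[str, Transcript] = {}
        self._chain_index: dict[IntronChain, list[str]] | None = None
        self._trees: dict[tuple[str, str], IntervalTree] | None = None
        for t in transcripts:
            self.add(t)

    # -- container protocol ----------------------------------------------

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._transcripts[transcript_id]

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self._chain_index = None
        self._trees = None

    @property
    def transcripts(self) -> list[Transcript]:
        return list(self._transcripts.values())

    @property
    def genes(self) -> dict[str, Gene]:
        out: dict[str, Gene] = {}
        for t in self._transcripts.values():
            out.setdefault(t.gene_id, Gene(t.gene_id)).transcripts.append(t)
        return out

    # -- indexes ----------------------------------------------------------

    @property
    def chain_index(self) -> dict[IntronChain, list[str]]:
        if self._chain_index is None:
            idx: dict[IntronChain, list[str]] = {}
            for t in self._transcripts.values():
                c = t.chain()
                if c is not None:
                    idx.setdefault(c, []).append(t.transcript_id)
            self._chain_index = idx
        return self._chain_index

    def _interval_trees(self) -> dict[tuple[str, str], IntervalTree]:
        if self._trees is None:
            trees: dict[tuple[str, str], IntervalTree] = {}
            for t in self._transcripts.values():
                lo, hi = t.span
                trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
                    lo, hi + 1, t.transcript_id
                )
            self._trees = trees
        return self._trees

    def overlapping(
        self, chrom: str, strand: str, start: int, end: int, ignore_strand: bool = False
    ) -> list[Transcript]:
        """Transcripts whose span overlaps ``[start, end]`` on ``chrom``.

        Strand-aware by default; with ``ignore_strand`` all strands are
        searched.  A strand of ``"."`` only ever matches ``"."`` unless
        ``ignore_strand`` is set.
        """
        trees = self._interval_trees()
        strands = ("+", "-", ".") if ignore_strand else (strand,)
        hits: list[Transcript] = []
        for s in strands:
            tree = trees.get((chrom, s))
            if tree is None:
                continue
            hits.extend(self._transcripts[iv.data] for iv in tree.overlap(start, end + 1))
        hits.sort(key=lambda t: t.transcript_id)
        return hits

    # -- derived sets ------------------------------------------------------

    def boundaries(self, ignore_strand: bool = False) -> frozenset[Boundary]:
        out: set[Boundary] = set()
        for t in self._transcripts.values():
            out |= t.boundaries(ignore_strand)
        return frozenset(out)

    def junctions(self, ignore_strand: bool = False) -> frozenset[Junction]:
        out: set[Junction] = set()
        for t in self._transcripts.values():
            out |= t.junctions(ignore_strand)
        return frozenset(out)

    def chains(self, ignore_strand: bool = False) -> frozenset[IntronChain]:
        return frozenset(
            c
            for t in self._transcripts.values()
            if (c := t.chain(ignore_strand)) is not None
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Annotation({self.name!r}, {len(self)} transcripts)"


def boundary_set(
    x: Transcript | Gene | Annotation, ignore_strand: bool = False
) -> frozenset[Boundary]:
    """B(x): the union of intron-endpoint coordinates of ``x``."""
    return x.boundaries(ignore_strand)


def junction_set(
    x: Transcript | Gene | Annotation, ignore_strand: bool = False
) -> frozenset[Junction]:
    """J(x): the union of introns of ``x``, as boundary pairs."""
    return x.junctions(ignore_strand)


def chain_set(
    x: Transcript | Gene | Annotation, ignore_strand: bool = False
) -> frozenset[IntronChain]:
    """C(x): the set of distinct intron chains of ``x`` (multi-exon only)."""
    if isinstance(x, Transcript):
        c = x.chain(ignore_strand)
        return frozenset(() if c is None else (c,))
    return x.chains(ignore_strand)
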