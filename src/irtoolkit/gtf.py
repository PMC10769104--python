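"""GTF reading and writing.

Tolerates the attribute dialects produced by Ensembl, RefSeq, CHM13 and by
the StringTie / Scallop family of assemblers.  The raw attribute text of
every record is preserved, so records the toolkit does not modify round-trip
byte-identically.

The parser is deliberately small and stream-oriented: it keeps the original
attribute strings (which column-oriented GTF loaders discard) and never
touches the filesystem beyond the one file it is given.  Gzip-compressed
input is accepted transparently.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .model import Annotation, Transcript

__all__ = [
    "GtfRecord",
    "GtfFormatError",
    "ParseSummary",
    "DEFAULT_ABUNDANCE_KEYS",
    "DEFAULT_BIOTYPE_KEYS",
    "read_annotation",
    "write_annotation",
]

logger = logging.getLogger(__name__)

#: Attribute names probed, in order, for a transcript's abundance.  Covers
#: StringTie (cov/FPKM/TPM) and Scallop (cov/RPKM) outputs.
DEFAULT_ABUNDANCE_KEYS: tuple[str, ...] = ("cov", "FPKM", "TPM", "RPKM")

#: Attribute names probed, in order, for a transcript's biotype
#: (Ensembl vs GENCODE dialects).
DEFAULT_BIOTYPE_KEYS: tuple[str, ...] = ("transcript_biotype", "transcript_type")

_ATTR_RE = re.compile(r'(\S+)\s+"((?:[^"\\]|\\.)*)"\s*;')


class GtfFormatError(ValueError):
    """Raised for records that violate the GTF contract."""


@dataclass
class GtfRecord:
    """One parsed GTF feature line.

    ``attributes`` maps key -> value in file order; ``attribute_text`` is the
    verbatim ninth column, kept for byte-faithful output.
    """

    chrom: str
    source: str
    feature: str
    start: int
    end: int
    score: str
    strand: str
    frame: str
    attributes: dict[str, str]
    attribute_text: str

    @classmethod
    def parse(cls, line: str, lineno: int) -> "GtfRecord":
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise GtfFormatError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise GtfFormatError(f"line {lineno}: non-integer coordinates") from exc
        if start < 1 or end < start:
            raise GtfFormatError(f"line {lineno}: bad interval [{start},{end}]")
        attrs = {m.group(1): m.group(2) for m in _ATTR_RE.finditer(cols[8])}
        return cls(
            chrom=cols[0],
            source=cols[1],
            feature=cols[2],
            start=start,
            end=end,
            score=cols[5],
            strand=cols[6] if cols[6] in ("+", "-", ".") else ".",
            frame=cols[7],
            attributes=attrs,
            attribute_text=cols[8],
        )


@dataclass
class ParseSummary:
    """Bookkeeping from one :func:`read_annotation` call."""

    n_transcript_records: int = 0
    n_exon_records: int = 0
    n_other_records: int = 0
    merged_adjacent: list[str] = field(default_factory=list)
    repaired: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _first_present(attrs: dict[str, str], keys: Iterable[str]) -> str | None:
    for k in keys:
        if k in attrs:
            return attrs[k]
    return None


def _normalise_exons(
    tid: str,
    exons: list[tuple],
    on_malformed: str,
    summary: ParseSummary,
) -> list[tuple] | None:
    """Sort exons; merge zero-gap/overlapping ones or drop the transcript.

    Exactly adjacent exons (gap 0) are always merged — a zero-length intron
    is meaningless.  Overlapping exons are merged when ``on_malformed`` is
    ``"repair"``; with ``"drop"`` the transcript is discarded.  Returns the
    cleaned exon list or ``None`` if the transcript was dropped.
    """
    exons = sorted(exons)
    out = [exons[0]]
    for a, b, *rest in exons[1:]:
        pa, pb, *prest = out[-1]
        if a - pb >= 2:
            out.append((a, b, *rest))
            continue
        if a - pb == 1:  # exactly adjacent: merge, keep first exon's attributes
            summary.merged_adjacent.append(tid)
            logger.warning("transcript %s: merging exactly adjacent exons at %d", tid, pb)
            out[-1] = (pa, max(pb, b), *prest)
            continue
        # overlapping (or duplicate) exons
        if on_malformed == "repair":
            summary.repaired.append(tid)
            logger.warning("transcript %s: merging overlapping exons at %d", tid, a)
            out[-1] = (pa, max(pb, b), *prest)
        elif on_malformed == "drop":
            summary.dropped.append(tid)
            logger.warning("transcript %s: dropped (overlapping exons)", tid)
            return None
        else:
            raise ValueError(f"on_malformed must be 'repair' or 'drop', got {on_malformed!r}")
    return out


def read_annotation(
    path: str | Path,
    abundance_keys: Iterable[str] = DEFAULT_ABUNDANCE_KEYS,
    biotype_keys: Iterable[str] = DEFAULT_BIOTYPE_KEYS,
    name: str | None = None,
    on_malformed: str = "repair",
    return_summary: bool = False,
) -> Annotation | tuple[Annotation, ParseSummary]:
    """Parse a GTF file into an :class:`~irtoolkit.model.Annotation`.

    Parameters
    ----------
    path:
        GTF file, optionally gzip-compressed.
    abundance_keys:
        Attribute names probed in order for the transcript abundance; the
        first present wins.  Absent -> abundance recorded as unknown.
    biotype_keys:
        Attribute names probed in order for the biotype; absent -> empty.
    on_malformed:
        ``"repair"`` merges overlapping exons, ``"drop"`` discards the
        transcript.  Exactly adjacent exons are always merged.
    return_summary:
        Also return a :class:`ParseSummary` with record counts and the ids
        of repaired/merged/dropped transcripts.
    """
    abundance_keys = tuple(abundance_keys)
    biotype_keys = tuple(biotype_keys)
    summary = ParseSummary()
    # transcript_id -> list of (start, end, attr_text, score, frame)
    exons: dict[str, list[tuple]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = GtfRecord.parse(line, lineno)
            if rec.feature == "exon":
                tid = rec.attributes.get("transcript_id")
                if tid is None:
                    raise GtfFormatError(f"line {lineno}: exon record without transcript_id")
                gid = rec.attributes.get("gene_id", tid)
                summary.n_exon_records += 1
                if tid not in meta:
                    order.append(tid)
                    meta[tid] = {
                        "gene_id": gid,
                        "chrom": rec.chrom,
                        "strand": rec.strand,
                        "source": rec.source,
                        "attributes": None,
                        "attrs_from_exon": rec.attributes,
                    }
                exons.setdefault(tid, []).append(
                    (rec.start, rec.end, rec.attribute_text, rec.score, rec.frame)
                )
            elif rec.feature == "transcript":
                tid = rec.attributes.get("transcript_id")
                if tid is None:
                    raise GtfFormatError(f"line {lineno}: transcript record without transcript_id")
                summary.n_transcript_records += 1
                if tid not in meta:
                    order.append(tid)
                    meta[tid] = {}
                meta[tid].update(
                    gene_id=rec.attributes.get("gene_id", tid),
                    chrom=rec.chrom,
                    strand=rec.strand,
                    source=rec.source,
                    attributes=rec.attribute_text,
                    attrs=rec.attributes,
                    score=rec.score,
                    frame=rec.frame,
                )
            else:
                summary.n_other_records += 1

    transcripts: list[Transcript] = []
    for tid in order:
        info = meta[tid]
        if tid not in exons:
            logger.warning("transcript %s: no exon records; skipped", tid)
            continue
        cleaned = _normalise_exons(tid, exons[tid], on_malformed, summary)
        if cleaned is None:
            continue
        attrs = info.get("attrs") or info.get("attrs_from_exon") or {}
        raw_ab = _first_present(attrs, abundance_keys)
        try:
            abundance = float(raw_ab) if raw_ab is not None else None
        except ValueError:
            abundance = None
        biotype = _first_present(attrs, biotype_keys) or ""
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=info.get("gene_id", tid),
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple((e[0], e[1]) for e in cleaned),
                abundance=abundance,
                biotype=biotype,
                source=info.get("source", "irtoolkit"),
                attributes=info.get("attributes"),
                exon_attributes=tuple(e[2] for e in cleaned),
                score=info.get("score", "."),
                frame=info.get("frame", "."),
                exon_scores=tuple(e[3] for e in cleaned),
                exon_frames=tuple(e[4] for e in cleaned),
            )
        )

    ann = Annotation(name or str(path), transcripts)
    if return_summary:
        return ann, summary
    return ann


def _synth_attributes(t: Transcript) -> str:
    parts = [f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";']
    if t.abundance is not None:
        parts.append(f'cov "{t.abundance:g}";')
    if t.biotype:
        parts.append(f'transcript_biotype "{t.biotype}";')
    return " ".join(parts)


def write_annotation(ann: Annotation, path: str | Path) -> None:
    """Write ``ann`` as GTF: one transcript record, then its exon records.

    Original attribute text is emitted verbatim where the transcript came
    from a file; synthetic transcripts get a minimal attribute block that
    re-reads to an equal model.
    """
    path = Path(path)
    with open(path, "wt") as out:
        for t in ann:
            lo, hi = t.span
            tattrs = t.attributes if t.attributes is not None else _synth_attributes(t)
            out.write(
                f"{t.chrom}\t{t.source}\ttranscript\t{lo}\t{hi}\t{t.score}\t"
                f"{t.strand}\t{t.frame}\t{tattrs}\n"
            )
            for i, (a, b) in enumerate(t.exons):
                if t.exon_attributes is not None and i < len(t.exon_attributes):
                    eattrs = t.exon_attributes[i]
                else:
                    eattrs = _synth_attributes(t)
                score = t.exon_scores[i] if t.exon_scores and i < len(t.exon_scores) else "."
                frame = t.exon_frames[i] if t.exon_frames and i < len(t.exon_frames) else "."
                out.write(
                    f"{t.chrom}\t{t.source}\texon\t{a}\t{b}\t{score}\t"
                    f"{t.strand}\t{frame}\t{eattrs}\n"
                )
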