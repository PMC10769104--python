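"""Structural similarity between annotations.

Two annotations are compared by the Jaccard similarity of their boundary,
junction, and intron-chain sets:

    J_B(T1, T2) = |B(T1) & B(T2)| / |B(T1) | B(T2)|

and likewise ``J_J`` (junctions) and ``J_C`` (chains).  The boundary level
asks whether the same splice sites are annotated at all; the junction level
whether they are paired the same way; the chain level whether whole
transcript structures coincide.  Agreement can only fall as the level gets
more demanding.

Gene correspondence between two annotations is built structurally: two
multi-exon genes pair when they share at least one intron-exon boundary.
Each pair then gets its own three-level Jaccard, yielding per-gene-pair
similarity distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import Annotation, Gene, boundary_set, chain_set, junction_set

__all__ = [
    "LEVELS",
    "GenePair",
    "annotation_jaccard",
    "pair_genes",
    "gene_pair_jaccard",
    "jaccard_distribution",
    "validate_pairs_against_catalog",
]

LEVELS = ("boundary", "junction", "intron_chain")

_SET_FN = {
    "boundary": boundary_set,
    "junction": junction_set,
    "intron_chain": chain_set,
}


def _level_fn(level: str):
    if level not in _SET_FN:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    return _SET_FN[level]


def _jaccard(a: frozenset, b: frozenset) -> float | None:
    union = a | b
    if not union:
        return None  # undefined, reported as such rather than 0 or 1
    return len(a & b) / len(union)


def annotation_jaccard(
    T1: Annotation, T2: Annotation, level: str, ignore_strand: bool = False
) -> float | None:
    """Jaccard similarity of two annotations at one structural level.

    All multi-exon transcripts contribute (no gene pairing is involved);
    single-exon transcripts have no splice structure and are ignored.
    Returns ``None`` (undefined) when both sets are empty.
    """
    fn = _level_fn(level)
    return _jaccard(fn(T1, ignore_strand), fn(T2, ignore_strand))


@dataclass
class GenePair:
    """Two genes, one from each annotation, sharing >= 1 boundary."""

    gene_a: Gene
    gene_b: Gene
    jaccard: dict[str, float | None]

    @property
    def id_pair(self) -> tuple[str, str]:
        return self.gene_a.gene_id, self.gene_b.gene_id


def gene_pair_jaccard(pair: GenePair, level: str) -> float | None:
    """Per-pair Jaccard at one level (precomputed at construction)."""
    _level_fn(level)
    return pair.jaccard[level]


def _pair(ga: Gene, gb: Gene, ignore_strand: bool) -> GenePair:
    jac = {
        level: _jaccard(
            _SET_FN[level](ga, ignore_strand), _SET_FN[level](gb, ignore_strand)
        )
        for level in LEVELS
    }
    return GenePair(ga, gb, jac)


def pair_genes(
    T1: Annotation, T2: Annotation, ignore_strand: bool = False
) -> list[GenePair]:
    """Construct gene correspondence: multi-exon genes of ``T1`` and ``T2``
    pair when their boundary sets intersect.

    One gene may appear in several pairs (rare in real annotations, since
    genes of one annotation seldom share splice sites).  Output is sorted by
    ``(gene_id_a, gene_id_b)`` for determinism.
    """
    genes2 = [g for g in T2.genes.values() if g.is_multi_exon]
    by_boundary: dict = {}
    for g in genes2:
        for b in g.boundaries(ignore_strand):
            by_boundary.setdefault(b, set()).add(g.gene_id)
    genes2_by_id = {g.gene_id: g for g in genes2}

    pairs: list[GenePair] = []
    for ga in T1.genes.values():
        if not ga.is_multi_exon:
            continue
        hits: set[str] = set()
        for b in ga.boundaries(ignore_strand):
            hits |= by_boundary.get(b, set())
        for gid in sorted(hits):
            pairs.append(_pair(ga, genes2_by_id[gid], ignore_strand))
    pairs.sort(key=lambda p: p.id_pair)
    return pairs


def jaccard_distribution(
    pairs: Sequence[GenePair], level: str, bins: int = 20
) -> tuple[np.ndarray, np.ndarray, dict[int, float]]:
    """Histogram and quartiles of per-pair Jaccard values at one level.

    Returns ``(counts, bin_edges, quartiles)`` where ``quartiles`` maps
    {25, 50, 75} to the nearest-rank percentile of the raw values (the
    value at rank ``ceil(p/100 * n)`` of the sorted sample — no
    interpolation).
    """
    if not pairs:
        raise ValueError("jaccard_distribution requires at least one gene pair")
    values = np.sort(
        np.array([v for p in pairs if (v := gene_pair_jaccard(p, level)) is not None])
    )
    if values.size == 0:
        raise ValueError(f"no defined Jaccard values at level {level!r}")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    n = values.size
    quartiles = {
        p: float(values[min(n - 1, max(0, int(np.ceil(p / 100 * n)) - 1))])
        for p in (25, 50, 75)
    }
    return counts, edges, quartiles


def validate_pairs_against_catalog(
    pairs: Iterable[GenePair], catalog: Iterable[tuple[str, str]]
) -> float:
    """Fraction of catalog gene-id pairs recovered by structural pairing.

    The catalog (e.g. a nomenclature-based gene correspondence) uses the
    same id namespaces as the two annotations.  Returns
    ``|catalog & constructed| / |catalog|``; an empty catalog is an error.
    """
    catalog_set = set(catalog)
    if not catalog_set:
        raise ValueError("empty catalog")
    constructed = {p.id_pair for p in pairs}
    return len(catalog_set & constructed) / len(catalog_set)
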