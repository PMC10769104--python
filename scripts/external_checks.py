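#!/usr/bin/env python
"""Whole-release annotation comparisons on locally downloaded GTFs.

These checks need real annotation releases (multi-GB downloads), so they
are not part of the default test suite.  Given two GTFs they compute the
three-level structural Jaccard and, optionally, the recovery of a
nomenclature gene-pair catalog by structural pairing.

Usage:
    python scripts/external_checks.py <ref.gtf[.gz]> <query.gtf[.gz]> \
        [--catalog pairs.tsv] [--out results.json]

The catalog TSV has two whitespace-separated gene-id columns using the
same id namespaces as the two GTFs (reference ids first).
"""

from __future__ import annotations

import argparse
import json
import sys

from irtoolkit.gtf import read_annotation
from irtoolkit.similarity import (
    LEVELS,
    annotation_jaccard,
    pair_genes,
    validate_pairs_against_catalog,
)


def main(argv: list[str] | None = None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("reference")
    ap.add_argument("query")
    ap.add_argument("--catalog", default=None,
                    help="TSV of known gene-id pairs (reference id, query id)")
    ap.add_argument("--out", default=None, help="write results JSON here")
    args = ap.parse_args(argv)

    print(f"reading {args.reference} ...", file=sys.stderr)
    ref = read_annotation(args.reference, name="reference")
    print(f"reading {args.query} ...", file=sys.stderr)
    qry = read_annotation(args.query, name="query")

    results: dict[str, float | None] = {}
    for lv in LEVELS:
        results[f"jaccard_{lv}"] = annotation_jaccard(ref, qry, lv)
        print(f"jaccard {lv}: {results[f'jaccard_{lv}']}", file=sys.stderr)

    if args.catalog:
        with open(args.catalog) as fh:
            catalog = [tuple(line.split()[:2]) for line in fh if line.strip()]
        pairs = pair_genes(ref, qry)
        results["n_gene_pairs"] = len(pairs)
        results["catalog_recovery"] = validate_pairs_against_catalog(pairs, catalog)
        print(f"catalog recovery: {results['catalog_recovery']:.4f} "
              f"({len(catalog)} catalog pairs, {len(pairs)} constructed)",
              file=sys.stderr)

    payload = json.dumps(results, indent=2)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(payload + "\n")
    print(payload)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
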