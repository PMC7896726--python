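"""Attach gene lists to called regions by interval overlap against GFF genes.

Overlap is any-bp on half-open intervals (the bedtools-intersect default):
a gene abutting a region's end coordinate is not reported.  Genes without a
symbol attribute are listed as ``"unknown"``; duplicate symbols from
distinct gene records are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .sync_io import Gene, Region


@dataclass
class AnnotatedRegion:
    region: Region
    genes: list[tuple[str, str]]  # (gene id, symbol-or-"unknown"), by gene start

    @property
    def symbols(self) -> list[str]:
        return [sym for _, sym in self.genes]


def genes_in_regions(regions: Sequence[Region], genes: Sequence[Gene]) -> list[AnnotatedRegion]:
    """List the genes overlapping each region by >= 1 bp, ordered by gene start."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out: list[AnnotatedRegion] = []
    for r in sorted(regions, key=Region.sort_key):
        hits = trees[r.chrom].overlap(r.start, r.end) if r.chrom in trees else ()
        ordered = sorted((iv.data for iv in hits), key=lambda g: (g.start, g.end, g.gene_id))
        out.append(AnnotatedRegion(
            r, [(g.gene_id, g.symbol if g.symbol else "unknown") for g in ordered]
        ))
    return out


def annotation_table(annotated: Sequence[AnnotatedRegion]) -> pd.DataFrame:
    """Region summary table: chrom, 1-based region string, length, gene symbols."""
    rows = []
    for a in annotated:
        r = a.region
        rows.append({
            "chrom": r.chrom,
            "region": f"{r.start + 1}-{r.end}",
            "length_bp": r.length,
            "genes": ", ".join(a.symbols),
        })
    return pd.DataFrame(rows, columns=["chrom", "region", "length_bp", "genes"])
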