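"""Selective-sweep calling from windowed counts of differentiated SNPs.

The scan lays fixed windows (default 100 kb, 50 kb step) on a genome-anchored
grid, counts SNPs with |dAF| above a threshold (default 0.6) per window,
extends qualifying windows (>= 10 such SNPs by default) by a flank (50 kb)
on each side, and merges overlapping-or-touching intervals into sweeps.
At the defaults an unclipped sweep is therefore never shorter than
window + 2*extension = 200 kb.

Also provides the generic interval algebra (merge, intersect) the rest of
the pipeline shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .allele_stats import DafTable
from .sync_io import Region, StructuralError

logger = logging.getLogger("poolscan")


@dataclass
class SweepParams:
    """Window geometry and thresholds of the sweep scan."""

    window_size: int = 100_000
    step: int = 50_000
    min_daf: float = 0.6
    min_snps: int = 10
    extension: int = 50_000
    signed: bool = False  # True: threshold signed dAF (contrast group only)

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step >= 1):
            raise StructuralError("require window_size >= step >= 1")
        if not (0 < self.min_daf <= 1):
            raise StructuralError("require 0 < min_daf <= 1")
        if self.min_snps < 1:
            raise StructuralError("require min_snps >= 1")
        if self.extension < 0:
            raise StructuralError("require extension >= 0")


def merge_regions(regions: Sequence[Region], merge_touching: bool = True) -> list[Region]:
    """Merge overlapping (and by default book-ended) intervals per chromosome.

    Labels of merged members are joined with ','; integer payloads are summed.
    """
    out: list[Region] = []
    for r in sorted(regions, key=Region.sort_key):
        if out and out[-1].chrom == r.chrom and (
            r.start < out[-1].end or (merge_touching and r.start == out[-1].end)
        ):
            prev = out[-1]
            labels = [x for x in (prev.label, r.label) if x]
            payload = None
            if prev.payload is not None or r.payload is not None:
                payload = (prev.payload or 0) + (r.payload or 0)
            out[-1] = Region(prev.chrom, prev.start, max(prev.end, r.end),
                             ",".join(dict.fromkeys(labels)), payload)
        else:
            out.append(Region(r.chrom, r.start, r.end, r.label, r.payload))
    return out


def intersect_regions(a: Sequence[Region], b: Sequence[Region]) -> list[Region]:
    """All maximal intervals covered by some region of ``a`` AND some of ``b``.

    Overlap must be >= 1 bp (half-open semantics).  Each output carries the
    labels of the two contributing regions joined with '|'.
    """
    by_chrom_b: dict[str, list[Region]] = {}
    for r in sorted(b, key=Region.sort_key):
        by_chrom_b.setdefault(r.chrom, []).append(r)
    pieces: list[Region] = []
    for ra in sorted(a, key=Region.sort_key):
        for rb in by_chrom_b.get(ra.chrom, ()):
            if rb.start >= ra.end:
                break
            lo, hi = max(ra.start, rb.start), min(ra.end, rb.end)
            if lo < hi:
                label = "|".join(x for x in (ra.label, rb.label) if x)
                pieces.append(Region(ra.chrom, lo, hi, label))
    # maximal intervals: merge overlapping-or-touching pieces
    return merge_regions(pieces, merge_touching=True)


def window_daf_counts(
    daf: DafTable,
    params: SweepParams,
    lengths: Mapping[str, int],
) -> list[tuple[Region, int]]:
    """Count differentiated SNPs per grid window.

    Windows start at multiples of ``step`` from coordinate 0 and are clipped
    at the chromosome end; a SNP is differentiated when |dAF| >= ``min_daf``
    (signed dAF >= min_daf with ``signed=True``).  Every chromosome of the
    input must have a known length.
    """
    chroms = sorted(set(daf.chrom.astype(str)))
    missing = [c for c in chroms if c not in lengths]
    if missing:
        raise StructuralError(f"chromosomes missing from lengths table: {missing}")
    val = daf.daf if params.signed else np.abs(daf.daf)
    hits_mask = val >= params.min_daf
    out: list[tuple[Region, int]] = []
    chrom_arr = daf.chrom.astype(str)
    for chrom in chroms:
        L = lengths[chrom]
        sel = chrom_arr == chrom
        hit_pos = np.sort(daf.pos[sel & hits_mask])
        for start in range(0, L, params.step):
            end = min(start + params.window_size, L)
            count = int(
                np.searchsorted(hit_pos, end, side="left")
                - np.searchsorted(hit_pos, start, side="left")
            )
            out.append((Region(chrom, start, end, "window"), count))
    return out


def call_sweeps(
    window_counts: Sequence[tuple[Region, int]],
    params: SweepParams,
    lengths: Mapping[str, int],
    daf: DafTable | None = None,
) -> list[Region]:
    """Extend qualifying windows and merge them into sweep regions.

    A window qualifies with count >= ``min_snps``; it is extended by
    ``extension`` on each side (clipped to [0, chrom length]) and
    overlapping-or-touching extended windows are merged.  The payload is the
    number of differentiated SNPs in the merged region — recounted exactly
    when ``daf`` is given, else the sum of the member windows' counts (which
    double-counts SNPs shared by overlapping windows).
    """
    extended = []
    for region, count in window_counts:
        if count >= params.min_snps:
            L = lengths[region.chrom]
            extended.append(Region(
                region.chrom,
                max(0, region.start - params.extension),
                min(L, region.end + params.extension),
                "sweep", count,
            ))
    sweeps = merge_regions(extended, merge_touching=True)
    sweeps = [Region(r.chrom, r.start, r.end, f"sweep_{i + 1}", r.payload)
              for i, r in enumerate(sweeps)]
    if daf is not None:
        val = daf.daf if params.signed else np.abs(daf.daf)
        chrom_arr = daf.chrom.astype(str)
        for i, r in enumerate(sweeps):
            sel = (chrom_arr == r.chrom) & (daf.pos >= r.start) & (daf.pos < r.end)
            sweeps[i] = Region(r.chrom, r.start, r.end, r.label,
                               int((val[sel] >= params.min_daf).sum()))
    logger.info("call_sweeps: %d qualifying windows -> %d sweeps", len(extended), len(sweeps))
    return sweeps


def scan_sweeps(
    daf: DafTable,
    params: SweepParams,
    lengths: Mapping[str, int],
) -> list[Region]:
    """Full scan: window counts then sweep calling with exact SNP payloads."""
    counts = window_daf_counts(daf, params, lengths)
    return call_sweeps(counts, params, lengths, daf=daf)
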