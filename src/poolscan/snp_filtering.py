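"""SNP filters reducing raw pooled counts to the analysis SNP table.

Two named filter stacks are used downstream:

* ``daf`` preset — biallelic + global minor-allele-count (MAC) + per-population
  depth floor + contig exclusion.  Feeds the allele-frequency differentiation
  (dAF) scan and the F_ST phylogeny.
* ``hp`` preset — the ``daf`` preset plus a per-population depth *band*
  filter (depth within one standard deviation of the modal depth), applied
  only for the pooled-heterozygosity branch where inconsistent coverage
  inflates variance.

Filters drop sites, never error; each logs input/output site counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sync_io import AlleleCountTable, GroupAssignment, StructuralError, merge_pools

logger = logging.getLogger("poolscan")


@dataclass
class SnpTable:
    """Filtered biallelic sites with per-population two-allele counts.

    ``counts`` has shape ``(n_sites, n_pops, 2)``; column 0 is ``allele1``
    (the global major allele), column 1 the global minor.  ``pos`` is 0-based.
    ``ref`` carries the reference base for reference-allele orientation.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    counts: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.pos)
        if self.counts.shape != (n, len(self.populations), 2):
            raise StructuralError("counts shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def depth(self) -> np.ndarray:
        """Per-site per-population depth = count1 + count2, shape (n, n_pops)."""
        return self.counts.sum(axis=2)

    def take(self, mask: np.ndarray) -> "SnpTable":
        return SnpTable(
            self.chrom[mask], self.pos[mask], self.ref[mask],
            self.allele1[mask], self.allele2[mask], self.counts[mask],
            list(self.populations),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos + 1,
            "allele1": self.allele1, "allele2": self.allele2, "ref": self.ref,
        })
        for j, p in enumerate(self.populations):
            df[f"count1_{p}"] = self.counts[:, j, 0]
            df[f"count2_{p}"] = self.counts[:, j, 1]
        return df

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    pops = [c[len("count1_"):] for c in df.columns if c.startswith("count1_")]
    counts = np.stack(
        [np.stack([df[f"count1_{p}"], df[f"count2_{p}"]], axis=1) for p in pops],
        axis=1,
    )
    return SnpTable(
        df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy() - 1,
        df["ref"].to_numpy(dtype=object),
        df["allele1"].to_numpy(dtype=object), df["allele2"].to_numpy(dtype=object),
        counts, pops,
    )


def call_biallelic_snps(
    table: AlleleCountTable,
    min_mac: int = 2,
    max_third_allele_count: int = 0,
) -> SnpTable:
    """Retain sites with exactly two observed alleles and global MAC >= ``min_mac``.

    Allele observation is judged on base counts (A/C/G/T) summed over all
    count blocks; N and deletion counts are ignored.  ``allele1`` is the base
    with the larger global count (ties broken lexicographically).  Sites whose
    third-largest global base count exceeds ``max_third_allele_count`` are
    dropped; the default 0 is the strict "exactly two alleles" reading.
    """
    n = table.n_sites
    if n == 0:
        return SnpTable(table.chrom, table.pos, table.ref,
                        np.empty(0, dtype=object), np.empty(0, dtype=object),
                        np.zeros((0, len(table.pool_names), 2), dtype=np.int64),
                        list(table.pool_names))
    global_counts = table.counts[:, :, :4].sum(axis=1)  # (n, 4) in A,T,C,G order
    # rank bases per site by (count desc, base asc) for deterministic ties
    base_order = np.array(list("ATCG"))
    lex_rank = np.argsort(np.argsort(base_order))  # alphabetical rank per slot: A=0,T=3,C=1,G=2
    # sort key: primary -count, secondary alphabetical
    order = np.lexsort((np.broadcast_to(lex_rank, (n, 4)), -global_counts), axis=1)
    top = np.take_along_axis(global_counts, order, axis=1)
    major_idx, minor_idx, third_idx = order[:, 0], order[:, 1], order[:, 2]
    # exactly two observed alleles: 2nd count positive and MAC-sufficient,
    # 3rd count at most the tolerated noise level (0 by default)
    keep = (top[:, 1] > 0) & (top[:, 1] >= min_mac) & (top[:, 2] <= max_third_allele_count)
    idx = np.flatnonzero(keep)
    counts = np.stack(
        [
            np.take_along_axis(table.counts[idx, :, :4], major_idx[idx, None, None], axis=2)[:, :, 0],
            np.take_along_axis(table.counts[idx, :, :4], minor_idx[idx, None, None], axis=2)[:, :, 0],
        ],
        axis=2,
    )
    result = SnpTable(
        table.chrom[idx], table.pos[idx], table.ref[idx],
        base_order[major_idx[idx]].astype(object), base_order[minor_idx[idx]].astype(object),
        counts, list(table.pool_names),
    )
    logger.info("call_biallelic_snps: %d -> %d sites (min_mac=%d)", n, result.n_sites, min_mac)
    return result


def filter_min_depth(snps: SnpTable, min_depth: int = 5) -> SnpTable:
    """Drop sites with depth below ``min_depth`` in *any* population."""
    keep = (snps.depth >= min_depth).all(axis=1)
    out = snps.take(keep)
    logger.info("filter_min_depth: %d -> %d sites (floor=%d)", snps.n_sites, out.n_sites, min_depth)
    return out


@dataclass
class DepthProfile:
    """Per-population modal depth and depth standard deviation."""

    peak: dict[str, int]
    sd: dict[str, float]


def depth_profile(snps: SnpTable) -> DepthProfile:
    """Modal depth (ties -> smaller depth) and population (ddof=0) sd per population."""
    if snps.n_sites == 0:
        raise StructuralError("depth_profile: empty SNP table")
    peak: dict[str, int] = {}
    sd: dict[str, float] = {}
    depths = snps.depth
    for j, pop in enumerate(snps.populations):
        d = depths[:, j]
        vals, counts = np.unique(d, return_counts=True)  # vals ascending
        peak[pop] = int(vals[np.argmax(counts)])  # argmax -> first max -> smallest depth
        sd[pop] = float(np.std(d))
    return DepthProfile(peak, sd)


def filter_depth_band(snps: SnpTable, profile: DepthProfile) -> SnpTable:
    """Keep sites with |depth - peak| <= sd in every population (band inclusive)."""
    keep = np.ones(snps.n_sites, dtype=bool)
    depths = snps.depth
    for j, pop in enumerate(snps.populations):
        keep &= np.abs(depths[:, j] - profile.peak[pop]) <= profile.sd[pop]
    out = snps.take(keep)
    logger.info("filter_depth_band: %d -> %d sites", snps.n_sites, out.n_sites)
    return out


def drop_contigs(snps: SnpTable, exclude_patterns: Sequence[str]) -> SnpTable:
    """Drop sites on contigs matching any exact name or name prefix."""
    if not exclude_patterns:
        return snps
    chroms = snps.chrom.astype(str)
    drop = np.zeros(snps.n_sites, dtype=bool)
    for pat in exclude_patterns:
        drop |= np.char.startswith(chroms, pat) | (chroms == pat)
    out = snps.take(~drop)
    logger.info("drop_contigs: %d -> %d sites (patterns=%s)", snps.n_sites, out.n_sites, list(exclude_patterns))
    return out


def apply_filter_preset(
    table: AlleleCountTable,
    assignment: GroupAssignment,
    preset: str = "daf",
    min_mac: int = 2,
    min_depth: int = 5,
    exclude_contigs: Sequence[str] = (),
    max_third_allele_count: int = 0,
) -> SnpTable:
    """Merge pools into populations and apply a named filter stack.

    ``preset="daf"``: biallelic/MAC -> depth floor -> contig exclusion.
    ``preset="hp"``: the above plus the depth-band filter.
    """
    if preset not in ("daf", "hp"):
        raise StructuralError(f"unknown preset {preset!r}")
    merged = merge_pools(table, assignment)
    snps = call_biallelic_snps(merged, min_mac=min_mac,
                               max_third_allele_count=max_third_allele_count)
    snps = filter_min_depth(snps, min_depth=min_depth)
    snps = drop_contigs(snps, exclude_contigs)
    if preset == "hp":
        snps = filter_depth_band(snps, depth_profile(snps))
    return snps
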