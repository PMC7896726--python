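"""Pooled heterozygosity (Hp) in 50 kb windows at 1 bp step, via segments.

Hp of a window is the mean over its SNPs of 2p(1-p), p being the global
major-allele frequency.  The scan uses *every* window start s with
[s, s + window) fully inside the chromosome.  Enumerating each start
explicitly is quadratic in genome size; instead, window starts are
partitioned into maximal runs ("segments") sharing an identical SNP set —
membership can only change at s = p - window + 1 and s = p + 1 for a SNP at
position p — and Hp is computed once per segment.  This is exact: a brute
force per-start enumeration gives identical values (asserted in tests).

Per population, Hp is standardized to ZHp = (Hp - mu)/sigma where mu/sigma
are the mean/sd over all retained 1 bp-step windows, i.e. segment values
weighted by segment width.  dZHp = mean(ZHp_A) - mean(ZHp_L) contrasts the
two groups; consistency regions require every population of one group
strictly below 0 and every population of the other strictly above 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_stats import FreqTable
from .sweep_scan import intersect_regions, merge_regions
from .sync_io import FreqPanel, GroupAssignment, Region, StructuralError

logger = logging.getLogger("poolscan")


@dataclass
class HpParams:
    window_size: int = 50_000
    min_snps: int = 10
    step: int = 1  # fixed; kept for provenance

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.min_snps < 1 or self.step != 1:
            raise StructuralError("window_size >= 1, min_snps >= 1, step fixed at 1")


@dataclass
class HetSegments:
    """Maximal runs of window starts with identical SNP membership.

    Arrays are parallel over segments: ``s_lo``/``s_hi`` bound the start
    positions (inclusive), ``n_snps`` the shared membership size, ``hp``
    (n_segments, n_pops) the per-population window heterozygosity, and
    ``zhp`` the standardized values once normalized.
    """

    chrom: np.ndarray
    s_lo: np.ndarray
    s_hi: np.ndarray
    n_snps: np.ndarray
    hp: np.ndarray
    populations: list[str]
    window_size: int
    zhp: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.s_lo)

    @property
    def widths(self) -> np.ndarray:
        return self.s_hi - self.s_lo + 1

    def to_dataframe(self, groups: GroupAssignment | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chrom, "s_lo": self.s_lo, "s_hi": self.s_hi,
            "n_snps": self.n_snps,
        })
        for j, p in enumerate(self.populations):
            df[f"Hp_{p}"] = self.hp[:, j]
        if self.zhp is not None:
            for j, p in enumerate(self.populations):
                df[f"ZHp_{p}"] = self.zhp[:, j]
            if groups is not None:
                df["dZHp"] = dzhp(self, groups)
        return df


@dataclass
class ZhpSummary:
    """Width-weighted Hp mean and sd per population used for standardization."""

    mu: dict[str, float]
    sigma: dict[str, float]


def hp_of_window(freqs) -> float:
    """Mean of 2p(1-p) over the SNPs of one window."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise StructuralError("hp_of_window: empty SNP list")
    return float(np.mean(2.0 * p * (1.0 - p)))


def _segments_for_chrom(pos: np.ndarray, window: int, chrom_len: int):
    """Yield (a, b, i_lo, i_hi): starts [a, b) share members pos[i_lo:i_hi].

    A window start s is admissible when 0 <= s <= chrom_len - window; the
    window [s, s + window) contains a site at p iff p - window + 1 <= s <= p.
    """
    max_start = chrom_len - window
    if max_start < 0:
        return
    bps = {0, max_start + 1}
    for p in pos:
        for b in (p - window + 1, p + 1):
            if 0 < b <= max_start:
                bps.add(int(b))
    cuts = np.array(sorted(bps))
    for a, b in zip(cuts[:-1], cuts[1:]):
        i_lo = int(np.searchsorted(pos, a, side="left"))
        i_hi = int(np.searchsorted(pos, a + window, side="left"))
        yield int(a), int(b), i_lo, i_hi


def enumerate_hp_segments(
    freqs: FreqTable,
    params: HpParams,
    lengths: Mapping[str, int],
) -> HetSegments:
    """Partition all admissible window starts into constant-membership
    segments and compute per-population Hp for each.

    Segments with fewer than ``min_snps`` member SNPs are discarded.
    Chromosomes shorter than the window contribute no segments (logged).
    ``freqs`` should be in global-major orientation (Hp is symmetric in p,
    so any consistent per-site orientation yields the same values).
    """
    chroms_out, slo_out, shi_out, n_out, hp_rows = [], [], [], [], []
    chrom_arr = freqs.chrom.astype(str)
    het = 2.0 * freqs.p * (1.0 - freqs.p)  # (n_sites, n_pops)
    for chrom in sorted(set(chrom_arr)):
        if chrom not in lengths:
            raise StructuralError(f"chromosome {chrom!r} missing from lengths table")
        L = lengths[chrom]
        if L < params.window_size:
            logger.info("enumerate_hp_segments: %s shorter than window; skipped", chrom)
            continue
        sel = np.flatnonzero(chrom_arr == chrom)
        pos = freqs.pos[sel]
        order = np.argsort(pos)
        pos = pos[order]
        chet = het[sel][order]
        cum = np.vstack([np.zeros(chet.shape[1]), np.cumsum(chet, axis=0)])
        for a, b, i_lo, i_hi in _segments_for_chrom(pos, params.window_size, L):
            n = i_hi - i_lo
            if n < params.min_snps:
                continue
            chroms_out.append(chrom)
            slo_out.append(a)
            shi_out.append(b - 1)
            n_out.append(n)
            hp_rows.append((cum[i_hi] - cum[i_lo]) / n)
    hp = np.array(hp_rows) if hp_rows else np.zeros((0, len(freqs.populations)))
    return HetSegments(
        np.array(chroms_out, dtype=object),
        np.array(slo_out, dtype=np.int64),
        np.array(shi_out, dtype=np.int64),
        np.array(n_out, dtype=np.int64),
        hp, list(freqs.populations), params.window_size,
    )


def zhp_normalize(segments: HetSegments) -> tuple[HetSegments, ZhpSummary]:
    """Standardize Hp to ZHp per population over all retained windows.

    The mean and (population, ddof=0) sd are width-weighted so they equal
    the moments over every retained 1 bp-step window.  Errors if a
    population's Hp values are constant (sigma = 0).
    """
    if segments.n_segments < 2:
        raise StructuralError("zhp_normalize: need >=2 segments")
    w = segments.widths.astype(float)
    mu = (segments.hp * w[:, None]).sum(axis=0) / w.sum()
    var = ((segments.hp - mu) ** 2 * w[:, None]).sum(axis=0) / w.sum()
    sigma = np.sqrt(var)
    if (sigma <= 0).any():
        bad = [p for p, s in zip(segments.populations, sigma) if s <= 0]
        raise StructuralError(f"zhp_normalize: zero Hp variance for population(s) {bad}")
    zhp = (segments.hp - mu) / sigma
    out = HetSegments(segments.chrom, segments.s_lo, segments.s_hi,
                      segments.n_snps, segments.hp, list(segments.populations),
                      segments.window_size, zhp=zhp)
    summary = ZhpSummary(
        {p: float(m) for p, m in zip(segments.populations, mu)},
        {p: float(s) for p, s in zip(segments.populations, sigma)},
    )
    return out, summary


def _group_indices(populations: Sequence[str], groups: GroupAssignment,
                   group: str) -> list[int]:
    idx = {p: i for i, p in enumerate(populations)}
    cols = [idx[p] for p in groups.populations_in(group) if p in idx]
    if not cols:
        raise StructuralError(f"no populations of group {group!r} in segment table")
    return cols


def dzhp(segments: HetSegments, groups: GroupAssignment,
         group_a: str = "A", group_l: str = "L") -> np.ndarray:
    """Per-segment dZHp = mean(ZHp_A) - mean(ZHp_L) (positive = diversity
    depleted in the landlocked-like group)."""
    if segments.zhp is None:
        raise StructuralError("dzhp: normalize first")
    ia = _group_indices(segments.populations, groups, group_a)
    il = _group_indices(segments.populations, groups, group_l)
    return segments.zhp[:, ia].mean(axis=1) - segments.zhp[:, il].mean(axis=1)


def consistent_regions(
    segments: HetSegments,
    groups: GroupAssignment,
    direction: str,
    group_a: str = "A",
    group_l: str = "L",
) -> list[Region]:
    """Regions where heterozygosity is consistently reduced in one group.

    ``direction="low_in_L"``: every landlocked-like population has ZHp < 0
    and every anadromous-like population ZHp > 0 (strict; exact zeros
    disqualify).  ``"low_in_A"`` is the mirror image.  Qualifying segments
    are expanded to their full window extent [s_lo, s_hi + window) and
    merged when overlapping or touching.
    """
    if segments.zhp is None:
        raise StructuralError("consistent_regions: normalize first")
    ia = _group_indices(segments.populations, groups, group_a)
    il = _group_indices(segments.populations, groups, group_l)
    if direction == "low_in_L":
        ok = (segments.zhp[:, il] < 0).all(axis=1) & (segments.zhp[:, ia] > 0).all(axis=1)
    elif direction == "low_in_A":
        ok = (segments.zhp[:, ia] < 0).all(axis=1) & (segments.zhp[:, il] > 0).all(axis=1)
    else:
        raise StructuralError(f"unknown direction {direction!r}")
    regions = [
        Region(str(segments.chrom[i]), int(segments.s_lo[i]),
               int(segments.s_hi[i]) + segments.window_size, direction)
        for i in np.flatnonzero(ok)
    ]
    return merge_regions(regions, merge_touching=True)


def panel_to_freq_table(panel: FreqPanel) -> FreqTable:
    """View a frequency panel as a FreqTable (columns act as populations)."""
    return FreqTable(panel.chrom, panel.pos, panel.freqs, list(panel.columns),
                     orientation="as-given")


def cross_dataset_confirm(
    regions_a: Sequence[Region],
    panel: FreqPanel,
    groups_b: GroupAssignment,
    params: HpParams,
    direction: str,
    lengths: Mapping[str, int],
) -> list[Region]:
    """Confirm regions against an independent allele-frequency panel.

    Runs the full Hp -> ZHp -> consistency scan on the panel (frequencies
    used as given; 2p(1-p) is orientation-free) and returns the maximal
    intervals where ``regions_a`` and the panel's consistent regions overlap.
    """
    missing = [c for c in groups_b.populations if c not in panel.columns]
    if missing:
        raise StructuralError(f"panel lacks group columns: {missing}")
    freqs = panel_to_freq_table(panel)
    segments = enumerate_hp_segments(freqs, params, lengths)
    segments, _ = zhp_normalize(segments)
    panel_regions = consistent_regions(segments, groups_b, direction)
    confirmed = intersect_regions(list(regions_a), panel_regions)
    logger.info("cross_dataset_confirm: %d regions -> %d confirmed (%d panel regions)",
                len(regions_a), len(confirmed), len(panel_regions))
    return confirmed
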