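"""Per-SNP allele frequencies, group contrasts (dAF) and Nei F_ST.

Two allele orientations are used by the downstream scans:

* ``"reference"`` — p is the frequency of the reference base (dAF and the
  F_ST phylogeny);
* ``"major"`` — p is the frequency of the global major allele (pooled
  heterozygosity), where 2p(1-p) is orientation-symmetric anyway.

dAF at a site is the unweighted mean reference-allele frequency over the
landlocked-like group minus that of the anadromous-like group:
``dAF = p̄_L − p̄_A``.  Nei's per-SNP fixation index for two populations is

    F_ST = (p̄(1−p̄) − mean(p(1−p))) / (p̄(1−p̄)),   p̄ = (p1+p2)/2,

undefined where p̄ ∈ {0, 1}; such sites are skipped (and counted) in the
pairwise averages that feed the phylogeny.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_filtering import SnpTable
from .sync_io import GroupAssignment, StructuralError

logger = logging.getLogger("poolscan")


@dataclass
class FreqTable:
    """Per-site per-population frequency of the orientation allele."""

    chrom: np.ndarray
    pos: np.ndarray
    p: np.ndarray  # (n_sites, n_pops) in [0, 1]
    populations: list[str]
    orientation: str = "reference"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.pos), len(self.populations)):
            raise StructuralError("frequency matrix shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def allele_frequencies(snps: SnpTable, orientation: str = "reference") -> FreqTable:
    """Compute per-population allele frequencies from two-allele counts.

    ``orientation="reference"``: frequency of the reference base (0.0 where
    the reference base is not among the two alleles).
    ``orientation="major"``: frequency of allele1, the global major allele.
    Raises on zero depth (the depth floor guarantees it upstream).
    """
    depth = snps.depth
    if snps.n_sites and depth.min() == 0:
        raise StructuralError("zero depth encountered; apply a depth floor first")
    if orientation == "major":
        num = snps.counts[:, :, 0]
    elif orientation == "reference":
        ref = snps.ref.astype(str)
        a1 = snps.allele1.astype(str)
        a2 = snps.allele2.astype(str)
        sel1 = (ref == a1)[:, None]
        sel2 = (ref == a2)[:, None]
        num = np.where(sel1, snps.counts[:, :, 0], np.where(sel2, snps.counts[:, :, 1], 0))
    else:
        raise StructuralError(f"unknown orientation {orientation!r}")
    with np.errstate(invalid="ignore"):
        p = num / depth if snps.n_sites else np.zeros_like(depth, dtype=float)
    return FreqTable(snps.chrom, snps.pos, p, list(snps.populations), orientation)


@dataclass
class DafTable:
    """Signed per-site group allele-frequency difference."""

    chrom: np.ndarray
    pos: np.ndarray
    pbar_L: np.ndarray
    pbar_A: np.ndarray
    daf: np.ndarray  # pbar_L - pbar_A, in [-1, 1]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos + 1,
            "pbarL": self.pbar_L, "pbarA": self.pbar_A, "dAF": self.daf,
        })

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_daf_table(path) -> DafTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    return DafTable(df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy() - 1,
                    df["pbarL"].to_numpy(), df["pbarA"].to_numpy(), df["dAF"].to_numpy())


def daf(freqs: FreqTable, groups: GroupAssignment,
        contrast_group: str = "L", reference_group: str = "A") -> DafTable:
    """Per-site dAF: unweighted mean p over the contrast ("L") group minus
    the reference ("A") group's mean."""
    idx = {p: i for i, p in enumerate(freqs.populations)}
    pops_L = [p for p in groups.populations_in(contrast_group) if p in idx]
    pops_A = [p for p in groups.populations_in(reference_group) if p in idx]
    if not pops_L or not pops_A:
        raise StructuralError(
            f"both groups need >=1 population with frequencies "
            f"({contrast_group}: {len(pops_L)}, {reference_group}: {len(pops_A)})"
        )
    pbar_L = freqs.p[:, [idx[p] for p in pops_L]].mean(axis=1)
    pbar_A = freqs.p[:, [idx[p] for p in pops_A]].mean(axis=1)
    return DafTable(freqs.chrom, freqs.pos, pbar_L, pbar_A, pbar_L - pbar_A)


def nei_fst_snp(p1, p2):
    """Nei's per-SNP F_ST from two allele frequencies (vectorized).

    Returns NaN where p̄(1−p̄) = 0 (both populations fixed for the same
    allele, or frequencies averaging to 0 or 1).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2.0
    het_total = pbar * (1.0 - pbar)
    het_within = (p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = (het_total - het_within) / het_total
    return np.where(het_total > 0, fst, np.nan) if fst.ndim else (float(fst) if het_total > 0 else float("nan"))


def pairwise_fst(freqs: FreqTable) -> pd.DataFrame:
    """Mean per-SNP Nei F_ST for every population pair (symmetric, zero diagonal).

    Sites where F_ST is undefined for a pair are skipped in that pair's
    average, with a logged count; a pair with no defined site errors.
    """
    pops = freqs.populations
    if len(pops) < 2:
        raise StructuralError("pairwise_fst needs >=2 populations")
    n = len(pops)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = nei_fst_snp(freqs.p[:, i], freqs.p[:, j])
            defined = ~np.isnan(vals)
            n_skip = int((~defined).sum())
            if n_skip:
                logger.info("pairwise_fst: %s-%s: %d undefined sites skipped", pops[i], pops[j], n_skip)
            if not defined.any():
                raise StructuralError(f"no defined F_ST sites for pair {pops[i]}-{pops[j]}")
            mat[i, j] = mat[j, i] = float(vals[defined].mean())
    return pd.DataFrame(mat, index=pops, columns=pops)
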