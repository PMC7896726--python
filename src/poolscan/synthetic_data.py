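"""Synthetic Pool-seq data with the statistical structure the scan assumes.

Neutral allele frequencies follow the Balding–Nichols construction: a site
draws an ancestral frequency pi ~ Uniform(0.05, 0.95) and each population
draws p ~ Beta(pi (1-F)/F, (1-pi)(1-F)/F) around it, F being the
population's drift coefficient.  Two kinds of features are planted:

* ``parallel_sweep_L`` — every landlocked-like population draws its
  frequency from a Beta concentrated at a shared derived allele (mean 0.97
  by default) while anadromous-like populations stay near a low ancestral
  frequency (Uniform(0.05, 0.30)), so the group contrast dAF is ~ +0.8 and
  heterozygosity is depressed in the landlocked group.
* ``low_het_A`` — every anadromous-like population is concentrated near
  fixation (heterozygosity depressed in that group) while landlocked
  populations stay neutral.

Observed pooled counts follow the standard two-stage Pool-seq sampling
model: a pool of N diploids carries k ~ Binomial(2N, p) copies of the
reference allele; read depth is d ~ Poisson(lambda) (zero depths bumped to
1), and reference reads ~ Binomial(d, k / 2N).  Populations may comprise
several pools, exercising pool merging downstream.

Everything is driven by one integer seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sync_io import (
    AlleleCountTable,
    FreqPanel,
    GroupAssignment,
    Region,
    StructuralError,
    write_assignment,
    write_chrom_lengths,
    write_freq_panel,
    write_regions,
    write_sync,
)

BASES = np.array(list("ATCG"))


@dataclass
class Feature:
    """A planted selection signal (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    kind: str  # "parallel_sweep_L" | "low_het_A"
    derived_freq: float = 0.97
    concentration: float = 150.0
    # ancestral frequency range inside the feature; defaults depend on kind:
    # sweeps keep the unaffected (A) group low so dAF ~ derived - mean(pi) ~ +0.8;
    # low_het_A needs pi where the unaffected (L) group keeps above-average
    # heterozygosity (pi(1-pi) > genome mean) yet |dAF| stays well under the
    # sweep threshold: pi in (0.60, 0.75)
    ancestral_lo: float | None = None
    ancestral_hi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("parallel_sweep_L", "low_het_A"):
            raise StructuralError(f"unknown feature kind {self.kind!r}")
        if self.start < 0 or self.start >= self.end:
            raise StructuralError("invalid feature interval")
        if self.ancestral_lo is None:
            self.ancestral_lo = 0.05 if self.kind == "parallel_sweep_L" else 0.60
        if self.ancestral_hi is None:
            self.ancestral_hi = 0.30 if self.kind == "parallel_sweep_L" else 0.75

    @property
    def daf_effect(self) -> float:
        """Expected group-mean |dAF| inside the feature (sweeps only)."""
        return self.derived_freq - (self.ancestral_lo + self.ancestral_hi) / 2.0

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end, self.kind)


@dataclass
class Population:
    name: str
    group: str  # "A" | "L"
    fst: float  # Balding–Nichols drift coefficient
    depth_lambda: float  # Poisson read-depth mean, per pool
    pool_sizes: tuple[int, ...]  # diploids per pool


@dataclass
class SimConfig:
    """Study conditions of the simulated Pool-seq experiment.

    Defaults mirror the pooled salmon resequencing design: 3 anadromous-like
    and 6 landlocked-like populations, pools of 10–20 diploids, Poisson read
    depths spanning ~17–244x, per-population drift F in 0.05–0.15.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    snp_density: float = 1 / 200  # expected segregating sites per bp
    populations: list[Population] = field(default_factory=lambda: [
        Population("WN", "A", 0.05, 244.0, (20, 20)),
        Population("NN", "A", 0.06, 134.0, (15, 15)),
        Population("CON", "A", 0.08, 32.0, (20,)),
        Population("SEB", "L", 0.10, 30.0, (20,)),
        Population("GUL", "L", 0.11, 23.0, (20,)),
        Population("BLE", "L", 0.12, 25.0, (20,)),
        Population("LUZ", "L", 0.13, 18.0, (10,)),
        Population("SAI", "L", 0.14, 17.0, (10,)),
        Population("TUL", "L", 0.15, 17.0, (10,)),
    ])
    features: list[Feature] = field(default_factory=lambda: [
        Feature("chr1", 600_000, 750_000, "parallel_sweep_L"),
        Feature("chr2", 1_000_000, 1_080_000, "low_het_A"),
    ])
    pi_lo: float = 0.05
    pi_hi: float = 0.95
    # CV of the shared lognormal per-site depth factor: read depth at a site
    # co-varies across pools (mappability, repeat content), which is what lets
    # a joint all-population depth-band filter retain a sizable SNP fraction
    depth_site_cv: float = 0.3
    panel_density: float = 1 / 1000  # SNP-array marker density for the panel
    panel_fst: float = 0.02  # drift of the group-averaged panel frequencies
    panel_groups: dict[str, str] = field(default_factory=lambda: {
        "Barents": "A", "White": "A", "Ladoga": "L", "Onega": "L"})

    def __post_init__(self) -> None:
        if self.snp_density <= 0 or self.panel_density <= 0:
            raise StructuralError("densities must be positive")
        by_chrom: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.chrom not in self.chrom_lengths:
                raise StructuralError(f"feature on unknown chromosome {f.chrom!r}")
            if f.end > self.chrom_lengths[f.chrom]:
                raise StructuralError("feature exceeds chromosome bounds")
            by_chrom.setdefault(f.chrom, []).append(f)
        for feats in by_chrom.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats[:-1], feats[1:]):
                if b.start < a.end:
                    raise StructuralError("features overlap")

    def assignment(self) -> GroupAssignment:
        pool_to_pop = {}
        for pop in self.populations:
            for k in range(len(pop.pool_sizes)):
                pool_to_pop[f"{pop.name}_p{k + 1}"] = pop.name
        return GroupAssignment(pool_to_pop, {p.name: p.group for p in self.populations})

    def truth(self) -> list[Region]:
        return [f.as_region() for f in self.features]


@dataclass
class SimFrequencies:
    """True per-site, per-population reference-allele frequencies."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    pi: np.ndarray
    p: np.ndarray  # (n_sites, n_pops)
    populations: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def _balding_nichols(rng: np.random.Generator, pi: np.ndarray, fst: float) -> np.ndarray:
    c = (1.0 - fst) / fst
    return rng.beta(pi * c, (1.0 - pi) * c)


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimFrequencies:
    """Draw site positions (Poisson process) and true population frequencies."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms, poss = [], []
    for chrom in sorted(cfg.chrom_lengths):
        L = cfg.chrom_lengths[chrom]
        n = rng.poisson(cfg.snp_density * L)
        pos = np.sort(rng.choice(L, size=min(n, L), replace=False))
        chroms.extend([chrom] * len(pos))
        poss.append(pos)
    chrom = np.array(chroms, dtype=object)
    pos = np.concatenate(poss) if poss else np.zeros(0, dtype=np.int64)
    n_sites = len(pos)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    pi = rng.uniform(cfg.pi_lo, cfg.pi_hi, size=n_sites)
    in_sweep = np.zeros(n_sites, dtype=bool)
    in_lowhet_a = np.zeros(n_sites, dtype=bool)
    for f in cfg.features:
        sel = (chrom == f.chrom) & (pos >= f.start) & (pos < f.end)
        if f.kind == "parallel_sweep_L":
            in_sweep |= sel
        else:
            in_lowhet_a |= sel
        pi[sel] = rng.uniform(f.ancestral_lo, f.ancestral_hi, size=int(sel.sum()))

    p = np.empty((n_sites, len(cfg.populations)))
    for j, pop in enumerate(cfg.populations):
        pj = _balding_nichols(rng, pi, pop.fst)
        for f in cfg.features:
            sel = (chrom == f.chrom) & (pos >= f.start) & (pos < f.end)
            affected = (pop.group == "L") if f.kind == "parallel_sweep_L" else (pop.group == "A")
            if affected and sel.any():
                a = f.concentration * f.derived_freq
                b = f.concentration * (1.0 - f.derived_freq)
                pj[sel] = rng.beta(a, b, size=int(sel.sum()))
        p[:, j] = pj
    return SimFrequencies(chrom, pos, BASES[ref_idx].astype(object),
                          BASES[alt_idx].astype(object), pi, p,
                          [q.name for q in cfg.populations])


def sample_pool_counts(
    freqs: SimFrequencies,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> AlleleCountTable:
    """Two-stage pooled sampling of read counts from true frequencies."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = freqs.n_sites
    pool_names: list[str] = []
    blocks: list[np.ndarray] = []
    ref_col = np.array([{"A": 0, "T": 1, "C": 2, "G": 3}[b] for b in freqs.ref])
    alt_col = np.array([{"A": 0, "T": 1, "C": 2, "G": 3}[b] for b in freqs.alt])
    # per-site depth factor shared by all pools (local mappability)
    cv = cfg.depth_site_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    site_factor = rng.lognormal(-sigma * sigma / 2.0, sigma, size=n) if cv > 0 else np.ones(n)
    for j, pop in enumerate(cfg.populations):
        p = freqs.p[:, j]
        for k, size in enumerate(pop.pool_sizes):
            pool_names.append(f"{pop.name}_p{k + 1}")
            k_copies = rng.binomial(2 * size, p)
            depth = rng.poisson(pop.depth_lambda * site_factor)
            depth[depth == 0] = 1  # zero-depth records are not representable in sync
            ref_reads = rng.binomial(depth, k_copies / (2 * size))
            block = np.zeros((n, 6), dtype=np.int64)
            block[np.arange(n), ref_col] = ref_reads
            block[np.arange(n), alt_col] += depth - ref_reads
            blocks.append(block)
    counts = np.stack(blocks, axis=1) if n else np.zeros((0, len(pool_names), 6), dtype=np.int64)
    return AlleleCountTable(freqs.chrom, freqs.pos, freqs.ref, counts, pool_names)


def simulate_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> FreqPanel:
    """Independently re-sampled group-level frequency panel over the same
    features (emulating a SNP-array dataset with group-averaged frequencies)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    panel_cfg = replace(cfg, snp_density=cfg.panel_density,
                        populations=[
                            Population(name, grp, cfg.panel_fst, 0.0, ())
                            for name, grp in cfg.panel_groups.items()
                        ])
    freqs = simulate_frequencies(panel_cfg, rng)
    return FreqPanel(freqs.chrom, freqs.pos, freqs.p, list(cfg.panel_groups))


def generate_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset; deterministic given ``cfg.seed``.

    Files: ``pools.sync``, ``groups.tsv``, ``chroms.tsv``, ``truth.bed``,
    ``panel.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_frequencies(cfg, rng)
    table = sample_pool_counts(freqs, cfg, rng)
    panel = simulate_panel(cfg, rng)
    paths = {
        "sync": outdir / "pools.sync",
        "groups": outdir / "groups.tsv",
        "chroms": outdir / "chroms.tsv",
        "truth": outdir / "truth.bed",
        "panel": outdir / "panel.tsv",
    }
    write_sync(table, paths["sync"])
    write_assignment(cfg.assignment(), paths["groups"])
    write_chrom_lengths(cfg.chrom_lengths, paths["chroms"])
    truth = cfg.truth()
    if truth:
        write_regions(truth, paths["truth"])
    else:
        paths["truth"].write_text("")
    write_freq_panel(panel, paths["panel"])
    return paths
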