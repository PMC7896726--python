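"""Readers/writers for the text formats the genome scan touches.

Formats handled here:

* ``sync`` — the PoPoolation2 dialect: one line per site,
  ``chrom  pos  ref  A:T:C:G:N:del`` with one colon-separated count block
  per pool.  Positions are 1-based in the file.
* BED3/BED6 for genomic regions (0-based, half-open).
* GFF3 gene models (1-based, inclusive in the file).
* 2-column ``chrom  length`` TSV for chromosome lengths.
* headered TSV allele-frequency panels (SNP-array style data).
* 3-column ``pool  population  group`` assignment tables.

Internally every coordinate is 0-based half-open; 1-based inputs are
converted on read and converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("poolscan")

#: column order of a sync count block
SYNC_CATEGORIES = ("A", "T", "C", "G", "N", "del")
#: indices of the four nucleotide categories within a count block
BASE_INDICES = {"A": 0, "T": 1, "C": 2, "G": 3}
BASES = "ATCG"


class ParseError(ValueError):
    """Malformed record in an input file (message names the line)."""


class StructuralError(ValueError):
    """Input is well-formed but structurally inconsistent (e.g. pool count)."""


def _check_token(name: str, kind: str) -> str:
    """Pool/population/group names become file columns: plain ASCII, no tabs."""
    if not name or not name.isascii() or any(c.isspace() for c in name):
        raise StructuralError(f"{kind} name {name!r} must be a non-empty ASCII token without whitespace")
    return name


# ---------------------------------------------------------------------------
# AlleleCountTable
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Per-site, per-pool counts of the six sync categories.

    ``counts`` has shape ``(n_sites, n_pools, 6)`` in SYNC_CATEGORIES order.
    ``pos`` is 0-based.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    pool_names: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.pool_names) == 0:
            raise StructuralError("AlleleCountTable requires at least one pool")
        if len(set(self.pool_names)) != len(self.pool_names):
            raise StructuralError("pool names must be unique")
        for name in self.pool_names:
            _check_token(name, "pool")
        n = len(self.pos)
        if self.counts.shape != (n, len(self.pool_names), 6):
            raise StructuralError(
                f"counts shape {self.counts.shape} != ({n}, {len(self.pool_names)}, 6)"
            )
        if n and self.counts.min() < 0:
            raise StructuralError("negative counts")
        if n and self.pos.min() < 0:
            raise StructuralError("negative positions")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sort(self) -> "AlleleCountTable":
        """Return a copy sorted by (chrom, pos); positions must be unique per chrom."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return AlleleCountTable(
            self.chrom[order], self.pos[order], self.ref[order],
            self.counts[order], list(self.pool_names),
        )

    def is_sorted(self) -> bool:
        for i in range(1, self.n_sites):
            if self.chrom[i] == self.chrom[i - 1]:
                if self.pos[i] <= self.pos[i - 1]:
                    return False
        return True


def read_sync(path: str | Path, pool_names: Sequence[str]) -> AlleleCountTable:
    """Parse a PoPoolation2 sync file into an :class:`AlleleCountTable`.

    Raises :class:`ParseError` naming the offending line for malformed count
    blocks, and :class:`StructuralError` when the number of count blocks does
    not match ``pool_names``.  Unsorted input is sorted with a logged notice.
    """
    pool_names = [str(p) for p in pool_names]
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    counts: list[list[list[int]]] = []
    n_pools = len(pool_names)
    if n_pools == 0:
        raise StructuralError("pool_names must be non-empty")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected at least 3 fields")
            if len(fields) - 3 != n_pools:
                raise StructuralError(
                    f"{path}: line {lineno}: {len(fields) - 3} count blocks for "
                    f"{n_pools} pools"
                )
            try:
                pos1 = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer position {fields[1]!r}") from None
            if pos1 < 1:
                raise ParseError(f"{path}: line {lineno}: position {pos1} < 1")
            row = []
            for block in fields[3:]:
                parts = block.split(":")
                if len(parts) != 6:
                    raise ParseError(
                        f"{path}: line {lineno}: count block {block!r} has "
                        f"{len(parts)} fields, expected 6"
                    )
                try:
                    vals = [int(x) for x in parts]
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer count in block {block!r}"
                    ) from None
                if min(vals) < 0:
                    raise ParseError(f"{path}: line {lineno}: negative count in block {block!r}")
                row.append(vals)
            chroms.append(fields[0])
            poss.append(pos1 - 1)  # to 0-based
            refs.append(fields[2])
            counts.append(row)
    table = AlleleCountTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(counts, dtype=np.int64).reshape(len(poss), n_pools, 6),
        pool_names,
    )
    if not table.is_sorted():
        logger.info("read_sync: %s not sorted by (chrom, pos); sorting", path)
        table = table.sort()
    return table


def write_sync(table: AlleleCountTable, path: str | Path) -> None:
    """Write ``table`` in sync format (positions converted back to 1-based)."""
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            blocks = [
                ":".join(str(c) for c in table.counts[i, j])
                for j in range(len(table.pool_names))
            ]
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i] + 1}\t{table.ref[i]}\t" + "\t".join(blocks) + "\n"
            )


# ---------------------------------------------------------------------------
# GroupAssignment and pool merging
# ---------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    """Pool -> population and population -> group mapping.

    Exactly two group labels; by convention ``"A"`` is the anadromous-like
    reference group and ``"L"`` the landlocked-like contrast group.
    """

    pool_to_pop: dict[str, str]
    pop_to_group: dict[str, str]

    def __post_init__(self) -> None:
        for pool, pop in self.pool_to_pop.items():
            _check_token(pool, "pool")
            if pop not in self.pop_to_group:
                raise StructuralError(f"pool {pool!r} maps to unknown population {pop!r}")
        for pop, grp in self.pop_to_group.items():
            _check_token(pop, "population")
            _check_token(grp, "group")
        groups = set(self.pop_to_group.values())
        if len(groups) != 2:
            raise StructuralError(f"expected exactly two group labels, got {sorted(groups)}")
        for g in groups:
            if not any(v == g for v in self.pop_to_group.values()):
                raise StructuralError(f"group {g!r} is empty")

    @property
    def populations(self) -> list[str]:
        """Populations in first-appearance order of the pool map."""
        seen: list[str] = []
        for pop in self.pool_to_pop.values():
            if pop not in seen:
                seen.append(pop)
        for pop in self.pop_to_group:  # populations without pools (panel data)
            if pop not in seen:
                seen.append(pop)
        return seen

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.pop_to_group.values()))

    def populations_in(self, group: str) -> list[str]:
        return [p for p in self.populations if self.pop_to_group[p] == group]


def read_assignment(path: str | Path) -> GroupAssignment:
    """Read a 3-column TSV ``pool  population  group`` (no header)."""
    pool_to_pop: dict[str, str] = {}
    pop_to_group: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            pool, pop, grp = fields
            if pool in pool_to_pop:
                raise StructuralError(f"{path}: line {lineno}: duplicate pool {pool!r}")
            pool_to_pop[pool] = pop
            if pop in pop_to_group and pop_to_group[pop] != grp:
                raise StructuralError(f"{path}: line {lineno}: population {pop!r} in two groups")
            pop_to_group[pop] = grp
    return GroupAssignment(pool_to_pop, pop_to_group)


def write_assignment(assignment: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pool, pop in assignment.pool_to_pop.items():
            fh.write(f"{pool}\t{pop}\t{assignment.pop_to_group[pop]}\n")


def merge_pools(table: AlleleCountTable, assignment: GroupAssignment) -> AlleleCountTable:
    """Merge pools of the same population by summing their allele counts.

    Output has one count block per population, in the assignment's
    population order; record order is preserved.
    """
    unassigned = [p for p in table.pool_names if p not in assignment.pool_to_pop]
    if unassigned:
        raise StructuralError(f"pools not in assignment: {unassigned}")
    pops = [p for p in assignment.populations
            if any(assignment.pool_to_pop[q] == p for q in table.pool_names)]
    merged = np.zeros((table.n_sites, len(pops), 6), dtype=np.int64)
    pop_index = {p: i for i, p in enumerate(pops)}
    for j, pool in enumerate(table.pool_names):
        merged[:, pop_index[assignment.pool_to_pop[pool]], :] += table.counts[:, j, :]
    return AlleleCountTable(table.chrom, table.pos, table.ref, merged, pops)


# ---------------------------------------------------------------------------
# ChromLengths
# ---------------------------------------------------------------------------

def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV ``chrom  length``; lengths must be >= 1."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            chrom, length_s = fields
            try:
                length = int(length_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer length") from None
            if length < 1:
                raise ParseError(f"{path}: line {lineno}: length {length} < 1")
            if chrom in lengths:
                raise StructuralError(f"{path}: line {lineno}: duplicate chrom {chrom!r}")
            lengths[chrom] = length
    return lengths


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Regions (BED)
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """Half-open genomic interval with free-text provenance label."""

    chrom: str
    start: int
    end: int
    label: str = ""
    payload: int | None = None  # e.g. number of differentiated SNPs

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ParseError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


def read_regions(path: str | Path) -> list[Region]:
    """Read BED3+ (0-based half-open); output sorted by (chrom, start)."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}: line {lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else ""
            payload = None
            if len(fields) > 4:
                try:
                    payload = int(fields[4])
                except ValueError:
                    payload = None
            regions.append(Region(fields[0], start, end, label, payload))
    regions.sort(key=Region.sort_key)
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write BED (6 columns when label/payload present, else 3)."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=Region.sort_key):
            if r.label or r.payload is not None:
                score = r.payload if r.payload is not None else 0
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label or '.'}\t{score}\t.\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """Gene interval (0-based half-open) with identifier and optional symbol."""

    chrom: str
    start: int
    end: int
    gene_id: str
    symbol: str | None = None


_SYMBOL_KEYS = ("gene", "Name", "symbol", "gene_name")


def read_gff_genes(path: str | Path) -> list[Gene]:
    """Extract ``gene`` records from a GFF3 file.

    GFF is 1-based inclusive; intervals are converted to 0-based half-open.
    Records lacking an ID attribute are skipped with a logged warning.
    Output is sorted by (chrom, start).
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF fields")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            attrs: dict[str, str] = {}
            for item in fields[8].split(";"):
                item = item.strip()
                if not item or "=" not in item:
                    continue
                k, v = item.split("=", 1)
                attrs[k] = v
            gene_id = attrs.get("ID")
            if gene_id is None:
                logger.warning("read_gff_genes: %s line %d: gene without ID attribute skipped", path, lineno)
                continue
            symbol = next((attrs[k] for k in _SYMBOL_KEYS if k in attrs), None)
            genes.append(Gene(fields[0], start1 - 1, end1, gene_id, symbol))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


# ---------------------------------------------------------------------------
# FreqPanel
# ---------------------------------------------------------------------------

@dataclass
class FreqPanel:
    """Plain allele-frequency table: per site, one frequency per column.

    Emulates SNP-array data where each column is a (group-averaged)
    population frequency.  ``pos`` is 0-based internally.
    """

    chrom: np.ndarray
    pos: np.ndarray
    freqs: np.ndarray  # (n_sites, n_columns), values in [0, 1]
    columns: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        n = len(self.pos)
        if self.freqs.shape != (n, len(self.columns)):
            raise StructuralError("freqs shape does not match columns")
        if n and (self.freqs.min() < 0 or self.freqs.max() > 1):
            raise StructuralError("frequencies outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


def read_freq_panel(path: str | Path) -> FreqPanel:
    """Read a headered TSV ``chrom  pos  <freq columns...>`` (pos 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["chrom", "pos"]:
        raise ParseError(f"{path}: expected header starting with 'chrom\\tpos'")
    freq_cols = list(df.columns[2:])
    vals = df[freq_cols].to_numpy(dtype=float)
    bad = np.argwhere((vals < 0) | (vals > 1))
    if bad.size:
        i = int(bad[0, 0])
        raise ParseError(f"{path}: line {i + 2}: frequency outside [0, 1]")
    panel = FreqPanel(
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64) - 1,
        vals,
        freq_cols,
    )
    order = np.lexsort((panel.pos, panel.chrom.astype(str)))
    if not np.array_equal(order, np.arange(panel.n_sites)):
        logger.info("read_freq_panel: %s not sorted; sorting", path)
        panel = FreqPanel(panel.chrom[order], panel.pos[order], panel.freqs[order], freq_cols)
    return panel


def write_freq_panel(panel: FreqPanel, path: str | Path) -> None:
    df = pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos + 1})
    for j, c in enumerate(panel.columns):
        df[c] = panel.freqs[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
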