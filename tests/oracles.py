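"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by naive enumeration (per-start window
scans, all-pairs interval overlap, per-window rule evaluation) so they share
no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_window_starts(pos, het, window, min_snps, chrom_len):
    """Naive per-start window scan for one chromosome.

    Returns (starts, n_snps, hp) for every admissible start with
    >= min_snps member SNPs; ``het`` is (n_sites, n_pops) per-site 2p(1-p),
    ``pos`` sorted site positions.
    """
    pos = np.asarray(pos)
    starts, ns, hps = [], [], []
    for s in range(0, chrom_len - window + 1):
        member = (pos >= s) & (pos < s + window)
        n = int(member.sum())
        if n < min_snps:
            continue
        starts.append(s)
        ns.append(n)
        hps.append(het[member].mean(axis=0))
    return (np.array(starts, dtype=int), np.array(ns, dtype=int),
            np.array(hps) if hps else np.zeros((0, het.shape[1])))


def brute_force_zhp(hp_by_start):
    """Z-scores over per-start values (population sd, ddof=0)."""
    mu = hp_by_start.mean(axis=0)
    sd = hp_by_start.std(axis=0)
    return (hp_by_start - mu) / sd


def brute_force_consistent_intervals(starts, zhp_by_start, low_cols, high_cols, window):
    """Union of window extents of qualifying starts, as (start, end) pairs.

    A start qualifies when every ``low_cols`` population has z < 0 and every
    ``high_cols`` population z > 0.  The union is extracted from a coverage
    array, which merges overlapping and book-ended windows alike.
    """
    if len(starts) == 0:
        return []
    cov = np.zeros(int(starts.max()) + window + 1, dtype=bool)
    for s, z in zip(starts, zhp_by_start):
        if (z[low_cols] < 0).all() and (z[high_cols] > 0).all():
            cov[s:s + window] = True
    out = []
    in_run = False
    for i, c in enumerate(cov):
        if c and not in_run:
            run_start, in_run = i, True
        elif not c and in_run:
            out.append((run_start, i))
            in_run = False
    if in_run:
        out.append((run_start, len(cov)))
    return out


def brute_force_interval_intersection(a, b, space):
    """Coverage-array intersection of two interval lists on [0, space)."""
    cov_a = np.zeros(space, dtype=bool)
    cov_b = np.zeros(space, dtype=bool)
    for s, e in a:
        cov_a[s:e] = True
    for s, e in b:
        cov_b[s:e] = True
    cov = cov_a & cov_b
    out, in_run = [], False
    for i, c in enumerate(cov):
        if c and not in_run:
            run_start, in_run = i, True
        elif not c and in_run:
            out.append((run_start, i))
            in_run = False
    if in_run:
        out.append((run_start, space))
    return out


def brute_force_daf_window_counts(pos, absdaf, window, step, min_daf, chrom_len):
    """Naive recount of threshold-passing SNPs for every grid window."""
    counts = []
    for start in range(0, chrom_len, step):
        end = min(start + window, chrom_len)
        c = sum(1 for p, v in zip(pos, absdaf) if start <= p < end and v >= min_daf)
        counts.append(((start, end), c))
    return counts


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns the
    leaf-to-leaf distance matrix and leaf labels.

    Built by random sequential joins; distances computed by path summation
    over an explicit parent map (no tree library involved).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = list(range(n_taxa))
    parent: dict[int, tuple[int, float]] = {}
    nxt = n_taxa
    active = nodes[:]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        parent[a] = (nxt, float(rng.uniform(0.1, 1.0)))
        parent[b] = (nxt, float(rng.uniform(0.1, 1.0)))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    def path_to_root(x):
        out = {}
        dist = 0.0
        while x in parent:
            p, w = parent[x]
            dist += w
            out[p] = dist
            x = p
        return out

    d = np.zeros((n_taxa, n_taxa))
    paths = [path_to_root(i) for i in range(n_taxa)]
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            shared = set(paths[i]) & set(paths[j])
            mrca = min(shared, key=lambda p: paths[i][p])
            d[i, j] = d[j, i] = paths[i][mrca] + paths[j][mrca]
    return d, labels
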