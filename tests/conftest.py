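"""Shared fixtures: small simulated datasets and a full-scan helper."""

from __future__ import annotations

import numpy as np
import pytest

import poolscan as ps


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-scale simulated dataset (seed 7) with written files."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = ps.SimConfig(seed=7)
    paths = ps.generate_dataset(cfg, outdir)
    return cfg, paths


def run_scan(cfg: ps.SimConfig):
    """Run the full scan in memory on a simulated dataset; returns a dict of
    the main artifacts (sweeps, consistency regions, truth)."""
    rng = np.random.default_rng(cfg.seed)
    freqs = ps.simulate_frequencies(cfg, rng)
    table = ps.sample_pool_counts(freqs, cfg, rng)
    assignment = cfg.assignment()
    lengths = cfg.chrom_lengths

    snps = ps.apply_filter_preset(table, assignment, preset="daf")
    daf_table = ps.daf(ps.allele_frequencies(snps, "reference"), assignment)
    sweeps = ps.scan_sweeps(daf_table, ps.SweepParams(), lengths)

    snps_hp = ps.apply_filter_preset(table, assignment, preset="hp")
    freqs_major = ps.allele_frequencies(snps_hp, "major")
    segments, _ = ps.zhp_normalize(
        ps.enumerate_hp_segments(freqs_major, ps.HpParams(), lengths))
    low_L = ps.consistent_regions(segments, assignment, "low_in_L")
    low_A = ps.consistent_regions(segments, assignment, "low_in_A")
    return {
        "truth": cfg.truth(), "sweeps": sweeps,
        "low_L": low_L, "low_A": low_A, "segments": segments,
    }
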