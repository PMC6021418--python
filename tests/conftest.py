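"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pbscreen._util import revcomp
from pbscreen.simulate import SimConfig, generate_genome, plant_insertions, simulate_all

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Oracles (kept independent of the implementation paths they check)


def brute_force_map(sequences: dict[str, str], query: str, max_mm: int):
    """Exhaustive all-offset, both-strand Hamming scan.

    Returns (best_mismatches, {(chrom, start, strand), ...}) over every
    location within the budget, or (None, set()) when there is none.
    """
    best = None
    locs: set[tuple[str, int, str]] = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        qa = np.frombuffer(q.encode(), dtype="S1")
        m = len(q)
        for chrom, seq in sequences.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            if len(arr) < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, m)
            mm = (windows != qa).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                v = int(mm[pos])
                if best is None or v < best:
                    best = v
                    locs = {(chrom, int(pos), strand)}
                elif v == best:
                    locs.add((chrom, int(pos), strand))
    return best, locs


def scan_ttaa_oracle(seq: str) -> list[int]:
    """Position-by-position scan for TTAA, independent of str.find."""
    return [i for i in range(len(seq) - 3) if seq[i : i + 4] == "TTAA"]


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Error-free, fully readable study conditions for exact-recovery tests."""
    return SimConfig(seed=11, unreadable_fraction=0.0, base_error_rate=0.0)


@pytest.fixture(scope="session")
def clean_sim(clean_config, tmp_path_factory):
    """One full synthetic dataset (written to disk) shared across tests."""
    outdir = tmp_path_factory.mktemp("clean_sim")
    data = simulate_all(clean_config, outdir)
    data["outdir"] = outdir
    return data


@pytest.fixture(scope="session")
def toy_genome():
    """Small genome + annotation used by annotation and variant tests."""
    cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=350_000, n_genes=2,
                    n_driver_genes=1, n_shared_genes=1)
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def default_insertions(clean_config, clean_sim):
    return clean_sim["insertions"]
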