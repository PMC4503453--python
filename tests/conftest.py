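"""Shared fixtures: small seeded simulations reused across test modules."""

from __future__ import annotations

import pytest

from longform import SimConfig, simulate_all

ERR2 = (0.002, 0.010, 0.008)  # 2% total, indel-dominant
ERR15 = (0.01, 0.08, 0.06)  # 15% total


@pytest.fixture(scope="session")
def truth_small():
    """8-gene simulation with 2% read error (clustering-friendly)."""
    return simulate_all(SimConfig(seed=5, n_genes=8, error_rates=ERR2))


@pytest.fixture(scope="session")
def truth_errorfree():
    """12-gene error-free simulation (round-trip checks)."""
    return simulate_all(SimConfig(seed=11, n_genes=12, error_rates=(0, 0, 0)))


@pytest.fixture(scope="session")
def truth_default_errorfree():
    """Default-scale (60-gene) error-free simulation for PTU/PAS checks."""
    return simulate_all(SimConfig(seed=11, error_rates=(0, 0, 0)))


@pytest.fixture(scope="session")
def truth_seqs(truth_errorfree):
    return {i.id: i.seq(truth_errorfree.genome) for i in truth_errorfree.isoforms}
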