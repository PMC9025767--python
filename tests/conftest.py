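from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from repliconkit import (
    classify,
    copy_numbers,
    default_simulation,
    feature_complements,
    imprint_decision,
    load_panel,
    load_replicon_table,
    simulate_genome,
    simulate_reference,
)

N_SEEDS = 20


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def replicon_table():
    return load_replicon_table()


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated genome + reference at a fixed seed."""
    spec = default_simulation(7)
    genome, truth = simulate_genome(spec)
    return genome, truth, simulate_reference(spec)


@pytest.fixture(scope="session")
def end_to_end_runs():
    """Full pipeline runs over the study-condition simulations.

    Returns a list of (truth table, classification results, imprint
    decisions) tuples, one per seed; shared across the imprint
    separation and label-recovery tests.
    """
    runs = []
    for seed in range(N_SEEDS):
        spec = default_simulation(seed)
        genome, truth = simulate_genome(spec)
        reference = simulate_reference(spec)
        decisions = imprint_decision(genome, reference)
        results = classify(
            genome,
            copy_numbers(genome),
            decisions,
            feature_complements(genome),
        )
        runs.append((truth, results, decisions))
    return runs
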