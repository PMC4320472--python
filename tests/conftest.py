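"""Shared fixtures: hand-built toy panels and small simulated panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xpopacc.genotype_io import marker_qc, partition_candidates
from xpopacc.panel import GenotypePanel, PedigreeTable
from xpopacc.synthpop import SynthConfig, simulate_multibreed_panel


def make_panel(dosages, populations=None, chromosomes=None, positions=None, ids=None):
    """Small helper to assemble a valid panel from a dosage matrix."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    if populations is None:
        populations = ["P1"] * n
    if chromosomes is None:
        chromosomes = np.ones(m, dtype=int)
    if positions is None:
        positions = np.arange(m, dtype=float) + 1.0
    if ids is None:
        ids = [f"I{i}" for i in range(n)]
    return GenotypePanel(
        dosages=dosages,
        ids=np.asarray(ids, dtype=object),
        populations=np.asarray(populations, dtype=object),
        locus_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        chromosomes=chromosomes,
        positions_cm=positions,
    )


def make_pedigree(rows):
    """rows: iterable of (id, sire, dam, population, generation)."""
    return PedigreeTable(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "population", "generation"])
    )


@pytest.fixture(scope="session")
def toy_two_pop_panel():
    """4 individuals in 2 populations, hand-set dosages (frequency oracle)."""
    dos = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 2, 0],
            [2, 0, 0, 1],
            [2, 2, 1, 1],
        ]
    )
    return make_panel(dos, populations=["A", "A", "B", "B"])


@pytest.fixture(scope="session")
def small_sim():
    """Small two-population simulated panel, QC'd and partitioned."""
    config = SynthConfig(
        n_populations=2,
        founders_per_population=30,
        sires_per_generation=5,
        dams_per_generation=20,
        divergence_generations=10,
        loci_per_chromosome=500,
        final_panel_sizes=(120, 60),
        seed=11,
    )
    panel, pedigree = simulate_multibreed_panel(config)
    panel, _ = marker_qc(panel)
    partition = partition_candidates(panel, 300, seed=5)
    return panel, pedigree, partition


@pytest.fixture(scope="session")
def default_three_pop():
    """The default-scale three-population panel (drift/LD checks)."""
    panel, pedigree = simulate_multibreed_panel(SynthConfig(seed=1))
    return panel, pedigree


@pytest.fixture(scope="session")
def medium_two_pop():
    """Two-population panel big enough for GREML recovery studies."""
    config = SynthConfig(
        n_populations=2,
        final_panel_sizes=(250, 100),
        loci_per_chromosome=800,
        seed=13,
    )
    panel, pedigree = simulate_multibreed_panel(config)
    panel, _ = marker_qc(panel)
    partition = partition_candidates(panel, 500, seed=5)
    return panel, pedigree, partition
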