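"""Gene-dropping simulator for multi-population genotype panels.

Emulates a set of livestock breeds that diverged from a common ancestral
gene pool: an ancestral haplotype pool with short-range LD built up by
random-mating burn-in, independent drift per population, and a final
breeding phase with a small number of sires per generation that creates
paternal half-sib family structure.  Recombination follows Haldane's model
(no interference): the crossover count per chromosome is Poisson with mean
equal to the map length in Morgans and breakpoints are uniform.

The returned panel is one cohort (the last generation bred within each
population); the returned pedigree covers the whole breeding phase, with
the breeding founders carrying unknown parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xpopacc.panel import UNKNOWN_PARENT, GenotypePanel, PedigreeTable


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SynthConfig:
    """Configuration of the multi-population gene-dropping simulation.

    Defaults give three populations of effective size about 50 that drift
    apart for 20 generations and then breed with 10 sires per generation,
    yielding panels of 400/100/100 individuals on three ~1 Morgan
    chromosomes with ~2000 loci each.
    """

    n_populations: int = 3
    founders_per_population: int = 50
    sires_per_generation: int = 10
    dams_per_generation: int = 50
    offspring_generations_within: int = 2
    divergence_generations: int = 20
    ancestral_pool_size: int = 200  # haplotypes
    burnin_generations: int = 50
    chromosome_lengths: tuple[float, ...] = (1.0, 1.0, 1.0)  # Morgans
    loci_per_chromosome: int = 2000
    final_panel_sizes: tuple[int, ...] = (400, 100, 100)
    seed: int = 2025
    population_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts = {
            "n_populations": self.n_populations,
            "founders_per_population": self.founders_per_population,
            "sires_per_generation": self.sires_per_generation,
            "dams_per_generation": self.dams_per_generation,
            "ancestral_pool_size": self.ancestral_pool_size,
            "loci_per_chromosome": self.loci_per_chromosome,
        }
        for name, value in counts.items():
            if value < 1:
                raise SimulationError(f"{name} must be >= 1, got {value}")
        if self.offspring_generations_within < 0 or self.divergence_generations < 0:
            raise SimulationError("generation counts must be >= 0")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise SimulationError("zero-length chromosome in chromosome_lengths")
        if len(self.final_panel_sizes) != self.n_populations:
            raise SimulationError("final_panel_sizes must have one entry per population")
        if any(n < 1 for n in self.final_panel_sizes):
            raise SimulationError("final panel sizes must be >= 1")
        # Alternating sex assignment makes ~half of each cohort male.
        if self.sires_per_generation > self.founders_per_population // 2:
            raise SimulationError(
                f"sires_per_generation={self.sires_per_generation} exceeds the "
                f"males available among {self.founders_per_population} founders"
            )
        if not self.population_labels:
            self.population_labels = tuple(f"POP{i + 1}" for i in range(self.n_populations))
        if len(self.population_labels) != self.n_populations:
            raise SimulationError("population_labels must have one entry per population")


def _genetic_map(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced loci: (chromosome index, position in cM) per locus."""
    chroms, pos = [], []
    for c, length_m in enumerate(config.chromosome_lengths):
        m = config.loci_per_chromosome
        # midpoints of m equal bins over the chromosome
        p = (np.arange(m) + 0.5) / m * length_m * 100.0
        chroms.append(np.full(m, c + 1, dtype=int))
        pos.append(p)
    return np.concatenate(chroms), np.concatenate(pos)


def _gamete(
    haplotypes: np.ndarray,
    chrom_starts: np.ndarray,
    chrom_lengths_m: np.ndarray,
    positions_cm: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a (2, n_loci) pair of haplotypes."""
    out = np.empty(haplotypes.shape[1], dtype=np.uint8)
    for c, length_m in enumerate(chrom_lengths_m):
        lo, hi = chrom_starts[c], chrom_starts[c + 1]
        pos = positions_cm[lo:hi]
        n_xo = rng.poisson(length_m)
        current = int(rng.integers(2))
        if n_xo == 0:
            out[lo:hi] = haplotypes[current, lo:hi]
            continue
        breaks = np.sort(rng.uniform(0.0, length_m * 100.0, size=n_xo))
        # strand index per locus: start strand flipped at each breakpoint
        flips = np.searchsorted(breaks, pos, side="right")
        strand = (current + flips) % 2
        seg = haplotypes[:, lo:hi]
        out[lo:hi] = np.where(strand == 0, seg[0], seg[1])
    return out


class _Cohort:
    """Haplotypes plus ids/sexes for one generation of one population."""

    __slots__ = ("haplotypes", "ids", "sexes")

    def __init__(self, haplotypes: np.ndarray, ids: list[str], sexes: np.ndarray):
        self.haplotypes = haplotypes  # (n, 2, n_loci) uint8
        self.ids = ids
        self.sexes = sexes  # 0 = male, 1 = female

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]


def _random_mating(
    cohort: _Cohort,
    n_offspring: int,
    geom: tuple,
    rng: np.random.Generator,
    prefix: str = "",
) -> _Cohort:
    """Random union of gametes from random sire/dam pairs."""
    chrom_starts, chrom_lengths_m, positions_cm = geom
    males = np.flatnonzero(cohort.sexes == 0)
    females = np.flatnonzero(cohort.sexes == 1)
    if males.size == 0 or females.size == 0:
        raise SimulationError("cohort lacks one sex entirely; cannot mate")
    haps = np.empty((n_offspring, 2, cohort.haplotypes.shape[2]), dtype=np.uint8)
    for i in range(n_offspring):
        sire = int(rng.choice(males))
        dam = int(rng.choice(females))
        haps[i, 0] = _gamete(cohort.haplotypes[sire], chrom_starts, chrom_lengths_m, positions_cm, rng)
        haps[i, 1] = _gamete(cohort.haplotypes[dam], chrom_starts, chrom_lengths_m, positions_cm, rng)
    ids = [f"{prefix}{i + 1:05d}" for i in range(n_offspring)]
    sexes = np.arange(n_offspring) % 2  # alternating at birth
    return _Cohort(haps, ids, sexes)


def simulate_multibreed_panel(
    config: SynthConfig, return_haplotypes: bool = False
) -> tuple[GenotypePanel, PedigreeTable]:
    """Simulate a multi-population genotype panel and its pedigree.

    Deterministic given ``config.seed``.  When ``return_haplotypes`` is
    true, the per-individual haplotypes of the final panel are returned as
    a third element (used for internal-consistency checks).
    """
    rng = np.random.default_rng(config.seed)
    chroms, positions_cm = _genetic_map(config)
    n_loci = chroms.size
    chrom_lengths_m = np.asarray(config.chromosome_lengths, dtype=float)
    chrom_starts = np.concatenate(
        [[0], np.cumsum([config.loci_per_chromosome] * len(config.chromosome_lengths))]
    )
    geom = (chrom_starts, chrom_lengths_m, positions_cm)

    # Ancestral haplotype pool: locus-wise frequencies, then burn-in random
    # mating to establish short-range LD shared by all descendant populations.
    anc_freq = rng.uniform(0.1, 0.9, size=n_loci)
    n_anc = config.ancestral_pool_size
    pool_haps = (rng.random((n_anc, n_loci)) < anc_freq).astype(np.uint8)
    n_anc_ind = n_anc // 2
    if n_anc_ind < 2:
        raise SimulationError("ancestral_pool_size must provide at least 2 diploids")
    pool = _Cohort(
        pool_haps[: 2 * n_anc_ind].reshape(n_anc_ind, 2, n_loci),
        [f"ANC{i}" for i in range(n_anc_ind)],
        np.arange(n_anc_ind) % 2,
    )
    for _ in range(config.burnin_generations):
        pool = _random_mating(pool, n_anc_ind, geom, rng)

    ped_rows: list[tuple[str, str, str, str, int]] = []
    panel_blocks: list[_Cohort] = []
    panel_pops: list[str] = []

    for p in range(config.n_populations):
        label = config.population_labels[p]
        # Population founders drawn by random mating from the shared pool,
        # then independent drift at constant size.
        cohort = _random_mating(pool, config.founders_per_population, geom, rng)
        for _ in range(config.divergence_generations):
            cohort = _random_mating(cohort, config.founders_per_population, geom, rng)

        # Breeding phase with recorded pedigree and few sires per generation.
        cohort.ids = [f"{label}_G0_{i + 1:04d}" for i in range(cohort.n)]
        for iid in cohort.ids:
            ped_rows.append((iid, UNKNOWN_PARENT, UNKNOWN_PARENT, label, 0))
        target = config.final_panel_sizes[p]
        for g in range(1, config.offspring_generations_within + 1):
            males = np.flatnonzero(cohort.sexes == 0)
            females = np.flatnonzero(cohort.sexes == 1)
            if males.size < config.sires_per_generation:
                raise SimulationError(
                    f"only {males.size} males available in {label} generation {g - 1}, "
                    f"need {config.sires_per_generation} sires"
                )
            sires = rng.choice(males, size=config.sires_per_generation, replace=False)
            n_dams = min(config.dams_per_generation, females.size)
            dams = rng.choice(females, size=n_dams, replace=False)
            haps = np.empty((target, 2, n_loci), dtype=np.uint8)
            ids = [f"{label}_G{g}_{i + 1:04d}" for i in range(target)]
            for i in range(target):
                sire = int(rng.choice(sires))
                dam = int(rng.choice(dams))
                haps[i, 0] = _gamete(cohort.haplotypes[sire], *geom, rng)
                haps[i, 1] = _gamete(cohort.haplotypes[dam], *geom, rng)
                ped_rows.append((ids[i], cohort.ids[sire], cohort.ids[dam], label, g))
            cohort = _Cohort(haps, ids, np.arange(target) % 2)
        panel_blocks.append(cohort)
        panel_pops.extend([label] * cohort.n)

    all_haps = np.concatenate([c.haplotypes for c in panel_blocks], axis=0)
    dosages = all_haps.sum(axis=1).astype(np.int8)
    ids = np.concatenate([np.asarray(c.ids, dtype=object) for c in panel_blocks])
    panel = GenotypePanel(
        dosages=dosages,
        ids=ids,
        populations=np.asarray(panel_pops, dtype=object),
        locus_ids=np.array([f"chr{c}_snp{i}" for i, c in enumerate(chroms)], dtype=object),
        chromosomes=chroms,
        positions_cm=positions_cm,
    )
    pedigree = PedigreeTable(
        pd.DataFrame(ped_rows, columns=list(PedigreeTable.COLUMNS))
    )
    if return_haplotypes:
        return panel, pedigree, all_haps  # type: ignore[return-value]
    return panel, pedigree


def estimate_fst(panel: GenotypePanel, pop_a: str, pop_b: str) -> float:
    """Hudson-type FST between two populations, ratio of averages.

    Per polymorphic locus the numerator is
    ``(p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and the denominator
    ``p1(1-p2) + p2(1-p1)``, with ``n`` counted in allele copies; locus-wise
    numerators and denominators are averaged before taking the ratio, which
    keeps the estimator nearly unbiased at small sample sizes.
    """
    ga = panel.dosages[panel.population_mask(pop_a)]
    gb = panel.dosages[panel.population_mask(pop_b)]
    if ga.shape[0] < 2 or gb.shape[0] < 2:
        raise ValueError("need at least 2 individuals per population for FST")
    n1 = 2.0 * ga.shape[0]
    n2 = 2.0 * gb.shape[0]
    p1 = ga.mean(axis=0) / 2.0
    p2 = gb.mean(axis=0) / 2.0
    pooled = (p1 + p2) / 2.0
    poly = (pooled > 0) & (pooled < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci for FST estimation")
    p1, p2 = p1[poly], p2[poly]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
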