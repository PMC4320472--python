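"""Quantitative-trait simulation on a genotype panel.

QTL are sampled from a fixed candidate-locus pool; allele substitution
effects are standard normal per population with a chosen cross-population
correlation (via the Cholesky factor of the correlation matrix); true
breeding values are dosage-weighted sums rescaled to mean 0 and variance 1
across populations; environmental noise is added at a target heritability
computed from the TBV variance after correcting for the within-population
TBV means (the means themselves stay in the TBV and the phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from xpopacc.panel import GenotypePanel


class TraitError(ValueError):
    """Raised for invalid trait-simulation inputs."""


@dataclass
class TraitArchitecture:
    """QTL positions, per-population substitution effects and parameters."""

    qtl_indices: np.ndarray
    effects: np.ndarray  # (n_populations, n_qtl)
    genetic_correlation_matrix: np.ndarray
    h2: float
    seed: int

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)


@dataclass
class SimulatedPhenotypes:
    """True breeding values, environmental effects and phenotypes."""

    tbv: np.ndarray
    environment: np.ndarray
    phenotype: np.ndarray  # tbv + environment, exactly
    population_means: dict[str, float]
    environmental_variance: float


def _check_correlation_matrix(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise TraitError("correlation matrix must be square")
    if not np.allclose(np.diag(corr), 1.0):
        raise TraitError("correlation matrix must have unit diagonal")
    if not np.allclose(corr, corr.T):
        raise TraitError("correlation matrix must be symmetric")
    if np.any(np.abs(corr) > 1.0 + 1e-12):
        raise TraitError("correlations must lie in [-1, 1]")
    return corr


def sample_qtl_effects(n_qtl: int, correlation_matrix, seed: int) -> np.ndarray:
    """Per-population QTL effects with the given cross-population correlation.

    Each QTL's effects across populations are standard normal draws
    correlated through the Cholesky factor of the correlation matrix; a
    semidefinite matrix (e.g. all correlations 1) is handled through its
    eigendecomposition.
    """
    corr = _check_correlation_matrix(correlation_matrix)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((corr.shape[0], n_qtl))
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-8:
            raise TraitError(
                f"correlation matrix is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.3g})"
            ) from None
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return chol @ z


def compute_tbv(
    panel: GenotypePanel, qtl_indices, effects: np.ndarray
) -> np.ndarray:
    """Dosage-weighted TBV, rescaled to mean 0 and variance 1 overall.

    Each individual uses the effect vector of its own population; the
    rescaling is linear, so per-population TBV means remain (allele
    frequencies differ across populations) while the across-population
    mean is 0 and the variance is 1.
    """
    qtl_indices = np.asarray(qtl_indices)
    effects = np.asarray(effects, dtype=float)
    labels = panel.population_labels
    if effects.shape[0] != len(labels):
        raise TraitError(
            f"effects has {effects.shape[0]} rows for {len(labels)} populations"
        )
    if effects.shape[1] != qtl_indices.size:
        raise TraitError("one effect per QTL per population required")
    dos = panel.dosages[:, qtl_indices].astype(float)
    raw = np.empty(panel.n_individuals)
    for row, label in enumerate(labels):
        mask = panel.populations == label
        raw[mask] = dos[mask] @ effects[row]
    sd = raw.std(ddof=1)
    if sd <= 0.0:
        raise TraitError("raw TBV has zero variance; cannot rescale")
    return (raw - raw.mean()) / sd


def simulate_phenotypes(
    tbv: np.ndarray,
    populations: np.ndarray,
    h2: float,
    seed: int,
) -> SimulatedPhenotypes:
    """Add environmental noise at heritability ``h2``.

    The environmental variance is ``(1/h2 − 1)`` times the pooled variance
    of the TBV corrected for the within-population means; the same variance
    applies to every population (equal heritability).  The population
    means are subtracted only for this variance computation — TBV and
    phenotypes keep them.
    """
    if not 0.0 < h2 <= 1.0:
        raise TraitError(f"heritability must be in (0, 1], got {h2}")
    tbv = np.asarray(tbv, dtype=float)
    populations = np.asarray(populations, dtype=object)
    centered = tbv.copy()
    pop_means: dict[str, float] = {}
    for label in dict.fromkeys(populations):
        mask = populations == label
        m = float(tbv[mask].mean())
        pop_means[str(label)] = m
        centered[mask] -= m
    genetic_var = float(np.var(centered, ddof=1))
    env_var = (1.0 / h2 - 1.0) * genetic_var
    rng = np.random.default_rng(seed)
    env = rng.normal(0.0, np.sqrt(env_var), size=tbv.size) if env_var > 0 else np.zeros(tbv.size)
    return SimulatedPhenotypes(
        tbv=tbv,
        environment=env,
        phenotype=tbv + env,
        population_means=pop_means,
        environmental_variance=env_var,
    )


def simulate_trait(
    panel: GenotypePanel,
    candidate_pool,
    n_qtl: int,
    correlation_matrix,
    h2: float,
    seed: int,
) -> tuple[TraitArchitecture, SimulatedPhenotypes]:
    """One trait replicate: QTL draw, effects, TBV, phenotypes.

    QTL are drawn without replacement from the candidate pool; the marker
    set (the pool's complement) is untouched, so it stays constant across
    replicates that share a panel and partition.
    """
    candidate_pool = np.asarray(candidate_pool)
    if n_qtl > candidate_pool.size:
        raise TraitError(
            f"n_qtl={n_qtl} exceeds candidate pool of {candidate_pool.size}"
        )
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(candidate_pool, size=n_qtl, replace=False))
    effects = sample_qtl_effects(n_qtl, correlation_matrix, seed=seed + 1)
    tbv = compute_tbv(panel, qtl, effects)
    phen = simulate_phenotypes(tbv, panel.populations, h2, seed=seed + 2)
    arch = TraitArchitecture(
        qtl_indices=qtl,
        effects=effects,
        genetic_correlation_matrix=np.asarray(correlation_matrix, dtype=float),
        h2=h2,
        seed=seed,
    )
    return arch, phen
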