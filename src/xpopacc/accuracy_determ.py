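"""Deterministic accuracy of across-population genomic prediction.

Two predictors are implemented.  The selection-index one gives, for each
selection candidate, the accuracy

    r = r_G * sqrt( g' [G_B + R_B * (sigma_e^2 / sigma_a^2)]^-1 g )

with g the vector of genomic relationships between the candidate and the
reference individuals (GRM built with population-specific allele
frequencies), and its two-reference-population generalization with a
block phenotypic covariance carrying r_G_BC on the cross block.  The
population-parameter one uses only the reference size, heritability and
the effective number of chromosome segments:

    r_P = r_G * sqrt( N_p h^2 / (N_p h^2 + M_e) ).

A helper converts progeny counts into the reliability of a sire's
deregressed proof, which is the heritability relevant to such
pseudo-phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy.linalg import cho_factor, cho_solve

class AccuracyError(ValueError):
    """Raised for invalid deterministic-accuracy inputs."""


@dataclass
class VarianceComponents:
    """Genetic/environmental variances per population, unit phenotypic scale."""

    genetic: dict[str, float]
    environmental: dict[str, float]
    # environmental correlation structures; identity when absent
    env_structure: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, v in self.genetic.items():
            if v <= 0:
                raise AccuracyError(f"genetic variance for {label!r} must be > 0")
        for label, v in self.environmental.items():
            if v < 0:
                raise AccuracyError(f"environmental variance for {label!r} must be >= 0")

    def variance_ratio(self, label: str) -> float:
        """sigma_e^2 / sigma_a^2 for one population."""
        return self.environmental[label] / self.genetic[label]

    @classmethod
    def from_heritability(cls, h2: float, labels) -> "VarianceComponents":
        """Unit genetic variance with sigma_e^2 = (1/h2 - 1) per population."""
        if not 0.0 < h2 <= 1.0:
            raise AccuracyError(f"heritability must be in (0, 1], got {h2}")
        return cls(
            genetic={lab: 1.0 for lab in labels},
            environmental={lab: 1.0 / h2 - 1.0 for lab in labels},
        )


def _pd_solve(matrix: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Symmetric positive-definite solve with a single small-jitter retry."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or rhs.shape[0] != n:
        raise AccuracyError("dimension mismatch in positive-definite solve")
    try:
        return cho_solve(cho_factor(matrix, lower=True), rhs)
    except np.linalg.LinAlgError:
        pass
    # near-singular systems (duplicated relatives) get one ridge of 1e-8
    eigmin = float(np.linalg.eigvalsh(matrix).min())
    tol = -1e-8 * np.trace(matrix) / n
    if eigmin < tol:
        raise AccuracyError(
            f"phenotypic covariance is not positive definite "
            f"(smallest eigenvalue {eigmin:.3g})"
        )
    jittered = matrix + 1e-8 * np.eye(n)
    return cho_solve(cho_factor(jittered, lower=True), rhs)


def build_phenotypic_covariance(
    g_blocks, vc: VarianceComponents, labels
) -> np.ndarray:
    """Assemble Var(y) for one or two reference populations.

    ``g_blocks`` maps ``(label_i, label_j)`` to the corresponding GRM
    block; missing cross blocks default to zero, missing environmental
    structures to the identity.  For cross blocks, entries of
    ``vc.env_structure`` are ignored (environmental effects are
    uncorrelated across populations) and the genetic correlation scaling is
    applied by the caller.
    """
    sizes = [g_blocks[(lab, lab)].shape[0] for lab in labels]
    total = sum(sizes)
    v = np.zeros((total, total))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for bi, lab_b in enumerate(labels):
        sl_b = slice(offsets[bi], offsets[bi + 1])
        g_bb = np.asarray(g_blocks[(lab_b, lab_b)], dtype=float)
        r_env = vc.env_structure.get(lab_b)
        if r_env is None:
            r_env = np.eye(sizes[bi])
        v[sl_b, sl_b] = g_bb * vc.genetic[lab_b] + r_env * vc.environmental[lab_b]
        for bj in range(bi + 1, len(labels)):
            lab_c = labels[bj]
            sl_c = slice(offsets[bj], offsets[bj + 1])
            block = g_blocks.get((lab_b, lab_c))
            if block is None:
                blockT = g_blocks.get((lab_c, lab_b))
                block = None if blockT is None else np.asarray(blockT).T
            if block is not None:
                cross = np.asarray(block, dtype=float) * sqrt(
                    vc.genetic[lab_b] * vc.genetic[lab_c]
                )
                v[sl_b, sl_c] = cross
                v[sl_c, sl_b] = cross.T
    return v


def si_accuracy_single(
    g_vec: np.ndarray,
    g_ref: np.ndarray,
    vc: VarianceComponents | float,
    r_g: float = 1.0,
    label: str | None = None,
    env_structure: np.ndarray | None = None,
) -> float:
    """Selection-index accuracy with a single reference population.

    ``vc`` may be a :class:`VarianceComponents` (with ``label`` naming the
    reference population) or directly the variance ratio
    sigma_e^2/sigma_a^2.  Uses a positive-definite solve of
    ``G + R * ratio`` rather than an explicit inverse.
    """
    g_vec = np.asarray(g_vec, dtype=float).ravel()
    g_ref = np.asarray(g_ref, dtype=float)
    if g_ref.shape[0] != g_vec.size:
        raise AccuracyError("candidate-reference vector does not match reference GRM")
    if isinstance(vc, VarianceComponents):
        if label is None:
            if len(vc.genetic) != 1:
                raise AccuracyError("label required when several populations are defined")
            label = next(iter(vc.genetic))
        ratio = vc.variance_ratio(label)
        if env_structure is None:
            env_structure = vc.env_structure.get(label)
    else:
        ratio = float(vc)
    r_env = np.eye(g_ref.shape[0]) if env_structure is None else np.asarray(env_structure)
    quad = float(g_vec @ _pd_solve(g_ref + r_env * ratio, g_vec))
    return r_g * sqrt(max(quad, 0.0))


def si_accuracy_multi(
    g_vec_b: np.ndarray,
    g_vec_c: np.ndarray,
    g_b: np.ndarray,
    g_c: np.ndarray,
    g_bc: np.ndarray,
    vc: VarianceComponents,
    labels: tuple[str, str],
    r_g_ab: float,
    r_g_ac: float,
    r_g_bc: float,
) -> float:
    """Selection-index accuracy with two reference populations B and C.

    The bracketed block system is ``[[G_B + R_B eB/aB, r_BC G_BC],
    [r_BC G_BC', G_C + R_C eC/aC]]`` and the numerator vector stacks
    ``r_AB g_B`` and ``r_AC g_C``.
    """
    lab_b, lab_c = labels
    g_vec_b = np.asarray(g_vec_b, dtype=float).ravel()
    g_vec_c = np.asarray(g_vec_c, dtype=float).ravel()
    g_b = np.asarray(g_b, dtype=float)
    g_c = np.asarray(g_c, dtype=float)
    g_bc = np.asarray(g_bc, dtype=float)
    nb, nc = g_b.shape[0], g_c.shape[0]
    if g_bc.shape != (nb, nc) or g_vec_b.size != nb or g_vec_c.size != nc:
        raise AccuracyError("inconsistent block dimensions")
    r_env_b = vc.env_structure.get(lab_b, np.eye(nb))
    r_env_c = vc.env_structure.get(lab_c, np.eye(nc))
    block = np.block(
        [
            [g_b + r_env_b * vc.variance_ratio(lab_b), r_g_bc * g_bc],
            [r_g_bc * g_bc.T, g_c + r_env_c * vc.variance_ratio(lab_c)],
        ]
    )
    stacked = np.concatenate([r_g_ab * g_vec_b, r_g_ac * g_vec_c])
    quad = float(stacked @ _pd_solve(block, stacked))
    return sqrt(max(quad, 0.0))


def pp_accuracy(n_p: int, h2: float, me: float, r_g: float = 1.0) -> float:
    """Population-parameter accuracy r_G * sqrt(N h^2 / (N h^2 + Me))."""
    if n_p < 1:
        raise AccuracyError("reference size must be >= 1")
    if not 0.0 < h2 <= 1.0:
        raise AccuracyError(f"heritability must be in (0, 1], got {h2}")
    if me <= 0.0:
        raise AccuracyError("Me must be positive")
    return r_g * sqrt(n_p * h2 / (n_p * h2 + me))


def drp_reliability(n_daughters: int, h2: float) -> tuple[float, float]:
    """Accuracy and reliability of a sire's progeny-based proof.

    ``r = sqrt(n h^2 / (n h^2 + (4 - h^2)))`` for ``n`` daughters; the
    reliability (squared accuracy) is the heritability appropriate for
    deregressed proofs used as pseudo-phenotypes.
    """
    if n_daughters < 1:
        raise AccuracyError("need at least one daughter")
    if not 0.0 < h2 <= 1.0:
        raise AccuracyError(f"heritability must be in (0, 1], got {h2}")
    acc = sqrt(n_daughters * h2 / (n_daughters * h2 + (4.0 - h2)))
    return acc, acc * acc


@dataclass
class DeterministicAccuracy:
    """Per-candidate accuracies for one scenario and method."""

    accuracies: np.ndarray
    method: str  # {"selection_index", "population_parameters"}

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se(self) -> float:
        n = self.accuracies.size
        return float(np.std(self.accuracies, ddof=1) / sqrt(n)) if n > 1 else float("nan")


def si_accuracy_per_candidate(
    grm,
    reference_ids,
    candidate_ids,
    vc: VarianceComponents,
    reference_label: str,
    r_g: float = 1.0,
) -> DeterministicAccuracy:
    """Selection-index accuracy of every candidate given one reference set.

    The bracketed reference system is factorized once and reused across
    candidates.
    """
    g_ref = grm.submatrix(reference_ids)
    g_cr = grm.submatrix(candidate_ids, reference_ids)
    ratio = vc.variance_ratio(reference_label)
    r_env = vc.env_structure.get(reference_label, np.eye(g_ref.shape[0]))
    solved = _pd_solve(g_ref + r_env * ratio, g_cr.T)  # (n_ref, n_cand)
    quads = np.einsum("ij,ji->i", g_cr, solved)
    return DeterministicAccuracy(
        accuracies=r_g * np.sqrt(np.clip(quads, 0.0, None)),
        method="selection_index",
    )
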