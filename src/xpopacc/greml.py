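"""GREML: REML variance components with a genomic relationship matrix,
BLUP prediction for unphenotyped candidates, empirical accuracy, and the
two-population genetic-correlation model.

The single-trait model is ``y = Xb + a + e`` with ``Var(a) = G sigma_a^2``
and ``Var(e) = I sigma_e^2``; population is the (only) fixed effect.  The
restricted likelihood is evaluated through one eigendecomposition of the
reference-block GRM, after which every evaluation is O(n) — refitting per
replicate on a fixed panel is cheap.  The genetic-correlation model treats
the same trait in two populations as two traits with environmental
correlation 0; the focal population's variances and the correlation are
free while the other population's components are held at supplied values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize, minimize_scalar

from xpopacc.relationships import RelationshipMatrix


class RemlError(ValueError):
    """Raised for non-identifiable or unconvergent REML problems."""


@dataclass
class MixedModelFit:
    """Converged single-trait GREML fit."""

    sigma_a2: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int
    fixed_effects: dict[str, float]
    reference_ids: np.ndarray
    ebv_reference: np.ndarray
    # V^-1 (y - Xb) in the original basis; all BLUP predictions are linear in it
    vinv_resid: np.ndarray = field(repr=False)
    boundary: bool = False


def _design_matrix(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = list(dict.fromkeys(labels))
    x = np.zeros((labels.size, len(levels)))
    for j, lev in enumerate(levels):
        x[labels == lev, j] = 1.0
    return x, levels


_BIG = 1e12


def _profile_pieces(lam, d, yt, xt):
    """GLS pieces at variance ratio lam = sigma_e^2/sigma_a^2.

    With V = sigma_a^2 (D + lam I) in the eigenbasis, the scale
    sigma_a^2 profiles out analytically as quad/(n - p).
    """
    v = d + lam
    if v.min() <= 0:
        return None
    xv = xt / v[:, None]
    xtvx = xt.T @ xv
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    beta = np.linalg.solve(xtvx, xv.T @ yt)
    r = yt - xt @ beta
    quad = float(r @ (r / v))
    if quad <= 0:
        return None
    return v, beta, quad, logdet_xtvx


def _profile_nll(log_lam, d, yt, xt):
    """Negative restricted log-likelihood profiled over the scale."""
    pieces = _profile_pieces(np.exp(log_lam), d, yt, xt)
    if pieces is None:
        return _BIG
    v, _, quad, logdet_xtvx = pieces
    ndf = yt.size - xt.shape[1]
    sa2 = quad / ndf
    return 0.5 * (
        ndf * np.log(sa2) + float(np.sum(np.log(v))) + logdet_xtvx + ndf
    )


def reml_single(
    y: np.ndarray,
    populations: np.ndarray,
    grm: RelationshipMatrix,
    reference_ids,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 200,
) -> MixedModelFit:
    """Fit the single-trait GREML model on the reference individuals.

    ``y`` and ``populations`` are aligned with ``reference_ids``.  Pass
    ``eig = (eigenvalues, eigenvectors)`` of the reference GRM block to
    reuse a factorization across replicates.  Deterministic given inputs.
    """
    reference_ids = np.asarray(list(reference_ids), dtype=object)
    y = np.asarray(y, dtype=float)
    populations = np.asarray(populations, dtype=object)
    if y.size != reference_ids.size or populations.size != reference_ids.size:
        raise RemlError("y/populations must align with reference_ids")
    if eig is None:
        g_ref = grm.submatrix(reference_ids)
        d, u = eigh(g_ref)
    else:
        d, u = eig
    if float(np.std(d)) < 1e-10:
        raise RemlError(
            "reference GRM is (a multiple of) the identity; genetic and "
            "environmental variances are not identifiable"
        )
    x, levels = _design_matrix(populations)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RemlError("singular fixed-effect design")
    yt = u.T @ y
    xt = u.T @ x

    # 1-D bounded search over the log variance ratio lam = se2/sa2;
    # Ghat may carry tiny negative eigenvalues, so the ratio must keep
    # D + lam I positive definite.
    lam_floor = max(1e-8, -float(d.min()) * (1.0 + 1e-6) + 1e-12)
    lo, hi = np.log(lam_floor), np.log(1e8)
    res = minimize_scalar(
        _profile_nll,
        bounds=(lo, hi),
        args=(d, yt, xt),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    nll = _profile_nll(res.x, d, yt, xt)
    pieces = _profile_pieces(np.exp(res.x), d, yt, xt)
    if pieces is None or not np.isfinite(nll) or nll >= _BIG:
        raise RemlError("REML did not reach a finite optimum")
    _, beta, quad, _ = pieces
    lam = float(np.exp(res.x))
    sa2 = quad / (yt.size - xt.shape[1])
    se2 = lam * sa2
    boundary = bool(res.x - lo < 1e-4 or hi - res.x < 1e-4)
    # residual weighted by V^-1, back in the original basis
    v = sa2 * d + se2
    rt = yt - xt @ beta
    vinv_resid = u @ (rt / v)
    ebv_ref = sa2 * (u @ (d * (rt / v)))
    return MixedModelFit(
        sigma_a2=float(sa2),
        sigma_e2=float(se2),
        loglik=float(-nll),
        converged=bool(res.success),
        n_iter=int(res.nfev),
        fixed_effects=dict(zip(levels, map(float, beta))),
        reference_ids=reference_ids,
        ebv_reference=ebv_ref,
        vinv_resid=vinv_resid,
        boundary=boundary,
    )


def blup_predict(fit: MixedModelFit, grm: RelationshipMatrix, candidate_ids) -> np.ndarray:
    """EBV of unphenotyped candidates through their genomic relationships.

    ``a_hat = G_cand,ref sigma_a^2 V^-1 (y - Xb)``.  Candidates must not
    overlap the phenotyped reference.
    """
    if not fit.converged:
        raise RemlError("cannot predict from an unconverged fit")
    candidate_ids = list(candidate_ids)
    if set(candidate_ids) & set(fit.reference_ids):
        raise RemlError("candidates overlap the phenotyped reference")
    g_cr = grm.submatrix(candidate_ids, fit.reference_ids)
    return fit.sigma_a2 * (g_cr @ fit.vinv_resid)


def empirical_accuracy(
    ebv: np.ndarray, tbv: np.ndarray, populations: np.ndarray
) -> dict[str, float]:
    """Pearson correlation of EBV with TBV, within each population."""
    ebv = np.asarray(ebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    populations = np.asarray(populations, dtype=object)
    out: dict[str, float] = {}
    for label in dict.fromkeys(populations):
        mask = populations == label
        if mask.sum() < 3:
            raise RemlError(f"need >= 3 individuals in {label!r} for a correlation")
        e, t = ebv[mask], tbv[mask]
        if np.std(e) == 0 or np.std(t) == 0:
            raise RemlError(f"constant EBV or TBV in {label!r}; correlation undefined")
        out[str(label)] = float(np.corrcoef(e, t)[0, 1])
    return out


# ---------------------------------------------------------------------------
# two-population genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneticCorrelationFit:
    """Bivariate GREML fit with one population's components held fixed."""

    r_g: float
    sigma_a2_focal: float
    sigma_e2_focal: float
    sigma_a2_fixed: float
    sigma_e2_fixed: float
    loglik: float
    converged: bool
    n_iter: int
    boundary: bool


def _bivariate_nll(params, g_aa, g_ab, g_bb, sa2_b, se2_b, y, x, na):
    log_sa2, log_se2, z = params
    sa2_a, se2_a = np.exp(log_sa2), np.exp(log_se2)
    r = np.tanh(z)
    n = y.size
    v = np.empty((n, n))
    v[:na, :na] = sa2_a * g_aa
    v[:na, na:] = r * np.sqrt(sa2_a * sa2_b) * g_ab
    v[na:, :na] = v[:na, na:].T
    v[na:, na:] = sa2_b * g_bb
    v[:na, :na] += se2_a * np.eye(na)
    v[na:, na:] += se2_b * np.eye(n - na)
    try:
        c, low = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return _BIG
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vinv_y = cho_solve((c, low), y)
    vinv_x = cho_solve((c, low), x)
    xtvx = x.T @ vinv_x
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return _BIG
    beta = np.linalg.solve(xtvx, x.T @ vinv_y)
    resid = y - x @ beta
    quad = float(resid @ cho_solve((c, low), resid))
    return 0.5 * (logdet_v + logdet_xtvx + quad)


def reml_genetic_correlation(
    y_a: np.ndarray,
    y_b: np.ndarray,
    grm: RelationshipMatrix,
    ids_a,
    ids_b,
    fixed_components_b: tuple[float, float],
    start: tuple[float, float, float] | None = None,
    max_iter: int = 200,
) -> GeneticCorrelationFit:
    """Estimate the genetic correlation between two phenotyped populations.

    Population A's variances and the genetic correlation are estimated;
    population B's genetic and environmental variances are held at
    ``fixed_components_b`` (useful when B is small).  The environmental
    cross-covariance is 0 and each population gets its own fixed mean.
    The correlation is parameterized as tanh(z), hence constrained to
    (-1, 1); estimates within 1e-3 of the boundary are flagged.
    """
    ids_a, ids_b = list(ids_a), list(ids_b)
    if set(ids_a) & set(ids_b):
        raise RemlError("the two populations share individuals")
    sa2_b, se2_b = fixed_components_b
    if sa2_b <= 0 or se2_b <= 0:
        raise RemlError("fixed variance components must be positive")
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    na, nb = len(ids_a), len(ids_b)
    if y_a.size != na or y_b.size != nb:
        raise RemlError("phenotype vectors must align with the id lists")
    g_aa = grm.submatrix(ids_a)
    g_ab = grm.submatrix(ids_a, ids_b)
    g_bb = grm.submatrix(ids_b)
    y = np.concatenate([y_a, y_b])
    x = np.zeros((na + nb, 2))
    x[:na, 0] = 1.0
    x[na:, 1] = 1.0

    if start is None:
        vary = max(float(np.var(y_a, ddof=1)), 1e-6)
        start = (np.log(vary / 2), np.log(vary / 2), np.arctanh(0.5))
    zmax = np.arctanh(0.999)
    args = (g_aa, g_ab, g_bb, sa2_b, se2_b, y, x, na)
    bounds = [(-18.0, 18.0), (-18.0, 18.0), (-zmax, zmax)]
    res = minimize(
        _bivariate_nll,
        np.asarray(start, dtype=float),
        args=args,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-10},
    )
    # derivative-free polish; the quasi-Newton step can stall where the
    # finite-difference gradient crosses an infeasible region
    polish = minimize(
        _bivariate_nll,
        res.x,
        args=args,
        method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-7, "fatol": 1e-9},
    )
    if polish.fun <= res.fun:
        res = polish
    res.x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
    nll = _bivariate_nll(res.x, g_aa, g_ab, g_bb, sa2_b, se2_b, y, x, na)
    if not np.isfinite(nll):
        raise RemlError("bivariate REML did not reach a finite optimum")
    r_g = float(np.tanh(res.x[2]))
    return GeneticCorrelationFit(
        r_g=r_g,
        sigma_a2_focal=float(np.exp(res.x[0])),
        sigma_e2_focal=float(np.exp(res.x[1])),
        sigma_a2_fixed=float(sa2_b),
        sigma_e2_fixed=float(se2_b),
        loglik=float(-nll),
        converged=bool(res.success),
        n_iter=int(res.nit),
        boundary=bool(abs(r_g) > 0.998),
    )
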