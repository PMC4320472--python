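"""Scenario orchestration: cross-validation, replicate management, and the
standard experiments comparing deterministic and empirical accuracies.

A scenario names one or two reference populations and one candidate
population.  Per replicate a trait is simulated, GREML is fitted on the
reference phenotypes with the pooled-frequency adjusted GRM, candidates
are predicted, and the EBV-TBV correlation is taken per candidate
population.  Deterministic accuracies depend only on relationships, so
they are computed once per panel: the selection-index accuracy per
candidate (own-population-frequency GRM) and the population-parameter
accuracy with the across-population effective number of segments.  The
single-population base scenario uses leave-one-out for the deterministic
accuracy and k-fold cross-validation for the empirical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd

from xpopacc.accuracy_determ import (
    DeterministicAccuracy,
    VarianceComponents,
    pp_accuracy,
    si_accuracy_multi,
    si_accuracy_per_candidate,
)
from xpopacc.genotype_io import LocusPartition, marker_qc, partition_candidates
from xpopacc.greml import blup_predict, empirical_accuracy, reml_single
from xpopacc.panel import GenotypePanel, PedigreeTable
from xpopacc.relationships import (
    build_grm,
    effective_segments,
    pedigree_nrm,
    regress_to_nrm,
    rescale_inbreeding,
    truncate_pedigree,
)
from xpopacc.synthpop import SynthConfig, simulate_multibreed_panel
from xpopacc.trait_sim import simulate_trait
from scipy.linalg import eigh


class ScenarioError(ValueError):
    """Raised for inconsistent scenario specifications."""


@dataclass
class ScenarioSpec:
    """One prediction scenario: reference population(s) and candidates."""

    name: str
    reference_populations: tuple[str, ...]
    candidate_population: str
    r_g: float = 1.0
    h2: float = 0.95
    n_qtl: int = 300
    n_replicates: int = 10
    cv_folds: int = 20
    base_seed: int = 1

    def __post_init__(self) -> None:
        if not 1 <= len(self.reference_populations) <= 2:
            raise ScenarioError("one or two reference populations supported")
        self.is_base = self.candidate_population in self.reference_populations
        if self.is_base and len(self.reference_populations) != 1:
            raise ScenarioError(
                "within-population (base) scenario takes a single reference population"
            )
        if not 0 < self.h2 <= 1:
            raise ScenarioError("heritability must be in (0, 1]")
        if abs(self.r_g) > 1:
            raise ScenarioError("|r_G| must be <= 1")


@dataclass
class AccuracyReport:
    """Replicate-level empirical accuracies plus deterministic predictions."""

    scenario: str
    empirical: pd.DataFrame  # columns: replicate, population, accuracy
    det_si: DeterministicAccuracy
    pp: float
    me: float
    n_replicates: int
    seeds: dict = field(default_factory=dict)

    def empirical_mean(self, population: str | None = None) -> float:
        df = self.empirical
        if population is not None:
            df = df[df["population"] == population]
        return float(df.groupby("replicate")["accuracy"].mean().mean())

    def empirical_se(self, population: str | None = None) -> float:
        df = self.empirical
        if population is not None:
            df = df[df["population"] == population]
        per_rep = df.groupby("replicate")["accuracy"].mean()
        if len(per_rep) < 2:
            return float("nan")
        return float(per_rep.std(ddof=1) / sqrt(len(per_rep)))


def make_cv_folds(ids, k: int = 20, seed: int = 0) -> list[np.ndarray]:
    """Random split into k disjoint folds with sizes differing by <= 1."""
    ids = np.asarray(list(ids), dtype=object)
    if k > ids.size:
        raise ScenarioError(f"cannot make {k} folds from {ids.size} individuals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def summarize_replicates(reports: list[AccuracyReport]) -> pd.DataFrame:
    """Mean, sd and standard error per scenario x method x population."""
    if not reports:
        raise ScenarioError("no replicate reports to summarize")
    rows = []
    for rep in reports:
        for pop, grp in rep.empirical.groupby("population"):
            per_rep = grp.groupby("replicate")["accuracy"].mean()
            n = len(per_rep)
            sd = float(per_rep.std(ddof=1)) if n > 1 else float("nan")
            rows.append(
                {
                    "scenario": rep.scenario,
                    "method": "empirical_greml",
                    "population": pop,
                    "mean": float(per_rep.mean()),
                    "sd": sd,
                    "se": sd / sqrt(n) if n > 1 else float("nan"),
                    "n": n,
                }
            )
        rows.append(
            {
                "scenario": rep.scenario,
                "method": "selection_index",
                "population": "candidates",
                "mean": rep.det_si.mean,
                "sd": float("nan"),
                "se": rep.det_si.se,
                "n": rep.det_si.accuracies.size,
            }
        )
        rows.append(
            {
                "scenario": rep.scenario,
                "method": "population_parameters",
                "population": "candidates",
                "mean": rep.pp,
                "sd": float("nan"),
                "se": float("nan"),
                "n": 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full scenario pipeline
# ---------------------------------------------------------------------------

def _adjusted_greml_grm(panel, pedigree, marker_indices):
    """Pooled-frequency GRM with both adjustments, plus the truncated-pedigree NRM."""
    ped7 = truncate_pedigree(pedigree, max_generations=7, focal_ids=list(panel.ids))
    nrm = pedigree_nrm(ped7)
    fcoef = {iid: float(nrm.values[i, i] - 1.0) for i, iid in enumerate(nrm.ids)}
    grm = build_grm(panel, scheme="pooled_equal_weight", locus_subset=marker_indices)
    gstar = rescale_inbreeding(grm, ped7, fcoef=fcoef)
    ghat = regress_to_nrm(gstar, nrm, n_loci=grm.n_loci, ped=ped7)
    return ghat, nrm


def _deterministic_block(spec, grm_det, reference_ids_by_pop, candidate_ids, vc):
    """Selection-index accuracy per candidate for one scenario."""
    pops = spec.reference_populations
    if spec.is_base:
        # leave-one-out: each individual predicted from the remaining ones
        label = pops[0]
        ids = list(candidate_ids)
        accs = np.empty(len(ids))
        for i, iid in enumerate(ids):
            ref = [x for x in ids if x != iid]
            acc = si_accuracy_per_candidate(grm_det, ref, [iid], vc, label, r_g=spec.r_g)
            accs[i] = acc.accuracies[0]
        return DeterministicAccuracy(accuracies=accs, method="selection_index")
    if len(pops) == 1:
        return si_accuracy_per_candidate(
            grm_det, reference_ids_by_pop[pops[0]], candidate_ids, vc, pops[0], r_g=spec.r_g
        )
    lab_b, lab_c = pops
    ids_b = reference_ids_by_pop[lab_b]
    ids_c = reference_ids_by_pop[lab_c]
    g_b = grm_det.submatrix(ids_b)
    g_c = grm_det.submatrix(ids_c)
    g_bc = grm_det.submatrix(ids_b, ids_c)
    accs = []
    for iid in candidate_ids:
        gvb = grm_det.submatrix([iid], ids_b).ravel()
        gvc = grm_det.submatrix([iid], ids_c).ravel()
        accs.append(
            si_accuracy_multi(
                gvb, gvc, g_b, g_c, g_bc, vc, (lab_b, lab_c),
                r_g_ab=spec.r_g, r_g_ac=spec.r_g, r_g_bc=1.0,
            )
        )
    return DeterministicAccuracy(accuracies=np.asarray(accs), method="selection_index")


def run_scenario(
    spec: ScenarioSpec,
    panel: GenotypePanel,
    pedigree: PedigreeTable,
    partition: LocusPartition,
    fast_cv: bool = False,
) -> AccuracyReport:
    """Run one scenario end to end on a QC'd panel.

    ``fast_cv`` reuses the variance components of the first fold across
    the remaining folds of each base-scenario replicate.
    """
    for lab in (*spec.reference_populations, spec.candidate_population):
        panel.population_mask(lab)  # raises if absent
    used_pops = list(dict.fromkeys([*spec.reference_populations, spec.candidate_population]))
    rows = np.flatnonzero(np.isin(panel.populations, used_pops))
    sub = panel.subset(individuals=rows)

    markers = partition.marker_indices
    vc = VarianceComponents.from_heritability(spec.h2, used_pops)
    grm_det = build_grm(sub, scheme="own_population", locus_subset=markers)
    ghat, nrm = _adjusted_greml_grm(sub, pedigree, markers)

    ref_ids_by_pop = {
        lab: list(sub.ids[sub.populations == lab]) for lab in spec.reference_populations
    }
    cand_ids = list(sub.ids[sub.populations == spec.candidate_population])
    all_ref_ids = (
        cand_ids if spec.is_base else [i for lab in spec.reference_populations for i in ref_ids_by_pop[lab]]
    )

    det_si = _deterministic_block(spec, grm_det, ref_ids_by_pop, cand_ids, vc)

    # population-parameter accuracy with the matching Me
    if spec.is_base:
        me = effective_segments(grm_det, nrm, cand_ids, mode="within_population")
        n_p = len(cand_ids) - 1
    else:
        me = effective_segments(
            grm_det, nrm, all_ref_ids, cand_ids, mode="across_population"
        )
        n_p = len(all_ref_ids)
    pp = pp_accuracy(n_p, spec.h2, me.me, r_g=spec.r_g)

    corr = np.full((len(used_pops), len(used_pops)), spec.r_g)
    np.fill_diagonal(corr, 1.0)
    if spec.is_base:
        corr = np.ones((1, 1))

    ref_mask = np.isin(sub.ids, all_ref_ids)
    records = []
    for rep in range(spec.n_replicates):
        trait_seed = spec.base_seed + 1000 * (rep + 1)
        arch, phen = simulate_trait(
            sub, partition.candidate_qtl_indices, spec.n_qtl, corr, spec.h2, trait_seed
        )
        if spec.is_base:
            acc = _base_scenario_replicate(
                spec, sub, ghat, phen, cand_ids, rep, fast_cv
            )
            records.append({"replicate": rep, "population": spec.candidate_population, "accuracy": acc})
        else:
            fit = reml_single(
                phen.phenotype[ref_mask], sub.populations[ref_mask], ghat, sub.ids[ref_mask]
            )
            ebv = blup_predict(fit, ghat, cand_ids)
            cand_mask = sub.populations == spec.candidate_population
            accs = empirical_accuracy(ebv, phen.tbv[cand_mask], sub.populations[cand_mask])
            for pop, acc in accs.items():
                records.append({"replicate": rep, "population": pop, "accuracy": acc})

    return AccuracyReport(
        scenario=spec.name,
        empirical=pd.DataFrame(records),
        det_si=det_si,
        pp=pp,
        me=me.me,
        n_replicates=spec.n_replicates,
        seeds={"base_seed": spec.base_seed},
    )


def _base_scenario_replicate(spec, sub, ghat, phen, ids, rep, fast_cv):
    """k-fold cross-validated empirical accuracy for one replicate."""
    folds = make_cv_folds(ids, k=spec.cv_folds, seed=spec.base_seed + 500 + rep)
    idx = {iid: i for i, iid in enumerate(sub.ids)}
    ebv = np.empty(len(ids))
    pos = {iid: i for i, iid in enumerate(ids)}
    components = None
    for fold in folds:
        ref = np.asarray([i for i in ids if i not in set(fold)], dtype=object)
        ref_rows = np.array([idx[i] for i in ref])
        y = phen.phenotype[ref_rows]
        pops = sub.populations[ref_rows]
        if fast_cv and components is not None:
            fit = _fit_with_fixed_components(y, pops, ghat, ref, components)
        else:
            fit = reml_single(y, pops, ghat, ref)
            components = (fit.sigma_a2, fit.sigma_e2)
        pred = blup_predict(fit, ghat, list(fold))
        for iid, v in zip(fold, pred):
            ebv[pos[iid]] = v
    tbv = phen.tbv[np.array([idx[i] for i in ids])]
    return float(np.corrcoef(ebv, tbv)[0, 1])


def _fit_with_fixed_components(y, pops, ghat, ref_ids, components):
    """GLS/BLUP machinery at known variance components (no REML search)."""
    from xpopacc.greml import MixedModelFit, _design_matrix

    sa2, se2 = components
    g_ref = ghat.submatrix(ref_ids)
    v = sa2 * g_ref + se2 * np.eye(len(ref_ids))
    x, levels = _design_matrix(np.asarray(pops, dtype=object))
    vinv_x = np.linalg.solve(v, x)
    beta = np.linalg.solve(x.T @ vinv_x, vinv_x.T @ y)
    resid = y - x @ beta
    vinv_resid = np.linalg.solve(v, resid)
    return MixedModelFit(
        sigma_a2=sa2,
        sigma_e2=se2,
        loglik=float("nan"),
        converged=True,
        n_iter=0,
        fixed_effects=dict(zip(levels, map(float, beta))),
        reference_ids=np.asarray(list(ref_ids), dtype=object),
        ebv_reference=sa2 * (g_ref @ vinv_resid),
        vinv_resid=vinv_resid,
    )


# ---------------------------------------------------------------------------
# standard experiments (fixed study conditions, reused by the acceptance
# entry point and the test suite)
# ---------------------------------------------------------------------------

def two_population_config(seed: int) -> SynthConfig:
    """Two populations, 400 reference / 100 candidates, ~6000 post-QC loci."""
    return SynthConfig(
        n_populations=2,
        final_panel_sizes=(400, 100),
        loci_per_chromosome=2600,
        seed=seed,
    )


def single_population_config(seed: int) -> SynthConfig:
    """One population of 400 with strong paternal half-sib structure."""
    return SynthConfig(
        n_populations=1,
        final_panel_sizes=(400,),
        loci_per_chromosome=1000,
        seed=seed,
    )


def prepare_panel(config: SynthConfig, n_candidate_qtl: int = 1000, partition_seed: int = 77):
    """Simulate, QC and partition a panel; returns (panel, pedigree, partition)."""
    panel, pedigree = simulate_multibreed_panel(config)
    panel, _ = marker_qc(panel)
    partition = partition_candidates(panel, n_candidate_qtl, seed=partition_seed)
    return panel, pedigree, partition


def deterministic_ratio_experiment(
    seed: int, r_g: float = 0.6, h2: float = 0.95
) -> dict[str, float]:
    """Mean selection-index accuracy at r_G vs at 1 on one two-population panel.

    The candidate population is predicted from the other population's 400
    reference individuals; returns the two means and their ratio in %.
    """
    panel, _, partition = prepare_panel(two_population_config(seed))
    ref_lab, cand_lab = panel.population_labels
    grm = build_grm(panel, scheme="own_population", locus_subset=partition.marker_indices)
    ref_ids = list(panel.ids[panel.populations == ref_lab])
    cand_ids = list(panel.ids[panel.populations == cand_lab])
    vc = VarianceComponents.from_heritability(h2, [ref_lab, cand_lab])
    at_one = si_accuracy_per_candidate(grm, ref_ids, cand_ids, vc, ref_lab, r_g=1.0)
    at_rg = si_accuracy_per_candidate(grm, ref_ids, cand_ids, vc, ref_lab, r_g=r_g)
    return {
        "mean_at_1": at_one.mean,
        "mean_at_rg": at_rg.mean,
        "r_g": r_g,
        "ratio_percent": 100.0 * at_rg.mean / at_one.mean,
    }


def empirical_ratio_experiment(
    seed: int,
    r_g_values: tuple[float, ...] = (1.0, 0.8, 0.2),
    n_replicates: int = 20,
    n_qtl: int = 300,
    h2: float = 0.95,
) -> dict[float, dict[str, float]]:
    """Mean empirical across-population accuracy per simulated r_G.

    One shared panel and marker set; replicate seeds are matched across
    the r_G settings so the ratio of means isolates the correlation
    effect.  GREML uses the pooled-frequency GRM with both adjustments.
    """
    panel, pedigree, partition = prepare_panel(two_population_config(seed))
    ref_lab, cand_lab = panel.population_labels
    ghat, _ = _adjusted_greml_grm(panel, pedigree, partition.marker_indices)
    ref_ids = list(panel.ids[panel.populations == ref_lab])
    cand_ids = list(panel.ids[panel.populations == cand_lab])
    ref_mask = np.isin(panel.ids, ref_ids)
    cand_mask = panel.populations == cand_lab
    eig = eigh(ghat.submatrix(ref_ids))

    out: dict[float, dict[str, float]] = {}
    for r_g in r_g_values:
        corr = np.array([[1.0, r_g], [r_g, 1.0]])
        accs = []
        for rep in range(n_replicates):
            trait_seed = seed + 1000 * (rep + 1)
            _, phen = simulate_trait(
                panel, partition.candidate_qtl_indices, n_qtl, corr, h2, trait_seed
            )
            fit = reml_single(
                phen.phenotype[ref_mask],
                panel.populations[ref_mask],
                ghat,
                ref_ids,
                eig=eig,
            )
            ebv = blup_predict(fit, ghat, cand_ids)
            acc = empirical_accuracy(ebv, phen.tbv[cand_mask], panel.populations[cand_mask])
            accs.append(acc[cand_lab])
        accs = np.asarray(accs)
        out[r_g] = {
            "mean": float(accs.mean()),
            "se": float(accs.std(ddof=1) / sqrt(len(accs))),
            "n_replicates": n_replicates,
        }
    return out


def within_population_loo_experiment(seed: int, h2: float = 0.95) -> dict[str, float]:
    """Mean leave-one-out selection-index accuracy on a single population."""
    panel, _, partition = prepare_panel(single_population_config(seed))
    label = panel.population_labels[0]
    grm = build_grm(panel, scheme="own_population", locus_subset=partition.marker_indices)
    ids = list(panel.ids)
    vc = VarianceComponents.from_heritability(h2, [label])
    accs = np.empty(len(ids))
    for i, iid in enumerate(ids):
        ref = ids[:i] + ids[i + 1:]
        accs[i] = si_accuracy_per_candidate(grm, ref, [iid], vc, label).accuracies[0]
    return {
        "mean": float(accs.mean()),
        "se": float(accs.std(ddof=1) / sqrt(len(accs))),
        "n": len(ids),
    }
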