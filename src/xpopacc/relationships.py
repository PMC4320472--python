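"""Relationship matrices and the effective number of chromosome segments.

Genomic relationships follow G = XX'/n with Yang-style standardized
dosages x = (g - 2p) / sqrt(2p(1-p)).  Two centering schemes are
supported: each individual standardized with the allele frequencies of its
own population (expectation of cross-population relationships is then 0),
or with frequencies averaged over the populations with equal weight per
population.  Pedigree relationships use the tabular method.  The two
adjustments applied to the GRM before REML — rescaling within-population
blocks to the pedigree inbreeding level and regressing towards the
pedigree matrix within relationship bins — are implemented here, as is the
effective number of chromosome segments Me = 1/Var(G_ij - A_ij).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from xpopacc.panel import GenotypePanel, PedigreeTable, PedigreeError, UNKNOWN_PARENT


class RelationshipError(ValueError):
    """Raised for invalid relationship-matrix requests."""


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencySet:
    """Observed allele frequencies per population and their pooled mean.

    ``per_population`` has one row per population (ordered as
    ``populations``); ``pooled`` is the unweighted arithmetic mean over
    populations, so it is not dominated by the largest population.
    """

    populations: list[str]
    per_population: np.ndarray  # (n_pops, n_loci)
    pooled: np.ndarray  # (n_loci,)

    def frequencies_for(self, label: str) -> np.ndarray:
        try:
            return self.per_population[self.populations.index(label)]
        except ValueError:
            raise RelationshipError(f"no frequencies for population {label!r}") from None


def allele_frequencies(panel: GenotypePanel) -> AlleleFrequencySet:
    """Per-population second-allele frequencies and their equal-weight mean."""
    labels = panel.population_labels
    rows = []
    for label in labels:
        mask = panel.population_mask(label)
        rows.append(panel.dosages[mask].mean(axis=0) / 2.0)
    per_pop = np.vstack(rows)
    return AlleleFrequencySet(
        populations=labels,
        per_population=per_pop,
        pooled=per_pop.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# relationship matrix container
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with provenance tags."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # {"genomic", "pedigree"}
    frequency_scheme: str = "not_applicable"
    n_loci: int = 0
    adjustments: set = field(default_factory=set)
    n_excluded_loci: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise RelationshipError("matrix dimension does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise RelationshipError("matrix is not symmetric")

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise RelationshipError(f"id {exc.args[0]!r} missing from matrix") from None

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        rows = self.index_of(row_ids)
        cols = rows if col_ids is None else self.index_of(col_ids)
        return self.values[np.ix_(rows, cols)]


# ---------------------------------------------------------------------------
# genomic relationship matrices
# ---------------------------------------------------------------------------

def build_grm(
    panel: GenotypePanel,
    freqs: AlleleFrequencySet | None = None,
    scheme: str = "own_population",
    locus_subset=None,
) -> RelationshipMatrix:
    """Yang-style GRM over the panel's individuals and a locus subset.

    Loci whose standardizing frequency is not strictly inside (0, 1) under
    the chosen scheme — for ``own_population``, in any of the populations
    present — are excluded entirely and counted in ``n_excluded_loci``, so
    one common denominator applies to every pair.
    """
    if scheme not in ("own_population", "pooled_equal_weight"):
        raise RelationshipError(f"unknown frequency scheme {scheme!r}")
    if freqs is None:
        freqs = allele_frequencies(panel)
    cols = np.arange(panel.n_loci) if locus_subset is None else np.asarray(locus_subset)
    dos = panel.dosages[:, cols].astype(float)

    labels = panel.population_labels
    per_pop = np.vstack([freqs.frequencies_for(lab)[cols] for lab in labels])
    if scheme == "own_population":
        usable = np.all((per_pop > 0.0) & (per_pop < 1.0), axis=0)
    else:
        pooled = per_pop.mean(axis=0)
        usable = (pooled > 0.0) & (pooled < 1.0)
    n_used = int(usable.sum())
    if n_used == 0:
        raise RelationshipError("no usable loci for GRM under the chosen scheme")
    dos = dos[:, usable]

    x = np.empty_like(dos)
    if scheme == "own_population":
        for row, lab in enumerate(labels):
            p = per_pop[row][usable]
            mask = panel.populations == lab
            x[mask] = (dos[mask] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    else:
        p = per_pop.mean(axis=0)[usable]
        x[:] = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))

    g = x @ x.T / n_used
    g = (g + g.T) / 2.0
    return RelationshipMatrix(
        values=g,
        ids=panel.ids,
        kind="genomic",
        frequency_scheme=scheme,
        n_loci=n_used,
        n_excluded_loci=int(cols.size - n_used),
    )


# ---------------------------------------------------------------------------
# pedigree relationships
# ---------------------------------------------------------------------------

def truncate_pedigree(
    ped: PedigreeTable, max_generations: int = 7, focal_ids=None
) -> PedigreeTable:
    """Cut the pedigree at ``max_generations`` above the focal individuals.

    ``focal_ids`` defaults to the terminal individuals (those that are not
    a parent of anyone).  Ancestors further than ``max_generations``
    meioses above every focal individual are dropped and references to
    them replaced by the unknown-parent sentinel.
    """
    df = ped.table
    if focal_ids is None:
        parents = set(df["sire"]) | set(df["dam"])
        focal_ids = [i for i in df["id"] if i not in parents]
    focal = set(map(str, focal_ids))
    unknown = focal - set(df["id"])
    if unknown:
        raise PedigreeError(f"focal id {sorted(unknown)[0]!r} missing from pedigree")

    parent_of = {row.id: (row.sire, row.dam) for row in df.itertuples()}
    depth = {i: 0 for i in focal}
    frontier = set(focal)
    while frontier:
        nxt = set()
        for child in frontier:
            d = depth[child] + 1
            for parent in parent_of[child]:
                if parent != UNKNOWN_PARENT and d < depth.get(parent, np.inf):
                    depth[parent] = d
                    nxt.add(parent)
        frontier = nxt

    keep = {i for i, d in depth.items() if d <= max_generations}
    out = df.loc[df["id"].isin(keep)].copy()
    for col in ("sire", "dam"):
        out.loc[~out[col].isin(keep), col] = UNKNOWN_PARENT
    return PedigreeTable(out)


def pedigree_nrm(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A_ii = 1 + F_i`` with ``F_i = 0.5 A(sire, dam)``;
    ``A_ij = 0.5 (A(j, sire_i) + A(j, dam_i))`` processed in an order where
    parents precede offspring.
    """
    order = ped.topological_ids()
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    parent_of = {row.id: (row.sire, row.dam) for row in ped.table.itertuples()}
    for i, iid in enumerate(order):
        sire, dam = parent_of[iid]
        si = index.get(sire, -1) if sire != UNKNOWN_PARENT else -1
        di = index.get(dam, -1) if dam != UNKNOWN_PARENT else -1
        f = 0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0
        a[i, i] = 1.0 + f
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * a[:i, si]
        if di >= 0:
            row += 0.5 * a[:i, di]
        a[i, :i] = row
        a[:i, i] = row
    return RelationshipMatrix(values=a, ids=np.asarray(order, dtype=object), kind="pedigree")


def inbreeding_coefficients(ped: PedigreeTable) -> dict[str, float]:
    """Pedigree inbreeding coefficient F per individual (diagonal of A − 1)."""
    nrm = pedigree_nrm(ped)
    return {iid: float(nrm.values[i, i] - 1.0) for i, iid in enumerate(nrm.ids)}


# ---------------------------------------------------------------------------
# the two GRM adjustments used before REML
# ---------------------------------------------------------------------------

def rescale_inbreeding(
    grm: RelationshipMatrix, ped: PedigreeTable, fcoef: dict[str, float] | None = None
) -> RelationshipMatrix:
    """Rescale within-population blocks to the pedigree inbreeding level.

    For each population b with mean pedigree inbreeding F̄_b of its panel
    individuals, the within-block entries become
    ``(1 − F̄_b) G + 2 F̄_b``; cross-population blocks are untouched.
    ``fcoef`` may carry precomputed inbreeding coefficients.
    """
    if grm.kind != "genomic":
        raise RelationshipError("inbreeding rescaling applies to genomic matrices")
    if fcoef is None:
        fcoef = inbreeding_coefficients(ped)
    pop_of = ped.population_of()
    missing = [i for i in grm.ids if i not in pop_of]
    if missing:
        raise RelationshipError(f"individual {missing[0]!r} has no pedigree record")
    pops = np.array([pop_of[i] for i in grm.ids], dtype=object)
    out = grm.values.copy()
    for label in dict.fromkeys(pops):
        mask = pops == label
        fbar = float(np.mean([fcoef[i] for i in grm.ids[mask]]))
        block = np.ix_(mask, mask)
        out[block] = (1.0 - fbar) * out[block] + 2.0 * fbar
    return RelationshipMatrix(
        values=out,
        ids=grm.ids,
        kind="genomic",
        frequency_scheme=grm.frequency_scheme,
        n_loci=grm.n_loci,
        adjustments=grm.adjustments | {"inbreeding_rescaled"},
        n_excluded_loci=grm.n_excluded_loci,
    )


#: Relationship bins used for the regression towards A, closed on the right;
#: cross-population pairs (A approximately 0) fall in the first bin.
DEFAULT_A_BINS = (0.10, 0.25, 0.50)


def regress_to_nrm(
    gstar: RelationshipMatrix,
    nrm: RelationshipMatrix,
    n_loci: int | None = None,
    ped: PedigreeTable | None = None,
    bins: tuple[float, ...] = DEFAULT_A_BINS,
) -> RelationshipMatrix:
    """Regress the GRM towards the pedigree matrix within relationship bins.

    Within each population pair and each bin of pedigree relationships, the
    regression coefficient ``b = (Var(G* − A) − 1/n) / Var(G* − A)`` is
    estimated over the eligible pairs — self-relationships and direct
    parent-offspring pairs are excluded, being nearly free of sampling
    error — clipped to [0, 1], and applied as ``Ĝ = A + b (G* − A)``.
    Excluded pairs and the diagonal keep their ``G*`` values.  A bin with
    at most one eligible pair defaults to ``b = 1`` (no shrinkage).
    """
    if n_loci is None:
        n_loci = gstar.n_loci
    if n_loci <= 0:
        raise RelationshipError("n_loci must be positive for the sampling-variance term")
    ids = gstar.ids
    a = nrm.submatrix(ids)
    g = gstar.values
    n = len(ids)

    # population label per individual (from pedigree when available)
    if ped is not None:
        pop_of = ped.population_of()
        pops = np.array([pop_of.get(i, "?") for i in ids], dtype=object)
    else:
        pops = np.array(["?"] * n, dtype=object)

    # parent-offspring pairs from direct pedigree links only
    po = np.zeros((n, n), dtype=bool)
    if ped is not None:
        index = {iid: k for k, iid in enumerate(ids)}
        for row in ped.table.itertuples():
            ci = index.get(row.id)
            if ci is None:
                continue
            for parent in (row.sire, row.dam):
                pi = index.get(parent)
                if pi is not None:
                    po[ci, pi] = po[pi, ci] = True

    edges = np.array([-np.inf, *bins, np.inf])
    iu, ju = np.triu_indices(n, k=1)
    pair_bin = np.searchsorted(edges, a[iu, ju], side="left") - 1
    pair_bin = np.clip(pair_bin, 0, len(edges) - 2)
    pair_class = np.array(
        [tuple(sorted((pops[i], pops[j]))) for i, j in zip(iu, ju)], dtype=object
    )
    eligible = ~po[iu, ju]

    out = g.copy()
    d = g - a
    for cls in {tuple(c) for c in pair_class}:
        cls_mask = np.array([tuple(c) == cls for c in pair_class])
        for bin_idx in range(len(edges) - 1):
            sel = cls_mask & (pair_bin == bin_idx)
            if not sel.any():
                continue
            est = sel & eligible
            dev = d[iu[est], ju[est]]
            if dev.size <= 1:
                b = 1.0
            else:
                var = float(np.var(dev, ddof=1))
                b = 1.0 if var <= 0 else float(np.clip((var - 1.0 / n_loci) / var, 0.0, 1.0))
            apply = sel & eligible  # excluded pairs stay at their G* values
            rows, colz = iu[apply], ju[apply]
            out[rows, colz] = a[rows, colz] + b * d[rows, colz]
            out[colz, rows] = out[rows, colz]
    return RelationshipMatrix(
        values=out,
        ids=ids,
        kind="genomic",
        frequency_scheme=gstar.frequency_scheme,
        n_loci=gstar.n_loci,
        adjustments=gstar.adjustments | {"regressed_to_A"},
        n_excluded_loci=gstar.n_excluded_loci,
    )


# ---------------------------------------------------------------------------
# effective number of chromosome segments
# ---------------------------------------------------------------------------

@dataclass
class EffectiveSegments:
    """Effective number of independent chromosome segments Me."""

    me: float
    mode: str  # {"within_population", "across_population"}
    n_pairs: int


def effective_segments(
    grm: RelationshipMatrix,
    nrm: RelationshipMatrix,
    reference_ids,
    candidate_ids=None,
    mode: str = "within_population",
) -> EffectiveSegments:
    """Me = 1 / Var(G_ij − A_ij) over the designated individual pairs.

    ``within_population`` uses all distinct pairs among the reference
    individuals (diagonal excluded); ``across_population`` uses every
    reference x candidate pair, with the GRM built from population-specific
    allele frequencies so unrelated pairs have expectation 0.
    """
    reference_ids = list(reference_ids)
    if mode == "within_population":
        if len(reference_ids) < 3:
            raise RelationshipError("need >= 3 reference individuals for within-population Me")
        g = grm.submatrix(reference_ids)
        a = nrm.submatrix(reference_ids)
        iu, ju = np.triu_indices(len(reference_ids), k=1)
        dev = (g - a)[iu, ju]
    elif mode == "across_population":
        if candidate_ids is None:
            raise RelationshipError("across_population mode requires candidate_ids")
        candidate_ids = list(candidate_ids)
        if set(reference_ids) & set(candidate_ids):
            raise RelationshipError("reference and candidate id sets overlap")
        g = grm.submatrix(reference_ids, candidate_ids)
        a = nrm.submatrix(reference_ids, candidate_ids)
        dev = (g - a).ravel()
    else:
        raise RelationshipError(f"unknown Me mode {mode!r}")
    if dev.size < 2:
        raise RelationshipError("not enough pairs to estimate Me")
    var = float(np.var(dev, ddof=1))
    if var <= 0.0:
        raise RelationshipError("zero variance of relationship deviations; Me is infinite")
    return EffectiveSegments(me=1.0 / var, mode=mode, n_pairs=int(dev.size))
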