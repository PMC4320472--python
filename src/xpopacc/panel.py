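"""Core in-memory containers: genotype panels and pedigrees.

A :class:`GenotypePanel` holds a complete (no missing values) individuals x
loci dosage matrix counting copies of the second allele, together with
population labels and a genetic map.  A :class:`PedigreeTable` holds
parentage records used to build numerator relationship matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an unknown parent in pedigree records.
UNKNOWN_PARENT = "0"


class PanelError(ValueError):
    """Raised for invalid genotype-panel contents."""


class PedigreeError(ValueError):
    """Raised for invalid pedigrees (cycles, missing parents)."""


@dataclass
class GenotypePanel:
    """Individuals x loci dosage matrix with population labels and a map.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_individuals, n_loci)`` with values in
        ``{0, 1, 2}`` counting copies of the second allele.  No missing
        values are allowed.
    ids
        Individual identifiers, unique.
    populations
        Population label per individual.
    locus_ids
        Locus identifiers, unique.
    chromosomes
        Chromosome index per locus.
    positions_cm
        Genetic position (cM) per locus; strictly increasing within a
        chromosome.
    """

    dosages: np.ndarray
    ids: np.ndarray
    populations: np.ndarray
    locus_ids: np.ndarray
    chromosomes: np.ndarray
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.ids = np.asarray(self.ids, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.validate()

    # -- basic shape ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def population_labels(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.ids) != n or len(self.populations) != n:
            raise PanelError("individual annotation length mismatch")
        if len(self.locus_ids) != m or len(self.chromosomes) != m or len(self.positions_cm) != m:
            raise PanelError("locus annotation length mismatch")
        if len(set(self.ids)) != n:
            raise PanelError("individual ids are not unique")
        bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise PanelError(
                f"dosage out of range at individual {self.ids[i]!r}, "
                f"locus {self.locus_ids[k]!r}: {self.dosages[i, k]}"
            )
        for c in np.unique(self.chromosomes):
            pos = self.positions_cm[self.chromosomes == c]
            if np.any(np.diff(pos) <= 0):
                raise PanelError(f"positions not strictly increasing on chromosome {c}")

    # -- selection helpers ---------------------------------------------
    def individual_index(self, ids) -> np.ndarray:
        """Row indices of the given individual ids (order preserved)."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise PanelError(f"unknown individual id {exc.args[0]!r}") from None

    def population_mask(self, label: str) -> np.ndarray:
        mask = self.populations == label
        if not mask.any():
            raise PanelError(f"population {label!r} not present in panel")
        return mask

    def subset(self, individuals=None, loci=None) -> "GenotypePanel":
        """Return a new panel restricted to row/column index arrays."""
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(rows, cols)],
            ids=self.ids[rows],
            populations=self.populations[rows],
            locus_ids=self.locus_ids[cols],
            chromosomes=self.chromosomes[cols],
            positions_cm=self.positions_cm[cols],
        )

    def __eq__(self, other) -> bool:  # identity of content, used in round-trip tests
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.populations, other.populations)
            and np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.allclose(self.positions_cm, other.positions_cm)
        )


@dataclass
class PedigreeTable:
    """Parentage records ``(id, sire, dam, population, generation)``.

    Unknown parents carry the sentinel ``"0"``.  Validation checks that the
    parent-child graph is acyclic and every named parent has a record.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("id", "sire", "dam", "population", "generation")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        for col in ("id", "sire", "dam", "population"):
            df[col] = df[col].astype(str)
        df["generation"] = df["generation"].astype(int)
        self.table = df.reset_index(drop=True)
        self.validate()

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(dtype=object)

    def validate(self) -> None:
        df = self.table
        ids = set(df["id"])
        if len(ids) != len(df):
            raise PedigreeError("duplicate individual ids in pedigree")
        for col in ("sire", "dam"):
            named = df.loc[df[col] != UNKNOWN_PARENT, col]
            unknown = set(named) - ids
            if unknown:
                raise PedigreeError(
                    f"{col} {sorted(unknown)[0]!r} is not an individual in the pedigree"
                )
        self._toposort()

    def _toposort(self) -> list[str]:
        """Kahn topological order parents-before-children; raises on cycles."""
        df = self.table
        children: dict[str, list[str]] = {i: [] for i in df["id"]}
        indeg = {i: 0 for i in df["id"]}
        for _, row in df.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent != UNKNOWN_PARENT:
                    children[parent].append(row["id"])
                    indeg[row["id"]] += 1
        queue = [i for i, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            node = queue.pop()
            order.append(node)
            for child in children[node]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(df):
            raise PedigreeError("cycle detected in pedigree")
        return order

    def topological_ids(self) -> list[str]:
        """Individual ids ordered so parents precede their offspring."""
        return self._toposort()

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == individual]
        if row.empty:
            raise PedigreeError(f"individual {individual!r} missing from pedigree")
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["population"]))
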