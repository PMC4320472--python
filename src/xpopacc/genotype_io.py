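"""Readers/writers for panels, pedigrees and relationship matrices, plus
marker quality control and the candidate-QTL/marker partition.

Supported on-disk formats
-------------------------
* genotypes: a PLINK ``.raw``-style whitespace table
  (``FID IID PAT MAT SEX PHENOTYPE <locus>...``, FID = population) or a
  simple CSV (``id,population,<locus>...``); both carry a sidecar map file
  at ``<path>.map`` with columns ``chromosome,locus,position_cm``
* pedigree: CSV with header ``id,sire,dam,population,generation``
  (``0`` = unknown parent)
* relationship matrices: GCTA-style text pair — ``<prefix>.grm.id`` (two
  columns) and ``<prefix>.grm.txt`` with lower-triangle triplet lines
  ``i j n_snps value`` (1-based indices)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from xpopacc.panel import GenotypePanel, PanelError, PedigreeTable


class FormatError(ValueError):
    """Raised for malformed genotype/pedigree/GRM files."""


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------

def _map_path(path) -> Path:
    return Path(str(path) + ".map")


def write_panel(panel: GenotypePanel, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(panel.dosages, columns=panel.locus_ids)
        df.insert(0, "population", panel.populations)
        df.insert(0, "id", panel.ids)
        df.to_csv(path, index=False)
    elif format == "plink_raw":
        df = pd.DataFrame(panel.dosages, columns=panel.locus_ids)
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", panel.ids)
        df.insert(0, "FID", panel.populations)
        df.to_csv(path, sep=" ", index=False)
    else:
        raise FormatError(f"unknown panel format {format!r}")
    pd.DataFrame(
        {
            "chromosome": panel.chromosomes,
            "locus": panel.locus_ids,
            "position_cm": panel.positions_cm,
        }
    ).to_csv(_map_path(path), index=False)


def read_panel(path, format: str = "csv") -> GenotypePanel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, dtype={"id": str, "population": str})
        if list(df.columns[:2]) != ["id", "population"]:
            raise FormatError(f"{path}: CSV header must start with 'id,population'")
        ids = df["id"].to_numpy(dtype=object)
        pops = df["population"].to_numpy(dtype=object)
        geno = df.iloc[:, 2:]
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
        expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != expected:
            raise FormatError(f"{path}: malformed .raw header, expected {expected}")
        ids = df["IID"].to_numpy(dtype=object)
        pops = df["FID"].to_numpy(dtype=object)
        geno = df.iloc[:, 6:]
    else:
        raise FormatError(f"unknown panel format {format!r}")

    if geno.isna().any().any():
        row, col = np.argwhere(geno.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing dosage for individual {ids[row]!r} at locus "
            f"{geno.columns[col]!r} (missing genotypes are not supported)"
        )
    dosages = geno.to_numpy()
    bad = (dosages < 0) | (dosages > 2) | (dosages != np.floor(dosages))
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid dosage {dosages[row, col]!r} for individual "
            f"{ids[row]!r} at locus {geno.columns[col]!r}"
        )

    mpath = _map_path(path)
    if not mpath.exists():
        raise FormatError(f"missing sidecar map file {mpath}")
    gmap = pd.read_csv(mpath)
    if list(gmap["locus"].astype(str)) != [str(c) for c in geno.columns]:
        raise FormatError(f"{mpath}: map loci do not match genotype columns")
    try:
        return GenotypePanel(
            dosages=dosages.astype(np.int8),
            ids=ids,
            populations=pops,
            locus_ids=np.asarray(geno.columns, dtype=object),
            chromosomes=gmap["chromosome"].to_numpy(),
            positions_cm=gmap["position_cm"].to_numpy(),
        )
    except PanelError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def write_pedigree(ped: PedigreeTable, path) -> None:
    ped.table.to_csv(path, index=False)


def read_pedigree(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str, "population": str})
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# GCTA-style relationship matrices
# ---------------------------------------------------------------------------

def write_grm(matrix: np.ndarray, ids, prefix, n_snps: int = 0) -> None:
    """Write a symmetric matrix as GCTA text (``.grm.txt`` + ``.grm.id``)."""
    matrix = np.asarray(matrix, dtype=float)
    ids = list(ids)
    n = len(ids)
    if matrix.shape != (n, n):
        raise FormatError("matrix dimension does not match id count")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")
    with open(str(prefix) + ".grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{matrix[i, j]:.10g}\n")


def read_grm(prefix) -> tuple[np.ndarray, list[str], int]:
    """Read a GCTA text pair; returns (matrix, ids, n_snps)."""
    id_path = Path(str(prefix) + ".grm.id")
    mat_path = Path(str(prefix) + ".grm.txt")
    if not id_path.exists() or not mat_path.exists():
        raise FileNotFoundError(f"expected {id_path} and {mat_path}")
    ids = [line.split()[1] for line in id_path.read_text().splitlines() if line.strip()]
    n = len(ids)
    matrix = np.zeros((n, n))
    n_snps = 0
    for line in mat_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{mat_path}: malformed triplet line {line!r}")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        n_snps = int(parts[2])
        matrix[i, j] = matrix[j, i] = float(parts[3])
    return matrix, ids, n_snps


# ---------------------------------------------------------------------------
# marker quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Counts of loci removed per filtering rule."""

    maf_low: int
    two_genotype_classes: int
    adjacent_complete_ld: int
    retained: int

    @property
    def removed(self) -> int:
        return self.maf_low + self.two_genotype_classes + self.adjacent_complete_ld


def marker_qc(panel: GenotypePanel, maf_threshold: float = 0.005) -> tuple[GenotypePanel, QcReport]:
    """Apply the marker filters, in order.

    1. pooled minor allele frequency equal to or below ``maf_threshold``;
    2. fewer than three genotype classes observed in the pooled panel;
    3. squared dosage correlation of exactly 1 with the nearest retained
       locus to the left on the same chromosome (the leftmost of such a
       pair is kept).
    """
    if panel.n_loci == 0:
        raise PanelError("empty panel")
    dos = panel.dosages
    freq = dos.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > maf_threshold
    n_maf = int((~keep).sum())

    n_classes = np.array([np.unique(dos[:, k]).size for k in range(panel.n_loci)])
    two_class = keep & (n_classes < 3)
    n_two = int(two_class.sum())
    keep &= ~two_class

    # adjacent complete LD, scanned left to right per chromosome
    n_ld = 0
    centered = dos - dos.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    for c in np.unique(panel.chromosomes):
        idx = np.flatnonzero((panel.chromosomes == c) & keep)
        prev = None
        for k in idx:
            if prev is not None:
                denom = norms[prev] * norms[k]
                r = (centered[:, prev] @ centered[:, k]) / denom if denom > 0 else 0.0
                if r * r >= 1.0 - 1e-12:
                    keep[k] = False
                    n_ld += 1
                    continue
            prev = k

    retained = int(keep.sum())
    report = QcReport(
        maf_low=n_maf,
        two_genotype_classes=n_two,
        adjacent_complete_ld=n_ld,
        retained=retained,
    )
    if retained == 0:
        raise PanelError("marker QC removed all loci")
    return panel.subset(loci=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# candidate-QTL / marker partition
# ---------------------------------------------------------------------------

@dataclass
class LocusPartition:
    """Disjoint split of retained loci into candidate QTL and markers.

    The candidate set is a uniform random sample without replacement; the
    remaining loci are the markers, kept constant across replicates.
    """

    candidate_qtl_indices: np.ndarray
    marker_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        cand = set(self.candidate_qtl_indices.tolist())
        mark = set(self.marker_indices.tolist())
        if cand & mark:
            raise ValueError("candidate and marker sets overlap")


def partition_candidates(panel: GenotypePanel, n_candidates: int, seed: int) -> LocusPartition:
    total = panel.n_loci
    if n_candidates >= total:
        raise ValueError(f"n_candidates={n_candidates} must be below total loci {total}")
    rng = np.random.default_rng(seed)
    cand = np.sort(rng.choice(total, size=n_candidates, replace=False))
    mask = np.ones(total, dtype=bool)
    mask[cand] = False
    return LocusPartition(
        candidate_qtl_indices=cand,
        marker_indices=np.flatnonzero(mask),
        seed=seed,
    )
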