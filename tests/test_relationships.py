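"""Relationship matrices: frequencies, GRM schemes, NRM, adjustments, Me."""

import numpy as np
import pytest

from xpopacc.panel import UNKNOWN_PARENT
from xpopacc.relationships import (
    RelationshipError,
    RelationshipMatrix,
    allele_frequencies,
    build_grm,
    effective_segments,
    inbreeding_coefficients,
    pedigree_nrm,
    regress_to_nrm,
    rescale_inbreeding,
    truncate_pedigree,
)

from conftest import make_panel, make_pedigree


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_pooled_is_equal_weight_mean(self):
        dos = np.array([[0, 1], [1, 1], [2, 2], [2, 2], [2, 2], [2, 2]])
        panel = make_panel(dos, populations=["A", "A", "B", "B", "C", "C"])
        freqs = allele_frequencies(panel)
        # per-population frequencies at locus 0: 0.25, 1.0, 1.0
        assert freqs.pooled[0] == pytest.approx((0.25 + 1.0 + 1.0) / 3)

    def test_hand_counted_toy(self, toy_two_pop_panel):
        freqs = allele_frequencies(toy_two_pop_panel)
        expected_a = np.array([1, 2, 4, 1]) / 4.0
        expected_b = np.array([4, 2, 1, 2]) / 4.0
        assert np.allclose(freqs.frequencies_for("A"), expected_a)
        assert np.allclose(freqs.frequencies_for("B"), expected_b)
        assert np.allclose(freqs.pooled, (expected_a + expected_b) / 2)

    def test_monomorphic_locus_excluded_from_grm(self):
        dos = np.array([[0, 1], [0, 1], [0, 2], [0, 0]])
        panel = make_panel(dos)
        grm = build_grm(panel, scheme="own_population")
        assert grm.n_loci == 1 and grm.n_excluded_loci == 1


# ---------------------------------------------------------------------------
# genomic relationship matrices
# ---------------------------------------------------------------------------

class TestBuildGrm:
    def test_single_locus_closed_form(self):
        panel = make_panel(np.array([[0], [2]]))
        grm = build_grm(panel, scheme="own_population")
        # p = 0.5: x = -sqrt(2), +sqrt(2); G = xx'/1
        assert np.allclose(grm.values, [[2, -2], [-2, 2]])

    def test_cross_population_blocks_center_to_zero(self, small_sim):
        panel, _, _ = small_sim
        grm = build_grm(panel, scheme="own_population")
        lab_a, lab_b = panel.population_labels
        block = grm.submatrix(
            panel.ids[panel.populations == lab_a],
            panel.ids[panel.populations == lab_b],
        )
        assert abs(block.mean()) < 1e-12

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(5, 10))
        panel = make_panel(dos, populations=["A"] * 3 + ["B"] * 2)
        grm = build_grm(panel, scheme="pooled_equal_weight")
        freqs = allele_frequencies(panel)
        p = freqs.pooled
        usable = (p > 0) & (p < 1)
        x = (dos[:, usable] - 2 * p[usable]) / np.sqrt(2 * p[usable] * (1 - p[usable]))
        n = usable.sum()
        for i in range(5):
            for j in range(5):
                assert grm.values[i, j] == pytest.approx(
                    sum(x[i, k] * x[j, k] for k in range(n)) / n
                )

    def test_mean_diagonal_near_one_for_outbred_panel(self, small_sim):
        panel, _, _ = small_sim
        grm = build_grm(panel, scheme="own_population")
        for lab in panel.population_labels:
            ids = panel.ids[panel.populations == lab]
            diag = np.diag(grm.submatrix(ids))
            assert abs(diag.mean() - 1.0) < 0.08

    def test_unknown_scheme_rejected(self, toy_two_pop_panel):
        with pytest.raises(RelationshipError):
            build_grm(toy_two_pop_panel, scheme="nonsense")


# ---------------------------------------------------------------------------
# pedigree relationships
# ---------------------------------------------------------------------------

def kinship_oracle(ped):
    """Recursive coefficient-of-kinship oracle; A = 2f off the tabular path."""
    parent_of = {r.id: (r.sire, r.dam) for r in ped.table.itertuples()}
    order = {iid: k for k, iid in enumerate(ped.topological_ids())}

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == UNKNOWN_PARENT or j == UNKNOWN_PARENT:
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        si, di = parent_of[i]
        if i == j:
            return 0.5 * (1.0 + f(si, di))
        return 0.5 * (f(si, j) + f(di, j))

    ids = list(ped.ids)
    return ids, np.array([[2 * f(i, j) for j in ids] for i in ids])


PEDIGREES = {
    "parent_offspring": [
        ("S", "0", "0", "P", 0),
        ("D", "0", "0", "P", 0),
        ("O", "S", "D", "P", 1),
    ],
    "half_sib_mating": [
        ("S", "0", "0", "P", 0),
        ("D1", "0", "0", "P", 0),
        ("D2", "0", "0", "P", 0),
        ("H1", "S", "D1", "P", 1),
        ("H2", "S", "D2", "P", 1),
        ("X", "H1", "H2", "P", 2),
    ],
    "full_sib_chain": [
        ("A", "0", "0", "P", 0),
        ("B", "0", "0", "P", 0),
        ("C", "A", "B", "P", 1),
        ("D", "A", "B", "P", 1),
        ("E", "C", "D", "P", 2),
        ("F", "C", "D", "P", 2),
        ("G", "E", "F", "P", 3),
    ],
    "mixed": [
        ("A", "0", "0", "P", 0),
        ("B", "0", "0", "P", 0),
        ("C", "0", "0", "P", 0),
        ("D", "A", "B", "P", 1),
        ("E", "A", "C", "P", 1),
        ("F", "D", "E", "P", 2),
        ("G", "D", "C", "P", 2),
        ("H", "F", "G", "P", 3),
    ],
}


class TestPedigreeNrm:
    def test_parent_offspring_textbook_values(self):
        ped = make_pedigree(PEDIGREES["parent_offspring"])
        nrm = pedigree_nrm(ped)
        assert nrm.submatrix(["S"], ["O"])[0, 0] == 0.5
        assert nrm.submatrix(["O"])[0, 0] == 1.0

    def test_half_sib_mating_inbreeding(self):
        ped = make_pedigree(PEDIGREES["half_sib_mating"])
        assert inbreeding_coefficients(ped)["X"] == pytest.approx(0.125)
        nrm = pedigree_nrm(ped)
        assert nrm.submatrix(["X"])[0, 0] == pytest.approx(1.125)

    @pytest.mark.parametrize("name", sorted(PEDIGREES))
    def test_matches_kinship_oracle(self, name):
        ped = make_pedigree(PEDIGREES[name])
        ids, expected = kinship_oracle(ped)
        nrm = pedigree_nrm(ped)
        assert np.allclose(nrm.submatrix(ids), expected, atol=1e-12)


class TestTruncatePedigree:
    @staticmethod
    def chain(n):
        rows = [("I0", "0", "0", "P", 0)]
        rows += [(f"I{g}", f"I{g-1}", "0", "P", g) for g in range(1, n)]
        return rows

    def test_deep_ancestors_cut_to_unknown(self):
        ped = make_pedigree(self.chain(10))  # I9 has 9 generations of ancestors
        cut = truncate_pedigree(ped, max_generations=7, focal_ids=["I9"])
        kept = set(cut.ids)
        assert kept == {f"I{g}" for g in range(2, 10)}
        assert cut.parents_of("I2") == (UNKNOWN_PARENT, UNKNOWN_PARENT)

    def test_truncated_nrm_equals_manual_truncation(self):
        ped = make_pedigree(self.chain(10))
        cut = truncate_pedigree(ped, max_generations=7, focal_ids=["I9"])
        manual_rows = [("I2", "0", "0", "P", 2)] + [
            (f"I{g}", f"I{g-1}", "0", "P", g) for g in range(3, 10)
        ]
        manual = make_pedigree(manual_rows)
        ids = [f"I{g}" for g in range(2, 10)]
        assert np.allclose(
            pedigree_nrm(cut).submatrix(ids), pedigree_nrm(manual).submatrix(ids)
        )

    def test_noop_on_shallow_pedigree(self, small_sim):
        _, ped, _ = small_sim
        cut = truncate_pedigree(ped, max_generations=7)
        assert set(cut.ids) == set(ped.ids)


# ---------------------------------------------------------------------------
# GRM adjustments
# ---------------------------------------------------------------------------

def _grm_with_ped(seed=0, n=8):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 30))
    g = x @ x.T / 30
    ids = [f"I{i}" for i in range(n)]
    pops = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    grm = RelationshipMatrix(g, ids, kind="genomic", n_loci=30)
    ped = make_pedigree([(i, "0", "0", p, 0) for i, p in zip(ids, pops)])
    return grm, ped, ids, pops


class TestRescaleInbreeding:
    def test_zero_inbreeding_is_identity(self):
        grm, ped, ids, _ = _grm_with_ped()
        out = rescale_inbreeding(grm, ped)
        assert np.array_equal(out.values, grm.values)
        assert "inbreeding_rescaled" in out.adjustments

    def test_direct_substitution_at_fbar_half(self):
        grm, ped, ids, pops = _grm_with_ped()
        fcoef = {i: (0.5 if p == "A" else 0.0) for i, p in zip(ids, pops)}
        out = rescale_inbreeding(grm, ped, fcoef=fcoef)
        a_ids = [i for i, p in zip(ids, pops) if p == "A"]
        expected = 0.5 * grm.submatrix(a_ids) + 1.0
        assert np.allclose(out.submatrix(a_ids), expected)

    def test_cross_population_block_untouched(self):
        grm, ped, ids, pops = _grm_with_ped()
        fcoef = {i: 0.3 for i in ids}
        out = rescale_inbreeding(grm, ped, fcoef=fcoef)
        a_ids = [i for i, p in zip(ids, pops) if p == "A"]
        b_ids = [i for i, p in zip(ids, pops) if p == "B"]
        assert np.array_equal(out.submatrix(a_ids, b_ids), grm.submatrix(a_ids, b_ids))
        assert np.allclose(out.values, out.values.T)


class TestRegressToNrm:
    def test_limit_b_one_reproduces_gstar(self):
        """Var(G*-A) >> 1/n: no shrinkage."""
        grm, ped, ids, _ = _grm_with_ped(seed=1)
        a = RelationshipMatrix(np.eye(len(ids)), ids, kind="pedigree")
        out = regress_to_nrm(grm, a, n_loci=10**9, ped=ped)
        assert np.allclose(out.values, grm.values, atol=1e-9)

    def test_arithmetic_oracle_single_bin(self):
        """Var(G*-A)=0.02 with n=100 loci gives b=0.5 exactly."""
        ids = ["a", "b", "c", "d"]
        a = RelationshipMatrix(np.eye(4), ids, kind="pedigree")
        # +-d pattern with zero mean: sample variance 6 d^2 / 5 = 0.02
        dev = np.sqrt(0.02 * 5 / 6) * np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        g = np.eye(4)
        iu, ju = np.triu_indices(4, k=1)
        g[iu, ju] = dev
        g[ju, iu] = dev
        assert np.var(g[iu, ju], ddof=1) == pytest.approx(0.02)
        grm = RelationshipMatrix(g, ids, kind="genomic", n_loci=100)
        out = regress_to_nrm(grm, a, n_loci=100)
        expected = 0.5 * g[iu, ju]  # A=0 off-diagonal, b = (0.02-0.01)/0.02
        assert np.allclose(out.values[iu, ju], expected)
        assert np.allclose(np.diag(out.values), np.diag(g))  # self pairs untouched

    def test_degenerate_bin_defaults_to_one(self):
        ids = ["a", "b"]
        a = RelationshipMatrix(np.eye(2), ids, kind="pedigree")
        g = np.array([[1.0, 0.3], [0.3, 1.0]])
        grm = RelationshipMatrix(g, ids, kind="genomic", n_loci=100)
        out = regress_to_nrm(grm, a, n_loci=100)  # single eligible pair
        assert np.allclose(out.values, g)

    def test_parent_offspring_pairs_keep_gstar_value(self):
        ids = ["S", "D", "O", "U"]
        ped = make_pedigree(
            [("S", "0", "0", "P", 0), ("D", "0", "0", "P", 0),
             ("O", "S", "D", "P", 1), ("U", "0", "0", "P", 0)]
        )
        nrm = pedigree_nrm(ped)
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 20))
        g = x @ x.T / 20
        grm = RelationshipMatrix(g, ids, kind="genomic", n_loci=20)
        out = regress_to_nrm(grm, nrm, n_loci=20, ped=ped)
        i, j = 0, 2  # S-O parent-offspring
        assert out.values[i, j] == g[i, j]


# ---------------------------------------------------------------------------
# effective number of chromosome segments
# ---------------------------------------------------------------------------

class TestEffectiveSegments:
    @staticmethod
    def _mats(dev, ids):
        n = len(ids)
        a = RelationshipMatrix(np.eye(n), ids, kind="pedigree")
        g = np.eye(n) + dev
        g = (g + g.T) / 2
        return RelationshipMatrix(g, ids, kind="genomic"), a

    def test_reciprocal_of_pair_variance(self):
        rng = np.random.default_rng(0)
        ids = [f"I{i}" for i in range(6)]
        dev = rng.normal(0, 0.1, (6, 6))
        grm, nrm = self._mats(dev, ids)
        res = effective_segments(grm, nrm, ids, mode="within_population")
        iu, ju = np.triu_indices(6, k=1)
        expected = 1.0 / np.var((grm.values - np.eye(6))[iu, ju], ddof=1)
        assert res.me == pytest.approx(expected)
        assert res.n_pairs == 15

    def test_across_mode_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        ids = [f"I{i}" for i in range(7)]
        dev = rng.normal(0, 0.05, (7, 7))
        grm, nrm = self._mats(dev, ids)
        refs, cands = ids[:4], ids[4:]
        res = effective_segments(grm, nrm, refs, cands, mode="across_population")
        vals = [
            grm.submatrix([r], [c])[0, 0] - nrm.submatrix([r], [c])[0, 0]
            for r in refs
            for c in cands
        ]
        assert res.me == pytest.approx(1.0 / np.var(vals, ddof=1))
        assert res.n_pairs == 12

    def test_zero_variance_is_an_error(self):
        ids = ["a", "b", "c"]
        grm, nrm = self._mats(np.zeros((3, 3)), ids)
        with pytest.raises(RelationshipError, match="infinite"):
            effective_segments(grm, nrm, ids, mode="within_population")

    def test_overlapping_sets_rejected_in_across_mode(self):
        rng = np.random.default_rng(2)
        ids = [f"I{i}" for i in range(5)]
        grm, nrm = self._mats(rng.normal(0, 0.1, (5, 5)), ids)
        with pytest.raises(RelationshipError, match="overlap"):
            effective_segments(grm, nrm, ids[:3], ids[2:], mode="across_population")
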