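"""Pair scores, APC, pressures, class partitions, PPV."""

import numpy as np
import pytest

from lpbench.contact_scoring import (
    PairScoreMatrix,
    apc,
    classify_pairs,
    contact_matrix_top_eigenvalue,
    frobenius_apc_scores,
    ppv_curve,
    pressure_denominator,
    pressures,
    theoretical_pressures,
)
from lpbench.energetics import CompetitorProfile, competitor_profile
from lpbench.lattice_conformations import ContactMap, enumerate_compact_folds, forbidden_pairs
from lpbench.potts_inference import PottsModel
from lpbench.workbench import hp_energy_matrix


class TestAPC:
    def test_constant_matrix_maps_to_zero(self):
        F = np.full((6, 6), 3.0)
        assert np.allclose(apc(F), 0.0, atol=1e-10)

    def test_rank_one_background_removed(self):
        r = np.array([1.0, 2.0, 0.5, 3.0])
        F = np.outer(r, r)
        np.fill_diagonal(F, 0.0)
        # rank-one with zero diagonal is not exactly annihilated; use the
        # exact product structure including the diagonal contribution
        F2 = np.outer(r, r)
        corrected = apc(F2)
        offdiag = corrected[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(offdiag)) < 0.35 * np.max(F2)


class TestFrobeniusScores:
    def test_single_block_dominates(self, random_model_factory):
        m = random_model_factory(5, 3, seed=0)
        m.J[:] = 0.0
        block = np.random.default_rng(1).normal(size=(3, 3))
        m.J[1, 3] = block
        m.J[3, 1] = block.T
        scores = frobenius_apc_scores(m, apply_apc=False)
        assert scores.ranked_pairs()[0] == (1, 3)
        assert scores.scores[1, 3] == pytest.approx(np.sum(block**2))

    def test_literal_transcription_of_apc(self, random_model_factory):
        m = random_model_factory(6, 3, seed=2)
        F = np.einsum("ijab->ij", m.J**2)
        np.fill_diagonal(F, 0.0)
        row = F.sum(axis=1) / 5  # mean over the 5 partners
        expected = F - np.outer(row, row) / (F.sum() / 30)
        np.fill_diagonal(expected, 0.0)
        got = frobenius_apc_scores(m).scores
        assert np.allclose(got, expected, atol=1e-12)

    def test_score_matrix_validation(self):
        with pytest.raises(ValueError):
            PairScoreMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), "MI")  # asymmetric


class TestPressures:
    def _uniformish_freqs(self, L, q, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(q) * 5, size=L)
        return f

    def test_projection_identity(self):
        E = hp_energy_matrix(3)
        L, q = 4, 3
        f = self._uniformish_freqs(L, q)
        cons = np.argmax(f, axis=1)
        lam_true = {(0, 1): 1.7, (0, 2): -0.6, (0, 3): 0.0, (1, 2): 0.9,
                    (1, 3): -1.2, (2, 3): 0.4}
        J = np.zeros((L, L, q, q))
        for (i, j), lam in lam_true.items():
            Eg = (E.matrix - E.matrix[cons[i], :][None, :]
                  - E.matrix[:, cons[j]][:, None] + E.matrix[cons[i], cons[j]])
            J[i, j] = lam * (-Eg)
            J[j, i] = J[i, j].T
        model = PottsModel(np.zeros((L, q)), J, gauge="consensus")
        pm = pressures(model, E, f, restrict_to_observed=False)
        for (i, j), lam in lam_true.items():
            assert pm.lam[i, j] == pytest.approx(lam, abs=1e-10)

    def test_constant_energy_matrix_gives_zero(self):
        from lpbench.energetics import ContactEnergyMatrix

        E = ContactEnergyMatrix("AB", np.full((2, 2), -1.0))
        f = self._uniformish_freqs(3, 2, seed=1)
        rng = np.random.default_rng(2)
        J = np.zeros((3, 3, 2, 2))
        b = rng.normal(size=(2, 2))
        J[0, 1] = b
        J[1, 0] = b.T
        model = PottsModel(np.zeros((3, 2)), J, gauge="consensus")
        pm = pressures(model, E, f, restrict_to_observed=False)
        assert np.allclose(pm.lam, 0.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, random_model_factory):
        model = random_model_factory(4, 3, seed=3)
        with pytest.raises(ValueError):
            pressures(model, hp_energy_matrix(3), np.ones((5, 3)) / 3)


class TestTheoreticalPressures:
    def test_zero_where_maps_agree(self):
        cmap = ContactMap(frozenset({(0, 3)}), 4)
        cbar = cmap.dense.astype(float)
        prof = CompetitorProfile(0, np.array([0.0, 1.0]), np.exp(-1.0), cbar, 1)
        pm = theoretical_pressures(prof, cmap, beta=100.0)
        assert np.allclose(pm.lam, 0.0, atol=1e-12)

    def test_literal_transcription_on_two_structure_library(self):
        lib = enumerate_compact_folds((2, 2, 2))
        two = type(lib)(lib.walks[:2], lib.box)
        E = hp_energy_matrix(2)
        rng = np.random.default_rng(4)
        msa = rng.integers(0, 2, size=(10, 8)).astype(np.int8)
        prof = competitor_profile(0, two, msa, E)
        beta = 50.0
        pm = theoretical_pressures(prof, two.contact_map(0), beta)
        c = two.contact_map(0).dense
        denom = np.log(1 + 1 / (beta * prof.aggregate))
        expected = (c - prof.cbar) / denom
        assert np.allclose(pm.lam, expected, atol=1e-12)

    def test_denominator_functional_form(self):
        assert pressure_denominator(1e3, 5e-3) == pytest.approx(np.log(1.2))


class TestClassification:
    def test_native_as_its_own_competitor(self):
        lib = enumerate_compact_folds((2, 2, 2))
        cmap = lib.contact_map(0)
        classes = classify_pairs(cmap, cmap)
        counts = classes.counts()
        assert counts["SN"] == 5 and counts["UN"] == 0 and counts["CC"] == 0

    def test_partition_covers_all_pairs(self):
        lib = enumerate_compact_folds((2, 2, 2))
        classes = classify_pairs(lib.contact_map(0), lib.contact_map(1))
        counts = classes.counts()
        L = 8
        assert sum(counts.values()) == L * (L - 1) // 2
        assert counts["UN"] + counts["SN"] == 5
        assert counts["forbidden"] == len(forbidden_pairs(L))

    def test_labels_match_definitions(self):
        lib = enumerate_compact_folds((2, 2, 2))
        native, comp = lib.contact_map(0), lib.contact_map(2)
        classes = classify_pairs(native, comp)
        for (i, j), label in classes.labels.items():
            in_nat, in_comp = (i, j) in native, (i, j) in comp
            if (i, j) in forbidden_pairs(8):
                assert label == "forbidden"
            elif in_nat and in_comp:
                assert label == "SN"
            elif in_nat:
                assert label == "UN"
            elif in_comp:
                assert label == "CC"
            else:
                assert label == "NN"


class TestPPV:
    def test_perfect_scores(self):
        lib = enumerate_compact_folds((2, 2, 2))
        truth = lib.contact_map(0)
        scores = PairScoreMatrix(truth.dense.astype(float), "MI")
        ppv = ppv_curve(scores, truth)
        n = len(truth)
        assert np.allclose(ppv[:n], 1.0)
        assert np.all(np.diff(ppv[n - 1 :]) <= 1e-12)  # non-increasing beyond

    def test_random_scores_hit_base_rate(self):
        lib = enumerate_compact_folds((2, 2, 2))
        truth = lib.contact_map(0)
        rng = np.random.default_rng(6)
        finals = []
        for _ in range(50):
            s = rng.normal(size=(8, 8))
            s = s + s.T
            np.fill_diagonal(s, 0.0)
            ppv = ppv_curve(PairScoreMatrix(s, "MI"), truth)
            finals.append(ppv[9])  # PPV at rank 10 of 21 ranked pairs
        base = len(truth) / 21
        assert np.mean(finals) == pytest.approx(base, abs=0.08)

    def test_forbidden_exclusion_flag(self):
        lib = enumerate_compact_folds((2, 2, 2))
        truth = lib.contact_map(0)
        scores = PairScoreMatrix(np.ones((8, 8)) - np.eye(8), "MI")
        full = ppv_curve(scores, truth, exclude_forbidden=False)
        reduced = ppv_curve(scores, truth, exclude_forbidden=True)
        assert len(reduced) < len(full)
        assert reduced[-1] == pytest.approx(5 / len(reduced))

    def test_ranking_tie_break_deterministic(self):
        s = np.zeros((5, 5))
        scores = PairScoreMatrix(s, "MI")
        assert scores.ranked_pairs() == scores.ranked_pairs()
        assert scores.ranked_pairs()[0] == (0, 2)


class TestTopEigenvalue:
    def test_empty_and_single_contact(self):
        assert contact_matrix_top_eigenvalue(ContactMap(frozenset(), 5)) == 0.0
        single = ContactMap(frozenset({(0, 3)}), 5)
        assert contact_matrix_top_eigenvalue(single) == pytest.approx(1.0)

    def test_shared_site_pair_of_contacts(self):
        # contacts (0,3) and (3,6) form a path: top eigenvalue sqrt(2)
        cmap = ContactMap(frozenset({(0, 3), (3, 6)}), 7)
        assert contact_matrix_top_eigenvalue(cmap) == pytest.approx(np.sqrt(2))
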