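"""Contact energies, folding probabilities and competitor statistics."""

import numpy as np
import pytest
from scipy.special import logsumexp

from lpbench.energetics import (
    CompetitorProfile,
    ContactEnergyMatrix,
    EnergyEvaluator,
    all_fold_energies,
    competitor_profile,
    fold_energy,
    load_mj_matrix,
    pnat,
)
from lpbench.lattice_conformations import ContactMap, enumerate_compact_folds, forbidden_pairs
from lpbench.workbench import hp_energy_matrix


class TestContactEnergyMatrix:
    def test_mj_table_properties(self):
        E = load_mj_matrix()
        assert E.q == 20
        assert np.allclose(E.matrix, E.matrix.T)
        assert np.all(E.matrix < 0)  # contact energies are attractive in MJ units

    def test_file_roundtrip(self, tmp_path):
        E = hp_energy_matrix(3)
        path = tmp_path / "toy.txt"
        E.to_file(path)
        back = ContactEnergyMatrix.from_file(path)
        assert back.alphabet == E.alphabet
        assert np.allclose(back.matrix, E.matrix)
        assert back.checksum() == E.checksum()

    def test_validation(self):
        with pytest.raises(ValueError):
            ContactEnergyMatrix("HP", np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            ContactEnergyMatrix("HP", np.array([[np.inf, 0.0], [0.0, 0.0]]))
        with pytest.raises(KeyError):
            hp_energy_matrix(2).index("X")


class TestFoldEnergy:
    def test_empty_map_and_single_pair(self):
        E = hp_energy_matrix(2)
        empty = ContactMap(frozenset(), 4)
        assert fold_energy("HPHP", empty, E) == 0.0
        one = ContactMap(frozenset({(0, 3)}), 4)
        assert fold_energy("HPPH", one, E) == E.matrix[0, 0]
        assert fold_energy("HPPP", one, E) == E.matrix[0, 1]

    def test_matches_naive_double_loop(self):
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(3)
        rng = np.random.default_rng(3)
        seq = rng.integers(0, 3, size=8)
        cm = lib.contact_map(1)
        dense = cm.dense
        expected = sum(
            dense[i, j] * E.matrix[seq[i], seq[j]]
            for i in range(8)
            for j in range(i + 1, 8)
        )
        assert fold_energy(seq, cm, E) == pytest.approx(expected, abs=1e-12)

    def test_unknown_letter_rejected(self):
        lib = enumerate_compact_folds((2, 2, 2))
        with pytest.raises(KeyError):
            fold_energy("HPXPHPHP", lib.contact_map(0), hp_energy_matrix(2))


class TestAllFoldEnergies:
    def test_single_structure_library(self):
        lib = enumerate_compact_folds((2, 2, 2))
        single = type(lib)(lib.walks[:1], lib.box)
        E = hp_energy_matrix(2)
        e = all_fold_energies("HPHPHPHP", single, E)
        assert e.shape == (1,)
        assert e[0] == pytest.approx(fold_energy("HPHPHPHP", single.contact_map(0), E))

    def test_homopolymer_energy_is_contact_count_times_diagonal(self):
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(2)
        e = all_fold_energies("H" * 8, lib, E)
        assert np.allclose(e, 5 * E.matrix[0, 0])

    def test_incremental_update_agrees_with_recomputation(self):
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(3)
        ev = EnergyEvaluator(lib, E)
        rng = np.random.default_rng(7)
        seq = rng.integers(0, 3, size=8).astype(np.int8)
        e = ev.energies(seq)
        for _ in range(50):
            site = int(rng.integers(0, 8))
            new = int(rng.integers(0, 3))
            delta = ev.delta_energies(seq, site, new)
            seq[site] = new
            e = e + delta
            assert np.allclose(e, ev.energies(seq), atol=1e-12)


class TestPnat:
    def test_single_structure_gives_one(self):
        lib = enumerate_compact_folds((2, 2, 2))
        single = type(lib)(lib.walks[:1], lib.box)
        assert pnat("HPHPHPHP", 0, single, hp_energy_matrix(2)) == pytest.approx(1.0)

    def test_homopolymer_is_uniform(self):
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(2)
        for k in range(lib.N):
            assert pnat("H" * 8, k, lib, E) == pytest.approx(1 / lib.N, abs=1e-12)

    def test_normalisation_and_direct_summation(self):
        lib = enumerate_compact_folds((3, 3, 2)).subsample(10, seed=1)
        E = hp_energy_matrix(3)
        rng = np.random.default_rng(11)
        seq = rng.integers(0, 3, size=18)
        e = all_fold_energies(seq, lib, E)
        direct = np.exp(-e) / np.exp(-e).sum()
        total = 0.0
        for k in range(lib.N):
            p = pnat(seq, k, lib, E)
            assert p == pytest.approx(direct[k], rel=1e-12)
            total += p
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_native_energy(self):
        e = np.array([-3.0, -2.0, -1.0])
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(2)
        p1 = np.exp(-e[0] - logsumexp(-e))
        e2 = e.copy()
        e2[0] -= 0.5  # stabilise the native fold only
        p2 = np.exp(-e2[0] - logsumexp(-e2))
        assert p2 > p1
        assert pnat("HPHPHPHP", 0, lib, E, energies=e) == pytest.approx(p1)

    def test_index_validation(self):
        lib = enumerate_compact_folds((2, 2, 2))
        with pytest.raises(IndexError):
            pnat("HPHPHPHP", 5, lib, hp_energy_matrix(2))


class TestCompetitorProfile:
    def test_identical_energy_competitor(self):
        # two structures; sequences see equal energies -> gap 0, cbar = S1 map
        lib = enumerate_compact_folds((2, 2, 2))
        two = type(lib)(lib.walks[:2], lib.box)
        E = hp_energy_matrix(2)
        msa = np.zeros((4, 8), dtype=np.int8)  # homopolymers: all folds degenerate
        prof = competitor_profile(0, two, msa, E)
        assert prof.gaps[1] == pytest.approx(0.0, abs=1e-12)
        assert prof.aggregate == pytest.approx(1.0)
        assert np.allclose(prof.cbar, two.contact_map(1).dense)
        assert prof.closest_competitor == 1

    def test_matches_literal_transcription(self):
        lib = enumerate_compact_folds((3, 3, 2)).subsample(6, seed=2)
        E = hp_energy_matrix(3)
        rng = np.random.default_rng(5)
        msa = rng.integers(0, 3, size=(5, 18)).astype(np.int8)
        native = 2
        prof = competitor_profile(native, lib, msa, E)
        # literal implementation of the gap definition
        ev = EnergyEvaluator(lib, E)
        w = np.zeros(lib.N)
        for s in range(lib.N):
            acc = 0.0
            for t in range(5):
                e = ev.energies(msa[t])
                acc += np.exp(-(e[s] - e[native]))
            w[s] = acc / 5
        gaps = -np.log(w)
        assert np.allclose(prof.gaps, gaps, atol=1e-10)
        comp = [s for s in range(lib.N) if s != native]
        agg = sum(w[s] for s in comp)
        assert prof.aggregate == pytest.approx(agg, rel=1e-12)
        cbar = sum(w[s] * lib.contact_map(s).dense for s in comp) / agg
        assert np.allclose(prof.cbar, cbar, atol=1e-12)
        assert prof.closest_competitor == comp[int(np.argmax([w[s] for s in comp]))]

    def test_cbar_zero_on_forbidden_pairs_and_bounded(self):
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(2)
        rng = np.random.default_rng(8)
        msa = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
        prof = competitor_profile(0, lib, msa, E)
        assert np.all(prof.cbar >= 0) and np.all(prof.cbar <= 1 + 1e-12)
        for i, j in forbidden_pairs(8):
            assert prof.cbar[i, j] == 0.0

    def test_larger_gap_means_smaller_weight(self):
        w = CompetitorProfile(
            native_index=0,
            gaps=np.array([0.0, 1.0, 2.0]),
            aggregate=np.exp(-1) + np.exp(-2),
            cbar=np.zeros((2, 2)),
            closest_competitor=1,
        ).weights
        assert w[1] > w[2] > 0

    def test_empty_msa_rejected(self):
        lib = enumerate_compact_folds((2, 2, 2))
        with pytest.raises(ValueError):
            competitor_profile(0, lib, np.zeros((0, 8), dtype=np.int8), hp_energy_matrix(2))

    def test_tsv_export(self, tmp_path):
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(2)
        msa = np.random.default_rng(9).integers(0, 2, size=(4, 8)).astype(np.int8)
        prof = competitor_profile(0, lib, msa, E)
        path = tmp_path / "profile.tsv"
        prof.save_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[1] == "structure\tgap\tweight"
        assert len(lines) == 2 + lib.N + 1 + lib.L  # header, gaps, cbar marker, cbar
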