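"""Potts inference (IM, DCA, PLM, ACE), gauges, serialization."""

import numpy as np
import pytest

from lpbench.msa_statistics import frequencies
from lpbench.potts_inference import (
    PottsModel,
    enumerate_states,
    exact_entropy,
    exact_log_probabilities,
    exact_marginals,
    gauge_transform,
    infer_ace,
    infer_dca_meanfield,
    infer_im,
    infer_plm,
    potts_energy,
)
from lpbench.sequence_sampler import AlignmentSet


class TestPottsEnergy:
    def test_zero_model(self):
        m = PottsModel(np.zeros((4, 3)), np.zeros((4, 4, 3, 3)))
        assert potts_energy([0, 1, 2, 0], m) == 0.0

    def test_fields_only(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(4, 3))
        m = PottsModel(h, np.zeros((4, 4, 3, 3)))
        seq = [2, 0, 1, 1]
        assert potts_energy(seq, m) == pytest.approx(-sum(h[i, a] for i, a in enumerate(seq)))

    def test_double_loop_oracle(self, random_model_factory):
        m = random_model_factory(5, 3, seed=1)
        rng = np.random.default_rng(2)
        seq = rng.integers(0, 3, 5)
        expected = -sum(m.h[i, seq[i]] for i in range(5))
        for i in range(5):
            for j in range(i + 1, 5):
                expected -= m.J[i, j, seq[i], seq[j]]
        assert potts_energy(seq, m) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_validation(self):
        J = np.zeros((2, 2, 2, 2))
        J[0, 1, 0, 1] = 1.0  # missing transpose partner
        with pytest.raises(ValueError):
            PottsModel(np.zeros((2, 2)), J)


class TestGauges:
    @pytest.fixture
    def model_and_freqs(self, random_model_factory):
        m = random_model_factory(5, 4, seed=3)
        f = np.random.default_rng(4).dirichlet(np.ones(4), size=5)
        return m, f

    @pytest.mark.parametrize("target", ["zero-sum", "consensus", "least-probable"])
    def test_energy_differences_preserved(self, model_and_freqs, target):
        m, f = model_and_freqs
        mt = gauge_transform(m, target, reference=f)
        rng = np.random.default_rng(5)
        for _ in range(10):
            s1, s2 = rng.integers(0, 4, (2, 5))
            d0 = potts_energy(s1, m) - potts_energy(s2, m)
            d1 = potts_energy(s1, mt) - potts_energy(s2, mt)
            assert d1 == pytest.approx(d0, abs=1e-10)

    def test_zero_sum_condition_and_idempotence(self, model_and_freqs):
        m, _ = model_and_freqs
        zs = gauge_transform(m, "zero-sum")
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert np.allclose(zs.J[i, j].sum(axis=0), 0, atol=1e-10)
                    assert np.allclose(zs.J[i, j].sum(axis=1), 0, atol=1e-10)
        again = gauge_transform(zs, "zero-sum")
        assert np.allclose(again.h, zs.h, atol=1e-12)
        assert np.allclose(again.J, zs.J, atol=1e-12)

    def test_reference_gauge_conditions(self, model_and_freqs):
        m, f = model_and_freqs
        cons = np.argmax(f, axis=1)
        mc = gauge_transform(m, "consensus", reference=f)
        for i in range(5):
            assert mc.h[i, cons[i]] == pytest.approx(0.0, abs=1e-12)
            for j in range(5):
                if i != j:
                    assert np.allclose(mc.J[i, j][cons[i], :], 0, atol=1e-10)

    def test_round_trip_closure(self, model_and_freqs):
        m, f = model_and_freqs
        zs = gauge_transform(m, "zero-sum")
        back = gauge_transform(gauge_transform(zs, "consensus", f), "zero-sum")
        assert np.allclose(back.h, zs.h, atol=1e-10)
        assert np.allclose(back.J, zs.J, atol=1e-10)

    def test_missing_reference_rejected(self, model_and_freqs):
        m, _ = model_and_freqs
        with pytest.raises(ValueError):
            gauge_transform(m, "consensus")

    def test_gauge_change_preserves_distribution(self, random_model_factory):
        m = random_model_factory(4, 3, seed=6)
        f = np.random.default_rng(7).dirichlet(np.ones(3), size=4)
        _, logp0 = exact_log_probabilities(m)
        for target in ("zero-sum", "consensus", "least-probable"):
            _, logp = exact_log_probabilities(gauge_transform(m, target, f))
            assert np.allclose(logp, logp0, atol=1e-10)


class TestInferIM:
    def test_uniform_frequencies_give_flat_fields(self):
        msa = AlignmentSet(np.array([[0, 1], [1, 0], [2, 2]], dtype=np.int8), "ABC")
        stats = frequencies(msa, pseudocount=1.0)
        model = infer_im(stats)
        assert np.allclose(model.h, 0.0, atol=1e-12)
        assert not np.any(model.J)

    def test_fields_rank_letters_by_frequency(self):
        msa = AlignmentSet(np.array([[0, 0], [0, 1], [0, 1]], dtype=np.int8), "AB")
        model = infer_im(frequencies(msa, q=2), pseudocount=0.01)
        assert model.h[0, 0] > model.h[0, 1]
        assert model.h[1, 1] > model.h[1, 0]

    def test_zero_frequency_requires_pseudocount(self):
        msa = AlignmentSet(np.array([[0, 0]], dtype=np.int8), "AB")
        with pytest.raises(ValueError):
            infer_im(frequencies(msa, q=2))

    def test_sample_and_reinfer_self_consistency(self):
        rng = np.random.default_rng(8)
        h = np.log(rng.dirichlet(np.ones(3), size=4))
        truth = PottsModel(h - h.mean(axis=1, keepdims=True), np.zeros((4, 4, 3, 3)))
        p = np.exp(truth.h) / np.exp(truth.h).sum(axis=1, keepdims=True)
        X = np.stack([rng.choice(3, size=20000, p=p[i]) for i in range(4)], axis=1)
        model = infer_im(frequencies(AlignmentSet(X.astype(np.int8), "ABC")), pseudocount=1e-4)
        assert np.allclose(model.h, truth.h, atol=0.05)


class TestInferDCA:
    def test_independent_data_gives_negligible_couplings(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, size=(5000, 5)).astype(np.int8)
        stats = frequencies(AlignmentSet(X, "ABC"), pseudocount=0.5)
        model = infer_dca_meanfield(stats)
        norms = np.sqrt((model.J**2).sum(axis=(2, 3)))
        assert np.max(norms) < 0.2  # noise floor at this sample size

    def test_two_site_weak_coupling_closed_form(self):
        # exact correlations of a 2-site q=2 model, inverted by hand
        J0 = 0.15
        truth = PottsModel(
            np.zeros((2, 2)),
            np.array(
                [
                    [[[0, 0], [0, 0]], [[J0, 0], [0, 0]]],
                    [[[J0, 0], [0, 0]], [[0, 0], [0, 0]]],
                ],
                dtype=float,
            ),
        )
        f_i, f_ij = exact_marginals(truth)
        stats = frequencies(
            AlignmentSet(np.zeros((1, 2), dtype=np.int8), "AB"), q=2
        )
        stats.f_i, stats.f_ij, stats.M_eff = f_i, f_ij, 1e9
        model = infer_dca_meanfield(stats)
        # literal 2x2 inversion of the restricted covariance
        C = np.array(
            [
                [f_i[0, 0] * (1 - f_i[0, 0]), f_ij[0, 1, 0, 0] - f_i[0, 0] * f_i[1, 0]],
                [f_ij[0, 1, 0, 0] - f_i[0, 0] * f_i[1, 0], f_i[1, 0] * (1 - f_i[1, 0])],
            ]
        )
        expected_J = -np.linalg.inv(C)[0, 1]
        zs = gauge_transform(model, "zero-sum")
        # zero-sum form of a single-entry 2x2 block spreads J/4 on each cell
        assert zs.J[0, 1, 0, 0] == pytest.approx(expected_J / 4, rel=1e-6)
        # weak-coupling consistency with the true parameter
        assert expected_J == pytest.approx(J0, rel=0.25)

    def test_symmetric_blocks(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, size=(500, 4)).astype(np.int8)
        model = infer_dca_meanfield(frequencies(AlignmentSet(X, "ABC"), pseudocount=0.5))
        assert np.allclose(model.J, np.transpose(model.J, (1, 0, 3, 2)), atol=1e-9)

    def test_singular_without_pseudocount(self):
        X = np.zeros((10, 3), dtype=np.int8)  # constant alignment
        with pytest.raises(ValueError, match="pseudocount"):
            infer_dca_meanfield(frequencies(AlignmentSet(X, "ABC")))


class TestInferPLM:
    def test_penalty_shrinks_couplings(self, small_potts_truth, exact_sampler):
        msa = exact_sampler(small_potts_truth, 2000, seed=1)
        norms = []
        for gamma in (0.01, 0.3, 10.0):
            model = infer_plm(msa, gamma=gamma)
            norms.append(float(np.sqrt((model.J**2).sum())))
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 0.05  # gamma -> inf drives parameters to zero

    def test_recovery_improves_with_sample_size(self, small_potts_truth, exact_sampler):
        truth_zs = small_potts_truth["model_zs"]
        errs = []
        for M in (500, 5000):
            msa = exact_sampler(small_potts_truth, M, seed=2)
            model = infer_plm(msa, gamma=5.0 / M)
            errs.append(
                np.linalg.norm(model.J - truth_zs.J) / np.linalg.norm(truth_zs.J)
            )
        assert errs[1] < errs[0]

    def test_objective_trace_non_increasing(self, small_potts_truth, exact_sampler):
        msa = exact_sampler(small_potts_truth, 500, seed=3)
        model = infer_plm(msa, gamma=0.01)
        for trace in model.meta["objective_traces"]:
            arr = np.array(trace)
            # L-BFGS may evaluate trial points; the running minimum must decrease
            run_min = np.minimum.accumulate(arr)
            assert run_min[-1] <= run_min[0]
            assert np.all(np.diff(run_min) <= 1e-12)

    def test_deterministic(self, small_potts_truth, exact_sampler):
        msa = exact_sampler(small_potts_truth, 400, seed=4)
        m1 = infer_plm(msa, gamma=0.01)
        m2 = infer_plm(msa, gamma=0.01)
        assert np.allclose(m1.J, m2.J, atol=1e-12)

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError):
            infer_plm(AlignmentSet(np.zeros((0, 4), dtype=np.int8), "AB"))


class TestInferACE:
    def test_independent_site_data(self):
        rng = np.random.default_rng(11)
        p = rng.dirichlet(np.ones(3) * 5, size=4)
        X = np.stack([rng.choice(3, size=4000, p=p[i]) for i in range(4)], axis=1)
        msa = AlignmentSet(X.astype(np.int8), "ABC")
        model, est = infer_ace(msa, seed=0)
        stats = frequencies(msa)
        site_entropy = -np.sum(stats.f_i * np.log(stats.f_i + 1e-12))
        assert est.entropy == pytest.approx(site_entropy, rel=0.02)
        assert np.sqrt((model.J**2).sum()) < 1.0
        assert est.entropy <= 4 * np.log(3) + 1e-9

    def test_small_system_entropy_oracle(self, random_model_factory):
        truth = random_model_factory(4, 3, seed=12)
        states, logp = exact_log_probabilities(truth)
        p = np.exp(logp)
        s_true = exact_entropy(truth)
        idx = np.random.default_rng(13).choice(len(p), size=20000, p=p)
        msa = AlignmentSet(states[idx], "ABC")
        model, est = infer_ace(msa, seed=0)
        assert est.entropy == pytest.approx(s_true, rel=0.02)
        assert model.gauge == "least-probable"

    def test_least_probable_gauge_condition(self, small_potts_truth, exact_sampler):
        msa = exact_sampler(small_potts_truth, 3000, seed=5)
        model, _ = infer_ace(msa, seed=1)
        f = frequencies(msa).f_i
        rare = np.argmin(f, axis=1)
        for i in range(model.L):
            assert model.h[i, rare[i]] == pytest.approx(0.0, abs=1e-9)

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError):
            infer_ace(AlignmentSet(np.zeros((0, 4), dtype=np.int8), "AB"))


class TestSerialization:
    def test_model_file_roundtrip(self, tmp_path, random_model_factory):
        m = random_model_factory(4, 3, seed=14)
        m.gauge = "zero-sum"
        m.method = "PLM"
        m.gamma = 0.01
        path = tmp_path / "model.prm"
        m.save(path, alphabet="ABC")
        back = PottsModel.load(path)
        assert np.allclose(back.h, m.h, atol=0)
        assert np.allclose(back.J, m.J, atol=0)
        assert back.gauge == "zero-sum" and back.method == "PLM"
        assert back.gamma == 0.01

    def test_enumeration_guard(self):
        with pytest.raises(ValueError):
            enumerate_states(20, 20)
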