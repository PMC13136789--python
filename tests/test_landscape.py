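"""Ising maximum-entropy fits, energies, basins and the mMDS embedding."""

import numpy as np
import pandas as pd
import pytest

from stochassembly import landscape as ls


def exact_sampler(h, J, n, seed):
    states = ls._states_matrix(h.size)
    E = -(states @ h + 0.5 * np.einsum("si,ij,sj->s", states, J, states))
    p = np.exp(-E)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    return states[rng.choice(states.shape[0], size=n, p=p)], states, p


class TestBinarize:
    def test_threshold_zero_is_any_nonzero(self):
        counts = pd.DataFrame({"s1": [99, 1, 0], "s2": [1, 0, 99],
                               "s3": [0, 1, 50], "s4": [5, 0, 5]},
                              index=["a", "b", "c"])
        binary, retained, dropped = ls.binarize(counts, 0.0,
                                                prevalence_bounds=(0.0, 1.0))
        assert (binary.loc["s1"] == [1, 1, 0]).all()

    def test_strict_threshold_boundary(self):
        """Presence requires relative abundance strictly above the threshold."""
        counts = pd.DataFrame({"s1": [99, 1], "s2": [50, 50], "s3": [1, 99]},
                              index=["a", "b"])
        binary, _, _ = ls.binarize(counts, 0.01, prevalence_bounds=(0.0, 1.1))
        assert binary["a"].tolist() == [1, 1, 0]  # rel 0.99, 0.5, 0.01 (strict >)
        binary0, _, _ = ls.binarize(counts, 0.0, prevalence_bounds=(0.0, 1.1))
        assert binary0["a"].tolist() == [1, 1, 1]

    def test_constant_taxon_dropped(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 50, (3, 20)),
                              index=["always", "vary1", "vary2"])
        counts.iloc[1, :10] = 0
        counts.iloc[2, 10:] = 0
        binary, retained, dropped = ls.binarize(counts, 0.0)
        assert "always" in dropped
        assert set(retained) == {"vary1", "vary2"}

    def test_fewer_than_two_retained_errors(self):
        counts = pd.DataFrame(np.ones((2, 10)), index=["a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ls.binarize(counts, 0.0)


class TestFitIsing:
    def test_independent_taxa_give_small_couplings(self):
        rng = np.random.default_rng(0)
        X = (rng.random((5000, 5)) < [0.2, 0.4, 0.5, 0.6, 0.8]).astype(float)
        model = ls.fit_ising(X, mode="exact", l2_penalty=0.01)
        assert np.abs(model.J).max() < 0.25
        # model marginals match empirical
        states, E = ls._energies_all(model.h, model.J)
        p = np.exp(-E)
        p /= p.sum()
        marg = p @ states
        assert np.allclose(marg, X.mean(axis=0), atol=0.02)

    def test_recovers_known_parameters(self):
        h = np.array([0.5, -0.3, 0.2])
        J = np.array([[0, 0.8, -0.6], [0.8, 0, 0.3], [-0.6, 0.3, 0]])
        X, _, _ = exact_sampler(h, J, 10_000, seed=3)
        model = ls.fit_ising(X, mode="exact", l2_penalty=1e-4)
        assert np.abs(model.h - h).max() < 0.1
        assert np.abs(model.J - J).max() < 0.1

    def test_duplicated_dataset_identical_fit(self):
        rng = np.random.default_rng(1)
        X = (rng.random((200, 4)) < 0.5).astype(float)
        m1 = ls.fit_ising(X, mode="exact")
        m2 = ls.fit_ising(np.vstack([X, X]), mode="exact")
        assert np.allclose(m1.h, m2.h, atol=1e-6)
        assert np.allclose(m1.J, m2.J, atol=1e-6)

    def test_pseudolikelihood_close_to_exact(self):
        rng = np.random.default_rng(5)
        h = rng.normal(0, 0.5, 6)
        J = rng.normal(0, 0.4, (6, 6))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0)
        X, _, _ = exact_sampler(h, J, 5000, seed=6)
        me = ls.fit_ising(X, mode="exact", l2_penalty=1e-3)
        mp = ls.fit_ising(X, mode="pl", l2_penalty=1e-3)
        iu = np.triu_indices(6, 1)
        diff = np.concatenate([me.h - mp.h, me.J[iu] - mp.J[iu]])
        assert np.sqrt(np.mean(diff ** 2)) < 0.15

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ls.fit_ising(np.full((12, 3), 0.5), mode="exact")


class TestEnergy:
    def test_empty_state_has_zero_energy(self):
        model = ls.IsingModel(np.array([1.0, -2.0]), np.zeros((2, 2)))
        assert ls.energy(model, [0, 0]) == 0.0

    def test_single_field_term(self):
        model = ls.IsingModel(np.array([1.0, 0.0]), np.zeros((2, 2)))
        assert ls.energy(model, [1, 0]) == -1.0

    def test_wrong_length_errors(self):
        model = ls.IsingModel(np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            ls.energy(model, [1, 0, 0])

    def test_exponential_of_negative_energy_is_probability(self):
        h = np.array([0.4, -0.2, 0.1])
        J = np.array([[0, 0.5, 0], [0.5, 0, -0.4], [0, -0.4, 0]])
        X, states, p_true = exact_sampler(h, J, 10_000, seed=9)
        model = ls.fit_ising(X, mode="exact", l2_penalty=1e-4)
        E = np.array([ls.energy(model, s) for s in states])
        p_model = np.exp(-E)
        p_model /= p_model.sum()
        lp = np.array([model.log_prob(s) for s in states])
        assert np.allclose(np.exp(lp), p_model, atol=1e-10)
        # energy differences are log probability ratios
        assert E[1] - E[2] == pytest.approx(lp[2] - lp[1])


class TestMinimaAndBasins:
    def test_all_positive_fields_single_minimum(self):
        model = ls.IsingModel(np.array([1.0, 2.0, 0.5]), np.zeros((3, 3)))
        minima = ls.find_minima(model)
        assert minima == [((1, 1, 1), pytest.approx(-3.5))]

    def test_mutual_exclusion_two_minima(self):
        model = ls.IsingModel(np.array([2.0, 2.0]),
                              np.array([[0.0, -5.0], [-5.0, 0.0]]))
        minima = ls.find_minima(model)
        assert sorted(s for s, _ in minima) == [(0, 1), (1, 0)]

    def test_minima_assign_to_themselves(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=5)
        J = rng.normal(0, 1, (5, 5))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0)
        model = ls.IsingModel(h, J)
        minima = ls.find_minima(model)
        for idx, (state, _) in enumerate(minima):
            assert ls.assign_basin(model, np.array(state, float), minima) == idx


class TestMMDS:
    def test_two_points_exact(self):
        coords, stress = ls.mmds_embed(np.array([[0.0, 0.7], [0.7, 0.0]]))
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.7)
        assert stress == pytest.approx(0.0, abs=1e-12)

    def test_three_equidistant_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, _ = ls.mmds_embed(D, seed=0)
        d01 = np.linalg.norm(coords[0] - coords[1])
        d02 = np.linalg.norm(coords[0] - coords[2])
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert d01 == pytest.approx(d02, abs=1e-6)
        assert d01 == pytest.approx(d12, abs=1e-6)

    def test_planar_configuration_recovered(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 2]])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, stress = ls.mmds_embed(D, seed=0)
        Dhat = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert stress < 1e-6
        assert np.allclose(Dhat, D, atol=1e-4)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ls.mmds_embed(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestFrameworkSplit:
    def test_framework_counts(self, bistable_experiment):
        assert len(ls.framework_split(bistable_experiment, 1)) == 2
        assert len(ls.framework_split(bistable_experiment, 2)) == 8

    def test_single_setting_identical_either_way(self, small_table):
        sub = small_table.subset(
            small_table.meta[small_table.meta["dilution"] == 1.0].index)
        f1 = ls.framework_split(sub, 1)
        f2 = ls.framework_split(sub, 2)
        assert [sorted(v) for v in f1.values()] == \
            [sorted(v) for v in f2.values()]
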