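"""Exact enumeration, Boltzmann-learning fits, entropy and KL divergence.

Closed-form oracles: a single spin with field h is Bernoulli with
P(+1) = e^h / (e^h + e^-h) and <σ> = tanh(h); two spins coupled by J with
h = 0 have <σ0 σ1> = tanh(J).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromaxent import (
    FitConfig,
    FitError,
    IsingModel,
    ModelBank,
    MomentSet,
    NeighborhoodScheme,
    enumerate_distribution,
    fit_bank,
    fit_ising,
    kl_divergence,
    model_entropy,
    model_moments,
    pair_index,
    state_table,
)
from chromaxent.maxent import HARD_CAP
from chromaxent.neighborhoods import ensemble_moments, extract_ensemble
from chromaxent.synthetic import SyntheticConfig, generate_states, plant_bank, simulate_contacts
from conftest import toy_map


def uniform_moments(n: int) -> MomentSet:
    return MomentSet(n, np.zeros(n), {p: 0.0 for p in pair_index(n)})


class TestEnumeration:
    def test_uniform_n3(self):
        p = enumerate_distribution(IsingModel(3, np.zeros(3)))
        assert np.allclose(p, 1 / 8, atol=1e-15)

    def test_single_spin_logistic(self):
        p = enumerate_distribution(IsingModel(1, np.array([1.0])))
        expected_up = np.e / (np.e + np.exp(-1))
        # state index 1 has bit 0 set -> σ = +1
        assert p[1] == pytest.approx(expected_up, abs=1e-12)

    def test_strong_coupling_aligns(self):
        m = IsingModel(2, np.zeros(2), np.array([10.0]))
        p = enumerate_distribution(m)
        # closed form: P(++) = P(--) = e^10 / (2 e^10 + 2 e^-10)
        aligned = np.exp(10) / (2 * np.exp(10) + 2 * np.exp(-10))
        assert p[0] == pytest.approx(aligned, abs=1e-12)
        assert p[3] == pytest.approx(aligned, abs=1e-12)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        m = IsingModel(6, rng.normal(size=6), rng.normal(size=15, scale=0.3))
        assert enumerate_distribution(m).sum() == pytest.approx(1.0, abs=1e-12)

    def test_enumeration_limit(self):
        with pytest.raises(ValueError, match="limit"):
            enumerate_distribution(IsingModel(12, np.zeros(12)), limit=10)
        with pytest.raises(ValueError):
            IsingModel(HARD_CAP + 1, np.zeros(HARD_CAP + 1))

    def test_state_table_cached_identity(self):
        assert state_table(9) is state_table(9)


class TestModelMoments:
    def test_zero_model(self):
        mom = model_moments(IsingModel(3, np.zeros(3)), order=3)
        assert np.allclose(mom.m, 0, atol=1e-15)
        assert all(abs(v) < 1e-15 for v in mom.c.values())
        assert all(abs(v) < 1e-15 for v in mom.t.values())

    def test_tanh_field(self):
        mom = model_moments(IsingModel(1, np.array([1.0])), order=1)
        assert mom.m[0] == pytest.approx(np.tanh(1.0), abs=1e-12)

    def test_tanh_coupling(self):
        mom = model_moments(IsingModel(2, np.zeros(2), np.array([0.5])))
        assert mom.c[(0, 1)] == pytest.approx(np.tanh(0.5), abs=1e-12)


class TestFitIsing:
    def test_uniform_target(self):
        model, _ = fit_ising(uniform_moments(3), config=FitConfig(seed=2))
        assert np.abs(model.h).max() < 5e-3
        assert np.abs(model.j).max() < 5e-3

    def test_two_spin_parameter_recovery(self):
        planted = IsingModel(2, np.array([0.5, -0.3]), np.array([0.2]))
        model, _ = fit_ising(model_moments(planted), config=FitConfig(seed=0))
        assert np.allclose(model.h, planted.h, atol=0.02)
        assert np.allclose(model.j, planted.j, atol=0.02)

    def test_boundary_moment_rejected(self):
        bad = MomentSet(2, np.array([1.0, 0.0]), {(0, 1): 0.0})
        with pytest.raises(ValueError, match="unrealizable"):
            fit_ising(bad)

    def test_converged_moments_within_tolerance(self):
        rng = np.random.default_rng(4)
        planted = IsingModel(5, rng.normal(size=5, scale=0.5),
                             rng.normal(size=10, scale=0.3))
        target = model_moments(planted)
        model, _ = fit_ising(target, config=FitConfig(seed=1))
        got = model_moments(model)
        assert np.abs(got.m - target.m).max() < 1e-4
        assert max(abs(got.c[p] - target.c[p]) for p in target.c) < 1e-4

    def test_order1_leaves_couplings_zero(self):
        target = model_moments(IsingModel(3, np.array([0.4, -0.2, 0.1])))
        model, _ = fit_ising(target, order=1, config=FitConfig(seed=3))
        assert np.all(model.j == 0)
        assert np.allclose(model_moments(model).m, target.m, atol=1e-4)

    def test_max_iter_exceeded(self):
        target = model_moments(IsingModel(2, np.array([1.5, 1.5]), np.array([0.8])))
        with pytest.raises(FitError, match="residual"):
            fit_ising(target, config=FitConfig(max_iter=5, seed=0))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_moment_round_trip(self, seed):
        """fit(model_moments(M)) reproduces the moments of random planted M."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        planted = IsingModel(
            n,
            rng.uniform(-1, 1, size=n),
            rng.uniform(-1, 1, size=n * (n - 1) // 2) * 0.8,
        )
        target = model_moments(planted)
        model, _ = fit_ising(target, config=FitConfig(seed=seed % 17))
        got = model_moments(model)
        assert np.abs(got.m - target.m).max() < 1e-4
        assert max(abs(got.c[p] - target.c[p]) for p in target.c) < 1e-4


class TestEntropyKl:
    def test_uniform_entropy(self):
        assert model_entropy(IsingModel(3, np.zeros(3))) == pytest.approx(3.0, abs=1e-12)

    def test_strong_field_kills_entropy(self):
        assert model_entropy(IsingModel(1, np.array([20.0]))) < 1e-8

    def test_two_spin_closed_form(self):
        m = IsingModel(2, np.zeros(2), np.array([0.5]))
        z = 2 * np.exp(0.5) + 2 * np.exp(-0.5)
        probs = np.array([np.exp(0.5), np.exp(-0.5), np.exp(-0.5), np.exp(0.5)]) / z
        expected = -np.sum(probs * np.log2(probs))
        assert model_entropy(m) == pytest.approx(expected, abs=1e-12)

    def test_kl_identical_zero(self):
        m = IsingModel(2, np.array([0.3, -0.1]), np.array([0.2]))
        assert kl_divergence(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_kl_bernoulli_closed_form(self):
        p = IsingModel(1, np.array([1.0]))
        q = IsingModel(1, np.zeros(1))
        pu = np.e / (np.e + np.exp(-1))
        expected = pu * np.log2(pu / 0.5) + (1 - pu) * np.log2((1 - pu) / 0.5)
        assert kl_divergence(p, q) == pytest.approx(expected, abs=1e-12)

    def test_kl_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = IsingModel(4, rng.normal(size=4), rng.normal(size=6, scale=0.5))
            q = IsingModel(4, rng.normal(size=4), rng.normal(size=6, scale=0.5))
            assert kl_divergence(p, q) >= 0

    def test_kl_size_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence(IsingModel(2, np.zeros(2)), IsingModel(3, np.zeros(3)))


@pytest.fixture(scope="module")
def tiny_fit():
    cfg = SyntheticConfig(n_bins=1500, d_max=3, window_size=2, depth=40.0, seed=5)
    rng = np.random.default_rng(cfg.seed)
    states = generate_states(cfg, rng)
    cmap = simulate_contacts(states, plant_bank(cfg), cfg, rng)
    bank = fit_bank(states, cmap, range(1, 4), cfg.scheme, FitConfig(seed=2))
    return states, cmap, bank


class TestFitBank:
    def test_three_model_pairs_converged(self, tiny_fit):
        _, _, bank = tiny_fit
        assert bank.distances == [1, 2, 3]
        assert set(bank.iterations) == {1, 2, 3}
        for d in bank.distances:
            mc, mb = bank.models_at(d)
            assert mc.n == mb.n == NeighborhoodScheme(2).size(d)

    def test_all_zero_distance_raises(self, toy_states):
        cmap = toy_map([(5, 6, 4.0)])  # counts only at d=1
        with pytest.raises(ValueError, match="empty ensemble at d=2"):
            fit_bank(toy_states, cmap, [2], NeighborhoodScheme(2), FitConfig(seed=0))

    def test_json_round_trip(self, tiny_fit, tmp_path):
        _, _, bank = tiny_fit
        path = tmp_path / "bank.json"
        bank.save(path)
        back = ModelBank.load(path)
        assert back.distances == bank.distances
        assert back.scheme == bank.scheme
        for d in bank.distances:
            for store in ("contact", "background"):
                a = getattr(bank, store)[d]
                b = getattr(back, store)[d]
                assert np.array_equal(a.h, b.h) and np.array_equal(a.j, b.j)
        assert np.array_equal(back.profile.mean_counts, bank.profile.mean_counts)


class TestFitSymmetries:
    def test_seed_uniqueness(self, small_synthetic):
        """Convexity: fits from different seeds land on the same parameters."""
        _, states, _, cmap = small_synthetic
        ens = extract_ensemble(states, cmap, 2, "contact", scheme=NeighborhoodScheme(4))
        target = ensemble_moments(ens)
        models = [fit_ising(target, config=FitConfig(seed=s))[0] for s in (0, 1)]
        assert np.abs(models[0].h - models[1].h).max() < 1e-2
        assert np.abs(models[0].j - models[1].j).max() < 1e-2

    def test_palindromic_parameters(self, small_synthetic):
        """Reversal-closed ensembles give mirror-symmetric fields/couplings."""
        _, states, _, cmap = small_synthetic
        ens = extract_ensemble(states, cmap, 3, "contact", scheme=NeighborhoodScheme(4))
        model, _ = fit_ising(ensemble_moments(ens), config=FitConfig(seed=6))
        assert np.abs(model.h - model.h[::-1]).max() < 1e-3
        jm = model.j_matrix()
        assert np.abs(jm - jm[::-1, ::-1]).max() < 1e-3
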