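"""Replicator dynamics: costs, growth rates, kill probabilities, trajectories."""

import itertools

import numpy as np
import pytest

from psdcoex import (
    ExtinctionError,
    ModelParams,
    NonviableStrainError,
    growth_rates,
    kill_probabilities,
    parse_community,
    realized_costs,
    replicator_step,
    simulate_trajectory,
    update_map,
)
from psdcoex.community import Phenotype

from conftest import random_community


class TestRealizedCosts:
    def test_zero_jitter_reproduces_base_costs(self, low_cost_params):
        costs = realized_costs(low_cost_params, 3)
        assert np.all(costs.cr_j == 0.16)
        assert np.all(costs.cd_j == pytest.approx(1.4 * 0.16))
        assert np.all(costs.cp_j == pytest.approx(2.5 * 0.16))

    def test_jitter_bounds(self):
        p = ModelParams(cr=0.16, cd=0.224, cp=0.4, jitter_scale=0.0005)
        costs = realized_costs(p, 50, np.random.default_rng(0))
        assert np.all(costs.cr_j >= 0.1595) and np.all(costs.cr_j <= 0.1605)

    def test_same_seed_reproducible(self):
        p = ModelParams(jitter_scale=0.0005)
        a = realized_costs(p, 4, np.random.default_rng(11))
        b = realized_costs(p, 4, np.random.default_rng(11))
        assert np.array_equal(a.cr_j, b.cr_j)

    def test_zero_cr_with_costs_rejected(self):
        p = ModelParams(cr=0.0, cd=0.1, cp=0.2)
        with pytest.raises(ValueError):
            realized_costs(p, 2)


class TestGrowthRates:
    def test_hand_evaluated_low_cost(self, circulant_2psd, low_cost_params):
        costs = realized_costs(low_cost_params, 2)
        r = growth_rates(circulant_2psd, costs, 1.0)
        # strain 1: P and D; strain 2: S and P; strain 3: D and S
        assert r == pytest.approx([0.376, 0.600, 0.776])

    def test_all_sensitive_pays_nothing(self, low_cost_params):
        c = parse_community("[SS,SS]".replace("SS,SS", "SS,SR"))  # distinct rows
        costs = realized_costs(low_cost_params, 2)
        r = growth_rates(c, costs, 1.0)
        assert r[0] == pytest.approx(1.0)

    def test_psr_community(self, low_cost_params):
        costs = realized_costs(low_cost_params, 1)
        r = growth_rates(parse_community("[P,S,R]"), costs, 1.0)
        assert r == pytest.approx([0.6, 1.0, 0.84])

    def test_nonviable_strain_raises(self):
        p = ModelParams(g=0.3, cr=0.16, cd=0.224, cp=0.4, jitter_scale=0.0)
        costs = realized_costs(p, 1)
        with pytest.raises(NonviableStrainError):
            growth_rates(parse_community("[P,S,D]"), costs, 0.3)


class TestKillProbabilities:
    def test_no_producers_no_killing(self, low_cost_params):
        c = parse_community("[S,D,R]")
        X = np.array([0.2, 0.3, 0.5])
        assert np.all(kill_probabilities(c, X, low_cost_params) == 0.0)

    def test_symbolic_evaluation_psd(self, low_cost_params):
        c = parse_community("[P,S,D]")
        X = np.full(3, 1 / 3)
        p = kill_probabilities(c, X, low_cost_params)
        expected_s = np.exp(-10 / 3) * (1 - np.exp(-40 / 3))
        assert p[1] == pytest.approx(expected_s, abs=1e-12)
        assert p[0] == 0.0 and p[2] == 0.0
        assert expected_s == pytest.approx(0.03567, abs=5e-5)

    def test_fully_protected_strain(self, low_cost_params):
        c = parse_community("[PR,SP,DS]")  # strain 1 is P or R everywhere
        for _ in range(5):
            X = np.random.default_rng(3).dirichlet(np.ones(3))
            assert kill_probabilities(c, X, low_cost_params)[0] == 0.0

    def test_inclusion_exclusion_identity(self, rng, low_cost_params):
        """Product form equals the explicit inclusion-exclusion expansion."""
        for _ in range(30):
            n = int(rng.integers(2, 5))
            m = int(rng.integers(1, 5))
            c = random_community(rng, n, m)
            X = rng.dirichlet(np.ones(n))
            S = c.indicator(Phenotype.S)
            D = c.indicator(Phenotype.D)
            P = c.indicator(Phenotype.P)
            pij = (
                S
                * np.exp(-low_cost_params.KD * (D.T @ X))
                * (1 - np.exp(-low_cost_params.KP * (P.T @ X)))
            )
            expected = np.zeros(n)
            for i in range(n):
                total = 0.0
                for size in range(1, m + 1):
                    for subset in itertools.combinations(range(m), size):
                        term = np.prod([pij[i, j] for j in subset])
                        total += (-1) ** (size + 1) * term
                expected[i] = total
            got = kill_probabilities(c, X, low_cost_params)
            assert np.max(np.abs(got - expected)) < 1e-12


class TestReplicatorStep:
    def test_equal_fitness_is_identity(self):
        X = np.array([0.2, 0.3, 0.5])
        assert replicator_step(X, np.full(3, 1.7)) == pytest.approx(X)

    def test_hand_evaluated(self):
        out = replicator_step(np.array([0.5, 0.5]), np.array([1.0, 3.0]))
        assert out == pytest.approx([0.25, 0.75])

    def test_vertex_absorbing(self):
        X = np.array([1.0, 0.0])
        out = replicator_step(X, np.array([0.3, 0.9]))
        assert out == pytest.approx([1.0, 0.0])

    def test_total_extinction_signalled(self):
        with pytest.raises(ExtinctionError):
            replicator_step(np.array([0.5, 0.5]), np.zeros(2))


class TestTrajectories:
    def test_simplex_conserved_along_random_trajectories(self, rng, low_cost_params):
        for _ in range(5):
            c = random_community(rng, 3, 2)
            F = update_map(c, low_cost_params)
            X = rng.dirichlet(np.ones(3))
            for _ in range(200):
                X = F(X)
                assert abs(X.sum() - 1.0) < 1e-12
                assert np.all(X >= 0)

    def test_psd_sensitive_fixes(self, low_cost_params):
        res = simulate_trajectory(
            parse_community("[P,S,D]"),
            np.array([0.4, 0.3, 0.3]),
            low_cost_params,
            max_steps=50_000,
        )
        assert res.converged
        assert res.terminal[1] == pytest.approx(1.0, abs=1e-6)

    def test_vertex_start_is_constant(self, low_cost_params):
        res = simulate_trajectory(
            parse_community("[P,S,D]"), np.array([0.0, 0.0, 1.0]), low_cost_params
        )
        assert res.steps == 1 and res.terminal == pytest.approx([0, 0, 1])

    def test_permutation_equivariance(self, rng, low_cost_params):
        c = parse_community("[PD,SP,DS]")
        rp, cp = rng.permutation(3), rng.permutation(2)
        cperm = c.permuted(rp, cp)
        X0 = rng.dirichlet(np.ones(3))
        F = update_map(c, low_cost_params)
        Fp = update_map(cperm, low_cost_params)
        X, Xp = X0.copy(), X0[rp].copy()
        for _ in range(100):
            X, Xp = F(X), Fp(Xp)
            # identical up to reordering of the floating-point products
            assert np.max(np.abs(X[rp] - Xp)) < 1e-12

    def test_symmetric_fixed_point_machine_precision(
        self, circulant_3psd, low_cost_params
    ):
        F = update_map(circulant_3psd, low_cost_params)
        X = np.full(3, 1 / 3)
        assert np.max(np.abs(F(X) - X)) < 1e-15
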