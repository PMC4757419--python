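"""The illusion model: neighbor activation mixing, binomial tails, Gaussian form."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

import netillusion as ni
from netillusion.analytic_model import (
    conditional_active_neighbor_prob,
    empirical_conditional_activation,
    expected_paradox_fraction,
    gaussian_approx_conditional,
    paradox_probability,
)
from netillusion.graph_core import DegreeStats

from conftest import random_simple_graph


def binomial_tail_by_summation(k: int, p: float, phi: float) -> float:
    """Independent oracle: direct summation of the strict binomial upper tail."""
    return sum(
        math.comb(k, n) * p**n * (1 - p) ** (k - n)
        for n in range(k + 1)
        if n > phi * k
    )


def product_mixing_stats(q: dict) -> DegreeStats:
    """DegreeStats with uncorrelated mixing e(k,k') = q(k)q(k')."""
    p = {k: qk / k for k, qk in q.items()}
    z = sum(p.values())
    p = {k: v / z for k, v in p.items()}
    mean_degree = 1.0 / z
    e = {(a, b): qa * qb for a, qa in q.items() for b, qb in q.items()}
    mu_q = sum(k * v for k, v in q.items())
    sigma_q_sq = sum(k * k * v for k, v in q.items()) - mu_q**2
    return DegreeStats(
        p=p, q=q, e=e, mean_degree=mean_degree,
        sigma_q_sq=sigma_q_sq, assortativity=0.0, n_edges=1,
    )


class TestEmpiricalConditionalActivation:
    def test_star_hub_active(self):
        g, x = ni.make_fixture("star5-hub-active")
        cond = empirical_conditional_activation(g, x)
        assert cond == {1: 0.0, 4: 1.0}

    def test_all_active_is_one_everywhere(self, medium_er):
        x = np.ones(medium_er.number_of_nodes(), dtype=np.int8)
        cond = empirical_conditional_activation(medium_er, x)
        assert all(v == 1.0 for v in cond.values())

    def test_random_activation_near_fraction(self, medium_er):
        f = 0.3
        x = ni.activate_random(medium_er, f, rng_seed=0)
        cond = empirical_conditional_activation(medium_er, x)
        k = ni.degree_array(medium_er)
        for d, val in cond.items():
            n_d = int((k == d).sum())
            if n_d < 30:
                continue  # tiny degree classes are too noisy to bound tightly
            se = math.sqrt(f * (1 - f) / n_d)
            assert abs(val - f) < 4 * se


class TestConditionalActiveNeighborProb:
    def test_uncorrelated_mixing_with_constant_activation(self):
        stats = product_mixing_stats({1: 0.3, 2: 0.3, 5: 0.4})
        profile = conditional_active_neighbor_prob(stats, {1: 0.7, 2: 0.7, 5: 0.7})
        for val in profile.cond_prob.values():
            assert val == pytest.approx(0.7, abs=1e-12)

    def test_star_k13_hand_computed(self):
        # K_{1,3} with the hub active: e(1,3) = e(3,1) = 1/2,
        # so a degree-1 node's neighbor is active w.p. 1, the hub's w.p. 0,
        # and globally P(x'=1) = p(1) * 1 = 3/4.
        g = nx.star_graph(3)
        x = np.array([1, 0, 0, 0])
        stats = ni.degree_stats(g)
        assert stats.e[(1, 3)] == pytest.approx(0.5)
        profile = conditional_active_neighbor_prob(
            stats, empirical_conditional_activation(g, x)
        )
        assert profile.cond_prob[1] == pytest.approx(1.0)
        assert profile.cond_prob[3] == pytest.approx(0.0)
        assert profile.global_prob == pytest.approx(0.75)

    def test_mixing_weights_normalized(self, medium_powerlaw):
        stats = ni.degree_stats(medium_powerlaw)
        # sum_k' e(k,k')/q(k) = 1 for every k: constant activation maps to itself
        profile = conditional_active_neighbor_prob(
            stats, {k: 1.0 for k in stats.q}
        )
        for val in profile.cond_prob.values():
            assert val == pytest.approx(1.0, abs=1e-9)


class TestParadoxProbability:
    @pytest.mark.parametrize(
        "k,p,phi,expected",
        [
            (1, 0.3, 0.5, 0.3),  # only n=1 clears the strict bound
            (2, 0.3, 0.5, 0.09),  # only n=2 (the tie n=1 is excluded)
            (3, 0.5, 0.5, 0.5),  # P(n in {2,3}) for Bin(3, 1/2)
            (0, 0.9, 0.5, 0.0),
            (4, 0.0, 0.5, 0.0),
            (4, 1.0, 0.5, 1.0),
        ],
    )
    def test_known_values(self, k, p, phi, expected):
        assert paradox_probability(k, p, phi) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 7, 16, 33, 64])
    @pytest.mark.parametrize("p", [0.05, 0.3, 0.77])
    @pytest.mark.parametrize("phi", [0.0, 0.25, 0.5, 0.9])
    def test_matches_direct_summation(self, k, p, phi):
        assert paradox_probability(k, p, phi) == pytest.approx(
            binomial_tail_by_summation(k, p, phi), abs=1e-12
        )

    def test_even_degree_tie_excluded(self):
        # for even k, n = k/2 must not count: P(Bin(2, 1) > 1) includes only n=2
        assert paradox_probability(2, 0.5, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            paradox_probability(3, 1.2, 0.5)
        with pytest.raises(ValueError):
            paradox_probability(-1, 0.5, 0.5)


class TestExpectedParadoxFraction:
    def test_point_mass_on_degree_one(self):
        stats = product_mixing_stats({1: 1.0})
        profile = conditional_active_neighbor_prob(stats, {1: 0.3})
        pred = expected_paradox_fraction(stats, profile)
        assert pred.overall == pytest.approx(0.3, abs=1e-12)

    def test_two_degree_mixture(self):
        # p(1) = p(2) = 1/2 with constant neighbor activation 0.3:
        # 0.5 * 0.3 + 0.5 * 0.09 = 0.195
        stats = product_mixing_stats({1: 1 / 3, 2: 2 / 3})  # gives p(1)=p(2)=1/2
        assert stats.p[1] == pytest.approx(0.5)
        profile = ni.NeighborActivationProfile({1: 0.3, 2: 0.3}, 0.3)
        pred = expected_paradox_fraction(stats, profile)
        assert pred.overall == pytest.approx(0.195, abs=1e-12)

    def test_overall_is_p_weighted_mean(self, medium_powerlaw):
        x = ni.activate_random(medium_powerlaw, 0.1, 0)
        pred = ni.predict_paradox(medium_powerlaw, x)
        stats = ni.degree_stats(medium_powerlaw)
        recomputed = sum(
            pk * pred.per_degree[k] for k, pk in stats.p.items() if k > 0
        )
        assert pred.overall == pytest.approx(recomputed, abs=1e-9)

    def test_independent_activation_matches_per_node_oracle(self, medium_er):
        # with i.i.d. activation the model collapses to the exact per-node
        # binomial mixture (1/N) sum_i P(Bin(k_i, f) > k_i/2)
        f = 0.3
        k = ni.degree_array(medium_er)
        oracle = np.mean([paradox_probability(int(d), f) for d in k])
        stats = ni.degree_stats(medium_er)
        profile = conditional_active_neighbor_prob(stats, {d: f for d in stats.q})
        pred = expected_paradox_fraction(stats, profile)
        assert pred.overall == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_activation_profile(self, medium_er):
        stats = ni.degree_stats(medium_er)
        lo = conditional_active_neighbor_prob(stats, {d: 0.2 for d in stats.q})
        hi = conditional_active_neighbor_prob(stats, {d: 0.35 for d in stats.q})
        assert (
            expected_paradox_fraction(stats, hi).overall
            >= expected_paradox_fraction(stats, lo).overall
        )


class TestGaussianApproximation:
    def test_zero_correlation_gives_mean(self):
        for k in (1, 5, 40):
            assert gaussian_approx_conditional(0.2, 0.0, 0.4, 3.0, 5.0, k) == 0.2

    def test_mean_degree_gives_mean_regardless_of_rho(self):
        assert gaussian_approx_conditional(0.2, 0.8, 0.4, 3.0, 5.0, 5) == 0.2

    def test_clamped_to_unit_interval(self):
        assert gaussian_approx_conditional(0.9, 1.0, 0.5, 0.5, 2.0, 100) == 1.0
        assert gaussian_approx_conditional(0.1, 1.0, 0.5, 0.5, 50.0, 0) == 0.0

    def test_zero_sigma_k_rejected(self):
        with pytest.raises(ValueError):
            gaussian_approx_conditional(0.2, 0.5, 0.4, 0.0, 5.0, 3)

    def test_er_gaussian_matches_empirical_model(self, medium_er):
        # Poisson-like degrees near r_kk = 0: both routes nearly coincide
        x = ni.activate_random(medium_er, 0.1, 3)
        res = ni.swap_to_correlation(medium_er, x, 0.2, rng_seed=4)
        p_emp = ni.predict_paradox(medium_er, res.attributes, method="empirical").overall
        p_gau = ni.predict_paradox(medium_er, res.attributes, method="gaussian").overall
        assert abs(p_emp - p_gau) < 0.02

    def test_model_tracks_measurement_on_powerlaw(self, medium_powerlaw):
        devs = []
        for seed in range(5):
            x = ni.activate_random(medium_powerlaw, 0.05, seed)
            res = ni.swap_to_correlation(medium_powerlaw, x, 0.3, rng_seed=seed + 50)
            emp = ni.paradox_fraction(medium_powerlaw, res.attributes).paradox_fraction
            pred = ni.predict_paradox(medium_powerlaw, res.attributes).overall
            devs.append(abs(emp - pred))
        assert np.mean(devs) < 0.05
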