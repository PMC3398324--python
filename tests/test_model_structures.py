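import numpy as np
import pytest

from devexpr.model_structures import (FlatModel, Network, ParameterSet,
                                      STRUCTURES, class_keys,
                                      degradation_factor, integrate_trajectory,
                                      parameter_count, rhs,
                                      transcription_term)


def uniform_network(C, q, rng=None):
    """Uniform in-connectivity q (first q regulators per class, cyclically)."""
    edges = frozenset((int((c + k) % C), c) for c in range(C)
                      for k in range(q))
    return Network(C, edges)


def random_params(structure, net, rng):
    pset = ParameterSet.zeros(structure, net)
    lo = np.array([b[0] for b in pset.bounds()])
    hi = np.array([b[1] for b in pset.bounds()])
    # modest magnitudes keep integrations tame
    theta = rng.uniform(np.maximum(lo, -2.0), np.minimum(hi, 2.0))
    return pset.with_flat(theta)


class TestParameterCount:
    @pytest.mark.parametrize("structure,q,C,p", [
        ("m_NN_exp", 3, 10, 110),
        ("m_lin", 3, 10, 40),
        ("m_NC_exp", 3, 10, 70),
        ("m_CN_exp", 3, 10, 70),
        ("m_NC_pol", 3, 10, 100),
        ("m_NC_pol", 7, 12, 216),
        ("m_CN_exp", 7, 12, 132),
        ("m_NC_exp", 7, 12, 132),
        ("m_lin", 7, 12, 96),
        ("m_NN_exp", 7, 12, 228),
        ("m_lin", 1, 1, 2),
    ])
    def test_count_formulas(self, structure, q, C, p):
        assert parameter_count(structure, q, C) == p

    @pytest.mark.parametrize("structure", STRUCTURES)
    @pytest.mark.parametrize("q,C", [(1, 1), (2, 4), (3, 5)])
    def test_census_matches_formula(self, structure, q, C):
        # regression documenting the offset layout: a materialized
        # uniform-q ParameterSet has exactly the advertised free-parameter
        # census for every structure
        net = uniform_network(C, q)
        pset = ParameterSet.zeros(structure, net)
        assert pset.n_free == parameter_count(structure, q, C)


class TestTerms:
    def test_cn_exp_transcription_is_constant(self, rng):
        net = uniform_network(2, 1)
        pset = ParameterSet.zeros("m_CN_exp", net)
        vals = dict(pset.values)
        vals[("rho", 0, None)] = 1.3
        pset = ParameterSet("m_CN_exp", net, vals)
        for _ in range(5):
            x = rng.uniform(0, 5, size=2)
            assert transcription_term("m_CN_exp", pset.class_block(0), x) == 1.3

    def test_nc_exp_degradation_is_constant(self, rng):
        net = uniform_network(2, 1)
        pset = ParameterSet.zeros("m_NC_exp", net)
        vals = dict(pset.values)
        vals[("gamma", 0, None)] = 0.4
        pset = ParameterSet("m_NC_exp", net, vals)
        for _ in range(5):
            x = rng.uniform(0, 5, size=2)
            assert degradation_factor("m_NC_exp", pset.class_block(0), x) == 0.4

    def test_sigmoid_midpoint_and_saturation(self):
        net = Network(1, frozenset({(0, 0)}))
        vals = {("lambda_plus", 0, None): 2.0, ("lambda_minus", 0, None): 0.0,
                ("kappa_plus", 0, None): 1.0, ("kappa_minus", 0, None): 3.0,
                ("L0", 0, None): 0.0, ("L", 0, 0): 1.0, ("K", 0, 0): 1.0}
        pset = ParameterSet("m_NN_exp", net, vals)
        block = pset.class_block(0)
        # S_L = 0 at x = 0 -> midpoint (lambda+ + lambda-)/2
        assert transcription_term("m_NN_exp", block, np.array([0.0])) \
            == pytest.approx(1.0)
        # S -> +inf saturates Theta at lambda+ and Delta at kappa+
        big = np.array([500.0])
        assert transcription_term("m_NN_exp", block, big) == pytest.approx(2.0)
        assert degradation_factor("m_NN_exp", block, big) == pytest.approx(1.0)
        # overflow-safe at S -> -inf too
        small = np.array([-500.0])
        assert transcription_term("m_NN_exp", block, small) == pytest.approx(0.0)
        assert degradation_factor("m_NN_exp", block, small) == pytest.approx(3.0)

    def test_cn_exp_midpoint(self):
        net = Network(1, frozenset({(0, 0)}))
        vals = {("rho", 0, None): 1.0, ("kappa_plus", 0, None): 1.0,
                ("kappa_minus", 0, None): 3.0, ("K0", 0, None): 0.0,
                ("K", 0, 0): 1.0}
        pset = ParameterSet("m_CN_exp", net, vals)
        assert degradation_factor("m_CN_exp", pset.class_block(0),
                                  np.array([0.0])) == pytest.approx(2.0)

    @pytest.mark.parametrize("structure", ["m_CN_exp", "m_NC_exp", "m_NN_exp"])
    def test_exponential_terms_bounded_by_plateaus(self, structure, rng):
        net = uniform_network(3, 2)
        for _ in range(20):
            pset = random_params(structure, net, rng)
            x = rng.uniform(-5, 5, size=3)
            for c in range(3):
                blk = pset.class_block(c)
                s = blk["scalars"]
                th = transcription_term(structure, blk, x)
                de = degradation_factor(structure, blk, x)
                if structure in ("m_NC_exp", "m_NN_exp"):
                    lo = min(s["lambda_plus"], s["lambda_minus"])
                    hi = max(s["lambda_plus"], s["lambda_minus"])
                    assert lo - 1e-12 <= th <= hi + 1e-12
                if structure in ("m_CN_exp", "m_NN_exp"):
                    lo = min(s["kappa_plus"], s["kappa_minus"])
                    hi = max(s["kappa_plus"], s["kappa_minus"])
                    assert lo - 1e-12 <= de <= hi + 1e-12

    def test_nc_pol_transcription_in_zero_rho(self, rng):
        net = uniform_network(2, 1)
        for _ in range(20):
            pset = random_params("m_NC_pol", net, rng)
            x = rng.uniform(0, 5, size=2)
            for c in range(2):
                blk = pset.class_block(c)
                th = transcription_term("m_NC_pol", blk, x)
                assert 0.0 <= th <= blk["scalars"]["rho"] + 1e-12


class TestRhs:
    def test_null_linear_system(self):
        net = uniform_network(3, 1)
        pset = ParameterSet.zeros("m_lin", net)
        assert np.allclose(rhs("m_lin", pset, np.array([1.0, 2.0, 3.0])), 0.0)

    def test_one_dim_linear(self):
        net = Network(1, frozenset({(0, 0)}))
        pset = ParameterSet("m_lin", net,
                            {("b", 0, None): 0.0, ("M", 0, 0): -1.0})
        assert rhs("m_lin", pset, np.array([2.0]))[0] == pytest.approx(-2.0)

    def test_fixed_point_balance(self):
        net = Network(1, frozenset({(0, 0)}))
        vals = {("rho", 0, None): 1.0, ("kappa_plus", 0, None): 1.0,
                ("kappa_minus", 0, None): 1.0, ("K0", 0, None): 0.0,
                ("K", 0, 0): 0.7}
        pset = ParameterSet("m_CN_exp", net, vals)
        # Delta == 1 everywhere, Theta == 1, so x = 1 is a fixed point
        assert rhs("m_CN_exp", pset, np.array([1.0]))[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("structure", STRUCTURES)
    def test_flat_model_agrees_with_reference_rhs(self, structure, rng):
        net = uniform_network(4, 2)
        for _ in range(10):
            pset = random_params(structure, net, rng)
            model = FlatModel(structure, 4, pset.keys)
            x = rng.uniform(0.1, 4.0, size=4)
            assert np.allclose(model.rhs(pset.to_flat(), x),
                               rhs(structure, pset, x), rtol=1e-12, atol=1e-12)


class TestIntegration:
    def one_dim(self, m):
        net = Network(1, frozenset({(0, 0)}))
        return ParameterSet("m_lin", net,
                            {("b", 0, None): 0.0, ("M", 0, 0): m})

    def test_decay_matches_closed_form(self):
        traj, div = integrate_trajectory("m_lin", self.one_dim(-1.0),
                                         np.array([1.0]),
                                         np.array([0.0, 1.0]))
        assert not div
        assert traj[0, -1] == pytest.approx(np.exp(-1.0), abs=1e-5)

    def test_growth_matches_closed_form(self):
        traj, div = integrate_trajectory("m_lin", self.one_dim(1.0),
                                         np.array([1.0]),
                                         np.array([0.0, 3.0]))
        assert not div
        assert traj[0, -1] == pytest.approx(np.exp(3.0), rel=1e-5)

    def test_random_linear_matches_closed_form(self, rng):
        for _ in range(10):
            m = rng.uniform(-1.0, 1.0)
            x0 = rng.uniform(0.5, 2.0)
            traj, div = integrate_trajectory("m_lin", self.one_dim(m),
                                             np.array([x0]),
                                             np.array([0.0, 0.7, 2.0]))
            assert not div
            assert np.allclose(traj[0], x0 * np.exp(m * np.array([0, 0.7, 2.0])),
                               rtol=1e-5)

    def test_fixed_point_stays_constant(self):
        net = Network(1, frozenset({(0, 0)}))
        vals = {("rho", 0, None): 1.0, ("kappa_plus", 0, None): 1.0,
                ("kappa_minus", 0, None): 1.0, ("K0", 0, None): 0.0,
                ("K", 0, 0): 0.7}
        pset = ParameterSet("m_CN_exp", net, vals)
        traj, div = integrate_trajectory("m_CN_exp", pset, np.array([1.0]),
                                         np.linspace(0, 10, 6))
        assert not div
        assert np.allclose(traj, 1.0, atol=1e-6)

    def test_divergence_is_flagged_and_capped(self):
        # dx/dt = 10 x blows past the cap well before t = 5
        traj, div = integrate_trajectory("m_lin", self.one_dim(10.0),
                                         np.array([1.0]),
                                         np.array([0.0, 1.0, 5.0]))
        assert div
        assert np.max(np.abs(traj)) <= 1e6
        assert traj[0, 0] == pytest.approx(1.0)


class TestParameterSet:
    def test_json_roundtrip_is_exact(self, rng):
        net = uniform_network(3, 2)
        pset = random_params("m_NN_exp", net, rng)
        back = ParameterSet.from_json(pset.to_json())
        assert back.structure == pset.structure
        assert back.network == pset.network
        assert back.values == pset.values
        assert back.keys == pset.keys

    def test_drop_coupling_removes_edge_when_last(self):
        net = Network(2, frozenset({(0, 0), (1, 0), (0, 1)}))
        pset = ParameterSet.zeros("m_NN_exp", net)
        # class 0 has regulators {0, 1}; edge (1,0) carries L and K
        p1 = pset.drop_coupling(("L", 0, 1))
        assert (1, 0) in p1.network.edges  # K coupling still alive
        p2 = p1.drop_coupling(("K", 0, 1))
        assert (1, 0) not in p2.network.edges
        assert p2.n_free == pset.n_free - 2

    def test_bounds_follow_sign_constraints(self):
        net = Network(1, frozenset({(0, 0)}))
        pset = ParameterSet.zeros("m_NC_pol", net)
        assert all(lo == 0.0 and hi == 10.0 for lo, hi in pset.bounds())
        lin = ParameterSet.zeros("m_lin", net)
        assert all(lo == -10.0 and hi == 10.0 for lo, hi in lin.bounds())
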