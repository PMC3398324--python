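import numpy as np
import pytest

from devexpr.invariant_clustering import ClusterProfiles
from devexpr.model_structures import Network, ParameterSet, integrate_trajectory
from devexpr.network_inference import FitSolution, OptimizerSettings, sigma
from devexpr.profile_data import ExpressionProfile, ProfileSet, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_settings():
    """Small search budgets for unit tests."""
    return OptimizerSettings(direct_maxfun=200, polish_maxiter=80,
                             stage2_maxiter=60)


@pytest.fixture
def grid4():
    return TimeGrid([0.0, 1.0, 2.0, 3.0], ("embryonic",) * 4)


@pytest.fixture
def small_pset(grid4):
    return ProfileSet(grid4, (
        ExpressionProfile("gA", [1.0, 2.0, 3.0, 4.0]),
        ExpressionProfile("gB", [2.0, 4.0, 6.0, 8.0]),
        ExpressionProfile("gC", [5.0, 3.0, 2.0, 1.0]),
    ))


def make_lin_solution(M, b, x0, times, coord="hours"):
    """Build a fitted m_lin FitSolution directly from a coupling matrix,
    basal vector and initial state (helper for reduction/evaluation tests)."""
    M = np.atleast_2d(np.asarray(M, float))
    C = M.shape[0]
    edges = frozenset((d, c) for c in range(C) for d in range(C)
                      if M[c, d] != 0.0)
    net = Network(C, edges)
    vals = {}
    for c in range(C):
        vals[("b", c, None)] = float(np.asarray(b, float).ravel()[c])
        for d in net.incoming(c):
            vals[("M", c, d)] = float(M[c, d])
    params = ParameterSet("m_lin", net, vals)
    times = np.asarray(times, float)
    grid = TimeGrid(times, ("embryonic",) * times.size)
    traj, diverged = integrate_trajectory("m_lin", params, np.asarray(x0, float),
                                          times)
    assert not diverged
    data = ClusterProfiles(grid, traj)
    sig, sig_c, traj = sigma("m_lin", params, data, coord)
    sol = FitSolution("m_lin", net, params, traj, sig_c, sig, coord)
    return sol, data
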