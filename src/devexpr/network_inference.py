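"""Two-stage identification of cluster regulatory networks.

Stage 1 (gradient matching): the ODE right-hand side is fitted to
smoothing-spline estimates of the trajectory derivatives, evaluated on the
*measured* states.  This decouples the classes into independent algebraic
problems scored by

    zeta_c = sqrt( (1/N) sum_k ( dXbar_c(tau_k) - rhs_c(Xbar(tau_k)) )^2 ),
    zeta   = sqrt( (1/C) sum_c zeta_c^2 ).

The incoming connections of each class are grown greedily from q = 1 up to
q_max: every candidate regulator is trialled with a deterministic
dividing-rectangles (DIRECT) global search inside the parameter box followed
by a bounded quasi-Newton polish; the candidate minimizing zeta_c is kept,
and every addition re-frees and re-optimizes the class's whole block.

Stage 2 (trajectory matching): with the network fixed per q, all parameters
are optimized against the coupled objective

    sigma_c = sqrt( (1/N) sum_k ( Xbar_c(tau_k) - Xhat_c(tau_k) )^2 ),
    sigma   = sqrt( (1/C) sum_c sigma_c^2 ),

where Xhat is the ODE trajectory integrated from the measured initial state.
The lowest q is initialized from stage 1 or from zero (whichever gives the
smaller sigma); each subsequent q warm-starts from the q-1 solution with the
newly added couplings at zero, so sigma(q) is non-increasing.  The final
connectivity q_m is the smallest q after which sigma stops improving by more
than a declared relative tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import direct, minimize

from .invariant_clustering import ClusterProfiles
from .model_structures import (PENALTY_SIGMA, FlatModel, Network, ParameterSet,
                               _integrate_flat, class_bounds, class_keys)
from .profile_data import TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerSettings",
    "DerivativeEstimates",
    "FitSolution",
    "Stage1Result",
    "estimate_derivatives",
    "zeta",
    "zeta_total",
    "sigma",
    "stage1_greedy",
    "stage2_fit",
    "select_qm",
    "ClusterNetworkODE",
]


@dataclass(frozen=True)
class OptimizerSettings:
    """Search budgets; every run artifact records them.

    direct_maxfun: function evaluations for the DIRECT global search per
    candidate connection.  polish_maxiter / gtol: bounded L-BFGS-B polish.
    stage2_maxiter: iterations for each coupled trajectory fit.
    """

    direct_maxfun: int = 500
    polish_maxiter: int = 200
    gtol: float = 1e-8
    stage2_maxiter: int = 200
    rtol: float = 1e-7
    atol: float = 1e-9


@dataclass(frozen=True)
class DerivativeEstimates:
    grid: TimeGrid
    values: np.ndarray  # (C, N)
    coord: str = "hours"


@dataclass(frozen=True)
class FitSolution:
    """A fitted (structure, network, parameters) triple with diagnostics."""

    structure: str
    network: Network
    params: ParameterSet
    trajectories: np.ndarray      # (C, N) integrated estimate
    sigma_c: np.ndarray
    sigma: float
    coord: str = "hours"
    zeta: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return self.params.n_free

    @property
    def mean_connectivity(self) -> float:
        return self.network.mean_connectivity


@dataclass(frozen=True)
class Stage1Result:
    q: int
    network: Network
    params: ParameterSet
    zeta_c: np.ndarray
    zeta: float


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def estimate_derivatives(data: ClusterProfiles, smoothing: float | None = 0.99,
                         coord: str = "hours") -> DerivativeEstimates:
    """Cubic smoothing-spline derivative estimates at the grid points.

    ``smoothing`` is the csaps-style parameter p in (0, 1]; the spline
    minimizes sum (y - f)^2 + lam * int f''^2 on the abscissa normalized to
    [0, 1], with lam = (1-p)/p (p = 1: natural interpolating spline;
    None: generalized cross-validation).
    """
    t = data.grid.coordinate(coord)
    if t.size < 4:
        raise ValueError("need at least 4 points for cubic smoothing splines")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate grid times")
    span = t[-1] - t[0]
    u = (t - t[0]) / span
    if smoothing is None:
        lam = None
    else:
        if not 0.0 < smoothing <= 1.0:
            raise ValueError("smoothing must be in (0, 1]")
        lam = (1.0 - smoothing) / smoothing
    derivs = np.empty_like(data.trajectories)
    for c, y in enumerate(data.trajectories):
        spl = make_smoothing_spline(u, y, lam=lam)
        derivs[c] = spl.derivative()(u) / span
    return DerivativeEstimates(data.grid, derivs, coord)


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def zeta(rate_residuals: np.ndarray) -> float:
    """RMS of one class's derivative residuals."""
    r = np.asarray(rate_residuals, float)
    return float(np.sqrt(np.mean(r * r)))


def zeta_total(zeta_c) -> float:
    z = np.asarray(zeta_c, float)
    return float(np.sqrt(np.mean(z * z)))


def sigma(structure: str, params: ParameterSet, data: ClusterProfiles,
          coord: str = "hours", rtol: float = 1e-7, atol: float = 1e-9
          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Coupled trajectory objective: integrate from Xbar(tau_1) and score
    the per-class RMS deviations.  Divergence yields the penalty value."""
    model = FlatModel(structure, params.network.n_classes, params.keys)
    return _sigma_flat(model, params.to_flat(), data, coord, rtol, atol)


def _sigma_flat(model: FlatModel, theta, data: ClusterProfiles, coord,
                rtol=1e-7, atol=1e-9):
    times = data.grid.coordinate(coord)
    x0 = data.trajectories[:, 0]
    traj, diverged = _integrate_flat(model, theta, x0, times, rtol, atol)
    if diverged:
        C = data.trajectories.shape[0]
        return PENALTY_SIGMA, np.full(C, PENALTY_SIGMA), traj
    res = data.trajectories - traj
    sig_c = np.sqrt(np.mean(res * res, axis=1))
    return float(np.sqrt(np.mean(sig_c * sig_c))), sig_c, traj


# ---------------------------------------------------------------------------
# stage 1: greedy connection growth on the decoupled gradient-matching score
# ---------------------------------------------------------------------------

class _ClassObjective:
    """zeta_c as a function of one class's flat parameter block, evaluated
    algebraically on the measured states."""

    def __init__(self, structure, C, c, regulators, data: ClusterProfiles,
                 derivs: DerivativeEstimates):
        self.keys = class_keys(structure, c, regulators)
        self.bounds = class_bounds(structure, self.keys)
        # single-class FlatModel: reindex class c to position 0 but keep
        # regulator indices into the full state vector
        self.model = _SingleClassRates(structure, c, self.keys)
        self.X = data.trajectories
        self.target = derivs.values[c]

    def __call__(self, theta):
        r = self.model.rates(theta, self.X) - self.target
        return float(np.sqrt(np.mean(r * r)))


class _SingleClassRates:
    """Vectorized rhs_c over all time points for a single class."""

    def __init__(self, structure, c, keys):
        self.structure = structure
        self.c = c
        self.scalar = {name: i for i, (name, cc, d) in enumerate(keys) if d is None}
        self.coup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        kinds: dict[str, tuple[list, list]] = {}
        for i, (name, cc, d) in enumerate(keys):
            if d is not None:
                kinds.setdefault(name, ([], []))[0].append(d)
                kinds[name][1].append(i)
        for kind, (regs, pos) in kinds.items():
            self.coup[kind] = (np.array(regs, int), np.array(pos, int))

    def _sum(self, theta, kind, X, offset=None):
        s = theta[self.scalar[offset]] if offset else 0.0
        if kind in self.coup:
            regs, pos = self.coup[kind]
            s = s + theta[pos] @ X[regs]
        return s

    def rates(self, theta, X):
        from scipy.special import expit
        st, c = self.structure, self.c
        if st == "m_lin":
            return self._sum(theta, "M", X, "b") + np.zeros(X.shape[1])
        if st == "m_NC_pol":
            SA = self._sum(theta, "A", X, "A0")
            SB = self._sum(theta, "B", X, "B0")
            return (theta[self.scalar["rho"]] * (SA / (1.0 + SA)) / (1.0 + SB)
                    - theta[self.scalar["gamma"]] * X[c])
        if st == "m_CN_exp":
            kp, km = theta[self.scalar["kappa_plus"]], theta[self.scalar["kappa_minus"]]
            delta = kp + (km - kp) * expit(self._sum(theta, "K", X, "K0"))
            return theta[self.scalar["rho"]] - delta * X[c]
        lp, lm = theta[self.scalar["lambda_plus"]], theta[self.scalar["lambda_minus"]]
        theta_c = lm + (lp - lm) * expit(self._sum(theta, "L", X, "L0"))
        if st == "m_NC_exp":
            return theta_c - theta[self.scalar["gamma"]] * X[c]
        kp, km = theta[self.scalar["kappa_plus"]], theta[self.scalar["kappa_minus"]]
        delta = km + (kp - km) * expit(self._sum(theta, "K", X, None))
        return theta_c - delta * X[c]


def _global_then_local(obj, x_warm=None, settings=OptimizerSettings()):
    """DIRECT global search in the box, polished by L-BFGS-B; an optional
    warm start is polished too and the better optimum kept."""
    candidates = []
    try:
        res = direct(obj, obj.bounds, maxfun=settings.direct_maxfun,
                     maxiter=max(1000, settings.direct_maxfun))
        candidates.append(res.x)
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("DIRECT failed (%s); falling back to warm start", exc)
    if x_warm is not None:
        candidates.append(np.asarray(x_warm, float))
    if not candidates:
        candidates.append(np.array([0.5 * (lo + hi) for lo, hi in obj.bounds]))
    best_x, best_f = None, np.inf
    for x0 in candidates:
        x0 = np.clip(x0, [lo for lo, _ in obj.bounds], [hi for _, hi in obj.bounds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(obj, x0, method="L-BFGS-B", bounds=obj.bounds,
                           options={"maxiter": settings.polish_maxiter,
                                    "gtol": settings.gtol})
        f = obj(res.x)
        if f < best_f:
            best_x, best_f = res.x, f
    return best_x, best_f


def stage1_greedy(structure: str, data: ClusterProfiles,
                  derivs: DerivativeEstimates, q_max: int,
                  settings: OptimizerSettings = OptimizerSettings()
                  ) -> list[Stage1Result]:
    """Greedy per-class connection growth on the gradient-matching score.

    For q = 1..q_max and each class independently: trial every regulator not
    yet connected (self-edges included), keep the one minimizing zeta_c, and
    re-optimize the class's whole parameter block after each addition.
    """
    C = data.trajectories.shape[0]
    if not 1 <= q_max <= C:
        raise ValueError("need 1 <= q_max <= C")
    per_class_regs: list[list[int]] = [[] for _ in range(C)]
    per_class_theta: list[np.ndarray | None] = [None] * C
    per_class_zeta = np.full(C, np.inf)
    results: list[Stage1Result] = []
    for q in range(1, q_max + 1):
        for c in range(C):
            best = None  # (zeta, d, theta, keys)
            for d in range(C):
                if d in per_class_regs[c]:
                    continue
                regs = sorted(per_class_regs[c] + [d])
                obj = _ClassObjective(structure, C, c, regs, data, derivs)
                warm = None
                if per_class_theta[c] is not None:
                    old_keys = class_keys(structure, c, per_class_regs[c])
                    old = dict(zip(old_keys, per_class_theta[c]))
                    warm = np.array([old.get(k, 0.0) for k in obj.keys])
                try:
                    x, f = _global_then_local(obj, warm, settings)
                except Exception as exc:
                    logger.warning("class %d candidate %d skipped: %s", c, d, exc)
                    continue
                if best is None or f < best[0]:
                    best = (f, d, x, obj.keys)
            if best is None:
                raise RuntimeError(f"no viable candidate connection for class {c}")
            f, d, x, keys = best
            per_class_regs[c] = sorted(per_class_regs[c] + [d])
            per_class_theta[c] = x
            per_class_zeta[c] = f
        edges = frozenset((d, c) for c in range(C) for d in per_class_regs[c])
        net = Network(C, edges)
        pset = ParameterSet.zeros(structure, net)
        vals = dict(pset.values)
        for c in range(C):
            for k, v in zip(class_keys(structure, c, per_class_regs[c]),
                            per_class_theta[c]):
                vals[k] = float(v)
        pset = ParameterSet(structure, net, vals)
        results.append(Stage1Result(q, net, pset, per_class_zeta.copy(),
                                    zeta_total(per_class_zeta)))
    return results


# ---------------------------------------------------------------------------
# stage 2: coupled trajectory fitting
# ---------------------------------------------------------------------------

def _polish_sigma(structure, params: ParameterSet, data, coord, settings):
    model = FlatModel(structure, params.network.n_classes, params.keys)
    bounds = params.bounds()

    def obj(theta):
        return _sigma_flat(model, theta, data, coord,
                           settings.rtol, settings.atol)[0]

    x0 = np.clip(params.to_flat(), [lo for lo, _ in bounds],
                 [hi for _, hi in bounds])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": settings.stage2_maxiter,
                                "gtol": settings.gtol})
    cand = params.with_flat(res.x)
    f_new = obj(res.x)
    f_old = obj(x0)
    if f_old < f_new:  # optimizer wobble guard: never accept a regression
        cand, f_new = params.with_flat(x0), f_old
    return cand, f_new


def stage2_fit(structure: str, stage1_results: list[Stage1Result],
               data: ClusterProfiles, coord: str = "hours",
               settings: OptimizerSettings = OptimizerSettings()
               ) -> list[FitSolution]:
    """Fit the coupled trajectories for each stage-1 network.

    Lowest q: stage-1 values vs all-zero initialization, whichever has the
    lower sigma, then polish.  Higher q: warm start from the q-1 solution
    with newly added parameters at zero, then polish with all parameters
    free.
    """
    solutions: list[FitSolution] = []
    prev: ParameterSet | None = None
    for s1 in stage1_results:
        if prev is None:
            zero = ParameterSet.zeros(structure, s1.network)
            s_stage1 = sigma(structure, s1.params, data, coord,
                             settings.rtol, settings.atol)[0]
            s_zero = sigma(structure, zero, data, coord,
                           settings.rtol, settings.atol)[0]
            init = s1.params if s_stage1 <= s_zero else zero
        else:
            vals = {k: 0.0 for k in ParameterSet.zeros(structure, s1.network).values}
            for k, v in prev.values.items():
                if k in vals:
                    vals[k] = v
            init = ParameterSet(structure, s1.network, vals)
        fitted, _ = _polish_sigma(structure, init, data, coord, settings)
        sig, sig_c, traj = sigma(structure, fitted, data, coord,
                                 settings.rtol, settings.atol)
        solutions.append(FitSolution(
            structure, s1.network, fitted, traj, sig_c, sig, coord,
            zeta=s1.zeta,
            provenance={"stage": 2, "q": s1.q, "settings": vars(settings)}))
        prev = fitted
    return solutions


def select_qm(sigma_curve, rel_tol: float = 0.05) -> int:
    """Smallest q whose step to q+1 improves sigma by at most ``rel_tol``
    (relative); the last q if improvement persists.  Returns a 1-based
    position into the curve."""
    s = list(sigma_curve)
    if not s:
        raise ValueError("empty sigma curve")
    for i in range(len(s) - 1):
        improvement = (s[i] - s[i + 1]) / s[i] if s[i] > 0 else 0.0
        if improvement <= rel_tol * (1.0 + 1e-9):
            return i + 1
    return len(s)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ClusterNetworkODE:
    """Two-stage ODE network identification as a fit/predict estimator.

    Parameters mirror the pipeline knobs: model ``structure``, maximum
    connectivity ``q_max``, spline ``smoothing``, the q_m stopping
    ``rel_tol``, the integration coordinate, and optimizer settings.

    Attributes (after fit)
    ----------------------
    derivatives_ : DerivativeEstimates
    stage1_results_ : list[Stage1Result]
    solutions_ : list[FitSolution] (one per q)
    q_m_ : selected connectivity
    solution_ : FitSolution at q_m
    sigma_ : its sigma
    """

    def __init__(self, structure: str = "m_NN_exp", q_max: int = 3,
                 smoothing: float | None = 0.99, rel_tol: float = 0.05,
                 coord: str = "hours",
                 settings: OptimizerSettings = OptimizerSettings()):
        self.structure = structure
        self.q_max = q_max
        self.smoothing = smoothing
        self.rel_tol = rel_tol
        self.coord = coord
        self.settings = settings

    def get_params(self, deep=True):
        return {"structure": self.structure, "q_max": self.q_max,
                "smoothing": self.smoothing, "rel_tol": self.rel_tol,
                "coord": self.coord, "settings": self.settings}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, *, grid: TimeGrid | None = None):
        """X: ClusterProfiles, or (C, N) array with ``grid``."""
        if isinstance(X, ClusterProfiles):
            data = X
        else:
            X = np.atleast_2d(np.asarray(X, float))
            if grid is None:
                grid = TimeGrid(np.arange(X.shape[1], dtype=float),
                                ("embryonic",) * X.shape[1])
            data = ClusterProfiles(grid, X)
        self.data_ = data
        self.derivatives_ = estimate_derivatives(data, self.smoothing, self.coord)
        self.stage1_results_ = stage1_greedy(
            self.structure, data, self.derivatives_, self.q_max, self.settings)
        self.solutions_ = stage2_fit(self.structure, self.stage1_results_,
                                     data, self.coord, self.settings)
        self.q_m_ = select_qm([s.sigma for s in self.solutions_], self.rel_tol)
        self.solution_ = self.solutions_[self.q_m_ - 1]
        self.sigma_ = self.solution_.sigma
        return self

    def predict(self, times=None) -> np.ndarray:
        """Integrated trajectories of the selected solution at ``times``
        (defaults to the fitted grid), shape (C, len(times))."""
        from .model_structures import integrate_trajectory
        sol = self.solution_
        if times is None:
            return sol.trajectories
        traj, _ = integrate_trajectory(
            sol.structure, sol.params, self.data_.trajectories[:, 0],
            np.asarray(times, float))
        return traj
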