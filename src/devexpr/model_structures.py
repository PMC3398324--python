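"""The five ODE model structures for cluster-average expression dynamics.

Every structure is of the production/removal form

    dXbar_c/dt = Theta_c(Xbar) - Delta_c(Xbar) * Xbar_c ,

with a transcription term Theta_c and a degradation factor Delta_c whose
parameterization defines the structure:

====================  =======================================  ==================
name                  Theta_c                                  Delta_c
====================  =======================================  ==================
m_lin                 b_c + sum_d M_cd X_d   (unconstrained)   0
m_NC_pol              rho_c * S_A/(1+S_A) * 1/(1+S_B)          gamma_c
m_CN_exp              rho_c                                    sig+(kappa; S_K)
m_NC_exp              sig-(lambda; S_L)                        gamma_c
m_NN_exp              sig-(lambda; S_L)                        sig-(kappa; S_K)
====================  =======================================  ==================

where S_A = A_c0 + sum_d A_cd X_d (similarly S_B, S_K, S_L over the incoming
edges of class c), sig-(p; S) = (p+ + p- e^{-S}) / (1 + e^{-S}) and
sig+(p; S) uses e^{+S}.  Each regulator sum carries a constant offset
(m_NN_exp: only the L sum), so the free-parameter counts at uniform
in-connectivity q are

    p = (q+1)C  [m_lin],  (2q+4)C  [m_NC_pol],  (q+4)C  [m_CN_exp, m_NC_exp],
    (2q+5)C  [m_NN_exp].

All parameters are box-bounded (|J| <= 10, roughly the dynamic range of the
data); rho, gamma, kappa+-, lambda+- and the m_NC_pol parameters are
additionally non-negative.  The linear model's "transcription" term may be
negative, the one structural exception to the positivity convention; its
pathologies under extrapolation are part of the analysis.

Sigmoids are evaluated as p- + (p+ - p-) * logistic(S) (overflow-safe).
Diverging integrations return a capped trajectory flagged for a penalty
objective rather than raising, so global searches can probe wild parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "STRUCTURES",
    "PARAM_BOUND",
    "DIVERGENCE_CAP",
    "PENALTY_SIGMA",
    "Network",
    "ParameterSet",
    "class_keys",
    "class_bounds",
    "parameter_count",
    "transcription_term",
    "degradation_factor",
    "rhs",
    "integrate_trajectory",
    "FlatModel",
]

STRUCTURES = ("m_lin", "m_NC_pol", "m_CN_exp", "m_NC_exp", "m_NN_exp")

PARAM_BOUND = 10.0          # |J| <= 10 box constraint
DIVERGENCE_CAP = 1e6        # state magnitude treated as divergence
PENALTY_SIGMA = 1e6         # objective value returned for divergent fits

# per-class scalar parameters: (name, non-negative?)
_CLASS_PARAMS: dict[str, tuple[tuple[str, bool], ...]] = {
    "m_lin": (("b", False),),
    "m_NC_pol": (("rho", True), ("gamma", True), ("A0", True), ("B0", True)),
    "m_CN_exp": (("rho", True), ("kappa_plus", True), ("kappa_minus", True),
                 ("K0", False)),
    "m_NC_exp": (("gamma", True), ("lambda_plus", True), ("lambda_minus", True),
                 ("L0", False)),
    "m_NN_exp": (("lambda_plus", True), ("lambda_minus", True),
                 ("kappa_plus", True), ("kappa_minus", True), ("L0", False)),
}

# per-edge coupling kinds: (kind, non-negative?)
_COUPLING_KINDS: dict[str, tuple[tuple[str, bool], ...]] = {
    "m_lin": (("M", False),),
    "m_NC_pol": (("A", True), ("B", True)),
    "m_CN_exp": (("K", False),),
    "m_NC_exp": (("L", False),),
    "m_NN_exp": (("L", False), ("K", False)),
}

COUPLING_NAMES = frozenset(k for kinds in _COUPLING_KINDS.values()
                           for k, _ in kinds)


def _check_structure(structure: str) -> None:
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; one of {STRUCTURES}")


def parameter_count(structure: str, q: int, C: int) -> int:
    """Free parameters of a structure at uniform in-connectivity q with C
    classes: census of per-class scalars plus q couplings per edge kind."""
    _check_structure(structure)
    if q < 1 or C < 1:
        raise ValueError("need q >= 1 and C >= 1")
    per_class = len(_CLASS_PARAMS[structure]) + q * len(_COUPLING_KINDS[structure])
    return per_class * C


# ---------------------------------------------------------------------------
# network and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Network:
    """Directed cluster network: edge (d, c) means class d regulates class c.

    Classes are 0-based internally; self-edges are allowed.
    """

    n_classes: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self):
        object.__setattr__(self, "edges",
                           frozenset((int(d), int(c)) for d, c in self.edges))
        for d, c in self.edges:
            if not (0 <= d < self.n_classes and 0 <= c < self.n_classes):
                raise ValueError(f"edge ({d},{c}) outside 0..{self.n_classes-1}")

    def incoming(self, c: int) -> list[int]:
        return sorted(d for d, cc in self.edges if cc == c)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_connectivity(self) -> float:
        """Average number of connections ending at a node (fractional after
        reduction)."""
        return self.n_edges / self.n_classes

    def validate_covered(self) -> None:
        orphans = [c for c in range(self.n_classes) if not self.incoming(c)]
        if orphans:
            raise ValueError(f"classes without incoming edges: {orphans}")


ParamKey = tuple[str, int, int | None]   # (name, class c, regulator d or None)


def class_keys(structure: str, c: int, regulators: list[int]) -> list[ParamKey]:
    """Canonical parameter order for one class: scalars first, then the
    coupling kinds per regulator in ascending regulator order."""
    keys: list[ParamKey] = [(name, c, None) for name, _ in _CLASS_PARAMS[structure]]
    for d in sorted(regulators):
        keys.extend((kind, c, d) for kind, _ in _COUPLING_KINDS[structure])
    return keys


def class_bounds(structure: str, n_keys_or_keys) -> list[tuple[float, float]]:
    """Box bounds per key (non-negative parameters get [0, 10])."""
    keys = n_keys_or_keys
    nonneg = {name for name, nn in _CLASS_PARAMS[structure] if nn}
    nonneg |= {kind for kind, nn in _COUPLING_KINDS[structure] if nn}
    return [(0.0 if k[0] in nonneg else -PARAM_BOUND, PARAM_BOUND) for k in keys]


@dataclass
class ParameterSet:
    """Parameter values for (structure, network), keyed canonically.

    ``values`` maps (name, c, d) -> float, ordered as the flat optimization
    vector.  Coupling entries exist only for network edges; after reduction
    a two-coupling edge may carry a single surviving coupling.
    """

    structure: str
    network: Network
    values: dict[ParamKey, float]

    @classmethod
    def zeros(cls, structure: str, network: Network) -> "ParameterSet":
        _check_structure(structure)
        vals: dict[ParamKey, float] = {}
        for c in range(network.n_classes):
            for k in class_keys(structure, c, network.incoming(c)):
                vals[k] = 0.0
        return cls(structure, network, vals)

    # -- flat-vector interface --------------------------------------------
    @property
    def keys(self) -> list[ParamKey]:
        return list(self.values.keys())

    @property
    def n_free(self) -> int:
        return len(self.values)

    def to_flat(self) -> np.ndarray:
        return np.array(list(self.values.values()), float)

    def with_flat(self, theta: np.ndarray) -> "ParameterSet":
        theta = np.asarray(theta, float)
        if theta.size != self.n_free:
            raise ValueError("flat vector length mismatch")
        return ParameterSet(self.structure, self.network,
                            dict(zip(self.values.keys(), theta)))

    def bounds(self) -> list[tuple[float, float]]:
        return class_bounds(self.structure, self.keys)

    def coupling_keys(self) -> list[ParamKey]:
        return [k for k in self.values if k[0] in COUPLING_NAMES]

    def edge_couplings(self, d: int, c: int) -> list[ParamKey]:
        return [k for k in self.values
                if k[0] in COUPLING_NAMES and k[1] == c and k[2] == d]

    def drop_coupling(self, key: ParamKey) -> "ParameterSet":
        """Remove one coupling; its edge disappears when no coupling for
        that (regulator, class) pair remains."""
        if key[0] not in COUPLING_NAMES or key not in self.values:
            raise KeyError(f"not a live coupling: {key}")
        vals = {k: v for k, v in self.values.items() if k != key}
        name, c, d = key
        net = self.network
        if not [k for k in vals if k[0] in COUPLING_NAMES
                and k[1] == c and k[2] == d]:
            net = Network(net.n_classes, net.edges - {(d, c)})
        return ParameterSet(self.structure, net, vals)

    # -- structured access -------------------------------------------------
    def class_block(self, c: int) -> dict:
        """Readable view: {"scalars": {name: v}, "couplings": {kind: {d: v}}}."""
        scalars = {name: self.values[(name, c, None)]
                   for name, _ in _CLASS_PARAMS[self.structure]}
        couplings: dict[str, dict[int, float]] = {
            kind: {} for kind, _ in _COUPLING_KINDS[self.structure]}
        for (name, cc, d), v in self.values.items():
            if cc == c and d is not None:
                couplings[name][d] = v
        return {"scalars": scalars, "couplings": couplings}

    # -- serialization (exact round trip) ----------------------------------
    def to_json(self) -> str:
        payload = {
            "structure": self.structure,
            "n_classes": self.network.n_classes,
            "edges": sorted(self.network.edges),
            "values": [[name, c, d, v] for (name, c, d), v in self.values.items()],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        payload = json.loads(text)
        net = Network(payload["n_classes"],
                      frozenset(tuple(e) for e in payload["edges"]))
        vals = {(name, c, None if d is None else int(d)): float(v)
                for name, c, d, v in payload["values"]}
        return cls(payload["structure"], net, vals)


# ---------------------------------------------------------------------------
# per-class terms (readable reference implementation)
# ---------------------------------------------------------------------------

def _sums(block: dict, x: np.ndarray, kind: str, offset: str | None) -> float:
    s = block["scalars"][offset] if offset else 0.0
    for d, v in block["couplings"].get(kind, {}).items():
        s += v * x[d]
    return s


def transcription_term(structure: str, block: dict, x: np.ndarray) -> float:
    """Theta_c for one class given its parameter block and the state."""
    _check_structure(structure)
    x = np.asarray(x, float)
    s = block["scalars"]
    if structure == "m_lin":
        return _sums(block, x, "M", "b")
    if structure == "m_NC_pol":
        SA = _sums(block, x, "A", "A0")
        SB = _sums(block, x, "B", "B0")
        return s["rho"] * (SA / (1.0 + SA)) * (1.0 / (1.0 + SB))
    if structure == "m_CN_exp":
        return s["rho"]
    # m_NC_exp, m_NN_exp: (l+ + l- e^{-S}) / (1 + e^{-S})
    SL = _sums(block, x, "L", "L0")
    return s["lambda_minus"] + (s["lambda_plus"] - s["lambda_minus"]) * expit(SL)


def degradation_factor(structure: str, block: dict, x: np.ndarray) -> float:
    """Delta_c for one class."""
    _check_structure(structure)
    x = np.asarray(x, float)
    s = block["scalars"]
    if structure == "m_lin":
        return 0.0
    if structure in ("m_NC_pol", "m_NC_exp"):
        return s["gamma"]
    if structure == "m_CN_exp":
        # positive exponent: (k+ + k- e^{+S}) / (1 + e^{+S})
        SK = _sums(block, x, "K", "K0")
        return s["kappa_plus"] + (s["kappa_minus"] - s["kappa_plus"]) * expit(SK)
    # m_NN_exp: negative exponent, no K offset
    SK = _sums(block, x, "K", None)
    return s["kappa_minus"] + (s["kappa_plus"] - s["kappa_minus"]) * expit(SK)


def rhs(structure: str, params: ParameterSet, x: np.ndarray) -> np.ndarray:
    """Right-hand side dXbar/dt, component c = Theta_c - Delta_c * Xbar_c."""
    x = np.asarray(x, float)
    out = np.empty(params.network.n_classes)
    for c in range(out.size):
        block = params.class_block(c)
        out[c] = (transcription_term(structure, block, x)
                  - degradation_factor(structure, block, x) * x[c])
    return out


# ---------------------------------------------------------------------------
# compiled flat-vector evaluation (hot path for fitting)
# ---------------------------------------------------------------------------

class FlatModel:
    """Precompiled evaluation of a structure over a fixed key order.

    Maps a flat parameter vector theta (ordered as ``keys``) to the ODE
    right-hand side; used by the optimizers so that repacking dictionaries
    is not on the objective's hot path.
    """

    def __init__(self, structure: str, n_classes: int, keys: list[ParamKey]):
        _check_structure(structure)
        self.structure = structure
        self.n_classes = n_classes
        self.keys = list(keys)
        self._scalar_idx: list[dict[str, int]] = [dict() for _ in range(n_classes)]
        coup: list[dict[str, tuple[list[int], list[int]]]] = [
            {kind: ([], []) for kind, _ in _COUPLING_KINDS[structure]}
            for _ in range(n_classes)]
        for i, (name, c, d) in enumerate(self.keys):
            if d is None:
                self._scalar_idx[c][name] = i
            else:
                regs, pos = coup[c][name]
                regs.append(d)
                pos.append(i)
        self._coup = [{kind: (np.array(regs, int), np.array(pos, int))
                       for kind, (regs, pos) in per.items()} for per in coup]

    def _s(self, theta, c, name):
        return theta[self._scalar_idx[c][name]]

    def _sum(self, theta, c, kind, x, offset=None):
        regs, pos = self._coup[c][kind]
        s = self._s(theta, c, offset) if offset else 0.0
        if regs.size:
            s = s + theta[pos] @ x[regs]
        return s

    def rhs(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, -DIVERGENCE_CAP * 10, DIVERGENCE_CAP * 10)
        st = self.structure
        out = np.empty(self.n_classes)
        for c in range(self.n_classes):
            if st == "m_lin":
                theta_c, delta_c = self._sum(theta, c, "M", x, "b"), 0.0
            elif st == "m_NC_pol":
                SA = self._sum(theta, c, "A", x, "A0")
                SB = self._sum(theta, c, "B", x, "B0")
                theta_c = self._s(theta, c, "rho") * (SA / (1.0 + SA)) / (1.0 + SB)
                delta_c = self._s(theta, c, "gamma")
            elif st == "m_CN_exp":
                theta_c = self._s(theta, c, "rho")
                kp, km = self._s(theta, c, "kappa_plus"), self._s(theta, c, "kappa_minus")
                delta_c = kp + (km - kp) * expit(self._sum(theta, c, "K", x, "K0"))
            elif st == "m_NC_exp":
                lp, lm = self._s(theta, c, "lambda_plus"), self._s(theta, c, "lambda_minus")
                theta_c = lm + (lp - lm) * expit(self._sum(theta, c, "L", x, "L0"))
                delta_c = self._s(theta, c, "gamma")
            else:  # m_NN_exp
                lp, lm = self._s(theta, c, "lambda_plus"), self._s(theta, c, "lambda_minus")
                kp, km = self._s(theta, c, "kappa_plus"), self._s(theta, c, "kappa_minus")
                theta_c = lm + (lp - lm) * expit(self._sum(theta, c, "L", x, "L0"))
                delta_c = km + (kp - km) * expit(self._sum(theta, c, "K", x, None))
            out[c] = theta_c - delta_c * x[c]
        return out


# ---------------------------------------------------------------------------
# trajectory integration
# ---------------------------------------------------------------------------

def integrate_trajectory(structure: str, params: ParameterSet,
                         x0: np.ndarray, times: np.ndarray,
                         rtol: float = 1e-7, atol: float = 1e-9,
                         ) -> tuple[np.ndarray, bool]:
    """Integrate the ODE from x0, sampling at ``times``.

    Returns (trajectory of shape (C, len(times)), diverged flag).  On solver
    failure or state escape beyond ``DIVERGENCE_CAP`` the remaining samples
    are filled with the capped last state and the flag is set, so callers
    can assign a penalty objective instead of raising.
    """
    model = FlatModel(structure, params.network.n_classes, params.keys)
    theta = params.to_flat()
    return _integrate_flat(model, theta, x0, times, rtol, atol)


#: rhs-evaluation budget per integration; stalling (near-stiff) parameter
#: draws are treated as divergent rather than letting the solver crawl
MAX_RHS_EVALS = 20_000


class _BudgetExceeded(Exception):
    pass


def _integrate_flat(model: FlatModel, theta: np.ndarray, x0: np.ndarray,
                    times: np.ndarray, rtol: float = 1e-7, atol: float = 1e-9
                    ) -> tuple[np.ndarray, bool]:
    times = np.asarray(times, float)
    x0 = np.asarray(x0, float)
    budget = [MAX_RHS_EVALS]

    def fun(t, x):
        budget[0] -= 1
        if budget[0] < 0:
            raise _BudgetExceeded
        return model.rhs(theta, x)

    def escape(t, x):
        return float(np.max(np.abs(x)) - DIVERGENCE_CAP)
    escape.terminal = True
    escape.direction = 1.0

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(fun, (times[0], times[-1]), x0, t_eval=times,
                            rtol=rtol, atol=atol, events=escape, method="RK45")
    except _BudgetExceeded:
        traj = np.full((x0.size, times.size), np.clip(x0, -DIVERGENCE_CAP,
                                                      DIVERGENCE_CAP)[:, None])
        return traj, True
    n_got = sol.y.shape[1] if sol.y.size else 0
    traj = np.empty((x0.size, times.size))
    if n_got:
        traj[:, :n_got] = sol.y
    diverged = (not sol.success) or (n_got < times.size)
    if n_got < times.size:
        last = np.clip(traj[:, n_got - 1] if n_got else x0,
                       -DIVERGENCE_CAP, DIVERGENCE_CAP)
        traj[:, n_got:] = last[:, None]
    traj = np.nan_to_num(traj, nan=DIVERGENCE_CAP, posinf=DIVERGENCE_CAP,
                         neginf=-DIVERGENCE_CAP)
    if np.max(np.abs(traj)) > DIVERGENCE_CAP:
        traj = np.clip(traj, -DIVERGENCE_CAP, DIVERGENCE_CAP)
        diverged = True
    return traj, diverged
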