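"""One-at-a-time parameter elimination with refitting.

Only coupling parameters (M, A, B, K, L) are droppable; rates, plateaus and
offsets persist as long as their class keeps at least one incoming edge,
and every class must keep one throughout.  Five selection rules are
implemented:

  Psi_v   : drop the coupling of smallest absolute value;
  Psi_s   : drop the coupling whose zeroing (before refit) increases sigma
            the least;
  Psi_P   : drop the coupling most sensitive to a finite +-1% perturbation
            (largest resulting sigma);
  Psi_F-  : among couplings correlated with another parameter in the Fisher
            sense (F_ij >= 0.9 sqrt(F_ii F_jj), i != j), drop the one with
            the smallest diagonal sensitivity F_ii;
  Psi_F+  : likewise, largest F_ii.

After each drop the remaining parameters are refitted by bounded local
optimization of sigma; the loop stops once sigma exceeds a cap (0.5 by
default: beyond it measured and fitted profiles differ too much) or no
eligible candidate remains.  The Fisher information matrix is

    F_ij = sum_c sum_k dXhat_c(tau_k)/dJ_i * dXhat_c(tau_k)/dJ_j,

with sensitivities estimated by central finite differences of the
integrated trajectories (relative step 1e-4; one-sided fallback when a
perturbed integration diverges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .invariant_clustering import ClusterProfiles
from .model_structures import ParameterSet, ParamKey, integrate_trajectory
from .network_inference import FitSolution, OptimizerSettings, _polish_sigma, sigma

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMES",
    "FisherMatrix",
    "ReductionTrace",
    "fisher_matrix",
    "eligible_couplings",
    "select_drop_candidate",
    "reduce_solution",
    "select_best_reduced",
]

SCHEMES = ("psi_v", "psi_sigma", "psi_P", "psi_F_minus", "psi_F_plus")
FISHER_CORRELATION = 0.9
PERTURBATION = 0.01


@dataclass(frozen=True)
class FisherMatrix:
    keys: tuple[ParamKey, ...]
    matrix: np.ndarray

    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


@dataclass
class ReductionStep:
    dropped: ParamKey
    solution: FitSolution
    sigma: float


@dataclass
class ReductionTrace:
    scheme: str
    initial: FitSolution
    steps: list[ReductionStep] = field(default_factory=list)
    sigma_cap: float = 0.5

    def selected_index(self) -> int | None:
        """Most-reduced step with sigma <= cap (None: keep the unreduced
        solution)."""
        sel = None
        for i, st in enumerate(self.steps):
            if st.sigma <= self.sigma_cap:
                sel = i
        return sel

    def selected_solution(self) -> FitSolution:
        i = self.selected_index()
        return self.initial if i is None else self.steps[i].solution

    def candidate_solutions(self) -> list[FitSolution]:
        """Unreduced solution plus every within-cap step, most reduced last."""
        return [self.initial] + [st.solution for st in self.steps
                                 if st.sigma <= self.sigma_cap]


# ---------------------------------------------------------------------------
# Fisher information
# ---------------------------------------------------------------------------

def fisher_matrix(solution: FitSolution, data: ClusterProfiles,
                  step: float = 1e-4) -> FisherMatrix:
    """Central finite-difference Fisher matrix over the free parameters."""
    params = solution.params
    keys = tuple(params.keys)
    theta = params.to_flat()
    times = data.grid.coordinate(solution.coord)
    x0 = data.trajectories[:, 0]

    def traj_at(vec):
        tr, div = integrate_trajectory(solution.structure,
                                       params.with_flat(vec), x0, times)
        return tr, div

    base, _ = traj_at(theta)
    S = np.empty((len(keys), base.size))
    for i in range(len(keys)):
        h = step * abs(theta[i]) if theta[i] != 0.0 else step
        up = theta.copy(); up[i] += h
        dn = theta.copy(); dn[i] -= h
        tu, du = traj_at(up)
        td, dd = traj_at(dn)
        if du and dd:
            logger.warning("both Fisher perturbations of %s diverged", keys[i])
            S[i] = 0.0
        elif du:
            logger.warning("one-sided Fisher difference for %s", keys[i])
            S[i] = (base - td).ravel() / h
        elif dd:
            logger.warning("one-sided Fisher difference for %s", keys[i])
            S[i] = (tu - base).ravel() / h
        else:
            S[i] = (tu - td).ravel() / (2.0 * h)
    F = S @ S.T
    return FisherMatrix(keys, 0.5 * (F + F.T))


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def eligible_couplings(params: ParameterSet) -> list[ParamKey]:
    """Couplings whose removal leaves every class with >= 1 incoming edge."""
    out = []
    for key in params.coupling_keys():
        name, c, d = key
        # removal deletes the edge only if it is the last coupling on it
        last_on_edge = len(params.edge_couplings(d, c)) == 1
        if last_on_edge and len(params.network.incoming(c)) <= 1:
            continue
        out.append(key)
    return out


def select_drop_candidate(solution: FitSolution, scheme: str,
                          data: ClusterProfiles,
                          fisher: FisherMatrix | None = None,
                          settings: OptimizerSettings = OptimizerSettings()
                          ) -> ParamKey | None:
    """Next coupling to drop under a scheme; None signals termination."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    params = solution.params
    eligible = eligible_couplings(params)
    if not eligible:
        return None

    if scheme == "psi_v":
        return min(eligible, key=lambda k: (abs(params.values[k]), _rank(params, k)))

    if scheme == "psi_sigma":
        best, best_s = None, np.inf
        for k in eligible:
            vals = dict(params.values)
            vals[k] = 0.0
            s = sigma(solution.structure,
                      ParameterSet(params.structure, params.network, vals),
                      data, solution.coord, settings.rtol, settings.atol)[0]
            if s < best_s:
                best, best_s = k, s
        return best

    if scheme == "psi_P":
        worst, worst_s = None, -np.inf
        for k in eligible:
            s_max = -np.inf
            for sgn in (1.0, -1.0):
                vals = dict(params.values)
                vals[k] = vals[k] * (1.0 + sgn * PERTURBATION)
                s = sigma(solution.structure,
                          ParameterSet(params.structure, params.network, vals),
                          data, solution.coord, settings.rtol, settings.atol)[0]
                s_max = max(s_max, s)
            if s_max > worst_s:
                worst, worst_s = k, s_max
        return worst

    # Fisher-based schemes
    F = fisher if fisher is not None else fisher_matrix(solution, data)
    idx = {k: i for i, k in enumerate(F.keys)}
    diag = F.diagonal()
    correlated = []
    for k in eligible:
        i = idx[k]
        thr = FISHER_CORRELATION * np.sqrt(np.abs(diag[i] * diag))
        mask = np.abs(F.matrix[i]) >= thr
        mask[i] = False
        if mask.any():
            correlated.append(k)
    if not correlated:
        return None
    if scheme == "psi_F_minus":
        return min(correlated, key=lambda k: (diag[idx[k]], _rank(params, k)))
    return max(correlated, key=lambda k: (diag[idx[k]], -_rank(params, k)))


def _rank(params: ParameterSet, key: ParamKey) -> int:
    return params.keys.index(key)


# ---------------------------------------------------------------------------
# reduction loop and final selection
# ---------------------------------------------------------------------------

def reduce_solution(solution: FitSolution, scheme: str, data: ClusterProfiles,
                    sigma_cap: float = 0.5,
                    settings: OptimizerSettings = OptimizerSettings()
                    ) -> ReductionTrace:
    """Iteratively drop couplings under ``scheme``, refitting after each
    drop, until sigma exceeds the cap or nothing is droppable."""
    trace = ReductionTrace(scheme, solution, sigma_cap=sigma_cap)
    current = solution
    while True:
        key = select_drop_candidate(current, scheme, data, settings=settings)
        if key is None:
            break
        reduced = current.params.drop_coupling(key)
        refit, _ = _polish_sigma(current.structure, reduced, data,
                                 current.coord, settings)
        sig, sig_c, traj = sigma(current.structure, refit, data,
                                 current.coord, settings.rtol, settings.atol)
        current = FitSolution(current.structure, refit.network, refit, traj,
                              sig_c, sig, current.coord,
                              provenance={**solution.provenance,
                                          "reduction": scheme,
                                          "n_dropped": len(trace.steps) + 1})
        trace.steps.append(ReductionStep(key, current, sig))
        if sig > sigma_cap:
            break
    return trace


def select_best_reduced(traces: dict[str, ReductionTrace],
                        data: ClusterProfiles,
                        sigma_cap: float = 0.5,
                        ranking: tuple[str, ...] = ("sigma", "sigma_pert",
                                                    "chi", "p"),
                        ) -> tuple[FitSolution, list[dict]]:
    """Pick the winning reduced solution across schemes.

    Per trace, the most reduced step whose *per-class* sigma_c are all
    <= ``sigma_cap`` is a candidate; candidates are ranked lexicographically
    on the evaluation report fields (default sigma, sigma_pert, chi, p).
    If no candidate exists, the unreduced solution is returned with a
    diagnostic row (mirrors excluding a structure from the comparison).
    """
    from .robustness_evaluation import evaluate_solution

    candidates: list[tuple[str, FitSolution]] = []
    for scheme, trace in traces.items():
        chosen = None
        for sol in trace.candidate_solutions():
            if np.all(sol.sigma_c <= sigma_cap):
                chosen = sol  # keep the most reduced (later entries)
        if chosen is not None:
            candidates.append((scheme, chosen))
    table = []
    if not candidates:
        any_trace = next(iter(traces.values()))
        base = any_trace.initial
        rep = evaluate_solution(base, data)
        table.append({"scheme": "unreduced", **rep.as_dict(),
                      "diagnostic": "no reduced solution satisfies the "
                                    "per-class sigma cap"})
        return base, table
    ranked = []
    for scheme, sol in candidates:
        rep = evaluate_solution(sol, data)
        row = {"scheme": scheme, **rep.as_dict()}
        ranked.append((tuple(row[k] for k in ranking), scheme, sol, row))
    ranked.sort(key=lambda t: (t[0], t[1]))
    table = [r[3] for r in ranked]
    return ranked[0][2], table
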