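"""Ground-truth generators for end-to-end pipeline benchmarking.

The generator emulates the statistical shape of a developmental microarray
series: C archetype trajectories produced by a known sparse ODE system on a
multi-phase grid, expanded into many per-gene profiles through gene-specific
affine distortions (each gene's ratio profile is its archetype up to a
scale and offset, mirroring gene-dependent reference intensities) plus
additive Gaussian noise.  Because the clustering distance is exactly
invariant under such affine maps, noise-free synthetic genes sit at
distance zero from their archetype, tying the generator mathematically to
the clustering stage.

Grid presets mirror the canonical study shapes: an "embryonic-like" grid of
31 points over 24 h, and a "full-series-like" grid of 67 points with phase
lengths 31/10/18/8 (24 h / 81 h / 111 h / 30 d).  For the full-series
preset the true parameters may switch at phase boundaries
(piecewise-constant), emulating the abrupt transitions between
developmental stages; this is a deliberate extension for fixture realism.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .invariant_clustering import (ClusterProfiles, InvariantProfileClustering)
from .model_structures import (Network, ParameterSet, STRUCTURES,
                               _CLASS_PARAMS, _COUPLING_KINDS,
                               class_keys, integrate_trajectory)
from .profile_data import ExpressionProfile, ProfileSet, TimeGrid

__all__ = [
    "make_grid",
    "SyntheticSystem",
    "generate_true_system",
    "simulate_cluster_profiles",
    "expand_to_genes",
    "recovery_benchmark",
]

#: trajectory acceptance window for rejection sampling
TRAJ_LO, TRAJ_HI = 0.05, 10.0
#: minimal per-class dynamic range so the dynamics are non-trivial
MIN_RANGE = 0.2
#: archetype-diversity screens, matched to each structure's mimicry class.
#: m_lin couplings enter linearly, so two regulators are interchangeable
#: when their trajectories are near-affine images of each other: cap
#: |Pearson r|.  The non-linear structures regulate through monotone
#: (sigmoid) terms, so a regulator is additionally mimicked by any monotone
#: transform of its trajectory: cap |Spearman rank correlation| on top.
MAX_CORR = 0.9
MAX_RANK_CORR = 0.7
#: per-class RMS mismatch allowed between interpolating-spline derivative
#: estimates and the true rates: gradient matching presumes the grid
#: resolves the dynamics, so unresolved fast transients are rejected
DERIV_TOL = 0.02
#: minimal range, over the trajectory, of each regulated term's
#: contribution to the rates: a connection whose sigmoid is saturated (or
#: whose plateaus coincide) has no detectable effect and cannot be
#: recovered by any method, so such ground truths are rejected
MIN_MODULATION = 0.1

# default sampling sub-ranges of the +-10 parameter box, chosen to yield
# bounded, distinguishable dynamics on a day-scale grid.  Sigmoid couplings
# are drawn as magnitude-and-sign so arguments neither vanish nor saturate;
# plateau pairs are forced apart so regulation has a detectable amplitude.
_DEFAULT_RANGES = {
    "coupling": {"m_lin": (-0.4, 0.4), "m_NC_pol": (0.2, 1.5),
                 "m_CN_exp": (0.5, 1.5), "m_NC_exp": (0.5, 1.5),
                 "m_NN_exp": (0.5, 1.5)},   # magnitude for sigmoid models
    "plateau": (0.2, 1.0),       # low side of rho/lambda pairs
    "plateau_gap": (0.8, 2.0),   # separation of the lambda+- pair
    "rate": (0.1, 0.4),          # low side of gamma/kappa (per hour:
                                 # hours-scale turnover the grid resolves)
    "rate_gap": (0.3, 0.6),      # separation of the kappa+- pair
    "offset_jitter": (-0.3, 0.3),  # around the centering value of K0/L0
    "x_ref": 1.25,               # typical level used to center sigmoids
    "b": (-0.2, 0.2),            # m_lin basal term
    "x0": (0.5, 2.0),
}


def make_grid(preset: str = "embryonic-like") -> TimeGrid:
    """Preset multi-phase grids.

    "embryonic-like": 31 uniform points over 24 h, one phase.
    "full-series-like": 67 points with phase lengths 31/10/18/8 covering
    24 h, 81 h, 111 h and 30 days; sampling is uniform within a phase, so
    the real-time step jumps abruptly between phases.
    """
    if preset == "embryonic-like":
        return TimeGrid(np.linspace(0.0, 24.0, 31), ("embryonic",) * 31)
    if preset == "full-series-like":
        times = [np.linspace(0.0, 24.0, 31)]
        labels = ["embryonic"] * 31
        start = 24.0
        for span, n, phase in ((81.0, 10, "larval"), (111.0, 18, "pupal"),
                               (720.0, 8, "adult")):
            step = span / n
            times.append(start + step * np.arange(1, n + 1))
            labels += [phase] * n
            start += span
        return TimeGrid(np.concatenate(times), tuple(labels))
    raise ValueError(f"unknown preset {preset!r}")


@dataclass(frozen=True)
class SyntheticSystem:
    """A known-truth sparse ODE system plus its grid and seed.

    ``phase_params`` holds one ParameterSet per phase (a single entry when
    parameters do not switch)."""

    structure: str
    network: Network
    phase_params: tuple[ParameterSet, ...]
    x0: np.ndarray
    grid: TimeGrid
    coord: str
    seed: int

    @property
    def params(self) -> ParameterSet:
        return self.phase_params[0]

    def true_edges(self) -> frozenset[tuple[int, int]]:
        return self.network.edges


def _pair(rng, lo_range, gap_range):
    """A well-separated (plus, minus) pair in random order."""
    lo = rng.uniform(*lo_range)
    hi = lo + rng.uniform(*gap_range)
    return (hi, lo) if rng.random() < 0.5 else (lo, hi)


def _sample_params(rng: np.random.Generator, structure: str, net: Network,
                   ranges: dict) -> ParameterSet:
    coupling = ranges["coupling"][structure]
    x_ref = ranges["x_ref"]
    vals: dict = {}
    for c in range(net.n_classes):
        regs = net.incoming(c)
        keys = class_keys(structure, c, regs)
        draw: dict = {}
        if structure == "m_lin":
            draw["b"] = rng.uniform(*ranges["b"])
            for d in regs:
                draw[("M", d)] = rng.uniform(*coupling)
        elif structure == "m_NC_pol":
            draw["rho"] = rng.uniform(ranges["plateau"][0] + ranges["plateau_gap"][0],
                                      sum(ranges["plateau_gap"]))
            draw["gamma"] = rng.uniform(*ranges["rate"])
            draw["A0"], draw["B0"] = rng.uniform(0.0, 1.0, size=2)
            for d in regs:
                draw[("A", d)] = rng.uniform(*coupling)
                draw[("B", d)] = rng.uniform(0.0, 0.5)
        else:
            signs = {d: rng.choice([-1.0, 1.0]) for d in regs}
            mags = {d: rng.uniform(*coupling) for d in regs}
            if structure in ("m_NC_exp", "m_NN_exp"):
                lp, lm = _pair(rng, ranges["plateau"], ranges["plateau_gap"])
                draw["lambda_plus"], draw["lambda_minus"] = lp, lm
                for d in regs:
                    draw[("L", d)] = signs[d] * mags[d]
                draw["L0"] = (-sum(draw[("L", d)] for d in regs) * x_ref
                              + rng.uniform(*ranges["offset_jitter"]))
            if structure == "m_NC_exp":
                draw["gamma"] = rng.uniform(*ranges["rate"])
            if structure in ("m_CN_exp", "m_NN_exp"):
                kp, km = _pair(rng, ranges["rate"], ranges["rate_gap"])
                draw["kappa_plus"], draw["kappa_minus"] = kp, km
                ksigns = {d: rng.choice([-1.0, 1.0]) for d in regs}
                kmags = {d: rng.uniform(*coupling) for d in regs}
                for d in regs:
                    draw[("K", d)] = ksigns[d] * kmags[d]
                if structure == "m_CN_exp":
                    draw["rho"] = rng.uniform(
                        ranges["plateau"][0] + ranges["plateau_gap"][0],
                        sum(ranges["plateau_gap"]))
                    draw["K0"] = (-sum(draw[("K", d)] for d in regs) * x_ref
                                  + rng.uniform(*ranges["offset_jitter"]))
        for key in keys:
            name, _, d = key
            vals[key] = float(draw[name] if d is None else draw[(name, d)])
    return ParameterSet(structure, net, vals)


def _integrate_system(system: SyntheticSystem) -> tuple[np.ndarray, bool]:
    """Noise-free trajectory; piecewise integration when parameters switch
    at phase boundaries."""
    grid = system.grid
    times = grid.coordinate(system.coord)
    if len(system.phase_params) == 1:
        return integrate_trajectory(system.structure, system.params,
                                    system.x0, times)
    traj = np.empty((system.network.n_classes, times.size))
    x, diverged = system.x0, False
    pos = 0
    for phase, pset in zip(grid.phases, system.phase_params):
        mask = grid.phase_mask(phase)
        seg = times[mask]
        if pos > 0:
            seg = np.concatenate(([times[pos - 1]], seg))
        t_seg, div = integrate_trajectory(system.structure, pset, x, seg)
        diverged |= div
        block = t_seg[:, 1:] if pos > 0 else t_seg
        traj[:, pos:pos + int(mask.sum())] = block
        x = traj[:, pos + int(mask.sum()) - 1]
        pos += int(mask.sum())
    return traj, diverged


def generate_true_system(C: int, q_true: int, structure: str, seed: int,
                         param_ranges: dict | None = None,
                         grid: TimeGrid | None = None, coord: str = "hours",
                         phase_switch: bool = False,
                         max_tries: int = 2000) -> SyntheticSystem:
    """Rejection-sample a bounded, non-trivial ground-truth system.

    The network has uniform in-connectivity ``q_true`` (regulators drawn
    without replacement, self-edges allowed).  Parameter draws are repeated
    until the noise-free trajectory stays inside [0.05, 10] over the whole
    grid and every class moves by at least 0.2 (flat archetypes are
    unidentifiable).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if not 1 <= q_true <= C:
        raise ValueError("need 1 <= q_true <= C")
    rng = np.random.default_rng(seed)
    grid = grid if grid is not None else make_grid("embryonic-like")
    ranges = dict(_DEFAULT_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    n_param_sets = len(grid.phases) if phase_switch else 1
    for _ in range(max_tries):
        edges = frozenset((int(d), c) for c in range(C)
                          for d in rng.choice(C, size=q_true, replace=False))
        net = Network(C, edges)
        psets = tuple(_sample_params(rng, structure, net, ranges)
                      for _ in range(n_param_sets))
        x0 = rng.uniform(*ranges["x0"], size=C)
        system = SyntheticSystem(structure, net, psets, x0, grid, coord, seed)
        traj, diverged = _integrate_system(system)
        if diverged:
            continue
        if traj.min() < TRAJ_LO or traj.max() > TRAJ_HI:
            continue
        if (traj.max(axis=1) - traj.min(axis=1)).min() < MIN_RANGE:
            continue
        if C > 1:
            iu = np.triu_indices(C, 1)
            if np.max(np.abs(np.corrcoef(traj)[iu])) > MAX_CORR:
                continue
            if structure != "m_lin":
                ranks = np.argsort(np.argsort(traj, axis=1), axis=1).astype(float)
                if np.max(np.abs(np.corrcoef(ranks)[iu])) > MAX_RANK_CORR:
                    continue
        if not _edges_influential(system, traj):
            continue
        if not phase_switch and not _derivatives_resolved(system, traj):
            continue
        return system
    raise RuntimeError(
        f"no acceptable system in {max_tries} draws; widen param_ranges")


def _edges_influential(system: SyntheticSystem, traj: np.ndarray) -> bool:
    """True when every regulated term moves the rates by at least
    MIN_MODULATION somewhere along the trajectory."""
    from .model_structures import degradation_factor, transcription_term
    st = system.structure
    N = traj.shape[1]
    for pset in system.phase_params:
        for c in range(system.network.n_classes):
            block = pset.class_block(c)
            if st == "m_lin":
                for d, v in block["couplings"]["M"].items():
                    if np.ptp(v * traj[d]) < MIN_MODULATION:
                        return False
                continue
            theta_k = np.array([transcription_term(st, block, traj[:, k])
                                for k in range(N)])
            delta_k = np.array([degradation_factor(st, block, traj[:, k])
                                for k in range(N)])
            if st in ("m_NC_pol", "m_NC_exp", "m_NN_exp"):
                if np.ptp(theta_k) < MIN_MODULATION:
                    return False
            if st in ("m_CN_exp", "m_NN_exp"):
                if np.ptp(delta_k * traj[c]) < MIN_MODULATION:
                    return False
    return True


def _derivatives_resolved(system: SyntheticSystem, traj: np.ndarray) -> bool:
    """True when interpolating-spline derivatives of the noise-free
    trajectory match the true rates to within DERIV_TOL per class."""
    from .model_structures import FlatModel
    from .network_inference import estimate_derivatives
    est = estimate_derivatives(ClusterProfiles(system.grid, traj),
                               smoothing=1.0, coord=system.coord)
    model = FlatModel(system.structure, system.network.n_classes,
                      system.params.keys)
    theta = system.params.to_flat()
    true_rates = np.stack([model.rhs(theta, traj[:, k])
                           for k in range(traj.shape[1])], axis=1)
    err = np.sqrt(np.mean((est.values - true_rates) ** 2, axis=1))
    return bool(np.all(err <= DERIV_TOL))


def simulate_cluster_profiles(system: SyntheticSystem, noise_sd: float = 0.05,
                              seed: int | None = None) -> ClusterProfiles:
    """Integrate the truth and add i.i.d. Gaussian noise per sample."""
    traj, diverged = _integrate_system(system)
    if diverged:
        raise RuntimeError("true system diverged; regenerate")
    if noise_sd > 0:
        rng = np.random.default_rng(system.seed + 1 if seed is None else seed)
        traj = traj + rng.normal(0.0, noise_sd, size=traj.shape)
    return ClusterProfiles(system.grid, traj)


def expand_to_genes(cluster_profiles: ClusterProfiles,
                    genes_per_cluster: int = 20,
                    scale_range: tuple[float, float] = (0.5, 2.0),
                    shift_range: tuple[float, float] = (0.0, 1.0),
                    gene_noise_sd: float = 0.05,
                    seed: int = 0) -> tuple[ProfileSet, dict[str, int]]:
    """Per-gene affine distortions of the archetypes.

    Gene mu of cluster c gets a_mu * Xbar_c + b_mu + eps with
    a_mu ~ U(scale_range), b_mu ~ U(shift_range) and Gaussian eps; values
    are floored at 1e-3 to stay valid intensity ratios.  Returns the
    ProfileSet and the truth table gene_id -> cluster (1-based).
    """
    if scale_range[0] <= 0:
        raise ValueError("scale_range must be positive")
    rng = np.random.default_rng(seed)
    profiles, truth = [], {}
    C = cluster_profiles.n_clusters
    for c in range(C):
        arch = cluster_profiles.trajectories[c]
        for g in range(genes_per_cluster):
            a = rng.uniform(*scale_range)
            b = rng.uniform(*shift_range)
            vals = a * arch + b
            if gene_noise_sd > 0:
                vals = vals + rng.normal(0.0, gene_noise_sd, size=vals.shape)
            gene = f"c{c + 1:02d}_g{g + 1:03d}"
            profiles.append(ExpressionProfile(gene, np.clip(vals, 1e-3, None)))
            truth[gene] = c + 1
    return ProfileSet(cluster_profiles.grid, tuple(profiles)), truth


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    structure_true: str = "m_lin"
    structures_fit: tuple[str, ...] = ("m_lin",)
    C: int = 3
    q_true: int = 1
    q_max: int = 1
    noise_sd: float = 0.0
    genes_per_cluster: int = 0    # 0: fit the archetypes directly
    gene_noise_sd: float = 0.05
    seed: int = 0
    grid_preset: str = "embryonic-like"
    coord: str = "hours"
    smoothing: float = 1.0   # interpolating spline: the default run is noiseless
    rel_tol: float = 0.05
    schemes: tuple[str, ...] = ()
    sigma_cap: float = 0.5
    settings: "OptimizerSettings | None" = None


def _edge_metrics(found: frozenset, truth: frozenset) -> tuple[float, float]:
    tp = len(found & truth)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall


def recovery_benchmark(config: BenchmarkConfig) -> dict:
    """Run generate -> (cluster) -> stage1 -> stage2 -> (reduce) -> evaluate
    on synthetic truth and report recovery metrics.

    Deterministic given the config (seed included).  Returns a nested dict:
    per fitted structure, edge precision/recall at q_true, sigma, the
    evaluation quintuple, optional per-scheme reduction summaries, and the
    clustering ARI when genes were generated.
    """
    from .network_inference import ClusterNetworkODE, OptimizerSettings
    from .reduction_schemes import reduce_solution
    from .robustness_evaluation import evaluate_solution

    settings = config.settings or OptimizerSettings()
    grid = make_grid(config.grid_preset)
    system = generate_true_system(config.C, config.q_true,
                                  config.structure_true, config.seed,
                                  grid=grid, coord=config.coord)
    archetypes = simulate_cluster_profiles(system, config.noise_sd)
    out: dict = {"config": vars(config).copy(), "truth_edges":
                 sorted(system.true_edges()), "fits": {}}

    data = archetypes
    if config.genes_per_cluster > 0:
        genes, truth = expand_to_genes(
            archetypes, config.genes_per_cluster,
            gene_noise_sd=config.gene_noise_sd, seed=config.seed + 17)
        clus = InvariantProfileClustering(n_clusters=config.C).fit(genes)
        from sklearn.metrics import adjusted_rand_score
        found_labels = [clus.cluster_set_.assignment[g] for g in genes.gene_ids]
        true_labels = [truth[g] for g in genes.gene_ids]
        out["clustering_ari"] = float(
            adjusted_rand_score(true_labels, found_labels))
        data = clus.cluster_profiles_

    for structure in config.structures_fit:
        est = ClusterNetworkODE(structure=structure, q_max=config.q_max,
                                smoothing=config.smoothing,
                                rel_tol=config.rel_tol, coord=config.coord,
                                settings=settings).fit(data)
        at_q_true = est.solutions_[min(config.q_true, config.q_max) - 1]
        precision, recall = _edge_metrics(at_q_true.network.edges,
                                          system.true_edges())
        report = evaluate_solution(at_q_true, data)
        entry = {
            "edge_precision": precision,
            "edge_recall": recall,
            "sigma": at_q_true.sigma,
            "sigma_curve": [s.sigma for s in est.solutions_],
            "q_m": est.q_m_,
            "evaluation": report.as_dict(),
            "reductions": {},
        }
        for scheme in config.schemes:
            trace = reduce_solution(at_q_true, scheme, data,
                                    config.sigma_cap, settings)
            sel = trace.selected_solution()
            entry["reductions"][scheme] = {
                "n_dropped": len(trace.steps),
                "selected_p": sel.params.n_free,
                "selected_q": sel.network.mean_connectivity,
                "selected_sigma": sel.sigma,
            }
        out["fits"][structure] = entry
    return out
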