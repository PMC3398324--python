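# devexpr

Reverse engineering of **cluster-level gene regulatory networks** from
developmental expression time series, with coupled ordinary differential
equations.

Given a genes × time-points matrix of normalized expression ratios
X<sub>μ</sub>(τ<sub>k</sub>) — the canonical example being a whole-development
microarray series (embryonic → larval → pupal → adult) — the pipeline:

1. **clusters** the gene profiles with a translation- and scale-invariant
   distance, D(X, Y) = √(2 ς<sub>X</sub> ς<sub>Y</sub> (1 − |r|)), cut to a
   user-chosen number of classes C, and summarizes each class by the average
   of its members after affine superposition on the class representative;
2. **models** the C cluster-average trajectories X̄<sub>c</sub>(t) with
   autonomous ODEs of the form

   dX̄<sub>c</sub>/dt = Θ<sub>c</sub>(X̄) − Δ<sub>c</sub>(X̄)·X̄<sub>c</sub>,

   where the transcription term Θ and degradation factor Δ come from one of
   five structures: linear (`m_lin`), polynomial activator/repressor
   (`m_NC_pol`), and three sigmoid ("exponential") families (`m_CN_exp`,
   `m_NC_exp`, `m_NN_exp`) built from (p⁺ + p⁻e<sup>∓S</sup>)/(1 + e<sup>∓S</sup>)
   with S a linear combination of expression levels over the incoming edges;
3. **identifies** sparse networks in two stages: gradient matching
   (derivative RMS score ζ, greedy connection growth with a deterministic
   DIRECT global search plus bounded local polish) followed by coupled
   trajectory fitting (profile RMS score σ, warm-started across
   connectivities q);
4. **prunes** parameters with five one-at-a-time reduction schemes
   (Ψ<sub>v</sub>, Ψ<sub>σ</sub>, Ψ<sub>P</sub>, Ψ<sub>F−</sub>, Ψ<sub>F+</sub>;
   the Fisher-based ones use F<sub>ij</sub> = Σ<sub>c,k</sub>
   ∂X̄̂<sub>c</sub>/∂J<sub>i</sub> · ∂X̄̂<sub>c</sub>/∂J<sub>j</sub> and the
   correlation rule F<sub>ij</sub> ≥ 0.9·√(F<sub>ii</sub>F<sub>jj</sub>)),
   refitting after every drop and stopping once σ > 0.5;
5. **scores** every solution by the quintuple (σ, σ<sub>pert</sub>, χ, p, q):
   fit quality, robustness to the worst ±1 % single-parameter perturbation,
   stability under extrapolation to 3× the measured span (capped at the
   organism's 80-day life span), free-parameter count, and mean connectivity.

A fully seeded **synthetic-data generator** produces ground-truth systems,
cluster archetypes and gene-level matrices (per-gene affine distortions plus
noise) so that every stage is testable without external data.

## Worked example

Recover a known 3-class sigmoid-transcription system end to end — simulate
60 noisy genes, cluster them, and identify the network from the cluster
averages:

```python
from devexpr import BenchmarkConfig, recovery_benchmark
from devexpr.network_inference import OptimizerSettings

out = recovery_benchmark(BenchmarkConfig(
    structure_true="m_NC_exp", structures_fit=("m_NC_exp",),
    C=3, q_true=1, q_max=1, noise_sd=0.0, genes_per_cluster=20,
    gene_noise_sd=0.05, seed=1, smoothing=1.0,
    settings=OptimizerSettings(direct_maxfun=1000, polish_maxiter=200,
                               stage2_maxiter=150)))
fit = out["fits"]["m_NC_exp"]
print("true edges           :", out["truth_edges"])
print("clustering ARI       :", round(out["clustering_ari"], 3))
print("edge recall / prec   :", fit["edge_recall"], "/", fit["edge_precision"])
print("sigma (q = 1)        :", round(fit["sigma"], 4))
print("sigma_pert           :", round(fit["evaluation"]["sigma_pert"], 4))
print("chi (3x horizon)     :", round(fit["evaluation"]["chi"], 4))
```

prints

```
true edges           : [(0, 2), (2, 0), (2, 1)]
clustering ARI       : 1.0
edge recall / prec   : 1.0 / 1.0
sigma (q = 1)        : 0.0085
sigma_pert           : 0.0278
chi (3x horizon)     : 0.409
```

Reading: the 60 noisy genes were grouped back into their three source
classes perfectly (ARI 1.0); greedy gradient matching followed by coupled
fitting recovered all three true regulatory edges; the fitted trajectories
deviate from the data by an RMS of 0.0085 expression-ratio units; the worst
±1 % parameter perturbation only degrades that to 0.028 (robust); and
extrapolating threefold past the measured window moves the levels by 0.41
summed over classes (stable).

The same machinery is exposed as sklearn-style estimators
(`InvariantProfileClustering`, `ClusterNetworkODE`) and as a CLI:

```sh
devexpr simulate --preset embryonic-like -C 3 --seed 7 --out sim/
devexpr cluster --expression sim/expression.tsv --grid sim/grid.tsv -C 3 --out clus/
devexpr run --config cfg.yaml --out runs/exp1
```

## Layout

| module                  | contents                                             |
|-------------------------|------------------------------------------------------|
| `profile_data`          | TSV formats, TimeGrid (hours + index coordinates), ratio profiles, phase slicing |
| `invariant_clustering`  | invariant distance, average linkage, representatives, cluster averages |
| `model_structures`      | the five ODE families, parameter layout/bounds/counts, integration |
| `network_inference`     | spline derivatives, ζ/σ objectives, stage-1 greedy growth, stage-2 coupled fits, q<sup>m</sup> selection |
| `reduction_schemes`     | Fisher matrix, the five Ψ elimination rules, reduction traces, final selection |
| `robustness_evaluation` | σ_pert, extrapolation χ, evaluation reports/tables   |
| `synthetic_data`        | seeded ground-truth generators and the recovery benchmark |
| `pipeline` / `cli`      | resumable artifact-writing orchestration, `devexpr` command |
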