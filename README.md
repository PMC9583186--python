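# manifoldpeaks

Distance-based analysis of data manifolds: intrinsic-dimension
estimation, adaptive density estimation, density-peak clustering with
statistical peak merging, and rank-based comparison of distance
metrics — as a Python library with an `mpk` command line.

High-dimensional datasets (molecular-simulation frames, single-cell
expression profiles, image or network embeddings) almost never fill
their feature space: the points concentrate on a manifold of much lower
intrinsic dimension (ID), with a non-uniform density whose peaks are the
natural clusters. `manifoldpeaks` characterizes that manifold using
only the distances between points — no projection, no parametrization —
so it works even when the manifold is topologically complex (curved,
twisted, non-isomorphic to a hyperplane) or when only a distance matrix
is available. Everything is driven by per-point neighbor lists
truncated at `maxk` (default 100), keeping time and memory near-linear
in N.

## The methods

**Intrinsic dimension.** For locally uniform samples the ratio
μ_i = r_{i,2}/r_{i,1} of second- to first-neighbor distance is
Pareto-distributed, p(μ|d) = d μ^−(d+1), depending only on the ID d.
The 2NN family estimates d from {μ_i} by maximum likelihood
(d̂ = N / Σ ln μ_i), Bayesian inference (conjugate Gamma posterior), or
regression on the empirical CDF. Two scans probe the ID across length
scales: *decimation* (random subsampling) and *Gride* (generalized
ratios μ = r_{2k}/r_k of the full dataset, no subsampling).

**Density.** The kNN estimator is ρ_i = (1/N) k / (ω_d r_{i,k}^d) with
ω_d the unit-ball volume in the *intrinsic* dimension d. The
point-adaptive PAk estimator grows each neighborhood while a
likelihood-ratio test accepts local homogeneity, then fits the shell
occupancies with a log-density plus a linear correction term —
per-point F_i = ln ρ_i, slope a_i, error σ_i.

**Clustering.** With δ_i = min_{j: ρ_j > ρ_i} d_ij, density peaks are
points with both ρ and δ large (DP: user-chosen centers) or all local
density maxima pruned automatically (ADP): a peak c is merged with a
neighbor c′ whenever ln ρ_c − ln ρ_cc′ ≤ Z (σ_c + σ_cc′), where ρ_cc′
is the highest-density saddle point on their border and Z (default
1.65, typical range 1–5) sets the statistical significance of the
surviving peaks. The peak/saddle structure is summarized as a
dendrogram with cluster spans proportional to populations.

**Metric comparison.** The neighborhood overlap
χ(a,b) = ⟨|kNN_a(i) ∩ kNN_b(i)|⟩/k measures equivalence of two
metrics; the information imbalance
Δ(a→b) = (2/N²) Σ_i r^b(i, nn_a(i)) measures, asymmetrically, how well
metric a predicts metric b (≈0: fully informative; ≈1: independent).
Greedy forward selection by Δ finds small feature subsets that preserve
a target metric.

## Worked example

The package ships a topologically complex benchmark: eight Gaussian
density clusters on a 2D sheet, twisted into a 3D Möbius strip and
embedded in a noisy 50-dimensional space.

```python
import numpy as np
import manifoldpeaks as mp

data = mp.make_mobius_benchmark(n=10_000, seed=42)     # 10000 x 50
graph = mp.build_neighbor_graph(data.cloud, maxk=100)

scan = mp.id_gride_scan(graph, (1, 2, 4, 8, 16))
for e in scan.estimates:
    print(f"scale={e.scale:.4f}  id={e.id:.2f} +- {e.err:.2f}")
plateau = mp.plateau_estimate(scan)

density = mp.pak_density(graph, id_used=round(plateau.id))
result = mp.adp_cluster(graph, density)                # default Z=1.65
print(f"clusters: {result.n_clusters}")
print(f"populations: {result.population.tolist()}")
```

prints

```
scale=0.0091  id=2.66 +- 0.03
scale=0.0128  id=2.24 +- 0.02
scale=0.0179  id=2.12 +- 0.01
scale=0.0249  id=2.07 +- 0.01
scale=0.0346  id=2.04 +- 0.01
clusters: 8
populations: [1293, 1191, 1232, 1290, 1261, 1274, 1220, 1239]
```

The Gride scan starts slightly above 2 at the shortest scale (the 50D
noise inflates the very first neighbor shells) and settles onto a
plateau at ≈ 2.05: the intrinsic dimension of the sheet, read without
ever unrolling the strip. PAk density plus ADP merging then recovers
exactly the eight generative clusters — here with 99.98% label
agreement against the generator's truth — even though the strip is
one-sided and no 2D projection of it exists.

The same pipeline from the shell:

```bash
mpk synth mobius --n 10000 --seed 42 --out data.csv
mpk id data.csv --method gride --out id.tsv
mpk density data.csv --id 2 --out den.tsv
mpk cluster data.csv --id 2 --out labels.tsv --dendro dendro.json
```

Every command writes a `<out>.manifest.json` with the package version,
full configuration and input digests, so a run can be reproduced
exactly; rerunning with the same seed is byte-identical.

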