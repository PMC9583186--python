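# Methods

This note records the models implemented in `manifoldpeaks`, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Neighbor graphs

All estimators consume per-point neighbor lists truncated at `maxk`
(default 100, capped at N−1). Construction uses a kd-tree for
embedding dimension D ≤ 20 and brute-force search above, where tree
structures lose their advantage; both paths produce identical output
because every row is re-sorted by the pair (distance, point id). That
id tie-break is used everywhere — neighbor lists, ranks, density
comparisons — so all results are deterministic without any seed. Ties
that straddle the `maxk` truncation boundary are resolved exactly with
a radius query rather than trusting the tree's arbitrary tie order.

Graphs can also be built from precomputed distances (square matrix or
(i, j, d) triplets with symmetric closure), in which case the metric is
whatever the user computed; operations that must see beyond the
truncation (the exact δ fallback, exact conditional ranks) require
either coordinates or a full matrix and raise otherwise.

Duplicate points break every log-ratio (a zero first-neighbor distance),
so `remove_duplicates` collapses groups of points closer than `tol`
(default 0: exact matches) to their lowest-id representative before
estimation. Grouping is transitive (connected components of the
close-pair graph).

## Intrinsic dimension

The 2NN likelihood treats μ_i = r_{i,2}/r_{i,1} as i.i.d.
Pareto(d): p(μ|d) = d μ^−(d+1). Implemented estimators:

- **MLE** d̂ = n / Σ ln μ_i, err d̂/√n, probed scale = mean r₂.
- **Bayes** with conjugate Gamma(shape, rate) prior (default (1, 0),
  flat on d > 0): posterior Gamma(shape+n, rate+Σ ln μ); the point
  estimate is the posterior mean, the error the posterior std.
- **Regression** of −ln(1−F) on ln μ through the origin over the order
  statistics, discarding the top `discard_fraction` (default 0.1) of the
  ratios: the top of the empirical CDF is noise-dominated and F = 1 is
  singular. The reported error is d̂/√n: the naive regression SE is
  invalid here because CDF residuals are strongly correlated (it comes
  out ~100× too small).

Two scale scans:

- **Decimation**: fractions (1, 1/2, 1/4, 1/8), `n_reps` = 10 random
  subsamples each, explicit seed required; value = mean over reps,
  error = std over reps, scale = mean r₂ of the subsamples. Subsampling
  stretches typical distances by ~f^(−1/d) at the cost of variance.
- **Gride**: generalized ratios μ = r_{2n₁}/r_{n₁} for a doubling
  schedule n₁ ∈ {1, 2, 4, …} with 2·max(n₁) ≤ maxk, density
  f(μ|d) = d (μ^d − 1)^{n₁−1} / [B(n₁,n₁) μ^{(2n₁−1)d+1}]. The score
  is strictly decreasing in d, so the MLE is the unique root of the
  score, found by Brent's method in [0.01, 1000] (written in terms of
  μ^−d so it cannot overflow); the error is the inverse square root of
  the observed Fisher information. At n₁ = 1 the density reduces
  algebraically to the Pareto law (B(1,1) = 1), so the closed-form 2NN
  MLE is returned there — the two estimators agree exactly by
  construction, which is also the correctness gate for the generalized
  likelihood, together with simulation recovery.

Scale selection is deliberately not automated: the scans return the
full (scale, id, err) profile. `plateau_estimate` offers one
non-interactive convention — the adjacent scan pair with the smallest
relative difference (later pairs win near-ties), averaged — used by the
benchmark scripts; inspecting the profile remains the recommended
practice.

Known behavior: on bounded uniform supports (hypercubes) the family has
a finite-size negative bias that grows with d and with the probed scale
(boundary shells are truncated); at N = 10⁴ and d = 5 the Gride
estimate at n₁ = 8 is ≈ 4.6 while the statistical error is only ≈ 0.02.
Recovery tests on such supports therefore use a 10% relative band,
whereas on exact Pareto samples all three estimators are unbiased and
are tested at ±3·(d/√n).

## Density

Volumes are always measured in the intrinsic dimension `id_used`
(typically the rounded Gride plateau; callers may override), never the
embedding dimension: ω_d = π^(d/2)/Γ(d/2+1), ball volume ω_d r^d,
shell volumes v_{i,l} = ω_d (r_{i,l}^d − r_{i,l−1}^d).

- **kNN**: ρ_i = (1/N) k/(ω_d r_{i,k}^d), σ_i = 1/√k.
- **Adaptive k**: starting at k_min = 4, the neighborhood of i grows
  while the likelihood-ratio statistic against its (k+1)-th neighbor j,
  D_k = 2k ln[(V_i+V_j)²/(4 V_i V_j)] (χ²₁ under equal density),
  stays below `D_thr` = 23.928 (the χ²₁ quantile at p = 10⁻⁶); k̂_i is
  the last accepted size, up to maxk. On uniform data most points keep
  k̂ = maxk; across a sharp density step the neighborhood stops early.
- **PAk**: per point, maximize L(F, a) = Σ_{l≤k̂} [F + a·l −
  v_l exp(F + a·l)] by a damped 2×2 Newton iteration (init F from the
  kNN value, a = 0, steps clipped to ±2, gradient tolerance 1e−10, max
  100 iterations; non-converged points — rare, degenerate shell
  patterns — fall back to kNN at k̂ with a warning). The slope a
  captures the *radial* trend of the log-density across shells; note a
  symmetric first-order gradient cancels when shells average both
  sides, so a responds to curvature/one-sidedness of the local density,
  not to the sign of a linear ramp. σ_i = √((4k̂+2)/(k̂(k̂−1))), the
  asymptotic std of the two-parameter fit.

Normalization: PAk's raw exp(F) estimates N·ρ; the reported F subtracts
ln N so both estimators share the per-point (1/N) convention and agree
on uniform data. Clustering uses only differences of F, so this global
constant is immaterial there — that invariance is the actual contract.

## Clustering

δ_i = min distance to a higher-density point (Eq. above), searched
inside the maxk neighborhood first with an exact global fallback for
the points whose truncated neighborhood contains no higher-density
point — a truncated δ would fabricate spurious peaks. The global
maximum takes δ = max_j d_ij. Density ties are ordered by id.

DP: explicit centers (or thresholds on ρ and δ); points are processed
in descending density order and inherit the label of their nearest
higher-density neighbor, so every point's chain ends at a center.

ADP: initial peaks are the points denser than everything in their own
k̂-neighborhood. After a DP assignment to those peaks, border points
between clusters c and c′ are the points with a *mutual*
adapted-neighborhood neighbor on the other side (i within j's first k̂_j
neighbors and vice versa); the saddle ρ_cc′ is the highest-density
border point of the pair (peaks excluded, so a saddle can never exceed
either peak), σ_cc′ its error; pairs with no border have no saddle and
are never merged. While any pair's *lower* peak fails
F_c − F_cc′ > Z(σ_c + σ_cc′), the failing pair with the highest saddle
(the most entangled one) is merged — the lower peak is deleted and the
points are re-assigned from the surviving centers, so the running state
is always exactly a DP clustering of the surviving peaks; saddles are
recomputed and the loop repeats to a fixed point. This makes the final
result identical to `dp_cluster` run on the surviving peaks (a tested
invariant), and the cluster count non-increasing in Z in practice
(tested over Z ∈ {0..5}). Z defaults to 1.65 (a one-sided ~95%
significance); no halo/outlier assignment is performed.

The dendrogram summary is plain data (no rendering): peak and saddle
log-densities on y, clusters centered in x-spans proportional to their
populations, saddles at the midpoint of their two peaks.

## Metric comparison

χ uses k_overlap = 30 by default (results are insensitive to k in the
k ≪ N regime). Δ(a→b) sums the exact rank in b of each point's
nearest neighbor under a — full-row searches, never truncated at maxk,
with the same (distance, id) tie order; Δ(a→a) = 2/N exactly, and any
strictly monotone transform of the distances leaves Δ at 2/N (ranks are
invariant). For very large N a seeded row-subsampled sum is available
(off by default). Greedy selection evaluates candidate subsets with
plain Euclidean distance over the selected columns (optional per-feature
standardization, since the original features may carry mixed units);
constant features are skipped with a warning; the Δ trace is reported
as measured — it typically falls to a plateau but is not guaranteed
monotone.

## Synthetic benchmarks

Generators are pure functions of (parameters, seed); their truth fields
(labels, dimension, log-density) are consumed only by tests.

The Möbius benchmark draws (u, v) from an 8-mode Gaussian mixture on a
strip (modes at u = (2k+1)π/8, v = ±0.18 alternating, σ_u = 0.12,
σ_v = 0.06: the closest pair of modes is > 7σ apart, so the generative
clusters are unambiguous), maps them through the standard Möbius
embedding of mid-circle radius 1, rotates the 3D result into 50
dimensions with a seeded orthogonal matrix, and adds isotropic Gaussian
noise. The default `noise_sigma` = 2×10⁻⁴ per coordinate (total RMS
displacement ≈ 0.0014, ~0.14% of the strip width) was chosen by a
geometric argument: with 10⁴ points the typical first-neighbor spacing
inside a mode is ~3×10⁻³, and the pairwise noise norm (~10·noise_sigma
across 50 coordinates) must stay below the neighbor spacings at the
probed scales for the manifold to remain two-dimensional to the
estimators; much larger noise genuinely changes the short-scale
dimension of the data rather than merely perturbing it. The visible
remnant of the noise is the mild ID inflation of the shortest-scale
Gride point (2.66 at n₁ = 1 in the worked example).

What passing these benchmarks shows: the full pipeline reads the
correct ID through a twist and a 50D embedding, and the significance
merging prunes spurious density maxima down to exactly the generative
modes. What it does not show: behavior under heavy-tailed noise,
strongly unbalanced cluster populations, densities without clear modes,
or real measurement noise structure (correlated, non-Gaussian) — real
datasets should always be inspected through the scan profiles and the
dendrogram rather than trusted to defaults.

## Problem sizes

The shipped tests and the acceptance script run at the sizes stated in
their sources — Möbius at N = 10⁴ (maxk 100), recovery suites at
N = 10³–10⁴, exhaustive oracles at N ≤ 300 — sizes at which the
brute-force O(N²) oracles are exact and cheap while the statistical
claims (±3 SE bands, 5% density bands) have comfortable power.
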