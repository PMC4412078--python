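# Methods

## The entropy-rate model

Each sample's transcriptome is mapped onto a fixed, undirected, connected
interaction network by the mass-action principle: the probability that
protein *i* signals to its neighbour *j* is taken proportional to the
product of their expression values, giving the row-stochastic matrix
`p_ij = A_ij E_j / x_T,i` with `x_T,i = Σ_j A_ij E_j`. Three facts drive
everything else in the package:

1. **Detailed balance.** `π_i p_ij = π_j p_ji` holds identically for this
   family, so the stationary distribution has the closed form
   `π_i = E_i x_T,i / F`, `F = Σ_k E_k x_T,k`. No eigensolve is needed for
   π; the dominant-left-eigenvector route is kept only as a test oracle.
2. **Degree-bounded local entropies.** `LS_i = −Σ_j p_ij log p_ij ≤ log k_i`,
   with equality at uniform expression. The entropy rate
   `SR = Σ_i π_i LS_i` therefore mixes a topology term (log-degrees) with an
   expression-placement term (π).
3. **A topological ceiling.** Over all stochastic matrices supported on the
   network, SR is maximised at `log λ` (λ the dominant adjacency
   eigenvalue), attained by `p_ij = A_ij v_j/(λ v_i)`. The uniform-expression
   state maximises every *local* entropy but not the *global* rate, which is
   what allows single-node perturbations to push SR in either direction.

Entropies are reported in nats; the CLI's `--log2` flag divides by log 2.
Scale invariance (`E → cE` leaves everything unchanged) is exact in the
algebra and asserted to 1e-12 in tests.

## Analytic perturbations

Perturbation experiments start from the uniform configuration `x_i = x` and
change one node *u* by `Δx`. Only local quantities move:
`x'_T,i = k_i x + A_iu Δx`, `π'_i ∝ x'_i x'_T,i`, and the local entropies of
*u*'s neighbours become the two-valued distributions
`p'_{i,u} = (x+Δx)/(k_i x+Δx)`, `p'_{ij} = x/(k_i x+Δx)`; all other LS stay
`log k_i` (including *u*'s own). `SR′` follows in O(V) per node, which makes
whole-network sweeps cheap. The module's primary correctness guarantee is
oracle equivalence: the closed form agrees with brute-force recomputation of
the full entropy state on the modified profile to better than 1e-10 for every
node of a 20-graph ER/BA panel.

Default regimes mirror a log2 microarray scale, where high expression sits
above 12 and low expression below 4: activating perturbations drive a low
baseline `x = 2` up by `Δx = +12` (to 14); inactivating ones drive a high
baseline `x = 16` down by `Δx = −14` (to 2). Both are configurable; the
qualitative sign structure (below) is insensitive to the exact magnitudes as
long as the perturbation is strong enough to dominate its neighbourhood.

The package's central topology result, checked on 5-seed panels at V = 500,
⟨k⟩ = 8: on Erdős–Rényi graphs every activating perturbation *lowers* SR; on
Barabási–Albert graphs the top hub responds bi-modally (activation raises
SR, inactivation lowers it) while attachment-floor nodes always lose.

## Graph generators and diagnostics

- ER graphs are `G(V, M)` with `M = round(V⟨k⟩/2)` so mean degree is matched
  exactly; the largest connected component is returned, redrawing up to 20
  times when it holds under 90% of nodes. The precondition admits
  `⟨k⟩ = V−1` (the complete graph).
- Scale-free graphs are Barabási–Albert with `m = round(⟨k⟩/2)`; connected
  by construction with exactly `m(V−m)` edges.
- Degree-matched rewiring is a double-edge-swap chain that skips (and
  counts) swaps creating self- or multi-edges. Note that BA graphs are
  already at configuration-model clustering levels, so rewiring changes
  their clustering only within noise; the erosion of clustering under
  rewiring is demonstrated on genuinely clustered (powerlaw-cluster) graphs.
- The power-law diagnostic is a least-squares slope on a log-binned log-log
  degree histogram, plus an optional closed-form discrete Hill/MLE exponent
  whose `kmin` defaults to the smallest observed degree. Both are
  diagnostics, not inference: the claim they support is "approximately
  scale-free", nothing sharper. On BA(2000, m=3) the slope lands in
  [−3.5, −2] and the MLE near 2.6.

Generated nodes are named `n0001…` in creation order; all node orderings are
lexicographic, and every generator takes one explicit integer seed.

## Cohort analyses

`CohortEntropy(network, cohort).fit()` computes per-sample SR, the
one-tailed Wilcoxon rank-sum test (alternative: group B = "cancer" has
higher SR) with its Mann-Whitney-equivalent AUC `U/(n_A n_B)`, and per-gene
group-mean differentials of expression, local entropy, stationary mass and
local entropy rate (`dE, dLS, dpi, dLSR`). `Σ dpi = 0` identically.
Supporting statistics:

- **Hub skew**: two-sample KS comparing `dE` of hubs (degree > 316, a cut at
  `10^2.5` that falls on the log10 degree-bin grid) against degree-1 nodes;
  the threshold falls back to the top-decile degree with a warning when a
  stratum is empty (as on any desk-scale graph).
- **Degree correlation**: Spearman ρ between `dE` and degree.
- **Neighbour centile**: for each neighbour *j* of a chosen hub, rank *j*'s
  neighbours by `dE` and record the hub's centile. Feasibility caveat: rank
  1 in a degree-m neighbourhood is centile `1/m`, so tight centile cuts are
  only meaningful when neighbourhoods are large (in desk-scale tests the cut
  is set above `1/m`).
- **Top-k fold-change**: genes ranked by `|dE|` (the data are log-like, so
  mean difference is log fold-change); ties, including the all-zero case,
  fall back to gene-id order. Feeding these through `perturb_profile` from
  the mean group-A profile reproduces the qualitative pattern that SR gains
  concentrate on high-degree over-expressed genes.
- **Permutation control**: one node-relabelling permutation per seed applied
  to every sample. Sharing the permutation across samples preserves
  inter-sample structure while destroying expression placement; the
  per-sample alternative (flag `shared=False`) would also destroy the
  gene-wise group differences and is not the default.

## The ER topology control

`er_control_experiment` re-evaluates a cohort on an ER graph matched in size
and mean degree. Expression is transported by pairing nodes of the two
networks in (degree, node-id) rank order — a monotone bijection, so every
rank correlation between an expression statistic and degree is preserved by
construction; only the degree distribution's shape changes. Size
reconciliation prefers redrawing the ER graph (up to 20 seeds) until its
component spans all V nodes; truncating the source's lowest-degree nodes is
a loudly-logged fallback. The AUC direction is fixed (higher SR ⇒ group B),
not auto-oriented.

## The synthetic cohort generator

The generator emulates the statistical structure the cohort analyses assume,
on a log2-microarray-like scale:

| parameter | default | meaning |
|---|---|---|
| V, mean_degree, topology | 2000, 8, BA | network size/class |
| n_A, n_B | 50, 50 | samples per group |
| baseline_mean, baseline_sd | 8, 2 | per-gene baseline, clipped to [2, 16] |
| rho_target | 0.3 | Spearman(shift, degree) |
| effect_sd | 1.0 | scale of the per-gene group-B shift |
| noise_sd | 0.5 | i.i.d. per-gene, per-sample noise |
| effect_het | 0.5 | sd of the per-sample shift multiplier (group B) |
| coupling_sd | 0.3 | sd of the per-sample degree-coupled component |

The group-B shift is a Gaussian copula mixture `a·z_k + √(1−a²)·ε` of
normal-scored degree ranks and independent noise, with `a` solved by
bisection on the realised (draw-conditional) Spearman correlation so the
target is hit within ±0.05; because the degree-rank component shares the
degree tie pattern, even extreme targets are reachable. Hubs are thereby
up-shifted in the "cancer" group and low-degree nodes down-shifted — the
planted version of the degree–differential-expression correlation.

The two sample-level terms are what make the fixture behave like a cohort
rather than a noiseless average: a per-sample multiplier on the shift
(tumour heterogeneity) and a per-sample degree-coupled component in both
groups. With only i.i.d. gene noise, per-sample SR would be nearly
deterministic (noise averages out across thousands of genes) and any
systematic shift would yield AUC = 1.0 on *any* topology, erasing the
scale-free-vs-ER contrast the generator exists to exercise. With the
defaults, the fixture gives AUC ≈ 0.74 on its BA network and ≈ 0.65 on
degree-rank-matched ER controls — reduced but not abolished, matching the
mixed picture real datasets show.

What the generator does **not** emulate: count-based noise models
(negative-binomial mean–variance coupling, library-size effects), batch
effects, correlated gene modules beyond the degree coupling, and any
PPI-specific wiring beyond the BA/ER topology classes. Passing fixture tests
therefore demonstrates the machinery and the topology-dependence of the
entropy rate, not performance on real RNA-seq data.

## Numerical choices and degenerate inputs

- π via the detailed-balance closed form everywhere; eigensolvers appear
  only in `max_entropy_rate` (dense `eigh` for V ≤ 400, ARPACK `eigsh`
  with tol 1e-12 / 10⁴ iterations above) and in test oracles.
- `0 log 0 := 0`; transition probabilities below 1e-300 contribute zero
  entropy.
- Expression must be strictly positive; offending nodes are named in the
  error. An opt-in pseudocount (default 1.0 when enabled) handles matrices
  with zeros.
- Genes absent from the network (or vice versa) are intersected away and the
  largest connected component of the intersection is used.
- All rankings break ties lexicographically by node id; sweep outputs are
  sorted by (degree, node). Floats are written at 12 significant digits, so
  identical configurations produce byte-identical files.
- Problem sizes in tests and the acceptance script (V = 60–100 oracle
  panels, V = 500 sweeps, V = 2000 cohorts) were chosen as the smallest
  sizes at which each qualitative phenomenon is stable across seeds.

## Known limitations

- The entropy rate is defined on the largest connected component only;
  disconnected inputs are silently reduced to it (with a log line), which
  changes V.
- `perturb_node_analytic` is exact only from the uniform baseline;
  `perturb_profile` recomputes the full state for arbitrary baselines
  (exactness over speed — fine at desk scale, O(V·E) for whole-profile
  sweeps).
- The hub threshold 316 is meaningful for PPI-scale networks (~10⁴ nodes);
  desk-scale fixtures always trigger the top-decile fallback.
- The power-law exponent estimates are diagnostics; no goodness-of-fit test
  is attempted.
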