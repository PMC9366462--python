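# Methods

## Model

Amino-acid substitution is a stationary, time-homogeneous continuous-time
Markov chain on the 20 amino acids (fixed PAML order
`A R N D C Q E G H I L K M F P S T W Y V`, used by every file format and
in-memory index in the package). A model is a rate matrix `Q` with
non-negative off-diagonals and zero row sums, together with its stationary
distribution `π` (`πQ = 0`). Matrices are normalized by
`μ = −Σ_x π_x q_xx` so one time unit equals one expected substitution per
site; the Pearson correlation used for convergence and reporting is
computed over the 380 off-diagonal entries (the diagonal is determined by
them) and is invariant to this scale.

Reversible models are built from symmetric exchangeabilities,
`q_xy = π_y r_xy`, and satisfy detailed balance; they have
190 − 1 (scale) + 19 (frequencies) = 208 free parameters. General
(nonreversible) models have 380 − 1 = 379. Under a reversible model the
likelihood of a rooted tree is invariant to root placement (pulley
principle); under a nonreversible model it is not, which is what makes
the root estimable. Stationarity is assumed throughout: root state
frequencies equal `π(Q)`; non-stationary processes are out of scope.

## Transition probabilities

`P(t) = exp(Qt)` via complex eigendecomposition (`Q = UΛU⁻¹`, cached per
matrix). The decomposition is declared unusable when the eigenvector
condition number exceeds 1e12 or the reconstruction residual exceeds
1e-6; then a second-order Taylor expansion with scaling and squaring is
used. The scaled norm target is 5e-4: the accumulated truncation error of
the second-order expansion is ≈ `‖Qt‖·θ²/6`, so θ = 5e-4 keeps the
fallback within 1e-6 of the eigen path (a coarser θ = 0.1 would only give
~1e-3 and would violate the agreement contract between the two paths).
Round-off negatives/imaginaries in `P(t)` are clamped/dropped and rows
renormalized; magnitudes above 1e-6 raise instead, since they indicate a
genuine failure.

## Site-rate models

Discrete gamma uses equal-weight quantile bins with **bin means** (the
incomplete-gamma partial-expectation identity), matching the common
default in ML phylogenetics; bin means make the discretized mean exactly
1 but converge to the continuous variance only like ~1/c (the deficit is
still ~4% at c = 64 for shape 0.3). +I adds a zero-rate category and
rescales the rest; +R stores arbitrary (sorted) rates and weights. Every
model is renormalized to mean rate exactly 1 so branch lengths keep their
units. The default candidate set for per-locus selection is
{uniform, +G4, +I, +I+G4, +R2, +R3, +R4}.

## Likelihood

Felsenstein pruning on rooted trees with `P(t)` applied
ancestor→descendant (rows index the ancestral state) and `π` at the root.
Site patterns are compressed; per-node, per-pattern log-scalers prevent
underflow on large trees. Gaps and `? X * . ~` are missing data
(all-ones partials); `B`, `Z`, `J` are two-state ambiguities.

The same forward/backward machinery yields, per edge and rate category,
the posterior weight matrix `W_ab = Σ_p c_p f_a(p) b_b(p)` — the gradient
of the total log-likelihood with respect to that edge's transition-matrix
entries. From `W` follow both the analytic branch-length gradient
(`dlogL/dt = Σ_c r_c ⟨W, Q P⟩`) and the expected sufficient statistics
for matrix estimation.

## Estimation

**Branch lengths.** All branch lengths of a tree (the two root-adjacent
edges included as separate free parameters, so the root slides along its
branch) are optimized jointly by bounded L-BFGS-B in log space with the
analytic gradient, bounds [1e-8, 100]. One gradient evaluation costs two
tree passes, so joint optimization replaces the classical per-branch
Brent sweeps at a fraction of the cost; the result is kept only if it
does not decrease the likelihood, preserving monotonicity of the outer
loop.

**Rate matrix.** With trees, branch lengths and rate models fixed, the
joint `Q` over all loci is estimated by the expected-sufficient-statistics
(EM) update for continuous-time Markov chains: for each edge of elapsed
time `s`, the contraction `A = Uiᵀ((UᵀWUiᵀ)∘J)Uᵀ` with the
divided-difference kernel `J_kl = (e^{λ_k s} − e^{λ_l s})/(λ_k − λ_l)`
gives expected dwell times (`A_xx`) and expected transition counts
(`q_xy A_xy`); the M-step is `q_xy ← E[N_xy]/E[T_x]`. (A block
matrix-exponential computes the same integral when `Q` is not
diagonalizable.) Because the root distribution is tied to `π(Q)`, the
plain EM step is not exactly ascent-guaranteed; a backtracking line
search in log-rate space toward the previous matrix enforces monotone
ascent, and a failed backtrack is treated as numerical convergence. A
quasi-Newton optimizer with numerical gradients over 379 parameters (760
likelihood evaluations per gradient) was rejected as infeasible at the
tested scales; the EM converges in ~20–40 iterations. The matrix is kept
unnormalized during the iteration (its scale is pinned by the fixed
branch lengths); on exit it is normalized and all branch lengths are
multiplied by `μ`, which leaves every likelihood bit-identical and avoids
the flat scale direction entirely.

**Outer loop.** Step 2 assigns each locus the minimum-BIC
(matrix, rate model) pair — scored on a fixed starting tree with only the
rate-model parameters and a tree-scale multiplier optimized — then
estimates the locus tree under the winner (branch lengths, optional NNI,
exhaustive root-edge scan when the matrix is nonreversible). Step 3
alternates matrix EM and branch-length optimization until the joint
log-likelihood gain per cycle is ≤ 0.1. Step 4 compares the previous
iteration's best matrix with the new estimate; correlation ≥ 0.999 stops,
otherwise the new matrix joins the candidate set (counting its 379
parameters in subsequent BIC comparisons, since it was estimated from the
data at hand; published matrices count zero matrix parameters, branch
lengths and rate-model parameters always count, and the BIC sample size
is the number of alignment columns).

Topology search is deliberately modest: neighbor-joining on
Poisson-corrected (20-state) distances as the start, followed by greedy
NNI hill climbing that scores neighbors at current branch lengths and
re-optimizes lengths after each accepted swap. Full tree-search
heuristics of production ML software are out of scope. In edge-linked
mode all loci share one topology and branch-length vector, with per-locus
rate multipliers (first locus pinned to 1 as the gauge).

## Rooting

`find_ml_root` places the root on every branch in turn, optimizing only
the two root-adjacent lengths (directional messages for both orientations
of every edge are precomputed once, so each candidate evaluation is a
pair of 20×20 matrix products per category). Reversible models are
rejected — the root is unidentifiable. Rootstrap support is the fraction
of nonparametric site-bootstrap replicates (multinomial resampling of
pattern multiplicities; topology and non-root branch lengths fixed) whose
ML root lands on a branch; the messages are multiplicity-independent and
reused across replicates, making 100 replicates cheap. Supports over all
branches sum to 1 by construction. The report includes each branch's
ΔlogL from the ML branch for users who want likelihood-based confidence
sets; the AU test is out of scope.

## Simulator

The generator draws root states from `π`, assigns each site a rate
category, and walks the tree sampling from `P(rate·t)` per branch. Random
matrices start from log-normal exchangeabilities (σ = 1) and
Dirichlet(5) frequencies — mildly uneven, like empirical amino-acid
profiles — and multiply each off-diagonal by an independent log-normal
factor whose log-sd is the `asymmetry` parameter. `asymmetry = 1` (the
"strong nonreversibility" setting used in the recovery and rooting
fixtures) makes typical forward/backward rate ratios differ ~4-fold;
`asymmetry = 0` returns an exactly reversible model. Random rooted trees
are uniform over labeled rooted topologies (stepwise addition with a
uniform edge choice including a virtual edge above the root) with
exponential branch lengths, mean 0.1 substitutions/site — typical for
single-gene protein trees.

What the simulator does **not** emulate: indels and alignment error,
compositional heterogeneity across lineages or sites,
mixture-of-matrices processes, and data-curation artifacts of real
databases. Green recovery tests therefore establish correctness of the
estimator under its own model assumptions, not robustness to their
violation.

## Scaled-down validation choices

The headline validations run on simulated data sized to a single CPU:
matrix recovery uses 16 taxa × 50,000 sites with single-category rates
(the generating process has none, so the rate-model search is switched
off via configuration) and no NNI (the NJ start recovers the topology at
this sample size); root recovery uses 8 taxa × 20,000 sites with 100
bootstrap replicates. Convergence thresholds (0.1 logL, 0.999
correlation) and acceptance bars (correlation ≥ 0.95 with the generating
matrix, rootstrap ≥ 0.95 on the true edge) are fixed a priori.

## Known limitations

- Per-locus rate-model parameters are frozen within step 3 and refreshed
  each outer iteration (re-optimizing them inside the alternation would
  be straightforward but slow).
- NNI hill climbing scores candidate swaps at current branch lengths, so
  it can miss rearrangements that only pay off after length
  re-optimization.
- The EM treats the root-frequency coupling approximately (see above);
  the backtracking safeguard makes this safe but can slow the last few
  iterations.
- BIC parameter counting follows the fixed-vs-estimated matrix
  convention; users comparing externally estimated matrices should count
  parameters consistently with how those matrices were obtained.
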