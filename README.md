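# nonrev

Maximum-likelihood estimation of **time-nonreversible amino-acid
substitution models** and **rooted phylogenies** from collections of
protein alignments.

Almost all amino-acid substitution matrices in routine use (LG, WAG, JTT,
…) are time-reversible: the exchange rate between amino acids `x` and `y`
is assumed equal in both directions. That assumption is computational
convenience, not biology — and it makes the likelihood of a tree
independent of where the root is placed (the *pulley principle*), so
reversible models cannot root trees without an outgroup. `nonrev` drops
the symmetry constraint: a general 20-state rate matrix `Q` with all 380
off-diagonal rates free (379 after normalization, versus 208 for a
reversible model) is estimated jointly from many alignments on rooted
maximum-likelihood trees, and the position of the root itself becomes an
estimable model parameter with bootstrap ("rootstrap") support.

## The model

Substitution follows a stationary, time-homogeneous Markov process with
instantaneous rate matrix `Q = {q_xy}` (rows sum to zero), normalized so
that `−Σ_x π_x q_xx = 1` — branch lengths are then expected substitutions
per site. Transition probabilities are `P(t) = exp(Qt)`, computed through
the complex eigendecomposition `Q = U Λ U⁻¹` with a scaling-and-squaring
fallback for defective matrices. Site likelihoods are computed by the
pruning algorithm on rooted trees, with the stationary distribution at
the root; among-site rate variation uses discrete-gamma (+G), invariant
sites (+I), or free-rate (+R) categories.

Estimation alternates four steps until the matrix stabilizes:

1. start from a candidate set (LG, WAG, JTT);
2. per locus, pick the best (matrix, rate model) by BIC and estimate its
   (rooted, if nonreversible) tree;
3. with trees fixed, alternate re-estimating the joint `Q` (an
   expected-counts EM update over all edges and loci, monotone in the
   likelihood) and re-optimizing branch lengths, until the joint
   log-likelihood gain drops to 0.1;
4. stop when the Pearson correlation between successive estimates of the
   off-diagonal rates reaches 0.999; otherwise add the new matrix to the
   candidate set and repeat.

Departure from reversibility is summarized by the **net flux**
`|π_i q_ij − π_j q_ji|` per amino-acid pair — identically zero exactly
when the model is reversible.

## Worked example

Estimate a matrix from three simulated loci and compare with the truth:

```python
import nonrev as nv
from nonrev.estimation import EstimationConfig, nqmaker_estimate

truth = nv.random_nonreversible_matrix(seed=7, asymmetry=1.0)
trees = [nv.random_rooted_tree(8, seed=100 + i) for i in range(3)]
loci = [nv.simulate_alignment(truth, nv.UNIFORM_RATES, t, 3000, seed=200 + i,
                              name=f"locus{i}") for i, t in enumerate(trees)]

cfg = EstimationConfig(rate_model_names=("",), nni=False)
estimate, state = nqmaker_estimate(loci, config=cfg)

print(f"outer iterations: {state.iteration}  converged: {state.converged}")
for rec in state.history:
    print(f"  iter {rec['iteration']}: logL = {rec['log_likelihood']:.1f}, "
          f"correlation with previous = {rec['correlation']:.4f}")
print(f"correlation with generating matrix: "
      f"{nv.matrix_correlation(estimate, truth):.4f}")
```

prints

```
outer iterations: 3  converged: True
  iter 1: logL = -92585.9, correlation with previous = 0.0454
  iter 2: logL = -92269.4, correlation with previous = 0.9964
  iter 3: logL = -92269.1, correlation with previous = 1.0000
correlation with generating matrix: 0.9891
```

The loop stabilized after three outer iterations (the first correlation
compares the estimate against the LG starting matrix, hence near zero),
and the estimated off-diagonal rates correlate at 0.989 with the matrix
that generated the data — 9,000 sites is already enough to pin down most
of the 379 parameters. The strongest detailed-balance violations:

```python
from nonrev.matrix_analytics import flux_table
print(flux_table(estimate).head(3).to_string(index=False))
```

```
pair  flux_ij  flux_ji  net_flux  normalized_net_flux
  CW 0.035902 0.004420  0.031481             1.561500
  RG 0.013803 0.037305  0.023502             0.919719
  GM 0.001631 0.021514  0.019883             1.718091
```

e.g. the C→W flux is eight times the W→C flux — a pair a reversible model
would force into balance (normalized net flux ranges over [0, 2), with 0
meaning detailed balance).

Rooting a tree under a nonreversible model:

```python
report = nv.rootstrap(truth, nv.UNIFORM_RATES, tree, alignment,
                      n_replicates=100, seed=1)
print(report.ml_edge, report.per_edge[report.ml_edge]["rootstrap"])
```

The same functionality is available from the shell: `nonrev estimate -S
ALN_DIR` (independent trees per locus) or `-p ALN_DIR` (one edge-linked
topology), `nonrev root ALN TREE --model MATRIX`, and `nonrev simulate`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, a full simulate-then-estimate cycle (three
10-taxon loci of 4,000 sites; correlation of the recovered matrix with
the generating one) and a root-placement run with 50 bootstrap
replicates on 10,000 sites, printing the summary and writing the results
file.
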