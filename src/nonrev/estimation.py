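"""Iterative joint estimation of a substitution matrix from many alignments.

The estimator alternates four steps until the matrix stabilizes:

1. start from a candidate set of published matrices (LG, WAG, JTT);
2. for every locus pick the best-fitting (matrix, site-rate model) pair by
   BIC and estimate a tree for it (rooted when the matrix is nonreversible);
3. with trees fixed, alternate (a) re-estimating the joint rate matrix over
   all loci and (b) re-optimizing branch lengths, until the log-likelihood
   gain per cycle drops to 0.1;
4. stop when the Pearson correlation between successive matrix estimates
   reaches 0.999, otherwise add the new matrix to the candidate set and
   return to step 2.

The rate-matrix M-step uses the expected-sufficient-statistics (EM) update
for continuous-time Markov chains — expected transition counts divided by
expected state dwell times, accumulated over all edges and loci — with a
backtracking safeguard that guarantees monotone log-likelihood ascent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt
from scipy.linalg import expm as _dense_expm

from .likelihood import Alignment, PartitionedData, TreeLikelihood
from .model_selection import ModelFit, select_best
from .rate_heterogeneity import (DEFAULT_RATE_MODEL_NAMES, SiteRateModel,
                                 UNIFORM_RATES, discretize_gamma, free_rate,
                                 with_invariant)
from .rooting import find_ml_root
from .substitution_model import (RateMatrix, free_parameter_count,
                                 load_builtin, matrix_correlation, normalize,
                                 stationary_distribution)
from .trees import PhyloTree, parse_newick

__all__ = [
    "EstimationConfig",
    "EstimationState",
    "LocusAssignment",
    "assign_best_models",
    "optimize_branch_lengths",
    "optimize_q_nonreversible",
    "nqmaker_estimate",
    "neighbor_joining_tree",
    "estimate_tree",
]

_LENGTH_BOUNDS = (1e-8, 100.0)


# ---------------------------------------------------------------------------
# Configuration and state
# ---------------------------------------------------------------------------

@dataclass
class EstimationConfig:
    """Thresholds and modes of the estimation loop.

    ``logl_epsilon`` — minimum log-likelihood gain to continue the inner
    matrix/branch-length alternation (0.1).  ``corr_threshold`` — Pearson
    correlation between successive matrices at which the outer loop stops
    (0.999).  ``mode`` — ``"independent"`` (a tree per locus) or
    ``"edge-linked"`` (one shared topology, per-locus rate multipliers).
    """

    logl_epsilon: float = 0.1
    corr_threshold: float = 0.999
    max_outer_iterations: int = 10
    rate_model_names: tuple = DEFAULT_RATE_MODEL_NAMES
    mode: str = "independent"
    topology: PhyloTree | None = None
    nni: bool = True
    seed: int = 0
    em_max_iter: int = 100
    em_tol: float = 0.05
    bl_max_iter: int = 100

    @classmethod
    def from_file(cls, path) -> "EstimationConfig":
        """Read a ``key = value`` text config; unknown keys are rejected."""
        kwargs = {}
        for line in open(path):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "rate_models":
                kwargs["rate_model_names"] = tuple(v.strip() for v in value.split(","))
            elif key in ("logl_epsilon", "corr_threshold", "em_tol"):
                kwargs[key] = float(value)
            elif key in ("max_outer_iterations", "seed", "em_max_iter",
                         "bl_max_iter"):
                kwargs[key] = int(value)
            elif key == "mode":
                kwargs[key] = value
            elif key == "nni":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class LocusAssignment:
    """Step-2 result for one locus: chosen matrix and rate model, the tree
    estimated under them, and the per-candidate fits."""

    matrix: RateMatrix
    rate_model: SiteRateModel
    tree: PhyloTree
    log_likelihood: float
    fits: list = field(default_factory=list)


@dataclass
class EstimationState:
    """Evolving state of the estimation loop (step logs included)."""

    candidates: list
    best_matrix: RateMatrix
    per_locus: dict = field(default_factory=dict)
    iteration: int = 0
    converged: bool = False
    history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Branch lengths
# ---------------------------------------------------------------------------

def _optimize_engine_lengths(engine: TreeLikelihood, max_iter: int = 100,
                             weights=None) -> float:
    """Joint bounded quasi-Newton over all log branch lengths with the
    analytic gradient; returns the (non-decreased) log-likelihood."""
    lo, hi = np.log(_LENGTH_BOUNDS[0]), np.log(_LENGTH_BOUNDS[1])
    x0 = np.log(np.clip(engine.get_lengths(), *_LENGTH_BOUNDS))

    def neg(x):
        engine.set_lengths(np.exp(x))
        logl, grad = engine.branch_gradient(weights)
        return -logl, -grad * np.exp(x)

    f0 = neg(x0)[0]
    res = sciopt.minimize(neg, x0, jac=True, method="L-BFGS-B",
                          bounds=[(lo, hi)] * x0.size,
                          options={"maxiter": max_iter, "ftol": 1e-12})
    if res.fun <= f0:
        engine.set_lengths(np.exp(res.x))
        final = -res.fun
    else:  # optimizer failed to improve; keep the starting point
        engine.set_lengths(np.exp(x0))
        final = -f0
    engine.sync_tree()
    return final


def _optimize_shared_lengths(engines, max_iter: int = 100) -> float:
    """Edge-linked mode: one shared branch-length vector across loci (each
    engine applying its own scale), then per-locus scale refinement."""
    lo, hi = np.log(_LENGTH_BOUNDS[0]), np.log(_LENGTH_BOUNDS[1])
    x0 = np.log(np.clip(engines[0].get_lengths(), *_LENGTH_BOUNDS))

    def neg(x):
        t = np.exp(x)
        total, grad = 0.0, np.zeros_like(t)
        for e in engines:
            e.set_lengths(t)
            logl, g = e.branch_gradient()
            total += logl
            grad += g
        return -total, -grad * t

    f0 = neg(x0)[0]
    res = sciopt.minimize(neg, x0, jac=True, method="L-BFGS-B",
                          bounds=[(lo, hi)] * x0.size,
                          options={"maxiter": max_iter, "ftol": 1e-12})
    x_best = res.x if res.fun <= f0 else x0
    for e in engines:
        e.set_lengths(np.exp(x_best))
    # per-locus rate multipliers (first locus pinned to 1 as the gauge)
    for e in engines[1:]:
        s0 = e.scale
        l0 = e.log_likelihood()

        def neg_scale(s, e=e):
            e.set_scale(float(np.exp(s)))
            return -e.log_likelihood()

        r = sciopt.minimize_scalar(neg_scale, bounds=(-3, 3),
                                   method="bounded", options={"xatol": 1e-3})
        if -r.fun >= l0:
            e.set_scale(float(np.exp(r.x)))
        else:
            e.set_scale(s0)
    engines[0].sync_tree()
    return _joint_logl(engines)


def optimize_branch_lengths(model: RateMatrix, rate_model: SiteRateModel,
                            tree: PhyloTree, alignment: Alignment,
                            max_iter: int = 100) -> tuple[PhyloTree, float]:
    """Optimize all branch lengths of a rooted tree; returns (tree, logL).

    The two root-adjacent edges are free parameters like any other edge, so
    under a nonreversible model the root slides along its branch implicitly.
    """
    tree = tree.copy()
    engine = TreeLikelihood(model, rate_model, tree, alignment)
    logl = _optimize_engine_lengths(engine, max_iter=max_iter)
    return tree, logl


# ---------------------------------------------------------------------------
# Rate-matrix estimation (EM)
# ---------------------------------------------------------------------------

def _edge_expectations(model: RateMatrix, stats: dict, rate_model: SiteRateModel,
                       lengths: np.ndarray, scale: float):
    """Expected dwell times T_x and transition counts N_xy from per-edge
    posterior weight matrices.

    For each edge with elapsed time ``s`` the contraction
    ``A = Ui^T ((U^T W Ui^T) o J) U^T`` (J the divided-difference kernel of
    the eigenvalues) yields ``A_xx`` = expected time in x and
    ``q_xy A_xy`` = expected number of x->y transitions.
    """
    es = model.eigensystem()
    q = model.rates
    n = model.n_states
    T = np.zeros(n)
    N = np.zeros((n, n))
    for (edge, cat), w in stats.items():
        s = lengths[edge] * rate_model.category_rates[cat] * scale
        if s <= 0 or not np.any(w):
            continue
        if es.is_valid:
            lam = es.eigenvalues
            e = np.exp(lam * s)
            diff = lam[:, None] - lam[None, :]
            num = e[:, None] - e[None, :]
            small = np.abs(diff) < 1e-9
            J = np.where(small, s * np.exp((lam[:, None] + lam[None, :]) * s / 2),
                         num / np.where(small, 1.0, diff))
            m = (es.right_vectors.T @ w @ es.inverse_vectors.T) * J
            a = (es.inverse_vectors.T @ m @ es.right_vectors.T).real
        else:  # defective Q: block matrix exponential for the integral
            big = np.zeros((2 * n, 2 * n))
            big[:n, :n] = q.T * s
            big[:n, n:] = w
            big[n:, n:] = q.T * s
            a = _dense_expm(big)[:n, n:] * s
        T += np.maximum(np.diag(a), 0.0)
        off = ~np.eye(n, dtype=bool)
        contrib = np.where(off, q * a, 0.0)
        N += np.maximum(contrib, 0.0)
    return T, N


def _joint_logl(engines) -> float:
    return sum(e.log_likelihood() for e in engines)


def optimize_q_nonreversible(engines, start: RateMatrix, max_iter: int = 100,
                             tol: float = 0.05):
    """EM estimation of a joint (nonreversible) rate matrix over loci.

    ``engines`` hold fixed trees, branch lengths, and site-rate models; the
    matrix maximizing the summed log-likelihood is sought by iterating the
    expected-counts update ``q_xy <- E[N_xy] / E[T_x]``, backtracking in
    log-rate space whenever a step would decrease the likelihood.  On exit
    the matrix is normalized and every engine's branch lengths are rescaled
    by the same factor, leaving all likelihoods unchanged.

    Returns ``(model, info)`` with an iteration log in
    ``info["history"]``; ``info["converged"]`` is False when the
    iteration cap was hit first.
    """
    current = RateMatrix(start.rates, start.frequencies, name="Q.em")
    for e in engines:
        e.set_model(current)
    logl = _joint_logl(engines)
    history = [logl]
    converged = False
    for _ in range(max_iter):
        T = np.zeros(current.n_states)
        N = np.zeros_like(current.rates)
        for e in engines:
            _, stats = e.edge_statistics()
            t_part, n_part = _edge_expectations(
                current, stats, e.rate_model, e.get_lengths(), e.scale)
            T += t_part
            N += n_part
        T = np.maximum(T, 1e-12)
        q_new = N / T[:, None]
        np.fill_diagonal(q_new, 0.0)
        q_new = np.maximum(q_new, 1e-10)  # keep the chain irreducible
        np.fill_diagonal(q_new, 0.0)

        # backtracking ascent safeguard (the plain EM step is not exact here
        # because the root distribution is tied to the stationary
        # distribution of Q, which the M-step ignores)
        step = 1.0
        accepted = None
        for _try in range(6):
            off = ~np.eye(current.n_states, dtype=bool)
            q_try = current.rates.copy()
            q_try[off] = np.exp((1 - step) * np.log(np.maximum(current.rates[off], 1e-300))
                                + step * np.log(q_new[off]))
            np.fill_diagonal(q_try, 0.0)
            np.fill_diagonal(q_try, -q_try.sum(axis=1))
            cand = RateMatrix(q_try, stationary_distribution(q_try), name="Q.em")
            for e in engines:
                e.set_model(cand)
            cand_logl = _joint_logl(engines)
            if cand_logl >= logl - 1e-9:
                accepted = (cand, cand_logl)
                break
            step *= 0.5
        if accepted is None:
            # no step in this direction improves the likelihood: the
            # current matrix is (numerically) a fixed point
            for e in engines:
                e.set_model(current)
            converged = True
            break
        gain = accepted[1] - logl
        current, logl = accepted
        history.append(logl)
        if gain < tol:
            converged = True
            break
    # normalize; rescale branch lengths so that likelihood is preserved
    mu = current.mean_rate
    final = normalize(current.rates, frequencies=current.frequencies,
                      name="Q.new")
    for e in engines:
        e.set_model(final)
        e.set_lengths(e.get_lengths() * mu)
        e.sync_tree()
    return final, {"history": history, "converged": converged,
                   "log_likelihood": logl}


# ---------------------------------------------------------------------------
# Starting trees and topology search
# ---------------------------------------------------------------------------

def neighbor_joining_tree(alignment: Alignment, root_split: float = 0.5) -> PhyloTree:
    """Rooted starting tree: NJ on gamma-free corrected protein distances.

    Pairwise distances are Poisson-corrected p-distances with 20 states,
    ``d = -(19/20) ln(1 - (20/19) p)`` (capped at 5 substitutions per
    site); the NJ tree is then rooted on its first edge — the root is
    provisional and is revisited whenever a nonreversible model is in play.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    taxa = alignment.taxa
    n = len(taxa)
    if n < 3:
        tree = parse_newick(f"({taxa[0]}:0.1,{taxa[1]}:0.1);")
        return tree
    codes = alignment.patterns  # (n_taxa, n_patterns)
    mult = alignment.multiplicities
    valid = codes < 20  # unambiguous residues only
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = float(mult[both].sum())
            diff = float(mult[both & (codes[i] != codes[j])].sum())
            p = diff / total if total else 0.0
            arg = 1.0 - 20.0 / 19.0 * p
            d[i, j] = d[j, i] = -0.95 * np.log(arg) if arg > 1e-4 else 5.0
    tree = parse_newick(str(nj(DistanceMatrix(d, ids=taxa))))
    for node in tree.postorder():
        if node.parent is not None and node.length < 1e-6:
            node.length = 1e-6
    split = next(iter(tree.edge_splits()))
    return tree.reroot_on_edge(split, root_split)


def _nni_neighbors(tree: PhyloTree):
    """Yield rooted NNI rearrangements: for each internal non-root node,
    swap one of its children with one of its siblings."""
    for node in tree.postorder():
        if node.is_leaf or node is tree.root or node.parent is None:
            continue
        parent = node.parent
        siblings = [s for s in parent.children if s is not node]
        for sib in siblings[:1]:
            for child in node.children:
                yield node, child, sib


def _apply_swap(tree: PhyloTree, node_path, child_idx, sib_idx) -> PhyloTree:
    """Copy the tree and swap child <-> sibling identified by tree paths."""
    new = tree.copy()

    def follow(path):
        cur = new.root
        for i in path:
            cur = cur.children[i]
        return cur

    node = follow(node_path)
    parent = node.parent
    child = node.children[child_idx]
    sib = parent.children[sib_idx]
    node.children[child_idx] = sib
    parent.children[sib_idx] = child
    sib.parent, child.parent = node, parent
    return new


def _node_path(tree: PhyloTree, node) -> list[int]:
    path = []
    cur = node
    while cur.parent is not None:
        path.append(cur.parent.children.index(cur))
        cur = cur.parent
    return list(reversed(path))


def nni_search(model: RateMatrix, rate_model: SiteRateModel, tree: PhyloTree,
               alignment: Alignment, max_rounds: int = 5,
               bl_max_iter: int = 50) -> tuple[PhyloTree, float]:
    """Greedy NNI hill climbing on a rooted tree.

    Each round scores all NNI neighbors at current branch lengths, applies
    the best improving swap, and re-optimizes branch lengths; stops when no
    neighbor improves the log-likelihood.
    """
    tree = tree.copy()
    engine = TreeLikelihood(model, rate_model, tree, alignment)
    logl = _optimize_engine_lengths(engine, max_iter=bl_max_iter)
    for _ in range(max_rounds):
        best = None
        for node, child, sib in _nni_neighbors(tree):
            cand = _apply_swap(tree, _node_path(tree, node),
                               node.children.index(child),
                               node.parent.children.index(sib))
            cand_logl = TreeLikelihood(model, rate_model, cand,
                                       alignment).log_likelihood()
            if cand_logl > logl + 1e-6 and (best is None or cand_logl > best[1]):
                best = (cand, cand_logl)
        if best is None:
            break
        tree = best[0]
        engine = TreeLikelihood(model, rate_model, tree, alignment)
        logl = _optimize_engine_lengths(engine, max_iter=bl_max_iter)
    return tree, logl


def estimate_tree(model: RateMatrix, rate_model: SiteRateModel,
                  alignment: Alignment, topology: PhyloTree | None = None,
                  nni: bool = True, bl_max_iter: int = 100) -> tuple[PhyloTree, float]:
    """Tree for one locus under a fixed model.

    Starts from ``topology`` (or an NJ tree), optimizes branch lengths,
    optionally NNI hill-climbs, and — when the model is nonreversible —
    places the root by an exhaustive root-edge scan.
    """
    tree = (topology.copy() if topology is not None
            else neighbor_joining_tree(alignment))
    if not tree.rooted:
        tree = tree.reroot_on_edge(next(iter(tree.edge_splits())), 0.5)
    tree, logl = optimize_branch_lengths(model, rate_model, tree, alignment,
                                         max_iter=bl_max_iter)
    if nni and topology is None and len(alignment.taxa) > 3:
        tree, logl = nni_search(model, rate_model, tree, alignment,
                                bl_max_iter=bl_max_iter)
    if not model.is_reversible:
        report = find_ml_root(model, rate_model, tree, alignment)
        tree = report.tree
        tree, logl = optimize_branch_lengths(model, rate_model, tree,
                                             alignment, max_iter=bl_max_iter)
    return tree, logl


# ---------------------------------------------------------------------------
# Step 2: per-locus model assignment
# ---------------------------------------------------------------------------

def _make_rate_model(name: str, params: np.ndarray | None = None) -> SiteRateModel:
    """Instantiate a rate model from its name and a parameter vector."""
    if name == "":
        return UNIFORM_RATES
    if name == "+I":
        p = params[0] if params is not None else 0.1
        return with_invariant(UNIFORM_RATES, float(np.clip(p, 0.0, 0.95)))
    if name.startswith("+I+G"):
        c = int(name[4:] or 4)
        p, a = (params if params is not None else (0.1, 1.0))
        return with_invariant(discretize_gamma(float(np.exp(a)) if params is not None
                                               else 1.0, c),
                              float(np.clip(p, 0.0, 0.95)))
    if name.startswith("+G"):
        c = int(name[2:] or 4)
        a = params[0] if params is not None else 0.0
        return discretize_gamma(float(np.exp(a)), c)
    if name.startswith("+R"):
        c = int(name[2:])
        if params is None:
            base = discretize_gamma(1.0, c)
            return free_rate(np.maximum(base.category_rates, 1e-3),
                             base.category_weights)
        rates = np.exp(params[:c])
        w = np.exp(params[c:2 * c - 1])
        w = np.concatenate([w, [1.0]])
        return free_rate(rates, w / w.sum())
    raise ValueError(f"unknown rate model {name!r}")


def _rate_model_start(name: str) -> np.ndarray:
    if name == "":
        return np.array([])
    if name == "+I":
        return np.array([0.1])
    if name.startswith("+I+G"):
        return np.array([0.1, 0.0])
    if name.startswith("+G"):
        return np.array([0.0])
    if name.startswith("+R"):
        c = int(name[2:])
        base = discretize_gamma(1.0, c)
        return np.concatenate([np.log(np.maximum(base.category_rates, 1e-3)),
                               np.zeros(c - 1)])
    raise ValueError(name)


def _fit_rate_model(model: RateMatrix, name: str, tree: PhyloTree,
                    alignment: Alignment) -> tuple[SiteRateModel, float, float]:
    """Optimize rate-model parameters plus a tree-scale multiplier on a
    fixed tree; returns (rate_model, scale, logL)."""
    x0 = np.concatenate([_rate_model_start(name), [0.0]])  # last = log scale

    def neg(x):
        try:
            rm = _make_rate_model(name, x[:-1] if name else None)
        except (ValueError, FloatingPointError):
            return 1e12
        engine = TreeLikelihood(model, rm, tree, alignment,
                                scale=float(np.exp(x[-1])))
        return -engine.log_likelihood()

    if x0.size == 1 and name == "":
        res = sciopt.minimize_scalar(lambda s: neg(np.array([s])),
                                     bounds=(-2, 2), method="bounded",
                                     options={"xatol": 1e-3})
        x_best = np.array([res.x])
    else:
        res = sciopt.minimize(neg, x0, method="Nelder-Mead",
                              options={"maxiter": 200 * x0.size,
                                       "xatol": 1e-3, "fatol": 1e-3})
        x_best = res.x if res.fun <= neg(x0) else x0
    rm = _make_rate_model(name, x_best[:-1] if name else None)
    scale = float(np.exp(x_best[-1]))
    logl = -neg(x_best)
    return rm, scale, logl


def assign_best_models(data, candidates, rate_model_names=DEFAULT_RATE_MODEL_NAMES,
                       topology: PhyloTree | None = None, nni: bool = True,
                       bl_max_iter: int = 100,
                       estimated_names: set | None = None) -> dict:
    """Step 2: best (matrix, rate model) per locus by BIC, then a tree.

    A starting tree per locus (NJ, or the supplied topology) is optimized
    once under the first candidate; every (matrix, rate model) pair is then
    scored with branch lengths fixed, optimizing only the rate-model
    parameters and a tree-scale factor.  The winner gets a full tree
    estimate (branch lengths, optional NNI, root scan for nonreversible
    matrices).

    ``estimated_names`` marks candidates whose matrix parameters were
    estimated from this data set (their 379 or 208 matrix parameters then
    count towards BIC); published matrices count zero.
    """
    loci = data.loci if isinstance(data, PartitionedData) else list(data)
    estimated_names = estimated_names or set()
    out = {}
    for idx, locus in enumerate(loci):
        if locus.n_taxa < 3:
            warnings.warn(f"locus {locus.name or idx}: fewer than 3 taxa, skipped")
            continue
        start = (topology.copy() if topology is not None
                 else neighbor_joining_tree(locus))
        if not start.rooted:
            start = start.reroot_on_edge(next(iter(start.edge_splits())), 0.5)
        start, _ = optimize_branch_lengths(candidates[0], UNIFORM_RATES,
                                           start, locus, max_iter=bl_max_iter)
        n_branches = len(start.postorder()) - 1
        fits = []
        details = {}
        for cand in candidates:
            for rname in rate_model_names:
                rm, scale, logl = _fit_rate_model(cand, rname, start, locus)
                k = n_branches + rm.n_free_params
                if cand.name in estimated_names:
                    k += free_parameter_count(cand)
                fit = ModelFit(f"{cand.name}{rname}", logl, k, locus.n_sites)
                fits.append(fit)
                details[fit.model_name] = (cand, rm)
        best_fit = select_best(fits)
        best_matrix, best_rm = details[best_fit.model_name]
        tree, logl = estimate_tree(best_matrix, best_rm, locus,
                                   topology=topology, nni=nni,
                                   bl_max_iter=bl_max_iter)
        out[idx] = LocusAssignment(best_matrix, best_rm, tree, logl, fits)
    if not out:
        raise ValueError("no usable locus (all have fewer than 3 taxa)")
    return out


# ---------------------------------------------------------------------------
# The outer loop
# ---------------------------------------------------------------------------

def nqmaker_estimate(data, initial_candidates=None,
                     config: EstimationConfig | None = None):
    """Estimate a joint nonreversible matrix from a collection of loci.

    Parameters
    ----------
    data : list of Alignment or PartitionedData
    initial_candidates : list of RateMatrix, optional
        Defaults to the bundled LG, WAG and JTT.
    config : EstimationConfig, optional

    Returns
    -------
    (RateMatrix, EstimationState)
        The final normalized matrix and the full iteration record;
        ``state.converged`` reports whether the correlation threshold was
        reached within the iteration budget.
    """
    cfg = config or EstimationConfig()
    candidates = (list(initial_candidates) if initial_candidates
                  else [load_builtin(n) for n in ("LG", "WAG", "JTT")])
    state = EstimationState(candidates=list(candidates),
                            best_matrix=candidates[0])
    estimated_names: set = set()
    topology = cfg.topology
    loci = data.loci if isinstance(data, PartitionedData) else list(data)
    if cfg.mode == "edge-linked" and topology is None:
        topology, _ = estimate_tree(candidates[0], UNIFORM_RATES, loci[0],
                                    nni=cfg.nni, bl_max_iter=cfg.bl_max_iter)

    for outer in range(1, cfg.max_outer_iterations + 1):
        state.iteration = outer
        # --- step 2: per-locus assignments and trees
        state.per_locus = assign_best_models(
            data, state.candidates, rate_model_names=cfg.rate_model_names,
            topology=topology, nni=cfg.nni, bl_max_iter=cfg.bl_max_iter,
            estimated_names=estimated_names)
        if cfg.mode == "edge-linked":
            shared = state.per_locus[min(state.per_locus)].tree.copy()
            engines = [TreeLikelihood(a.matrix, a.rate_model, shared, loci[i])
                       for i, a in state.per_locus.items()]
        else:
            engines = [TreeLikelihood(a.matrix, a.rate_model, a.tree, loci[i])
                       for i, a in state.per_locus.items()]

        # --- step 3: alternate matrix (3a) and branch lengths (3b)
        start = state.best_matrix
        for e in engines:
            e.set_model(start)
        logl = _joint_logl(engines)
        cycle_log = [("start", logl)]
        while True:
            q_new, info = optimize_q_nonreversible(
                engines, start, max_iter=cfg.em_max_iter, tol=cfg.em_tol)
            logl_a = info["log_likelihood"]
            assert logl_a >= logl - 1e-6, "matrix step decreased logL"
            cycle_log.append(("matrix", logl_a))
            if cfg.mode == "edge-linked":
                logl_b = _optimize_shared_lengths(engines,
                                                  max_iter=cfg.bl_max_iter)
            else:
                logl_b = sum(_optimize_engine_lengths(e, max_iter=cfg.bl_max_iter)
                             for e in engines)
            assert logl_b >= logl_a - 1e-6, "branch step decreased logL"
            cycle_log.append(("branch_lengths", logl_b))
            gain, logl, start = logl_b - logl, logl_b, q_new
            if gain <= cfg.logl_epsilon:
                break

        # --- step 4: convergence by matrix correlation
        corr = matrix_correlation(state.best_matrix, q_new)
        state.history.append({"iteration": outer, "log_likelihood": logl,
                              "correlation": corr, "cycles": cycle_log})
        q_new = RateMatrix(q_new.rates, q_new.frequencies,
                           name=f"NQ.iter{outer}")
        state.best_matrix = q_new
        estimated_names.add(q_new.name)
        if corr >= cfg.corr_threshold:
            state.converged = True
            break
        state.candidates.append(q_new)

    final = RateMatrix(state.best_matrix.rates, state.best_matrix.frequencies,
                       name="NQ.estimated")
    state.best_matrix = final
    return final, state
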