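"""Maximum-likelihood root placement and rootstrap support.

Under a nonreversible model the likelihood depends on where the tree is
rooted, so the root can be inferred: every branch is tried as the root
position (the two root-adjacent branch lengths re-optimized), and the
branch with the highest likelihood wins.  Rootstrap support for a branch
is the fraction of nonparametric bootstrap replicates (sites resampled
with replacement, topology fixed) whose ML root lies on that branch.

Reversible models are rejected: by the pulley principle their likelihood
is root-invariant and the root is unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt

from .likelihood import Alignment
from .rate_heterogeneity import SiteRateModel
from .substitution_model import RateMatrix
from .trees import PhyloTree, write_newick

__all__ = ["RootReport", "UnidentifiableRootError", "find_ml_root", "rootstrap"]

_LENGTH_BOUNDS = (1e-8, 100.0)


class UnidentifiableRootError(ValueError):
    """Root inference was requested under a reversible (root-invariant) model."""


@dataclass
class RootReport:
    """Per-branch root likelihoods and rootstrap supports.

    ``per_edge`` maps each canonical split to a dict with keys ``logL``,
    ``delta_logL`` (difference to the ML edge) and ``rootstrap``.
    ``tree`` is the input topology rooted on ``ml_edge`` with the two
    root-adjacent lengths at their ML values.
    """

    per_edge: dict
    ml_edge: frozenset
    tree: PhyloTree
    n_bootstrap: int = 0

    def annotated_newick(self) -> str:
        ann = {split: f"&rootstrap={rec['rootstrap']:.3f}"
               for split, rec in self.per_edge.items()}
        return write_newick(self.tree, annotations=ann)

    def table(self):
        import pandas as pd
        rows = [{"edge": "|".join(sorted(split)), **rec}
                for split, rec in self.per_edge.items()]
        return (pd.DataFrame(rows)
                .sort_values("logL", ascending=False).reset_index(drop=True))


class _RootScanner:
    """Directional-message machinery shared by the point estimate and the
    bootstrap: messages are independent of site multiplicities, so each
    bootstrap replicate only re-runs the cheap per-edge optimizations."""

    def __init__(self, model: RateMatrix, rate_model: SiteRateModel,
                 tree: PhyloTree, alignment: Alignment):
        if model.is_reversible:
            raise UnidentifiableRootError(
                "the root is unidentifiable under a reversible model "
                "(pulley principle)")
        self.model = model
        self.rate_model = rate_model
        self.alignment = alignment
        self.base = tree.unrooted() if tree.rooted else tree.copy()
        # engine only used for tips / bookkeeping consistency
        self._tips = {}
        for leaf in self.base.leaves():
            self._tips[leaf.label] = alignment.tip_partials(leaf.label)
        self._compute_messages()
        self.edge_list = [(split, node) for split, node
                          in self.base.edge_splits().items()]
        below: dict[int, frozenset] = {}
        for node in self.base.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
        #: leafset of the subtree side of each scanned edge
        self.below = {split: below[id(node)] for split, node in self.edge_list}

    def _p(self, t: float, cat: int) -> np.ndarray:
        return self.model.transition(
            t * self.rate_model.category_rates[cat]).probs

    def _compute_messages(self):
        """Up (subtree below v, state at v) and down (rest of tree, state at
        v's parent) messages for every non-base node, per rate category."""
        n_cat = self.rate_model.n_categories
        n_pat = self.alignment.n_patterns
        post = self.base.postorder()
        self.up = [dict() for _ in range(n_cat)]      # id(node) -> (n_pat, 20)
        self.up_ls = [dict() for _ in range(n_cat)]
        self.down = [dict() for _ in range(n_cat)]
        self.down_ls = [dict() for _ in range(n_cat)]
        for c in range(n_cat):
            up, up_ls = self.up[c], self.up_ls[c]
            for node in post:
                if node.is_leaf:
                    up[id(node)] = self._tips[node.label]
                    up_ls[id(node)] = np.zeros(n_pat)
                    continue
                acc, sc = None, np.zeros(n_pat)
                for ch in node.children:
                    msg = up[id(ch)] @ self._p(ch.length, c).T
                    acc = msg if acc is None else acc * msg
                    sc += up_ls[id(ch)]
                m = np.maximum(acc.max(axis=1), 1e-300)
                up[id(node)] = acc / m[:, None]
                up_ls[id(node)] = sc + np.log(m)
            down, down_ls = self.down[c], self.down_ls[c]
            for node in self.base.preorder():
                for ch in node.children:
                    acc, sc = None, np.zeros(n_pat)
                    if node is not self.base.root:
                        msg = down[id(node)] @ self._p(node.length, c).T
                        acc, sc = msg, down_ls[id(node)].copy()
                    for sib in node.children:
                        if sib is ch:
                            continue
                        msg = up[id(sib)] @ self._p(sib.length, c).T
                        acc = msg if acc is None else acc * msg
                        sc += up_ls[id(sib)]
                    m = np.maximum(acc.max(axis=1), 1e-300)
                    down[id(ch)] = acc / m[:, None]
                    down_ls[id(ch)] = sc + np.log(m)

    def edge_logl(self, node, t1: float, t2: float, weights: np.ndarray) -> float:
        """logL with the root on node's parent edge: t1 on the subtree side
        (below ``node``), t2 on the rest-of-tree side."""
        pi = self.model.frequencies
        n_cat = self.rate_model.n_categories
        cat_ll = np.empty((n_cat, self.alignment.n_patterns))
        for c in range(n_cat):
            a1 = self.up[c][id(node)] @ self._p(t1, c).T
            a2 = self.down[c][id(node)] @ self._p(t2, c).T
            like = np.maximum((a1 * a2) @ pi, 0.0)
            with np.errstate(divide="ignore"):
                cat_ll[c] = (np.log(like) + self.up_ls[c][id(node)]
                             + self.down_ls[c][id(node)])
        logw = np.log(self.rate_model.category_weights)[:, None]
        m = np.max(cat_ll + logw, axis=0)
        site_ll = m + np.log(np.exp(cat_ll + logw - m).sum(axis=0))
        return float(site_ll @ weights)

    def optimize_edge(self, node, weights) -> tuple[float, float, float]:
        """ML root position on one edge: returns (logL, t1, t2)."""
        t0 = max(node.length, 1e-6)
        lo, hi = np.log(_LENGTH_BOUNDS[0]), np.log(_LENGTH_BOUNDS[1])

        def neg(x):
            return -self.edge_logl(node, float(np.exp(x[0])),
                                   float(np.exp(x[1])), weights)

        x0 = np.log([t0 / 2, t0 / 2])
        res = sciopt.minimize(neg, x0, method="L-BFGS-B",
                              bounds=[(lo, hi)] * 2,
                              options={"maxiter": 60, "ftol": 1e-10})
        best_x = res.x if res.fun <= neg(x0) else x0
        t1, t2 = np.exp(best_x)
        return -neg(best_x), float(t1), float(t2)

    def scan(self, weights) -> dict:
        out = {}
        for split, node in self.edge_list:
            logl, t1, t2 = self.optimize_edge(node, weights)
            out[split] = (logl, t1, t2)
        return out


def find_ml_root(model: RateMatrix, rate_model: SiteRateModel,
                 tree: PhyloTree, alignment: Alignment) -> RootReport:
    """Scan every branch as a candidate root position.

    For each branch the root is placed on it and the two root-adjacent
    lengths are optimized (all other lengths fixed); the branch attaining
    the maximum log-likelihood is the ML root.  Input tree may be rooted
    (it is unrooted first) or unrooted.
    """
    scanner = _RootScanner(model, rate_model, tree, alignment)
    scan = scanner.scan(alignment.multiplicities)
    ml_edge = max(scan, key=lambda s: scan[s][0])
    best_logl = scan[ml_edge][0]
    per_edge = {s: {"logL": logl, "delta_logL": logl - best_logl,
                    "rootstrap": 0.0}
                for s, (logl, _, _) in scan.items()}
    rooted = _rooted_on(scanner.base, ml_edge, scanner.below[ml_edge],
                        scan[ml_edge][1], scan[ml_edge][2])
    return RootReport(per_edge, ml_edge, rooted)


def rootstrap(model: RateMatrix, rate_model: SiteRateModel, tree: PhyloTree,
              alignment: Alignment, n_replicates: int = 100,
              seed: int = 0) -> RootReport:
    """Rootstrap supports by nonparametric site bootstrap (topology fixed).

    Each replicate resamples site multiplicities, re-runs the root scan,
    and contributes its single ML root branch; the rootstrap value of a
    branch is the fraction of replicates rooting there.  Deterministic
    given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    scanner = _RootScanner(model, rate_model, tree, alignment)
    scan = scanner.scan(alignment.multiplicities)
    ml_edge = max(scan, key=lambda s: scan[s][0])
    best_logl = scan[ml_edge][0]
    counts = {s: 0 for s in scan}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        w = alignment.subsample_multiplicities(rng)
        rep = scanner.scan(w)
        counts[max(rep, key=lambda s: rep[s][0])] += 1
    per_edge = {s: {"logL": logl, "delta_logL": logl - best_logl,
                    "rootstrap": counts[s] / n_replicates}
                for s, (logl, _, _) in scan.items()}
    rooted = _rooted_on(scanner.base, ml_edge, scanner.below[ml_edge],
                        scan[ml_edge][1], scan[ml_edge][2])
    return RootReport(per_edge, ml_edge, rooted, n_bootstrap=n_replicates)


def _rooted_on(base: PhyloTree, split: frozenset, subtree_leaves: frozenset,
               t_subtree: float, t_rest: float) -> PhyloTree:
    """Root ``base`` on ``split`` with the optimized root-adjacent lengths;
    ``subtree_leaves`` identifies which side gets ``t_subtree``."""
    rooted = base.reroot_on_edge(split, fraction=0.5)
    below: dict[int, frozenset] = {}
    for node in rooted.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    a, b = rooted.root.children
    if below[id(a)] == subtree_leaves:
        a.length, b.length = t_subtree, t_rest
    else:
        a.length, b.length = t_rest, t_subtree
    return rooted
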