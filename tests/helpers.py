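"""Independent oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
summation, long-double arithmetic — and shares no code with the package's
computational paths.
"""

import itertools

import numpy as np

from nonrev.likelihood import _AMBIGUITY, _MISSING
from nonrev.substitution_model import AMINO_ACIDS


def allowed_states(symbol: str, n_states: int = 20):
    s = symbol.upper()
    if s in AMINO_ACIDS[:n_states]:
        return [AMINO_ACIDS.index(s)]
    if s in _AMBIGUITY:
        return [AMINO_ACIDS.index(a) for a in _AMBIGUITY[s]]
    if s in _MISSING:
        return list(range(n_states))
    raise ValueError(symbol)


def brute_force_site_likelihood(model, rate_model, tree, pattern: dict) -> float:
    """Site likelihood by exhaustive marginalization over every internal
    (and ambiguous tip) state assignment.  Exponential in tree size; only
    usable on trees with a handful of internal nodes."""
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    n_states = model.n_states
    total = 0.0
    for c in range(rate_model.n_categories):
        rate = rate_model.category_rates[c]
        pmats = {id(n): model.transition(n.length * rate).probs
                 for n in nodes if n is not tree.root}
        cat_total = 0.0
        leaf_choices = [(n, allowed_states(pattern[n.label], n_states))
                        for n in nodes if n.is_leaf]
        for internal_states in itertools.product(range(n_states),
                                                 repeat=len(internal)):
            state_of = {id(n): s for n, s in zip(internal, internal_states)}
            base = model.frequencies[state_of[id(tree.root)]]
            for n in internal:
                if n is tree.root:
                    continue
                base *= pmats[id(n)][state_of[id(n.parent)], state_of[id(n)]]
            if base == 0.0:
                continue
            leaf_term = 1.0
            for leaf, choices in leaf_choices:
                p = pmats[id(leaf)]
                leaf_term *= sum(p[state_of[id(leaf.parent)], s]
                                 for s in choices)
            cat_total += base * leaf_term
        total += rate_model.category_weights[c] * cat_total
    return total


def pruning_longdouble(model, rate_model, tree, alignment) -> float:
    """Reference pruning in long-double arithmetic with no underflow
    protection (usable only on small trees)."""
    logl = np.longdouble(0.0)
    pi = model.frequencies.astype(np.longdouble)
    for p_idx in range(alignment.n_patterns):
        site = np.longdouble(0.0)
        for c in range(rate_model.n_categories):
            rate = rate_model.category_rates[c]

            def partial(node):
                if node.is_leaf:
                    return alignment.tip_partials(node.label)[p_idx].astype(
                        np.longdouble)
                out = np.ones(model.n_states, dtype=np.longdouble)
                for ch in node.children:
                    p = model.transition(ch.length * rate).probs.astype(
                        np.longdouble)
                    out *= p @ partial(ch)
                return out

            site += rate_model.category_weights[c] * (pi @ partial(tree.root))
        logl += alignment.multiplicities[p_idx] * np.log(site)
    return float(logl)


def pearson_oracle(x, y) -> float:
    """Textbook Pearson correlation, written independently."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def rooted_shape_id(tree) -> str:
    """Canonical label-sorted newick without lengths (topology identity)."""

    def fmt(node):
        if node.is_leaf:
            return node.label
        parts = sorted(fmt(c) for c in node.children)
        return "(" + ",".join(parts) + ")"

    return fmt(tree.root)


def true_root_split(tree):
    """Canonical split of the root edge of a rooted tree."""
    below = {}
    for n in tree.postorder():
        below[id(n)] = (frozenset([n.label]) if n.is_leaf else
                        frozenset().union(*(below[id(c)] for c in n.children)))
    return tree.canonical_split(below[id(tree.root.children[0])])
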