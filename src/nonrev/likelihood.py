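"""Pruning-algorithm likelihood of alignments on rooted trees.

The likelihood of a site is computed by propagating conditional (partial)
likelihood vectors from the tips to the root; transition probabilities are
applied in the ancestor-to-descendant direction (rows of ``P(t)`` index the
ancestral state), and the root is closed with the stationary distribution
``pi``.  Site patterns are compressed and per-node log-scalers guard
against underflow on large trees.

Besides plain log-likelihoods, :class:`TreeLikelihood` exposes the per-edge
posterior statistics (outer products of forward and backward partials) that
drive analytic branch-length gradients and the expectation step of rate
matrix estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .rate_heterogeneity import SiteRateModel, UNIFORM_RATES
from .substitution_model import AMINO_ACIDS, N_STATES, RateMatrix
from .trees import PhyloTree

__all__ = [
    "Alignment",
    "PartitionedData",
    "TreeLikelihood",
    "site_log_likelihood",
    "tree_log_likelihood",
    "partitioned_log_likelihood",
    "read_fasta",
    "read_phylip",
    "write_fasta",
]

_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Ambiguity codes resolve to a set of states; missing data to all 20.
_AMBIGUITY = {
    "B": ("N", "D"),
    "Z": ("Q", "E"),
    "J": ("I", "L"),
}
_MISSING = set("-.?X*~")


def _tip_row(symbol: str) -> np.ndarray:
    row = np.zeros(N_STATES)
    s = symbol.upper()
    if s in _STATE_INDEX:
        row[_STATE_INDEX[s]] = 1.0
    elif s in _AMBIGUITY:
        for aa in _AMBIGUITY[s]:
            row[_STATE_INDEX[aa]] = 1.0
    elif s in _MISSING:
        row[:] = 1.0
    else:
        raise ValueError(f"unknown residue symbol {symbol!r}")
    return row


# one row per recognized symbol code; built lazily below
_SYMBOLS = list(AMINO_ACIDS) + sorted(_AMBIGUITY) + sorted(_MISSING)
_SYMBOL_CODE = {s: i for i, s in enumerate(_SYMBOLS)}
_CODE_ROWS = np.stack([_tip_row(s) for s in _SYMBOLS])


class Alignment:
    """Aligned amino-acid sequences with lossless site-pattern compression.

    Parameters
    ----------
    taxa : sequence of str
        Unique sequence names.
    sequences : sequence of str
        Equal-length amino-acid strings; gaps and ambiguity codes
        (``- . ? X * ~ B Z J``) are accepted.
    """

    def __init__(self, taxa, sequences, name: str = ""):
        self.taxa = list(taxa)
        self.name = name
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        seqs = [s.upper() for s in sequences]
        if len(seqs) != len(self.taxa):
            raise ValueError("one sequence per taxon required")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        self.n_sites = lengths.pop()
        if self.n_sites < 1:
            raise ValueError("empty alignment")
        codes = np.empty((len(seqs), self.n_sites), dtype=np.uint8)
        for i, s in enumerate(seqs):
            try:
                codes[i] = [_SYMBOL_CODE[ch] for ch in s]
            except KeyError as exc:
                raise ValueError(f"unknown residue symbol {exc.args[0]!r} "
                                 f"in sequence {self.taxa[i]!r}") from exc
        self._codes = codes
        self.patterns, self.multiplicities = np.unique(
            codes, axis=1, return_counts=True)
        self.multiplicities = self.multiplicities.astype(float)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(_SYMBOLS[c] for c in self._codes[i])

    def tip_partials(self, taxon: str) -> np.ndarray:
        """(n_patterns, 20) indicator/ambiguity matrix for one taxon."""
        i = self.taxa.index(taxon)
        return _CODE_ROWS[self.patterns[i]]

    def subsample_multiplicities(self, rng: np.random.Generator) -> np.ndarray:
        """Bootstrap pattern weights: resample ``n_sites`` sites with
        replacement (a multinomial draw over patterns)."""
        p = self.multiplicities / self.n_sites
        return rng.multinomial(self.n_sites, p).astype(float)

    def __repr__(self):
        return (f"<Alignment {self.name or '?'}: {self.n_taxa} taxa x "
                f"{self.n_sites} sites ({self.n_patterns} patterns)>")


@dataclass
class PartitionedData:
    """A collection of loci analysed together.

    In edge-linked mode all loci share one topology and branch lengths,
    each locus applying its own positive rate multiplier (``scales``) and
    site-rate model.
    """

    loci: list
    models: list | None = None
    rate_models: list | None = None
    scales: list | None = None

    def __post_init__(self):
        if not self.loci:
            raise ValueError("at least one locus required")
        n = len(self.loci)
        if self.scales is None:
            self.scales = [1.0] * n
        if any(s <= 0 for s in self.scales):
            raise ValueError("per-locus scales must be positive")
        if self.rate_models is None:
            self.rate_models = [UNIFORM_RATES] * n
        for attr in ("models", "rate_models", "scales"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ValueError(f"{attr} must have one entry per locus")

    @property
    def shared_taxa(self) -> set:
        out = set()
        for loc in self.loci:
            out |= set(loc.taxa)
        return out


# ---------------------------------------------------------------------------
# Core engine
# ---------------------------------------------------------------------------

_SCALE_THRESHOLD = 1e-100


class TreeLikelihood:
    """Pruning likelihood engine for one (model, rate model, tree, alignment).

    Branch lengths are owned by the engine (initialized from the tree) and
    can be updated in place; transition matrices are cached per edge and
    rate category and invalidated on length changes.  An optional ``scale``
    multiplies every branch length (edge-linked partition support).
    """

    def __init__(self, model: RateMatrix, rate_model: SiteRateModel,
                 tree: PhyloTree, alignment: Alignment, scale: float = 1.0):
        if not tree.rooted:
            raise ValueError("likelihood on a rooted tree required "
                             "(root the tree first)")
        missing = set(l.label for l in tree.leaves()) - set(alignment.taxa)
        if missing:
            raise ValueError(f"taxa missing from alignment: {sorted(missing)}")
        self.model = model
        self.rate_model = rate_model
        self.tree = tree
        self.alignment = alignment
        self.scale = float(scale)

        self._post = tree.postorder()  # root last
        self._index = {id(n): i for i, n in enumerate(self._post)}
        self.edge_nodes = [n for n in self._post if n is not tree.root]
        self._lengths = np.array([n.length for n in self.edge_nodes])
        self._tips = {i: alignment.tip_partials(n.label)
                      for i, n in enumerate(self._post) if n.is_leaf}
        self._pcache: dict[tuple[int, int], np.ndarray] = {}
        self.multiplicities = alignment.multiplicities.copy()

    # -- branch lengths -----------------------------------------------------
    def get_lengths(self) -> np.ndarray:
        return self._lengths.copy()

    def set_lengths(self, lengths) -> None:
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != self._lengths.shape:
            raise ValueError("length vector has wrong size")
        changed = lengths != self._lengths
        for e in np.nonzero(changed)[0]:
            for c in range(self.rate_model.n_categories):
                self._pcache.pop((e, c), None)
        self._lengths = lengths.copy()

    def sync_tree(self) -> None:
        """Write the engine's branch lengths back onto the tree nodes."""
        for node, t in zip(self.edge_nodes, self._lengths):
            node.length = float(t)

    def set_scale(self, scale: float) -> None:
        if scale != self.scale:
            self.scale = float(scale)
            self._pcache.clear()

    def set_model(self, model: RateMatrix) -> None:
        """Swap the substitution matrix, keeping tree, tips and lengths."""
        self.model = model
        self._pcache.clear()

    def set_rate_model(self, rate_model: SiteRateModel) -> None:
        self.rate_model = rate_model
        self._pcache.clear()

    # -- transition matrices ------------------------------------------------
    def _p_matrix(self, edge: int, cat: int) -> np.ndarray:
        key = (edge, cat)
        p = self._pcache.get(key)
        if p is None:
            t = self._lengths[edge] * self.rate_model.category_rates[cat] * self.scale
            p = self.model.transition(t).probs
            self._pcache[key] = p
        return p

    # -- pruning ------------------------------------------------------------
    def _backward(self, cat: int):
        """Post-order partials ``b`` and log-scalers for one category.

        ``b[i][p, x]`` is the probability of the pattern-p data below node i
        given state x at node i, up to ``exp(ls[i][p])``.
        """
        n_pat = self.alignment.n_patterns
        b: list = [None] * len(self._post)
        ls: list = [None] * len(self._post)
        for i, node in enumerate(self._post):
            if node.is_leaf:
                b[i] = self._tips[i]
                ls[i] = np.zeros(n_pat)
                continue
            acc = None
            sc = np.zeros(n_pat)
            # postorder index doubles as edge index: the root is last, so
            # every non-root node keeps its position in ``edge_nodes``
            for ch in node.children:
                j = self._index[id(ch)]
                msg = b[j] @ self._p_matrix(j, cat).T
                acc = msg if acc is None else acc * msg
                sc += ls[j]
            m = np.maximum(acc.max(axis=1), _SCALE_THRESHOLD)
            b[i] = acc / m[:, None]
            ls[i] = sc + np.log(m)
        return b, ls

    def _category_site_logl(self):
        """(n_categories, n_patterns) per-category site log-likelihoods."""
        pi = self.model.frequencies
        out = np.empty((self.rate_model.n_categories, self.alignment.n_patterns))
        for c in range(self.rate_model.n_categories):
            b, ls = self._backward(c)
            root_like = b[-1] @ pi
            with np.errstate(divide="ignore"):
                out[c] = np.log(np.maximum(root_like, 0.0)) + ls[-1]
        return out

    def site_log_likelihoods(self) -> np.ndarray:
        """(n_patterns,) site log-likelihoods, categories marginalized."""
        cat_ll = self._category_site_logl()
        logw = np.log(self.rate_model.category_weights)[:, None]
        m = np.max(cat_ll + logw, axis=0)
        return m + np.log(np.exp(cat_ll + logw - m).sum(axis=0))

    def log_likelihood(self, weights=None) -> float:
        w = self.multiplicities if weights is None else np.asarray(weights, float)
        return float(self.site_log_likelihoods() @ w)

    # -- edge statistics ----------------------------------------------------
    def edge_statistics(self, weights=None):
        """Posterior edge weight matrices for gradients and EM.

        Returns ``(logL, stats)`` where ``stats[(edge, cat)]`` is the 20x20
        matrix ``W_ab = sum_p c_p f_a(p) b_b(p)`` with
        ``c_p = mult_p * w_cat * exp(scalers - site_logL_p)``: the
        derivative of the total log-likelihood with respect to the entries
        of that edge's transition matrix, ``dlogL/dP_ab``.
        """
        mult = self.multiplicities if weights is None else np.asarray(weights, float)
        pi = self.model.frequencies
        n_cat = self.rate_model.n_categories
        cat_ll = self._category_site_logl()
        logw = np.log(self.rate_model.category_weights)[:, None]
        m = np.max(cat_ll + logw, axis=0)
        site_ll = m + np.log(np.exp(cat_ll + logw - m).sum(axis=0))
        logl = float(site_ll @ mult)

        stats: dict[tuple[int, int], np.ndarray] = {}
        for c in range(n_cat):
            b, ls_b = self._backward(c)
            w_c = self.rate_model.category_weights[c]
            # forward pass: f[v] defined on the parent's state space
            f: dict[int, np.ndarray] = {}
            ls_f: dict[int, np.ndarray] = {}
            root_i = len(self._post) - 1
            f[root_i] = np.broadcast_to(pi, b[-1].shape)
            ls_f[root_i] = np.zeros(self.alignment.n_patterns)
            for node in reversed(self._post):  # pre-order
                i = self._index[id(node)]
                if node.is_leaf:
                    continue
                g = f[i] if node is self.tree.root else f[i] @ self._p_matrix(i, c)
                ls_g = ls_f[i]
                msgs = []
                for ch in node.children:
                    j = self._index[id(ch)]
                    msgs.append(b[j] @ self._p_matrix(j, c).T)
                for k, ch in enumerate(node.children):
                    j = self._index[id(ch)]
                    acc = g
                    sc = ls_g.copy()
                    for k2, ch2 in enumerate(node.children):
                        if k2 == k:
                            continue
                        j2 = self._index[id(ch2)]
                        acc = acc * msgs[k2]
                        sc += ls_b[j2]
                    mx = np.maximum(acc.max(axis=1), _SCALE_THRESHOLD)
                    acc = acc / mx[:, None]
                    sc = sc + np.log(mx)
                    with np.errstate(over="ignore"):
                        c_p = mult * w_c * np.exp(sc + ls_b[j] - site_ll)
                    stats[(j, c)] = acc.T @ (b[j] * c_p[:, None])
                    if not ch.is_leaf:
                        f[j] = acc
                        ls_f[j] = sc
                if node is not self.tree.root:
                    del f[i], ls_f[i]
        return logl, stats

    def branch_gradient(self, weights=None):
        """Analytic gradient of logL with respect to every branch length.

        Uses ``dP(r t)/dt = r Q P(r t)``; returns ``(logL, grad)`` with one
        entry per edge (postorder node order, root excluded).
        """
        logl, stats = self.edge_statistics(weights)
        q = self.model.rates
        grad = np.zeros(len(self.edge_nodes) + 1)  # indexed by node position
        for (j, c), w in stats.items():
            r = self.rate_model.category_rates[c] * self.scale
            if r == 0:
                continue
            qp = q @ self._p_matrix(j, c)
            grad[j] += r * float(np.sum(w * qp))
        # drop the root slot, keep postorder edge order
        return logl, np.array([grad[self._index[id(n)]] for n in self.edge_nodes])


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def site_log_likelihood(model: RateMatrix, rate_model: SiteRateModel,
                        tree: PhyloTree, pattern: dict) -> float:
    """Log-likelihood of a single site column (taxon -> residue mapping)."""
    taxa = sorted(pattern)
    aln = Alignment(taxa, [pattern[t] for t in taxa])
    return TreeLikelihood(model, rate_model, tree, aln).log_likelihood()


def tree_log_likelihood(model: RateMatrix, rate_model: SiteRateModel,
                        tree: PhyloTree, alignment: Alignment) -> float:
    """Total log-likelihood of an alignment on a rooted tree."""
    return TreeLikelihood(model, rate_model, tree, alignment).log_likelihood()


def partitioned_log_likelihood(data: PartitionedData, topology: PhyloTree) -> float:
    """Edge-linked multi-locus log-likelihood on one shared topology.

    Each locus contributes its own substitution and site-rate model and a
    branch-length multiplier applied to the shared lengths.
    """
    total = 0.0
    for i, locus in enumerate(data.loci):
        model = data.models[i]
        engine = TreeLikelihood(model, data.rate_models[i], topology, locus,
                                scale=data.scales[i])
        total += engine.log_likelihood()
    return total


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

def _from_biopython(msa, name="") -> Alignment:
    return Alignment([rec.id for rec in msa], [str(rec.seq) for rec in msa],
                     name=name)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file (wrapped or single-line)."""
    msa = AlignIO.read(str(path), "fasta")
    return _from_biopython(msa, name=Path(path).stem)


def read_phylip(path) -> Alignment:
    """Read a relaxed (sequential) PHYLIP alignment."""
    msa = AlignIO.read(str(path), "phylip-relaxed")
    return _from_biopython(msa, name=Path(path).stem)


def write_fasta(alignment: Alignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon in alignment.taxa:
            fh.write(f">{taxon}\n")
            seq = alignment.sequence(taxon)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
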