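"""General (nonreversible) and reversible 20-state amino-acid substitution models.

A substitution model is a continuous-time Markov process on the 20 amino
acids, specified by an instantaneous rate matrix ``Q`` whose rows sum to
zero.  Matrices are normalized so that one unit of time corresponds to one
expected substitution per site at stationarity, i.e. ``-sum_x pi_x q_xx = 1``.

Reversible models factor as ``q_xy = pi_y * r_xy`` with a symmetric
exchangeability matrix ``R``; general models carry 380 independent
off-diagonal rates (379 free after normalization).  Transition probabilities
``P(t) = expm(Q t)`` are computed through the complex eigendecomposition of
``Q``, with a scaling-and-squaring fallback for defective or ill-conditioned
matrices.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "N_STATES",
    "RateMatrix",
    "TransitionMatrix",
    "EigenSystem",
    "DegenerateModelError",
    "normalize",
    "stationary_distribution",
    "transition_probabilities",
    "build_reversible",
    "free_parameter_count",
    "matrix_correlation",
    "read_paml_dat",
    "read_rate_matrix",
    "write_rate_matrix",
    "load_builtin",
    "BUILTIN_MODELS",
]

#: Amino acids in PAML order; every matrix in this package is indexed this way.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20

BUILTIN_MODELS = ("LG", "WAG", "JTT")

_ROWSUM_TOL = 1e-10
_STATIONARY_TOL = 1e-8
_DETBAL_TOL = 1e-10


class DegenerateModelError(ValueError):
    """Raised for rate matrices that do not define a usable Markov process."""


@dataclass(frozen=True)
class EigenSystem:
    """Complex eigendecomposition ``Q = U diag(lam) U^-1``."""

    eigenvalues: np.ndarray
    right_vectors: np.ndarray
    inverse_vectors: np.ndarray
    is_valid: bool

    def reconstruct(self) -> np.ndarray:
        return (self.right_vectors * self.eigenvalues) @ self.inverse_vectors


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix ``P(t)``; rows index the ancestral state."""

    probs: np.ndarray
    time: float

    def __post_init__(self):
        rs = self.probs.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > 1e-8:
            raise ValueError("transition matrix rows must sum to 1")


@dataclass(frozen=True)
class RateMatrix:
    """Normalized instantaneous rate matrix with its stationary distribution.

    Attributes
    ----------
    rates : (n, n) ndarray
        Row-sum-zero rate matrix, off-diagonals non-negative, scaled to one
        expected substitution per time unit at stationarity.
    frequencies : (n,) ndarray
        Stationary distribution ``pi`` (left null vector of ``rates``).
    is_reversible : bool
        Whether the matrix was built under the detailed-balance constraint.
    name : str
        Identifier, e.g. ``"LG"`` or ``"NQ.sim"``.
    """

    rates: np.ndarray
    frequencies: np.ndarray
    is_reversible: bool = False
    name: str = ""
    labels: str = AMINO_ACIDS
    _eigen: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        q = self.rates
        pi = self.frequencies
        n = q.shape[0]
        if q.shape != (n, n) or pi.shape != (n,):
            raise ValueError("inconsistent matrix/frequency dimensions")
        off = q[~np.eye(n, dtype=bool)]
        if off.min() < -1e-12:
            raise ValueError("negative off-diagonal rate")
        if np.max(np.abs(q.sum(axis=1))) > _ROWSUM_TOL * max(1.0, np.abs(q).max()):
            raise ValueError("rate matrix rows must sum to zero")
        if abs(pi.sum() - 1.0) > 1e-10 or pi.min() < -1e-12:
            raise ValueError("frequencies must form a probability vector")
        if np.max(np.abs(pi @ q)) > _STATIONARY_TOL:
            raise ValueError("frequencies are not stationary for these rates")
        if self.is_reversible:
            flux = pi[:, None] * q
            if np.max(np.abs(flux - flux.T)) > _DETBAL_TOL:
                raise ValueError("detailed balance violated for reversible model")

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def mean_rate(self) -> float:
        """Expected substitutions per time unit, ``-sum_x pi_x q_xx``."""
        return float(-np.dot(self.frequencies, np.diag(self.rates)))

    def eigensystem(self) -> EigenSystem:
        """Cached complex eigendecomposition of the rate matrix."""
        if not self._eigen:
            self._eigen.append(_eigendecompose(self.rates))
        return self._eigen[0]

    def off_diagonal(self) -> np.ndarray:
        """The n*(n-1) off-diagonal rates as a flat vector (row-major)."""
        n = self.n_states
        return self.rates[~np.eye(n, dtype=bool)]

    def transition(self, t: float) -> TransitionMatrix:
        return transition_probabilities(self, t)

    def reversible_projection(self, name: str = "") -> "RateMatrix":
        """Closest reversible model sharing this model's stationary flux.

        Symmetrizes the probability flux: ``pi_x q'_xy = (pi_x q_xy +
        pi_y q_yx) / 2``, then renormalizes.  For a reversible input this is
        the identity operation.
        """
        pi = self.frequencies
        flux = pi[:, None] * self.rates
        sym = 0.5 * (flux + flux.T)
        q = sym / pi[:, None]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return normalize(q, frequencies=pi, is_reversible=True,
                         name=name or (self.name + ".rev" if self.name else ""))


def _eigendecompose(q: np.ndarray, cond_limit: float = 1e12,
                    residual_limit: float = 1e-6) -> EigenSystem:
    lam, u = np.linalg.eig(q)
    try:
        u_inv = np.linalg.inv(u)
    except np.linalg.LinAlgError:
        return EigenSystem(lam, u, np.full_like(u, np.nan), False)
    cond = np.linalg.cond(u)
    residual = np.max(np.abs((u * lam) @ u_inv - q))
    ok = bool(np.isfinite(cond) and cond < cond_limit and residual < residual_limit)
    return EigenSystem(lam, u, u_inv, ok)


def stationary_distribution(rates: np.ndarray) -> np.ndarray:
    """Stationary distribution ``pi`` with ``pi Q = 0`` and ``sum(pi) = 1``.

    Solved as a linear system: one column of ``Q^T`` is replaced by ones,
    which is better conditioned than extracting the null eigenvector.
    """
    q = np.asarray(rates, dtype=float)
    n = q.shape[0]
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateModelError("rate matrix has no unique stationary "
                                   "distribution (reducible?)") from exc
    if pi.min() < -1e-9 or np.max(np.abs(pi @ q)) > 1e-8 * max(1.0, np.abs(q).max()):
        raise DegenerateModelError("rate matrix has no unique stationary "
                                   "distribution (reducible?)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def normalize(raw: np.ndarray, frequencies: np.ndarray | None = None,
              is_reversible: bool = False, name: str = "") -> RateMatrix:
    """Scale a rate matrix to one expected substitution per time unit.

    The diagonal is recomputed so rows sum to zero, the stationary
    distribution is obtained (or validated) and all entries are divided by
    ``mu = -sum_x pi_x q_xx``.
    """
    q = np.array(raw, dtype=float)
    n = q.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    if q[off_mask].min() < 0:
        raise ValueError("negative off-diagonal rate")
    if not np.any(q[off_mask] > 0):
        raise DegenerateModelError("all-zero rate matrix")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if frequencies is None:
        pi = stationary_distribution(q)
    else:
        pi = np.asarray(frequencies, dtype=float)
        if np.max(np.abs(pi @ q)) > 1e-8 * max(1.0, np.abs(q).max()):
            raise ValueError("supplied frequencies are not stationary")
    mu = -float(np.dot(pi, np.diag(q)))
    if mu <= 0:
        raise DegenerateModelError("non-positive normalization factor")
    return RateMatrix(q / mu, pi, is_reversible=is_reversible, name=name)


def build_reversible(exchangeabilities: np.ndarray, frequencies: np.ndarray,
                     name: str = "") -> RateMatrix:
    """Reversible model from exchangeabilities ``R`` and frequencies ``pi``.

    ``q_xy = pi_y r_xy`` for ``x != y``; the result satisfies detailed
    balance by construction and is returned normalized.
    """
    r = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    if np.max(np.abs(r - r.T)) > 1e-12:
        raise ValueError("exchangeability matrix must be symmetric")
    if r[~np.eye(r.shape[0], dtype=bool)].min() < 0:
        raise ValueError("negative exchangeability")
    q = r * pi[None, :]
    np.fill_diagonal(q, 0.0)
    return normalize(q, frequencies=pi / pi.sum(), is_reversible=True, name=name)


def transition_probabilities(model: RateMatrix, t: float) -> TransitionMatrix:
    """``P(t) = expm(Q t)`` via eigendecomposition (scaling-squaring fallback).

    Imaginary parts and negative entries produced by round-off are discarded
    (and rows renormalized); magnitudes above 1e-6 abort, since they signal a
    genuine numerical failure rather than round-off.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return TransitionMatrix(np.eye(model.n_states), 0.0)
    es = model.eigensystem()
    if es.is_valid:
        p = (es.right_vectors * np.exp(es.eigenvalues * t)) @ es.inverse_vectors
        if np.max(np.abs(p.imag)) > 1e-6:
            raise FloatingPointError("eigendecomposition path numerically failed")
        p = p.real
    else:
        p = _expm_taylor_scaling_squaring(model.rates * t)
    if p.min() < -1e-6:
        raise FloatingPointError("transition probabilities significantly negative")
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return TransitionMatrix(p, float(t))


def _expm_taylor_scaling_squaring(a: np.ndarray,
                                  target_norm: float = 5e-4) -> np.ndarray:
    """Second-order Taylor expansion with scaling and squaring.

    Squaring depth k is chosen so that ``||A||_inf / 2^k <= target_norm``.
    The accumulated truncation error is about ``||A|| * target_norm^2 / 6``,
    so the default keeps the result within ~1e-6 of the exact exponential
    for the matrix norms seen in practice (||Q t|| up to ~10).
    """
    norm = np.linalg.norm(a, np.inf)
    k = 0 if norm <= target_norm else int(np.ceil(np.log2(norm / target_norm)))
    b = a / (2 ** k)
    p = np.eye(a.shape[0]) + b + 0.5 * (b @ b)
    for _ in range(k):
        p = p @ p
    return p


def free_parameter_count(model: RateMatrix, count_frequencies: bool = True) -> int:
    """Number of free parameters of the substitution matrix itself.

    A general model has all 380 off-diagonal rates free minus one overall
    scale: 379.  A reversible model has 190 exchangeabilities minus the
    scale (189) plus, when ``count_frequencies``, 19 free frequencies: 208.
    """
    n = model.n_states
    if model.is_reversible:
        k = n * (n - 1) // 2 - 1
        if count_frequencies:
            k += n - 1
        return k
    return n * (n - 1) - 1


def matrix_correlation(a: RateMatrix, b: RateMatrix) -> float:
    """Pearson correlation between the off-diagonal rates of two models."""
    x = a.off_diagonal()
    y = b.off_diagonal()
    tiny = 1e-14
    if np.std(x) <= tiny * max(1.0, np.abs(x).max()) or \
            np.std(y) <= tiny * max(1.0, np.abs(y).max()):
        raise ValueError("correlation undefined for zero-variance rate vector")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Matrix file I/O
# ---------------------------------------------------------------------------

def _tokens(path) -> list[str]:
    return Path(path).read_text().split()


def read_paml_dat(path, name: str = "") -> RateMatrix:
    """Read a reversible model from a PAML-style ``.dat`` file.

    Layout: 19 lower-triangle rows of exchangeabilities (190 values),
    followed by 20 frequencies, all whitespace-separated, amino acids in
    PAML order.  Anything after the frequencies (comments, literature
    references) is ignored.
    """
    toks = _tokens(path)
    vals = []
    for tok in toks:
        try:
            vals.append(float(tok))
        except ValueError:
            break  # trailing commentary
        if len(vals) == 210:
            break
    if len(vals) < 210:
        raise ValueError(f"{path}: expected 190 exchangeabilities + 20 "
                         f"frequencies, found {len(vals)} numbers")
    r = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            r[i, j] = r[j, i] = vals[k]
            k += 1
    pi = np.array(vals[190:210])
    return build_reversible(r, pi / pi.sum(),
                            name=name or Path(path).stem)


def read_rate_matrix(path, name: str = "") -> RateMatrix:
    """Read a general (nonreversible) model from a full-matrix file.

    Layout: 20 rows x 20 whitespace-separated rates (diagonal included, or
    recomputed when row sums deviate from zero by more than 1e-6), followed
    by an optional 20-value frequency line.  A supplied frequency line is
    checked against the computed stationary distribution (warning on
    disagreement beyond 1e-4); the computed distribution is authoritative.
    """
    vals = [float(t) for t in _tokens(path)]
    if len(vals) not in (400, 420):
        raise ValueError(f"{path}: expected 400 rates (+ optional 20 "
                         f"frequencies), found {len(vals)} numbers")
    q = np.array(vals[:400]).reshape(N_STATES, N_STATES)
    if np.max(np.abs(q.sum(axis=1))) > 1e-6:
        np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, 0.0)
    model = normalize(q, name=name or Path(path).stem)
    if len(vals) == 420:
        pi_file = np.array(vals[400:])
        if np.max(np.abs(pi_file / pi_file.sum() - model.frequencies)) > 1e-4:
            warnings.warn(f"{path}: frequency line disagrees with the "
                          "stationary distribution of the rates; using the "
                          "computed distribution")
    return model


def write_rate_matrix(model: RateMatrix, path) -> None:
    """Write a model as a full 20x20 matrix file plus a frequency line."""
    lines = [" ".join(f"{v:.10g}" for v in row) for row in model.rates]
    lines.append("")
    lines.append(" ".join(f"{v:.10g}" for v in model.frequencies))
    Path(path).write_text("\n".join(lines) + "\n")


def load_builtin(name: str) -> RateMatrix:
    """Load a bundled published reversible model (``LG``, ``WAG``, ``JTT``)."""
    key = name.upper()
    if key not in BUILTIN_MODELS:
        raise KeyError(f"unknown builtin model {name!r}; "
                       f"available: {', '.join(BUILTIN_MODELS)}")
    ref = importlib.resources.files("nonrev") / "matrices" / f"{key}.dat"
    with importlib.resources.as_file(ref) as p:
        return read_paml_dat(p, name=key)
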