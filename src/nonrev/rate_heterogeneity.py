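"""Among-site rate variation: discrete gamma (+G), invariant sites (+I),
and distribution-free rates (+R).

All models are represented by a small set of discrete rate categories with
weights, normalized so the mean rate is exactly 1 — branch lengths then
retain their meaning of expected substitutions per site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SiteRateModel",
    "UNIFORM_RATES",
    "discretize_gamma",
    "with_invariant",
    "free_rate",
    "parse_model_string",
    "DEFAULT_RATE_MODEL_NAMES",
]

#: Candidate set mirrored from common model-selection practice, with free-rate
#: models capped at four categories.
DEFAULT_RATE_MODEL_NAMES = ("", "+G4", "+I", "+I+G4", "+R2", "+R3", "+R4")


@dataclass(frozen=True)
class SiteRateModel:
    """Discrete site-rate distribution with mean rate one.

    ``kind`` is one of ``""`` (uniform), ``"G"``, ``"I"``, ``"I+G"``,
    ``"R<c>"``.  ``category_rates`` are non-decreasing; ``category_weights``
    sum to one; ``sum(w_i * r_i) == 1``.
    """

    kind: str
    category_rates: np.ndarray
    category_weights: np.ndarray
    gamma_shape: float | None = None
    p_invariant: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.category_rates, dtype=float)
        w = np.asarray(self.category_weights, dtype=float)
        if r.shape != w.shape or r.ndim != 1 or r.size < 1:
            raise ValueError("rates and weights must be equal-length vectors")
        if r.min() < 0 or w.min() < 0:
            raise ValueError("rates and weights must be non-negative")
        if np.any(np.diff(r) < 0):
            raise ValueError("category rates must be non-decreasing")
        if abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        if abs(float(r @ w) - 1.0) > 1e-10:
            raise ValueError("mean rate must be 1")
        object.__setattr__(self, "category_rates", r)
        object.__setattr__(self, "category_weights", w)

    @property
    def n_categories(self) -> int:
        return self.category_rates.size

    @property
    def n_free_params(self) -> int:
        """Free parameters: alpha for +G, p_inv for +I, 2c-2 for +Rc."""
        k = 0
        if "G" in self.kind:
            k += 1
        if "I" in self.kind:
            k += 1
        if self.kind.startswith("R"):
            k += 2 * self.n_categories - 2
        return k

    def label(self) -> str:
        if self.kind == "":
            return ""
        if self.kind == "I":
            return "+I"
        if self.kind == "G":
            return f"+G{self.n_categories}"
        if self.kind == "I+G":
            return f"+I+G{self.n_categories - 1}"
        return f"+R{self.n_categories}"


#: Single-category model: every site evolves at the same rate.
UNIFORM_RATES = SiteRateModel("", np.array([1.0]), np.array([1.0]))


def discretize_gamma(alpha: float, categories: int = 4) -> SiteRateModel:
    """Equal-weight discrete gamma model.

    Rates are gamma(alpha, alpha) bin means over the ``categories`` quantile
    bins, which makes the discretized mean exactly 1:
    ``r_k = c * [F_{alpha+1}(b_{k+1}) - F_{alpha+1}(b_k)]`` using the
    incomplete-gamma identity for the partial expectation.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    c = int(categories)
    if c < 1:
        raise ValueError("need at least one category")
    if c == 1:
        return SiteRateModel("G", np.array([1.0]), np.array([1.0]),
                             gamma_shape=float(alpha))
    edges = stats.gamma.ppf(np.linspace(0, 1, c + 1), a=alpha, scale=1 / alpha)
    # E[X; bin] / P(bin) with X ~ gamma(a, a): partial expectation is
    # F_{a+1}(edge) evaluated under shape a+1, same scale.
    cdf_hi = stats.gamma.cdf(edges[1:], a=alpha + 1, scale=1 / alpha)
    cdf_lo = stats.gamma.cdf(edges[:-1], a=alpha + 1, scale=1 / alpha)
    rates = c * (cdf_hi - cdf_lo)
    rates = rates / (rates.mean())  # exact mean-1 against round-off
    weights = np.full(c, 1.0 / c)
    return SiteRateModel("G", rates, weights, gamma_shape=float(alpha))


def with_invariant(base: SiteRateModel, p_inv: float) -> SiteRateModel:
    """Add an invariant (rate-0) category with weight ``p_inv``.

    The remaining categories are rescaled by ``1 / (1 - p_inv)`` so the
    overall mean rate stays 1.
    """
    if not 0 <= p_inv < 1:
        raise ValueError("p_invariant must lie in [0, 1)")
    if p_inv == 0:
        return base
    if base.category_rates[0] == 0:
        raise ValueError("base model already has an invariant category")
    rates = np.concatenate([[0.0], base.category_rates / (1.0 - p_inv)])
    weights = np.concatenate([[p_inv], base.category_weights * (1.0 - p_inv)])
    kind = "I" if base.kind == "" else f"I+{base.kind}"
    return SiteRateModel(kind, rates, weights, gamma_shape=base.gamma_shape,
                         p_invariant=float(p_inv))


def free_rate(rates, weights) -> SiteRateModel:
    """Distribution-free rate model: arbitrary positive rates and weights.

    Input is sorted by rate (weights permuted along) and rescaled to mean
    rate 1.
    """
    r = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.size < 2:
        raise ValueError("free-rate model needs at least two categories")
    if r.min() <= 0:
        raise ValueError("free rates must be positive")
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must form a probability vector")
    w = w / w.sum()
    order = np.argsort(r)
    r, w = r[order], w[order]
    r = r / float(r @ w)
    return SiteRateModel(f"R{r.size}", r, w)


_MODEL_RE = re.compile(
    r"^(?P<matrix>[^+]+)(?P<inv>\+I)?(?:\+(?P<kind>[GR])(?P<cats>\d+)?)?"
    r"(?:\{(?P<params>[^}]*)\})?$")


def parse_model_string(text: str) -> tuple[str, dict]:
    """Split an IQ-TREE-style model string like ``"LG+I+G4"``.

    Returns ``(matrix_name, spec)`` where ``spec`` has keys ``invariant``
    (bool), ``kind`` (``""``, ``"G"`` or ``"R"``) and ``categories``.
    """
    m = _MODEL_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse model string {text!r}")
    kind = m.group("kind") or ""
    cats = int(m.group("cats")) if m.group("cats") else (4 if kind else 1)
    return m.group("matrix"), {
        "invariant": bool(m.group("inv")),
        "kind": kind,
        "categories": cats,
    }
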