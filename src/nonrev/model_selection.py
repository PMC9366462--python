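"""Model-fit comparison with the Bayesian information criterion.

BIC = k ln(n) - 2 logL with n the number of alignment sites (columns).
Matrix parameters are counted only when the matrix was estimated from the
data under comparison; fixed published matrices contribute none.  Branch
lengths and site-rate parameters are always counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ModelFit", "bic", "bic_weights", "select_best", "comparison_table"]


def bic(logL: float, k: int, n: int) -> float:
    """Bayesian information criterion, ``k * ln(n) - 2 * logL``."""
    if n < 1:
        raise ValueError("sample size must be at least 1")
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return k * math.log(n) - 2.0 * logL


@dataclass(frozen=True)
class ModelFit:
    """One fitted candidate: name, log-likelihood, parameter count, BIC."""

    model_name: str
    log_likelihood: float
    n_free_params: int
    sample_size: int

    @property
    def bic(self) -> float:
        return bic(self.log_likelihood, self.n_free_params, self.sample_size)


def bic_weights(fits: list[ModelFit]) -> np.ndarray:
    """Normalized evidence weights ``exp(-dBIC/2) / sum(exp(-dBIC/2))``."""
    if not fits:
        raise ValueError("no fits given")
    b = np.array([f.bic for f in fits])
    d = b - b.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def select_best(fits: list[ModelFit]) -> ModelFit:
    """Minimum-BIC fit; ties broken by fewer parameters, then input order."""
    if not fits:
        raise ValueError("no fits given")
    return min(enumerate(fits),
               key=lambda kv: (kv[1].bic, kv[1].n_free_params, kv[0]))[1]


def comparison_table(fits_by_locus: dict[str, list[ModelFit]]) -> pd.DataFrame:
    """Long-format report: one row per (locus, candidate) with BIC and weight."""
    rows = []
    for locus, fits in fits_by_locus.items():
        weights = bic_weights(fits)
        best = select_best(fits)
        for fit, w in zip(fits, weights):
            rows.append({
                "locus": locus,
                "model": fit.model_name,
                "logL": fit.log_likelihood,
                "n_params": fit.n_free_params,
                "BIC": fit.bic,
                "BIC_weight": w,
                "best": fit.model_name == best.model_name,
            })
    return pd.DataFrame(rows)
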