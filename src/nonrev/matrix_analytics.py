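"""Departure-from-reversibility analytics for substitution matrices.

For a stationary model the probability flux from amino acid i to j is
``pi_i * q_ij``.  Detailed balance means the flux is the same in both
directions; the *net flux* ``|pi_i q_ij - pi_j q_ji|`` measures how far a
pair departs from reversibility, and is identically zero exactly for
reversible models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .substitution_model import RateMatrix

__all__ = ["net_flux", "normalized_net_flux", "flux_table", "vectorize"]


def net_flux(model: RateMatrix) -> np.ndarray:
    """``net_flux[i, j] = |pi_i q_ij - pi_j q_ji|``; symmetric, zero diagonal."""
    flux = model.frequencies[:, None] * model.rates
    out = np.abs(flux - flux.T)
    np.fill_diagonal(out, 0.0)
    return out


def normalized_net_flux(model: RateMatrix) -> np.ndarray:
    """Net flux scaled per pair: ``2 * net_flux_ij / (flux_ij + flux_ji)``.

    Values lie in [0, 2): 0 means the pair satisfies detailed balance, the
    upper limit is approached for one-way pairs.  Pairs with zero total
    flux are reported as 0.
    """
    flux = model.frequencies[:, None] * model.rates
    np.fill_diagonal(flux, 0.0)
    total = flux + flux.T
    nf = net_flux(model)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 2.0 * nf / np.where(total > 0, total, 1.0), 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def flux_table(model: RateMatrix) -> pd.DataFrame:
    """Per-pair flux report, sorted by net flux descending.

    Columns: pair, flux_ij, flux_ji, net_flux, normalized_net_flux — one
    row per unordered amino-acid pair (190 rows for 20 states).
    """
    labels = model.labels
    flux = model.frequencies[:, None] * model.rates
    nf = net_flux(model)
    nnf = normalized_net_flux(model)
    rows = []
    n = model.n_states
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({
                "pair": f"{labels[i]}{labels[j]}",
                "flux_ij": flux[i, j],
                "flux_ji": flux[j, i],
                "net_flux": nf[i, j],
                "normalized_net_flux": nnf[i, j],
            })
    return (pd.DataFrame(rows)
            .sort_values("net_flux", ascending=False, kind="mergesort")
            .reset_index(drop=True))


def vectorize(model: RateMatrix) -> np.ndarray:
    """Flatten a model to its off-diagonal rate vector (row-major), the
    representation used for matrix correlation and PCA-style comparisons."""
    return model.off_diagonal()
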