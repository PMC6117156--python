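"""Gaussian mixture fits of coupling distributions, selected by BIC.

Each position pair's distribution of mutant-cycle couplings is fit with a one-
and a two-component Gaussian mixture (EM, multiple restarts); the model with
the lower BIC = p ln n - 2 ln L is kept, with a parsimony tie-break toward one
component when the BIC difference is negligible.  The population-weighted mean
sum_k w_k mu_k of the selected mixture is the estimate of the native coupling
at that position pair; assembling weighted means over all pairs gives the
symmetric coupling matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture


@dataclass
class MixtureFit:
    """Selected Gaussian mixture for one coupling distribution."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: dict
    weighted_mean: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "bic": {str(k): v for k, v in self.bic.items()},
            "weighted_mean": self.weighted_mean,
            "n": self.n,
        }


def fit_gaussian_mixture(
    values,
    k_max: int = 2,
    n_restarts: int = 5,
    seed: int = 0,
    weight_floor: float = 0.02,
    bic_margin: float = 2.0,
    min_n: int = 20,
) -> MixtureFit:
    """Fit k = 1..k_max Gaussian mixtures and select by minimum BIC.

    Two-component fits whose smaller weight falls below ``weight_floor`` are
    treated as degenerate spikes and discarded; if the best multi-component
    model beats k = 1 by less than ``bic_margin`` BIC units, the single
    Gaussian wins (parsimony).  Deterministic given (values, seed).
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} values, got {len(x)}")
    fits, bics = {}, {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            tol=1e-6,
            max_iter=200,
            random_state=seed,
        )
        with warnings.catch_warnings():
            # a non-improving extra EM restart is routine, not a failure
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(x)
        if k > 1 and gm.weights_.min() < weight_floor:
            continue
        fits[k] = gm
        bics[k] = float(gm.bic(x))
    best_k = min(bics, key=bics.get)
    if best_k > 1 and bics[best_k] > bics.get(1, np.inf) - bic_margin:
        best_k = 1
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.reshape(-1)[order])
    return MixtureFit(
        n_components=best_k,
        weights=w,
        means=mu,
        sds=sd,
        bic=bics,
        weighted_mean=float(w @ mu),
        n=len(x),
    )


def fit_pair_mixtures(couplings, min_n: int = 20, seed: int = 0, **kwargs) -> dict:
    """Mixture fit per position pair from a long-format coupling table."""
    from .coupling import couplings_by_pair

    fits = {}
    for (i, j), vals in couplings_by_pair(couplings):
        if len(vals) >= min_n:
            fits[(i, j)] = fit_gaussian_mixture(vals, seed=seed, min_n=min_n, **kwargs)
    return fits


def coupling_matrix(fits: dict, n_positions: int) -> np.ndarray:
    """Symmetric matrix of population-weighted mean couplings (NaN = unfit)."""
    m = np.full((n_positions, n_positions), np.nan)
    for (i, j), fit in fits.items():
        m[i - 1, j - 1] = m[j - 1, i - 1] = fit.weighted_mean
    return m
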