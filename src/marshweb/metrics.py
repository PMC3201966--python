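"""Web-level summary statistics and degree-distribution model selection.

Implements the classic food-web descriptors — species richness ``S``,
potential links ``S^2``, observed links ``L_o``, linkage density
``d = L_o / S`` and directed connectance ``C = L_o / S^2`` — plus the
cumulative degree distribution ``P(k)`` (the fraction of species with
``k`` or more trophic links) and least-squares model selection among
the three distribution shapes standard in the food-web literature:

* exponential            ``P(k) = a * exp(-gamma * k)``
* power law              ``P(k) = a * k ** -gamma``
* truncated power law    ``P(k) = a * k ** -gamma * exp(-k / kx)``

Models are ranked by small-sample AICc computed from the Gaussian
residual likelihood of the nonlinear least-squares fit, with the
distinct observed ``k`` values as the regression observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .webio import FoodWeb

__all__ = [
    "WebMetrics",
    "DegreeDistributionFit",
    "basic_metrics",
    "generality_vulnerability",
    "cumulative_degree_distribution",
    "fit_degree_models",
]


@dataclass(frozen=True)
class WebMetrics:
    """Table-2-style summary for one web."""

    name: str
    S: int
    S2: int
    Lo: int
    d: float
    C: float

    def to_row(self) -> dict:
        return {"web": self.name, "S": self.S, "S2": self.S2,
                "Lo": self.Lo, "d": self.d, "C": self.C}


def basic_metrics(web: FoodWeb) -> WebMetrics:
    """Species, potential/observed links, linkage density, connectance."""
    S = web.n_species
    Lo = web.n_links
    return WebMetrics(name=web.name, S=S, S2=S * S, Lo=Lo,
                      d=Lo / S, C=Lo / (S * S))


def generality_vulnerability(web: FoodWeb) -> pd.DataFrame:
    """Per-species trophic generality (prey count) and vulnerability
    (predator count).

    ``G_i`` is the row sum of ``A`` and ``V_i`` the column sum; a
    diagonal entry contributes to both.  ``sum(G) == sum(V) == L_o``.
    """
    G = web.A.sum(axis=1).astype(int)
    V = web.A.sum(axis=0).astype(int)
    return pd.DataFrame({"label": list(web.labels), "G": G, "V": V})


def cumulative_degree_distribution(web: FoodWeb) -> pd.DataFrame:
    """Cumulative degree distribution: fraction of species with >= k links.

    Total degree is ``k_i = G_i + V_i`` (feeding links counted in both
    directions, diagonal twice since it is both a prey and a predator
    link of the same species).  The returned table has one row per
    distinct observed degree, in increasing ``k`` order, with ``P``
    non-increasing and ``P`` at the smallest observed ``k`` equal to 1.
    Isolated species (``k = 0``) are retained.
    """
    gv = generality_vulnerability(web)
    k = (gv["G"] + gv["V"]).to_numpy()
    S = web.n_species
    ks = np.unique(k)
    P = np.array([(k >= kk).sum() / S for kk in ks])
    return pd.DataFrame({"k": ks, "P": P})


# -- degree-distribution models ------------------------------------------

def _exponential(k, a, gamma):
    return a * np.exp(-gamma * k)


def _power_law(k, a, gamma):
    return a * np.power(k, -gamma)


def _truncated_power_law(k, a, gamma, kx):
    return a * np.power(k, -gamma) * np.exp(-k / kx)


_MODELS = {
    "exponential": (_exponential, 2),
    "power_law": (_power_law, 2),
    "truncated_power_law": (_truncated_power_law, 3),
}


@dataclass(frozen=True)
class DegreeDistributionFit:
    model: str
    gamma: float
    kx: float | None
    a: float
    r2: float
    aicc: float
    n_points: int
    delta_aic: float = 0.0

    def to_row(self) -> dict:
        return {"model": self.model, "gamma": self.gamma, "kx": self.kx,
                "r2": self.r2, "AICc": self.aicc, "deltaAIC": self.delta_aic,
                "n_points": self.n_points}


def _aicc(rss: float, n: int, k_shape: int) -> float:
    # K counts shape parameters plus 1 for the residual variance
    K = k_shape + 1
    if n <= K + 1:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def _warm_start(model: str, k: np.ndarray, P: np.ndarray) -> list[float]:
    logP = np.log(P)
    if model == "exponential":
        slope, intercept = np.polyfit(k, logP, 1)
        return [float(np.exp(intercept)), float(max(-slope, 1e-3))]
    slope, intercept = np.polyfit(np.log(k), logP, 1)
    gamma0 = float(max(-slope, 1e-3))
    a0 = float(np.exp(intercept))
    if model == "power_law":
        return [a0, gamma0]
    return [a0, gamma0, float(k.max())]


def fit_degree_models(dist: pd.DataFrame) -> list[DegreeDistributionFit]:
    """Fit the three candidate models to ``(k, P(k))`` and rank by AICc.

    Requires at least four distinct positive ``k`` values with ``P > 0``.
    A model whose optimiser fails to converge is excluded from the
    ranking with a warning.  The returned list is sorted ascending by
    AICc and carries each model's AICc difference to the best model.
    """
    k = np.asarray(dist["k"], dtype=float)
    P = np.asarray(dist["P"], dtype=float)
    keep = k > 0  # power laws undefined at k=0
    k, P = k[keep], P[keep]
    if len(np.unique(k)) < 4:
        raise ValueError("need >= 4 distinct positive k values to fit")
    if np.any(P <= 0):
        raise ValueError("P(k) must be positive")

    fits: list[DegreeDistributionFit] = []
    n = len(k)
    for name, (fn, k_shape) in _MODELS.items():
        p0 = _warm_start(name, k, P)
        # decaying-distribution family: amplitude and shape parameters >= 0
        lower = [0.0] * k_shape
        upper = [np.inf] * k_shape
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fn, k, P, p0=np.maximum(p0, 1e-8),
                                    bounds=(lower, upper), maxfev=20000)
            resid = P - fn(k, *popt)
            if not np.all(np.isfinite(resid)):
                raise RuntimeError("non-finite residuals")
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"degree model {name} failed to fit: {exc}")
            continue
        rss = float(resid @ resid)
        sst = float(((P - P.mean()) ** 2).sum())
        r2 = 1.0 - rss / sst if sst > 0 else 1.0
        fits.append(DegreeDistributionFit(
            model=name,
            a=float(popt[0]),
            gamma=float(popt[1]),
            kx=float(popt[2]) if name == "truncated_power_law" else None,
            r2=r2,
            aicc=_aicc(rss, n, k_shape),
            n_points=n,
        ))
    fits.sort(key=lambda f: f.aicc)
    if fits:
        best = fits[0].aicc
        fits = [DegreeDistributionFit(**{**f.__dict__, "delta_aic": f.aicc - best})
                for f in fits]
    return fits
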