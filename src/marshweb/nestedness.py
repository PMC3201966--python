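"""Nestedness temperature, Ce null ensembles, and relative nestedness.

A consumer x resource incidence matrix is *nested* when specialists
interact with subsets of the partners of generalists.  The matrix
temperature ``T`` (0-100) quantifies departure from perfect nestedness:
the matrix is packed (rows and columns sorted by marginal totals), an
isocline of perfect nestedness is drawn through the unit square at the
observed fill, and every "unexpected" cell — an absence on the filled
side of the isocline or a presence on the empty side — is charged the
squared distance to the isocline along the cell's 45-degree diagonal,
relative to the diagonal's full length.  T = 0 is perfectly nested,
T = 100 maximally disordered.

The isocline follows the standard temperature-calculator geometry:
with x running left-to-right and y top-to-bottom over the packed
matrix mapped onto the unit square, the boundary of the perfectly
nested region at fill ``phi`` is

    y(x) = 1 - (1 - (1 - x)**p) ** (1/p)

with the shape parameter ``p > 0`` chosen so the area under the curve
equals ``phi`` (p = 1 gives the anti-diagonal at fill 0.5).  The mean
squared scaled distance over all cells is divided by the maximum
attainable value 0.04145 and multiplied by 100.

Significance is assessed against the Ce null model: each null cell
(i, j) is occupied independently with probability equal to the mean of
row *i*'s and column *j*'s observed fill.  Nestedness is reported both
as ``N = (100 - T)/100`` and as relative nestedness
``n* = (N - Nbar)/Nbar`` against the null ensemble mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .webio import FoodWeb

__all__ = [
    "NestednessResult",
    "matrix_temperature",
    "ce_null_ensemble",
    "nestedness_analysis",
]

#: Maximum expected mean squared scaled diagonal distance; the classic
#: normalisation constant that maps maximal disorder to T = 100.
_U_MAX = 0.04145


def _as_matrix(web) -> np.ndarray:
    if isinstance(web, FoodWeb):
        return np.asarray(web.A, dtype=np.int8)
    M = np.asarray(web, dtype=np.int8)
    if M.ndim != 2:
        raise ValueError("expected a 2-D binary matrix")
    return M


def _pack(M: np.ndarray) -> np.ndarray:
    """Sort rows and columns by marginal totals, descending.

    Ties are broken by permutation-invariant secondary keys (the sum of
    the other axis's marginals over the line's presences, then the
    line's pattern under the other axis's preliminary order) so that T
    does not depend on the input ordering of species.
    """
    rs = M.sum(axis=1)
    cs = M.sum(axis=0)
    row_w = M @ cs  # presence-weighted column fill
    col_w = M.T @ rs
    pre_rows = np.lexsort((-row_w, -rs))
    pre_cols = np.lexsort((-col_w, -cs))
    # final tie-break: pattern as tuple under the other axis's preliminary order
    row_keys = [(-rs[i], -row_w[i], tuple(-M[i, pre_cols])) for i in range(M.shape[0])]
    col_keys = [(-cs[j], -col_w[j], tuple(-M[pre_rows, j])) for j in range(M.shape[1])]
    rorder = sorted(range(M.shape[0]), key=lambda i: row_keys[i])
    corder = sorted(range(M.shape[1]), key=lambda j: col_keys[j])
    return M[np.ix_(rorder, corder)]


# Gauss-Legendre nodes on [0, 1] for the isocline area integral
_GL_X, _GL_W = np.polynomial.legendre.leggauss(96)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _isocline_p(fill: float) -> float:
    """Shape parameter p such that the isocline encloses area ``fill``."""

    def area(p: float) -> float:
        return float(_GL_W @ _isocline_y(_GL_X, p))

    # area(p) is decreasing in p: area(1e-4) ~ 1, area(1e4) ~ 0
    return brentq(lambda p: area(p) - fill, 1e-4, 1e4, xtol=1e-10, rtol=1e-12)


def _isocline_y(x: np.ndarray, p: float) -> np.ndarray:
    base = 1.0 - np.clip(1.0 - x, 0.0, 1.0) ** p
    return 1.0 - np.clip(base, 0.0, 1.0) ** (1.0 / p)


def matrix_temperature(web) -> float:
    """Matrix temperature T in [0, 100] of a binary matrix or web.

    All-zero and all-one matrices are perfectly ordered by convention
    (T = 0, with a warning): the isocline is undefined at fill 0 or 1.
    """
    M = _as_matrix(web)
    n, m = M.shape
    fill = M.sum() / (n * m)
    if fill == 0.0 or fill == 1.0:
        warnings.warn("degenerate matrix (fill 0 or 1): T = 0 by convention")
        return 0.0
    M = _pack(M)
    p = _isocline_p(fill)

    # cell centres in the unit square; y runs downward from the top row
    x = (np.arange(m) + 0.5) / m
    y = (np.arange(n) + 0.5) / n
    X, Y = np.meshgrid(x, y)
    iso_at_x = _isocline_y(X, p)
    presence = M == 1
    unexpected = np.where(presence, Y > iso_at_x, Y < iso_at_x)
    if not unexpected.any():
        return 0.0

    # distance to the isocline along the cell's 45-degree diagonal y = x + c
    c = (Y - X)[unexpected]
    x0 = X[unexpected]
    x_iso = _diagonal_crossing(c, p)
    D = 1.0 - np.abs(c)  # diagonal length within the square, / sqrt(2)
    u = ((x0 - x_iso) / np.maximum(D, 1e-12)) ** 2
    T = 100.0 * u.sum() / (n * m) / _U_MAX
    return float(min(T, 100.0))


def _diagonal_crossing(c: np.ndarray, p: float) -> np.ndarray:
    """x-coordinate where the line y = x + c meets the isocline.

    ``g(x) = isocline(x) - x - c`` is strictly decreasing, so a
    vectorised bisection over all cells at once suffices.
    """
    lo = np.maximum(0.0, -c)
    hi = np.minimum(1.0, 1.0 - c)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = _isocline_y(mid, p) - mid - c
        lo = np.where(g > 0, mid, lo)
        hi = np.where(g > 0, hi, mid)
    return 0.5 * (lo + hi)


def ce_null_ensemble(web, replicates: int = 1000, seed: int | None = None
                     ) -> list[np.ndarray]:
    """Ce null matrices: cell (i, j) filled with probability equal to the
    mean of row i's and column j's observed fill.

    Reproducible from ``seed``; requires ``replicates >= 100`` for a
    stable tail estimate.
    """
    M = _as_matrix(web)
    if M.sum() == 0:
        raise ValueError("cannot build a null ensemble for an empty web")
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    n, m = M.shape
    row_fill = M.sum(axis=1) / m
    col_fill = M.sum(axis=0) / n
    P = (row_fill[:, None] + col_fill[None, :]) / 2.0
    rng = np.random.default_rng(seed)
    return [(rng.random((n, m)) < P).astype(np.int8) for _ in range(replicates)]


@dataclass(frozen=True)
class NestednessResult:
    name: str
    T: float
    N: float
    null_mean: float
    null_sd: float
    p_value: float
    n_star: float
    replicates: int
    seed: int | None

    def to_row(self) -> dict:
        return {"web": self.name, "T": self.T, "N": self.N,
                "null_mean": self.null_mean, "null_sd": self.null_sd,
                "p_value": self.p_value, "n_star": self.n_star,
                "replicates": self.replicates, "seed": self.seed}


def nestedness_analysis(web, replicates: int = 1000, seed: int | None = None
                        ) -> NestednessResult:
    """Temperature, Ce-null significance and relative nestedness.

    ``p`` is the pseudo-count tail probability that a null matrix is at
    least as nested (temperature <= observed):
    ``p = (1 + #{T_null <= T_obs}) / (replicates + 1)``.
    ``n* = (N - Nbar) / Nbar`` with ``N = (100 - T)/100``.
    """
    T_obs = matrix_temperature(web)
    nulls = ce_null_ensemble(web, replicates=replicates, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate nulls are fine in bulk
        T_null = np.array([matrix_temperature(Mn) for Mn in nulls])
    N_obs = (100.0 - T_obs) / 100.0
    N_null = (100.0 - T_null) / 100.0
    null_mean = float(N_null.mean())
    null_sd = float(N_null.std(ddof=1))
    p = (1 + int((T_null <= T_obs).sum())) / (replicates + 1)
    n_star = (N_obs - null_mean) / null_mean if null_mean > 0 else np.nan
    name = web.name if isinstance(web, FoodWeb) else "matrix"
    return NestednessResult(name=name, T=T_obs, N=N_obs, null_mean=null_mean,
                            null_sd=null_sd, p_value=p, n_star=float(n_star),
                            replicates=replicates, seed=seed)
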