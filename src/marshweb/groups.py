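"""Group (block) model for directed food webs: likelihood, AIC, and a
simulated-annealing search over partitions.

Species are partitioned into ``g`` groups; every ordered group pair
``(k, l)`` gets its own link probability, estimated by maximum
likelihood as ``p_kl = L_kl / N_kl`` where ``L_kl`` counts observed
links from consumers in group ``k`` to resources in group ``l`` and
``N_kl = n_k * n_l`` counts the potential ones (diagonal self-cells
included, consistent with connectance on ``S^2`` cells).  The model's
log-likelihood is the sum of independent Bernoulli terms

    sum_kl [ L_kl ln p_kl + (N_kl - L_kl) ln (1 - p_kl) ]

with ``0 ln 0 := 0``, and ``AIC = -2 loglik + 2 g^2`` (the block
probability matrix is the parameter set; group memberships are not
counted — an alternative convention adding ``S`` assignment terms is
available behind ``param_convention="g2+assign"``).

The partition search is a simulated annealing over single-species
moves with geometric cooling and multiple restarts, exposed both as a
scikit-learn-style clusterer (:class:`GroupBlockModel`) and as the
functional wrappers :func:`anneal_partition` / :func:`scan_group_sizes`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .webio import FoodWeb

__all__ = [
    "GroupModelResult",
    "group_loglik_aic",
    "GroupBlockModel",
    "anneal_partition",
    "scan_group_sizes",
]


@dataclass(frozen=True)
class GroupModelResult:
    partition: np.ndarray  # group index 1..g per species
    g: int
    p_kl: np.ndarray
    loglik: float
    n_params: int
    aic: float
    seed: int | None = None
    restarts: int = 1

    def to_rows(self, labels) -> pd.DataFrame:
        return pd.DataFrame({"label": list(labels), "group": self.partition})


def _block_counts(A: np.ndarray, z: np.ndarray, g: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Link counts L_kl and potential counts N_kl for 0-based labels z."""
    Z = np.zeros((A.shape[0], g))
    Z[np.arange(A.shape[0]), z] = 1.0
    L = Z.T @ A @ Z
    sizes = Z.sum(axis=0)
    N = np.outer(sizes, sizes)
    return L, N


def _loglik_from_counts(L: np.ndarray, N: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(N > 0, L / np.maximum(N, 1), 0.0)
        ll = xlogy(L, p) + xlogy(N - L, 1.0 - p)
    return float(ll.sum())


def group_loglik_aic(web: FoodWeb, partition,
                     param_convention: str = "g2") -> GroupModelResult:
    """Likelihood and AIC of a given partition.

    ``partition`` maps each species (in label order) to a group; any
    hashable labels are accepted and relabelled 1..g.  Empty groups are
    disallowed: g is the number of distinct labels present.
    """
    z_raw = np.asarray(partition)
    if z_raw.shape != (web.n_species,):
        raise ValueError("partition must assign every species to a group")
    uniq, z = np.unique(z_raw, return_inverse=True)
    g = len(uniq)
    A = np.asarray(web.A, dtype=float)
    L, N = _block_counts(A, z, g)
    ll = _loglik_from_counts(L, N)
    n_params = g * g if param_convention == "g2" else g * g + web.n_species
    aic = -2.0 * ll + 2.0 * n_params
    with np.errstate(invalid="ignore"):
        p_kl = np.where(N > 0, L / np.maximum(N, 1), 0.0)
    return GroupModelResult(partition=z + 1, g=g, p_kl=p_kl, loglik=ll,
                            n_params=n_params, aic=aic)


class GroupBlockModel:
    """Directed block-model clustering of a food web by annealed AIC search.

    Parameters
    ----------
    n_groups : int
        Number of groups ``g``.
    n_steps : int or None
        Annealing proposals per restart; default ``max(3000, 60 * S)``.
    cooling : float
        Geometric cooling factor applied per proposal.
    restarts : int
        Independent annealing runs; the best final state wins.
    init_temp : float or None
        Starting temperature; if None, calibrated so that roughly half
        of the uphill moves sampled from the initial state are accepted.
    polish : bool
        Run a strict-descent sweep phase (temperature zero) after
        annealing until no single-species move improves the AIC.
    param_convention : {"g2", "g2+assign"}
        AIC parameter count: the g x g block matrix alone, or with S
        extra membership terms.
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray — group index 1..g per species.
    aic_, loglik_, p_kl_ : fitted block model at the best partition.
    result_ : :class:`GroupModelResult`
    """

    def __init__(self, n_groups: int = 2, n_steps: int | None = None,
                 cooling: float = 0.995, restarts: int = 10,
                 init_temp: float | None = None, polish: bool = True,
                 param_convention: str = "g2",
                 random_state: int | None = None):
        self.n_groups = n_groups
        self.n_steps = n_steps
        self.cooling = cooling
        self.restarts = restarts
        self.init_temp = init_temp
        self.polish = polish
        self.param_convention = param_convention
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_groups", "n_steps", "cooling", "restarts", "init_temp",
            "polish", "param_convention", "random_state")}

    def set_params(self, **params) -> "GroupBlockModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None) -> "GroupBlockModel":
        if isinstance(X, FoodWeb):
            X = X.A
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        S = A.shape[0]
        g = self.n_groups
        if not 1 <= g <= S:
            raise ValueError(f"n_groups must be in [1, {S}]")
        rng = np.random.default_rng(self.random_state)
        n_steps = self.n_steps if self.n_steps is not None else max(3000, 60 * S)
        extra = S if self.param_convention == "g2+assign" else 0

        if g == 1:
            z = np.zeros(S, dtype=int)
            best = (self._aic(A, z, g, extra), z)
        else:
            best = None
            for _ in range(self.restarts):
                z = self._anneal_once(A, g, n_steps, extra, rng)
                aic = self._aic(A, z, g, extra)
                if best is None or aic < best[0]:
                    best = (aic, z)

        aic, z = best
        L, N = _block_counts(A, z, g)
        ll = _loglik_from_counts(L, N)
        with np.errstate(invalid="ignore"):
            p_kl = np.where(N > 0, L / np.maximum(N, 1), 0.0)
        self.labels_ = z + 1
        self.loglik_ = ll
        self.aic_ = -2.0 * ll + 2.0 * (g * g + extra)
        self.p_kl_ = p_kl
        self.result_ = GroupModelResult(
            partition=self.labels_, g=g, p_kl=p_kl, loglik=ll,
            n_params=g * g + extra, aic=self.aic_,
            seed=self.random_state, restarts=self.restarts)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    @staticmethod
    def _aic(A, z, g, extra) -> float:
        L, N = _block_counts(A, z, g)
        return -2.0 * _loglik_from_counts(L, N) + 2.0 * (g * g + extra)

    def _anneal_once(self, A, g, n_steps, extra, rng) -> np.ndarray:
        S = A.shape[0]
        # random init guaranteed to have no empty group
        z = np.concatenate([np.arange(g), rng.integers(0, g, S - g)])
        rng.shuffle(z)
        state = _MoveState(A, z, g)
        aic = -2.0 * state.loglik() + 2.0 * (g * g + extra)

        temp = self.init_temp
        if temp is None:
            temp = _calibrate_temperature(state, aic, extra, rng)
        best_aic, best_z = aic, z.copy()

        for _ in range(n_steps):
            s = int(rng.integers(S))
            a = state.z[s]
            if state.sizes[a] == 1:
                continue  # move would empty a group
            b = int(rng.integers(g - 1))
            if b >= a:
                b += 1
            state.move(s, b)
            new_aic = -2.0 * state.loglik() + 2.0 * (g * g + extra)
            delta = new_aic - aic
            if delta <= 0 or (temp > 0 and rng.random() < np.exp(-delta / temp)):
                aic = new_aic
                if aic < best_aic:
                    best_aic, best_z = aic, state.z.copy()
            else:
                state.move(s, a)  # revert
            temp *= self.cooling

        z = best_z
        if self.polish:
            z = _greedy_polish(A, z, g, extra)
        return z


def _calibrate_temperature(state: "_MoveState", aic0: float, extra: int,
                           rng: np.random.Generator) -> float:
    """Sample uphill move magnitudes from the initial state; pick the
    temperature at which the mean uphill move accepts with prob ~0.5."""
    g = state.g
    ups = []
    for _ in range(100):
        s = int(rng.integers(state.z.shape[0]))
        a = state.z[s]
        if state.sizes[a] == 1:
            continue
        b = int(rng.integers(g - 1))
        if b >= a:
            b += 1
        state.move(s, b)
        new_aic = -2.0 * state.loglik() + 2.0 * (g * g + extra)
        state.move(s, a)
        d = new_aic - aic0
        if d > 0:
            ups.append(d)
    if not ups:
        return 1.0
    return float(np.mean(ups) / np.log(2.0))


def _greedy_polish(A, z, g, extra) -> np.ndarray:
    """Best-improvement single-move descent to a local AIC optimum."""
    state = _MoveState(A, z.copy(), g)
    aic = -2.0 * state.loglik() + 2.0 * (g * g + extra)
    S = A.shape[0]
    improved = True
    while improved:
        improved = False
        for s in range(S):
            a = state.z[s]
            if state.sizes[a] == 1:
                continue
            best_b, best_aic = None, aic
            for b in range(g):
                if b == a:
                    continue
                state.move(s, b)
                cand = -2.0 * state.loglik() + 2.0 * (g * g + extra)
                if cand < best_aic - 1e-9:
                    best_b, best_aic = b, cand
                state.move(s, a)
            if best_b is not None:
                state.move(s, best_b)
                aic = best_aic
                improved = True
    return state.z


class _MoveState:
    """Incremental block-count bookkeeping for single-species moves."""

    def __init__(self, A: np.ndarray, z: np.ndarray, g: int):
        self.A = A
        self.z = z.astype(int)
        self.g = g
        Z = np.zeros((A.shape[0], g))
        Z[np.arange(A.shape[0]), self.z] = 1.0
        self.L = Z.T @ A @ Z
        self.sizes = Z.sum(axis=0)
        self.out_to = A @ Z     # links s -> group k (incl. self-cell)
        self.in_from = A.T @ Z  # links group k -> s

    def loglik(self) -> float:
        N = np.outer(self.sizes, self.sizes)
        return _loglik_from_counts(self.L, N)

    def move(self, s: int, b: int) -> None:
        a = self.z[s]
        if a == b:
            return
        A = self.A
        self_link = A[s, s]
        # remove s's row/column contributions from group a's blocks
        self.L[a, :] -= self.out_to[s]
        self.L[:, a] -= self.in_from[s]
        self.L[a, a] += self_link  # self-cell subtracted twice above
        # shift every species' group-resolved counts for s's column/row
        # (this includes s itself, re-homing the self-cell)
        col_s = A[:, s]
        row_s = A[s, :]
        self.out_to[:, a] -= col_s
        self.out_to[:, b] += col_s
        self.in_from[:, a] -= row_s
        self.in_from[:, b] += row_s
        self.z[s] = b
        # add s's row/column contributions to group b's blocks
        self.L[b, :] += self.out_to[s]
        self.L[:, b] += self.in_from[s]
        self.L[b, b] -= self_link  # self-cell added twice above
        self.sizes[a] -= 1
        self.sizes[b] += 1


def anneal_partition(web: FoodWeb, g: int, n_steps: int | None = None,
                     cooling: float = 0.995, restarts: int = 10,
                     seed: int | None = None,
                     param_convention: str = "g2") -> GroupModelResult:
    """Annealed search for the best g-group partition of a web."""
    model = GroupBlockModel(n_groups=g, n_steps=n_steps, cooling=cooling,
                            restarts=restarts, random_state=seed,
                            param_convention=param_convention).fit(web)
    return model.result_


def scan_group_sizes(web: FoodWeb, g_range, n_steps: int | None = None,
                     cooling: float = 0.995, restarts: int = 10,
                     seed: int | None = None,
                     param_convention: str = "g2"
                     ) -> tuple[int, pd.DataFrame, dict[int, GroupModelResult]]:
    """Run the annealed search for each g; best g minimises AIC."""
    g_list = list(g_range)
    rows = []
    results: dict[int, GroupModelResult] = {}
    ss = np.random.SeedSequence(seed)
    for g, child in zip(g_list, ss.spawn(len(g_list))):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        res = anneal_partition(web, g, n_steps=n_steps, cooling=cooling,
                               restarts=restarts, seed=sub_seed,
                               param_convention=param_convention)
        results[g] = res
        rows.append({"web": web.name, "g": g, "aic": res.aic,
                     "loglik": res.loglik, "seed": sub_seed})
    table = pd.DataFrame(rows)
    best_g = int(table.loc[table["aic"].idxmin(), "g"])
    return best_g, table, results
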