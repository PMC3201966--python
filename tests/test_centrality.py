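from collections import deque

import numpy as np
import pytest

from marshweb import FoodWeb, MinresCorePeriphery, centrality_suite, coreness_minres


# -- independent shortest-path oracle (BFS path counting) --------------------

def _bfs_paths(adj: list[list[int]], s: int):
    """Distances and shortest-path counts from source s."""
    n = len(adj)
    dist = [-1] * n
    sigma = [0] * n
    dist[s], sigma[s] = 0, 1
    order = []
    q = deque([s])
    while q:
        v = q.popleft()
        order.append(v)
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma, order


def oracle_betweenness_closeness(web: FoodWeb):
    """Brute-force pair-dependency accumulation on the symmetrized web."""
    n = web.n_species
    S = ((web.A + web.A.T) > 0).astype(int)
    np.fill_diagonal(S, 0)
    adj = [list(np.flatnonzero(S[i])) for i in range(n)]
    btw = np.zeros(n)
    cls = np.zeros(n)
    for s in range(n):
        dist, sigma, order = _bfs_paths(adj, s)
        # closeness: reachable-based (n_reach - 1) / sum distances
        reach = [d for d in dist if d > 0]
        cls[s] = (len(reach) / sum(reach)) if reach else 0.0
        # betweenness: fraction of s-t geodesics through v, summed
        delta = [0.0] * n
        for w in reversed(order):
            for v in adj[w]:
                if dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                btw[w] += delta[w]
    return btw / 2.0, cls  # each unordered pair visited from both ends


class TestCentralitySuite:
    def test_star_closed_forms(self, star_web):
        t = centrality_suite(star_web).table.set_index("label")
        assert t.loc["hub", "eigenvector"] == pytest.approx(1.0)
        for leaf in "abcd":
            assert t.loc[leaf, "eigenvector"] == pytest.approx(0.5, abs=1e-8)
            assert t.loc[leaf, "betweenness"] == 0.0
        assert t.loc["hub", "betweenness"] == pytest.approx(6.0)  # C(4,2)

    def test_path_graph_closeness(self):
        A = np.zeros((3, 3), int)
        A[0, 1] = A[1, 2] = 1
        t = centrality_suite(FoodWeb(("x", "y", "z"), A)).table.set_index("label")
        assert t.loc["y", "closeness"] == pytest.approx(1.0)
        assert t.loc["x", "closeness"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, random_web_factory, seed):
        web = random_web_factory(S=12, fill=0.25, seed=seed)
        if web.A.sum() == 0:
            pytest.skip("degenerate draw")
        res = centrality_suite(web)
        btw, cls = oracle_betweenness_closeness(web)
        np.testing.assert_allclose(res.table["betweenness"], btw, atol=1e-9)
        np.testing.assert_allclose(res.table["closeness"], cls, atol=1e-9)

    def test_eigenvector_matches_dense_eigensolver(self, random_web_factory):
        web = random_web_factory(S=25, fill=0.2, seed=3)
        S = ((web.A + web.A.T) > 0).astype(float)
        vals, vecs = np.linalg.eigh(S)
        lead = np.abs(vecs[:, np.argmax(vals)])
        lead /= lead.max()
        got = centrality_suite(web).table["eigenvector"].to_numpy()
        np.testing.assert_allclose(got, lead, atol=1e-7)

    def test_leaf_of_tree_has_zero_betweenness(self):
        # path a-b-c-d: ends are degree-1 tree leaves
        A = np.zeros((4, 4), int)
        A[0, 1] = A[1, 2] = A[2, 3] = 1
        t = centrality_suite(FoodWeb(tuple("abcd"), A)).table.set_index("label")
        assert t.loc["a", "betweenness"] == 0.0
        assert t.loc["d", "betweenness"] == 0.0

    def test_disconnected_web_flagged(self):
        A = np.zeros((4, 4), int)
        A[0, 1] = A[2, 3] = 1
        with pytest.warns(UserWarning, match="disconnected"):
            res = centrality_suite(FoodWeb(tuple("abcd"), A))
        assert not res.connected

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            centrality_suite(FoodWeb(tuple("ab"), np.zeros((2, 2), int)))


class TestCorePeriphery:
    @staticmethod
    def _ideal_web(n_core=5, n_peri=12):
        n = n_core + n_peri
        A = np.zeros((n, n), int)
        A[:n_core, :n_core] = 1
        np.fill_diagonal(A, 0)
        A[:n_core, n_core:] = 1  # core eats periphery; no peri-peri links
        return FoodWeb(tuple(f"s{i}" for i in range(n)), A), n_core

    def test_ideal_core_scores_above_periphery(self):
        web, n_core = self._ideal_web()
        res = coreness_minres(web)
        assert res.coreness[:n_core].min() > res.coreness[n_core:].max()
        assert res.converged
        assert -1 <= res.fit <= 1

    def test_permutation_equivariance(self):
        web, _ = self._ideal_web(4, 8)
        res = coreness_minres(web)
        rng = np.random.default_rng(0)
        perm = rng.permutation(web.n_species)
        web_p = FoodWeb(tuple(web.labels[i] for i in perm),
                        web.A[np.ix_(perm, perm)])
        res_p = coreness_minres(web_p)
        np.testing.assert_allclose(res_p.coreness, res.coreness[perm],
                                   atol=1e-6)

    def test_complete_graph_equal_coreness(self):
        n = 8
        A = np.ones((n, n), int)
        np.fill_diagonal(A, 0)
        res = coreness_minres(FoodWeb(tuple(f"s{i}" for i in range(n)), A))
        assert np.ptp(res.coreness) < 1e-4

    def test_objective_non_increasing_in_iterations(self, random_web_factory):
        web = random_web_factory(S=20, fill=0.25, seed=2)
        objs = [MinresCorePeriphery(max_iter=k, tol=0).fit(web).objective_
                for k in (1, 2, 5, 20, 100)]
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_sklearn_param_protocol(self):
        est = MinresCorePeriphery()
        est.set_params(max_iter=77)
        assert est.get_params()["max_iter"] == 77
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
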