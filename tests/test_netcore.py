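"""Network-core oracles: soft adjacency, topological overlap, distance,
branch cutting, eigengenes and module merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stagenet import netcore
from stagenet.iohub import ExpressionMatrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference implementation of the topological overlap."""
    n = len(a)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    w = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                w[i, j] = 1.0
                continue
            l = sum(a[i, d] * a[d, j] for d in range(n) if d not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            w[i, j] = (l + a[i, j]) / denom if denom != 0 else 0.0
    return w


def _sym_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def _frame(arr, prefix="g"):
    ids = [f"{prefix}{i}" for i in range(len(arr))]
    return pd.DataFrame(arr, index=ids, columns=ids)


class TestSoftAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.linspace(1, 5, 10)
        df = pd.DataFrame([x, 2 * x + 1], index=["a", "b"],
                          columns=[f"s{i}" for i in range(10)])
        adj = netcore.soft_adjacency(df, beta=7, log_transform=False)
        assert adj.loc["a", "b"] == pytest.approx(1.0)

    def test_negative_half_correlation_squared(self):
        rng = np.random.default_rng(0)
        # construct two profiles with Pearson r exactly -0.5
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        y = y - (x @ y / 200) * x  # orthogonalize
        y /= y.std()
        z = -0.5 * x + np.sqrt(1 - 0.25) * y
        df = pd.DataFrame([x, z], index=["a", "b"])
        adj = netcore.soft_adjacency(df, beta=2, log_transform=False)
        assert adj.loc["a", "b"] == pytest.approx(0.25, abs=1e-10)

    def test_matches_brute_force_pearson_power(self):
        rng = np.random.default_rng(1)
        arr = rng.exponential(10, size=(10, 16))
        em = ExpressionMatrix(
            pd.DataFrame(arr, index=[f"g{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(16)]),
            kind="fpkm",
        )
        adj = netcore.soft_adjacency(em, beta=6).to_numpy()
        log = np.log2(arr + 1)
        for i in range(10):
            for j in range(i + 1, 10):
                r = np.corrcoef(log[i], log[j])[0, 1]
                assert adj[i, j] == pytest.approx(abs(r) ** 6, abs=1e-12)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            netcore.soft_adjacency(pd.DataFrame(np.ones((3, 4))), beta=0.5)


class TestTopologicalOverlap:
    def test_isolated_connected_pair(self):
        a = _frame([[0, 1], [1, 0]])
        w = netcore.topological_overlap(a)
        assert w.iloc[0, 1] == pytest.approx(1.0)

    def test_complete_graph_all_one(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        w = netcore.topological_overlap(_frame(a)).to_numpy()
        assert np.allclose(w, 1.0)

    def test_isolated_pair_zero(self):
        a = _frame([[0.0, 0.0], [0.0, 0.0]])
        w = netcore.topological_overlap(a)
        assert w.iloc[0, 1] == 0.0
        assert w.iloc[0, 0] == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _sym_adjacency(rng, 20)
            w = netcore.topological_overlap(_frame(a)).to_numpy()
            assert np.max(np.abs(w - brute_force_tom(a))) <= 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        hnp.arrays(
            np.float64, (8, 8),
            elements=st.floats(0, 1, allow_nan=False),
        )
    )
    def test_bounds_and_symmetry_property(self, raw):
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        w = netcore.topological_overlap(_frame(a)).to_numpy()
        assert np.all(w >= 0) and np.all(w <= 1)
        assert np.allclose(w, w.T)

    def test_out_of_range_adjacency_rejected(self):
        with pytest.raises(ValueError, match="adjacency"):
            netcore.topological_overlap(_frame([[0, 2.0], [2.0, 0]]))


class TestTomDistance:
    def test_extremes_and_range(self):
        rng = np.random.default_rng(3)
        a = _sym_adjacency(rng, 15)
        w = netcore.topological_overlap(_frame(a))
        d = netcore.tom_distance(w).to_numpy()
        wn = w.to_numpy()
        off = ~np.eye(15, dtype=bool)
        assert np.allclose(d[off], 1.0 - wn[off])
        assert np.allclose(d, d.T)
        assert np.all((d >= 0) & (d <= 1))
        assert np.allclose(np.diag(d), 0.0)


class TestClusterAndCut:
    def _block_distance(self, sizes, within=0.1, between=0.9):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return _frame(d)

    def test_two_planted_blocks_recovered_exactly(self):
        dist = self._block_distance([50, 50])
        modules, labels = netcore.cluster_and_cut(dist, min_module_size=30)
        assert len(modules) == 2
        assert sorted(m.size for m in modules) == [50, 50]
        assert (labels != netcore.GREY).all()
        members = {frozenset(m.genes) for m in modules}
        assert frozenset(f"g{i}" for i in range(50)) in members

    def test_all_equal_distances_all_grey(self):
        n = 60
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        modules, labels = netcore.cluster_and_cut(_frame(d), min_module_size=10)
        assert modules == []
        assert (labels == netcore.GREY).all()

    def test_min_size_gate(self):
        dist = self._block_distance([50, 50])
        modules, labels = netcore.cluster_and_cut(dist, min_module_size=60)
        assert modules == []
        assert (labels == netcore.GREY).all()

    def test_fewer_genes_than_min_size_all_grey(self):
        dist = self._block_distance([10])
        modules, labels = netcore.cluster_and_cut(dist, min_module_size=30)
        assert modules == []
        assert (labels == netcore.GREY).all()


class TestModuleEigengene:
    def test_single_gene_module_is_standardized_profile(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=16)
        df = pd.DataFrame([x], index=["g0"], columns=[f"s{i}" for i in range(16)])
        eg, ve = netcore.module_eigengene(df)
        z = (x - x.mean()) / x.std()
        cos = np.dot(eg, z) / (np.linalg.norm(eg) * np.linalg.norm(z))
        assert cos == pytest.approx(1.0)
        assert ve == pytest.approx(1.0)

    def test_identical_genes_explain_all_variance(self):
        x = np.linspace(0, 5, 16)
        df = pd.DataFrame([x, x], index=["a", "b"],
                          columns=[f"s{i}" for i in range(16)])
        _, ve = netcore.module_eigengene(df)
        assert ve == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(30, 16))
        df = pd.DataFrame(arr, index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(16)])
        eg, ve = netcore.module_eigengene(df)
        z = (arr - arr.mean(1, keepdims=True)) / arr.std(1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)
        v = evecs[:, np.argmax(evals)]
        assert np.allclose(np.abs(eg), np.abs(v), atol=1e-8)
        assert ve == pytest.approx(evals.max() / evals.sum(), abs=1e-8)

    def test_sign_aligned_with_mean_profile(self, small_dataset):
        counts, fpkm, truth = small_dataset
        genes = truth.module_genes("planted1")
        log = netcore.log_expression(fpkm).loc[genes]
        eg, _ = netcore.module_eigengene(log)
        z = (log.to_numpy() - log.to_numpy().mean(1, keepdims=True))
        z /= z.std(1, keepdims=True)
        assert np.dot(eg, z.mean(axis=0)) > 0

    def test_constant_module_errors(self):
        df = pd.DataFrame([[1.0] * 8], index=["g0"],
                          columns=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="constant"):
            netcore.module_eigengene(df)


class TestMergeModules:
    def _correlated_modules(self, r_target, seed=6):
        """Two 10-gene modules whose eigengenes correlate ~ r_target."""
        rng = np.random.default_rng(seed)
        n = 16
        base = rng.normal(size=n)
        other = rng.normal(size=n)
        other -= (base @ other / (base @ base)) * base
        second = r_target * base + np.sqrt(1 - r_target**2) * other / other.std() * base.std()
        rows, ids = [], []
        for i in range(10):
            rows.append(base + rng.normal(0, 0.05, n))
            ids.append(f"a{i}")
        for i in range(10):
            rows.append(second + rng.normal(0, 0.05, n))
            ids.append(f"b{i}")
        df = pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(n)])
        mods = [
            netcore.Module("A", [f"a{i}" for i in range(10)]),
            netcore.Module("B", [f"b{i}" for i in range(10)]),
        ]
        return df, mods

    def test_high_correlation_merges(self):
        df, mods = self._correlated_modules(0.95)
        merged = netcore.merge_modules(mods, df, log_transform=False)
        assert len(merged) == 1
        assert merged[0].size == 20

    def test_below_threshold_unchanged(self):
        df, mods = self._correlated_modules(0.3)
        merged = netcore.merge_modules(mods, df, log_transform=False)
        assert len(merged) == 2

    def test_threshold_monotonicity(self):
        df, mods = self._correlated_modules(0.8)
        counts = []
        for thr in (0.5, 0.7, 0.9, 0.99):
            counts.append(
                len(netcore.merge_modules(mods, df, merge_threshold=thr,
                                          log_transform=False))
            )
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))

    def test_chain_merge_traces_iterative_procedure(self):
        # three modules A~B and B~C correlated, A~C weak: the documented
        # procedure merges the best pair first, recomputes, then re-tests
        rng = np.random.default_rng(7)
        n = 16
        b = rng.normal(size=n)
        noise1 = rng.normal(size=n)
        noise2 = rng.normal(size=n)
        a = 0.78 * b + 0.62 * (noise1 - (b @ noise1 / (b @ b)) * b) / noise1.std()
        c = 0.78 * b + 0.62 * (noise2 - (b @ noise2 / (b @ b)) * b) / noise2.std()
        rows, ids = [], []
        for name, prof in (("a", a), ("b", b), ("c", c)):
            for i in range(8):
                rows.append(prof + rng.normal(0, 0.02, n))
                ids.append(f"{name}{i}")
        df = pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(n)])
        mods = [
            netcore.Module("A", [f"a{i}" for i in range(8)]),
            netcore.Module("B", [f"b{i}" for i in range(8)]),
            netcore.Module("C", [f"c{i}" for i in range(8)]),
        ]
        merged = netcore.merge_modules(mods, df, log_transform=False)
        # trace oracle: step-by-step hand simulation of the same rule
        sim = [list(m.genes) for m in mods]
        while len(sim) > 1:
            egs = [netcore.module_eigengene(df.loc[g])[0] for g in sim]
            best, pair = -np.inf, None
            for i in range(len(sim)):
                for j in range(i + 1, len(sim)):
                    r = np.corrcoef(egs[i], egs[j])[0, 1]
                    if r > best:
                        best, pair = r, (i, j)
            if best <= 0.7:
                break
            i, j = pair
            sim = [g for k, g in enumerate(sim) if k not in (i, j)] + [
                sorted(sim[i] + sim[j])
            ]
        assert sorted(len(m.genes) for m in merged) == sorted(len(g) for g in sim)
        assert {frozenset(m.genes) for m in merged} == {frozenset(g) for g in sim}


class TestPickBeta:
    def test_modular_data_selects_moderate_beta(self, small_dataset):
        _, fpkm, _ = small_dataset
        beta = netcore.pick_beta(fpkm)
        assert beta <= 12

    def test_empty_candidates_error(self, small_dataset):
        _, fpkm, _ = small_dataset
        with pytest.raises(ValueError, match="candidate"):
            netcore.pick_beta(fpkm, candidates=())

    def test_fallback_when_unreachable(self, small_dataset):
        _, fpkm, _ = small_dataset
        beta = netcore.pick_beta(fpkm, candidates=(1,), r2_target=0.999)
        assert beta == 6.0
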