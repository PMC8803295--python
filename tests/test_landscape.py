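"""Geographic/environmental distances, PCA reduction, Mantel tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hybkit as hk
from hybkit.landscape import EnvTable, linearize_fst


def env_table(values, lats=None, lons=None):
    df = pd.DataFrame(values)
    df.index = [f"p{k}" for k in range(len(df))]
    n = len(df)
    lats = pd.Series(lats if lats is not None else np.zeros(n),
                     index=df.index)
    lons = pd.Series(lons if lons is not None else np.zeros(n),
                     index=df.index)
    return EnvTable(df.astype(float), lats, lons)


def sym(mat, labels=None):
    m = np.asarray(mat, dtype=float)
    labels = labels or [f"p{k}" for k in range(m.shape[0])]
    return pd.DataFrame(m, index=labels, columns=labels)


class TestGeoDistance:
    def test_identical_and_equator_degree(self):
        env = env_table({"v1": [0, 0, 0], "v2": [0, 1, 2]},
                        lats=[0, 0, 10], lons=[0, 1, 0])
        d = hk.geo_distance(env)
        assert d.iloc[0, 0] == 0.0
        assert d.iloc[0, 1] == pytest.approx(111.3, abs=0.3)

    def test_metric_properties(self):
        rng = np.random.default_rng(0)
        env = env_table({"v": np.zeros(10)},
                        lats=rng.uniform(-60, 60, 10),
                        lons=rng.uniform(-170, 170, 10))
        d = hk.geo_distance(env).to_numpy()
        assert np.allclose(d, d.T)
        for i, j, k in itertools.permutations(range(10), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_out_of_range_rejected(self):
        env = env_table({"v": [0, 0]}, lats=[95, 0], lons=[0, 0])
        with pytest.raises(ValueError, match="range"):
            hk.geo_distance(env)


class TestEnvDistance:
    def test_identity_covariance_equals_euclidean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        # decorrelate exactly so the covariance is the identity
        cov = np.cov(X, rowvar=False)
        X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
        env = env_table({f"v{k}": X[:, k] for k in range(3)})
        d = hk.env_distance(env).to_numpy()
        eu = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d, eu, atol=1e-8)

    def test_duplicated_variable_pseudo_inverse(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        envd = hk.env_distance(env_table({"a": x, "b": y, "c": y}))
        ref = hk.env_distance(env_table({"a": x, "b": y}))
        assert np.allclose(envd.to_numpy(), ref.to_numpy(), atol=1e-8)

    def test_identical_rows_zero_and_constant_dropped(self):
        env = env_table({"a": [1., 1., 2.], "b": [3., 3., 4.],
                         "const": [7., 7., 7.]})
        d = hk.env_distance(env)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestEnvPca:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        env = env_table({"a": x, "b": 2 * x + 1})
        reduced, frac = hk.env_pca_reduce(env, retain=1)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_threshold_semantics(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 3))
        cols = {f"v{k}": base[:, k % 3] + 0.05 * rng.normal(size=30)
                for k in range(9)}
        env = env_table(cols)
        reduced, frac = hk.env_pca_reduce(env, retain=0.955)
        k = reduced.data.shape[1]
        assert np.cumsum(frac)[-1] >= 0.955
        _, full = hk.env_pca_reduce(env, retain=9)
        assert np.cumsum(full)[k - 2] < 0.955   # k is the smallest such

    def test_retain_beyond_rank_rejected(self):
        x = np.arange(6.0)
        env = env_table({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            hk.env_pca_reduce(env, retain=2)


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(1, 5, size=(8, 8))
        d = sym((m + m.T) / 2)
        np.fill_diagonal(d.values, 0)
        r, p = hk.mantel(d, d, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(size=(4, 4))
        b = rng.uniform(size=(4, 4))
        d1 = sym((a + a.T) / 2)
        d2 = sym((b + b.T) / 2)
        np.fill_diagonal(d1.values, 0)
        np.fill_diagonal(d2.values, 0)
        r_obs, p = hk.mantel(d1, d2, exhaustive=True)

        def corr(x, y):
            iu = np.triu_indices(4, 1)
            return np.corrcoef(x[iu], y[iu])[0, 1]

        m1, m2 = d1.to_numpy(), d2.to_numpy()
        count = sum(corr(m1, m2[np.ix_(perm, perm)]) >= r_obs - 1e-12
                    for perm in map(list,
                                    itertools.permutations(range(4))))
        assert p == pytest.approx(count / 24)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(size=(6, 6))
        b = rng.uniform(size=(6, 6))
        d1 = sym((a + a.T) / 2)
        d2 = sym((b + b.T) / 2)
        np.fill_diagonal(d1.values, 0)
        np.fill_diagonal(d2.values, 0)
        r1, p1 = hk.mantel(d1, d2, n_perm=199, seed=1)
        r2, p2 = hk.mantel(d1, sym(3.0 * d2.to_numpy() + 1.0), n_perm=199,
                           seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == p2

    def test_constant_matrix_rejected(self):
        d = sym(1.0 - np.eye(5))
        with pytest.raises(ValueError, match="constant"):
            hk.mantel(d, d)


class TestPartialMantel:
    def make(self, seed, n=8):
        rng = np.random.default_rng(seed)
        mats = []
        for _ in range(3):
            m = rng.uniform(size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            mats.append(sym(d))
        return mats

    def test_control_equal_to_d2_gives_zero(self):
        d1, d2, _ = self.make(7)
        r, _ = hk.partial_mantel(d1, d2, d2.copy(), n_perm=99, seed=0)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_d1_equals_d2_gives_one(self):
        d1, _, c = self.make(8)
        r, p = hk.partial_mantel(d1, d1.copy(), c, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p <= 0.05

    def test_independent_control_close_to_simple(self):
        # with a control uncorrelated with both matrices, the partial r
        # tracks the simple r (checked in expectation over replicates)
        diffs = []
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            n = 10
            base = rng.uniform(size=(n, n))
            noise = rng.uniform(size=(n, n))
            ctrl = rng.uniform(size=(n, n))
            d1 = sym((base + base.T) / 2)
            d2 = sym((base + base.T) / 2 + 0.5 * (noise + noise.T))
            c = sym((ctrl + ctrl.T) / 2)
            for m in (d1, d2, c):
                np.fill_diagonal(m.values, 0)
            r_simple, _ = hk.mantel(d1, d2, n_perm=5, seed=0)
            r_part, _ = hk.partial_mantel(d1, d2, c, n_perm=5, seed=0)
            diffs.append(r_part - r_simple)
        assert abs(float(np.mean(diffs))) < 0.05

    def test_degenerate_control_rejected(self):
        d1, _, _ = self.make(9)
        with pytest.raises(ValueError, match="perfectly correlated"):
            hk.partial_mantel(d1, self.make(10)[0], d1.copy(), n_perm=9)


def test_linearized_fst():
    f = sym([[0, .2], [.2, 0]], labels=["a", "b"])
    out = linearize_fst(f)
    assert out.loc["a", "b"] == pytest.approx(0.25)
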