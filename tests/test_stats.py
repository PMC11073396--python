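from itertools import permutations

import numpy as np
import pandas as pd
import pytest
import skbio
import skbio.stats.distance as ssd
from scipy.spatial.distance import pdist, squareform

from assemblage.io_core import SampleMetadata
from assemblage.stats import (
    convergence_trend,
    env_distance,
    mantel,
    permanova,
    time_decay,
)


def _meta(ids, **cols):
    base = dict(sample_id=ids,
                lake=cols.get("lake", ["L1"] * len(ids)),
                day=cols.get("day", [3] * len(ids)),
                polymer=cols.get("polymer", ["PP"] * len(ids)),
                fraction=cols.get("fraction", ["plastisphere"] * len(ids)))
    return SampleMetadata(pd.DataFrame(base))


def _sim_matrix(ids, fn, days):
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            data[i, j] = data[j, i] = fn(abs(days[i] - days[j]))
    return skbio.DistanceMatrix(data, ids=ids)


class TestTimeDecay:
    def test_power_law_recovered_exactly(self):
        days = [1, 2, 4, 8, 16, 32]
        ids = [f"s{d}" for d in days]
        sim = _sim_matrix(ids, lambda dt: dt ** -0.2, days)
        meta = _meta(ids, day=days)
        fit = time_decay(sim, meta)[0]
        assert fit.slope == pytest.approx(-0.2, abs=1e-9)
        assert fit.turnover_rate == pytest.approx(0.2, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_similarity_zero_slope_zero_r2(self):
        days = [1, 2, 4, 8]
        ids = [f"s{d}" for d in days]
        sim = _sim_matrix(ids, lambda dt: 0.5, days)
        fit = time_decay(sim, _meta(ids, day=days))[0]
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_single_time_distance_errors(self):
        # zero-similarity pairs are excluded; every usable pair then shares
        # one time lag, so no regression is possible
        days = [0, 10, 20, 30]
        ids = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            m[i, j] = m[j, i] = 0.5
        with pytest.raises(ValueError):
            time_decay(skbio.DistanceMatrix(m, ids=ids), _meta(ids, day=days))

    def test_scaling_similarity_moves_intercept_only(self):
        days = [1, 2, 4, 8, 16]
        ids = [f"s{d}" for d in days]
        rng = np.random.default_rng(0)
        noise = {}
        def f(dt):
            if dt not in noise:
                noise[dt] = 0.5 * dt ** -0.3 * rng.uniform(0.9, 1.1)
            return noise[dt]
        sim1 = _sim_matrix(ids, f, days)
        sim2 = skbio.DistanceMatrix(sim1.data * 1.7, ids=ids)
        meta = _meta(ids, day=days)
        f1, f2 = time_decay(sim1, meta)[0], time_decay(sim2, meta)[0]
        assert f1.slope == pytest.approx(f2.slope, rel=1e-9)
        assert f2.intercept == pytest.approx(f1.intercept + np.log10(1.7), rel=1e-6)


class TestPermanova:
    @staticmethod
    def _random_dm(n, seed, dims=3):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, dims))
        return skbio.DistanceMatrix(squareform(pdist(pts)),
                                    ids=[f"s{i}" for i in range(n)])

    def test_r2_sums_to_one_with_interactions(self):
        dm = self._random_dm(24, 1)
        rng = np.random.default_rng(2)
        meta = _meta(list(dm.ids),
                     lake=list(rng.choice(["L1", "L2"], 24)),
                     day=list(rng.choice([3, 7, 15], 24)),
                     polymer=list(rng.choice(["PP", "PE"], 24)))
        tab = permanova(dm, meta, ["day", "lake", "polymer", "day:lake"],
                        n_permutations=99, seed=0)
        assert tab["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (tab["df"].iloc[:-1] >= 1).all()

    def test_exact_enumeration_matches_brute_force(self):
        dm = self._random_dm(4, 3)
        meta = _meta(list(dm.ids), lake=["g1", "g1", "g2", "g2"])
        tab = permanova(dm, meta, ["lake"], n_permutations=10_000, seed=0)

        def gower(d):
            a = -0.5 * d ** 2
            n = d.shape[0]
            j = np.eye(n) - 1 / n
            return j @ a @ j

        G = gower(dm.data)
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        H0 = np.full((4, 4), 0.25)

        def F(Gp):
            ss = np.trace((H - H0) @ Gp)
            ssr = np.trace((np.eye(4) - H) @ Gp)
            return ss / (ssr / 2)

        f_obs = F(G)
        hits = [F(G[np.ix_(p, p)]) >= f_obs - 1e-12
                for p in map(np.array, permutations(range(4)))]
        assert tab["p"].iloc[0] == pytest.approx(np.mean(hits))

    def test_scale_invariance(self):
        dm = self._random_dm(16, 5)
        rng = np.random.default_rng(6)
        meta = _meta(list(dm.ids), lake=list(rng.choice(["L1", "L2"], 16)))
        t1 = permanova(dm, meta, ["lake"], n_permutations=99, seed=1)
        dm2 = skbio.DistanceMatrix(dm.data * 2, ids=dm.ids)
        t2 = permanova(dm2, meta, ["lake"], n_permutations=99, seed=1)
        assert t1["F"].iloc[0] == pytest.approx(t2["F"].iloc[0])
        assert t1["R2"].iloc[0] == pytest.approx(t2["R2"].iloc[0])
        assert t1["p"].iloc[0] == t2["p"].iloc[0]

    def test_single_level_term_errors(self):
        dm = self._random_dm(8, 7)
        meta = _meta(list(dm.ids))
        with pytest.raises(ValueError, match="polymer"):
            permanova(dm, meta, ["polymer"], n_permutations=99, seed=0)

    def test_one_way_f_matches_skbio(self):
        dm = self._random_dm(14, 8)
        grouping = ["A"] * 7 + ["B"] * 7
        expected = ssd.permanova(dm, grouping=grouping, permutations=9)
        meta = _meta(list(dm.ids), lake=grouping)
        tab = permanova(dm, meta, ["lake"], n_permutations=99, seed=0)
        assert tab["F"].iloc[0] == pytest.approx(
            float(expected["test statistic"]), rel=1e-9)

    def test_strata_restricts_permutations(self):
        dm = self._random_dm(12, 9)
        rng = np.random.default_rng(10)
        meta = _meta(list(dm.ids),
                     lake=list(rng.choice(["L1", "L2"], 12)),
                     day=[3] * 6 + [7] * 6)
        tab = permanova(dm, meta, ["lake"], n_permutations=199, seed=0,
                        strata="day")
        assert 0 < tab["p"].iloc[0] <= 1


class TestMantel:
    @staticmethod
    def _dm(n, seed):
        rng = np.random.default_rng(seed)
        return skbio.DistanceMatrix(squareform(pdist(rng.normal(size=(n, 3)))),
                                    ids=[f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self):
        a = self._dm(12, 0)
        assert mantel(a, a, n_permutations=9).r == pytest.approx(1.0)

    def test_affine_invariance_pearson(self):
        a = self._dm(12, 1)
        b = skbio.DistanceMatrix(3 * a.data + 0.1 * (1 - np.eye(12)), ids=a.ids)
        assert mantel(a, b, n_permutations=9).r == pytest.approx(1.0)

    def test_r_equals_offdiagonal_correlation_oracle(self):
        a, b = self._dm(15, 2), self._dm(15, 3)
        iu = np.triu_indices(15, k=1)
        expected = np.corrcoef(a.data[iu], b.data[iu])[0, 1]
        assert mantel(a, b, n_permutations=9).r == pytest.approx(expected)
        sk_r = ssd.mantel(a, b, permutations=0)[0]
        assert mantel(a, b, n_permutations=9).r == pytest.approx(float(sk_r))

    def test_spearman_matches_offdiagonal_spearman(self):
        from scipy.stats import spearmanr
        a, b = self._dm(12, 4), self._dm(12, 5)
        iu = np.triu_indices(12, k=1)
        expected = spearmanr(a.data[iu], b.data[iu])[0]
        got = mantel(a, b, method="spearman", n_permutations=9).r
        assert got == pytest.approx(float(expected))

    def test_size_mismatch_errors(self):
        with pytest.raises(ValueError):
            mantel(self._dm(10, 6), self._dm(11, 7))

    def test_env_distance_lookup(self, tiny_study):
        _, meta, _, env, _ = tiny_study
        ids = meta.sample_ids[:6]
        dm = env_distance(env, ["T", "TN"], meta, ids)
        assert dm.shape == (6, 6)
        assert np.allclose(dm.data, dm.data.T)


class TestConvergenceTrend:
    def test_identical_communities_flat_zero(self):
        ids = [f"s{i}" for i in range(6)]
        data = np.zeros((6, 6))
        meta = _meta(ids, day=[3, 3, 30, 30, 60, 60],
                     polymer=["PP", "PE"] * 3)
        fits = convergence_trend(skbio.DistanceMatrix(data, ids=ids), meta)
        f = fits[0]
        assert f.slope == 0.0
        assert (f.per_day["mean_dissimilarity"] == 0).all()
        assert not f.convergent

    def test_decreasing_dissimilarity_is_convergent(self):
        ids = [f"s{i}" for i in range(6)]
        days = [3, 3, 30, 30, 60, 60]
        vals = {3: 0.9, 30: 0.5, 60: 0.2}
        n = len(ids)
        data = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if days[i] == days[j]:
                    data[i, j] = data[j, i] = vals[days[i]]
                else:
                    data[i, j] = data[j, i] = 0.95
        meta = _meta(ids, day=days, polymer=["PP", "PE"] * 3)
        f = convergence_trend(skbio.DistanceMatrix(data, ids=ids), meta)[0]
        assert f.convergent
        assert f.slope < 0
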