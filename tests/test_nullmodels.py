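from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from assemblage.io_core import AbundanceTable, SampleMetadata, patristic_distances
from assemblage.nullmodels import (
    NullConfig,
    PROCESSES,
    assembly_analysis,
    bmntd,
    bnti,
    classify_assembly,
    process_fractions,
    raup_crick_bray,
)
from assemblage.synthetic import generate_tree


class TestBmntd:
    def test_identical_communities_zero(self, tree3):
        assert bmntd(tree3, {"A": 3, "C": 1}, {"A": 3, "C": 1}) == 0.0

    def test_single_taxon_pair_equals_patristic(self, tree3):
        assert bmntd(tree3, {"A": 5}, {"C": 3}) == pytest.approx(4.0)

    def test_linear_in_branch_lengths(self, tree3):
        doubled = tree3.copy()
        for n in doubled.traverse(include_self=False):
            n.length *= 2
        x, y = {"A": 2, "B": 1}, {"B": 1, "C": 4}
        assert bmntd(doubled, x, y) == pytest.approx(2 * bmntd(tree3, x, y))

    def test_empty_community_rejected(self, tree3):
        with pytest.raises(ValueError):
            bmntd(tree3, {}, {"A": 1})

    @pytest.mark.parametrize("weighted", [True, False])
    def test_exhaustive_nearest_taxon_oracle(self, weighted):
        """All community pairs on a small tree vs a brute-force loop."""
        tree = generate_tree(5, seed=7)
        tips = [t.name for t in tree.tips()]
        dm = patristic_distances(tree)
        rng = np.random.default_rng(0)
        subsets = [s for s in chain.from_iterable(
            combinations(tips, k) for k in range(1, 6))]
        for sx in subsets:
            for sy in subsets:
                x = {t: int(rng.integers(1, 5)) for t in sx}
                y = {t: int(rng.integers(1, 5)) for t in sy}

                def directed(a, b):
                    wa = np.array(list(a.values()), dtype=float)
                    wa = wa / wa.sum() if weighted else np.full(len(a), 1 / len(a))
                    total = 0.0
                    for w, ta in zip(wa, a):
                        total += w * min(dm[ta, tb] for tb in b)
                    return total

                expected = 0.5 * (directed(x, y) + directed(y, x))
                got = bmntd(tree, x, y, abundance_weighted=weighted)
                assert got == pytest.approx(expected, rel=1e-9)


class TestBnti:
    def test_relabel_invariance(self):
        """Jointly renaming taxa (order-preserving) leaves betaNTI unchanged."""
        tree = generate_tree(12, seed=3)
        tips = [t.name for t in tree.tips()]
        x = {tips[0]: 4, tips[3]: 1, tips[5]: 2}
        y = {tips[1]: 3, tips[5]: 2, tips[9]: 1}
        cfg = NullConfig(n_null=199, seed=11)
        z1 = bnti(tree, x, y, cfg, pool_taxa=tips)
        renamed = tree.copy()
        mapping = {t: t.replace("ASV", "OTU") for t in tips}  # keeps sort order
        for tip in renamed.tips():
            tip.name = mapping[tip.name]
        z2 = bnti(renamed, {mapping[k]: v for k, v in x.items()},
                  {mapping[k]: v for k, v in y.items()}, cfg,
                  pool_taxa=[mapping[t] for t in tips])
        assert z1 == pytest.approx(z2)

    def test_zero_spread_null_flagged(self, tree3, caplog):
        # pool of the pair's union only; x == y == whole pool -> every
        # shuffle reproduces betaMNTD 0
        with caplog.at_level("WARNING"):
            z = bnti(tree3, {"A": 1, "B": 1, "C": 1}, {"A": 1, "B": 1, "C": 1},
                     NullConfig(n_null=99, seed=0))
        assert np.isnan(z)


class TestRaupCrick:
    @staticmethod
    def _pool_table():
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=(12, 6))
        counts[:, 0] = counts[:, 1]  # identical pair s0/s1
        counts[:3, 2] = 0
        return AbundanceTable([f"t{i}" for i in range(12)],
                              [f"s{i}" for i in range(6)], counts)

    def test_identical_pair_hits_lower_bound(self):
        table = self._pool_table()
        rc = raup_crick_bray(table, ("s0", "s1"), NullConfig(n_null=99, seed=2))
        assert rc == -1.0

    def test_opposed_dominance_hits_upper_bound(self):
        # both samples span the whole pool (null membership is forced) but
        # with opposing dominance; null fills follow the balanced pooled
        # abundance, so every null pair is far more similar than observed
        counts = np.array([
            [100, 1],
            [1, 100],
            [1, 1],
        ])
        table = AbundanceTable(["t1", "t2", "t3"], ["s1", "s2"], counts)
        rc = raup_crick_bray(table, ("s1", "s2"), NullConfig(n_null=99, seed=3))
        assert rc == 1.0

    def test_bounded(self):
        table = self._pool_table()
        rc = raup_crick_bray(table, ("s2", "s3"), NullConfig(n_null=99, seed=4))
        assert -1.0 <= rc <= 1.0


class TestClassification:
    @pytest.mark.parametrize("b, r, expected", [
        (-3.1, 0.2, "homogeneous_selection"),
        (2.5, -0.1, "heterogeneous_selection"),
        (0.4, 0.99, "dispersal_limitation"),
        (0.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.0, "drift"),
        # boundaries route to the stochastic / drift side (strict inequalities)
        (2.0, 0.0, "drift"),
        (-2.0, 0.0, "drift"),
        (0.0, 0.95, "drift"),
        (0.0, -0.95, "drift"),
        (2.0000001, 0.0, "heterogeneous_selection"),
        (0.0, 0.9500001, "dispersal_limitation"),
    ])
    def test_rule(self, b, r, expected):
        assert classify_assembly(b, r) == expected

    def test_total_on_grid(self):
        for b in np.linspace(-4, 4, 33):
            for r in np.linspace(-1, 1, 21):
                assert classify_assembly(b, r) in PROCESSES

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_assembly(np.nan, 0.0)


class TestProcessFractions:
    @staticmethod
    def _results(processes, lakes):
        n = len(processes)
        sids_i = [f"a{k}" for k in range(n)]
        sids_j = [f"b{k}" for k in range(n)]
        meta = SampleMetadata(pd.DataFrame(dict(
            sample_id=sids_i + sids_j, lake=lakes + lakes,
            day=[3] * (2 * n), polymer=["PP"] * (2 * n),
            fraction=["plastisphere"] * (2 * n))))
        res = pd.DataFrame(dict(sample_i=sids_i, sample_j=sids_j,
                                process=processes))
        return res, meta

    def test_all_one_process(self):
        res, meta = self._results(["homogeneous_selection"] * 10, ["L1"] * 10)
        out = process_fractions(res, meta, group_by=["lake"])
        row = out.iloc[0]
        assert row["homogeneous_selection"] == 1.0
        assert row["deterministic"] == 1.0
        assert row["homogenizing"] == 1.0

    def test_stochastic_share(self):
        res, meta = self._results(
            ["drift"] * 5 + ["dispersal_limitation"] * 5, ["L1"] * 10)
        out = process_fractions(res, meta, group_by=["lake"])
        row = out.iloc[0]
        assert row["stochastic"] == 1.0
        assert row["differentiating"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        procs = list(rng.choice(PROCESSES, size=40))
        lakes = list(rng.choice(["L1", "L2"], size=40))
        res, meta = self._results(procs, lakes)
        out = process_fractions(res, meta, group_by=["lake"])
        for _, row in out.iterrows():
            assert sum(row[p] for p in PROCESSES) == pytest.approx(1.0, abs=1e-12)


class TestAssemblyAnalysis:
    def test_tiny_end_to_end(self, tiny_study):
        table, meta, tree, _, _ = tiny_study
        cfg = NullConfig(n_null=99, seed=1)
        res = assembly_analysis(table, tree, meta, cfg,
                                pair_filter={"fraction": "plastisphere"})
        n_plast = (meta.frame["fraction"] == "plastisphere").sum()
        assert len(res) == n_plast * (n_plast - 1) // 2
        classified = res.dropna(subset=["process"])
        assert set(classified["process"]).issubset(set(PROCESSES))
        assert res["rc_bray"].between(-1, 1).all()

    def test_seeded_reproducibility(self, tiny_study):
        table, meta, tree, _, _ = tiny_study
        cfg = NullConfig(n_null=99, seed=7)
        r1 = assembly_analysis(table, tree, meta, cfg)
        r2 = assembly_analysis(table, tree, meta, cfg)
        pd.testing.assert_frame_equal(r1, r2)
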