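import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from guildflow import (
    AbundanceTable,
    CutParams,
    DistanceMatrix,
    FilterParams,
    GuildPartition,
    SampleMetadata,
    correlation_distance_matrix,
    cut_tree_to_guilds,
    filter_prevalent,
    guild_abundance,
    permanova,
    repeated_measures_correlation,
    ward_tree,
)
from guildflow.guilds import UndefinedCorrelationError
from guildflow.tables import TableError

from conftest import make_metadata


def brute_pseudo_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Independent pseudo-F via explicit pair sums (oracle)."""
    n = len(labels)
    d2 = d**2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in set(labels.tolist()):
        idx = np.where(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(set(labels.tolist()))
    denom = ss_within / (n - a)
    if denom == 0:
        return np.inf
    return ((ss_total - ss_within) / (a - 1)) / denom


class TestFilterPrevalent:
    def make(self, presence_counts, n_samples=10):
        values = np.zeros((len(presence_counts), n_samples))
        for i, c in enumerate(presence_counts):
            values[i, :c] = 1.0
        values = values / np.maximum(values.sum(axis=0), 1)
        return AbundanceTable(
            [f"f{i}" for i in range(len(presence_counts))],
            [f"s{j}" for j in range(n_samples)],
            values,
            "relative",
        )

    def test_rare_feature_dropped_boundary_kept(self):
        table = self.make([10, 1, 2])
        kept, report = filter_prevalent(table, FilterParams(0.20))
        assert kept.feature_ids == ["f0", "f2"]
        assert report.n_kept == 2 and report.n_total == 3

    def test_abundance_share_hand_value(self):
        # 5 features holding 50 abundance units; the kept ones hold 49
        units = np.array(
            [[24.0, 24.0], [0.25, 0.25], [0.25, 0.25], [0.5, 0.0], [0.0, 0.5]]
        )
        table = AbundanceTable(
            [f"f{i}" for i in range(5)], ["s0", "s1"],
            units / units.sum(axis=0), "relative",
        )
        kept, report = filter_prevalent(table, FilterParams(min_prevalence=1.0))
        assert kept.feature_ids == ["f0", "f1", "f2"]
        assert report.abundance_share == pytest.approx(49 / 50, abs=1e-12)

    def test_no_survivors_is_error(self):
        table = self.make([1, 1])
        with pytest.raises(TableError, match="no features"):
            filter_prevalent(table, FilterParams(0.5))


class TestRepeatedMeasuresCorrelation:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.subjects = np.repeat([f"S{i}" for i in range(4)], 5)
        self.x = rng.normal(size=20)

    def test_identity_and_antisymmetry(self):
        assert repeated_measures_correlation(self.x, self.x, self.subjects) == pytest.approx(1.0)
        assert repeated_measures_correlation(self.x, -self.x, self.subjects) == pytest.approx(-1.0)

    def test_single_subject_equals_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        subjects = np.array(["S0"] * 10)
        r = repeated_measures_correlation(x, y, subjects)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_between_subject_shift_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=20)
        r0 = repeated_measures_correlation(self.x, y, self.subjects)
        shifts = np.repeat([0.0, 10.0, -40.0, 7.0], 5)
        r1 = repeated_measures_correlation(self.x + shifts, y, self.subjects)
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_explicit_centering_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        xc = np.concatenate([g - g.mean() for g in self.x.reshape(4, 5)])
        yc = np.concatenate([g - g.mean() for g in y.reshape(4, 5)])
        oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert repeated_measures_correlation(self.x, y, self.subjects) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_constant_within_subject_is_undefined(self):
        x = np.repeat([1.0, 5.0, 3.0, 2.0], 5)  # varies between, not within
        with pytest.raises(UndefinedCorrelationError):
            repeated_measures_correlation(x, x, self.subjects)


class TestCorrelationDistanceMatrix:
    def test_matches_pairwise_oracle(self):
        meta = make_metadata(4, ["0", "2", "4"])
        rng = np.random.default_rng(5)
        table = AbundanceTable(
            [f"f{i}" for i in range(4)], meta.sample_ids,
            rng.uniform(0.01, 1, size=(4, 12)), "counts",
        )
        D = correlation_distance_matrix(
            AbundanceTable(table.feature_ids, table.sample_ids,
                           table.values / table.values.sum(axis=0), "relative"),
            meta,
        )
        subjects = meta.subjects_of(table.sample_ids)
        rel = table.values / table.values.sum(axis=0)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert D.values[i, j] == 0.0
                else:
                    r = repeated_measures_correlation(rel[i], rel[j], subjects)
                    assert D.values[i, j] == pytest.approx(1 - r, abs=1e-10)

    def test_perfect_pairs_hit_bounds(self):
        meta = make_metadata(3, ["0", "2", "4"])
        rng = np.random.default_rng(6)
        base = rng.normal(size=9)
        values = np.vstack([base, base, -base])
        table = AbundanceTable(["a", "b", "c"], meta.sample_ids, values - values.min() + 0.1, "counts")
        # co-varying pair -> distance 0; anti-varying -> 2 (no closure so signs survive)
        D = correlation_distance_matrix(
            AbundanceTable(table.feature_ids, table.sample_ids, table.values, "counts"), meta
        )
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert D.values[0, 2] == pytest.approx(2.0, abs=1e-10)

    def test_degenerate_feature_gets_unit_distance(self, caplog):
        meta = make_metadata(3, ["0", "2"])
        values = np.vstack([np.repeat([1.0, 2.0, 3.0], 2), np.arange(6.0) + 1])
        table = AbundanceTable(["flat", "ok"], meta.sample_ids, values, "counts")
        with caplog.at_level("WARNING"):
            D = correlation_distance_matrix(table, meta)
        assert D.values[0, 1] == pytest.approx(1.0)
        assert "zero variance" in caplog.text


class TestWardTree:
    def test_identical_pair_merges_first(self):
        d = np.array(
            [[0.0, 0.0, 5.0], [0.0, 0.0, 5.0], [5.0, 5.0, 0.0]]
        )
        tree = ward_tree(DistanceMatrix(["a", "b", "c"], d))
        assert set(tree.linkage[0, :2]) == {0.0, 1.0}
        assert tree.linkage[0, 2] == 0.0

    def test_matches_scipy_linkage_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.normal(size=(5, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            mine = ward_tree(DistanceMatrix([f"i{k}" for k in range(5)], d)).linkage
            theirs = linkage(squareform(d, checks=False), method="ward")
            np.testing.assert_allclose(mine, theirs, atol=1e-10)

    def test_exchangeable_items_have_flat_heights(self):
        n = 6
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = ward_tree(DistanceMatrix([f"i{k}" for k in range(n)], d))
        np.testing.assert_allclose(tree.linkage[:, 2], 2.0, atol=1e-10)


class TestPermanova:
    def test_single_group_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(d, np.zeros(4), 99, 0)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        pts = np.array([[0.0], [0.1], [10.0], [10.2]]) + rng.normal(0, 0.01, (4, 1))
        d = np.abs(pts - pts.T)
        labels = np.array([0, 0, 1, 1])
        res = permanova(d, labels, seed=0, exhaustive=True)
        f_obs = brute_pseudo_f(d, labels)
        hits, count = 0, 0
        for perm in set(itertools.permutations(labels.tolist())):
            count += 1
            hits += brute_pseudo_f(d, np.array(perm)) >= f_obs - 1e-12
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-10)
        assert res.p_value == pytest.approx(hits / count, abs=1e-12)
        # huge separation: only identity and its mirror reach F_obs -> p = 2/6
        assert res.p_value == pytest.approx(2 / 6, abs=1e-12)

    def test_random_p_in_unit_interval_and_plus_one_rule(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array([0] * 4 + [1] * 4)
        res = permanova(d, labels, n_permutations=99, seed=4)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_degenerate_strata_force_p_one(self):
        # labels constant within each subject: within-stratum shuffles change nothing
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.repeat([0, 0, 1, 1], 2)
        strata = np.repeat(["s1", "s2", "s3", "s4"], 2)
        res = permanova(d, labels, n_permutations=199, seed=1, strata=strata)
        assert res.p_value == pytest.approx(1.0)


class TestCutTree:
    def planted_distance(self, sizes, within=0.1, between=1.9, seed=0):
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        rng = np.random.default_rng(seed)
        d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
        noise = rng.uniform(0, 0.02, size=(n, n))
        d = d + (noise + noise.T) / 2
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix([f"i{k}" for k in range(n)], d), labels

    def test_two_planted_blocks_recovered(self):
        # unequal blocks so no permuted relabeling can reproduce the split
        D, labels = self.planted_distance([6, 4])
        tree = ward_tree(D)
        part = cut_tree_to_guilds(tree, D, CutParams(alpha=0.01, n_permutations=999, seed=0))
        found = part.labels_for(D.item_ids)
        assert part.n_guilds == 2
        assert len(set(zip(found.tolist(), labels.tolist()))) == 2

    def test_exchangeable_matrix_gives_one_guild(self):
        n = 10
        d = np.full((n, n), 1.0)
        np.fill_diagonal(d, 0.0)
        D = DistanceMatrix([f"i{k}" for k in range(n)], d)
        part = cut_tree_to_guilds(ward_tree(D), D, CutParams(alpha=0.001, n_permutations=199, seed=0))
        assert part.n_guilds == 1

    def test_two_items_form_one_guild(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        D = DistanceMatrix(["a", "b"], d)
        part = cut_tree_to_guilds(ward_tree(D), D, CutParams(seed=0))
        assert part.n_guilds == 1
        assert set(part.assignments.values()) == {1}

    def test_raising_alpha_never_merges_guilds(self):
        D, _ = self.planted_distance([4, 4, 4], within=0.4, between=1.2, seed=3)
        tree = ward_tree(D)
        counts = [
            cut_tree_to_guilds(tree, D, CutParams(alpha=a, n_permutations=199, seed=5)).n_guilds
            for a in (0.001, 0.01, 0.05, 0.2, 0.6)
        ]
        assert counts == sorted(counts)


class TestGuildAbundance:
    def test_conservation_and_identity(self, small_table):
        one = GuildPartition({f: 1 for f in small_table.feature_ids})
        total = guild_abundance(small_table, one)
        np.testing.assert_allclose(
            total.values[0], small_table.values.sum(axis=0), atol=1e-10
        )
        singletons = GuildPartition(
            {f: i + 1 for i, f in enumerate(small_table.feature_ids)}
        )
        same = guild_abundance(small_table, singletons)
        np.testing.assert_allclose(same.values, small_table.values, atol=1e-12)

    def test_two_guild_hand_sum(self):
        table = AbundanceTable(
            ["a", "b", "c"], ["s1", "s2"],
            np.array([[0.2, 0.1], [0.3, 0.4], [0.5, 0.5]]), "relative",
        )
        part = GuildPartition({"a": 1, "b": 1, "c": 2})
        out = guild_abundance(table, part)
        np.testing.assert_allclose(out.values, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)

    def test_partition_mismatch_rejected(self, small_table):
        with pytest.raises(ValueError, match="cover"):
            guild_abundance(small_table, GuildPartition({"F0": 1}))
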