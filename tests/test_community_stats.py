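"""Inferential layer: PERMANOVA, Kruskal-Wallis, ANCOM, standardization,
positional and depth-trend tests, and scale decay."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from skbio import DistanceMatrix

from halospat import synthetic_data as sd
from halospat.community_stats import (
    SCALE_CLASSES,
    ancom,
    distance_trend,
    group_alpha_test,
    pair_scale_label,
    permanova,
    position_test,
    replicate_dissimilarity,
    scale_decay,
    slice_standardize,
)
from halospat.diversity import bray_curtis


def kruskal_oracle(groups):
    """Rank-sum arithmetic with tie correction, written out by hand."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    correction = 1 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    return h / correction


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up, written out by hand."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def ancom_oracle(table, labels, alpha=0.05, pseudocount=1.0):
    """Full enumeration of pairwise log-ratio t-tests per taxon."""
    logs = np.log(table.to_numpy(float) + pseudocount)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    m = table.shape[1]
    w = np.zeros(m, dtype=int)
    for i in range(m):
        ps = []
        for j in range(m):
            if j == i:
                continue
            ratio = logs[:, i] - logs[:, j]
            gs = [ratio[labels == g] for g in uniq]
            if all(np.ptp(g) == 0 for g in gs) and np.ptp(ratio) == 0:
                ps.append(1.0)
            else:
                p = sps.ttest_ind(*gs, equal_var=True).pvalue
                if np.isnan(p):
                    p = 1.0 if np.isclose(gs[0].mean(), gs[1].mean()) else 0.0
                ps.append(p)
        w[i] = int((bh_adjust(ps) < alpha).sum())
    return w


class TestPermanova:
    def two_cluster_dm(self, n=6, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 0.1, (n, 2)),
                         rng.normal(sep, 0.1, (n, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series(["a"] * n + ["b"] * n, index=ids)
        return DistanceMatrix(d, ids=ids), labels

    def test_separated_clusters_reach_minimal_p(self):
        dm, labels = self.two_cluster_dm()
        res = permanova(dm, labels, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.pseudo_f > 100

    def test_deterministic_under_seed(self):
        dm, labels = self.two_cluster_dm(sep=1.0)
        a = permanova(dm, labels, n_perm=199, seed=3)
        b = permanova(dm, labels, n_perm=199, seed=3)
        assert (a.pseudo_f, a.p_value) == (b.pseudo_f, b.p_value)

    def test_duplicating_samples_does_not_reduce_pseudo_f(self):
        dm, labels = self.two_cluster_dm(n=4, sep=2.0, seed=5)
        res = permanova(dm, labels, n_perm=99, seed=0)
        d = dm.data
        dd = np.block([[d, d], [d, d]])
        ids = [f"x{i}" for i in range(len(dd))]
        dup_labels = pd.Series(list(labels) * 2, index=ids)
        dup = permanova(DistanceMatrix(dd, ids=ids), dup_labels,
                        n_perm=99, seed=0)
        assert dup.pseudo_f >= res.pseudo_f - 1e-9

    def test_singleton_group_rejected(self):
        dm, labels = self.two_cluster_dm(n=2)
        labels.iloc[0] = "c"
        with pytest.raises(ValueError, match="fewer than two"):
            permanova(dm, labels, n_perm=99)

    def test_too_few_permutations_rejected(self):
        dm, labels = self.two_cluster_dm()
        with pytest.raises(ValueError, match="n_perm"):
            permanova(dm, labels, n_perm=10)


class TestGroupAlphaTest:
    def test_identical_groups_give_p_one(self):
        h, p = group_alpha_test([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                                ["a"] * 3 + ["b"] * 3)
        assert p > 0.9

    def test_constant_values_are_degenerate(self):
        h, p = group_alpha_test([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_maximal_rank_separation_hand_value(self):
        values = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = ["a"] * 3 + ["b"] * 3
        h, _ = group_alpha_test(values, labels)
        assert h == pytest.approx(27 / 7)  # 3.857...
        assert h == pytest.approx(
            kruskal_oracle([np.array(values[:3]), np.array(values[3:])]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=12)
        labels = ["a", "b", "c"] * 4
        h1, p1 = group_alpha_test(values, labels)
        h2, p2 = group_alpha_test(np.exp(values), labels)
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.integers(0, 5, size=15).astype(float)
            labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
            if all(np.ptp(values[labels == g]) == 0 for g in "abc") and \
                    np.ptp(values) == 0:
                continue
            h, _ = group_alpha_test(values, labels)
            groups = [values[labels == g] for g in "abc"]
            assert h == pytest.approx(kruskal_oracle(groups), abs=1e-10)


class TestAncom:
    def test_w_bounded_by_taxa_minus_one(self, random_table):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_samples=10, n_taxa=6)
        labels = ["a"] * 5 + ["b"] * 5
        res = ancom(t, labels)
        assert (res["W"] <= 5).all() and (res["W"] >= 0).all()

    def test_spiked_taxon_attains_w_two_of_three(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 100, size=(12, 3))
        t = pd.DataFrame(base, columns=list("xyz"))
        t.loc[:5, "x"] *= 10  # group a has taxon x at 10x
        labels = ["a"] * 6 + ["b"] * 6
        res = ancom(t, labels)
        assert res.loc["x", "W"] == 2
        assert res.loc["x", "significant"]

    def test_exchangeable_null_rarely_flags(self):
        rng = np.random.default_rng(3)
        flags = 0
        for rep in range(20):
            probs = rng.dirichlet(np.ones(5))
            counts = np.stack([rng.multinomial(300, probs) for _ in range(12)])
            t = pd.DataFrame(counts + 1, columns=[f"t{j}" for j in range(5)])
            res = ancom(t, ["a"] * 6 + ["b"] * 6)
            flags += int(res["significant"].sum())
        assert flags <= 2

    def test_matches_brute_force_enumeration(self, random_table):
        rng = np.random.default_rng(4)
        for rep in range(20):
            n_taxa = int(rng.integers(3, 7))
            t = random_table(rng, n_samples=10, n_taxa=n_taxa)
            labels = np.array(["a"] * 5 + ["b"] * 5)
            res = ancom(t, labels)
            np.testing.assert_array_equal(
                res["W"].to_numpy(), ancom_oracle(t, labels))

    def test_fewer_than_two_taxa_rejected(self):
        t = pd.DataFrame({"only": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="two taxa"):
            ancom(t, ["a", "a", "b", "b"])


class TestSliceStandardize:
    def test_hand_example(self):
        rel = pd.DataFrame({"t": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        out = slice_standardize(rel, ["s1", "s1", "s1"])
        np.testing.assert_allclose(out["t"], [0.5, 1.0, 1.5])

    def test_constant_taxon_maps_to_one(self):
        rel = pd.DataFrame({"t": [0.2, 0.2, 0.2]})
        out = slice_standardize(rel, ["s1"] * 3)
        np.testing.assert_allclose(out["t"], 1.0)

    def test_absent_taxon_is_missing_not_infinite(self):
        rel = pd.DataFrame({"t": [0.0, 0.0], "u": [1.0, 1.0]})
        out = slice_standardize(rel, ["s1", "s1"])
        assert out["t"].isna().all()
        assert np.isfinite(out["u"]).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_within_slice_means_are_exactly_one(self, seed):
        rng = np.random.default_rng(seed)
        rel = pd.DataFrame(rng.dirichlet(np.ones(5), size=9))
        slices = rng.choice(["s1", "s2", "s3"], size=9)
        out = slice_standardize(rel, slices)
        for s in np.unique(slices):
            means = out[slices == s].mean()
            ok = means.notna()
            np.testing.assert_allclose(means[ok], 1.0, rtol=1e-12)


class TestPositionTest:
    def make_std(self, top, middle, n_slices=4):
        slices = [f"L{i}" for i in range(n_slices)]
        idx = [f"{s}-{p}" for s in slices for p in ("top", "middle")]
        values = []
        for i in range(n_slices):
            values += [top[i], middle[i]]
        std = pd.DataFrame({"t": values}, index=idx)
        positions = pd.Series([p for s in slices for p in ("top", "middle")],
                              index=idx)
        pairing = pd.Series([s for s in slices for _ in range(2)], index=idx)
        return std, positions, pairing

    def test_identical_positions_give_null_result(self):
        std, pos, pair = self.make_std([1.0, 1.2, 0.9, 1.1],
                                       [1.0, 1.2, 0.9, 1.1])
        res = position_test(std, pos, pair)
        row = res.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_constant_nonzero_difference_flagged_degenerate(self):
        std, pos, pair = self.make_std([2.0, 3.0, 1.5, 2.5],
                                       [1.0, 2.0, 0.5, 1.5])
        res = position_test(std, pos, pair)
        row = res.iloc[0]
        assert row["degenerate"]
        assert row["p"] == 0.0

    def test_insufficient_pairs_skipped_with_notice(self):
        std, pos, pair = self.make_std([1.0], [2.0], n_slices=1)
        res = position_test(std, pos, pair)
        assert np.isnan(res.iloc[0]["p"])
        assert "pairs" in res.iloc[0]["note"]

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(9)
        top = rng.normal(1.3, 0.2, size=6)
        mid = rng.normal(1.0, 0.2, size=6)
        std, pos, pair = self.make_std(top, mid, n_slices=6)
        res = position_test(std, pos, pair)
        t_ref, p_ref = sps.ttest_rel(top, mid)
        assert res.iloc[0]["t"] == pytest.approx(t_ref)
        assert res.iloc[0]["p"] == pytest.approx(p_ref)


class TestDistanceTrend:
    def test_monotone_abundance_has_rho_one(self):
        d = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        std = pd.DataFrame({"t": d * 2.0})
        (res,) = distance_trend(std, d)
        assert res.rho == pytest.approx(1.0)

    def test_constant_abundance_reported_missing(self):
        d = np.array([0.5, 1.0, 2.0, 3.0])
        std = pd.DataFrame({"t": np.ones(4)})
        (res,) = distance_trend(std, d)
        assert np.isnan(res.rho)

    def test_too_few_distinct_distances_rejected(self):
        std = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="distinct"):
            distance_trend(std, [1.0, 1.0, 2.0])

    def test_interior_peaked_taxon_smoothed_argmax_in_2_3_band(self, local_design):
        hits = 0
        for rep in range(10):
            meta = sd.generate_metadata(local_design, seed=rep)
            eff = sd.EffectSpec.intra_nodule_gradient(local_design.n_taxa)
            t, _ = sd.generate_counts(meta, eff, local_design, seed=300 + rep)
            rel = t.div(t.sum(axis=1), axis=0)
            std = slice_standardize(rel, meta["slice"])
            results = distance_trend(std, meta["distance_cm"],
                                     pairing=meta["slice"])
            strong_interior = results[1]  # taxon with the ~+310% preset
            argmax = strong_interior.curve.grid[
                np.nanargmax(strong_interior.curve.fitted)]
            hits += 2.0 <= argmax <= 3.0
        assert hits >= 9


class TestScaleDecay:
    def test_identical_samples_give_zero_everywhere(self, local_design):
        meta = sd.generate_metadata(local_design, seed=0)
        n = len(meta)
        dm = DistanceMatrix(np.zeros((n, n)), ids=list(meta.index))
        res = scale_decay(dm, meta)
        for cls, vals in res.classes.items():
            if len(vals):
                assert (vals == 0).all()
        assert (res.tests["p"] == 1.0).all()

    def test_single_class_pair_count(self):
        # n samples in one nodule-position class -> n(n-1)/2 pairs at 3 cm
        meta = pd.DataFrame({
            "region": ["R0"] * 4, "site": ["R0-S0"] * 4,
            "nodule": ["R0-S0-N0"] * 4, "position": ["top"] * 4,
        }, index=[f"s{i}" for i in range(4)])
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4),
                            ids=list(meta.index))
        res = scale_decay(dm, meta)
        assert len(res.classes["3 cm"]) == 6
        assert all(len(res.classes[c]) == 0 for c in SCALE_CLASSES[1:])

    def test_classes_partition_all_labeled_pairs(self, local_design):
        design = sd.DesignSpec(n_regions=2, sites_per_region=2,
                               nodules_per_site=2, slices_per_nodule=2)
        meta = sd.generate_metadata(design, seed=1)
        meta.loc[meta.index[0], "nodule"] = np.nan  # one incomplete sample
        eff = sd.EffectSpec.null(design.n_taxa)
        t, _ = sd.generate_counts(
            sd.generate_metadata(design, seed=1), eff, design, seed=2)
        dm = bray_curtis(t)
        res = scale_decay(dm, meta)
        n = len(meta)
        counted = sum(len(v) for v in res.classes.values())
        assert counted + res.n_excluded == n * (n - 1) // 2
        assert res.n_excluded == n - 1

    def test_pair_scale_label_matches_decay_classification(self, local_design):
        design = sd.DesignSpec(n_regions=2, sites_per_region=2,
                               nodules_per_site=2, slices_per_nodule=1)
        meta = sd.generate_metadata(design, seed=3)
        counts = {k: 0 for k in SCALE_CLASSES}
        for a, b in itertools.combinations(meta.index, 2):
            counts[pair_scale_label(meta.loc[a], meta.loc[b])] += 1
        n = len(meta)
        dm = DistanceMatrix(np.ones((n, n)) - np.eye(n), ids=list(meta.index))
        res = scale_decay(dm, meta)
        assert {k: len(v) for k, v in res.classes.items()} == counts


class TestReplicateDissimilarity:
    def test_identical_pairs_are_zero(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        mean, sd_ = replicate_dissimilarity(dm, [("a", "b")])
        assert mean == 0.0 and np.isnan(sd_)

    def test_mean_at_reported_noise_floor(self):
        d = np.zeros((6, 6))
        pairs = [("s0", "s1"), ("s2", "s3"), ("s4", "s5")]
        vals = [0.09, 0.105, 0.12]
        ids = [f"s{i}" for i in range(6)]
        for (a, b), v in zip(pairs, vals):
            i, j = ids.index(a), ids.index(b)
            d[i, j] = d[j, i] = v
        dm = DistanceMatrix(d, ids=ids)
        mean, sd_ = replicate_dissimilarity(dm, pairs)
        assert mean == pytest.approx(0.105)
        assert sd_ == pytest.approx(np.std(vals, ddof=1))

    def test_empty_pair_list_rejected(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        with pytest.raises(ValueError, match="pairs"):
            replicate_dissimilarity(dm, [])
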