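"""Regulatory potential, gene groups, KS inference, targets, distances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bindexpr.beta import (
    GeneGroups,
    RPConfig,
    direct_targets,
    distance_comparison,
    group_genes,
    ks_activating_repressive,
    regulatory_potential,
)
from bindexpr.core import GeneModel, GenomicInterval


def gene(gene_id, tss, chrom="chr1", strand="+"):
    return GeneModel(gene_id, chrom, strand, tss, tss + 2000, tss, tss + 2000)


def peak(chrom, midpoint, width=200, name=None):
    return GenomicInterval(chrom, max(0, midpoint - width // 2), midpoint + width // 2, name=name)


def expr_frame(rows):
    """rows: list of (gene_id, log2fc, pvalue)."""
    return pd.DataFrame(
        {
            "log2fc": [r[1] for r in rows],
            "pvalue": [r[2] for r in rows],
            "padj": [r[2] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="gene_id"),
    )


def rp_brute_force(peaks, genes, cfg):
    """Naive all-pairs evaluation of the distance-decay sum."""
    per_gene = {}
    for g in genes:
        s, k = 0.0, 0
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            d = abs(p.midpoint - g.tss)
            if d <= cfg.window:
                k += 1
                s += math.exp(-(cfg.offset + cfg.scale * d / cfg.window))
        prev = per_gene.get(g.gene_id)
        if prev is None or s > prev[0]:
            per_gene[g.gene_id] = (s, k)
    return per_gene


class TestRegulatoryPotential:
    def test_peak_at_tss_scores_e_to_minus_half(self):
        rp = regulatory_potential([peak("chr1", 50_000)], [gene("g1", 50_000)])
        assert rp.loc["g1", "score"] == pytest.approx(math.exp(-0.5), abs=1e-9)
        assert rp.loc["g1", "score"] == pytest.approx(0.606531, abs=1e-6)

    def test_no_peak_in_window_scores_zero(self):
        rp = regulatory_potential([peak("chr2", 1000)], [gene("g1", 50_000)])
        assert rp.loc["g1", "score"] == 0.0 and rp.loc["g1", "k"] == 0

    def test_ten_and_fifty_kb_peaks(self):
        # Delta = 0.1 (10 kb) and 0.5 (50 kb): e^-0.9 + e^-2.5
        rp = regulatory_potential(
            [peak("chr1", 210_000), peak("chr1", 250_000)], [gene("g1", 200_000)]
        )
        assert rp.loc["g1", "score"] == pytest.approx(
            math.exp(-0.9) + math.exp(-2.5), rel=1e-12
        )
        assert rp.loc["g1", "score"] == pytest.approx(0.4886546583644979, abs=1e-6)

    def test_window_boundary_closed_at_100kb(self):
        inside = regulatory_potential([peak("chr1", 300_000)], [gene("g1", 200_000)])
        assert inside.loc["g1", "k"] == 1
        assert inside.loc["g1", "score"] == pytest.approx(math.exp(-4.5), rel=1e-12)
        outside = regulatory_potential(
            [GenomicInterval("chr1", 300_001, 300_002)], [gene("g1", 200_000)]
        )
        assert outside.loc["g1", "k"] == 0

    def test_score_zero_iff_no_peaks(self):
        rp = regulatory_potential(
            [peak("chr1", 10_000)], [gene("g1", 10_000), gene("g2", 500_000)]
        )
        assert (rp["score"] == 0) [rp["k"] == 0].all()
        assert (rp["score"] > 0)[rp["k"] > 0].all()

    def test_additivity_of_identical_distances(self):
        peaks = [peak("chr1", 60_000, name=f"p{i}") for i in range(7)]
        rp = regulatory_potential(peaks, [gene("g1", 50_000)])
        single = regulatory_potential(peaks[:1], [gene("g1", 50_000)])
        assert rp.loc["g1", "score"] == pytest.approx(7 * single.loc["g1", "score"], rel=1e-12)

    def test_monotone_under_added_peaks(self, rng):
        genes = [gene(f"g{i}", int(rng.integers(0, 2_000_000))) for i in range(30)]
        peaks = [peak("chr1", int(rng.integers(0, 2_000_000))) for _ in range(50)]
        base = regulatory_potential(peaks, genes)["score"]
        more = regulatory_potential(peaks + [peak("chr1", 1_000_000)], genes)["score"]
        assert (more >= base - 1e-15).all()
        # adding a peak beyond every window changes nothing
        far = regulatory_potential(peaks + [peak("chr9", 5)], genes)["score"]
        np.testing.assert_allclose(far, base, rtol=0, atol=0)

    def test_matches_brute_force_on_random_instances(self, rng):
        cfg = RPConfig()
        genes = [
            gene(f"g{i:03d}", int(rng.integers(0, 3_000_000)), chrom=f"chr{rng.integers(1, 3)}")
            for i in range(200)
        ]
        peaks = [
            peak(f"chr{rng.integers(1, 3)}", int(rng.integers(0, 3_000_000)))
            for _ in range(500)
        ]
        rp = regulatory_potential(peaks, genes, cfg)
        oracle = rp_brute_force(peaks, genes, cfg)
        for gid, (s, k) in oracle.items():
            assert rp.loc[gid, "k"] == k
            assert rp.loc[gid, "score"] == pytest.approx(s, rel=1e-12, abs=1e-15)

    def test_multi_transcript_gene_takes_best_tss(self):
        transcripts = [gene("g1", 50_000), gene("g1", 500_000)]
        rp = regulatory_potential([peak("chr1", 50_000)], transcripts)
        assert rp.loc["g1", "score"] == pytest.approx(math.exp(-0.5))
        assert len(rp) == 1

    def test_rank_descending_with_gene_id_ties(self):
        genes = [gene("gB", 10_000), gene("gA", 30_000), gene("gC", 500_000)]
        rp = regulatory_potential([peak("chr1", 20_000)], genes)
        # gA and gB are equidistant: tie broken lexicographically
        assert rp.loc["gA", "rank"] == 1 and rp.loc["gB", "rank"] == 2
        assert rp.loc["gC", "rank"] == 3


class TestGroupGenes:
    def test_fewer_significant_than_da(self):
        # 30 genes moved up, the rest flat at zero: |up| = 30 < da
        rows = [(f"u{i}", 1.0, 1e-5) for i in range(30)] + [
            (f"s{i}", 0.0, 0.5) for i in range(100)
        ]
        groups = group_genes(expr_frame(rows), RPConfig(da=500))
        assert sorted(groups.up) == sorted(f"u{i}" for i in range(30))
        assert groups.down == []
        assert len(groups.static) == 100
        # a min_abs_lfc filter likewise keeps weak movers out of the groups
        rows.append(("w1", 0.2, 0.4))
        groups = group_genes(expr_frame(rows), RPConfig(da=500), min_abs_lfc=0.5)
        assert "w1" not in groups.up and "w1" in groups.static

    def test_da_caps_group_at_most_significant(self):
        rows = [(f"u{i:03d}", 2.0, (i + 1) * 1e-6) for i in range(800)] + [
            (f"s{i}", 0.0, 0.9) for i in range(50)
        ]
        groups = group_genes(expr_frame(rows), RPConfig(da=500))
        assert len(groups.up) == 500
        assert set(groups.up) == {f"u{i:03d}" for i in range(500)}  # smallest p kept

    def test_static_excludes_near_significant(self):
        rows = [("a", 1.0, 1e-9), ("b", -1.0, 1e-9), ("c", 0.3, 0.05), ("d", 0.0, 0.9)]
        groups = group_genes(expr_frame(rows), RPConfig(da=1), static_p_floor=0.1)
        assert groups.static == ["d"]  # c is near-significant, in no group

    def test_empty_static_background_is_an_error(self):
        rows = [("a", 1.0, 1e-9), ("b", -1.0, 1e-9)]
        with pytest.raises(ValueError, match="static"):
            group_genes(expr_frame(rows), RPConfig(da=5))

    def test_groups_disjoint_invariant(self):
        with pytest.raises(ValueError, match="disjoint"):
            GeneGroups(up=["a"], down=["a"], static=["b"])


def rp_frame(scores):
    df = pd.DataFrame(
        {"score": list(scores.values()), "k": [1 if s > 0 else 0 for s in scores.values()]},
        index=pd.Index(list(scores), name="gene_id"),
    )
    order = df.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = pd.Series(np.arange(1, len(df) + 1), index=order.index)
    return df


class TestKS:
    def test_identical_distributions_give_d_zero_p_one(self):
        static_vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        scores = {f"u{i}": v for i, v in enumerate(static_vals)}
        scores.update({f"s{i}": v for i, v in enumerate(static_vals)})
        groups = GeneGroups(
            up=[f"u{i}" for i in range(5)], down=[], static=[f"s{i}" for i in range(5)]
        )
        res = ks_activating_repressive(rp_frame(scores), groups)
        assert res.stats["up"]["D"] == 0.0
        assert res.stats["up"]["p"] == pytest.approx(1.0)

    def test_shifted_group_matches_permutation_oracle(self, rng):
        """Group scores = static + 1: the one-sided KS p is < 1e-3 and a
        10,000-permutation oracle of the one-sided D statistic agrees."""
        static_vals = rng.uniform(0, 1, 100)
        up_vals = static_vals + 1.0
        scores = {f"u{i}": v for i, v in enumerate(up_vals)}
        scores.update({f"s{i}": v for i, v in enumerate(static_vals)})
        groups = GeneGroups(
            up=[f"u{i}" for i in range(100)], down=[], static=[f"s{i}" for i in range(100)]
        )
        res = ks_activating_repressive(rp_frame(scores), groups)
        assert res.stats["up"]["p"] < 1e-3

        def d_minus(a, b):  # one-sided statistic: sup(F_b - F_a)
            return stats.ks_2samp(a, b, alternative="less").statistic

        observed = d_minus(up_vals, static_vals)
        pooled = np.concatenate([up_vals, static_vals])
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if d_minus(pooled[:100], pooled[100:]) >= observed:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert p_perm < 1e-3

    def test_swapping_group_and_static_flips_alternative(self, rng):
        a = rng.normal(1, 1, 80)
        b = rng.normal(0, 1, 80)
        p_fwd = stats.ks_2samp(a, b, alternative="less", method="asymp").pvalue
        p_rev = stats.ks_2samp(b, a, alternative="greater", method="asymp").pvalue
        assert p_fwd == pytest.approx(p_rev)

    def test_small_group_not_applicable(self):
        scores = {"u1": 1.0, "u2": 0.5, "s1": 0.1, "s2": 0.2, "s3": 0.3}
        groups = GeneGroups(up=["u1", "u2"], down=[], static=["s1", "s2", "s3"])
        res = ks_activating_repressive(rp_frame(scores), groups)
        assert np.isnan(res.stats["up"]["p"])

    def test_cumulative_curves_nondecreasing_to_one(self, rng):
        scores = {f"g{i}": float(rng.uniform(0, 1)) for i in range(60)}
        ids = list(scores)
        groups = GeneGroups(up=ids[:20], down=ids[20:40], static=ids[40:])
        res = ks_activating_repressive(rp_frame(scores), groups)
        for col in ("up", "down", "static"):
            curve = res.curves[col].to_numpy()
            assert (np.diff(curve) >= 0).all()
            assert curve[-1] == pytest.approx(1.0)


class TestDirectTargets:
    def test_unbound_gene_never_called(self):
        scores = {"a": 0.5, "b": 0.0, "s": 0.2}
        groups = GeneGroups(up=["a", "b"], down=[], static=["s"])
        expr = expr_frame([("a", 2.0, 1e-6), ("b", 2.5, 1e-8), ("s", 0.0, 0.9)])
        targets = direct_targets(rp_frame(scores), groups, expr)
        assert targets["up"]["gene_id"].tolist() == ["a"]

    def test_all_static_expression_gives_empty_lists(self):
        scores = {"a": 0.5, "b": 0.3}
        groups = GeneGroups(up=[], down=[], static=["a", "b"])
        expr = expr_frame([("a", 0.0, 0.9), ("b", 0.0, 0.8)])
        targets = direct_targets(rp_frame(scores), groups, expr)
        assert targets["up"].empty and targets["down"].empty

    def test_rank_product_ordering(self):
        scores = {"a": 0.9, "b": 0.5, "c": 0.1}
        groups = GeneGroups(up=["a", "b", "c"], down=[], static=[])
        expr = expr_frame([("a", 2.0, 1e-3), ("b", 2.0, 1e-9), ("c", 2.0, 1e-6)])
        t = direct_targets(rp_frame(scores), groups, expr)["up"]
        # a: rp 1 de 3 -> 3; b: rp 2 de 1 -> 2; c: rp 3 de 2 -> 6
        assert t["gene_id"].tolist() == ["b", "a", "c"]
        assert t["rank_product"].tolist() == [2, 3, 6]


class TestDistanceComparison:
    def test_single_gene_group_at_zero_distance(self):
        genes = [gene("a", 50_000), gene("s", 500_000)]
        peaks = [peak("chr1", 50_000), peak("chr1", 520_000)]
        groups = GeneGroups(up=["a"], down=[], static=["s"])
        table = distance_comparison(peaks, genes, groups).set_index("group")
        assert table.loc["up", "median"] == 0.0
        assert table.loc["static", "median"] == 20_000.0

    def test_planted_proximity_detected_vs_permutation_oracle(self, rng):
        """Group genes with peaks planted ~5 kb away versus uniform background
        peaks: MWU p < 0.01 and a permutation oracle of the rank-sum agrees."""
        genes = [gene(f"g{i:03d}", 25_000 + i * 50_000) for i in range(200)]
        members = [g.gene_id for g in genes[:60]]
        peaks = [peak("chr1", g.tss + int(rng.exponential(5000))) for g in genes[:60]]
        peaks += [peak("chr1", int(rng.integers(0, 10_000_000))) for _ in range(100)]
        groups = GeneGroups(up=members, down=[], static=[g.gene_id for g in genes[60:]])
        table = distance_comparison(peaks, genes, groups).set_index("group")
        assert table.loc["up", "median"] < table.loc["static", "median"]
        p_mwu = table.loc["up", "mwu_p_vs_static"]
        assert p_mwu < 0.01
        # permutation oracle on the rank sum
        mids = np.sort([p.midpoint for p in peaks])
        def nearest(t):
            j = np.searchsorted(mids, t)
            return min(abs(int(mids[k]) - t) for k in (j - 1, j) if 0 <= k < len(mids))
        d_all = np.array([nearest(g.tss) for g in genes])
        labels = np.array([g.gene_id in set(members) for g in genes])
        obs = stats.mannwhitneyu(d_all[labels], d_all[~labels], alternative="less").statistic
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(labels)
            u = stats.mannwhitneyu(d_all[labels], d_all[~labels], alternative="less").statistic
            if u <= obs:
                hits += 1
        assert (hits + 1) / (n_perm + 1) < 0.01

    def test_empty_group_not_applicable(self):
        genes = [gene("s", 10_000)]
        groups = GeneGroups(up=[], down=[], static=["s"])
        table = distance_comparison([peak("chr1", 10_000)], genes, groups).set_index("group")
        assert table.loc["up", "n"] == 0 and np.isnan(table.loc["up", "median"])

    def test_null_pvalues_roughly_uniform(self, rng):
        """Identical group/static distance distributions: MWU p is uniform
        over replicates (KS uniformity check at 200 replicates)."""
        pvals = []
        for _ in range(200):
            d = rng.exponential(10_000, size=120)
            labels = np.zeros(120, dtype=bool)
            labels[:40] = True
            rng.shuffle(labels)
            pvals.append(
                stats.mannwhitneyu(d[labels], d[~labels], alternative="less").pvalue
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
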