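import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylcontrast.diffmeth import bh_adjust
from methylcontrast.dmr import (
    DMR,
    call_regions,
    dmrs_to_bed,
    annotate_context,
    enrich_gene_sets,
    filter_fold_change,
    kernel_smooth,
    rank_by_fold_change,
    smoothed_pvalues,
)
from methylcontrast.errors import UsageError


class TestKernelSmooth:
    def test_isolated_probe_is_its_own_stat(self):
        pos = np.array([0.0, 1e6, 2e6])  # >> 10 sigma apart
        wald = np.array([2.0, -3.0, 0.5])
        sm, df = kernel_smooth(pos, wald)
        assert np.allclose(sm, wald**2)
        assert np.allclose(df, 1.0)

    def test_colocated_pair_averages_squares(self):
        pos = np.array([500.0, 500.0])
        a, b = 2.0, -1.0
        sm, df = kernel_smooth(pos, np.array([a, b]))
        assert np.allclose(sm, (a * a + b * b) / 2.0)
        assert np.allclose(df, 2.0)

    def test_constant_stats_smooth_to_square(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.uniform(0, 20_000, 50))
        c = 1.7
        sm, _ = kernel_smooth(pos, np.full(50, c))
        assert np.allclose(sm, c * c)

    def test_hand_evaluated_two_probe_weights(self):
        # probes 500 bp apart, sigma = 500: w = exp(-0.5)
        pos = np.array([0.0, 500.0])
        a, b = 3.0, 1.0
        w = np.exp(-0.5)
        sm, df = kernel_smooth(pos, np.array([a, b]), lam=1000.0, C=2.0)
        exp0 = (a * a + w * b * b) / (1 + w)
        assert sm[0] == pytest.approx(exp0, rel=1e-12)
        a_vec = np.array([1.0, w]) / (1 + w)
        assert df[0] == pytest.approx(1.0 / np.sum(a_vec**2), rel=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.uniform(0, 50_000, 80))
        wald = rng.normal(0, 2, 80)
        sm1, df1 = kernel_smooth(pos, wald)
        sm2, df2 = kernel_smooth(pos + 123_456.0, wald)
        assert np.allclose(sm1, sm2)
        assert np.allclose(df1, df2)

    def test_df_bounds(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.uniform(0, 10_000, 60))
        _, df = kernel_smooth(pos, rng.normal(size=60))
        assert np.all(df >= 1.0 - 1e-9)
        assert np.all(df <= 60.0)

    def test_unsorted_raises(self):
        with pytest.raises(UsageError):
            kernel_smooth(np.array([100.0, 50.0]), np.array([1.0, 1.0]))

    def test_single_probe(self):
        sm, df = kernel_smooth(np.array([42.0]), np.array([2.5]))
        assert sm[0] == pytest.approx(6.25)
        assert df[0] == pytest.approx(1.0)

    def test_isolated_probe_pvalue_matches_wald(self):
        sm, df = kernel_smooth(np.array([0.0]), np.array([1.96]))
        p = smoothed_pvalues(sm, df)[0]
        assert p == pytest.approx(2 * stats.norm.sf(1.96), rel=1e-6)


def _probe_table(chroms, poss, qs, ests=None):
    n = len(poss)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "q": qs,
            "estimate": ests if ests is not None else np.ones(n),
        },
        index=[f"cg{i}" for i in range(n)],
    )


class TestCallRegions:
    def test_three_probes_at_1kb_one_region(self):
        tab = _probe_table(["chr1"] * 3, [1000, 2000, 3000], [0.01] * 3)
        dmrs = call_regions(tab, gap=1000)
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end, dmrs[0].n_probes) == (1000, 3000, 3)

    def test_probes_5kb_apart_no_region(self):
        tab = _probe_table(["chr1"] * 2, [1000, 6000], [0.01] * 2)
        assert call_regions(tab, gap=1000) == []

    def test_min_cpgs_enforced(self):
        tab = _probe_table(["chr1"] * 3, [1000, 1500, 9000], [0.01, 0.01, 0.001])
        dmrs = call_regions(tab, gap=1000, min_cpgs=2)
        assert len(dmrs) == 1 and dmrs[0].n_probes == 2

    def test_region_q_is_min_member_q(self):
        tab = _probe_table(["chr1"] * 3, [1000, 1800, 2600], [0.04, 0.002, 0.03])
        dmrs = call_regions(tab, gap=1000)
        assert dmrs[0].region_q == pytest.approx(0.002)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        tab = _probe_table(
            ["chr1"] * 6, [1000, 1900, 2800, 9000, 9900, 20_000],
            [0.01, 0.02, 0.01, 0.03, 0.04, 0.6],
        )
        shuffled = tab.sample(frac=1, random_state=7)
        d1 = call_regions(tab)
        d2 = call_regions(shuffled)
        assert [(d.start, d.end, d.n_probes) for d in d1] == [
            (d.start, d.end, d.n_probes) for d in d2
        ]

    def test_empty_significant_set(self):
        tab = _probe_table(["chr1"] * 3, [1000, 2000, 3000], [0.9, 0.5, 0.8])
        assert call_regions(tab) == []

    def test_max_fc_is_extremal_exponentiated_estimate(self):
        tab = _probe_table(
            ["chr1"] * 3, [1000, 1900, 2800], [0.01] * 3, ests=[0.3, -1.5, 0.8]
        )
        dmrs = call_regions(tab)
        assert dmrs[0].max_fc == pytest.approx(np.exp(-1.5))

    def test_planted_region_recovered(self):
        # planted 10-probe cluster on a 2,000-probe chromosome
        rng = np.random.default_rng(4)
        gaps = rng.exponential(500, 2000)
        gaps[1000:1010] = 400.0
        pos = np.cumsum(gaps).astype(int) + 1
        wald = rng.normal(0, 1, 2000)
        wald[1000:1010] = rng.normal(5, 1, 10)
        sm, df = kernel_smooth(pos.astype(float), wald)
        q = bh_adjust(smoothed_pvalues(sm, df))
        tab = _probe_table(["chr1"] * 2000, pos, q, ests=wald * 0.2)
        dmrs = call_regions(tab)
        t0, t1 = int(pos[1000]), int(pos[1009])
        best = 0.0
        for d in dmrs:
            inter = max(0, min(t1, d.end) - max(t0, d.start) + 1)
            union = (t1 - t0 + 1) + (d.end - d.start + 1) - inter
            best = max(best, inter / union)
        assert best >= 0.6


class TestFoldChangeFilter:
    def _dmr(self, fc):
        return DMR("chr1", 100, 200, 2, 0.01, fc, ["cg0", "cg1"])

    @pytest.mark.parametrize("fc,kept", [(2.5, True), (1.0, False), (0.4, True), (2.0, False)])
    def test_two_sided_rule(self, fc, kept):
        out = filter_fold_change([self._dmr(fc)])
        assert (len(out) == 1) == kept

    def test_bad_threshold(self):
        with pytest.raises(UsageError):
            filter_fold_change([self._dmr(3.0)], min_fc=0.5)

    def test_ranking_by_abs_log_fc(self):
        dmrs = [self._dmr(2.0), self._dmr(0.25), self._dmr(3.0)]
        ranked = rank_by_fold_change(dmrs)
        assert [d.max_fc for d in ranked] == [0.25, 3.0, 2.0]


class TestAnnotateContext:
    def test_flags_any_member(self, manifest_tiny):
        d = DMR("chr1", 100, 5000, 2, 0.01, 3.0, ["cg0", "cg1"])
        table, _ = annotate_context([d], manifest_tiny)
        row = table.iloc[0]
        assert row["island"] and row["shore"] and row["promoter"] and row["enhancer"]
        assert not row["shelf"]

    def test_open_sea_promoter_only(self, manifest_tiny):
        d = DMR("chr1", 120_000, 150_000, 2, 0.01, 3.0, ["cg4", "cg5"])
        table, _ = annotate_context([d], manifest_tiny)
        row = table.iloc[0]
        assert row["promoter"]
        assert not (row["island"] or row["shore"] or row["shelf"] or row["enhancer"])

    def test_counts_equal_brute_force_recount(self, small_cohort):
        _, _, _, manifest, _ = small_cohort
        rng = np.random.default_rng(5)
        dmrs = []
        ids = list(manifest.index)
        for k in range(8):
            members = sorted(rng.choice(len(ids), 3, replace=False))
            probes = [ids[i] for i in members]
            sub = manifest.loc[probes]
            dmrs.append(DMR(sub["chrom"].iloc[0], int(sub["pos"].min()),
                            int(sub["pos"].max()), 3, 0.01, 2.5, probes))
        table, summary = annotate_context(dmrs, manifest)
        for cat in ("island", "shore", "shelf"):
            brute = sum(
                any(manifest.loc[p, "relation"] == cat for p in d.probe_ids) for d in dmrs
            )
            assert int(table[cat].sum()) == brute
        for cat in ("promoter", "enhancer"):
            brute = sum(any(manifest.loc[p, cat] for p in d.probe_ids) for d in dmrs)
            assert int(table[cat].sum()) == brute

    def test_empty_list_zero_distribution(self, manifest_tiny):
        table, summary = annotate_context([], manifest_tiny)
        assert len(table) == 0
        counts = summary.set_index("category")["count"]
        assert all(counts[c] == 0 for c in ("island", "shore", "shelf", "promoter", "enhancer"))

    def test_bed_export_zero_based_half_open(self):
        d = DMR("chr1", 101, 200, 2, 0.01, 3.0, ["cg0", "cg1"])
        bed = dmrs_to_bed([d])
        assert (bed.iloc[0]["start"], bed.iloc[0]["end"]) == (100, 200)


def _gene_universe(counts, rng=None):
    probes, p2g = [], {}
    for g, c in counts.items():
        for j in range(c):
            pid = f"{g}_p{j}"
            probes.append(pid)
            p2g[pid] = [g]
    return probes, p2g


class TestEnrichment:
    def test_equal_weights_matches_fisher(self):
        # all genes carry the same probe count -> central hypergeometric
        counts = {f"G{i}": 4 for i in range(40)}
        probes, p2g = _gene_universe(counts)
        sig_genes = [f"G{i}" for i in range(10)]
        sig = [f"{g}_p0" for g in sig_genes]
        gene_set = {"S": [f"G{i}" for i in range(5, 15)]}
        res = enrich_gene_sets(sig, probes, gene_set, p2g)
        k = len(set(gene_set["S"]) & set(sig_genes))
        oracle = stats.hypergeom.sf(k - 1, 40, 10, 10)
        assert res["p"].iloc[0] == pytest.approx(oracle, abs=1e-6)
        # Fisher's one-sided exact test agrees with the hypergeometric sf
        table = [[k, 10 - k], [10 - k, 40 - 20 + k]]
        assert res["p"].iloc[0] == pytest.approx(
            stats.fisher_exact(table, alternative="greater")[1], abs=1e-6
        )

    def test_wallenius_odds_one_equals_hypergeom(self):
        # dual route on scipy itself: odds -> 1 limit
        p_w = stats.nchypergeom_wallenius.sf(4, 40, 10, 10, 1.0 + 1e-9)
        p_h = stats.hypergeom.sf(4, 40, 10, 10)
        assert p_w == pytest.approx(p_h, abs=1e-6)

    def test_extreme_enrichment_small_p(self):
        counts = {f"G{i}": 3 for i in range(30)}
        probes, p2g = _gene_universe(counts)
        sig = [f"G{i}_p0" for i in range(8)]
        gene_set = {"S": [f"G{i}" for i in range(8)]}
        res = enrich_gene_sets(sig, probes, gene_set, p2g)
        oracle = stats.hypergeom.sf(7, 30, 8, 8)  # minimum achievable p here
        assert res["p"].iloc[0] == pytest.approx(oracle, rel=1e-6)

    def test_sig_not_subset_raises(self):
        counts = {"G0": 2}
        probes, p2g = _gene_universe(counts)
        with pytest.raises(UsageError):
            enrich_gene_sets(["nope"], probes, {"S": ["G0"]}, p2g)

    def test_empty_set_raises(self):
        counts = {"G0": 2}
        probes, p2g = _gene_universe(counts)
        with pytest.raises(UsageError):
            enrich_gene_sets([probes[0]], probes, {"S": []}, p2g)

    def test_zero_probe_genes_excluded_with_warning(self):
        counts = {f"G{i}": 2 for i in range(10)}
        probes, p2g = _gene_universe(counts)
        gene_set = {"S": ["G0", "G1", "GHOST"]}
        with pytest.warns(UserWarning, match="no background probes"):
            res = enrich_gene_sets([probes[0]], probes, gene_set, p2g)
        assert res["n_genes"].iloc[0] == 2
        assert res.attrs["n_zero_probe_genes"] == 1

    def test_permutation_type_one_calibration(self):
        # uneven probe counts; uniform probe draws; nominal 0.05
        rng = np.random.default_rng(1)
        genes = [f"G{i:04d}" for i in range(300)]
        counts = dict(zip(genes, rng.integers(1, 31, 300)))
        probes, p2g = _gene_universe(counts)
        probes = np.array(probes)
        gene_set = {"S": list(rng.choice(genes, 60, replace=False))}
        hits = 0
        n_perm = 1000
        import warnings as _w
        for _ in range(n_perm):
            sig = rng.choice(probes, 500, replace=False)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                hits += enrich_gene_sets(sig, probes, gene_set, p2g)["p"].iloc[0] < 0.05
        assert 0.03 <= hits / n_perm <= 0.07

    def test_bh_applied(self):
        counts = {f"G{i}": 2 for i in range(20)}
        probes, p2g = _gene_universe(counts)
        sig = [f"G{i}_p0" for i in range(5)]
        sets = {f"S{j}": [f"G{i}" for i in range(j, j + 5)] for j in range(4)}
        res = enrich_gene_sets(sig, probes, sets, p2g)
        assert np.allclose(
            res["q"].to_numpy(), bh_adjust(res["p"].to_numpy()), atol=1e-12
        )


@given(st.integers(min_value=0, max_value=10_000_000))
@settings(max_examples=30, deadline=None)
def test_kernel_shift_invariance_property(shift):
    rng = np.random.default_rng(9)
    pos = np.sort(rng.uniform(0, 30_000, 40))
    wald = rng.normal(0, 2, 40)
    sm1, df1 = kernel_smooth(pos, wald)
    sm2, df2 = kernel_smooth(pos + shift, wald)
    assert np.allclose(sm1, sm2) and np.allclose(df1, df2)
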