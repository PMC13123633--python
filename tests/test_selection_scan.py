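"""FST/PBS/PBE chain against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wolfscan.errors import DegenerateNullError, UndefinedStatisticError
from wolfscan.selection_scan import (
    GeneAnnotationHit,
    PBEScan,
    SiteAlleleSummary,
    allele_summaries,
    annotate_outliers,
    call_outliers,
    cs_transform,
    nearest_gene,
    pbe,
    pbe_pvalues,
    pbs,
    wc_fst,
)
from wolfscan.synthetic_data import GenotypeSimConfig, simulate_three_pop_genotypes


def wc84_theta_oracle(ns, ps, hs):
    """Literal transcription of the Weir & Cockerham (1984) variance
    components for r populations; independent of the vectorized path."""
    r = len(ns)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return np.nan if denom == 0 else a / denom


def summaries_from_genotype_counts(counts):
    """(n_AA, n_Aa, n_aa) -> (n, alt freq, het fraction)."""
    n = sum(counts)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    h = counts[1] / n
    return n, p, h


class TestWcFst:
    def test_fixed_difference_is_one(self):
        s1 = SiteAlleleSummary(np.array([10.0]), np.array([0.0]), np.array([0.0]))
        s2 = SiteAlleleSummary(np.array([10.0]), np.array([1.0]), np.array([0.0]))
        assert wc_fst(s1, s2)[0] == pytest.approx(1.0)

    def test_pooled_monomorphic_is_undefined(self):
        s1 = SiteAlleleSummary(np.array([10.0]), np.array([0.0]), np.array([0.0]))
        s2 = SiteAlleleSummary(np.array([8.0]), np.array([0.0]), np.array([0.0]))
        assert np.isnan(wc_fst(s1, s2)[0])

    def test_genotype_count_example_matches_oracle(self):
        g1, g2 = (5, 3, 2), (1, 4, 5)
        n1, p1, h1 = summaries_from_genotype_counts(g1)
        n2, p2, h2 = summaries_from_genotype_counts(g2)
        got = wc_fst(
            SiteAlleleSummary(np.array([float(n1)]), np.array([p1]), np.array([h1])),
            SiteAlleleSummary(np.array([float(n2)]), np.array([p2]), np.array([h2])),
        )[0]
        expected = wc84_theta_oracle([n1, n2], [p1, p2], [h1, h2])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence_on_random_configurations(self, rng):
        """1000 random genotype configurations agree with the literal WC84
        transcription to 1e-12."""
        checked = 0
        while checked < 1000:
            g1 = rng.integers(0, 15, size=3) + np.array([1, 0, 0])
            g2 = rng.integers(0, 15, size=3) + np.array([0, 0, 1])
            n1, p1, h1 = summaries_from_genotype_counts(g1)
            n2, p2, h2 = summaries_from_genotype_counts(g2)
            expected = wc84_theta_oracle([n1, n2], [p1, p2], [h1, h2])
            got = wc_fst(
                SiteAlleleSummary(np.array([float(n1)]), np.array([p1]), np.array([h1])),
                SiteAlleleSummary(np.array([float(n2)]), np.array([p2]), np.array([h2])),
            )[0]
            pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
            if 0 < pooled < 1 and not np.isnan(expected):
                assert got == pytest.approx(expected, abs=1e-12)
                checked += 1


class TestTransforms:
    def test_cs_closed_forms(self):
        out = cs_transform(np.array([0.0, 0.5]))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.log(2.0))

    def test_cs_cap_keeps_fixed_differences_finite(self):
        t = cs_transform(np.array([1.0]))[0]
        assert np.isfinite(t)
        assert t == pytest.approx(-np.log(1e-9))

    def test_cs_clamps_negative_estimates_to_zero(self):
        assert cs_transform(np.array([-0.05]))[0] == 0.0

    @given(st.floats(0.0, 0.999), st.floats(0.0, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_cs_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert cs_transform(np.array([lo]))[0] < cs_transform(np.array([hi]))[0]

    @pytest.mark.parametrize(
        "t3,expected",
        [((0.4, 0.4, 0.4), 0.2), ((0.2, 0.3, 0.1), 0.2), ((0.05, 0.05, 0.3), -0.10)],
    )
    def test_pbs_arithmetic(self, t3, expected):
        assert pbs(*[np.array([v]) for v in t3])[0] == pytest.approx(expected)


class TestPbe:
    def test_single_locus_is_zero(self):
        assert pbe(np.array([0.3]), np.array([0.2]))[0] == pytest.approx(0.0)

    def test_median_scaled_expectation(self):
        out = pbe(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.1, 0.1]))
        assert out == pytest.approx([-0.1, 0.0, 0.1])

    @given(st.floats(0.01, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_proportionality_null(self, c):
        t_so = np.array([0.1, 0.25, 0.4, 0.05, 0.9])
        out = pbe(c * t_so, t_so)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_degenerate_null(self):
        with pytest.raises(DegenerateNullError):
            pbe(np.array([0.1, 0.2, 0.3]), np.array([0.0, 0.0, 0.1]))


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up, written independently."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestPbePvalues:
    def test_upper_tail_probability_of_z(self, rng):
        # p is the upper-tail normal probability of the zeroed z-score; a
        # site exactly 2 sd above the mean carries p = 1 - Phi(2) ~ 0.02275
        raw = rng.normal(0.2, 0.3, 50)
        _, z, p, _ = pbe_pvalues(raw)
        assert p == pytest.approx(stats.norm.sf(z))
        assert 1 - stats.norm.cdf(2.0) == pytest.approx(0.02275, abs=1e-5)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pbe_pvalues(np.array([0.5, 0.5, 0.5]))

    def test_bh_textbook_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert bh_stepup_oracle(p) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_stepup_oracle_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(3, 200))
            assert multipletests(p, method="fdr_bh")[1] == pytest.approx(
                bh_stepup_oracle(p), abs=1e-12
            )

    def test_empirical_p_is_rank_based(self, rng):
        raw = rng.normal(0.1, 0.3, 40)
        _, _, p, _ = pbe_pvalues(raw, method="empirical")
        zeroed = np.maximum(raw, 0.0)
        # most extreme locus carries p = (ties at the top) / m
        top = np.argmax(zeroed)
        assert p[top] == pytest.approx((zeroed >= zeroed[top]).sum() / 40)
        assert (p > 0).all() and (p <= 1).all()
        with pytest.raises(ValueError):
            pbe_pvalues(raw, method="bogus")

    def test_bh_monotone_and_bounded(self, rng):
        raw = rng.normal(0.1, 0.2, 500)
        _, _, p, p_adj = pbe_pvalues(raw)
        assert (p_adj >= p - 1e-15).all()
        assert (p_adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()


class TestCallOutliers:
    @pytest.mark.parametrize(
        "padj,tier", [(1.0, "none"), (1e-9, "outlier"), (1e-16, "extreme")]
    )
    def test_tiers(self, padj, tier):
        assert call_outliers(np.array([padj]))[0] == tier

    def test_extreme_subset_of_outlier_threshold_order(self):
        with pytest.raises(ValueError):
            call_outliers(np.array([0.5]), thr_outlier=10, thr_extreme=5)


ANN = pd.DataFrame(
    [
        # geneA: chr1 [1000, 4000) +, exons [1000,2000) and [3000,4000)
        {"chrom": "chr1", "start": 1000, "end": 4000, "strand": "+", "gene": "geneA", "feature": "gene"},
        {"chrom": "chr1", "start": 1000, "end": 2000, "strand": "+", "gene": "geneA", "feature": "exon"},
        {"chrom": "chr1", "start": 3000, "end": 4000, "strand": "+", "gene": "geneA", "feature": "exon"},
        # geneB: chr1 [8000, 9000) -
        {"chrom": "chr1", "start": 8000, "end": 9000, "strand": "-", "gene": "geneB", "feature": "gene"},
    ]
)


class TestNearestGene:
    def test_inside_exon(self):
        hit = nearest_gene("chr1", 1500, ANN)
        assert (hit.gene, hit.relation, hit.distance) == ("geneA", "exonic", 0)

    def test_inside_intron(self):
        hit = nearest_gene("chr1", 2500, ANN)
        assert (hit.gene, hit.relation, hit.distance) == ("geneA", "intronic", 0)

    def test_64bp_downstream_of_plus_strand_gene(self):
        # geneA ends at 0-based 4000; 64 bp past the 3' end is pos 4064 (1-based)
        hit = nearest_gene("chr1", 4064, ANN)
        assert (hit.gene, hit.relation, hit.distance) == ("geneA", "downstream", 64)

    def test_upstream_of_minus_strand_gene(self):
        hit = nearest_gene("chr1", 9101, ANN)  # 101 bp past geneB end; '-' strand
        assert (hit.gene, hit.relation, hit.distance) == ("geneB", "upstream", 101)

    def test_equidistant_tie_goes_to_lower_coordinate_gene(self):
        ann = ANN.copy()
        ann.loc[ann["gene"] == "geneB", "start"] = 8001
        # geneA ends 4000, geneB starts 8001: site 6001 (1-based) sits 2001 bp
        # from both -> lower-coordinate geneA wins the tie
        hit = nearest_gene("chr1", 6001, ann)
        assert hit.gene == "geneA"
        assert hit.distance == 2001

    def test_absent_chromosome_marker(self):
        hit = nearest_gene("chr9", 100, ANN)
        assert hit.gene is None
        assert hit.relation == "intergenic"


@pytest.fixture(scope="module")
def scan_result():
    cfg = GenotypeSimConfig(n_loci=4000, n_selected_focal=20)
    gm, truth = simulate_three_pop_genotypes(cfg, 7)
    gm.masked = True
    gm.site_filtered = True
    return PBEScan(gm).fit(), truth


class TestScanEndToEnd:

    def test_table_invariants(self, scan_result):
        res, _ = scan_result
        tab = res.table
        ok = tab["pbe_raw"].notna()
        assert (tab.loc[ok, "pbe"] >= 0).all()
        assert np.allclose(
            tab.loc[ok, "pbe"], np.maximum(tab.loc[ok, "pbe_raw"], 0.0)
        )
        assert (tab.loc[ok, "p_adj"] >= tab.loc[ok, "p"] - 1e-15).all()
        extreme = tab["tier"] == "extreme"
        assert (tab.loc[extreme, "p_adj"] < 1e-15).all()
        assert res.n_extreme <= res.n_outliers

    def test_selected_loci_show_elevated_differentiation(self, scan_result):
        res, truth = scan_result
        tab = res.table
        sel = np.zeros(len(tab), dtype=bool)
        sel[truth.selected_focal] = True
        fst = tab["fst_fs"].to_numpy()
        assert np.nanmean(fst[sel]) >= 5 * np.nanmean(fst[~sel])

    def test_summary_mentions_counts(self, scan_result):
        res, _ = scan_result
        text = res.summary()
        assert str(res.n_sites) in text and "outliers" in text


def test_focal_specificity_versus_sister_selection():
    """Sister-branch selection must not masquerade as focal divergence: the
    focal-selected loci dominate the PBE signal."""
    cfg = GenotypeSimConfig(n_selected_sister=50)
    gm, truth = simulate_three_pop_genotypes(cfg, 11)
    gm.masked = True
    gm.site_filtered = True
    tab = PBEScan(gm).fit().table
    pe = tab["pbe"].to_numpy()
    focal = pe[truth.selected_focal]
    sister = pe[truth.selected_sister]
    focal, sister = focal[~np.isnan(focal)], sister[~np.isnan(sister)]
    assert focal.mean() > 2 * sister.mean()
    assert stats.mannwhitneyu(focal, sister, alternative="greater").pvalue < 0.01
    order = np.argsort(-np.nan_to_num(pe, nan=-np.inf))
    top50 = order[:50]
    assert np.isin(top50, truth.selected_focal).sum() >= np.isin(
        top50, truth.selected_sister
    ).sum()


def test_null_scan_tail_fraction_is_reproducible():
    """With no selection, the fraction of sites with p < 0.05 reflects the
    zero-inflated z construction (not nominal 5%) and is stable between
    independent simulations."""
    fracs = []
    for seed in (21, 22):
        cfg = GenotypeSimConfig(n_loci=6000, n_selected_focal=0, selection_shift=0.0)
        gm, _ = simulate_three_pop_genotypes(cfg, seed)
        gm.masked = True
        gm.site_filtered = True
        p = PBEScan(gm).fit().table["p"].to_numpy()
        fracs.append(np.nanmean(p[~np.isnan(p)] < 0.05))
    f = np.mean(fracs)
    se = np.sqrt(2 * f * (1 - f) / 6000)
    assert abs(fracs[0] - fracs[1]) < 2 * se + 1e-3


def test_annotate_outliers_reports_only_flagged_sites():
    tab = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [1500, 6000],
            "p_adj": [1e-10, 0.5],
            "tier": ["outlier", "none"],
        }
    )
    report = annotate_outliers(tab, ANN)
    assert len(report) == 1
    assert report.iloc[0]["gene"] == "geneA"
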