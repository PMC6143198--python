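"""Attention accounting: universe filters, fractional counting,
inequality measures, trends and family comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ignorome import attention as A
from ignorome.containers import GeneCatalog, GeneLinkTable, PublicationTable


def make_pubs(rows):
    """rows: (pmid, year, types, journal)"""
    return PublicationTable(pd.DataFrame(
        rows, columns=["pmid", "year", "article_types", "journal_id"]))


def make_links(rows):
    """rows: (gene_id, pmid)"""
    t = pd.DataFrame(rows, columns=["gene_id", "pmid"])
    t.insert(0, "tax_id", 9606)
    return GeneLinkTable(t)


class TestReferencePublications:
    def test_three_rules(self):
        pubs = make_pubs([
            (1, 2000, ("journal article",), 1),           # kept
            (2, 2000, ("journal article", "review"), 1),  # review: excluded
            (3, 2000, ("editorial",), 1),                 # not whitelisted
            (4, 2000, ("journal article",), 2),           # review journal
            (5, 2000, ("review",), 2),
        ])
        kept = A.filter_reference_publications(pubs).table["pmid"].tolist()
        assert kept == [1]

    def test_fifty_percent_journal_boundary_inclusive(self):
        # journal 9: exactly half reviews -> every article excluded
        pubs = make_pubs([
            (1, 2000, ("journal article",), 9),
            (2, 2000, ("journal article", "review"), 9),
        ])
        assert len(A.filter_reference_publications(pubs).table) == 0

    def test_adding_review_label_is_monotone(self):
        pubs = make_pubs([
            (1, 2000, ("journal article",), 1),
            (2, 2000, ("journal article",), 1),
            (3, 2000, ("journal article",), 2),
        ])
        before = set(A.filter_reference_publications(pubs).table["pmid"])
        relabelled = pubs.table.copy()
        idx = relabelled.index[relabelled["pmid"] == 2][0]
        relabelled.at[idx, "article_types"] = ("journal article", "review")
        after = set(A.filter_reference_publications(
            PublicationTable(relabelled)).table["pmid"])
        assert after <= before


class TestReferenceGenes:
    def test_link_boundary_and_taxon(self):
        catalog = GeneCatalog(pd.DataFrame({
            "gene_id": [1, 2, 3],
            "symbol": ["AAA", "BBB", "ccc"],
            "tax_id": [9606, 9606, 10090],
        }))
        pubs = make_pubs([(10, 2000, ("journal article",), 1)])
        links = make_links([(1, 10), (3, 10)])
        ref = A.select_reference_genes(catalog, links, pubs)
        assert list(ref) == [1]  # gene 2 unlinked, gene 3 nonhuman


class TestFractionalAttention:
    def test_one_over_k_rule(self):
        pubs = make_pubs([(1, 2000, ("journal article",), 1),
                          (2, 2000, ("journal article",), 1),
                          (3, 2000, ("journal article",), 1)])
        links = make_links([("A", 1), ("A", 2), ("B", 2),
                            ("A", 3), ("B", 3), ("C", 3), ("D", 3)])
        att = A.fractional_attention(links, pubs)
        assert att.loc["A", "fractional"] == pytest.approx(1.75)
        assert att.loc["B", "fractional"] == pytest.approx(0.75)
        assert att.loc["C", "fractional"] == pytest.approx(0.25)
        assert att["fractional"].sum() == pytest.approx(3.0, abs=1e-9)

    def test_timeframe_restriction(self):
        pubs = make_pubs([(1, 1999, ("journal article",), 1),
                          (2, 2005, ("journal article",), 1)])
        links = make_links([("A", 1), ("A", 2)])
        att = A.fractional_attention(links, pubs, timeframe=(2000, 2010))
        assert att.loc["A", "fractional"] == 1.0

    def test_conservation_on_corpus(self, small_corpus):
        att = A.fractional_attention(small_corpus.gene_link_table,
                                     small_corpus.publication_table)
        linked = small_corpus.gene_link_table.table["pmid"].nunique()
        assert att["fractional"].sum() == pytest.approx(linked, abs=1e-9)


class TestGini:
    def test_oracle_1234(self):
        x = [1, 2, 3, 4]
        brute = np.mean([abs(a - b) for a in x for b in x]) / (2 * np.mean(x))
        assert A.gini(x) == pytest.approx(0.25, abs=1e-12)
        assert A.gini(x) == pytest.approx(brute, abs=1e-12)

    def test_equality_and_concentration(self):
        assert A.gini([3, 3, 3]) == pytest.approx(0.0, abs=1e-12)
        n = 7
        assert A.gini([10] + [0] * (n - 1)) == pytest.approx((n - 1) / n)

    def test_scale_invariance_100_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.gamma(1.0, 2.0, size=rng.integers(3, 40))
            c = rng.uniform(0.1, 100)
            assert A.gini(c * x) == pytest.approx(A.gini(x), abs=1e-12)

    def test_matches_pairwise_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.exponential(size=rng.integers(2, 30))
            brute = np.abs(x[:, None] - x[None, :]).mean() / (2 * x.mean())
            assert A.gini(x) == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize("bad", [[1.0], [0.0, 0.0], [-1.0, 2.0]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            A.gini(bad)


class TestCumulativeShare:
    def test_top_quarter_covers_forty_percent(self):
        curve = A.cumulative_share(pd.Series([4, 3, 2, 1]))
        row = curve[curve["gene_fraction"] == 0.25].iloc[0]
        assert row["attention_share"] == pytest.approx(0.4)

    def test_uniform_is_diagonal(self):
        curve = A.cumulative_share(pd.Series([2.0] * 10))
        np.testing.assert_allclose(curve["attention_share"],
                                   curve["gene_fraction"])

    def test_single_gene_steps_to_one(self):
        curve = A.cumulative_share(pd.Series([5.0]))
        assert curve["attention_share"].iloc[0] == 1.0


class TestDiscoveryYear:
    def test_minimum_and_missing(self):
        pubs = make_pubs([(1, 1993, ("journal article",), 1),
                          (2, 1988, ("journal article",), 1),
                          (3, 2001, ("journal article",), 1)])
        links = make_links([("A", 1), ("A", 2), ("A", 3)])
        years = A.discovery_year(links, pubs)
        assert years.loc["A"] == 1988
        assert "Z" not in years.index

    def test_never_exceeds_any_link(self, small_corpus):
        years = A.discovery_year(small_corpus.gene_link_table,
                                 small_corpus.publication_table)
        t = small_corpus.gene_link_table.table
        merged = t.assign(
            year=t["pmid"].map(small_corpus.publication_table.years()),
            disc=t["gene_id"].map(years),
        )
        assert (merged["disc"] <= merged["year"]).all()


class TestRecentTrend:
    def _corpus(self):
        rows, links = [], []
        pmid = 0
        # past window 2001-2010: gene X 20 pubs, gene Y 180 pubs
        for gene, n, year in [("X", 20, 2005), ("Y", 180, 2005),
                              ("X", 15, 2013), ("Y", 85, 2013)]:
            for _ in range(n):
                pmid += 1
                rows.append((pmid, year, ("journal article",), 1))
                links.append((gene, pmid))
        return make_pubs(rows), make_links(links)

    def test_worked_example(self):
        pubs, links = self._corpus()
        out = A.recent_trend_enrichment(links, pubs, (2001, 2010),
                                        (2011, 2015), min_recent=10)
        # totals 200 past vs 100 recent -> scale 0.5; X: 15 / 10
        assert out.loc["X", "log2_fold_change"] == pytest.approx(
            np.log2(1.5), abs=1e-12)

    def test_min_recent_filter(self):
        pubs, links = self._corpus()
        out = A.recent_trend_enrichment(links, pubs, (2001, 2010),
                                        (2011, 2015), min_recent=90)
        assert "X" not in out.index

    def test_identical_windows_rejected(self):
        pubs, links = self._corpus()
        with pytest.raises(ValueError):
            A.recent_trend_enrichment(links, pubs, (2001, 2010), (2005, 2012))

    def test_same_distribution_gives_zero(self):
        rows, link_rows = [], []
        pmid = 0
        for year in (2005, 2013):
            for _ in range(30):
                pmid += 1
                rows.append((pmid, year, ("journal article",), 1))
                link_rows.append(("G", pmid))
        out = A.recent_trend_enrichment(
            make_links(link_rows), make_pubs(rows), (2001, 2010),
            (2011, 2015), min_recent=10)
        assert out.loc["G", "log2_fold_change"] == pytest.approx(0.0)


class TestAttentionEnrichment:
    def test_direct_formula(self):
        att = pd.Series({1: 4.0, 2: 2.0, 3: 1.0, 4: 0.0})
        out = A.attention_enrichment(att, timeframe_total=100,
                                     n_reference_genes=50)
        assert out.loc[1, "log2_enrichment"] == pytest.approx(1.0)
        assert out.loc[2, "log2_enrichment"] == pytest.approx(0.0)
        assert out.loc[3, "log2_enrichment"] == pytest.approx(-1.0)
        assert out.loc[4, "censored"]


class TestFamilyFirstSecond:
    def _catalog(self, symbols):
        return GeneCatalog(pd.DataFrame({
            "gene_id": range(1, len(symbols) + 1),
            "symbol": symbols,
            "tax_id": 9606,
        }))

    def test_akt_pair_detected(self):
        catalog = self._catalog(["AKT1", "AKT2", "TP53"])
        att = pd.Series({1: 5.0, 2: 2.0, 3: 9.0})
        out = A.family_first_second(catalog, att)
        assert out["pairs"]["stem"].tolist() == ["AKT"]

    def test_lonely_entry_no_pair(self):
        out = A.family_first_second(self._catalog(["MYC1", "RAS3"]),
                                    pd.Series({1: 1.0, 2: 1.0}))
        assert len(out["pairs"]) == 0

    def test_short_stems_ignored(self):
        out = A.family_first_second(self._catalog(["T1", "T2"]),
                                    pd.Series({1: 1.0, 2: 1.0}))
        assert len(out["pairs"]) == 0

    def test_detects_planted_first_over_second(self):
        # 60 families where entry 1 receives stochastically more attention
        rng = np.random.default_rng(0)
        symbols, att = [], {}
        for i in range(60):
            stem = f"FM{chr(65 + i // 26)}{chr(65 + i % 26)}"
            symbols += [stem + "1", stem + "2"]
            att[2 * i + 1] = rng.lognormal(2.0, 0.5)
            att[2 * i + 2] = rng.lognormal(0.5, 0.5)
        out = A.family_first_second(self._catalog(symbols), pd.Series(att))
        assert len(out["pairs"]) == 60
        assert out["pvalue"] < 0.01


class TestUnstudiedFlag:
    def test_threshold_semantics(self):
        att = pd.Series({1: 0.8, 2: 1.5, 3: 1.0})
        flags = A.unstudied_flag(att)
        assert bool(flags.loc[1])
        assert not bool(flags.loc[2])
        assert not bool(flags.loc[3])  # boundary counts as studied


class TestCoverageExtrapolation:
    def _linear_corpus(self, per_year=10, n_years=20, n_genes=1000):
        rows, link_rows = [], []
        pmid = 0
        gene = 0
        for y in range(1996, 1996 + n_years):
            for _ in range(per_year):
                gene += 1
                pmid += 1
                rows.append((pmid, y, ("journal article",), 1))
                link_rows.append((gene, pmid))
        return make_pubs(rows), make_links(link_rows), n_genes

    def test_linear_growth_recovered(self):
        pubs, links, n = self._linear_corpus()
        out = A.coverage_extrapolation(links, pubs, n,
                                       fit_window=(2000, 2015))
        assert out.slope == pytest.approx(0.01, rel=1e-6)
        # 20% covered by 2015, 1%/year -> 80 years remain
        assert out.years_to_full == pytest.approx(80.0, rel=1e-6)

    def test_flat_series_infinite(self):
        rows = [(i, 2000 + i % 5, ("journal article",), 1) for i in range(10)]
        links = make_links([(1, i) for i in range(10)])
        with pytest.warns(UserWarning, match="nonpositive"):
            out = A.coverage_extrapolation(links, make_pubs(rows), 100,
                                           fit_window=(2001, 2004))
        assert np.isinf(out.years_to_full)


class TestBootstrap:
    def test_constant_values_zero_width(self):
        lo, hi = A.bootstrap_ci([2.0, 2.0, 2.0], np.mean, seed=0)
        assert lo == hi == 2.0

    def test_contains_mean_for_symmetric_data(self):
        rng = np.random.default_rng(3)
        hits = 0
        for seed in range(100):
            x = rng.normal(size=40)
            lo, hi = A.bootstrap_ci(x, np.mean, resamples=300, seed=seed)
            hits += lo <= x.mean() <= hi
        assert hits >= 95

    def test_single_resample_warns(self):
        with pytest.warns(UserWarning):
            A.bootstrap_ci([1.0, 2.0], np.mean, resamples=1, seed=0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=2,
                max_size=50))
def test_gini_bounded(values):
    g = A.gini(values)
    assert 0.0 <= g < 1.0
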