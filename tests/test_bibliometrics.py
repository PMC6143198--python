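"""Record linkage, citation analyses, human-specific genes and
career-transition statistics."""

import numpy as np
import pandas as pd
import pytest

from ignorome import bibliometrics as B
from ignorome.containers import (
    AuthorshipTable,
    CitationGraph,
    GeneCatalog,
    GeneLinkTable,
    HomologyMap,
    PublicationTable,
)
from ignorome.synthetic import SyntheticConfig, generate_corpus


def record_frame(rows):
    """rows: (record_id, doi, last_names, year, journal, title)"""
    return pd.DataFrame(rows, columns=["record_id", "doi", "last_names",
                                       "year", "journal", "title"])


class TestTitleSimilarity:
    def test_identical_titles_score_100(self):
        assert B.title_similarity("gene expression", "gene expression") == 100

    def test_score_is_normalized_levenshtein(self):
        # one edit over ten characters -> 90
        assert B.title_similarity("abcdefghij", "abcdefghiX") == \
            pytest.approx(90.0)

    def test_large_divergence_below_threshold(self):
        a = "x" * 100
        b = "x" * 94 + "y" * 6  # 6% of characters differ
        assert B.title_similarity(a, b) < 95


class TestLinkRecords:
    def test_doi_takes_priority(self):
        src = record_frame([(1, "10.1/x", ("smith",), 2000, "j",
                             "completely different title")])
        tgt = record_frame([(11, "10.1/x", ("smith",), 2000, "j",
                             "another title entirely")])
        out = B.link_records(src, tgt)
        assert out.iloc[0]["target_id"] == 11
        assert out.iloc[0]["method"] == "doi"

    def test_blocked_title_match(self):
        src = record_frame([(1, None, ("smith", "lee"), 2000, "j",
                             "the role of gene x in development")])
        tgt = record_frame([
            (11, None, ("smith", "lee"), 2000, "j",
             "the role of gene x in development"),
            (12, None, ("smith", "lee"), 2001, "j",
             "the role of gene x in development"),
        ])
        out = B.link_records(src, tgt)
        assert len(out) == 1
        assert out.iloc[0]["target_id"] == 11

    def test_identical_candidates_rejected_as_ambiguous(self):
        src = record_frame([(1, None, ("smith",), 2000, "j", "same title")])
        tgt = record_frame([
            (11, None, ("smith",), 2000, "j", "same title"),
            (12, None, ("smith",), 2000, "j", "same title"),
        ])
        assert len(B.link_records(src, tgt)) == 0

    def test_below_threshold_unmatched(self):
        src = record_frame([(1, None, ("smith",), 2000, "j", "a" * 20)])
        tgt = record_frame([(11, None, ("smith",), 2000, "j",
                             "a" * 18 + "bb")])
        out = B.link_records(src, tgt, threshold=95)
        assert len(out) == 0

    def test_planted_pairs_recovered_with_perfect_precision(self):
        # 100 titles perturbed below the rejection threshold
        rng = np.random.default_rng(0)
        letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
        src_rows, tgt_rows = [], []
        for i in range(100):
            title = "".join(rng.choice(letters, size=60))
            perturbed = list(title)
            perturbed[int(rng.integers(0, 60))] = "z"  # 1 edit in 60 < 5%
            src_rows.append((i, None, (f"a{i}",), 2000, "j", title))
            tgt_rows.append((1000 + i, None, (f"a{i}",), 2000, "j",
                             "".join(perturbed)))
        out = B.link_records(record_frame(src_rows), record_frame(tgt_rows))
        assert len(out) == 100
        assert (out["target_id"] - out["source_id"] == 1000).all()


def tiny_citation_fixture():
    """Two discovery publications: one leaning nonhuman, one balanced."""
    catalog = GeneCatalog(pd.DataFrame({
        "gene_id": [1, 2, 50, 51],
        "symbol": ["HA", "HB", "ma", "mb"],
        "tax_id": [9606, 9606, 10090, 10090],
    }))
    pubs = PublicationTable(pd.DataFrame({
        "pmid": [10, 11, 12, 13, 14, 20, 21],
        "year": [1990, 1990, 1990, 1991, 1991, 1995, 1995],
        "article_types": [("journal article",)] * 7,
        "journal_id": 1,
    }))
    links = GeneLinkTable(pd.DataFrame({
        "tax_id": [10090, 10090, 10090, 9606, 9606, 9606, 9606],
        "gene_id": [50, 51, 50, 1, 1, 1, 2],
        "pmid": [10, 11, 12, 13, 14, 20, 21],
    }))
    # pmid 13 is gene 1's discovery (1991); cites 3 nonhuman, 2 human? we
    # give it 3 nonhuman (10,11,12) and 2 human -> none exist before 1991
    # except 13/14 themselves; use 14 (human, same year).
    edges = pd.DataFrame({
        "citing": [13, 13, 13, 13, 21, 21],
        "cited": [10, 11, 12, 14, 20, 10],
    })
    return catalog, pubs, links, CitationGraph(edges)


class TestDiscoveryCitations:
    def test_counts_and_strict_majority(self):
        catalog, pubs, links, citations = tiny_citation_fixture()
        out = B.discovery_citation_analysis(links, pubs, citations, catalog)
        per_pub = out["per_publication"]
        # pmid 13: 3 nonhuman vs 1 human -> numerator
        assert per_pub.loc[13, "has_nonhuman"] == 3
        assert bool(per_pub.loc[13, "nonhuman_dominant"])
        # pmid 21: 1 human vs 1 nonhuman -> tie is not dominant
        assert not bool(per_pub.loc[21, "nonhuman_dominant"])

    def test_publications_without_gene_citations_excluded(self):
        catalog, pubs, links, _ = tiny_citation_fixture()
        citations = CitationGraph(pd.DataFrame({"citing": [13],
                                                "cited": [10]}))
        out = B.discovery_citation_analysis(links, pubs, citations, catalog)
        # 13 has gene-bearing citations; the other discovery pubs have none
        assert out["n_excluded_no_gene_citations"] > 0
        assert 0.0 <= out["overall_fraction"] <= 1.0

    def test_builtin_nonhuman_preference_recovered(self, small_corpus):
        out = B.discovery_citation_analysis(
            small_corpus.gene_link_table, small_corpus.publication_table,
            small_corpus.citation_graph, small_corpus.gene_catalog)
        assert out["overall_fraction"] > 0.5


class TestOrganismEnrichment:
    def test_formula_on_synthetic_corpus(self, small_corpus):
        out = B.organism_citation_enrichment(
            small_corpus.gene_link_table, small_corpus.publication_table,
            small_corpus.citation_graph, small_corpus.gene_catalog)
        assert len(out) > 0
        ok = out[~out["censored"]]
        np.testing.assert_allclose(
            ok["log2_enrichment"],
            np.log2(ok["fraction_all"] / ok["fraction_conditional"]))

    def test_fractions_sum_to_one(self, small_corpus):
        out = B.organism_citation_enrichment(
            small_corpus.gene_link_table, small_corpus.publication_table,
            small_corpus.citation_graph, small_corpus.gene_catalog)
        assert out["fraction_all"].sum() == pytest.approx(1.0, abs=1e-9)


class TestHighlyCited:
    def _fixture(self):
        n = 100
        pubs = PublicationTable(pd.DataFrame({
            "pmid": range(n),
            "year": [2000] * n,
            "article_types": [("journal article",)] * n,
            "journal_id": 1,
        }))
        # publication i receives i citations from year 2008 (tie-free)
        rows = []
        extra = []
        pmid = 10_000
        for i in range(n):
            for _ in range(i):
                rows.append((pmid, i))
                extra.append(pmid)
                pmid += 1
        citing = PublicationTable(pd.DataFrame({
            "pmid": extra, "year": 2008,
            "article_types": [("journal article",)] * len(extra),
            "journal_id": 1,
        }))
        all_pubs = PublicationTable(pd.concat([pubs.table, citing.table],
                                              ignore_index=True))
        edges = CitationGraph(pd.DataFrame(rows, columns=["citing", "cited"]))
        return all_pubs, edges

    def test_exactly_top_five_percent_flagged(self):
        pubs, citations = self._fixture()
        out = B.highly_cited_flag(citations, pubs, horizon=8, top=0.05)
        flagged = out[out["highly_cited"]]
        assert set(flagged.index) == set(range(95, 100))

    def test_young_publications_excluded(self):
        pubs, citations = self._fixture()
        t = pubs.table.copy()
        t.loc[t["pmid"] == 0, "year"] = 2005  # younger than 2008 + horizon
        out = B.highly_cited_flag(citations, PublicationTable(t), horizon=8)
        assert 0 not in out.index

    def test_team_flag_more_than_two_authors(self):
        pubs, citations = self._fixture()
        authors = AuthorshipTable(pd.DataFrame({
            "pmid": [1, 1, 1, 2, 2],
            "position": [0, 1, 2, 0, 1],
            "author_id": [7, 8, 9, 7, 8],
        }))
        out = B.highly_cited_flag(citations, pubs, authors)
        assert bool(out.loc[1, "team"])
        assert not bool(out.loc[2, "team"])


class TestHumanSpecific:
    def _catalog(self):
        return GeneCatalog(pd.DataFrame({
            "gene_id": [1, 2, 3, 60],
            "symbol": ["A", "B", "C", "D"],
            "tax_id": [9606] * 4,
        }))

    def test_grouped_with_mouse_not_specific(self):
        homology = HomologyMap(pd.DataFrame({
            "group_id": [0, 0],
            "gene_id": [1, 99],
            "tax_id": [9606, 10090],
        }), max_human_id=50)
        out = B.human_specific_genes(self._catalog(), homology)
        assert 1 not in out["human_specific"]
        assert {2, 3} <= set(out["human_specific"])

    def test_ids_above_cap_excluded_entirely(self):
        homology = HomologyMap(pd.DataFrame({
            "group_id": [0, 0], "gene_id": [1, 99],
            "tax_id": [9606, 10090]}), max_human_id=50)
        out = B.human_specific_genes(self._catalog(), homology)
        assert 60 not in out["human_specific"]
        assert out["n_excluded_above_cap"] == 1

    def test_empty_map_makes_all_eligible_specific(self):
        cfg = SyntheticConfig(n_genes=60, seed=8, homolog_fraction=0.0,
                              generate_sequences=False)
        corpus = generate_corpus(cfg)
        out = B.human_specific_genes(corpus.gene_catalog, corpus.homology_map)
        human = corpus.gene_catalog.human_genes()
        eligible = human[human["gene_id"]
                         <= corpus.homology_map.max_human_id]
        assert set(out["human_specific"]) == set(eligible["gene_id"])


class TestPiTransition:
    def test_pi_definition(self):
        pubs = PublicationTable(pd.DataFrame({
            "pmid": [1, 2, 3, 4],
            "year": [2000, 2001, 2002, 2003],
            "article_types": [("journal article",)] * 4,
            "journal_id": 1,
        }))
        authors = AuthorshipTable(pd.DataFrame({
            # author 7: two last-author pubs with coauthors -> PI
            # author 9: two solo pubs -> never PI
            "pmid": [1, 1, 2, 2, 3, 4],
            "position": [0, 1, 0, 1, 0, 0],
            "author_id": [8, 7, 8, 7, 9, 9],
        }))
        team = authors.team_sizes()
        last = authors.last_authors()
        qualifying = last[last["pmid"].map(team) >= 2]
        assert set(qualifying["author_id"]) == {7}

    def test_null_corpus_profile_is_flat(self, small_corpus):
        out = B.pi_transition(small_corpus.authorship_table,
                              small_corpus.publication_table,
                              small_corpus.gene_link_table)
        p = out["transition_probability"].dropna()
        assert len(p) == 5
        # authors are assigned independently of gene attention, so the
        # profile varies only within sampling noise
        assert p.max() - p.min() < 0.015


class TestAuthorComposition:
    def test_fractions_partition_authors(self, small_corpus):
        out = B.author_taxon_composition(
            small_corpus.authorship_table, small_corpus.publication_table,
            small_corpus.gene_link_table, small_corpus.gene_catalog)
        totals = out.sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)
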