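"""Citation- and authorship-level analyses.

Record linkage between bibliographic tables (DOI first, then blocked
Levenshtein title matching), discovery-citation analysis of model
organisms, highly-cited fractions, human-specific genes, author
composition trends and principal-investigator transition statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    HUMAN_TAX_ID,
    AuthorshipTable,
    CitationGraph,
    GeneCatalog,
    GeneLinkTable,
    HomologyMap,
    PublicationTable,
)

logger = logging.getLogger(__name__)


def title_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on a 0-100 scale:
    100 x (1 - distance / max length)."""
    if not a and not b:
        return 100.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def link_records(
    source: pd.DataFrame, target: pd.DataFrame, threshold: float = 95.0
) -> pd.DataFrame:
    """Link bibliographic records across two tables.

    Both tables carry ``record_id``, optional ``doi``, ``last_names``
    (tuple), ``year``, ``journal`` and ``title``.  Step 1 links on exact,
    unique DOIs.  Step 2 blocks remaining source records on (last-name
    list, year, journal) and scores candidate titles by normalized
    Levenshtein similarity (0-100); a link requires a unique best
    candidate with score >= ``threshold`` — ties at the best score are
    rejected as ambiguous.
    """
    out = []
    tgt = target.copy()
    tgt["_key"] = list(zip(
        tgt["last_names"].map(tuple), tgt["year"], tgt["journal"]
    ))

    doi_counts = tgt["doi"].dropna().value_counts()
    unique_doi = tgt[tgt["doi"].map(
        lambda d: pd.notna(d) and doi_counts.get(d, 0) == 1)]
    doi_map = unique_doi.set_index("doi")["record_id"]
    by_key = tgt.groupby("_key")

    for row in source.itertuples(index=False):
        if pd.notna(row.doi) and row.doi in doi_map.index:
            out.append((row.record_id, doi_map.loc[row.doi], 100.0, "doi"))
            continue
        key = (tuple(row.last_names), row.year, row.journal)
        if key not in by_key.groups:
            continue
        cands = by_key.get_group(key)
        scores = cands["title"].map(lambda t: title_similarity(row.title, t))
        best = scores.max()
        if best < threshold:
            continue
        ties = (scores == best).sum()
        if ties > 1:
            logger.info("record %s: %d candidates tied at %.1f; rejected",
                        row.record_id, ties, best)
            continue
        out.append((row.record_id,
                    cands.loc[scores.idxmax(), "record_id"], float(best),
                    "title"))
    return pd.DataFrame(out, columns=["source_id", "target_id", "score",
                                      "method"])


def _pub_gene_taxa(links: GeneLinkTable, catalog: GeneCatalog) -> pd.DataFrame:
    tax_of = catalog.table.set_index("gene_id")["tax_id"]
    t = links.table.assign(tax=links.table["gene_id"].map(tax_of))
    return pd.DataFrame({
        "has_human": (t["tax"] == HUMAN_TAX_ID).groupby(t["pmid"]).any(),
        "has_nonhuman": (t["tax"] != HUMAN_TAX_ID).groupby(t["pmid"]).any(),
    })


def discovery_publications(
    links: GeneLinkTable, publications: PublicationTable,
    catalog: GeneCatalog,
) -> pd.Index:
    """Publications reporting a human gene within its discovery year."""
    tax_of = catalog.table.set_index("gene_id")["tax_id"]
    t = links.table.assign(year=links.table["pmid"].map(publications.years()))
    human = t[t["gene_id"].map(tax_of) == HUMAN_TAX_ID]
    first = human.groupby("gene_id")["year"].transform("min")
    return pd.Index(sorted(set(human.loc[human["year"] == first, "pmid"])))


def discovery_citation_analysis(
    links: GeneLinkTable,
    publications: PublicationTable,
    citations: CitationGraph,
    catalog: GeneCatalog,
) -> dict:
    """How often gene-discovery publications lean on nonhuman literature.

    For every discovery publication, counts cited publications carrying
    at least one human gene and at least one nonhuman gene, then reports
    the per-year fraction of discovery publications citing nonhuman-gene
    publications strictly more often than human-gene ones.  Discovery
    publications citing no gene-bearing publication are excluded from
    the denominator and counted.
    """
    disc = discovery_publications(links, publications, catalog)
    flags = _pub_gene_taxa(links, catalog)
    edges = citations.edges
    edges = edges[edges["citing"].isin(disc)]
    edges = edges.join(flags, on="cited")
    counts = edges.groupby("citing")[["has_human", "has_nonhuman"]].sum()
    counts = counts.reindex(disc, fill_value=0)
    gene_bearing = counts.sum(axis=1) > 0
    per_pub = counts[gene_bearing]
    per_pub = per_pub.assign(
        year=per_pub.index.map(publications.years()),
        nonhuman_dominant=per_pub["has_nonhuman"] > per_pub["has_human"],
    )
    per_year = per_pub.groupby("year")["nonhuman_dominant"].agg(
        ["mean", "size"]).rename(columns={"mean": "fraction", "size": "n"})
    return {
        "per_publication": per_pub,
        "per_year": per_year,
        "overall_fraction": float(per_pub["nonhuman_dominant"].mean())
        if len(per_pub) else np.nan,
        "n_excluded_no_gene_citations": int((~gene_bearing).sum()),
    }


def organism_citation_enrichment(
    links: GeneLinkTable,
    publications: PublicationTable,
    citations: CitationGraph,
    catalog: GeneCatalog,
) -> pd.DataFrame:
    """Per-taxon citation fractions of gene-discovery publications.

    For each nonhuman taxon: the fraction of that taxon among citations
    of all discovery publications on human genes, the same fraction
    restricted to discovery publications that also cite human-gene
    publications, and the log2 ratio of the two (censored where the
    conditional fraction is zero).
    """
    disc = discovery_publications(links, publications, catalog)
    tax_of = catalog.table.set_index("gene_id")["tax_id"]
    pub_taxa = (
        links.table.assign(tax=links.table["gene_id"].map(tax_of))
        .groupby("pmid")["tax"].apply(lambda t: frozenset(t))
    )
    flags = _pub_gene_taxa(links, catalog)

    edges = citations.edges
    edges = edges[edges["citing"].isin(disc)].copy()
    edges["cited_taxa"] = edges["cited"].map(pub_taxa)
    edges = edges.dropna(subset=["cited_taxa"])
    cites_human = edges.join(flags["has_human"], on="cited")
    citing_with_human = set(
        cites_human.loc[cites_human["has_human"].fillna(False), "citing"]
    )
    cond_edges = edges[edges["citing"].isin(citing_with_human)]

    def taxon_fractions(e: pd.DataFrame) -> pd.Series:
        expl = e.explode("cited_taxa")
        expl = expl[expl["cited_taxa"] != HUMAN_TAX_ID]
        if len(expl) == 0:
            return pd.Series(dtype=float)
        return expl["cited_taxa"].value_counts(normalize=True)

    f_all = taxon_fractions(edges)
    f_cond = taxon_fractions(cond_edges)
    taxa = sorted(set(f_all.index) | set(f_cond.index))
    rows = []
    for t in taxa:
        fa = float(f_all.get(t, 0.0))
        fc = float(f_cond.get(t, 0.0))
        rows.append({
            "tax_id": t,
            "fraction_all": fa,
            "fraction_conditional": fc,
            "log2_enrichment": np.log2(fa / fc) if fa > 0 and fc > 0 else np.nan,
            "censored": fc == 0 or fa == 0,
        })
    return pd.DataFrame(rows)


def highly_cited_flag(
    citations: CitationGraph,
    publications: PublicationTable,
    authorships: AuthorshipTable | None = None,
    horizon: int = 8,
    top: float = 0.05,
    consortium_pmids: frozenset = frozenset(),
) -> pd.DataFrame:
    """Flag publications in the top citation percentile over a horizon.

    Citations are counted within (year, year + horizon]; publications
    younger than the horizon relative to the corpus end are excluded.
    The flag is count >= the (1 - top) percentile of eligible counts
    (ties flagged inclusively).  ``team`` marks publications with more
    than two authors or a consortium as sole affiliation.
    """
    years = publications.years()
    corpus_end = int(publications.table["year"].max())
    eligible = years[years + horizon <= corpus_end]
    edges = citations.edges.copy()
    edges["citing_year"] = edges["citing"].map(years)
    edges["cited_year"] = edges["cited"].map(years)
    in_window = (
        (edges["citing_year"] > edges["cited_year"])
        & (edges["citing_year"] <= edges["cited_year"] + horizon)
    )
    counts = edges[in_window].groupby("cited").size()
    counts = counts.reindex(eligible.index, fill_value=0)
    if len(counts) == 0:
        return pd.DataFrame(columns=["year", "citations_in_horizon",
                                     "highly_cited"])
    cut = float(np.percentile(counts.to_numpy(), 100 * (1 - top)))
    out = pd.DataFrame({
        "year": eligible,
        "citations_in_horizon": counts,
        "highly_cited": counts >= cut,
    })
    if authorships is not None:
        team_sizes = authorships.team_sizes()
        out["team"] = (
            (team_sizes.reindex(out.index).fillna(0) > 2)
            | out.index.isin(consortium_pmids)
        )
    out.index.name = "pmid"
    return out


def human_specific_genes(
    catalog: GeneCatalog,
    homology: HomologyMap,
    attention: pd.Series | None = None,
) -> dict:
    """Human genes in no homology group with a nonhuman member.

    Only genes with ids up to the map's maximum eligible human id are
    analysed (genes above the cap could never have been grouped and are
    excluded entirely).  When attention is given, human-specific genes
    are compared against the other eligible genes by a one-sided
    rank-sum test (human-specific less studied).
    """
    hm = homology.table
    nonhuman_groups = homology.groups_with_nonhuman()
    grouped_with_nonhuman = set(
        hm.loc[hm["group_id"].isin(nonhuman_groups), "gene_id"]
    )
    human = catalog.human_genes()
    eligible = human.loc[human["gene_id"] <= homology.max_human_id, "gene_id"]
    specific = pd.Index(
        [g for g in eligible if g not in grouped_with_nonhuman], name="gene_id"
    )
    other = pd.Index(
        [g for g in eligible if g in grouped_with_nonhuman], name="gene_id"
    )
    result = {"human_specific": specific, "eligible_other": other,
              "n_excluded_above_cap": int((human["gene_id"]
                                           > homology.max_human_id).sum())}
    if attention is not None and len(specific) and len(other):
        a = attention.reindex(specific).fillna(0.0)
        b = attention.reindex(other).fillna(0.0)
        test = stats.mannwhitneyu(a, b, alternative="less")
        result["pvalue"] = float(test.pvalue)
        result["median_specific"] = float(a.median())
        result["median_other"] = float(b.median())
    return result


def _cumulative_attention(
    links: GeneLinkTable, publications: PublicationTable
) -> pd.DataFrame:
    """Genes x years matrix of fractional attention accumulated up to and
    including each year."""
    t = links.table.merge(publications.table[["pmid", "year"]], on="pmid")
    k = t.groupby("pmid")["gene_id"].transform("size")
    t = t.assign(weight=1.0 / k)
    yearly = t.pivot_table(index="gene_id", columns="year", values="weight",
                           aggfunc="sum", fill_value=0.0)
    years = np.arange(publications.table["year"].min(),
                      publications.table["year"].max() + 1)
    yearly = yearly.reindex(columns=years, fill_value=0.0)
    return yearly.cumsum(axis=1)


def pi_transition(
    authorships: AuthorshipTable,
    publications: PublicationTable,
    links: GeneLinkTable,
    n_quantiles: int = 5,
    reference_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Transition probability to principal-investigator status by the
    attention quintile of an author's publications.

    PI status: at least two last-author publications each with at least
    one fellow coauthor; the transition year is the year of the second
    such publication.  For every author-publication before the author's
    transition (or for authors who never transition), the publication is
    scored by the median cumulative fractional attention of its genes up
    to its year and assigned to an attention quintile via the
    tie-averaged percentile rank of that median among all genes in the
    same year (yearly cohorts).  Transition probabilities are
    standardized across yearly cohorts — each quintile's probability is
    the year-share-weighted mean of per-(year, quintile) probabilities —
    so career stage and calendar year do not confound the profile.

    ``reference_years`` bounds the cohort grid (inclusive); the default
    is the most recent third of the corpus, where the attention
    distribution is established enough that every quantile bin is
    populated.  Early years, where cumulative attention is still mostly
    zero and rank ties collapse publications into the middle bins, would
    otherwise couple bin occupancy to calendar year.
    """
    auth = authorships.table
    years = publications.years()
    team = authorships.team_sizes()
    last = authorships.last_authors()
    qualifying = last[last["pmid"].map(team) >= 2].copy()
    qualifying["year"] = qualifying["pmid"].map(years)
    qualifying = qualifying.sort_values(["author_id", "year", "pmid"])
    qualifying["rank"] = qualifying.groupby("author_id").cumcount() + 1
    transition_year = (
        qualifying[qualifying["rank"] == 2].set_index("author_id")["year"]
    )

    cum = _cumulative_attention(links, publications)
    pub_genes = links.table.groupby("pmid")["gene_id"].apply(list)
    if reference_years is None:
        lo = int(publications.table["year"].min())
        hi = int(publications.table["year"].max())
        reference_years = (hi - max(1, (hi - lo) // 3), hi)

    rows = []
    for row in auth.itertuples(index=False):
        year = years.get(row.pmid)
        if year is None or row.pmid not in pub_genes.index:
            continue
        if not reference_years[0] <= year <= reference_years[1]:
            continue
        t_year = transition_year.get(row.author_id)
        if t_year is not None and not pd.isna(t_year) and year >= t_year:
            continue  # already a PI at publication time
        genes = [g for g in pub_genes.loc[row.pmid] if g in cum.index]
        if not genes:
            continue
        med = float(np.median(cum.loc[genes, int(year)]))
        became_pi = t_year is not None and not pd.isna(t_year)
        rows.append((int(year), med, became_pi))
    frame = pd.DataFrame(rows, columns=["year", "median_attention",
                                        "transition"])
    if len(frame) == 0:
        return pd.DataFrame({"n": 0, "transition_probability": np.nan},
                            index=pd.RangeIndex(n_quantiles, name="quintile"))

    # quintile of the median among all genes of the same year (ties
    # averaged, so a mass of zero-attention genes maps to mid-ranks)
    quintile = np.empty(len(frame), dtype=int)
    for year, idx in frame.groupby("year").groups.items():
        gene_vals = np.sort(cum[int(year)].to_numpy())
        med = frame.loc[idx, "median_attention"].to_numpy()
        lo = np.searchsorted(gene_vals, med, side="left")
        hi = np.searchsorted(gene_vals, med, side="right")
        mid = (lo + hi) / 2.0 / len(gene_vals)
        quintile[frame.index.get_indexer(idx)] = np.minimum(
            n_quantiles - 1, (mid * n_quantiles).astype(int))
    frame["quintile"] = quintile

    cells = frame.groupby(["year", "quintile"])["transition"].agg(
        ["size", "mean"])
    year_weight = frame.groupby("year").size() / len(frame)
    rows_out = []
    for q in range(n_quantiles):
        sub = cells.xs(q, level="quintile", drop_level=True) \
            if q in cells.index.get_level_values("quintile") else None
        if sub is None or len(sub) == 0:
            rows_out.append((q, 0, np.nan))
            continue
        w = year_weight.reindex(sub.index).to_numpy()
        p = float(np.average(sub["mean"].to_numpy(), weights=w))
        rows_out.append((q, int(sub["size"].sum()), p))
    out = pd.DataFrame(rows_out, columns=["quintile", "n",
                                          "transition_probability"])
    return out.set_index("quintile")


def author_taxon_composition(
    authorships: AuthorshipTable,
    publications: PublicationTable,
    links: GeneLinkTable,
    catalog: GeneCatalog,
) -> pd.DataFrame:
    """Per-year fractions of authors publishing exclusively on human
    genes, exclusively on nonhuman genes, or on both."""
    flags = _pub_gene_taxa(links, catalog)
    t = authorships.table.copy()
    t["year"] = t["pmid"].map(publications.years())
    t = t.join(flags, on="pmid").dropna(subset=["has_human", "has_nonhuman"])
    per_author = t.groupby(["year", "author_id"])[
        ["has_human", "has_nonhuman"]].any()
    both = per_author["has_human"] & per_author["has_nonhuman"]
    only_human = per_author["has_human"] & ~per_author["has_nonhuman"]
    only_nonhuman = ~per_author["has_human"] & per_author["has_nonhuman"]
    out = pd.DataFrame({
        "only_human": only_human.groupby(level="year").mean(),
        "only_nonhuman": only_nonhuman.groupby(level="year").mean(),
        "both": both.groupby(level="year").mean(),
    })
    return out
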