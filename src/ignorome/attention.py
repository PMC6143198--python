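"""Publication-attention accounting.

Defines the analysis universe (reference research publications and
reference genes) and computes attention statistics: fractional counts
(each publication contributes 1/k to each of its k linked genes), Gini
inequality and Lorenz curves, discovery years, recent-trend and
attention enrichments, gene-family first-vs-second comparisons, the
studied/unstudied threshold, coverage extrapolation and bootstrap CIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import (
    HUMAN_TAX_ID,
    GeneCatalog,
    GeneLinkTable,
    PublicationTable,
    rng_from,
)

logger = logging.getLogger(__name__)

#: MEDLINE article types that qualify a record as a research publication.
ARTICLE_TYPE_WHITELIST = frozenset({
    "case report",
    "classical article",
    "clinical trial",
    "clinical trial phase i",
    "clinical trial phase ii",
    "clinical trial phase iii",
    "clinical trial phase iv",
    "comparative study",
    "historical article",
    "journal article",
    "meta analysis",
    "multicenter study",
    "randomized controlled trial",
    "twin study",
    "validation study",
})


def filter_reference_publications(
    publications: PublicationTable,
    whitelist: frozenset = ARTICLE_TYPE_WHITELIST,
    review_journal_threshold: float = 0.5,
) -> PublicationTable:
    """Restrict to reference research publications.

    Keeps publications that (a) carry at least one whitelisted article
    type, (b) are not themselves labelled "review", and (c) do not appear
    in a journal where at least half of all articles are reviews (the
    boundary is inclusive).
    """
    t = publications.table
    types = t["article_types"]
    is_review = types.map(lambda labels: "review" in labels)
    journal_review_rate = is_review.groupby(t["journal_id"]).mean()
    bad_journal = t["journal_id"].map(
        journal_review_rate >= review_journal_threshold
    )
    whitelisted = types.map(lambda labels: bool(set(labels) & whitelist))
    keep = whitelisted & ~is_review & ~bad_journal
    return PublicationTable(t[keep].reset_index(drop=True))


def select_reference_genes(
    catalog: GeneCatalog,
    links: GeneLinkTable,
    reference_publications: PublicationTable,
) -> pd.Index:
    """Human genes with an official symbol and >=1 reference publication."""
    human = catalog.human_genes()
    named = human[human["symbol"].str.len() > 0]
    ref_pmids = set(reference_publications.table["pmid"])
    linked = set(links.table.loc[links.table["pmid"].isin(ref_pmids), "gene_id"])
    return pd.Index(sorted(set(named["gene_id"]) & linked), name="gene_id")


def fractional_attention(
    links: GeneLinkTable,
    publications: PublicationTable,
    timeframe: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-gene fractional and plain publication counts.

    A publication linking k genes contributes 1/k to each, so the summed
    fractional count over genes equals the number of gene-linked
    publications in the timeframe (both bounds inclusive).
    """
    t = links.table.merge(publications.table[["pmid", "year"]], on="pmid")
    if timeframe is not None:
        lo, hi = timeframe
        t = t[(t["year"] >= lo) & (t["year"] <= hi)]
    k = t.groupby("pmid")["gene_id"].transform("size")
    t = t.assign(weight=1.0 / k)
    out = t.groupby("gene_id").agg(
        fractional=("weight", "sum"), count=("pmid", "size")
    )
    out.index.name = "gene_id"
    return out


def gini(values: Sequence[float]) -> float:
    """Gini coefficient: mean absolute pairwise difference / (2 * mean).

    Pairwise differences are averaged over all ordered pairs (n^2), so
    equal values give 0 and a single holder among n gives (n-1)/n.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if (x < 0).any():
        raise ValueError("values must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for all-zero values")
    x = np.sort(x)
    n = x.size
    # sorted-form identity for the mean absolute difference
    return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * total))


def gini_per_year(
    links: GeneLinkTable, publications: PublicationTable, years: Sequence[int]
) -> pd.Series:
    """Gini of fractional attention across genes, per calendar year."""
    out = {}
    for y in years:
        att = fractional_attention(links, publications, (y, y))
        if len(att) >= 2 and att["fractional"].sum() > 0:
            out[y] = gini(att["fractional"].to_numpy())
    return pd.Series(out, name="gini")


def cumulative_share(attention: pd.Series) -> pd.DataFrame:
    """Lorenz-style curve: cumulative attention share of the top genes.

    Genes are sorted by descending attention; row i gives the fraction of
    genes considered and the fraction of total attention they cover.
    """
    if len(attention) == 0:
        raise ValueError("attention table is empty")
    x = np.sort(np.asarray(attention, dtype=float))[::-1]
    n = x.size
    return pd.DataFrame({
        "gene_fraction": np.arange(1, n + 1) / n,
        "attention_share": np.cumsum(x) / x.sum(),
    })


def discovery_year(
    links: GeneLinkTable, publications: PublicationTable
) -> pd.Series:
    """Earliest reference-publication year per gene (NaN if unlinked)."""
    t = links.table.merge(publications.table[["pmid", "year"]], on="pmid")
    return t.groupby("gene_id")["year"].min().rename("discovery_year")


def recent_trend_enrichment(
    links: GeneLinkTable,
    publications: PublicationTable,
    past_window: tuple[int, int],
    recent_window: tuple[int, int],
    min_recent: int = 10,
) -> pd.DataFrame:
    """Per-gene log2 fold change of recent over (rescaled) past counts.

    Past plain counts are rescaled so the total number of gene-publication
    pairs matches the recent window; only genes with at least
    ``min_recent`` recent publications are reported.  Genes with a zero
    past count receive the scaling factor as a floor pseudo-count.
    """
    if not (past_window[1] < recent_window[0] or recent_window[1] < past_window[0]):
        raise ValueError("windows must be disjoint")
    past = fractional_attention(links, publications, past_window)["count"]
    recent = fractional_attention(links, publications, recent_window)["count"]
    if past.sum() == 0:
        raise ValueError("no gene-publication pairs in the past window")
    scale = recent.sum() / past.sum()
    eligible = recent[recent >= min_recent]
    scaled_past = past.reindex(eligible.index, fill_value=0).astype(float) * scale
    floored = scaled_past == 0
    if floored.any():
        logger.info("floor pseudo-count applied to %d genes", int(floored.sum()))
        scaled_past[floored] = scale
    return pd.DataFrame({
        "recent": eligible,
        "scaled_past": scaled_past,
        "log2_fold_change": np.log2(eligible / scaled_past),
    })


def attention_enrichment(
    attention: pd.Series, timeframe_total: float, n_reference_genes: int
) -> pd.DataFrame:
    """log2 of a gene's fractional count over the equal-share baseline.

    The baseline is (total publications in the timeframe) / (number of
    reference genes).  Genes with zero attention are censored (-inf).
    """
    if timeframe_total <= 0 or n_reference_genes <= 0:
        raise ValueError("totals must be positive")
    baseline = timeframe_total / n_reference_genes
    with np.errstate(divide="ignore"):
        enr = np.log2(np.asarray(attention, dtype=float) / baseline)
    return pd.DataFrame(
        {"log2_enrichment": enr, "censored": ~np.isfinite(enr)},
        index=attention.index,
    )


def _family_stem(symbol: str) -> tuple[str, int] | None:
    """Split a symbol into (stem, trailing integer); None if no match.

    The maximal trailing integer is stripped; stems shorter than two
    characters are ignored to guard against symbols like "T2".
    """
    i = len(symbol)
    while i > 0 and symbol[i - 1].isdigit():
        i -= 1
    if i == len(symbol) or i < 2:
        return None
    return symbol[:i], int(symbol[i:])


def family_first_second(
    catalog: GeneCatalog, attention: pd.Series
) -> dict:
    """Compare attention of the first vs second member of gene families.

    Families are symbol stems with both a trailing-1 and a trailing-2
    entry (e.g. AKT1/AKT2).  Returns the paired table, the Spearman rank
    correlation across pairs, and a one-sided Mann-Whitney U test of
    first > second.
    """
    stems: dict[str, dict[int, int]] = {}
    for gene_id, symbol in zip(catalog.table["gene_id"], catalog.table["symbol"]):
        parsed = _family_stem(str(symbol))
        if parsed is None:
            continue
        stem, num = parsed
        if num in (1, 2):
            stems.setdefault(stem, {})[num] = gene_id
    rows = [
        (stem, members[1], members[2])
        for stem, members in sorted(stems.items())
        if 1 in members and 2 in members
    ]
    pairs = pd.DataFrame(rows, columns=["stem", "gene_1", "gene_2"])
    pairs["attention_1"] = pairs["gene_1"].map(attention).fillna(0.0)
    pairs["attention_2"] = pairs["gene_2"].map(attention).fillna(0.0)
    result = {"pairs": pairs, "spearman": np.nan, "pvalue": np.nan}
    if len(pairs) >= 2:
        result["spearman"] = float(
            stats.spearmanr(pairs["attention_1"], pairs["attention_2"]).statistic
        )
        result["pvalue"] = float(
            stats.mannwhitneyu(
                pairs["attention_1"], pairs["attention_2"], alternative="greater"
            ).pvalue
        )
    return result


def unstudied_flag(attention: pd.Series, threshold: float = 1.0) -> pd.Series:
    """True for genes with attention strictly below the threshold.

    A gene at exactly the threshold counts as studied (documented
    boundary).
    """
    return (attention < threshold).rename("unstudied")


@dataclass
class CoverageExtrapolation:
    """Linear extrapolation of single-gene-study coverage."""

    fractions: pd.Series
    slope: float
    intercept: float
    years_to_full: float

    def projected_year(self) -> float:
        if not np.isfinite(self.years_to_full):
            return float("inf")
        return float(self.fractions.index.max() + self.years_to_full)


def coverage_extrapolation(
    links: GeneLinkTable,
    publications: PublicationTable,
    n_genes_total: int,
    min_pubs: int = 1,
    fit_window: tuple[int, int] | None = None,
) -> CoverageExtrapolation:
    """Fraction of genes with >= n focused (single-gene) publications.

    Counts, per year, the cumulative fraction of all ``n_genes_total``
    genes having at least ``min_pubs`` single-gene reference publications
    so far, fits an ordinary least-squares line over ``fit_window``, and
    extrapolates the years remaining until full coverage.  A nonpositive
    slope yields an infinity sentinel.
    """
    t = links.table.merge(publications.table[["pmid", "year"]], on="pmid")
    k = t.groupby("pmid")["gene_id"].transform("size")
    single = t[k == 1]
    first_single = single.groupby("gene_id")["year"].apply(
        lambda y: np.sort(y.to_numpy())[min_pubs - 1]
        if len(y) >= min_pubs else np.nan
    ).dropna()
    years = np.arange(
        publications.table["year"].min(), publications.table["year"].max() + 1
    )
    fractions = pd.Series(
        [(first_single <= y).sum() / n_genes_total for y in years],
        index=years, name="fraction_covered",
    )
    if fit_window is None:
        fit_window = (int(years.max()) - 4, int(years.max()))
    lo, hi = fit_window
    window = fractions[(fractions.index >= lo) & (fractions.index <= hi)]
    if len(window) < 3:
        raise ValueError("need at least 3 years in the fit window")
    X = sm.add_constant(window.index.to_numpy(dtype=float))
    fit = sm.OLS(window.to_numpy(), X).fit()
    intercept, slope = fit.params
    last_year = fractions.index.max()
    last_frac = fractions.loc[last_year]
    if slope <= 1e-12:
        warnings.warn("nonpositive coverage slope; extrapolation diverges",
                      stacklevel=2)
        years_to_full = float("inf")
    else:
        years_to_full = max(0.0, (1.0 - last_frac) / slope)
    return CoverageExtrapolation(fractions, float(slope), float(intercept),
                                 float(years_to_full))


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    level: float = 0.95,
    resamples: int = 1000,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a statistic."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if resamples < 2:
        warnings.warn("too few resamples for a meaningful interval", stacklevel=2)
    rng = rng_from(seed)
    draws = np.array([
        statistic(x[rng.integers(0, x.size, x.size)]) for _ in range(resamples)
    ])
    alpha = (1 - level) / 2
    return (float(np.quantile(draws, alpha)), float(np.quantile(draws, 1 - alpha)))
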