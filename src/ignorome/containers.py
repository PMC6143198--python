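"""Shared in-memory containers for the analysis.

Every container wraps one or more :class:`pandas.DataFrame` objects in the
column layouts of the NCBI-style link tables the analysis consumes
(gene2pubmed-like link tables, gene_info-like catalogs, HomoloGene-like
group tables, ExPORTER-like grant tables).  All sequence intervals are
0-based half-open unless a function documents otherwise (GWAS intervals
are 1-based inclusive, matching catalog conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

HUMAN_TAX_ID = 9606

#: Default invertebrate model organisms (fly, worm) used for the M flag.
INVERTEBRATE_MODEL_TAXA = frozenset({7227, 6239})


@dataclass
class GeneCatalog:
    """Reference genes with identifiers, symbols, taxon and sequences.

    ``table`` columns: ``gene_id`` (int), ``symbol`` (str), ``tax_id``
    (int), ``chrom`` (str), ``start``/``end`` (1-based inclusive genomic
    span), ``cds`` (str), ``protein`` (str), ``partner_gene_id``
    (nullable int; for nonhuman genes, the human gene they are homologous
    to), ``source_tier`` (int; 1 = curated, 2 = unreviewed protein entry).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def human_genes(self) -> pd.DataFrame:
        return self.table[self.table["tax_id"] == HUMAN_TAX_ID]

    def nonhuman_genes(self) -> pd.DataFrame:
        return self.table[self.table["tax_id"] != HUMAN_TAX_ID]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FeatureMatrix:
    """Genes x named features with a missingness mask.

    ``values`` is a float DataFrame indexed by gene id; ``missing`` is a
    boolean DataFrame of identical shape (True = absent).  Missing cells
    hold NaN in ``values``.  ``zscored`` records whether columns have been
    standardized; ``constant_features`` lists columns that were constant
    at z-scoring time (set to 0).
    """

    values: pd.DataFrame
    missing: pd.DataFrame | None = None
    zscored: bool = False
    constant_features: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = self.values.isna()
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape must match values")
        self.missing = self.missing.astype(bool)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.missing.copy(), self.zscored, self.constant_features
        )

    def complete_genes(self) -> pd.Index:
        """Genes with no missing feature (the complete-catalog subset)."""
        return self.values.index[~self.missing.any(axis=1)]


@dataclass
class PublicationTable:
    """Publications with year, MEDLINE-style article types and journal.

    ``table`` columns: ``pmid`` (int), ``year`` (int), ``article_types``
    (tuple of lowercase labels), ``journal_id`` (int).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["pmid"].duplicated().any():
            raise ValueError("pmids must be unique")

    def years(self) -> pd.Series:
        return self.table.set_index("pmid")["year"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneLinkTable:
    """gene2pubmed-style links: ``tax_id``, ``gene_id``, ``pmid``."""

    table: pd.DataFrame

    def restrict(self, gene_ids: Iterable[int] | None = None,
                 pmids: Iterable[int] | None = None) -> "GeneLinkTable":
        t = self.table
        if gene_ids is not None:
            t = t[t["gene_id"].isin(set(gene_ids))]
        if pmids is not None:
            t = t[t["pmid"].isin(set(pmids))]
        return GeneLinkTable(t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GrantTable:
    """ExPORTER-style projects: ``project_id``, ``year``, ``amount`` and a
    ``pmids`` tuple of supported publications per row."""

    table: pd.DataFrame

    def support_links(self) -> pd.DataFrame:
        """Explode to one (project_id, pmid) row per support link."""
        if len(self.table) == 0:
            return pd.DataFrame(columns=["project_id", "pmid"])
        t = self.table[["project_id", "pmids"]].explode("pmids").dropna()
        return t.rename(columns={"pmids": "pmid"}).reset_index(drop=True)


@dataclass
class HomologyMap:
    """HomoloGene-style groups: ``group_id``, ``gene_id``, ``tax_id``.

    ``max_human_id`` is the largest human gene id that was eligible for
    grouping; human-specific analyses only consider ids up to this cap.
    """

    table: pd.DataFrame
    max_human_id: int = 0

    def groups_with_nonhuman(self) -> pd.Index:
        has_nonhuman = self.table.groupby("group_id")["tax_id"].apply(
            lambda t: (t != HUMAN_TAX_ID).any()
        )
        return has_nonhuman.index[has_nonhuman]


@dataclass
class GwasTable:
    """GWAS-catalog-style associations: ``study_id``, ``trait``, ``chrom``,
    ``start``, ``end`` (1-based inclusive interval of the association)."""

    table: pd.DataFrame


@dataclass
class CitationGraph:
    """Directed citation edges: ``citing`` -> ``cited`` publication ids."""

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges["citing"] == self.edges["cited"]).any():
            raise ValueError("self-citations are not allowed")

    def cited_by(self) -> pd.core.groupby.SeriesGroupBy:
        return self.edges.groupby("citing")["cited"]


@dataclass
class AuthorshipTable:
    """Ordered bylines: ``pmid``, ``position`` (0-based), ``author_id``."""

    table: pd.DataFrame

    def last_authors(self) -> pd.DataFrame:
        idx = self.table.groupby("pmid")["position"].idxmax()
        return self.table.loc[idx]

    def team_sizes(self) -> pd.Series:
        return self.table.groupby("pmid")["author_id"].size()


@dataclass
class ScreenTables:
    """Per-gene large-scale experiment calls.

    ``rnai``: ``gene_id``, ``study_id``, ``phenotype`` (bool),
    ``via_shrna`` (bool; abundance-readout screens, excluded upstream).
    ``diff_expr``: ``gene_id``, ``experiment_id``, ``pvalue``.
    ``affinity``: ``gene_id``, ``affinity_western`` (bool).
    """

    rnai: pd.DataFrame
    diff_expr: pd.DataFrame
    affinity: pd.DataFrame


@dataclass
class GroundTruth:
    """Latent generative state of a synthetic corpus."""

    latent_intensity: pd.Series
    causal_features: list[str]
    discovery_year: pd.Series


@dataclass
class SyntheticCorpus:
    """A complete synthetic study universe with known ground truth."""

    gene_catalog: GeneCatalog
    feature_matrix: FeatureMatrix
    publication_table: PublicationTable
    gene_link_table: GeneLinkTable
    grant_table: GrantTable | None = None
    cpi: pd.Series | None = None
    homology_map: HomologyMap | None = None
    gwas_table: GwasTable | None = None
    citation_graph: CitationGraph | None = None
    authorship_table: AuthorshipTable | None = None
    screen_tables: ScreenTables | None = None
    fpkm_table: pd.DataFrame | None = None
    ground_truth: GroundTruth | None = None
    config: object = None

    def validate(self) -> None:
        """Check referential integrity and the discovery-year invariant."""
        genes = set(self.gene_catalog.table["gene_id"])
        pmids = set(self.publication_table.table["pmid"])
        links = self.gene_link_table.table
        if not set(links["gene_id"]).issubset(genes):
            raise AssertionError("link table references unknown genes")
        if not set(links["pmid"]).issubset(pmids):
            raise AssertionError("link table references unknown publications")
        if self.ground_truth is not None:
            years = self.publication_table.years()
            earliest = (
                links.assign(year=links["pmid"].map(years))
                .groupby("gene_id")["year"].min()
            )
            truth = self.ground_truth.discovery_year.dropna()
            common = earliest.index.intersection(truth.index)
            if not (earliest.loc[common] == truth.loc[common]).all():
                raise AssertionError("discovery years disagree with earliest links")


def as_tuple_column(values: pd.Series) -> pd.Series:
    """Coerce a column of iterables (or '|'-joined strings) to tuples."""
    def conv(v):
        if isinstance(v, tuple):
            return v
        if isinstance(v, str):
            return tuple(s for s in v.split("|") if s)
        return tuple(v)
    return values.map(conv)


def rng_from(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
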