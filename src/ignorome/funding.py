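"""Per-gene research-funding allocation.

Splits each project's inflation-adjusted budget equally across the
publications it supports, then each publication's share equally across
its linked genes, yielding per-gene totals whose sum is conserved
(projects reaching no gene-linked publication are reported, not
silently dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneLinkTable, GrantTable

logger = logging.getLogger(__name__)


def inflation_adjust(
    amounts: pd.Series, years: pd.Series, cpi: pd.Series, base_year: int
) -> pd.Series:
    """Express nominal amounts in base-year currency: amount x
    CPI(base) / CPI(year).  Every year present must have a CPI entry."""
    if (amounts < 0).any():
        raise ValueError("amounts must be nonnegative")
    missing = set(years.unique()) - set(cpi.index)
    if missing or base_year not in cpi.index:
        raise ValueError(f"CPI series missing years: {sorted(missing) or [base_year]}")
    return amounts * (cpi.loc[base_year] / years.map(cpi).to_numpy())


@dataclass
class AllocationResult:
    """Per-gene funding totals plus conservation diagnostics."""

    table: pd.DataFrame            # gene_id, total_allocated, grant_count
    conserved_total: float         # adjusted money reaching >=1 gene
    unallocated_no_publication: float
    absorbed_no_genes: float


def allocate_funding(
    grants: GrantTable,
    links: GeneLinkTable,
    cpi: pd.Series | None = None,
    base_year: int | None = None,
) -> AllocationResult:
    """Equal-split allocation of project money to genes.

    Duplicate rows of one project id are summed first (amounts add,
    supported publications union).  Each project's adjusted amount is
    divided equally over its supported publications; each publication's
    share is divided equally over its linked genes.  Publications with no
    linked gene absorb their share, which is removed from the conserved
    total and reported; projects supporting no publication are likewise
    reported.  Genes also receive a distinct-grant count.
    """
    t = grants.table
    empty = pd.DataFrame(
        {"gene_id": pd.Series(dtype=int),
         "total_allocated": pd.Series(dtype=float),
         "grant_count": pd.Series(dtype=int)}
    )
    if len(t) == 0:
        return AllocationResult(empty, 0.0, 0.0, 0.0)
    merged = t.groupby("project_id").agg(
        year=("year", "min"),
        amount=("amount", "sum"),
        pmids=("pmids", lambda ps: tuple(sorted({p for tup in ps for p in tup}))),
    ).reset_index()
    if cpi is not None:
        if base_year is None:
            base_year = int(cpi.index.max())
        merged["adjusted"] = inflation_adjust(
            merged["amount"], merged["year"], cpi, base_year
        )
    else:
        merged["adjusted"] = merged["amount"].astype(float)

    no_pubs = merged["pmids"].map(len) == 0
    unallocated = float(merged.loc[no_pubs, "adjusted"].sum())
    if unallocated:
        logger.info("%d projects support no publication (%.2f unallocated)",
                    int(no_pubs.sum()), unallocated)
    active = merged[~no_pubs]

    support = active[["project_id", "adjusted", "pmids"]].explode("pmids")
    support = support.rename(columns={"pmids": "pmid"})
    support["pub_share"] = support["adjusted"] / support.groupby(
        "project_id")["pmid"].transform("size")

    genes_per_pub = links.table.groupby("pmid")["gene_id"].nunique()
    support["n_genes"] = support["pmid"].map(genes_per_pub).fillna(0).astype(int)
    absorbed = float(support.loc[support["n_genes"] == 0, "pub_share"].sum())
    funded = support[support["n_genes"] > 0]

    gene_links = links.table[["pmid", "gene_id"]].drop_duplicates()
    flow = funded.merge(gene_links, on="pmid")
    flow["gene_share"] = flow["pub_share"] / flow["n_genes"]
    table = flow.groupby("gene_id").agg(
        total_allocated=("gene_share", "sum"),
        grant_count=("project_id", "nunique"),
    ).reset_index()
    conserved = float(funded["pub_share"].sum())
    return AllocationResult(table, conserved, unallocated, absorbed)


def funding_targets(
    allocation: AllocationResult, links: GeneLinkTable
) -> dict:
    """Prediction target and diagnostics from an allocation.

    Returns the log10-transformed per-gene totals (zero-funded genes are
    excluded from the log target and counted) and a diagnostics table of
    grant counts versus publication counts per gene.
    """
    t = allocation.table.set_index("gene_id")
    positive = t[t["total_allocated"] > 0]
    target = np.log10(positive["total_allocated"]).rename("log10_funding")
    pub_counts = links.table.groupby("gene_id")["pmid"].nunique()
    diagnostics = pd.DataFrame({
        "grant_count": t["grant_count"],
        "publication_count": pub_counts.reindex(t.index).fillna(0).astype(int),
    })
    return {
        "target": target,
        "n_zero_funding": int((t["total_allocated"] <= 0).sum()),
        "diagnostics": diagnostics,
    }
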