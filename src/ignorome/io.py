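"""Readers and writers for the NCBI-style table layouts.

TSV layouts mirror the public link tables the analysis consumes:
gene2pubmed (tax_id, GeneID, PubMed_ID), gene_info-like catalogs,
HomoloGene group tables and an ExPORTER-like grants table
(project_id, year, amount, pmids pipe-joined).  Sequences are written
as uncompressed FASTA.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    GeneCatalog,
    GeneLinkTable,
    GrantTable,
    PublicationTable,
    SyntheticCorpus,
)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(name), description="")
        for name, seq in sequences.items() if seq
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gene2pubmed(links: GeneLinkTable, path) -> None:
    out = links.table.rename(columns={
        "tax_id": "#tax_id", "gene_id": "GeneID", "pmid": "PubMed_ID"})
    out[["#tax_id", "GeneID", "PubMed_ID"]].to_csv(path, sep="\t", index=False)


def read_gene2pubmed(path) -> GeneLinkTable:
    t = pd.read_csv(path, sep="\t")
    t.columns = ["tax_id", "gene_id", "pmid"]
    return GeneLinkTable(t)


def write_publications(pubs: PublicationTable, path) -> None:
    out = pubs.table.copy()
    out["article_types"] = out["article_types"].map("|".join)
    out.to_csv(path, sep="\t", index=False)


def read_publications(path) -> PublicationTable:
    t = pd.read_csv(path, sep="\t")
    t["article_types"] = t["article_types"].fillna("").map(
        lambda s: tuple(x for x in str(s).split("|") if x))
    return PublicationTable(t)


def write_grants(grants: GrantTable, path) -> None:
    out = grants.table.copy()
    if len(out):
        out["pmids"] = out["pmids"].map(
            lambda ps: "|".join(str(p) for p in ps))
    out.to_csv(path, sep="\t", index=False)


def read_grants(path) -> GrantTable:
    t = pd.read_csv(path, sep="\t")
    if len(t):
        t["pmids"] = t["pmids"].fillna("").map(
            lambda s: tuple(int(x) for x in str(s).split("|") if x))
    return GrantTable(t)


def write_feature_table(values: pd.DataFrame, path) -> None:
    """Long-format feature TSV: gene_id, feature, value."""
    long = values.stack().rename("value").reset_index()
    long.columns = ["gene_id", "feature", "value"]
    long.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    return long.pivot(index="gene_id", columns="feature", values="value")


def write_corpus(corpus: SyntheticCorpus, outdir) -> None:
    """Write a synthetic corpus as FASTA + TSV files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cat = corpus.gene_catalog.table
    cat.drop(columns=["cds", "protein"]).to_csv(
        out / "gene_info.tsv", sep="\t", index=False)
    write_fasta(dict(zip(cat["gene_id"].astype(str), cat["cds"])),
                out / "cds.fasta")
    write_fasta(dict(zip(cat["gene_id"].astype(str), cat["protein"])),
                out / "protein.fasta")
    corpus.feature_matrix.values.to_csv(out / "features.tsv", sep="\t")
    write_publications(corpus.publication_table, out / "publications.tsv")
    write_gene2pubmed(corpus.gene_link_table, out / "gene2pubmed.tsv")
    if corpus.fpkm_table is not None:
        corpus.fpkm_table.to_csv(out / "fpkm.tsv", sep="\t")
    if corpus.grant_table is not None:
        write_grants(corpus.grant_table, out / "grants.tsv")
    if corpus.cpi is not None:
        corpus.cpi.rename_axis("year").to_csv(out / "cpi.tsv", sep="\t")
    if corpus.homology_map is not None:
        corpus.homology_map.table.to_csv(
            out / "homologene.tsv", sep="\t", index=False)
    if corpus.gwas_table is not None:
        corpus.gwas_table.table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    if corpus.citation_graph is not None:
        corpus.citation_graph.edges.to_csv(
            out / "citations.tsv", sep="\t", index=False)
    if corpus.authorship_table is not None:
        corpus.authorship_table.table.to_csv(
            out / "authorships.tsv", sep="\t", index=False)
    if corpus.screen_tables is not None:
        corpus.screen_tables.rnai.to_csv(out / "rnai.tsv", sep="\t", index=False)
        corpus.screen_tables.diff_expr.to_csv(
            out / "diff_expr.tsv", sep="\t", index=False)
        corpus.screen_tables.affinity.to_csv(
            out / "affinity.tsv", sep="\t", index=False)
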