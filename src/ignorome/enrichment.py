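"""Annotation statistics and per-gene evidence flags.

Gene Ontology filtering, EASE-score enrichment (a conservative,
observation-corrected Fisher's exact test) with Benjamini-Hochberg FDR,
attention-bin property enrichment, strong-GWAS and loss-of-function
intolerance flags, screen-derived experimental-potential flags, and the
GEM aggregate (Genetic support, Experimental potential, invertebrate
Model-organism homolog).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import (
    HUMAN_TAX_ID,
    INVERTEBRATE_MODEL_TAXA,
    GwasTable,
    HomologyMap,
    ScreenTables,
)

logger = logging.getLogger(__name__)

#: Evidence codes marking temporarily valid, computationally predicted
#: annotations, and codes marking unmapped entries.
PREDICTED_EVIDENCE = frozenset({"IEA", "RCA"})
UNMAPPED_EVIDENCE = frozenset({"ND", "NR", "-"})


def filter_go(annotations: pd.DataFrame, mode: str = "curated") -> pd.DataFrame:
    """Filter gene2go-style annotation rows.

    Rows with a qualifier starting "NOT" are negating and always dropped,
    as are unmapped evidence codes (ND, NR, "-").  ``mode="curated"``
    additionally drops the computationally predicted codes (IEA, RCA);
    ``mode="predicted"`` keeps only those.  Unknown evidence codes are
    kept in curated mode and logged.
    """
    if mode not in ("curated", "predicted"):
        raise ValueError("mode must be 'curated' or 'predicted'")
    t = annotations.copy()
    qualifier = t["qualifier"].fillna("").astype(str)
    evidence = t["evidence"].fillna("-").astype(str)
    keep = ~qualifier.str.startswith("NOT") & ~evidence.isin(UNMAPPED_EVIDENCE)
    if mode == "curated":
        keep &= ~evidence.isin(PREDICTED_EVIDENCE)
        known = PREDICTED_EVIDENCE | UNMAPPED_EVIDENCE | {
            "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "NAS", "IC",
            "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD",
            "HDA", "HMP", "HGI", "HEP", "HTP",
        }
        odd = set(evidence[keep]) - known
        if odd:
            logger.info("keeping unknown evidence codes in curated mode: %s",
                        sorted(odd))
    else:
        keep &= evidence.isin(PREDICTED_EVIDENCE)
    return t[keep].reset_index(drop=True)


def ease_pvalue(overlap: int, cluster_size: int, term_size: int,
                universe_size: int) -> float:
    """EASE score: the hypergeometric upper-tail p-value recomputed after
    removing one gene from the overlap.  Zero (or one) overlapping gene
    gives p = 1 by convention."""
    if min(overlap, cluster_size, term_size) < 0 or universe_size <= 0:
        raise ValueError("table entries must be nonnegative, universe positive")
    if overlap <= 1:
        return 1.0
    return float(hypergeom.sf(overlap - 2, universe_size, term_size,
                              cluster_size))


def fisher_pvalue(overlap: int, cluster_size: int, term_size: int,
                  universe_size: int) -> float:
    """Classical Fisher's exact upper-tail p (P[X >= overlap])."""
    if overlap <= 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, term_size,
                              cluster_size))


def ease_enrichment(
    clusters: Mapping[str, Iterable],
    terms: Mapping[str, Iterable],
    universe: Iterable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """EASE enrichment of every (cluster, term) pair with BH FDR.

    Clusters and terms are gene-id sets restricted to the universe.  The
    returned frame carries the overlap, both the EASE and the classical
    Fisher p-value, and Benjamini-Hochberg q-values computed across all
    pairs at the given alpha.
    """
    uni = set(universe)
    n_universe = len(uni)
    rows = []
    for cname, cgenes in clusters.items():
        cset = set(cgenes) & uni
        for tname, tgenes in terms.items():
            tset = set(tgenes) & uni
            overlap = len(cset & tset)
            rows.append({
                "cluster": cname,
                "term": tname,
                "overlap": overlap,
                "cluster_size": len(cset),
                "term_size": len(tset),
                "universe_size": n_universe,
                "ease_p": ease_pvalue(overlap, len(cset), len(tset), n_universe),
                "fisher_p": fisher_pvalue(overlap, len(cset), len(tset),
                                          n_universe),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["ease_p"], alpha=alpha,
                                       method="fdr_bh")[1]
        out["significant"] = out["q_value"] <= alpha
    return out


def binned_property_enrichment(
    attention: pd.Series,
    property_flags: pd.Series,
    bins: Sequence[float],
) -> pd.DataFrame:
    """Relative enrichment of a boolean gene property across attention bins.

    Per bin: (fraction of bin genes carrying the property) / (overall
    fraction).  Bin edges partition the attention range; empty bins give
    a missing value and are logged.
    """
    flags = property_flags.reindex(attention.index).fillna(False).astype(bool)
    overall = flags.mean()
    if overall == 0:
        raise ValueError("property absent from every gene")
    binned = pd.cut(attention, bins=list(bins), include_lowest=True)
    rows = []
    for interval, idx in attention.groupby(binned, observed=False).groups.items():
        if len(idx) == 0:
            logger.info("empty attention bin %s", interval)
            rows.append({"bin": interval, "n_genes": 0,
                         "property_fraction": np.nan, "enrichment": np.nan})
            continue
        frac = flags.loc[idx].mean()
        rows.append({"bin": interval, "n_genes": len(idx),
                     "property_fraction": frac, "enrichment": frac / overall})
    return pd.DataFrame(rows)


def log_spaced_attention_bins(attention: pd.Series, n_bins: int = 6
                              ) -> np.ndarray:
    """Default binning style: log-spaced upper limits over the attention
    range, with a lower edge below the minimum."""
    positive = attention[attention > 0]
    lo = positive.min() if len(positive) else 0.1
    hi = attention.max()
    edges = np.geomspace(max(lo, 1e-3), hi, n_bins)
    return np.concatenate([[-np.inf], edges[:-1], [np.inf]])


@dataclass
class GwasFlagResult:
    strong: pd.Series
    gene_traits: pd.DataFrame
    n_discarded_multi_gene: int


def strong_gwas_flag(
    gwas: GwasTable, gene_intervals: pd.DataFrame,
    min_studies: int = 10, min_study_share: float = 0.2,
) -> GwasFlagResult:
    """Flag genes with strongly reproduced GWAS associations.

    Associations (1-based inclusive intervals) are kept only when fully
    contained in exactly one gene; multiple associations of one study to
    a (gene, trait) pair collapse to one occurrence.  A gene is strong
    for a trait iff the trait is covered by at least ``min_studies``
    distinct studies and the gene occurs in strictly more than
    ``min_study_share`` of them.
    """
    assoc = gwas.table
    genes = gene_intervals[["gene_id", "chrom", "start", "end"]]
    hits = []
    discarded = 0
    for chrom, group in assoc.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        gid = g["gene_id"].to_numpy()
        for row in group.itertuples(index=False):
            inside = (gs <= row.start) & (row.end <= ge)
            n_inside = int(inside.sum())
            if n_inside == 1:
                hits.append((row.study_id, row.trait, int(gid[inside][0])))
            elif n_inside > 1:
                discarded += 1
    kept = pd.DataFrame(hits, columns=["study_id", "trait", "gene_id"])
    kept = kept.drop_duplicates()  # >=1 association per study collapses
    all_flags = pd.Series(False, index=pd.Index(
        gene_intervals["gene_id"], name="gene_id"))
    if len(kept) == 0:
        return GwasFlagResult(all_flags, kept, discarded)
    trait_studies = kept.groupby("trait")["study_id"].nunique()
    gene_trait = (
        kept.groupby(["gene_id", "trait"])["study_id"].nunique()
        .rename("n_studies").reset_index()
    )
    gene_trait["trait_studies"] = gene_trait["trait"].map(trait_studies)
    gene_trait["share"] = gene_trait["n_studies"] / gene_trait["trait_studies"]
    gene_trait["strong"] = (
        (gene_trait["trait_studies"] >= min_studies)
        & (gene_trait["share"] > min_study_share)
    )
    strong_genes = set(gene_trait.loc[gene_trait["strong"], "gene_id"])
    all_flags.loc[all_flags.index.isin(strong_genes)] = True
    return GwasFlagResult(all_flags, gene_trait, discarded)


def lof_intolerance_flag(pli: pd.Series, threshold: float = 0.9) -> pd.Series:
    """True for genes with pLI strictly above the threshold (extreme
    loss-of-function intolerance).  Missing values are not flagged."""
    observed = pli.dropna()
    if ((observed < 0) | (observed > 1)).any():
        raise ValueError("pLI values must lie in [0, 1]")
    return (pli > threshold).fillna(False).rename("lof_intolerant")


def experimental_flags(
    screens: ScreenTables,
    fpkm: pd.DataFrame | None = None,
    min_rnai_studies: int = 20,
    rnai_phenotype_share: float = 0.3,
    de_pvalue_cut: float = 1e-4,
    frequent_de_quantile: float = 0.8,
    fpkm_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene experimental-potential flags from screen tables.

    strong_rnai: gene present in at least ``min_rnai_studies`` RNAi
    screens (shRNA-abundance readouts excluded) with a phenotype in
    strictly more than ``rnai_phenotype_share`` of them.  frequent_de:
    differential-expression hit (p strictly below ``de_pvalue_cut``) in a
    top-quantile number of experiments.  affinity_western: passed through
    from interaction evidence.  detectable_rna: at least one tissue at or
    above the FPKM floor.
    """
    index = pd.Index(screens.rnai["gene_id"].unique()).union(
        screens.diff_expr["gene_id"].unique()).union(
        screens.affinity["gene_id"].unique())

    rnai = screens.rnai[~screens.rnai["via_shrna"]]
    per_gene = rnai.groupby("gene_id").agg(
        n_studies=("study_id", "nunique"), n_phenotype=("phenotype", "sum")
    )
    eligible = per_gene["n_studies"] >= min_rnai_studies
    share = per_gene["n_phenotype"] / per_gene["n_studies"]
    strong_rnai = (eligible & (share > rnai_phenotype_share)).rename("strong_rnai")

    de = screens.diff_expr
    hits = de[de["pvalue"] < de_pvalue_cut].groupby("gene_id").size()
    de_genes = pd.Index(de["gene_id"].unique())
    hit_counts = hits.reindex(de_genes, fill_value=0)
    if len(hit_counts):
        cut = hit_counts.quantile(frequent_de_quantile)
        frequent_de = (hit_counts > cut).rename("frequent_de")
    else:
        frequent_de = pd.Series(dtype=bool, name="frequent_de")

    affinity = screens.affinity.set_index("gene_id")["affinity_western"]

    if fpkm is not None:
        detectable = (fpkm >= fpkm_floor).any(axis=1).rename("detectable_rna")
        index = index.union(detectable.index)
    else:
        detectable = pd.Series(dtype=bool, name="detectable_rna")

    out = pd.DataFrame(index=index.sort_values())
    out.index.name = "gene_id"
    for s in (strong_rnai, frequent_de, affinity.rename("affinity_western"),
              detectable):
        out[s.name] = s.reindex(out.index, fill_value=False).astype(bool)
    return out


def gem_flags(
    genetic_flags: pd.DataFrame,
    experimental: pd.DataFrame,
    homology: HomologyMap,
    invertebrate_taxa: frozenset = INVERTEBRATE_MODEL_TAXA,
    complex_membership: pd.Series | None = None,
) -> pd.DataFrame:
    """G/E/M evidence flags and their conjunction.

    G: loss-of-function intolerant or strong GWAS support.  E: any
    experimental-potential flag (strong RNAi, frequent differential
    expression, affinity western, detectable RNA; optionally membership
    in a complex with highly studied genes).  M: homology group contains
    an invertebrate model organism.  GEM = G and E and M.
    """
    index = genetic_flags.index.union(experimental.index)
    g = pd.Series(False, index=index)
    for col in genetic_flags.columns:
        g |= genetic_flags[col].reindex(index, fill_value=False).astype(bool)
    e = pd.Series(False, index=index)
    for col in experimental.columns:
        e |= experimental[col].reindex(index, fill_value=False).astype(bool)
    if complex_membership is not None:
        e |= complex_membership.reindex(index, fill_value=False).astype(bool)

    hm = homology.table
    invertebrate_groups = set(
        hm.loc[hm["tax_id"].isin(invertebrate_taxa), "group_id"]
    )
    genes_with_model = set(
        hm.loc[hm["group_id"].isin(invertebrate_groups), "gene_id"]
    )
    m = pd.Series(index.isin(genes_with_model), index=index)

    out = pd.DataFrame({"G": g, "E": e, "M": m})
    out["GEM"] = out["G"] & out["E"] & out["M"]
    out.index.name = "gene_id"
    return out
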