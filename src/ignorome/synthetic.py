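"""Synthetic study corpora with known ground truth.

Generates a complete in-memory study universe — genes with sequences,
a gene-by-feature matrix, a bipartite gene-publication corpus, grants,
homology groups, GWAS-style associations, a citation graph, authorships
and screen tables — under a configurable generative model:

* per-gene latent log10 publication intensity is a linear combination of
  z-scored causal features plus Gaussian noise;
* total publication counts per gene are marginally log-normal and
  monotone in the latent intensity (rank coupling);
* counts spread over calendar years by preferential attachment
  (``richer_gamma``), so the rich can get richer;
* nonhuman homolog genes enter the literature earlier than their human
  partners by a configurable lag, with a configurable correlation
  between homolog years and human discovery years.

All randomness flows from a single seed; regeneration under a fixed
seed is byte-identical.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._tables import GENETIC_CODE, HUMAN_CODON_USAGE_PER_1000, STOP_CODONS
from .attention import ARTICLE_TYPE_WHITELIST
from .containers import (
    HUMAN_TAX_ID,
    AuthorshipTable,
    CitationGraph,
    FeatureMatrix,
    GeneCatalog,
    GeneLinkTable,
    GrantTable,
    GroundTruth,
    GwasTable,
    HomologyMap,
    PublicationTable,
    ScreenTables,
    SyntheticCorpus,
)

logger = logging.getLogger(__name__)

_SENSE_CODONS = tuple(sorted(GENETIC_CODE))
_STOPS = tuple(sorted(STOP_CODONS))


class InvalidConfigError(ValueError):
    """A synthetic-corpus configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a synthetic corpus.

    The defaults describe a mid-sized literature: a few thousand genes, a
    three-decade publication record whose per-gene totals are log-normal
    with a heavy tail, five causal features of decaying effect size, and
    rich-get-richer year dynamics.  See docs/methods.md for the rationale
    behind each default.
    """

    n_genes: int = 2000
    n_years: int = 30
    end_year: int = 2015
    seed: int = 0

    # feature matrix
    n_features: int = 50
    causal_features: tuple[str, ...] | None = None  # default: first 5 features
    effect_sizes: tuple[float, ...] | None = None   # default: 1.0 .. 0.6
    noise_sd: float = 0.3
    missing_fraction: float = 0.0
    include_sequence_features: bool = False
    n_tissues: int = 12

    # publication counts and years
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.0
    richer_gamma: float = 1.0
    entry_span_fraction: float = 0.8
    discovery_noise_sd: float = 2.0
    link_geom_p: float = 0.55
    max_genes_per_publication: int = 50
    n_journals: int | None = None
    review_journal_fraction: float = 0.1
    review_journal_review_rate: float = 0.8
    review_article_fraction: float = 0.05
    nonresearch_fraction: float = 0.05

    # gene catalog
    family_pairs: int | None = None
    nonhuman_fraction: float = 0.4
    nonhuman_taxa: tuple[int, ...] = (10090, 10116, 7227, 6239, 559292, 7955)
    cds_codons_mean: float = 180.0
    codon_bias_strength: float = 0.5
    generate_sequences: bool = True

    # homology
    homolog_fraction: float = 0.6
    homolog_lag_mean: float = 5.0
    homolog_year_corr: float = 0.7
    homolog_latent_corr: float = 0.7
    homology_id_coverage: float = 0.95

    # GWAS
    n_traits: int = 30
    studies_per_trait_mean: float = 8.0
    gwas_single_gene_fraction: float = 0.8

    # grants
    n_projects: int | None = None
    pubs_per_project: int = 3
    budget_mu: float = 12.0
    budget_sigma: float = 0.5
    cpi_rate: float = 0.025

    # citations and authors
    citations_mean: float = 5.0
    citation_nonhuman_pref: float = 0.65
    team_size_mean: float = 4.0
    n_authors: int | None = None
    senior_fraction: float = 0.2

    # screens
    n_rnai_studies: int = 40
    rnai_coverage: float = 0.8
    via_shrna_fraction: float = 0.2
    n_de_experiments: int = 30
    affinity_fraction: float = 0.3

    def __post_init__(self):
        if self.n_genes < 2:
            raise InvalidConfigError("n_genes must be at least 2")
        if self.n_years < 1:
            raise InvalidConfigError("n_years must be positive")
        if self.noise_sd < 0 or self.richer_gamma < 0:
            raise InvalidConfigError("noise_sd and richer_gamma must be >= 0")
        for name in ("missing_fraction", "review_journal_fraction",
                     "review_article_fraction", "nonresearch_fraction",
                     "nonhuman_fraction", "homolog_fraction",
                     "gwas_single_gene_fraction", "rnai_coverage",
                     "via_shrna_fraction", "affinity_fraction",
                     "entry_span_fraction", "senior_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if not 0 < self.link_geom_p <= 1:
            raise InvalidConfigError("link_geom_p must lie in (0, 1]")

    @property
    def start_year(self) -> int:
        return self.end_year - self.n_years + 1

    def resolved_causal(self) -> tuple[tuple[str, ...], np.ndarray]:
        names = self.causal_features
        if names is None:
            names = tuple(f"feat_{i:03d}" for i in range(min(5, self.n_features)))
        effects = self.effect_sizes
        if effects is None:
            effects = tuple(1.0 - 0.1 * i for i in range(len(names)))
        if len(effects) != len(names):
            raise InvalidConfigError("effect_sizes must match causal_features")
        return tuple(names), np.asarray(effects, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)


@dataclass
class AncillaryTables:
    homology_map: HomologyMap
    gwas_table: GwasTable
    citation_graph: CitationGraph
    authorship_table: AuthorshipTable
    screen_tables: ScreenTables


def _letters(i: int) -> str:
    """Deterministic letters-only label: 0 -> AA, 1 -> AB, ..."""
    alphabet = string.ascii_uppercase
    out = ""
    i += 26  # at least two letters, avoiding single-letter stems
    while i > 0:
        i, r = divmod(i, 26)
        out = alphabet[r] + out
    return out


def _codon_probs(bias: float) -> np.ndarray:
    usage = np.array([HUMAN_CODON_USAGE_PER_1000[c] for c in _SENSE_CODONS])
    usage = usage / usage.sum()
    uniform = np.full(len(_SENSE_CODONS), 1.0 / len(_SENSE_CODONS))
    p = (1 - bias) * uniform + bias * usage
    return p / p.sum()


def generate_gene_catalog(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> GeneCatalog:
    """Genes with ids, symbols, taxa, genomic spans and sequences.

    The first ``2 * family_pairs`` human genes form symbol families
    (stem + trailing 1/2); a ``nonhuman_fraction`` of genes belongs to
    nonhuman taxa, each paired with a human partner gene for downstream
    homology.  CDS sequences start with ATG, end with a stop codon and
    use a codon distribution interpolating between uniform and a human
    reference usage (``codon_bias_strength``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_nonhuman = int(round(config.nonhuman_fraction * n))
    n_human = n - n_nonhuman
    if n_human < 1:
        raise InvalidConfigError("nonhuman_fraction leaves no human genes")

    family_pairs = config.family_pairs
    if family_pairs is None:
        family_pairs = n_human // 20
    if 2 * family_pairs > n_human:
        raise InvalidConfigError("family_pairs exceed available human genes")

    gene_ids = np.arange(1, n + 1)
    symbols: list[str] = []
    for j in range(family_pairs):
        stem = "FAM" + _letters(j)
        symbols += [stem + "1", stem + "2"]
    for j in range(n_human - 2 * family_pairs):
        symbols.append("G" + _letters(j))
    for j in range(n_nonhuman):
        symbols.append("Nh" + _letters(j).lower())

    tax = np.full(n, HUMAN_TAX_ID)
    if n_nonhuman:
        tax[n_human:] = rng.choice(config.nonhuman_taxa, size=n_nonhuman)

    partner = np.full(n, -1)
    if n_nonhuman:
        humans = gene_ids[:n_human]
        order = rng.permutation(n_human)
        partner[n_human:] = humans[order[np.arange(n_nonhuman) % n_human]]

    # non-overlapping spans along chromosomes 1..22
    chroms = [str(c) for c in range(1, 23)]
    chrom_col, starts, ends = [], [], []
    lengths = rng.integers(2_000, 50_000, size=n)
    gaps = rng.integers(1_000, 10_000, size=n)
    cursor = {c: 1 for c in chroms}
    for i in range(n):
        c = chroms[i % len(chroms)]
        s = cursor[c] + int(gaps[i])
        e = s + int(lengths[i]) - 1
        cursor[c] = e
        chrom_col.append(c)
        starts.append(s)
        ends.append(e)

    cds_list, protein_list = [], []
    if config.generate_sequences:
        n_codons = np.maximum(
            30, rng.poisson(config.cds_codons_mean, size=n)
        )
        probs = _codon_probs(config.codon_bias_strength)
        all_internal = rng.choice(
            len(_SENSE_CODONS), size=int(n_codons.sum()), p=probs
        )
        stops = rng.choice(len(_STOPS), size=n)
        offset = 0
        for i in range(n):
            k = int(n_codons[i])
            idx = all_internal[offset:offset + k]
            offset += k
            codons = ["ATG"] + [_SENSE_CODONS[j] for j in idx]
            protein_list.append("".join(GENETIC_CODE[c] for c in codons))
            codons.append(_STOPS[stops[i]])
            cds_list.append("".join(codons))
    else:
        cds_list = [""] * n
        protein_list = [""] * n

    table = pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": symbols,
        "tax_id": tax,
        "chrom": chrom_col,
        "start": starts,
        "end": ends,
        "cds": cds_list,
        "protein": protein_list,
        "partner_gene_id": partner,
        "source_tier": 1,
    })
    return GeneCatalog(table)


def generate_feature_matrix(
    catalog: GeneCatalog,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Random experimental-style features plus an FPKM tissue table.

    Features ``feat_000 ...`` are standard-normal draws per gene; a
    ``missing_fraction`` of cells is masked at random.  When
    ``include_sequence_features`` is set, sequence-derived columns
    computed by :mod:`ignorome.features` are appended.  The FPKM table
    (genes x tissues) has gene-level log-normal abundance with a subset
    of broadly silent genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ids = catalog.gene_ids
    n = len(ids)
    values = pd.DataFrame(
        rng.standard_normal((n, config.n_features)),
        index=ids,
        columns=[f"feat_{i:03d}" for i in range(config.n_features)],
    )
    values.index.name = "gene_id"
    if config.missing_fraction > 0:
        mask = rng.random((n, config.n_features)) < config.missing_fraction
        values = values.mask(mask)

    gene_level = rng.normal(1.0, 1.5, size=n)
    silent = rng.random(n) < 0.1
    gene_level[silent] = -3.0
    fpkm = pd.DataFrame(
        np.exp(gene_level[:, None] + rng.normal(0, 1.0, size=(n, config.n_tissues))),
        index=ids,
        columns=[f"tissue_{t:02d}" for t in range(config.n_tissues)],
    )
    fpkm.index.name = "gene_id"

    if config.include_sequence_features:
        from . import features as feats
        rows = []
        for cds, prot in zip(catalog.table["cds"], catalog.table["protein"]):
            row = {}
            row.update(feats.nucleotide_features(cds))
            row.update(feats.codon_features(cds))
            row.update(feats.protein_features(prot))
            row.update(feats.low_complexity_features(prot))
            rows.append(row)
        seq_df = pd.DataFrame(rows, index=ids)
        values = pd.concat([values, seq_df], axis=1)

    return FeatureMatrix(values), fpkm


def _spread_years(
    count: int, first_idx: int, n_years: int, gamma: float,
    rng: np.random.Generator, force_first: bool = True,
) -> np.ndarray:
    """Yearly counts for one gene, preferentially attached with weight
    (1 + cumulative)^gamma over the years from ``first_idx`` on.  With
    ``force_first`` the first publication lands exactly at ``first_idx``
    (entry year = discovery year); without it all publications are
    spread, so gamma = 0 gives an exchangeable multinomial."""
    counts = np.zeros(n_years, dtype=np.int64)
    k = n_years - first_idx
    if force_first:
        counts[first_idx] = 1
        remaining = count - 1
    else:
        remaining = count
    if remaining <= 0:
        return counts
    if gamma == 0:
        counts[first_idx:] += rng.multinomial(remaining, np.full(k, 1.0 / k))
    elif gamma == 1.0:
        # Polya-urn equivalence: Dirichlet-multinomial with the initial
        # urn weights as concentration
        alpha = 1.0 + counts[first_idx:]
        p = rng.dirichlet(alpha)
        counts[first_idx:] += rng.multinomial(remaining, p)
    else:
        local = counts[first_idx:]
        for _ in range(remaining):
            w = (1.0 + local) ** gamma
            local[rng.choice(k, p=w / w.sum())] += 1
    return counts


def generate_publication_corpus(
    catalog: GeneCatalog,
    features: FeatureMatrix,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PublicationTable, GeneLinkTable, GroundTruth]:
    """Publications, gene links and the latent ground truth.

    Latent log10 intensity per human gene is a linear combination of
    z-scored causal features plus Normal(0, noise_sd) noise; total counts
    are log-normal draws rank-coupled to the latent intensity; yearly
    spreads follow preferential attachment.  Nonhuman genes inherit a
    noisy copy of their human partner's latent intensity and enter the
    literature ``homolog_lag_mean`` years earlier, with the noise on
    their entry year set so that homolog years correlate with human
    discovery years at ``homolog_year_corr``.  Publications bundle 1..k
    gene slots of the same year (k-1 truncated-geometric), carry article
    types, journals and review labels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    causal_names, effects = config.resolved_causal()
    missing = [c for c in causal_names if c not in features.values.columns]
    if missing:
        raise InvalidConfigError(f"causal features absent from matrix: {missing}")
    if not causal_names and config.lognormal_sigma == 0:
        warnings.warn("degenerate corpus: no causal features and zero "
                      "log-normal spread", stacklevel=2)

    table = catalog.table
    ids = table["gene_id"].to_numpy()
    n = len(ids)
    is_human = (table["tax_id"] == HUMAN_TAX_ID).to_numpy()
    id_pos = {g: i for i, g in enumerate(ids)}

    z = features.values[list(causal_names)].astype(float)
    z = (z - z.mean()) / z.std(ddof=1)
    z = z.fillna(0.0)
    latent = z.to_numpy() @ effects + rng.normal(0, config.noise_sd, size=n)

    # entry-year ordering: earlier entry for higher (noisy) latent
    span = int(round(config.entry_span_fraction * (config.n_years - 1)))
    entry_score = latent + rng.normal(0, config.discovery_noise_sd, size=n)
    entry_idx = np.zeros(n, dtype=np.int64)

    # percentile of entry_score among humans; nonhumans handled separately
    def _percentile_ranks(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        ranks[order] = np.arange(len(x))
        return ranks / max(1, len(x) - 1)

    if span > 0:
        h = np.where(is_human)[0]
        entry_idx[h] = np.floor((1 - _percentile_ranks(entry_score[h])) * span).astype(int)

    # nonhuman homologs: correlated latent and lagged entry years
    partner = table["partner_gene_id"].to_numpy()
    nh = np.where(~is_human)[0]
    if len(nh):
        ppos = np.array([id_pos[g] for g in partner[nh]])
        r = config.homolog_latent_corr
        latent_sd = latent[is_human].std() or 1.0
        latent[nh] = r * latent[ppos] + rng.normal(
            0, latent_sd * np.sqrt(max(0.0, 1 - r ** 2)), size=len(nh)
        )
        ry = config.homolog_year_corr
        human_entry_sd = entry_idx[is_human].std()
        year_noise_sd = (
            human_entry_sd * np.sqrt(max(0.0, 1 / ry ** 2 - 1)) if ry > 0 else 0.0
        )
        raw = (
            entry_idx[ppos]
            - config.homolog_lag_mean
            + rng.normal(0, year_noise_sd, size=len(nh))
        )
        clipped = raw < 0
        if clipped.any():
            logger.info("clipped %d homolog entry years at corpus start",
                        int(clipped.sum()))
        entry_idx[nh] = np.clip(np.round(raw), 0, config.n_years - 1).astype(int)

    draws = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)
    counts = np.maximum(1, np.round(np.sort(draws))).astype(np.int64)
    order = np.argsort(latent, kind="stable")
    gene_counts = np.empty(n, dtype=np.int64)
    gene_counts[order] = counts

    yearly = np.zeros((n, config.n_years), dtype=np.int64)
    force_first = span > 0
    for i in range(n):
        yearly[i] = _spread_years(
            int(gene_counts[i]), int(entry_idx[i]), config.n_years,
            config.richer_gamma, rng, force_first,
        )

    years = np.arange(config.start_year, config.end_year + 1)
    realized_first = (yearly > 0).argmax(axis=1)

    # bundle same-year gene slots into publications
    pub_rows = []          # (year,)
    link_gene, link_pub = [], []
    pub_counter = 0
    for yi, year in enumerate(years):
        slot_genes = np.repeat(ids, yearly[:, yi])
        if len(slot_genes) == 0:
            continue
        rng.shuffle(slot_genes)
        sizes = 1 + np.minimum(
            rng.geometric(config.link_geom_p, size=len(slot_genes)) - 1,
            config.max_genes_per_publication - 1,
        )
        pos = 0
        si = 0
        while pos < len(slot_genes):
            k = int(sizes[si]); si += 1
            members = np.unique(slot_genes[pos:pos + k])
            pos += k
            pub_rows.append(year)
            link_gene.extend(members.tolist())
            link_pub.extend([pub_counter] * len(members))
            pub_counter += 1

    n_pubs = pub_counter
    pmids = 1_000_000 + np.arange(n_pubs)
    pub_years = np.array(pub_rows)

    n_journals = config.n_journals or max(5, n_pubs // 100)
    n_review_journals = int(round(config.review_journal_fraction * n_journals))
    journal_ids = rng.integers(0, n_journals, size=n_pubs)
    in_review_journal = journal_ids < n_review_journals

    research_types = sorted(ARTICLE_TYPE_WHITELIST)
    extra_type = rng.random(n_pubs) < 0.2
    extra_choice = rng.choice(len(research_types), size=n_pubs)
    nonresearch = rng.random(n_pubs) < config.nonresearch_fraction
    review_draw = rng.random(n_pubs)
    is_review = np.where(
        in_review_journal,
        review_draw < config.review_journal_review_rate,
        review_draw < config.review_article_fraction,
    )
    article_types = []
    for i in range(n_pubs):
        if nonresearch[i]:
            types = ("editorial",)
        else:
            types = ("journal article",)
            if extra_type[i] and research_types[extra_choice[i]] != "journal article":
                types += (research_types[extra_choice[i]],)
        if is_review[i]:
            types += ("review",)
        article_types.append(types)

    publications = PublicationTable(pd.DataFrame({
        "pmid": pmids,
        "year": pub_years,
        "article_types": article_types,
        "journal_id": journal_ids,
    }))
    links = GeneLinkTable(pd.DataFrame({
        "tax_id": [table["tax_id"].iloc[id_pos[g]] for g in link_gene],
        "gene_id": link_gene,
        "pmid": pmids[np.array(link_pub)],
    }))
    truth = GroundTruth(
        latent_intensity=pd.Series(latent, index=pd.Index(ids, name="gene_id"),
                                   name="latent_log10_intensity"),
        causal_features=list(causal_names),
        discovery_year=pd.Series(years[realized_first],
                                 index=pd.Index(ids, name="gene_id"),
                                 name="discovery_year"),
    )
    return publications, links, truth


def generate_grants(
    publications: PublicationTable,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GrantTable, pd.Series]:
    """Projects with yearly nominal budgets supporting >=1 publications.

    Each publication is supported by exactly one project (chunks of a
    random permutation, ``pubs_per_project`` each); budgets are
    log-normal (``budget_sigma = 0`` gives equal budgets).  A consumer
    price index series over the corpus years is returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    years = np.arange(config.start_year, config.end_year + 1)
    cpi = pd.Series(
        100.0 * (1 + config.cpi_rate) ** np.arange(len(years)),
        index=years, name="cpi",
    )
    pmids = publications.table["pmid"].to_numpy()
    pub_year = publications.table.set_index("pmid")["year"]
    if config.n_projects == 0 or len(pmids) == 0:
        empty = pd.DataFrame(columns=["project_id", "year", "amount", "pmids"])
        return GrantTable(empty), cpi
    per = max(1, config.pubs_per_project)
    perm = rng.permutation(pmids)
    chunks = [perm[i:i + per] for i in range(0, len(perm), per)]
    if config.n_projects is not None:
        chunks = chunks[:config.n_projects]
    amounts = np.exp(rng.normal(config.budget_mu, config.budget_sigma,
                                size=len(chunks)))
    rows = [{
        "project_id": 50_000 + i,
        "year": int(pub_year.loc[chunk].min()),
        "amount": float(amounts[i]),
        "pmids": tuple(int(p) for p in np.sort(chunk)),
    } for i, chunk in enumerate(chunks)]
    return GrantTable(pd.DataFrame(rows)), cpi


def generate_ancillary(
    corpus: SyntheticCorpus,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> AncillaryTables:
    """Homology groups, GWAS associations, citations, authors, screens."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    catalog = corpus.gene_catalog.table
    pubs = corpus.publication_table.table
    links = corpus.gene_link_table.table

    homology = _make_homology(catalog, config, rng)
    gwas = _make_gwas(catalog, config, rng)
    citations = _make_citations(catalog, pubs, links, config, rng)
    authorship = _make_authorship(pubs, config, rng)
    screens = _make_screens(catalog, config, rng)
    return AncillaryTables(homology, gwas, citations, authorship, screens)


def _make_homology(catalog, config, rng) -> HomologyMap:
    human = catalog[catalog["tax_id"] == HUMAN_TAX_ID]
    nonhuman = catalog[catalog["tax_id"] != HUMAN_TAX_ID]
    partnered = nonhuman.groupby("partner_gene_id")["gene_id"].apply(list)
    eligible_humans = [g for g in partnered.index if g > 0]
    target = int(round(config.homolog_fraction * len(human)))
    if target > len(eligible_humans):
        logger.info("homolog_fraction wants %d grouped humans; only %d have "
                    "nonhuman partners", target, len(eligible_humans))
        target = len(eligible_humans)
    chosen = rng.choice(eligible_humans, size=target, replace=False) if target else []
    tax_of = catalog.set_index("gene_id")["tax_id"]
    rows = []
    for gid, human_gene in enumerate(sorted(chosen)):
        rows.append({"group_id": gid, "gene_id": int(human_gene),
                     "tax_id": HUMAN_TAX_ID})
        for nh_gene in partnered.loc[human_gene]:
            rows.append({"group_id": gid, "gene_id": int(nh_gene),
                         "tax_id": int(tax_of.loc[nh_gene])})
    table = pd.DataFrame(rows, columns=["group_id", "gene_id", "tax_id"])
    human_ids = np.sort(human["gene_id"].to_numpy())
    cap_pos = int(np.ceil(config.homology_id_coverage * len(human_ids))) - 1
    max_human_id = int(human_ids[max(0, cap_pos)])
    return HomologyMap(table, max_human_id=max_human_id)


def _make_gwas(catalog, config, rng) -> GwasTable:
    human = catalog[catalog["tax_id"] == HUMAN_TAX_ID].reset_index(drop=True)
    rows = []
    study_counter = 0
    n_h = len(human)
    for t in range(config.n_traits):
        n_studies = 1 + rng.poisson(config.studies_per_trait_mean)
        core = int(rng.integers(0, n_h))
        for _ in range(n_studies):
            study_id = 900_000 + study_counter
            study_counter += 1
            n_assoc = 1 + rng.poisson(1.0)
            for _ in range(n_assoc):
                gi = core if rng.random() < 0.35 else int(rng.integers(0, n_h))
                g = human.iloc[gi]
                if rng.random() < config.gwas_single_gene_fraction:
                    lo = int(rng.integers(g["start"], g["end"]))
                    hi = min(int(g["end"]), lo + int(rng.integers(1, 500)))
                else:
                    # straddle the gene boundary: inside no single gene
                    lo = int(g["end"]) - int(rng.integers(1, 200))
                    hi = int(g["end"]) + int(rng.integers(1, 200))
                rows.append({"study_id": study_id, "trait": f"trait_{t:03d}",
                             "chrom": g["chrom"], "start": lo, "end": hi})
    return GwasTable(pd.DataFrame(
        rows, columns=["study_id", "trait", "chrom", "start", "end"]
    ))


def _make_citations(catalog, pubs, links, config, rng) -> CitationGraph:
    if config.citations_mean <= 0 or len(pubs) == 0:
        return CitationGraph(pd.DataFrame(columns=["citing", "cited"]))
    tax_of = catalog.set_index("gene_id")["tax_id"]
    link_tax = links["gene_id"].map(tax_of)
    pub_has_nonhuman = (link_tax != HUMAN_TAX_ID).groupby(links["pmid"]).any()
    pub_has_human = (link_tax == HUMAN_TAX_ID).groupby(links["pmid"]).any()

    # first-year publication per human gene -> discovery publications
    year_of = pubs.set_index("pmid")["year"]
    ltab = links.assign(year=links["pmid"].map(year_of))
    human_links = ltab[ltab["gene_id"].map(tax_of) == HUMAN_TAX_ID]
    first_year = human_links.groupby("gene_id")["year"].transform("min")
    discovery_pmids = set(human_links.loc[human_links["year"] == first_year, "pmid"])

    order = np.argsort(pubs["year"].to_numpy(), kind="stable")
    pmids_sorted = pubs["pmid"].to_numpy()[order]
    years_sorted = pubs["year"].to_numpy()[order]
    nonhuman_flag = pub_has_nonhuman.reindex(pmids_sorted, fill_value=False).to_numpy()
    human_flag = pub_has_human.reindex(pmids_sorted, fill_value=False).to_numpy()

    nh_positions = np.where(nonhuman_flag)[0]
    h_positions = np.where(human_flag)[0]
    n_cites = rng.poisson(config.citations_mean, size=len(pmids_sorted))
    pref = rng.random(int(n_cites.sum()))
    edges_citing, edges_cited = [], []
    pi = 0
    for i in range(len(pmids_sorted)):
        c = int(n_cites[i])
        if c == 0 or i == 0:
            pi += c
            continue
        limit = int(np.searchsorted(years_sorted, years_sorted[i], side="right"))
        nh_lim = int(np.searchsorted(nh_positions, limit))
        h_lim = int(np.searchsorted(h_positions, limit))
        is_discovery = pmids_sorted[i] in discovery_pmids
        for _ in range(c):
            want_nonhuman = (
                pref[pi] < config.citation_nonhuman_pref if is_discovery
                else pref[pi] < 0.3
            )
            pi += 1
            if want_nonhuman and nh_lim > 0:
                j = int(nh_positions[rng.integers(0, nh_lim)])
            elif h_lim > 0:
                j = int(h_positions[rng.integers(0, h_lim)])
            else:
                j = int(rng.integers(0, limit))
            if j == i:
                continue
            edges_citing.append(int(pmids_sorted[i]))
            edges_cited.append(int(pmids_sorted[j]))
    edges = pd.DataFrame({"citing": edges_citing, "cited": edges_cited})
    edges = edges.drop_duplicates().reset_index(drop=True)
    return CitationGraph(edges)


def _make_authorship(pubs, config, rng) -> AuthorshipTable:
    n_pubs = len(pubs)
    if n_pubs == 0:
        return AuthorshipTable(pd.DataFrame(columns=["pmid", "position", "author_id"]))
    pool = config.n_authors or max(10, n_pubs)
    n_senior = max(1, int(round(config.senior_fraction * pool)))
    team_sizes = 1 + rng.poisson(max(0.0, config.team_size_mean - 1), size=n_pubs)
    rows_pmid, rows_pos, rows_author = [], [], []
    for i, (pmid, size) in enumerate(zip(pubs["pmid"], team_sizes)):
        size = int(size)
        juniors = rng.integers(n_senior, pool, size=max(0, size - 1))
        senior = rng.integers(0, n_senior)
        team = list(dict.fromkeys(list(juniors) + [int(senior)]))
        for pos, author in enumerate(team):
            rows_pmid.append(int(pmid))
            rows_pos.append(pos)
            rows_author.append(int(author))
    return AuthorshipTable(pd.DataFrame({
        "pmid": rows_pmid, "position": rows_pos, "author_id": rows_author,
    }))


def _make_screens(catalog, config, rng) -> ScreenTables:
    ids = catalog.loc[catalog["tax_id"] == HUMAN_TAX_ID, "gene_id"].to_numpy()
    n = len(ids)
    hit_prone = rng.random(n) < 0.25
    p_hit = np.where(hit_prone, 0.5, 0.1)
    rnai_rows = []
    for s in range(config.n_rnai_studies):
        covered = rng.random(n) < config.rnai_coverage
        via_shrna = rng.random() < config.via_shrna_fraction
        phen = rng.random(n) < p_hit
        for g, ph in zip(ids[covered], phen[covered]):
            rnai_rows.append((int(g), s, bool(ph), via_shrna))
    rnai = pd.DataFrame(rnai_rows,
                        columns=["gene_id", "study_id", "phenotype", "via_shrna"])

    de_prone = rng.random(n) < 0.2
    de_rows = []
    for e in range(config.n_de_experiments):
        pvals = np.where(
            de_prone & (rng.random(n) < 0.5),
            rng.uniform(0, 1e-3, size=n),
            rng.uniform(0, 1, size=n),
        )
        de_rows.append(pd.DataFrame({
            "gene_id": ids, "experiment_id": e, "pvalue": pvals,
        }))
    diff_expr = pd.concat(de_rows, ignore_index=True) if de_rows else pd.DataFrame(
        columns=["gene_id", "experiment_id", "pvalue"])

    affinity = pd.DataFrame({
        "gene_id": ids,
        "affinity_western": rng.random(n) < config.affinity_fraction,
    })
    return ScreenTables(rnai, diff_expr, affinity)


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a full corpus; deterministic given ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]
    catalog = generate_gene_catalog(config, rngs[0])
    feature_matrix, fpkm = generate_feature_matrix(catalog, config, rngs[1])
    publications, links, truth = generate_publication_corpus(
        catalog, feature_matrix, config, rngs[2]
    )
    corpus = SyntheticCorpus(
        gene_catalog=catalog,
        feature_matrix=feature_matrix,
        publication_table=publications,
        gene_link_table=links,
        fpkm_table=fpkm,
        ground_truth=truth,
        config=config,
    )
    corpus.grant_table, corpus.cpi = generate_grants(publications, config, rngs[3])
    ancillary = generate_ancillary(corpus, config, rngs[4])
    corpus.homology_map = ancillary.homology_map
    corpus.gwas_table = ancillary.gwas_table
    corpus.citation_graph = ancillary.citation_graph
    corpus.authorship_table = ancillary.authorship_table
    corpus.screen_tables = ancillary.screen_tables
    corpus.validate()
    return corpus


def homolog_feature_table(corpus: SyntheticCorpus) -> pd.DataFrame:
    """Per-human-gene homolog features: discovery years and publication
    counts of grouped nonhuman homologs (NaN where no homolog exists;
    impute with -1 via :func:`ignorome.prediction.augment_features`)."""
    if corpus.homology_map is None:
        raise ValueError("corpus has no homology map")
    hm = corpus.homology_map.table
    links = corpus.gene_link_table.table
    years = corpus.publication_table.years()
    ltab = links.assign(year=links["pmid"].map(years))
    disc = ltab.groupby("gene_id")["year"].min()
    counts = ltab.groupby("gene_id")["pmid"].nunique()

    human_rows = hm[hm["tax_id"] == HUMAN_TAX_ID][["group_id", "gene_id"]]
    nonhuman_rows = hm[hm["tax_id"] != HUMAN_TAX_ID]
    agg = nonhuman_rows.assign(
        year=nonhuman_rows["gene_id"].map(disc),
        count=nonhuman_rows["gene_id"].map(counts),
    ).groupby("group_id").agg(
        homolog_discovery_year=("year", "min"),
        homolog_publication_count=("count", "sum"),
    )
    out = human_rows.merge(agg, on="group_id", how="left").set_index("gene_id")
    human_ids = corpus.gene_catalog.human_genes()["gene_id"]
    return out.reindex(human_ids)[
        ["homolog_discovery_year", "homolog_publication_count"]
    ]
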