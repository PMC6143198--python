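# Methods

This note documents the models and procedures implemented in
`ignorome`, the assumptions behind the synthetic-data generator, the
numerical choices, and known limitations.

## 1. The analysis universe

**Reference research publications.** A publication belongs to the
analysis universe when (a) at least one of its article-type labels is in
the 15-item research whitelist (case report, classical article, clinical
trial and its four phases, comparative study, historical article,
journal article, meta analysis, multicenter study, randomized controlled
trial, twin study, validation study); (b) it is not itself labelled
"review"; and (c) it does not appear in a journal in which ≥ 50% of
articles are reviews (boundary inclusive). The whitelist is a module
constant so synthetic corpora can label against it.

**Reference genes.** Human (taxon 9606) genes carrying a symbol and
linked to at least one reference publication.

**Attention.** Fractional counting: a publication linking *k* genes
contributes 1/*k* to each. The per-timeframe sum over genes equals the
number of linked publications exactly; this conservation law is asserted
in the tests at 1e-9 and is the main internal consistency check of the
accounting code.

**Discovery year.** The earliest reference-publication year of a gene.
Undefined (flagged missing) for unlinked genes.

**Studied/unstudied.** Genes with total fractional attention strictly
below 1 are unstudied; exactly 1 counts as studied (only the strict
"below 1" side of the definition is standard, so the boundary needed a
decision; we document it rather than leave it implicit).

## 2. The synthetic-corpus generator

The generator emulates, as in-memory tables, the statistical structure
of the public link tables the analysis would otherwise require
(gene2pubmed-like links, MEDLINE-like publication metadata,
HomoloGene-like groups, GWAS-catalog-like associations, ExPORTER-like
grants, citation and authorship records, RNAi / differential-expression
/ affinity screens). Key mechanisms:

* **Latent intensity.** Per-gene log10 publication intensity is a
  linear combination of z-scored causal features plus
  Normal(0, `noise_sd`) noise. Defaults: 50 features, 5 causal with
  effect sizes 1.0 … 0.6, `noise_sd` 0.3.
* **Publication counts.** Per-gene totals are i.i.d. log-normal draws
  (`lognormal_mu` 3.0, `lognormal_sigma` 1.0 on the natural-log scale,
  i.e. a median of ~20 publications per gene and a heavy tail)
  rank-coupled to the latent intensity: sorted draws are assigned in
  latent-intensity order. The marginal distribution is therefore
  log-normal by construction (Kolmogorov-Smirnov statistic < 0.05
  against the generating distribution at 5,000 genes, verified over
  three seeds), while the count is a monotone function of the latent
  intensity — so with `noise_sd = 0` and a single causal feature, the
  feature determines the count ranking exactly.
* **Entry years and rich-get-richer dynamics.** Each gene receives an
  entry (discovery) year by rank-transforming latent intensity plus
  Normal(0, `discovery_noise_sd`) noise onto the first
  `entry_span_fraction` of the corpus years: intrinsically "attractive"
  genes tend to enter the literature earlier, but with substantial
  scatter. Its publications then spread from the entry year onward by
  preferential attachment with weight (1 + cumulative count)^`richer_gamma`.
  For `richer_gamma = 1` the urn process is drawn in closed form as a
  Dirichlet-multinomial; `richer_gamma = 0` gives an exchangeable
  multinomial over years (verified by a chi-square uniformity test on a
  10,000-publication corpus).

  `discovery_noise_sd` defaults to 2.0 latent units (comparable to the
  latent SD of ~1.8 under the default effects). This places the
  feature-only predictability of discovery years at Spearman ≈ 0.6 —
  the qualitative regime of the real-data analyses this package
  emulates, where year-of-first-report models are clearly less accurate
  than publication-count models and leave room for homolog information
  to help.
* **Publications.** Same-year gene slots are bundled into publications
  whose gene count is 1 + a truncated geometric draw
  (`link_geom_p` 0.55, cap 50), so most publications are small-science
  single-gene reports and a few are large-scale surveys. The
  gene-count law is configurable because the empirical distribution in
  real corpora is not well characterized. Publications carry journals
  (`review_journal_fraction` of journals are review-dominated), article
  types drawn against the whitelist, and review labels.
* **Homologs.** A `nonhuman_fraction` (default 0.4) of catalog genes
  belongs to nonhuman taxa (mouse, rat, fly, worm, yeast, zebrafish by
  default), each paired with a human partner. Homolog latent intensity
  is a correlated copy of the partner's (`homolog_latent_corr` 0.7);
  homolog entry years precede the partner's by `homolog_lag_mean`
  (default 5) years, with year noise **derived** from the empirical
  variance of human entry years so that the homolog-year /
  human-discovery-year correlation equals `homolog_year_corr` (default
  0.7) by construction rather than by tuning. The HomoloGene-style map
  groups `homolog_fraction` of human genes with their partners and
  records the largest human id eligible for grouping (id-cap rule for
  human-specific analyses).
* **Grants.** Publications are partitioned randomly into projects
  (`pubs_per_project` 3); budgets are log-normal (`budget_sigma = 0`
  gives equal budgets, making per-gene allocation exactly proportional
  to attention — the oracle used in tests). A consumer-price-index
  series (2.5%/year) spans the corpus years.
* **Ancillary tables.** GWAS associations are 1-based inclusive
  intervals, a configurable fraction fully inside exactly one gene and
  the rest straddling gene boundaries; citation edges always point
  backward in time, with discovery publications preferring nonhuman-gene
  references (`citation_nonhuman_pref` 0.65); bylines place a senior
  author last; screen tables carry per-study RNAi phenotype calls
  (a fraction of screens flagged as shRNA-abundance readouts),
  per-experiment differential-expression p-values, and affinity-western
  flags.

All randomness flows from a single seed via spawned child generators;
regeneration under a fixed seed is byte-identical per table. The
generator does **not** attempt realistic MEDLINE vocabulary, real gene
symbols, realistic citation topology beyond time-consistency, or
network structure in author collaboration; passing tests therefore
demonstrate correctness of the accounting and modeling machinery and
recoverability of planted effects, not fidelity to any particular real
corpus.

## 3. Feature engineering

Sequence-derived features per gene: base fractions and GC content
(fractions over non-N positions), the 64 codon fractions, and four
codon-bias indices — Wright's effective number of codons (ENC), the
codon adaptation index (CAI) against a packaged standard human
codon-usage table (overridable), the maximum |RSCU − 1| deviation, and
GC3. Many codon-bias statistics exist; these four standard indices are
our documented choice. ENC uses the standard-code degeneracy classes with Wright's
fallbacks for unobserved families and is clipped to [20, 61].

Protein features: the 20 residue fractions; ten physicochemical class
fractions (acidic, aromatic, basic, charged, helix-affine, hydrophobic,
polar, uncharged-polar, sheet-affine, turn-affine — class sets are
documented constants); GRAVY (mean Kyte-Doolittle hydropathy, hence
bounded by [−4.5, 4.5]); the isoelectric point (bisection on the
net-charge curve under the Bjellqvist pKa set, via Biopython); and the
average molecular weight.

Low-complexity segmentation follows the SEG two-threshold scheme:
12-residue sliding windows, Shannon entropy in bits, trigger 2.2,
extension 2.5 (the cited tool's defaults). A window at or below the
trigger seeds a segment; the segment covers the maximal contiguous run
of windows at or below the extension threshold. Reported features:
fraction of the protein in low-complexity regions, longest region and
its fraction, region count, and counts of regions longer than 5/10/20/40
residues. Intervals are 0-based half-open.

Signal-peptide, repeat (RADAR-style), CRISPR-essentiality, pLI and
protein-abundance columns are consumed as precomputed feature tables,
never recomputed.

Matrix plumbing: entity-level tables (transcripts, proteins) map to
genes by the median after discarding entities that map to more than one
gene; missing values in expression / stability / abundance /
localization / homolog-year families are imputed as −1 ("absent means
low"), all other missingness excludes the gene from complete-catalog
analyses; z-scoring uses the sample SD (ddof 1) with constant columns
set to 0 and flagged; missingness structure is summarized by
average-linkage hierarchical clustering of the absence mask under
Hamming distance.

## 4. The prediction engine

`MonteCarloRegression` / `MonteCarloResults` follow the model/results
convention of statsmodels. Each fit draws `n_randomizations` random
90/10 train/test splits (without replacement within a split); per split
a gradient-boosted tree ensemble (300 estimators, Huber loss, learning
rate 0.1, depth 3, Huber quantile 0.9 — the tree implementation's
defaults frozen in `ModelSpec` and recorded in every run manifest) is
fitted on the training genes and predicts the held-out genes. Per-gene
predictions are pooled across the randomizations in which the gene was
held out, by the median; genes never held out are flagged and excluded
from evaluation. Accuracy is the Spearman rank correlation (average
ranks on ties) of pooled out-of-sample predictions against the observed
target; in-sample predictions are never used. Importances are the
ensemble's impurity-based importances normalized to sum to 1 per
randomization and aggregated as medians; Ward linkage over the
per-feature importance vectors provides a display ordering. 50
randomizations is the working default; full-scale analyses use 400+.

Feature augmentation merges extra columns (human discovery year,
homolog discovery years and publication counts, disease-annotation
indicators); missing homolog values become −1, disease columns
supported by fewer than 10 genes are dropped, and name collisions are
errors. The 2-D feature-space embedding is t-SNE with a fixed seed
(perplexity 30, reduced automatically for tiny inputs); coordinates are
persisted by callers so overlays reuse identical maps.

## 5. Enrichment and flags

EASE enrichment: the hypergeometric upper-tail p-value with the overlap
reduced by one (p = 1 for overlaps ≤ 1), which is always at least the
classical Fisher upper-tail p — verified exhaustively for all tables
with margins ≤ 30. FDR control is Benjamini-Hochberg at α = 0.05 across
all (cluster, term) pairs.

GO filtering: rows whose qualifier starts "NOT" or whose evidence is
ND / NR / "−" are always dropped; curated mode also drops IEA / RCA,
predicted mode keeps only IEA / RCA.

Flags use strict inequalities throughout: pLI **>** 0.9; GWAS-strong
requires a trait with **≥ 10** distinct studies and a gene in **> 20%**
of them, counting at most one association per study and keeping only
associations fully inside exactly one gene (1-based inclusive
coordinates); strong RNAi requires **≥ 20** studies (shRNA-abundance
screens excluded) and a phenotype in **> 30%**; a differential-
expression hit requires p **<** 1e-4, with "frequent" meaning a
top-quantile hit count (quantile configurable, default 0.8);
detectable RNA means ≥ 1 tissue at or above the FPKM floor (default 1
FPKM — there is no canonical "moderate abundance" threshold, so it is
exposed as configuration). The E (experimental
potential) aggregate is the disjunction of those flags plus optional
complex-membership evidence; G is LoF-intolerance or GWAS-strong; M is
an invertebrate model-organism homolog (fly or worm by default);
GEM = G ∧ E ∧ M.

Attention-bin enrichment reports, per bin, the fraction of genes
carrying a property divided by the overall fraction; bin-count-weighted
enrichments average to 1 by construction. Default bins are log-spaced
upper limits over the attention range.

## 6. Funding allocation

Duplicate rows of a project id are summed first. Nominal amounts are
inflation-adjusted by CPI(base)/CPI(year) with the base year defaulting
to the last corpus year. Each project's adjusted amount splits equally
over its supported publications, each publication's share equally over
its linked genes. Projects supporting no publication, and publication
shares reaching no gene, are removed from the conserved total and
reported — so the allocation table's sum equals the conserved total to
1e-6 relative, and scaling all budgets scales all totals linearly.
Publications supported by several projects receive each share
additively. The log10 of positive per-gene totals is the funding
prediction target; zero-funded genes are excluded from the log target
and counted.

## 7. Bibliometrics

**Record linkage.** Exact unique DOI first; otherwise candidates block
on (last-name list, year, journal) and score by normalized Levenshtein
title similarity, 100 × (1 − distance/max length). A link requires a
unique best candidate scoring ≥ 95; ties at the best score are rejected
as ambiguous.

**Discovery citations.** A discovery publication reports a human gene
in that gene's discovery year. Per discovery publication we count cited
publications carrying ≥ 1 human gene and ≥ 1 nonhuman gene; the
per-year statistic is the fraction of discovery publications citing
nonhuman-gene publications strictly more often. Publications with no
gene-bearing citations leave the denominator and are counted. The
per-taxon enrichment is the log2 ratio of a taxon's citation fraction
among all discovery publications to its fraction among discovery
publications that also cite human-gene work (censored at zero
denominators).

**Highly cited.** Citations are counted in the 8 years following
publication, (year, year+8]; publications younger than the horizon are
excluded; the flag is count ≥ the 95th percentile of eligible counts
(ties flagged inclusively). Team publications have > 2 authors or a
consortium as sole author.

**Human-specific genes.** Genes in no homology group containing a
nonhuman member, restricted to ids at or below the map's largest
eligible human id (genes above the cap could never have been grouped
and are excluded entirely); compared against grouped genes by a
one-sided rank-sum test.

**PI transitions.** An author transitions on their second last-author
publication with ≥ 1 coauthor. Every author-publication before the
author's transition is scored by the median cumulative fractional
attention of its genes up to its year and binned by the tie-averaged
percentile rank of that median among all genes of the same year.
Transition probabilities are standardized across yearly cohorts (each
quintile's probability is the year-share-weighted mean of per-year
probabilities), and the cohort grid defaults to the most recent third
of the corpus. Both choices are deliberate: early corpus years have
mostly-zero cumulative attention, so rank ties would otherwise couple
bin occupancy to calendar year and manufacture a spurious trend —
with them, a corpus with no attention-career coupling yields a flat
profile, which the tests assert.

## 8. Problem sizes and tolerances

The test suite runs the full pipeline at reduced but non-trivial sizes,
chosen as the package's standard working conditions: parameter-recovery
and null simulations at 2,000 genes × 50 features × 50 randomizations
of the full 300-tree Huber ensemble; the homolog-augmentation
comparison at 1,200 genes × 30 features × 20 randomizations over three
seeds; conservation laws on 20 random corpora each; the log-normal
Kolmogorov-Smirnov check at 5,000 genes over three seeds.
`scripts/acceptance.py` re-runs the same conditions with 25/15
randomizations. Exact identities (attention and funding conservation,
Gini against its pairwise oracle, the EASE worked example) are asserted
at 1e-9/1e-6/1e-12; stochastic recoveries use wide, pre-registered
bands (Spearman ≥ 0.8 for recovery, |ρ| ≤ 0.1 for the null, strict
improvement for augmentation).

## 9. Known limitations

* The generator's publication-bundling law and journal/review structure
  are simple parametric stand-ins; analyses sensitive to higher-order
  corpus structure (topic drift, journal prestige, author teams that
  persist over decades) are outside its reach.
* CAI depends on the supplied reference usage table; the packaged human
  table is a convenience default, not a claim about any particular
  genome build.
* The SEG implementation reproduces the two-threshold windowed-entropy
  scheme but not the original tool's recursive refinement of segment
  boundaries; segment edges can differ from the reference tool by a few
  residues.
* `pi_transition` treats "ever transitions in the corpus" as the
  outcome; right-censoring near the corpus end biases absolute
  transition probabilities downward (uniformly across quintiles, so the
  quintile *profile* is unaffected).
* GWAS interval containment assumes non-split gene models on a single
  assembly; no liftover, no trait ontology.
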