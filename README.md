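# ignorome

Why are some human genes studied in thousands of publications while
others — many with strong disease evidence — are barely touched?
`ignorome` is a toolkit for analysing that question quantitatively: it
models the relationship between intrinsic gene properties (sequence
composition, expression breadth, mutation intolerance, and so on) and
the research attention genes receive, measured through publication
counts, discovery years and research funding.

Because the real inputs (MEDLINE, Web of Science, NIH grant tables,
population-genetics databases) are licensed or enormous, the package is
built around a **synthetic-corpus generator** with known ground truth:
every analysis can be exercised, tested and calibrated on simulated
literatures whose generative parameters you control. The package is
aimed at meta-researchers and computational biologists who want to
study attention inequality in genomics, or to reuse the individual
components (fractional attention accounting, codon-bias features,
EASE enrichment, Monte-Carlo gradient boosting).

## The core quantities

**Fractional attention.** A publication linking *k* genes contributes
1/*k* to each, so a gene's attention is Σ 1/*k*ᵢ over its publications.
Summed over genes this equals the number of gene-linked publications —
an exact conservation law the tests enforce to 1e-9.

**Inequality.** Attention concentration is measured by the Gini
coefficient, *G* = Σᵢⱼ |xᵢ − xⱼ| / (2 n² x̄), and by Lorenz-style
cumulative-share curves.

**Prediction.** The modeling engine is a gradient-boosted regression
(300 trees, Huber loss) under Monte-Carlo cross-validation: repeated
random 90/10 splits, out-of-sample predictions pooled per gene by the
median, accuracy reported as Spearman's ρ between pooled predictions
and observed values, feature importances aggregated as medians across
randomizations. It is exposed statsmodels-style:

```python
model   = MonteCarloRegression(target, features, spec)
results = model.fit(seed=0)      # -> MonteCarloResults
print(results.summary())
```

**Enrichment.** Annotation enrichment uses the EASE score — Fisher's
exact upper-tail p-value recomputed after removing one gene from the
overlap, a deliberately conservative variant — with Benjamini-Hochberg
FDR control.

## Worked example

```python
import numpy as np
from ignorome import SyntheticConfig, generate_corpus, ModelSpec
from ignorome.prediction import MonteCarloRegression
from ignorome import attention as A

corpus = generate_corpus(SyntheticConfig(n_genes=500, seed=2,
                                         generate_sequences=False))

# attention accounting
att = A.fractional_attention(corpus.gene_link_table,
                             corpus.publication_table)
print(f"genes: {len(att)},  Gini: {A.gini(att['fractional']):.3f}")

# predict log10 publication counts from the gene features
counts = corpus.gene_link_table.table.groupby("gene_id")["pmid"].nunique()
target = np.log10(counts).rename("log10_publications")
spec = ModelSpec(n_randomizations=20)
results = MonteCarloRegression.from_feature_matrix(
    corpus.feature_matrix, target, spec).fit(seed=0)
print(f"pooled out-of-sample Spearman: {results.spearman:.2f}")
print("top features:", results.top_features(5))
```

Output:

```
genes: 500,  Gini: 0.550
pooled out-of-sample Spearman: 0.50
top features: ['feat_001', 'feat_002', 'feat_000', 'feat_003', 'feat_004']
```

The Gini of ~0.55 reflects the heavy-tailed (log-normal) publication
counts the generator produces, and the model ranks the five planted
causal features (`feat_000`–`feat_004`) on top. The pooled ρ of 0.5 is
expected for this default corpus: 40% of its genes are nonhuman
homologs whose attention tracks their human partner rather than their
own features. On a human-only corpus at the standard recovery
conditions (2,000 genes, noise 0.2) the same model reaches ρ ≈ 0.98 —
that run is part of `scripts/acceptance.py`.

## Command line

A thin CLI wraps the library:

```bash
ignorome simulate --config corpus.yaml --out corpus/ --seed 1
ignorome features --cds cds.fasta --protein prot.fasta --out features.tsv
ignorome attention --links gene2pubmed.tsv --pubs publications.tsv \
    --window 2011:2015 --out attention.tsv
ignorome predict --features features.tsv --target target.tsv --out run/
ignorome funding --grants grants.tsv --cpi cpi.tsv --links links.tsv \
    --out allocation.tsv
```

Table layouts mirror the public NCBI-style files (gene2pubmed, gene2go,
HomoloGene, ExPORTER-like grants).

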