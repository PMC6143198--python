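"""Sequence-derived gene features and feature-matrix plumbing.

Computes the sequence portion of the per-gene feature catalog —
nucleotide composition, codon usage and codon-bias indices, protein
physicochemistry, and SEG-style low-complexity segmentation — and the
matrix-level steps: merging precomputed experimental columns, imputation,
entity-to-gene mapping by median, z-scoring, and missingness clustering.

Externally measured columns (signal-peptide calls, repeat scores, CRISPR
essentiality, pLI, protein abundance) arrive as precomputed tables and are
merged as named features; they are not recomputed here.

All sequence intervals are 0-based half-open.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._tables import (
    AMINO_ACID_CLASSES,
    ALL_CODONS,
    GENETIC_CODE,
    HUMAN_CODON_USAGE_PER_1000,
    STANDARD_AMINO_ACIDS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)
from .containers import FeatureMatrix

__all__ = [
    "nucleotide_features",
    "codon_features",
    "protein_features",
    "low_complexity_features",
    "segment_low_complexity",
    "window_entropy",
    "expression_features",
    "impute_missing",
    "map_to_genes",
    "zscore",
    "missingness_profile",
    "LowComplexitySegmentation",
]

# SEG defaults of the cited segmentation approach: 12-residue window,
# trigger 2.2 bits, extension 2.5 bits.
SEG_WINDOW = 12
SEG_TRIGGER = 2.2
SEG_EXTENSION = 2.5

#: Feature-name prefixes whose absence encodes "low/undetected" and is
#: imputed as -1 (expression, stability, abundance, localization and
#: homolog-year families).  All other features stay missing and exclude
#: the gene from complete-catalog analyses.
MINUS_ONE_PREFIXES = (
    "fpkm_", "expression", "stability", "abundance", "localization", "homolog_",
)


def nucleotide_features(sequence: str) -> dict[str, float]:
    """Base composition of a DNA sequence.

    Fractions are computed over non-N positions; ``length`` counts every
    position.  Raises ``ValueError`` on an empty or all-N sequence or on
    characters outside {A, C, G, T, N}.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"unexpected characters: {sorted(set(seq) - set('ACGTN'))}")
    counts = {b: seq.count(b) for b in "ACGT"}
    informative = sum(counts.values())
    if informative == 0:
        raise ValueError("all-N sequence: base fractions undefined")
    out = {f"frac_{b.lower()}": counts[b] / informative for b in "ACGT"}
    out["gc_fraction"] = (counts["G"] + counts["C"]) / informative
    out["nucleotide_length"] = float(len(seq))
    return out


def _enc(codon_counts: Mapping[str, int]) -> float:
    """Wright's effective number of codons.

    Per synonymous family with n >= 2 codons observed, the homozygosity
    F = (n * sum p_i^2 - 1) / (n - 1).  ENC = 2 + 9/F2 + 1/F3 + 5/F4 +
    3/F6 with Fk the mean F over observed families of degeneracy k.  An
    unobserved 3-fold class is estimated as (F2 + F4)/2; any other empty
    class falls back to the overall mean F.  Bounded to [20, 61].
    """
    f_by_deg: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        deg = len(codons)
        if deg == 1:
            continue
        n = sum(codon_counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        s = sum((codon_counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            f_by_deg[deg].append(f)
    means = {k: float(np.mean(v)) for k, v in f_by_deg.items() if v}
    if not means:
        return float("nan")
    overall = float(np.mean([f for v in f_by_deg.values() for f in v]))
    if 3 not in means:
        if 2 in means and 4 in means:
            means[3] = (means[2] + means[4]) / 2.0
        else:
            means[3] = overall
    for k in (2, 4, 6):
        means.setdefault(k, overall)
    enc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return float(min(61.0, max(20.0, enc)))


def relative_adaptiveness(usage: Mapping[str, float]) -> dict[str, float]:
    """Codon weights w = usage / max usage within each synonymous family."""
    weights: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        top = max(usage.get(c, 0.0) for c in codons)
        for c in codons:
            weights[c] = usage.get(c, 0.0) / top if top > 0 else 1.0
    return weights


def codon_features(
    cds: str, reference_usage: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Codon composition and four codon-bias indices of a CDS.

    Returns the fraction of each of the 64 codons plus: ``enc`` (Wright's
    effective number of codons), ``cai`` (codon adaptation index against
    ``reference_usage``, default a standard human usage table),
    ``max_rscu_deviation`` (largest |RSCU - 1| over observed codons in
    degenerate families) and ``gc3`` (GC at third codon positions of
    sense codons).  The CDS length must be a multiple of 3; an internal
    stop codon is tolerated with a warning.
    """
    seq = cds.upper()
    if not seq or len(seq) % 3:
        raise ValueError("CDS length must be a positive multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        warnings.warn("internal stop codon in CDS; computing anyway", stacklevel=2)
    total = len(codons)
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    out = {f"codon_{c}": counts.get(c, 0) / total for c in ALL_CODONS}

    sense = [c for c in codons if c in GENETIC_CODE]
    sense_counts = {c: n for c, n in counts.items() if c in GENETIC_CODE}
    out["enc"] = _enc(sense_counts)

    usage = dict(reference_usage) if reference_usage is not None else dict(
        HUMAN_CODON_USAGE_PER_1000
    )
    weights = relative_adaptiveness(usage)
    logs = [
        math.log(max(weights[c], 1e-4))
        for c in sense
        if len(SYNONYMOUS_FAMILIES[GENETIC_CODE[c]]) > 1
    ]
    out["cai"] = float(math.exp(np.mean(logs))) if logs else 1.0

    max_dev = 0.0
    for codons_in_family in SYNONYMOUS_FAMILIES.values():
        k = len(codons_in_family)
        if k == 1:
            continue
        n = sum(sense_counts.get(c, 0) for c in codons_in_family)
        if n == 0:
            continue
        for c in codons_in_family:
            rscu = sense_counts.get(c, 0) / n * k
            max_dev = max(max_dev, abs(rscu - 1.0))
    out["max_rscu_deviation"] = max_dev

    thirds = [c[2] for c in sense]
    out["gc3"] = (
        sum(b in "GC" for b in thirds) / len(thirds) if thirds else float("nan")
    )
    return out


def protein_features(protein: str) -> dict[str, float]:
    """Residue composition and biophysical summary statistics of a protein.

    Residues outside the 20 standard amino acids are dropped with a
    warning.  GRAVY is the mean Kyte-Doolittle hydropathy; the isoelectric
    point is found by bisection on the net-charge curve under the
    Bjellqvist pKa set; the molecular weight is the average (isotope-
    abundance weighted) peptide mass.
    """
    seq = protein.upper().rstrip("*")
    dropped = [r for r in seq if r not in STANDARD_AMINO_ACIDS]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} nonstandard residues", stacklevel=2
        )
        seq = "".join(r for r in seq if r in STANDARD_AMINO_ACIDS)
    if not seq:
        raise ValueError("empty protein sequence")
    pa = ProteinAnalysis(seq)
    n = len(seq)
    out = {f"frac_{aa}": seq.count(aa) / n for aa in STANDARD_AMINO_ACIDS}
    for name, members in AMINO_ACID_CLASSES.items():
        out[f"frac_{name}"] = sum(seq.count(aa) for aa in members) / n
    out["gravy"] = pa.gravy()
    out["isoelectric_point"] = pa.isoelectric_point()
    out["molecular_weight"] = pa.molecular_weight()
    out["protein_length"] = float(n)
    return out


def window_entropy(window: str) -> float:
    """Shannon entropy (bits) of the residue multiset of a window."""
    n = len(window)
    counts = {}
    for r in window:
        counts[r] = counts.get(r, 0) + 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


@dataclass
class LowComplexitySegmentation:
    """Low-complexity segments (0-based half-open) and window entropies."""

    segments: list[tuple[int, int]]
    window_entropies: np.ndarray

    def __post_init__(self) -> None:
        for (a, b), (c, d) in zip(self.segments, self.segments[1:]):
            if c < b:
                raise ValueError("segments must be sorted and non-overlapping")


def segment_low_complexity(
    protein: str,
    window: int = SEG_WINDOW,
    trigger: float = SEG_TRIGGER,
    extension: float = SEG_EXTENSION,
) -> LowComplexitySegmentation:
    """Two-threshold entropy segmentation of a protein.

    Sliding windows with entropy <= ``trigger`` seed a segment; the
    segment extends over the maximal contiguous run of windows with
    entropy <= ``extension`` containing the seed.  Each run of windows
    [i, j] maps to residues [i, j + window).  Proteins shorter than the
    window yield no segments.
    """
    seq = protein.upper()
    L = len(seq)
    if L < window:
        return LowComplexitySegmentation([], np.empty(0))
    ent = np.array(
        [window_entropy(seq[i:i + window]) for i in range(L - window + 1)]
    )
    extendable = ent <= extension
    triggered = ent <= trigger
    segments: list[tuple[int, int]] = []
    i = 0
    m = len(ent)
    while i < m:
        if not extendable[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and extendable[j + 1]:
            j += 1
        if triggered[i:j + 1].any():
            segments.append((i, j + window))
        i = j + 1
    return LowComplexitySegmentation(segments, ent)


def low_complexity_features(
    protein: str,
    window: int = SEG_WINDOW,
    trigger: float = SEG_TRIGGER,
    extension: float = SEG_EXTENSION,
) -> dict[str, float]:
    """Low-complexity summary features of a protein.

    Reports total length, fraction of residues inside low-complexity
    regions, the longest region and its fraction of the protein, the
    number of regions, and the number of regions longer than 5/10/20/40
    residues.  Proteins shorter than the window get all-zero features.
    """
    seg = segment_low_complexity(protein, window, trigger, extension)
    L = len(protein)
    lengths = [b - a for a, b in seg.segments]
    covered = sum(lengths)
    longest = max(lengths, default=0)
    out = {
        "protein_length": float(L),
        "lc_fraction": covered / L if L else 0.0,
        "lc_longest": float(longest),
        "lc_longest_fraction": longest / L if L else 0.0,
        "lc_count": float(len(lengths)),
    }
    for cut in (5, 10, 20, 40):
        out[f"lc_count_gt{cut}"] = float(sum(l > cut for l in lengths))
    return out


def expression_features(fpkm: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Per-sample FPKM columns plus the fraction of samples below ``floor``.

    The below-floor fraction is a surrogate for the breadth of
    undetectable expression.  Negative FPKM values are rejected.
    """
    if (fpkm.values < 0).any():
        raise ValueError("FPKM values must be nonnegative")
    out = fpkm.add_prefix("fpkm_")
    out["expression_frac_below_1"] = (fpkm < floor).mean(axis=1)
    return out


def impute_missing(
    features: FeatureMatrix,
    minus_one_prefixes: Iterable[str] = MINUS_ONE_PREFIXES,
) -> tuple[FeatureMatrix, pd.Index]:
    """Impute absence-means-low columns with -1; return the complete set.

    Columns whose names start with one of ``minus_one_prefixes``
    (expression, stability, abundance, localization and homolog families)
    have missing entries set to -1, encoding "absent = low/undetected".
    Other features stay missing; genes still carrying a missing value are
    excluded from the returned complete-catalog index.
    """
    values = features.values.copy()
    mask = features.missing.copy()
    prefixes = tuple(minus_one_prefixes)
    for col in values.columns:
        if col.startswith(prefixes):
            hit = mask[col]
            values.loc[hit, col] = -1.0
            mask[col] = False
    imputed = FeatureMatrix(values, mask, features.zscored, features.constant_features)
    return imputed, imputed.complete_genes()


def map_to_genes(
    entity_values: pd.DataFrame, entity_to_gene: pd.Series
) -> pd.DataFrame:
    """Collapse entity-level features (transcripts, proteins) to genes.

    ``entity_to_gene`` maps entity id -> gene id; entities appearing with
    more than one gene are ambiguous and dropped.  Multiple entities of
    one gene are summarized by the median, per feature.  Already
    gene-level tables (one entity per gene) pass through unchanged.
    """
    mapping = entity_to_gene.dropna()
    n_genes = mapping.groupby(level=0).nunique()
    ambiguous = n_genes.index[n_genes > 1]
    if len(ambiguous):
        warnings.warn(
            f"dropping {len(ambiguous)} entities mapping to multiple genes",
            stacklevel=2,
        )
        mapping = mapping.drop(index=ambiguous)
    mapping = mapping[~mapping.index.duplicated()]
    usable = entity_values.index.intersection(mapping.index)
    frame = entity_values.loc[usable]
    return frame.groupby(mapping.loc[usable].values).median()


def zscore(features: FeatureMatrix) -> FeatureMatrix:
    """Standardize each feature over its non-missing entries (ddof=1).

    Constant columns (or columns with fewer than two observed values) are
    set to 0 and recorded in ``constant_features``.
    """
    if len(features.values) < 2:
        raise ValueError("z-scoring requires at least 2 genes")
    values = features.values.copy()
    constant = set()
    for col in values.columns:
        obs = values[col][~features.missing[col]]
        sd = obs.std(ddof=1)
        if len(obs) < 2 or not np.isfinite(sd) or sd == 0:
            values.loc[~features.missing[col], col] = 0.0
            constant.add(col)
        else:
            values[col] = (values[col] - obs.mean()) / sd
    return FeatureMatrix(values, features.missing.copy(), True, frozenset(constant))


def missingness_profile(
    features: FeatureMatrix, n_clusters: int = 2
) -> tuple[np.ndarray, pd.Series]:
    """Cluster genes by their feature-absence pattern.

    Hierarchical average-linkage clustering of the boolean missingness
    mask under Hamming distance (fraction of features whose absence
    status differs).  Returns the linkage matrix and per-gene labels at
    an ``n_clusters`` cut.
    """
    mask = features.missing.to_numpy(dtype=bool)
    if mask.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    dist = pdist(mask, metric="hamming")
    link = linkage(dist, method="average")
    labels = fcluster(link, t=n_clusters, criterion="maxclust")
    return link, pd.Series(labels, index=features.gene_ids, name="cluster")
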