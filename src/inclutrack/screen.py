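"""CRISPR-screen hit calling, MYTH interaction calls and set algebra.

The hit-selection thresholds are the printed ones: a gene is a top hit in a
pairwise comparison when |log2 fold change| >= 1 and FDR <= 0.1 (inclusive
boundaries). Heatmap-style categories use strict cutoffs: an enhancer of the
3K genotype drops out specifically there (lfc differential 3K - WT < -0.7,
3K FDR < 0.25, WT lfc < 1, the last to avoid genes that simply make WT cells
grow better); a suppressor is enriched specifically in 3K (differential > 1,
3K FDR < 0.2).

Gene-level scores come from a documented stand-in aggregator (this package
deliberately does not reimplement MAGeCK or edgeR): median per-gRNA log2
fold change after median-of-ratios library normalization with pseudocount 1,
a gRNA-label permutation p-value and Benjamini-Hochberg FDR. A
negative-binomial count simulator with planted essential / modifier genes
provides ground truth for recovery tests.

MYTH growth spots are scored 0-4 in two replicates; lenient call: both
scores >= 1; stringent call: both > 1, or one score 4 and the other >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

GENOTYPES = ("3K", "WT", "sfGFP")
TIMEPOINTS = ("t0", "d7", "d14")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Synthetic genome-scale knockout screen with planted gene classes."""

    n_genes: int = 1000
    grnas_per_gene: int = 5
    fraction_essential: float = 0.05      # depleted in every genotype
    fraction_enhancer: float = 0.025      # depleted in 3K only
    fraction_suppressor: float = 0.025    # enriched in 3K only
    essential_lfc: float = -2.0
    enhancer_lfc: float = -2.0
    suppressor_lfc: float = 1.5
    dispersion: float = 0.1               # NB: var = mu + dispersion * mu^2
    depth: float = 500.0                  # mean t0 reads per gRNA
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.grnas_per_gene < 2:
            raise ValidationError("need n_genes >= 1 and grnas_per_gene >= 2")
        fractions = (self.fraction_essential, self.fraction_enhancer,
                     self.fraction_suppressor)
        if any(not 0 <= f <= 1 for f in fractions) or sum(fractions) > 1:
            raise ValidationError("class fractions must be in [0,1] and sum to <= 1")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def _nb_counts(rng, mean, dispersion):
    """Negative-binomial draws parameterized by mean and dispersion."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(
    config: ScreenSimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """gRNA count table and gene-class truth table.

    Columns are ``{genotype}_{timepoint}_r{rep}``; the planted log2 fold
    change is fully expressed at day 14 and half-expressed at day 7.
    Essential genes deplete in all genotypes; enhancer genes deplete and
    suppressor genes enrich in the 3K genotype only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes, k = config.n_genes, config.grnas_per_gene

    classes = np.array(["neutral"] * n_genes, dtype=object)
    n_ess = int(round(config.fraction_essential * n_genes))
    n_enh = int(round(config.fraction_enhancer * n_genes))
    n_sup = int(round(config.fraction_suppressor * n_genes))
    order = rng.permutation(n_genes)
    classes[order[:n_ess]] = "essential"
    classes[order[n_ess:n_ess + n_enh]] = "enhancer"
    classes[order[n_ess + n_enh:n_ess + n_enh + n_sup]] = "suppressor"

    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    grna_gene = np.repeat(genes, k)
    grnas = np.array([f"{g}_g{j + 1}" for g in genes for j in range(k)])

    # per-gRNA baseline abundance (library skew) around the configured depth
    base = config.depth * rng.lognormal(mean=0.0, sigma=0.4, size=n_genes * k)

    def planted_lfc(genotype: str) -> np.ndarray:
        lfc = np.zeros(n_genes)
        lfc[classes == "essential"] = config.essential_lfc
        if genotype == "3K":
            lfc[classes == "enhancer"] = config.enhancer_lfc
            lfc[classes == "suppressor"] = config.suppressor_lfc
        return np.repeat(lfc, k)

    data = {}
    for genotype in GENOTYPES:
        lfc = planted_lfc(genotype)
        for timepoint, expressed in zip(TIMEPOINTS, (0.0, 0.5, 1.0)):
            mean = base * 2.0 ** (lfc * expressed)
            for rep in range(1, config.n_replicates + 1):
                col = f"{genotype}_{timepoint}_r{rep}"
                data[col] = _nb_counts(rng, mean, config.dispersion)

    counts = pd.DataFrame({"grna": grnas, "gene": grna_gene, **data})
    truth = pd.DataFrame({"gene": genes, "gene_class": classes})
    return counts, truth


# --------------------------------------------------------------------------
# gene-level aggregation (stand-in for MAGeCK / edgeR)
# --------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors over samples (columns)."""
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        return np.ones(counts.shape[1])
    log_geo = np.log(counts[positive]).mean(axis=1, keepdims=True)
    ratios = np.log(counts[positive]) - log_geo
    return np.exp(np.median(ratios, axis=0))


def aggregate_gene_scores(
    counts: pd.DataFrame,
    t0_cols: Sequence[str],
    t14_cols: Sequence[str],
    n_permutations: int = 1000,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene log2FC (median over gRNAs), permutation p-value and BH FDR.

    Per gRNA: log2((norm t14 + pseudocount) / (norm t0 + pseudocount)),
    averaging replicates after median-of-ratios normalization. Per gene: the
    median across its gRNAs. The null distribution re-draws gene-sized gRNA
    sets from the pooled per-gRNA log2FCs (``n_permutations`` independent
    draws per gene); p-values are two-sided and BH-corrected. Genes whose
    t0 counts are all zero are flagged and excluded.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    sample_cols = list(t0_cols) + list(t14_cols)
    matrix = counts[sample_cols].to_numpy(dtype=float)
    factors = median_of_ratios_size_factors(matrix)
    normed = matrix / factors
    t0 = normed[:, :len(t0_cols)].mean(axis=1)
    t14 = normed[:, len(t0_cols):].mean(axis=1)

    raw_t0 = counts[list(t0_cols)].to_numpy(dtype=float).sum(axis=1)
    grna_lfc = np.log2((t14 + pseudocount) / (t0 + pseudocount))

    per_gene = counts[["gene"]].copy()
    per_gene["lfc"] = grna_lfc
    per_gene["t0_zero"] = raw_t0 == 0
    grouped = per_gene.groupby("gene", sort=True)
    gene_lfc = grouped["lfc"].median()
    gene_k = grouped.size()
    all_zero = grouped["t0_zero"].all()

    if (gene_k < 2).any():
        bad = gene_k[gene_k < 2].index.tolist()
        raise ValidationError(f"genes with < 2 gRNAs: {bad[:5]}")

    rng = np.random.default_rng(seed)
    pool = grna_lfc
    k = int(gene_k.iloc[0]) if gene_k.nunique() == 1 else None
    genes = gene_lfc.index.to_numpy()
    pvals = np.ones(len(genes))
    if k is not None:
        # balanced design: draw an independent null set per gene, chunked
        observed = np.abs(gene_lfc.to_numpy())
        chunk = max(1, int(5_000_000 / (n_permutations * k)))
        for start in range(0, len(genes), chunk):
            stop = min(start + chunk, len(genes))
            draws = rng.choice(pool, size=(stop - start, n_permutations, k))
            null_medians = np.abs(np.median(draws, axis=2))
            exceed = (null_medians >= observed[start:stop, None]).sum(axis=1)
            pvals[start:stop] = (1 + exceed) / (1 + n_permutations)
    else:
        for i, gene in enumerate(genes):
            kg = int(gene_k.loc[gene])
            draws = rng.choice(pool, size=(n_permutations, kg))
            null_medians = np.abs(np.median(draws, axis=1))
            pvals[i] = (1 + (null_medians >= abs(gene_lfc.loc[gene])).sum()) / (
                1 + n_permutations)

    result = pd.DataFrame({
        "gene": genes,
        "log2fc": gene_lfc.to_numpy(),
        "p_value": pvals,
        "flagged_zero_t0": all_zero.to_numpy(),
    })
    keep = ~result.flagged_zero_t0
    fdr = np.full(len(result), np.nan)
    if keep.any():
        fdr[keep.to_numpy()] = multipletests(
            result.p_value[keep], method="fdr_bh")[1]
    result["fdr"] = fdr
    return result[keep].reset_index(drop=True) if (~keep).any() else result


# --------------------------------------------------------------------------
# hit calling
# --------------------------------------------------------------------------

def call_top_hits(
    scores: pd.DataFrame,
    lfc_col: str = "log2fc",
    fdr_col: str = "fdr",
    lfc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.1,
) -> Set[str]:
    """Genes with log2FC <= -cutoff or >= +cutoff and FDR <= cutoff (inclusive)."""
    for col in ("gene", lfc_col, fdr_col):
        if col not in scores.columns:
            raise ValidationError(f"scores table lacks column {col!r}")
    lfc = scores[lfc_col]
    hit = ((lfc <= -lfc_cutoff) | (lfc >= lfc_cutoff)) & (scores[fdr_col] <= fdr_cutoff)
    return set(scores.loc[hit, "gene"])


def classify_enhancers_suppressors(
    scores: pd.DataFrame,
    lfc_3k_col: str = "lfc_3K",
    lfc_wt_col: str = "lfc_WT",
    fdr_3k_col: str = "fdr_3K",
) -> pd.Series:
    """Per-gene labels: enhancer / suppressor / none (strict cutoffs).

    enhancer:  (lfc_3K - lfc_WT) < -0.7  and  fdr_3K < 0.25  and  lfc_WT < 1
    suppressor:(lfc_3K - lfc_WT) >  1    and  fdr_3K < 0.2
    The two conditions are mutually exclusive (differential sign).
    """
    for col in (lfc_3k_col, lfc_wt_col, fdr_3k_col):
        if col not in scores.columns:
            raise ValidationError(f"scores table lacks column {col!r}")
    differential = scores[lfc_3k_col] - scores[lfc_wt_col]
    enhancer = (differential < -0.7) & (scores[fdr_3k_col] < 0.25) & (scores[lfc_wt_col] < 1)
    suppressor = (differential > 1) & (scores[fdr_3k_col] < 0.2)
    labels = pd.Series("none", index=scores.index, name="label")
    labels[enhancer] = "enhancer"
    labels[suppressor] = "suppressor"
    return labels


# --------------------------------------------------------------------------
# MYTH interaction calls
# --------------------------------------------------------------------------

def myth_call(score_rep1: int, score_rep2: int, mode: str = "lenient") -> bool:
    """Interaction call from two replicate growth scores in {0..4}.

    lenient: both >= 1. stringent: both > 1, or one score is 4 and the
    other >= 1.
    """
    s1, s2 = int(score_rep1), int(score_rep2)
    for s in (s1, s2):
        if not 0 <= s <= 4:
            raise ValidationError(f"MYTH scores must be in 0..4, got {s}")
    if mode == "lenient":
        return s1 >= 1 and s2 >= 1
    if mode == "stringent":
        return (s1 > 1 and s2 > 1) or (max(s1, s2) == 4 and min(s1, s2) >= 1)
    raise ValidationError(f"mode must be 'lenient' or 'stringent', got {mode!r}")


def myth_call_table(pairs: pd.DataFrame, mode: str = "lenient") -> pd.Series:
    """Vectorized calls for a (prey, bait, score_rep1, score_rep2) table."""
    return pd.Series(
        [myth_call(r1, r2, mode) for r1, r2 in zip(pairs.score_rep1, pairs.score_rep2)],
        index=pairs.index, name=f"{mode}_positive",
    )


# --------------------------------------------------------------------------
# set algebra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    intersection: frozenset
    union: frozenset
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int


def normalize_symbols(symbols: Iterable[str]) -> Set[str]:
    return {s.strip().upper() for s in symbols if s and s.strip()}


def set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapResult:
    """Exact set algebra over case-normalized gene symbols."""
    a = normalize_symbols(set_a)
    b = normalize_symbols(set_b)
    inter = a & b
    union = a | b
    return OverlapResult(
        intersection=frozenset(inter), union=frozenset(union),
        n_a=len(a), n_b=len(b),
        n_intersection=len(inter), n_union=len(union),
    )
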