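"""Benchmarking against truth sets and cohort-level concordance statistics.

Covers the confusion-matrix benchmark of a variant pipeline against a
spiked-in truth set (precision/recall/F1 and the correlation of recovered
vs true allele fractions), per-sample mutational load, Fisher/hypergeometric
tests of gene-set overlap between cohorts, and per-gene over/under-expression
and gain/loss frequency statistics used to compare cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkResult",
    "benchmark",
    "mutational_load",
    "gene_overlap_fisher",
    "set_overlap_hypergeom",
    "expression_frequencies",
    "frequency_correlation",
    "top_varying_genes",
]


@dataclass
class BenchmarkResult:
    """Confusion counts and derived metrics at (chrom, pos, alt) resolution."""

    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    f1: float
    af_pearson: Optional[float]

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "af_pearson": self.af_pearson,
        }


def _locus_key(chrom, pos, alt):
    return (str(chrom), int(pos), str(alt))


def benchmark(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    universe: Iterable[tuple],
) -> BenchmarkResult:
    """Score predicted variants against a truth set.

    ``predicted`` needs columns ``chrom``, ``pos``, ``alt``, ``ALT_AF``;
    ``truth`` needs ``chrom``, ``pos``, ``alt``, ``true_af``.  ``universe``
    is the set of assessable (chrom, pos, alt) loci; it must contain every
    truth and predicted locus (true negatives are the universe loci in
    neither set).  Precision and recall default to 0 on empty denominators;
    F1 = 2*(recall*precision)/(recall+precision).  The allele-fraction
    Pearson correlation is over true positives (missing when fewer than 2).
    """
    universe = {_locus_key(*u) for u in universe}
    pred_af = {}
    for row in predicted.itertuples(index=False):
        pred_af[_locus_key(row.chrom, row.pos, row.alt)] = float(row.ALT_AF)
    true_af = {}
    for row in truth.itertuples(index=False):
        true_af[_locus_key(row.chrom, row.pos, row.alt)] = float(row.true_af)
    pred_keys, truth_keys = set(pred_af), set(true_af)
    outside = (pred_keys | truth_keys) - universe
    if outside:
        raise ValueError(f"loci outside the assessable universe: {sorted(outside)[:5]}")
    tp_keys = pred_keys & truth_keys
    tp, fp = len(tp_keys), len(pred_keys - truth_keys)
    fn = len(truth_keys - pred_keys)
    tn = len(universe - pred_keys - truth_keys)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * (recall * precision) / (recall + precision) if recall + precision else 0.0
    if len(tp_keys) >= 2:
        xs = np.array([pred_af[k] for k in tp_keys])
        ys = np.array([true_af[k] for k in tp_keys])
        if np.std(xs) == 0 or np.std(ys) == 0:
            af_pearson = None
        else:
            af_pearson = float(stats.pearsonr(xs, ys).statistic)
    else:
        af_pearson = None
    return BenchmarkResult(TP=tp, FP=fp, TN=tn, FN=fn, precision=precision,
                           recall=recall, f1=f1, af_pearson=af_pearson)


def mutational_load(sample_variants: pd.DataFrame, panel_genes: Iterable[str]) -> int:
    """Count of emitted non-silent coding mutations in panel genes.

    Variants qualify when ``effect == "non_silent_coding"``, ``gene`` is in
    the panel, and (when a ``final`` column is present) the pipeline emitted
    them as ``somatic_pass`` or ``rescued_clinical``.
    """
    if sample_variants.empty:
        return 0
    df = sample_variants
    mask = (df["effect"] == "non_silent_coding") & df["gene"].isin(set(panel_genes))
    if "final" in df.columns:
        mask &= df["final"].isin(["somatic_pass", "rescued_clinical"])
    return int(mask.sum())


def gene_overlap_fisher(set_a: Iterable, set_b: Iterable, universe: Iterable):
    """One-sided (enrichment) Fisher exact test of gene-set overlap.

    Builds the 2x2 table (in both / A only / B only / neither) over the
    universe and returns ``(table, p)`` with p the hypergeometric upper
    tail P[overlap >= observed].
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe - a - b)
    table = np.array([[both, a_only], [b_only, neither]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return table, float(p)


def set_overlap_hypergeom(set_a: Iterable, set_b: Iterable, universe: Iterable) -> float:
    """Hypergeometric upper-tail p of the observed overlap between two sets
    drawn from a common universe: P[X >= |A & B|], X ~ Hypergeom(N, |A|, |B|)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    observed = len(a & b)
    return float(stats.hypergeom.sf(observed - 1, len(universe), len(a), len(b)))


def expression_frequencies(z: pd.DataFrame, hi: float = 1.0, lo: float = -1.0) -> pd.DataFrame:
    """Per-gene fractions of samples over- (z > hi) or under-expressed
    (z < lo); both inequalities strict."""
    over = (z > hi).mean(axis=1)
    under = (z < lo).mean(axis=1)
    return pd.DataFrame({"over_freq": over, "under_freq": under})


def frequency_correlation(freqs_a: pd.Series, freqs_b: pd.Series) -> Optional[float]:
    """Pearson correlation of per-gene frequencies over the shared gene set.

    Applies equally to over/under-expression and gain/loss frequencies.
    Returns None when either vector has zero variance.
    """
    shared = freqs_a.index.intersection(freqs_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    a = freqs_a.loc[shared].astype(float)
    b = freqs_b.loc[shared].astype(float)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def top_varying_genes(
    z: pd.DataFrame,
    n: int = 1000,
    expression: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    expression_floor: float = 2.0,
) -> list:
    """Top ``n`` genes by variance of their z-scores.

    When an ``expression`` matrix (log2(TPM + 1)) is given, genes whose mean
    expression is below ``expression_floor`` in every cohort (``groups``
    maps samples to cohorts; one cohort assumed if omitted) are removed
    before ranking.

    When ``groups`` assigns samples to two or more cohorts, the ranking
    statistic is the variance of the per-cohort mean z-scores — the variance
    of z over a single standardization cohort is 1 for every gene by
    construction, so "varying" is only meaningful between cohorts.  Without
    groups the plain across-sample variance is used (appropriate when z was
    standardized on a different reference cohort).  Ties break
    lexicographically by gene identifier.
    """
    genes = z.index
    if expression is not None:
        floor_groups = groups if groups is not None else pd.Series(
            "all", index=expression.columns)
        means = expression.T.groupby(floor_groups).mean().T  # genes x cohorts
        genes = genes[means.loc[genes].max(axis=1) >= expression_floor]
    if n > len(genes):
        raise ValueError(f"requested {n} genes but only {len(genes)} expressed")
    if groups is not None and groups.nunique() > 1:
        group_means = z.loc[genes].T.groupby(groups).mean().T
        var = group_means.var(axis=1, ddof=1)
    else:
        var = z.loc[genes].var(axis=1, ddof=1)
    ranked = var.sort_index().sort_values(ascending=False, kind="mergesort")
    return list(ranked.index[:n])
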