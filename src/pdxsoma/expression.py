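"""Expression normalization and the EBV-lymphoma signature classifier.

Engrafted tumors in immunodeficient mice can be displaced by Epstein-Barr
virus transformed B-cell lymphomas; such samples show a distinct expression
pattern and must be flagged before downstream analysis.  The classifier
works on upper-quantile normalized counts: per-gene z-scores are computed
across the cohort, a signature of the most up- and down-shifted genes
(24 of each by default) is derived from labelled examples, and each sample
is scored by the sum of sign-corrected signature z-scores.  Scores strictly
above the decision threshold (3.0) flag a sample as a putative
EBV-associated lymphoma.

Matrices are pandas DataFrames with genes as rows and samples as columns.
An sklearn-style wrapper (:class:`EBVSignatureClassifier`) is provided for
composition with sklearn tooling; the module functions are the primary
interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Signature",
    "ClassifierScore",
    "human_read_gate",
    "upper_quantile_normalize",
    "zscore_by_gene",
    "derive_signature",
    "score_samples",
    "EBVSignatureClassifier",
]


@dataclass
class Signature:
    """Signed gene signature: +1 entries are up in the target class."""

    entries: pd.DataFrame  # columns: gene, sign

    def __post_init__(self) -> None:
        if self.entries["gene"].duplicated().any():
            raise ValueError("duplicate genes in signature")
        if not set(self.entries["sign"]).issubset({1, -1}):
            raise ValueError("signature signs must be +1 or -1")

    @property
    def genes(self) -> list:
        return list(self.entries["gene"])

    @property
    def signs(self) -> pd.Series:
        return self.entries.set_index("gene")["sign"]

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Signature":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ClassifierScore:
    sample_id: str
    score: float
    is_lymphoma: bool


def human_read_gate(human_read_counts: Mapping[str, int], min_reads: int = 1_000_000) -> pd.Series:
    """Per-sample gate requiring at least ``min_reads`` human reads for
    reliable expression quantification.  Returns a boolean pass Series."""
    if len(human_read_counts) == 0:
        raise ValueError("no human read-count metadata provided")
    counts = pd.Series(dict(human_read_counts))
    if counts.isna().any():
        missing = list(counts[counts.isna()].index)
        raise ValueError(f"missing human read counts for samples: {missing}")
    return counts >= min_reads


def upper_quantile_normalize(matrix: pd.DataFrame, scale: float = 1000.0) -> pd.DataFrame:
    """Upper-quantile normalization of non-zero counts, scaled.

    Per sample, the 75th percentile (linear interpolation) of the sample's
    *non-zero* counts is computed and every count divided by it and
    multiplied by ``scale``; zeros remain zero, so after normalization the
    75th percentile of each sample's non-zero values equals ``scale``.
    """
    if (matrix.values < 0).any():
        raise ValueError("expression counts must be non-negative")
    out = {}
    for sample in matrix.columns:
        col = matrix[sample].astype(float)
        nonzero = col[col > 0]
        if nonzero.empty:
            raise ValueError(f"sample {sample!r} has no non-zero counts")
        uq = float(np.percentile(nonzero, 75))
        out[sample] = col / uq * scale
    return pd.DataFrame(out, index=matrix.index)


def zscore_by_gene(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, n-1, by default).

    Genes with zero standard deviation get z = 0 everywhere.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scores require at least two samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=ddof)
    z = matrix.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def derive_signature(
    z: pd.DataFrame,
    labels: Mapping[str, bool] | pd.Series,
    n_up: int = 24,
    n_down: int = 24,
    expression_floor: float | None = 1.0,
    normalized: pd.DataFrame | None = None,
) -> Signature:
    """Derive a signed signature from a labelled cohort.

    ``labels`` marks target-class (EBV) samples True.  Genes failing the
    expression floor (mean normalized count > ``expression_floor`` when a
    normalized matrix is supplied) are removed first.  The per-gene ranking
    statistic is the difference of group mean z-scores (target minus rest);
    the top ``n_up`` genes get sign +1 and the bottom ``n_down`` sign -1.
    Ties break lexicographically by gene identifier for determinism.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(z.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    pos = z.columns[labels.astype(bool)]
    neg = z.columns[~labels.astype(bool)]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both labelled groups must be non-empty")
    genes = z.index
    if expression_floor is not None and normalized is not None:
        genes = genes[normalized.loc[genes].mean(axis=1) > expression_floor]
    if len(genes) < n_up + n_down:
        raise ValueError(
            f"only {len(genes)} expressed genes; need {n_up + n_down} for the signature"
        )
    stat = z.loc[genes, pos].mean(axis=1) - z.loc[genes, neg].mean(axis=1)
    # stable sorts after a lexicographic pre-sort give a deterministic tie-break
    desc = stat.sort_index().sort_values(ascending=False, kind="mergesort")
    asc = stat.sort_index().sort_values(ascending=True, kind="mergesort")
    up = list(desc.index[:n_up])
    down = list(asc.index[:n_down])
    if set(up) & set(down):
        raise ValueError("up and down signature halves overlap; too few genes")
    entries = pd.DataFrame(
        {"gene": up + down, "sign": [1] * len(up) + [-1] * len(down)}
    )
    return Signature(entries)


def score_samples(
    z: pd.DataFrame,
    signature: Signature,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Score every sample as the sum of sign-corrected signature z-scores.

    A sample is flagged a putative lymphoma when its score is strictly
    greater than ``threshold``.  Missing signature genes are an error.
    """
    missing = [g for g in signature.genes if g not in z.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    signs = signature.signs
    scores = z.loc[signs.index].mul(signs, axis=0).sum(axis=0)
    return pd.DataFrame({
        "sample_id": scores.index,
        "score": scores.values,
        "is_lymphoma": scores.values > threshold,
    })


class EBVSignatureClassifier:
    """sklearn-style estimator wrapping the signature derivation and scorer.

    ``X`` is samples x genes (sklearn orientation) of raw counts; ``y`` is a
    boolean/0-1 vector marking EBV-lymphoma samples.  ``fit`` normalizes,
    z-transforms, and derives the signature on the training cohort, storing
    the per-gene normalized-scale means and standard deviations so new
    samples can be scored against the training distribution.
    """

    def __init__(self, n_up: int = 24, n_down: int = 24, threshold: float = 3.0,
                 expression_floor: float | None = 1.0, scale: float = 1000.0):
        self.n_up = n_up
        self.n_down = n_down
        self.threshold = threshold
        self.expression_floor = expression_floor
        self.scale = scale

    def get_params(self, deep: bool = True) -> dict:
        return {"n_up": self.n_up, "n_down": self.n_down, "threshold": self.threshold,
                "expression_floor": self.expression_floor, "scale": self.scale}

    def set_params(self, **params) -> "EBVSignatureClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X))

    def fit(self, X, y) -> "EBVSignatureClassifier":
        X = self._to_frame(X)
        counts = X.T  # genes x samples
        norm = upper_quantile_normalize(counts, scale=self.scale)
        z = zscore_by_gene(norm)
        labels = pd.Series(np.asarray(y).astype(bool), index=counts.columns)
        self.signature_ = derive_signature(
            z, labels, n_up=self.n_up, n_down=self.n_down,
            expression_floor=self.expression_floor, normalized=norm,
        )
        sig_genes = self.signature_.genes
        self.gene_mean_ = norm.loc[sig_genes].mean(axis=1)
        self.gene_sd_ = norm.loc[sig_genes].std(axis=1, ddof=1)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "signature_"):
            raise RuntimeError("classifier is not fitted")
        X = self._to_frame(X)
        norm = upper_quantile_normalize(X.T, scale=self.scale)
        sig = self.signature_
        sd = self.gene_sd_.replace(0.0, np.nan)
        z = norm.loc[sig.genes].sub(self.gene_mean_, axis=0).div(sd, axis=0).fillna(0.0)
        scores = z.mul(sig.signs, axis=0).sum(axis=0)
        return scores.values - self.threshold

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X) > 0

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y).astype(bool)))
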