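"""Gene-level copy number, LOH, and ploidy-relative gain/loss calling.

Allele-specific copy-number segments (e.g. ASCAT output: per-segment major
and minor allele copy number, plus a per-sample mean cancer-genome ploidy)
are intersected with gene models.  A gene spanning a segment boundary takes
the most conservative (lowest) total copy number of its overlapping
segments.  Gains and losses are called from log2(CN / baseline) where the
baseline is either the sample's overall cancer-genome ploidy (preferred for
aneuploid tumors) or the diploid state 2; the low-level threshold is +-0.4
and the high-level threshold +-1.  Concordance of copy-number state with
expression is assessed by fold changes relative to stringently copy-neutral
samples and a two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CNSegment",
    "SampleCNProfile",
    "GeneCN",
    "call_loh",
    "gene_copy_number",
    "call_gain_loss",
    "cn_expression_concordance",
]

CALLS = ("high_loss", "loss", "normal", "gain", "high_gain")


@dataclass
class CNSegment:
    """One allele-specific copy-number segment (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    nMajor: float
    nMinor: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not (self.nMajor >= self.nMinor >= 0):
            raise ValueError("require nMajor >= nMinor >= 0")

    @property
    def total(self) -> float:
        return self.nMajor + self.nMinor


@dataclass
class SampleCNProfile:
    """A sample's segmented allele-specific copy-number profile."""

    sample_id: str
    segments: list
    ploidy: float
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )
        self._by_chrom = {c: sorted(s, key=lambda x: x.start) for c, s in by_chrom.items()}


@dataclass
class GeneCN:
    """Per-gene copy-number annotation."""

    gene: str
    total_cn: Optional[float]
    n_segments: int
    loh: bool
    log2_vs_ploidy: Optional[float] = None
    log2_vs_diploid: Optional[float] = None
    call: Optional[str] = None
    baseline: str = "ploidy"


def call_loh(seg: CNSegment) -> bool:
    """Loss of heterozygosity: major-allele CN >= 0.5 and minor-allele
    CN <= 0.1 (one parental allele effectively absent)."""
    return seg.nMajor >= 0.5 and seg.nMinor <= 0.1


def gene_copy_number(profile: SampleCNProfile, genes: pd.DataFrame) -> list:
    """Annotate genes with conservative total CN, segment count and LOH.

    ``genes`` has columns ``gene``, ``chrom``, ``start``, ``end`` (1-based
    inclusive).  A gene crossing a segment boundary takes the minimum total
    CN over its overlapping segments and is flagged LOH when any overlapping
    segment is LOH.  Genes overlapping no segment receive missing CN.
    """
    out = []
    for row in genes.itertuples(index=False):
        overlapping = [
            seg for seg in profile._by_chrom.get(str(row.chrom), [])
            if seg.start <= row.end and row.start <= seg.end
        ]
        if overlapping:
            total = min(seg.total for seg in overlapping)
            loh = any(call_loh(seg) for seg in overlapping)
        else:
            total, loh = None, False
        out.append(GeneCN(gene=str(row.gene), total_cn=total,
                          n_segments=len(overlapping), loh=loh))
    return out


def call_gain_loss(
    g: GeneCN,
    baseline: str = "ploidy",
    ploidy: float = 2.0,
    low_threshold: float = 0.4,
    high_threshold: float = 1.0,
) -> GeneCN:
    """Call the gene's CN state relative to a baseline.

    r = log2(total_cn / baseline_value) with baseline_value the sample
    ploidy (``baseline="ploidy"``) or 2 (``baseline="diploid"``).  States:
    high_gain (r > +1), gain (+0.4 < r <= +1), normal (|r| <= 0.4),
    loss (-1 <= r < -0.4), high_loss (r < -1).  total_cn = 0 maps to
    high_loss without evaluating log2(0).
    """
    if baseline not in ("ploidy", "diploid"):
        raise ValueError(f"baseline must be 'ploidy' or 'diploid', got {baseline!r}")
    base = ploidy if baseline == "ploidy" else 2.0
    if base <= 0:
        raise ValueError(f"baseline value must be > 0, got {base}")
    if g.total_cn is None:
        raise ValueError(f"gene {g.gene} has no copy number (no overlapping segment)")
    g.baseline = baseline
    if ploidy > 0:
        g.log2_vs_ploidy = math.log2(g.total_cn / ploidy) if g.total_cn > 0 else -math.inf
    g.log2_vs_diploid = math.log2(g.total_cn / 2.0) if g.total_cn > 0 else -math.inf
    if g.total_cn == 0:
        g.call = "high_loss"
        return g
    r = math.log2(g.total_cn / base)
    if r > high_threshold:
        g.call = "high_gain"
    elif r > low_threshold:
        g.call = "gain"
    elif r >= -low_threshold:
        g.call = "normal"
    elif r >= -high_threshold:
        g.call = "loss"
    else:
        g.call = "high_loss"
    return g


def annotate_sample(
    profile: SampleCNProfile,
    genes: pd.DataFrame,
    baseline: str = "ploidy",
) -> pd.DataFrame:
    """Full per-sample gene annotation as a tidy table."""
    rows = []
    for g in gene_copy_number(profile, genes):
        if g.total_cn is not None:
            g = call_gain_loss(g, baseline=baseline, ploidy=profile.ploidy)
        rows.append({
            "sample_id": profile.sample_id, "gene": g.gene, "total_cn": g.total_cn,
            "n_segments": g.n_segments, "loh": g.loh,
            "log2_vs_ploidy": g.log2_vs_ploidy, "log2_vs_diploid": g.log2_vs_diploid,
            "call": g.call, "baseline": g.baseline,
        })
    return pd.DataFrame(rows)


def cn_expression_concordance(
    gene_states: pd.DataFrame,
    expression: pd.DataFrame,
    gene_list: Iterable[str] | None = None,
    normal_window: float = 0.4,
    high_threshold: float = 1.0,
) -> pd.DataFrame:
    """Test whether high-level CN gains/losses shift expression.

    Parameters
    ----------
    gene_states:
        Tidy table with ``sample_id``, ``gene``, ``log2_vs_ploidy``.
    expression:
        log2(TPM + 1) matrix, genes x samples.
    gene_list:
        Genes to test (default: all genes present in both inputs).

    For each gene, samples are classed by log2(CN/ploidy): high-level loss
    (< -1), normal (within +-1) and high-level gain (> +1).  The reference
    expression is the mean over samples in the *stringent* normal state
    (within +-``normal_window``); per-sample fold change is expression minus
    that mean.  Gain and loss classes are each compared with the normal
    class by a two-sided equal-variance t-test; classes with fewer than two
    samples are untestable (NaN statistics).
    """
    genes = list(gene_list) if gene_list is not None else sorted(
        set(gene_states["gene"]) & set(expression.index)
    )
    rows = []
    for gene in genes:
        st = gene_states[gene_states["gene"] == gene].set_index("sample_id")
        shared = [s for s in expression.columns if s in st.index]
        if not shared:
            continue
        ratio = st.loc[shared, "log2_vs_ploidy"].astype(float)
        expr = expression.loc[gene, shared].astype(float)
        stringent = ratio.abs() <= normal_window
        if stringent.sum() == 0:
            rows.append({"gene": gene, "testable": False})
            continue
        ref = expr[stringent].mean()
        fc = expr - ref
        state = pd.Series("normal", index=ratio.index)
        state[ratio > high_threshold] = "high_gain"
        state[ratio < -high_threshold] = "high_loss"
        row = {"gene": gene, "testable": True,
               "mean_fc_normal": fc[state == "normal"].mean()}
        for which in ("high_gain", "high_loss"):
            grp = fc[state == which]
            norm = fc[state == "normal"]
            row[f"n_{which}"] = len(grp)
            row[f"mean_fc_{which}"] = grp.mean() if len(grp) else np.nan
            if len(grp) >= 2 and len(norm) >= 2:
                if grp.var(ddof=1) == 0 and norm.var(ddof=1) == 0:
                    # degenerate pooled variance: equal means -> no evidence
                    diff = grp.mean() - norm.mean()
                    t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
                    p = 1.0 if diff == 0 else 0.0
                else:
                    t, p = stats.ttest_ind(grp, norm, equal_var=True)
                row[f"t_{which}"], row[f"p_{which}"] = float(t), float(p)
            else:
                row[f"t_{which}"], row[f"p_{which}"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)
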