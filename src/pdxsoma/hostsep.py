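"""Read preprocessing and k-mer based host/graft read classification.

Sequencing reads from a xenografted tumor are a mixture of graft (human
tumor) and host (mouse stroma) molecules.  Before variant calling, reads are
quality-trimmed and then assigned to the graft or host genome by exact
k-mer membership: every canonical k-mer of the two reference sequence sets
is placed into one of three disjoint partitions (graft-only, host-only,
shared), and each read is classified from the partitions its k-mers hit.
Only read pairs in which *both* mates classify as human are carried into
variant calling; retention statistics feed sample-level QC gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "KmerIndex",
    "ReadClassification",
    "PreprocessReport",
    "preprocess_reads",
    "sample_read_gate",
    "build_kmer_index",
    "classify_read",
    "filter_read_pairs",
    "coverage_gate",
    "canonical_kmer",
    "reverse_complement",
]

CATEGORIES = ("human", "mouse", "both", "neither", "ambiguous")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _iter_kmers(seq: str, k: int) -> Iterator[str]:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= {"A", "C", "G", "T"}:
            yield canonical_kmer(kmer)


@dataclass
class KmerIndex:
    """Disjoint canonical k-mer partitions of the graft and host references."""

    k: int
    graft_only: frozenset
    host_only: frozenset
    shared: frozenset

    def __post_init__(self) -> None:
        if self.graft_only & self.host_only or self.graft_only & self.shared or self.host_only & self.shared:
            raise ValueError("k-mer partitions must be pairwise disjoint")


@dataclass
class ReadClassification:
    """Per-read outcome: category plus k-mer hit counts per partition."""

    category: str
    n_graft: int
    n_host: int
    n_shared: int
    n_unmatched: int


@dataclass
class PreprocessReport:
    """Accounting of read dispositions through quality preprocessing."""

    reads_in: int = 0
    reads_out: int = 0
    dispositions: dict = field(
        default_factory=lambda: {
            "kept": 0,
            "discarded_quality": 0,
            "discarded_short": 0,
            "discarded_mate": 0,
        }
    )


def _preprocess_single(quals: Sequence[int], quality_threshold: int, fraction_threshold: float):
    """Return (kept_length or None, reason) for one read's quality vector.

    Discards when the fraction of sub-threshold bases is >= fraction_threshold
    (boundary inclusive on the bad fraction), otherwise trims the maximal
    trailing run of sub-threshold bases and discards when strictly less than
    fraction_threshold of the original length survives.
    """
    q = np.asarray(quals)
    n = len(q)
    if n == 0:
        return None, "discarded_short"
    bad = q < quality_threshold
    if bad.mean() >= fraction_threshold:
        return None, "discarded_quality"
    keep = n
    while keep > 0 and bad[keep - 1]:
        keep -= 1
    if keep < fraction_threshold * n:
        return None, "discarded_short"
    return keep, "kept"


def preprocess_reads(
    read_pairs: Iterable[tuple],
    quality_threshold: int = 30,
    fraction_threshold: float = 0.70,
):
    """Quality-trim paired reads and drop failing pairs.

    Parameters
    ----------
    read_pairs:
        Iterable of ``(mate1, mate2)`` where each mate is a Biopython
        ``SeqRecord`` with ``letter_annotations["phred_quality"]``.
    quality_threshold:
        Phred score below which a base counts as low quality (default Q30).
    fraction_threshold:
        Fraction (default 0.70) governing both the bad-base discard rule and
        the minimum surviving length after 3' trimming.

    Returns
    -------
    (kept_pairs, report):
        Trimmed pairs in input order plus a :class:`PreprocessReport` whose
        dispositions partition ``reads_in``.  A pair is discarded whenever
        either mate is discarded; the surviving mate is tallied as
        ``discarded_mate``.
    """
    report = PreprocessReport()
    kept_pairs = []
    for r1, r2 in read_pairs:
        results = []
        for rec in (r1, r2):
            quals = rec.letter_annotations["phred_quality"]
            results.append(_preprocess_single(quals, quality_threshold, fraction_threshold))
        report.reads_in += 2
        reasons = [r for _, r in results]
        if all(r == "kept" for r in reasons):
            trimmed = []
            for rec, (keep, _) in zip((r1, r2), results):
                trimmed.append(rec[:keep])
            kept_pairs.append(tuple(trimmed))
            report.reads_out += 2
            report.dispositions["kept"] += 2
        else:
            for reason in reasons:
                if reason == "kept":
                    report.dispositions["discarded_mate"] += 1
                else:
                    report.dispositions[reason] += 1
    return kept_pairs, report


def sample_read_gate(report: PreprocessReport, min_fraction: float = 0.50) -> bool:
    """Sample-level retention gate: True (pass) unless the retained read
    fraction is strictly below ``min_fraction``."""
    if report.reads_in == 0:
        raise ValueError("preprocess report has zero input reads")
    return report.reads_out / report.reads_in >= min_fraction


def _collect_kmers(reference: Mapping[str, str] | Iterable[tuple], k: int) -> set:
    items = reference.items() if hasattr(reference, "items") else reference
    kmers: set = set()
    for _, seq in items:
        kmers.update(_iter_kmers(str(seq), k))
    return kmers


def build_kmer_index(graft_reference, host_reference, k: int = 25) -> KmerIndex:
    """Partition canonical k-mers of two references into graft-only /
    host-only / shared sets.

    References are mappings (or iterables of pairs) from sequence id to
    sequence.  k-mers containing non-ACGT symbols are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    graft = _collect_kmers(graft_reference, k)
    host = _collect_kmers(host_reference, k)
    return KmerIndex(
        k=k,
        graft_only=frozenset(graft - host),
        host_only=frozenset(host - graft),
        shared=frozenset(graft & host),
    )


def classify_read(read: str, index: KmerIndex) -> ReadClassification:
    """Classify one read from its canonical k-mer hits.

    graft-only hits without host-only hits -> human; the converse -> mouse;
    only shared hits -> both; graft-only and host-only hits together ->
    ambiguous; no hits at all (including reads shorter than k) -> neither.
    """
    g = h = s = n = 0
    if len(read) >= index.k:
        for kmer in _iter_kmers(str(read), index.k):
            if kmer in index.graft_only:
                g += 1
            elif kmer in index.host_only:
                h += 1
            elif kmer in index.shared:
                s += 1
            else:
                n += 1
    if g > 0 and h > 0:
        category = "ambiguous"
    elif g > 0:
        category = "human"
    elif h > 0:
        category = "mouse"
    elif s > 0:
        category = "both"
    else:
        category = "neither"
    return ReadClassification(category, g, h, s, n)


def filter_read_pairs(read_pairs: Iterable[tuple], index: KmerIndex):
    """Keep only pairs with both mates classified human.

    Returns ``(kept_pairs, counts)`` where counts maps each category to its
    read (not pair) count and carries ``fraction_mouse`` = mouse-classified
    reads / total classified reads.
    """
    counts = {c: 0 for c in CATEGORIES}
    kept = []
    total = 0
    for r1, r2 in read_pairs:
        cats = []
        for rec in (r1, r2):
            seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
            cats.append(classify_read(seq, index).category)
        for c in cats:
            counts[c] += 1
            total += 1
        if cats == ["human", "human"]:
            kept.append((r1, r2))
    counts["fraction_mouse"] = counts["mouse"] / total if total else 0.0
    return kept, counts


def coverage_gate(
    per_base_depth: Sequence[float],
    min_depth: int = 100,
    min_fraction: float = 0.75,
) -> bool:
    """Target-coverage gate: True (pass) unless the fraction of target bases
    with depth >= ``min_depth`` is strictly below ``min_fraction``."""
    depth = np.asarray(per_base_depth)
    if depth.size == 0:
        raise ValueError("empty target region")
    return float((depth >= min_depth).mean()) >= min_fraction
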