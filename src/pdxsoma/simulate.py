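"""Seeded synthetic-data generators for every pipeline input.

Emulates, with planted truth labels, the data a xenograft genomics pipeline
consumes: a graft ("human") reference and a diverged host ("mouse")
reference, paired-end reads with host contamination at a configurable
fraction of coverage, per-sample variant-call tables with spiked germline /
somatic / systematic-artifact loci, negative-binomial expression cohorts
with a planted lymphoma signature, and segmented aneuploid allele-specific
copy-number profiles.  Every generator is deterministic in the seed: each
draws from its own RNG stream (seed plus a fixed per-generator offset), so
adding one generator call never perturbs another's output.

Defaults mirror the simulated benchmarking conditions of the targeted-panel
workflow: coverage grid {500, 1000, 1500} (default 1000), host contamination
grid {0.10, 0.15, 0.25} (default 0.15), 150 bp paired-end reads, graft/host
divergence 0.15 (mouse and human protein-coding sequence is ~85% identical),
heterozygous/homozygous germline allele fractions {0.5, 1.0}, and artifact
loci recurring in 30% of a 20-sample cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import cna
from .expression import Signature
from .somatic import VARIANT_COLUMNS, GermlineResource

__all__ = [
    "SimConfig",
    "VariantCohort",
    "ExpressionCohort",
    "CNCohort",
    "gen_reference_pair",
    "gen_read_set",
    "gen_variant_cohort",
    "gen_expression_cohort",
    "gen_cn_profiles",
]

# fixed per-generator RNG stream offsets
_REFS, _READS, _VARIANTS, _EXPR, _CN = 11, 22, 33, 44, 55

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    ref_length: int = 10_000
    divergence: float = 0.15
    coverage: float = 1000.0
    contamination_fraction: float = 0.15
    read_length: int = 150
    base_error_rate: float = 0.001
    low_quality_read_fraction: float = 0.05
    n_samples: int = 20
    germline_af_set: tuple = (0.5, 1.0)
    somatic_af_range: tuple = (0.05, 1.0)
    fp_recurrence: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence must be in [0, 1], got {self.divergence}")
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError(
                f"contamination_fraction must be in [0, 1), got {self.contamination_fraction}"
            )
        if self.coverage <= 0:
            raise ValueError(f"coverage must be > 0, got {self.coverage}")
        lo, hi = self.somatic_af_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"somatic_af_range must lie in (0, 1], got {self.somatic_af_range}")
        for af in self.germline_af_set:
            if not 0.0 < af <= 1.0:
                raise ValueError(f"germline allele fractions must be in (0, 1], got {af}")

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(offset)])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_bases(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def gen_reference_pair(config: SimConfig):
    """Generate a graft reference and a host reference diverged from it by
    i.i.d. substitutions at rate ``config.divergence``.

    Returns ``(graft, host)`` as ordered mappings of contig id to sequence.
    """
    if config.ref_length < 10 * config.read_length:
        raise ValueError(
            f"ref_length {config.ref_length} must be >= 10 x read_length {config.read_length}"
        )
    rng = config.rng(_REFS)
    graft_seq = _random_seq(rng, config.ref_length)
    host_seq = _mutate_bases(rng, graft_seq, config.divergence)
    return {"graft_1": graft_seq}, {"host_1": host_seq}


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def gen_read_set(config: SimConfig, graft_reference, host_reference):
    """Simulate paired-end reads with host contamination.

    Pair count = coverage * ref_length / (2 * read_length); each pair is
    drawn from the host reference with probability
    ``config.contamination_fraction``.  Base-call errors are i.i.d.
    substitutions at ``base_error_rate``; a ``low_quality_read_fraction`` of
    reads receive a low-quality (Q2) 3' tail so the preprocessing rules are
    exercisable, all other bases are Q37.

    Returns ``(pairs, origins)`` where pairs are Biopython SeqRecord tuples
    with phred qualities and origins is a list of "graft"/"host" per pair.
    """
    rng = config.rng(_READS)
    graft_seqs = list(graft_reference.values())
    host_seqs = list(host_reference.values())
    rl = config.read_length
    total_bases = sum(len(s) for s in graft_seqs)
    n_pairs = int(config.coverage * total_bases / (2 * rl))
    if n_pairs == 0:
        raise ValueError("coverage too low: zero read pairs would be generated")
    insert = min(2 * rl + 50, min(len(s) for s in graft_seqs + host_seqs))
    pairs, origins = [], []
    for i in range(n_pairs):
        from_host = rng.random() < config.contamination_fraction
        seqs = host_seqs if from_host else graft_seqs
        src = seqs[rng.integers(len(seqs))]
        start = int(rng.integers(0, len(src) - insert + 1))
        frag = src[start : start + insert]
        r1 = frag[:rl]
        r2 = frag[-rl:].translate(_COMPLEMENT)[::-1]
        recs = []
        for mate, seq in enumerate((r1, r2), start=1):
            seq = _mutate_bases(rng, seq, config.base_error_rate)
            quals = [37] * len(seq)
            if rng.random() < config.low_quality_read_fraction:
                tail = int(len(seq) * rng.uniform(0.1, 0.5))
                if tail:
                    quals[-tail:] = [2] * tail
            rec = SeqRecord(Seq(seq), id=f"read_{i}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = quals
            recs.append(rec)
        pairs.append(tuple(recs))
        origins.append("host" if from_host else "graft")
    return pairs, origins


@dataclass
class VariantCohort:
    """Synthetic per-sample variant tables with planted truth labels."""

    calls: pd.DataFrame          # cohort variant table (VARIANT_COLUMNS)
    truth: pd.DataFrame          # sample_id chrom pos ref alt true_af label
    resource: GermlineResource   # synthetic aggregated germline resource
    panel_genes: list


def _clean_annotations(rng: np.random.Generator) -> dict:
    return {
        "QD": float(rng.uniform(10.0, 30.0)),
        "FS": float(rng.uniform(0.0, 10.0)),
        "MQ": float(rng.uniform(50.0, 60.0)),
        "MQRankSum": float(rng.uniform(-2.0, 2.0)),
        "ReadPosRankSum": float(rng.uniform(-2.0, 2.0)),
    }


def _failing_annotations(rng: np.random.Generator, vtype: str) -> dict:
    ann = _clean_annotations(rng)
    if vtype == "snv":
        failures = {
            "QD": lambda: float(rng.uniform(0.0, 1.9)),
            "FS": lambda: float(rng.uniform(61.0, 120.0)),
            "MQ": lambda: float(rng.uniform(10.0, 39.0)),
            "MQRankSum": lambda: float(rng.uniform(-20.0, -13.0)),
            "ReadPosRankSum": lambda: float(rng.uniform(-15.0, -8.5)),
        }
    else:
        failures = {
            "QD": lambda: float(rng.uniform(0.0, 1.9)),
            "FS": lambda: float(rng.uniform(201.0, 300.0)),
            "ReadPosRankSum": lambda: float(rng.uniform(-30.0, -20.5)),
        }
    which = rng.choice(sorted(failures))
    ann[which] = failures[which]()
    return ann


def gen_variant_cohort(
    config: SimConfig,
    n_germline_loci: int = 60,
    germline_carrier_prob: float = 0.5,
    n_somatic_per_sample: int = 20,
    n_artifact_loci: int = 5,
    depth: Optional[float] = None,
    quality_fail_fraction: float = 0.0,
    indel_fraction: float = 0.1,
    pindel_fraction: float = 0.0,
    n_panel_genes: int = 50,
) -> VariantCohort:
    """Generate per-sample variant-call tables with planted truth.

    Germline loci are drawn once for the cohort, entered into the synthetic
    germline resource, and carried by each sample with probability
    ``germline_carrier_prob`` at a true allele fraction from
    ``config.germline_af_set``.  Somatic loci are private per sample with
    true AF uniform in ``config.somatic_af_range``.  Artifact loci emulate
    systematic errors: each is planted, at mid-range AF and absent from the
    germline resource, in ``ceil(fp_recurrence * n_samples)`` samples.
    Observed AF at a locus is binomially resampled around the true AF at a
    Poisson-distributed depth (mean ``depth``, default ``config.coverage``);
    loci whose resampled alternate-read count is zero are not called (they
    stay in the truth table as reachable false negatives).  Caller quality
    annotations come from a clean regime, or from a failing regime for a
    ``quality_fail_fraction`` of calls.
    """
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    depth = depth if depth is not None else config.coverage
    rng = config.rng(_VARIANTS)
    panel_genes = [f"GENE{i:03d}" for i in range(1, n_panel_genes + 1)]
    samples = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]

    n_loci = n_germline_loci + n_artifact_loci + config.n_samples * n_somatic_per_sample
    if n_loci > config.ref_length:
        raise ValueError("more loci requested than reference positions")
    positions = rng.choice(np.arange(1, config.ref_length + 1), size=n_loci, replace=False)
    positions = [int(p) for p in positions]

    def _alleles(vtype: str):
        ref = str(rng.choice(_BASES))
        if vtype == "snv":
            alt = str(rng.choice(_BASES[_BASES != ref]))
        else:
            alt = ref + str(rng.choice(_BASES))
        return ref, alt

    def _locus(pos: int, label: str) -> dict:
        vtype = "indel" if rng.random() < indel_fraction else "snv"
        ref, alt = _alleles(vtype)
        caller = "pindel" if (vtype == "indel" and rng.random() < pindel_fraction) else "gatk"
        effect_p = 0.8 if label == "somatic" else 0.5
        effect = "non_silent_coding" if rng.random() < effect_p else "silent"
        return {
            "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt, "vtype": vtype,
            "caller": caller, "effect": effect,
            "gene": panel_genes[int(rng.integers(len(panel_genes)))],
        }

    cursor = iter(positions)
    germline_loci = [_locus(next(cursor), "germline") for _ in range(n_germline_loci)]
    artifact_loci = [_locus(next(cursor), "artifact") for _ in range(n_artifact_loci)]

    resource = GermlineResource()
    for loc in germline_loci:
        key = (loc["chrom"], loc["pos"], loc["ref"], loc["alt"])
        source = str(rng.choice(["dbsnp", "kg1000", "exac"]))
        maf = float(rng.uniform(0.01, 0.5)) if source == "exac" else None
        resource.add(key, source, maf)

    call_rows, truth_rows = [], []

    def _emit(sample: str, loc: dict, true_af: float, label: str) -> None:
        truth_rows.append({
            "sample_id": sample, "chrom": loc["chrom"], "pos": loc["pos"],
            "ref": loc["ref"], "alt": loc["alt"], "true_af": true_af, "label": label,
        })
        dp = max(int(rng.poisson(depth)), 1)
        alt_count = int(rng.binomial(dp, true_af))
        if alt_count == 0:
            return  # a caller would not report this locus: a true false negative
        if quality_fail_fraction > 0 and rng.random() < quality_fail_fraction:
            ann = _failing_annotations(rng, loc["vtype"])
        else:
            ann = _clean_annotations(rng)
        if loc["vtype"] == "indel":
            ann.pop("MQ", None)
            ann.pop("MQRankSum", None)
            ann = {k: ann.get(k) for k in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")}
        call_rows.append({
            "sample_id": sample, **{k: loc[k] for k in
                                    ("chrom", "pos", "ref", "alt", "vtype", "caller",
                                     "effect", "gene")},
            "DP": dp, "ALT_AF": alt_count / dp,
            "QD": ann.get("QD"), "FS": ann.get("FS"), "MQ": ann.get("MQ"),
            "MQRankSum": ann.get("MQRankSum"), "ReadPosRankSum": ann.get("ReadPosRankSum"),
            "protein_change": "",
        })

    for sample in samples:
        for loc in germline_loci:
            if rng.random() < germline_carrier_prob:
                af = float(rng.choice(np.array(config.germline_af_set)))
                _emit(sample, loc, af, "germline")
        lo, hi = config.somatic_af_range
        for _ in range(n_somatic_per_sample):
            loc = _locus(next(cursor), "somatic")
            _emit(sample, loc, float(rng.uniform(lo, hi)), "somatic")

    n_carriers = min(math.ceil(config.fp_recurrence * config.n_samples), config.n_samples)
    for loc in artifact_loci:
        carriers = rng.choice(samples, size=n_carriers, replace=False)
        for sample in sorted(carriers):
            _emit(sample, loc, float(rng.uniform(0.15, 0.35)), "artifact")

    calls = pd.DataFrame(call_rows, columns=VARIANT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "true_af", "label"]
    )
    dup = truth.duplicated(["sample_id", "chrom", "pos", "alt"])
    assert not dup.any(), "planted loci must be unique per sample"
    return VariantCohort(calls=calls, truth=truth, resource=resource,
                         panel_genes=panel_genes)


@dataclass
class ExpressionCohort:
    """Negative-binomial counts with a planted two-sided signature."""

    counts: pd.DataFrame     # genes x samples
    labels: pd.Series        # True for EBV samples
    signature: Signature     # planted (gene, sign) table


def gen_expression_cohort(
    n_ebv: int = 20,
    n_other: int = 100,
    signature_size: int = 48,
    effect: float = 2.0,
    n_genes: int = 2000,
    seed: int = 0,
    nb_size: float = 10.0,
) -> ExpressionCohort:
    """Generate a labelled expression cohort with a planted signature.

    Counts are negative binomial around per-gene lognormal means with
    per-sample library-size variation.  Half the signature genes are
    shifted up by ``effect`` (log2 scale) in EBV samples, half down; all
    other genes are exchangeable between groups.
    """
    if effect <= 0:
        raise ValueError(f"effect must be > 0, got {effect}")
    if n_ebv < 2 or n_other < 2:
        raise ValueError("need at least 2 samples per group")
    if signature_size % 2:
        raise ValueError(f"signature_size must be even, got {signature_size}")
    if signature_size > n_genes:
        raise ValueError("signature larger than gene count")
    rng = np.random.default_rng([int(seed), _EXPR])
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"EBV{i:03d}" for i in range(1, n_ebv + 1)] + [
        f"T{i:03d}" for i in range(1, n_other + 1)
    ]
    labels = pd.Series([True] * n_ebv + [False] * n_other, index=samples)

    mu = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    mu = np.clip(mu, 5.0, None)
    half = signature_size // 2
    sig_idx = rng.choice(n_genes, size=signature_size, replace=False)
    up_idx, down_idx = sig_idx[:half], sig_idx[half:]

    lib = rng.lognormal(mean=0.0, sigma=0.2, size=len(samples))
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        m = mu.copy()
        if labels[sample]:
            m[up_idx] *= 2.0 ** effect
            m[down_idx] /= 2.0 ** effect
        m = m * lib[j]
        p = nb_size / (nb_size + m)
        counts[:, j] = rng.negative_binomial(nb_size, p)

    planted = pd.DataFrame({
        "gene": [genes[i] for i in up_idx] + [genes[i] for i in down_idx],
        "sign": [1] * half + [-1] * half,
    })
    return ExpressionCohort(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        labels=labels,
        signature=Signature(planted),
    )


@dataclass
class CNCohort:
    """Synthetic segmented allele-specific copy-number profiles."""

    segments: pd.DataFrame    # sample_id chrom start end nMajor nMinor
    ploidy: pd.DataFrame      # sample_id ploidy
    genes: pd.DataFrame       # gene chrom start end
    expression: Optional[pd.DataFrame] = None  # log2(TPM+1), genes x samples
    gene_base: Optional[pd.Series] = None      # per-gene baseline expression

    def profile(self, sample_id: str) -> cna.SampleCNProfile:
        segs = self.segments[self.segments["sample_id"] == sample_id]
        ploidy = float(self.ploidy.set_index("sample_id").loc[sample_id, "ploidy"])
        return cna.SampleCNProfile(
            sample_id=sample_id,
            segments=[cna.CNSegment(r.chrom, int(r.start), int(r.end),
                                    float(r.nMajor), float(r.nMinor))
                      for r in segs.itertuples(index=False)],
            ploidy=ploidy,
        )


def gen_cn_profiles(
    n_samples: int = 5,
    genes: Optional[pd.DataFrame] = None,
    seed: int = 0,
    n_chrom: int = 4,
    chrom_length: int = 10_000_000,
    n_genes: int = 60,
    coupled: bool = False,
    noise_sd: float = 0.1,
) -> CNCohort:
    """Generate aneuploid segment profiles (and optionally coupled expression).

    Segments tile each chromosome without gaps or overlaps; total copy
    number per segment is drawn from a distribution spanning deletion to
    amplification, split into major/minor alleles; sample ploidy is the
    length-weighted mean total CN.  In ``coupled`` mode every gene's
    log2(TPM + 1) is its per-gene baseline plus log2(CN / ploidy) plus
    Gaussian noise (``noise_sd``), and zero-copy segments are not drawn.
    """
    rng = np.random.default_rng([int(seed), _CN])
    chroms = [f"chr{i}" for i in range(1, n_chrom + 1)]
    if genes is None:
        rows = []
        for i in range(1, n_genes + 1):
            chrom = chroms[int(rng.integers(n_chrom))]
            start = int(rng.integers(1, chrom_length - 300_000))
            rows.append({"gene": f"CNG{i:03d}", "chrom": chrom,
                         "start": start, "end": start + int(rng.integers(5_000, 300_000))})
        genes = pd.DataFrame(rows)
    else:
        required = {"gene", "chrom", "start", "end"}
        if not required <= set(genes.columns):
            raise ValueError(f"gene models need columns {sorted(required)}")

    totals = np.array([0, 1, 2, 3, 4, 5, 6])
    weights = np.array([0.02, 0.13, 0.40, 0.20, 0.15, 0.06, 0.04])
    if coupled:
        totals, weights = totals[1:], weights[1:]
    weights = weights / weights.sum()

    seg_rows, ploidy_rows = [], []
    samples = [f"P{i:03d}" for i in range(1, n_samples + 1)]
    for sample in samples:
        length_sum = 0.0
        cn_sum = 0.0
        for chrom in chroms:
            n_seg = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(2, chrom_length), size=n_seg - 1,
                                      replace=False)) if n_seg > 1 else np.array([], dtype=int)
            bounds = [1, *[int(c) for c in cuts], chrom_length + 1]
            for a, b in zip(bounds[:-1], bounds[1:]):
                start, end = a, b - 1
                total = int(rng.choice(totals, p=weights))
                minor = int(rng.integers(0, total // 2 + 1)) if total else 0
                seg_rows.append({"sample_id": sample, "chrom": chrom, "start": start,
                                 "end": end, "nMajor": total - minor, "nMinor": minor})
                length_sum += end - start + 1
                cn_sum += total * (end - start + 1)
        ploidy_rows.append({"sample_id": sample, "ploidy": cn_sum / length_sum})

    cohort = CNCohort(
        segments=pd.DataFrame(seg_rows),
        ploidy=pd.DataFrame(ploidy_rows),
        genes=genes.reset_index(drop=True),
    )
    if coupled:
        gene_base = pd.Series(rng.uniform(3.0, 8.0, size=len(genes)),
                              index=genes["gene"].values)
        expr = {}
        for sample in samples:
            prof = cohort.profile(sample)
            ann = cna.annotate_sample(prof, genes, baseline="ploidy")
            ratio = ann.set_index("gene")["log2_vs_ploidy"].astype(float)
            noise = rng.normal(0.0, noise_sd, size=len(ratio)) if noise_sd else 0.0
            expr[sample] = gene_base.loc[ratio.index] + ratio + noise
        cohort.expression = pd.DataFrame(expr)
        cohort.gene_base = gene_base
    return cohort
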