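"""Tumor-only somatic variant filtering with germline subtraction, recurrent
false-positive removal, and clinical rescue.

Without a patient-matched normal sample, somatic calls must be cleaned by
post-hoc filters: GATK-style hard filters plus depth/allele-fraction floors,
subtraction of known germline variants (public databases plus a compendium of
normal samples) at heterozygous/homozygous allele fractions, removal of
positions recurrently mutated across an implausible fraction of unrelated
models (systematic sequencing/alignment artifacts), and finally a "rescue"
that reinstates filtered variants curated as clinically actionable.  Every
variant carries an auditable trace of each filter's outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "VariantCall",
    "FilterThresholds",
    "PipelineConfig",
    "GermlineResource",
    "ClinicalKB",
    "FilterTrace",
    "RecurrenceTable",
    "apply_quality_filters",
    "build_germline_resource",
    "flag_germline",
    "compute_recurrence",
    "flag_recurrent_fp",
    "rescue_clinical",
    "run_somatic_pipeline",
    "FINAL_STATUSES",
]

FINAL_STATUSES = (
    "somatic_pass",
    "filtered_germline",
    "filtered_fp",
    "filtered_quality",
    "filtered_pindel_no_kb",
    "rescued_clinical",
)

#: columns of a cohort variant table
VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "vtype", "caller",
    "DP", "ALT_AF", "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum",
    "effect", "gene", "protein_change",
]


@dataclass
class VariantCall:
    """One called variant with caller annotations.

    Quality annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum) may be
    ``None``/NaN; per GATK filter-expression semantics a missing annotation
    never fails a hard filter.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str = "snv"            # snv | indel
    caller: str = "gatk"          # gatk | pindel
    DP: int = 0
    ALT_AF: float = 0.0
    QD: Optional[float] = None
    FS: Optional[float] = None
    MQ: Optional[float] = None
    MQRankSum: Optional[float] = None
    ReadPosRankSum: Optional[float] = None
    effect: str = "noncoding"     # non_silent_coding | silent | noncoding
    gene: str = ""
    protein_change: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.ALT_AF <= 1.0:
            raise ValueError(f"ALT_AF must be in [0, 1], got {self.ALT_AF}")
        if self.DP < 0:
            raise ValueError(f"DP must be >= 0, got {self.DP}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self):
        return (self.chrom, int(self.pos), self.ref, self.alt)


def variant_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Build a cohort variant table from VariantCall records."""
    rows = [{f.name: getattr(c, f.name) for f in fields(VariantCall)} for c in calls]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@dataclass
class FilterThresholds:
    """Hard-filter and depth/AF thresholds (defaults: targeted-panel values)."""

    min_dp: int = 140
    min_af: float = 0.05
    snv_hard: Mapping[str, tuple] = field(default_factory=lambda: {
        "QD": ("<", 2.0), "FS": (">", 60.0), "MQ": ("<", 40.0),
        "MQRankSum": ("<", -12.5), "ReadPosRankSum": ("<", -8.0),
    })
    indel_hard: Mapping[str, tuple] = field(default_factory=lambda: {
        "QD": ("<", 2.0), "FS": (">", 200.0), "ReadPosRankSum": ("<", -20.0),
    })


@dataclass
class PipelineConfig:
    """Switches and thresholds for the full filter-and-rescue pipeline."""

    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    germline_af_window: tuple = (0.40, 0.60)
    germline_af_high: float = 0.90
    recurrence_threshold: float = 0.25
    min_recurrent_samples: int = 2
    enable_germline_filter: bool = True
    enable_fp_filter: bool = True
    enable_rescue: bool = True
    # hard-filter failures are never reinstated by rescue
    rescue_quality_failed: bool = False


def _value(v, name):
    if isinstance(v, Mapping):
        x = v.get(name)
    else:
        x = getattr(v, name, None)
    if x is None:
        return None
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def apply_quality_filters(v, thresholds: FilterThresholds | None = None) -> str:
    """Quality status of one variant: ``fail_hard`` when any applicable
    hard-filter inequality fires, else ``fail_depth`` (DP below floor), else
    ``fail_af`` (allele fraction below floor), else ``pass``.

    Missing annotations never fire a hard filter.
    """
    thresholds = thresholds or FilterThresholds()
    vtype = _value(v, "vtype")
    if vtype == "snv":
        hard = thresholds.snv_hard
    elif vtype == "indel":
        hard = thresholds.indel_hard
    else:
        raise ValueError(f"unknown variant type: {vtype!r}")
    for name, (op, cut) in hard.items():
        x = _value(v, name)
        if x is None:
            continue
        if (op == "<" and x < cut) or (op == ">" and x > cut):
            return "fail_hard"
    if _value(v, "DP") < thresholds.min_dp:
        return "fail_depth"
    if _value(v, "ALT_AF") < thresholds.min_af:
        return "fail_af"
    return "pass"


class GermlineResource:
    """Aggregated putative germline variants, keyed by (chrom, pos, ref, alt).

    Combines public sources (dbSNP / 1000 Genomes / ExAC restricted to
    population MAF >= 1%) with a compendium of variants seen in normal
    samples sequenced on the same panel.
    """

    EXAC_MIN_MAF = 0.01

    def __init__(self) -> None:
        self.entries: dict = {}

    def add(self, key, source: str, maf: Optional[float] = None) -> None:
        key = (str(key[0]), int(key[1]), str(key[2]), str(key[3]))
        if source == "exac" and (maf is None or maf < self.EXAC_MIN_MAF):
            raise ValueError(
                f"exac entries require population MAF >= {self.EXAC_MIN_MAF}: {key}"
            )
        entry = self.entries.setdefault(key, {"sources": set(), "maf": None})
        entry["sources"].add(source)
        if maf is not None:
            entry["maf"] = maf

    def __contains__(self, key) -> bool:
        return (str(key[0]), int(key[1]), str(key[2]), str(key[3])) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "pos": p, "ref": r, "alt": a,
             "sources": ",".join(sorted(e["sources"])), "maf": e["maf"]}
            for (c, p, r, a), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sources", "maf"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GermlineResource":
        res = cls()
        for row in df.itertuples(index=False):
            maf = getattr(row, "maf", None)
            if maf is not None and isinstance(maf, float) and math.isnan(maf):
                maf = None
            for source in str(getattr(row, "sources", "dbsnp")).split(","):
                res.add((row.chrom, row.pos, row.ref, row.alt), source.strip(), maf)
        return res

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GermlineResource":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_germline_resource(
    public_sources: Mapping[str, Iterable],
    normal_samples: Mapping[str, Iterable] | None = None,
    pdx_cohort: Mapping[str, Iterable] | None = None,
    min_normals: int = 2,
    min_normals_with_pdx: int = 1,
    min_pdx: int = 2,
    proportional: bool = False,
    reference_normal_count: int = 20,
    reference_pdx_count: int = 20,
) -> GermlineResource:
    """Aggregate public germline databases with a normal-sample compendium.

    ``public_sources`` maps source name (``dbsnp``/``kg1000``/``exac``) to an
    iterable of ``(chrom, pos, ref, alt)`` keys or ``(key, maf)`` pairs for
    ExAC.  A compendium variant is admitted when seen in >= ``min_normals``
    normal samples, or in >= ``min_normals_with_pdx`` normals AND >=
    ``min_pdx`` tumor-cohort samples.  With ``proportional=True`` the count
    thresholds are rescaled from the reference compendium sizes (20 normals).
    """
    res = GermlineResource()
    for source, entries in public_sources.items():
        for item in entries:
            if source == "exac":
                key, maf = item
                res.add(key, source, maf)
            else:
                res.add(item, source)
    if normal_samples is None:
        return res
    if len(normal_samples) == 0:
        raise ValueError("compendium requested with zero normal samples")
    pdx_cohort = pdx_cohort or {}
    if proportional:
        scale_n = len(normal_samples) / reference_normal_count
        scale_p = max(len(pdx_cohort), 1) / reference_pdx_count
        min_normals = math.ceil(min_normals * scale_n)
        min_normals_with_pdx = math.ceil(min_normals_with_pdx * scale_n)
        min_pdx = math.ceil(min_pdx * scale_p)

    def _count(samples: Mapping[str, Iterable]) -> dict:
        counts: dict = {}
        for _, keys in samples.items():
            for key in set(tuple(k) for k in keys):
                counts[key] = counts.get(key, 0) + 1
        return counts

    n_counts = _count(normal_samples)
    p_counts = _count(pdx_cohort)
    for key, n in n_counts.items():
        if n >= min_normals or (n >= min_normals_with_pdx and p_counts.get(key, 0) >= min_pdx):
            res.add(key, "normal_compendium")
    return res


class ClinicalKB:
    """Clinical knowledgebase of actionable variants.

    Entries are keyed by (gene, protein_change) and/or genomic
    (chrom, pos, ref, alt); each carries at least one relevance tag.
    """

    TAGS = ("gain_or_loss_of_function", "treatment_approach", "drug_sensitivity_resistance")

    def __init__(self) -> None:
        self.site_entries: dict = {}
        self.gene_entries: dict = {}

    def add_site(self, key, tags: Iterable[str]) -> None:
        tags = set(tags)
        if not tags:
            raise ValueError("clinical entries require at least one relevance tag")
        key = (str(key[0]), int(key[1]), str(key[2]), str(key[3]))
        self.site_entries.setdefault(key, set()).update(tags)

    def add_gene_change(self, gene: str, protein_change: str, tags: Iterable[str]) -> None:
        tags = set(tags)
        if not tags:
            raise ValueError("clinical entries require at least one relevance tag")
        self.gene_entries.setdefault((gene, protein_change), set()).update(tags)

    def matches(self, v) -> bool:
        key = (str(_value(v, "chrom")), int(_value(v, "pos")),
               str(_value(v, "ref")), str(_value(v, "alt")))
        if key in self.site_entries:
            return True
        gene = _value(v, "gene") or ""
        change = _value(v, "protein_change") or ""
        return (gene, change) in self.gene_entries

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (c, p, r, a), tags in sorted(self.site_entries.items()):
            rows.append({"gene": "", "protein_change": "", "chrom": c, "pos": p,
                         "ref": r, "alt": a, "tags": ",".join(sorted(tags))})
        for (g, pc), tags in sorted(self.gene_entries.items()):
            rows.append({"gene": g, "protein_change": pc, "chrom": "", "pos": "",
                         "ref": "", "alt": "", "tags": ",".join(sorted(tags))})
        return pd.DataFrame(rows, columns=["gene", "protein_change", "chrom", "pos",
                                           "ref", "alt", "tags"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClinicalKB":
        kb = cls()
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        for row in df.itertuples(index=False):
            tags = [t for t in str(row.tags).split(",") if t]
            if str(row.chrom) and str(row.pos):
                kb.add_site((row.chrom, int(float(row.pos)), row.ref, row.alt), tags)
            else:
                kb.add_gene_change(str(row.gene), str(row.protein_change), tags)
        return kb


@dataclass
class FilterTrace:
    """Auditable per-variant filter outcome."""

    quality_status: str = "pass"
    germline_flag: bool = False
    recurrent_fp_flag: bool = False
    rescued: bool = False
    final: str = "somatic_pass"


@dataclass
class RecurrenceTable:
    """Per-position fraction of cohort samples carrying a non-germline call."""

    fractions: Mapping[tuple, float]
    cohort_size: int


def flag_germline(
    v,
    resource: GermlineResource,
    af_window: tuple = (0.40, 0.60),
    af_high: float = 0.90,
) -> bool:
    """A variant is flagged germline when it is present in the aggregated
    germline resource AND its allele fraction sits in the heterozygous window
    (closed ``af_window``) or strictly above ``af_high`` (homozygous)."""
    key = (_value(v, "chrom"), _value(v, "pos"), _value(v, "ref"), _value(v, "alt"))
    if key not in resource:
        return False
    af = _value(v, "ALT_AF")
    return (af_window[0] <= af <= af_window[1]) or af > af_high


def compute_recurrence(cohort: pd.DataFrame, cohort_size: int | None = None) -> RecurrenceTable:
    """Fraction of cohort samples with >=1 non-germline-flagged variant at
    each (chrom, pos).

    ``cohort`` is a variant table with ``sample_id``, ``chrom``, ``pos`` and a
    boolean ``germline_flag`` column (germline-flagged rows are excluded from
    the numerator but their positions remain in the table's domain).  The
    denominator is ``cohort_size`` when given (a sample may contribute no
    rows yet still count in the cohort), else the number of distinct samples
    in the table.
    """
    if "germline_flag" not in cohort.columns:
        raise ValueError("cohort table must carry a germline_flag column")
    n = cohort_size if cohort_size is not None else cohort["sample_id"].nunique()
    if n == 0:
        raise ValueError("empty cohort")
    non_germ = cohort[~cohort["germline_flag"].astype(bool)]
    counts = non_germ.groupby(["chrom", "pos"])["sample_id"].nunique()
    fractions = {key: 0.0 for key in
                 cohort.groupby(["chrom", "pos"]).groups}
    for key, c in counts.items():
        fractions[key] = c / n
    return RecurrenceTable(fractions=fractions, cohort_size=n)


def flag_recurrent_fp(
    v,
    table: RecurrenceTable,
    threshold: float = 0.25,
    germline_flag: bool = False,
    min_recurrent_samples: int = 2,
) -> bool:
    """Systematic false-positive flag: fires when the variant is not
    germline-flagged and its position recurs in >= ``threshold`` of the
    cohort.  The position must be present in the recurrence table.

    Recurrence additionally requires at least ``min_recurrent_samples``
    carrier samples: in a very small cohort any private variant trivially
    reaches the fraction threshold (in a single-sample cohort every variant
    recurs at 100%), and a position seen once is not recurrent.
    """
    key = (_value(v, "chrom"), _value(v, "pos"))
    if key not in table.fractions:
        raise KeyError(f"position {key} absent from recurrence table")
    if germline_flag:
        return False
    fraction = table.fractions[key]
    n_carriers = round(fraction * table.cohort_size)
    return fraction >= threshold and n_carriers >= min_recurrent_samples


def rescue_clinical(trace: FilterTrace, v, kb: ClinicalKB) -> FilterTrace:
    """Apply clinical rescue to one quality-passing variant's trace.

    GATK variants filtered as germline or recurrent-FP are reinstated on a
    knowledgebase hit; Pindel variants are retained only on a knowledgebase
    hit (otherwise dropped as ``filtered_pindel_no_kb``).
    """
    if trace.quality_status != "pass":
        return trace
    hit = kb.matches(v)
    caller = _value(v, "caller")
    if caller == "pindel":
        if not hit:
            trace.final = "filtered_pindel_no_kb"
            trace.rescued = False
        elif trace.final in ("filtered_germline", "filtered_fp"):
            trace.final = "rescued_clinical"
            trace.rescued = True
    elif hit and trace.final in ("filtered_germline", "filtered_fp"):
        trace.final = "rescued_clinical"
        trace.rescued = True
    return trace


@dataclass
class PipelineResult:
    """Output of the full filter-and-rescue pipeline."""

    calls: pd.DataFrame            # input columns + trace columns
    recurrence: RecurrenceTable
    summary: pd.DataFrame          # per-sample counts by final status

    def sample_calls(self, sample_id: str) -> pd.DataFrame:
        return self.calls[self.calls["sample_id"] == sample_id]

    def passing(self) -> pd.DataFrame:
        """Variants emitted as somatic (passing or clinically rescued)."""
        return self.calls[self.calls["final"].isin(["somatic_pass", "rescued_clinical"])]


def run_somatic_pipeline(
    calls: pd.DataFrame,
    resource: GermlineResource,
    kb: ClinicalKB | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run quality -> germline -> recurrence -> rescue over a cohort table.

    ``calls`` holds the whole cohort (the recurrence filter is defined across
    samples); per-sample outputs are slices of the result.  The returned
    table is row-aligned with the input regardless of input order.
    """
    config = config or PipelineConfig()
    kb = kb or ClinicalKB()
    df = calls.copy()
    if df.empty:
        raise ValueError("empty cohort variant table")

    df["quality_status"] = [
        apply_quality_filters(row, config.thresholds)
        for row in df.to_dict("records")
    ]
    qpass = df["quality_status"] == "pass"

    if config.enable_germline_filter:
        df["germline_flag"] = [
            flag_germline(row, resource, config.germline_af_window, config.germline_af_high)
            for row in df.to_dict("records")
        ]
    else:
        df["germline_flag"] = False

    # recurrence over quality-passing calls, germline occurrences excluded
    n_cohort = df["sample_id"].nunique()
    rec_input = df.loc[qpass, ["sample_id", "chrom", "pos", "germline_flag"]]
    if rec_input.empty:
        recurrence = RecurrenceTable(fractions={}, cohort_size=n_cohort)
    else:
        recurrence = compute_recurrence(rec_input, cohort_size=n_cohort)
    if config.enable_fp_filter:
        df["recurrent_fp_flag"] = [
            (row["quality_status"] == "pass")
            and flag_recurrent_fp(row, recurrence, config.recurrence_threshold,
                                  germline_flag=row["germline_flag"],
                                  min_recurrent_samples=config.min_recurrent_samples)
            for row in df.to_dict("records")
        ]
    else:
        df["recurrent_fp_flag"] = False

    finals = []
    rescued_col = []
    for row in df.to_dict("records"):
        trace = FilterTrace(quality_status=row["quality_status"],
                            germline_flag=row["germline_flag"],
                            recurrent_fp_flag=row["recurrent_fp_flag"])
        if trace.quality_status != "pass":
            trace.final = "filtered_quality"
        elif trace.germline_flag:
            trace.final = "filtered_germline"
        elif trace.recurrent_fp_flag:
            trace.final = "filtered_fp"
        else:
            trace.final = "somatic_pass"
        if config.enable_rescue or row["caller"] == "pindel":
            trace = rescue_clinical(trace, row, kb)
        finals.append(trace.final)
        rescued_col.append(trace.rescued)
    df["rescued"] = rescued_col
    df["final"] = finals

    summary = (
        df.groupby(["sample_id", "final"]).size().unstack(fill_value=0)
        .reindex(columns=list(FINAL_STATUSES), fill_value=0)
    )
    return PipelineResult(calls=df, recurrence=recurrence, summary=summary)
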