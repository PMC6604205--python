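"""File-format I/O: FASTA/FASTQ (Biopython), VCF 4.2 (pysam), TSV tables.

All on-disk formats are the field's standard text formats so outputs can be
inspected and consumed by standard tooling.  Variant tables round-trip
through VCF 4.2 with the filter outcome in FILTER and the audit trace in
INFO (``TRACE``, ``RESCUED``).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .somatic import VARIANT_COLUMNS

__all__ = [
    "write_fasta", "read_fasta", "write_fastq_pairs", "read_fastq_pairs",
    "write_vcf", "read_vcf", "write_truth", "read_truth",
    "write_segments", "read_segments", "write_ploidy", "read_ploidy",
]

#: FILTER value used for each final pipeline status
FILTER_BY_STATUS = {
    "somatic_pass": "PASS",
    "rescued_clinical": "PASS",
    "filtered_germline": "germline",
    "filtered_fp": "recurrent_fp",
    "filtered_pindel_no_kb": "pindel_no_kb",
}
FILTER_BY_QUALITY = {
    "fail_hard": "hard_filter",
    "fail_depth": "low_depth",
    "fail_af": "low_af",
}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(str(seq)), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(pairs: Iterable[tuple], r1_path, r2_path) -> None:
    pairs = list(pairs)
    SeqIO.write([p[0] for p in pairs], str(r1_path), "fastq")
    SeqIO.write([p[1] for p in pairs], str(r2_path), "fastq")


def read_fastq_pairs(r1_path, r2_path) -> list:
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError(f"unequal mate counts: {len(r1)} vs {len(r2)}")
    return list(zip(r1, r2))


def _vcf_header(df: pd.DataFrame) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in pd.unique(df["chrom"]):
        header.contigs.add(str(chrom))
    for name, desc in [
        ("DP", "Total read depth"),
        ("QD", "Quality by depth"),
        ("FS", "FisherStrand phred-scaled strand-bias p"),
        ("MQ", "RMS mapping quality"),
    ]:
        number_type = ("1", "Integer") if name == "DP" else ("1", "Float")
        header.info.add(name, number_type[0], number_type[1], desc)
    header.info.add("AF", "A", "Float", "Alternate allele fraction")
    header.info.add("MQRankSum", "1", "Float", "Mapping-quality rank-sum")
    header.info.add("ReadPosRankSum", "1", "Float", "Read-position rank-sum")
    header.info.add("CALLER", "1", "String", "Originating variant caller")
    header.info.add("VTYPE", "1", "String", "snv or indel")
    header.info.add("EFFECT", "1", "String", "Predicted coding effect")
    header.info.add("GENE", "1", "String", "Gene symbol")
    header.info.add("TRACE", "1", "String", "Semicolon-joined filter trace flags")
    header.info.add("RESCUED", "0", "Flag", "Reinstated by clinical rescue")
    for name, desc in [
        ("germline", "Matches the aggregated germline resource at germline AF"),
        ("recurrent_fp", "Position recurrently mutated across the cohort"),
        ("hard_filter", "Failed a GATK-style hard filter"),
        ("low_depth", "Read depth below the panel minimum"),
        ("low_af", "Alternate allele fraction below the minimum"),
        ("pindel_no_kb", "Pindel call without a clinical knowledgebase entry"),
    ]:
        header.filters.add(name, None, None, desc)
    return header


def write_vcf(calls: pd.DataFrame, path) -> None:
    """Write one sample's (or cohort slice's) annotated calls as VCF 4.2.

    Trace columns (``quality_status``, flags, ``final``), when present, are
    encoded in FILTER and INFO/TRACE.
    """
    df = calls.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)
    header = _vcf_header(df)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.to_dict("records"):
            rec = out.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(str(row["ref"])),
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.info["DP"] = int(row["DP"])
            rec.info["AF"] = (float(row["ALT_AF"]),)
            for ann in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
                val = row.get(ann)
                if val is not None and not (isinstance(val, float) and math.isnan(val)):
                    rec.info[ann] = float(val)
            for col, tag in [("caller", "CALLER"), ("vtype", "VTYPE"),
                             ("effect", "EFFECT"), ("gene", "GENE")]:
                if row.get(col):
                    rec.info[tag] = str(row[col])
            if "final" in row:
                final = row["final"]
                if final == "filtered_quality":
                    filt = FILTER_BY_QUALITY[row["quality_status"]]
                else:
                    filt = FILTER_BY_STATUS[final]
                rec.filter.add(filt)
                trace = [
                    f"quality={row['quality_status']}",
                    f"germline={int(bool(row.get('germline_flag', False)))}",
                    f"recurrent_fp={int(bool(row.get('recurrent_fp_flag', False)))}",
                    f"final={final}",
                ]
                rec.info["TRACE"] = ";".join(trace)
                if row.get("rescued"):
                    rec.info["RESCUED"] = True
            out.write(rec)


def read_vcf(path, sample_id: str = "") -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a variant table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(
                    f"{path}: multi-allelic record at line with pos {rec.pos}; "
                    "decompose to one alt per record"
                )
            info = rec.info
            af = info.get("AF")
            rows.append({
                "sample_id": sample_id,
                "chrom": rec.contig, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                "vtype": info.get("VTYPE", "snv"), "caller": info.get("CALLER", "gatk"),
                "DP": int(info.get("DP", 0)),
                "ALT_AF": float(af[0]) if af else 0.0,
                "QD": info.get("QD"), "FS": info.get("FS"), "MQ": info.get("MQ"),
                "MQRankSum": info.get("MQRankSum"),
                "ReadPosRankSum": info.get("ReadPosRankSum"),
                "effect": info.get("EFFECT", "noncoding"),
                "gene": info.get("GENE", ""),
                "protein_change": "",
            })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.rename(columns={"sample_id": "sample"})
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"sample": "sample_id"})


def write_segments(segments: pd.DataFrame, path) -> None:
    cols = ["sample_id", "chrom", "start", "end", "nMajor", "nMinor"]
    segments[cols].rename(columns={"sample_id": "sample"}).to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").rename(columns={"sample": "sample_id"})


def write_ploidy(ploidy: pd.DataFrame, path) -> None:
    ploidy.rename(columns={"sample_id": "sample"}).to_csv(path, sep="\t", index=False)


def read_ploidy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").rename(columns={"sample": "sample_id"})


def read_genes(path) -> pd.DataFrame:
    """Gene models from headered TSV (1-based inclusive) or 4-column BED
    (0-based half-open, converted on read)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene"])
        df["start"] = df["start"] + 1  # BED is 0-based half-open
        return df[["gene", "chrom", "start", "end"]]
    return pd.read_csv(path, sep="\t")
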