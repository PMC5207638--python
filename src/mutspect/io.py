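"""File-format I/O: FASTA, BED, GFF3, VCF v4.2, and tidy TSV tables.

Conventions: VCF is 1-based inclusive, BED is 0-based half-open; all
internal arithmetic is 1-based and conversion happens here.  Every table
written by the pipeline carries a ``# seed=`` header comment so a run can be
reproduced from its outputs.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filtering import VariantRecord


# ---------------------------------------------------------------------------
# FASTA / annotation
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=chrom, description="")
         for chrom, seq in genome.items()),
        str(path), "fasta",
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_fai(path: str | os.PathLike) -> dict[str, int]:
    """Chromosome lengths from a samtools .fai index (or any 2+ column TSV
    of name and length)."""
    df = pd.read_csv(str(path), sep="\t", header=None, usecols=[0, 1])
    return dict(zip(df[0].astype(str), df[1].astype(int)))


def write_annotation_bed(
    annotation: pd.DataFrame, path: str | os.PathLike
) -> None:
    """Coding intervals as BED6 (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for i, row in annotation.iterrows():
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\tcds{i}\t0\t"
                f"{row.strand}\n"
            )


def write_annotation_gff3(
    annotation: pd.DataFrame, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in annotation.iterrows():
            fh.write(
                f"{row.chrom}\tmutspect\tCDS\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t0\tID=cds{i}\n"
            )


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Coding annotation from BED6 or GFF3 into the internal 1-based frame."""
    path = str(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if path.endswith((".gff", ".gff3")):
                rows.append({
                    "chrom": parts[0], "start": int(parts[3]),
                    "end": int(parts[4]), "strand": parts[6],
                })
            else:
                rows.append({
                    "chrom": parts[0], "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                    "strand": parts[5] if len(parts) > 5 else "+",
                })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def read_bed_intervals(
    path: str | os.PathLike,
) -> tuple[tuple[str, int, int], ...]:
    """Mask intervals from a BED file, kept 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return tuple(out)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(
    records: Sequence[VariantRecord],
    strains: Sequence[str],
    contigs: Mapping[str, int],
    path: str | os.PathLike,
    seed: int | None = None,
) -> None:
    """Multi-sample VCF v4.2, one ALT per record, haploid genotypes."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_line(
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    if seed is not None:
        header.add_line(f"##mutspect_seed={seed}")
    for s in strains:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos + len(r.ref) - 1,
                alleles=(r.ref, *r.alt.split(",")),
            )
            rec.qual = r.qual
            rec.info["MQ"] = r.mq
            for i, s in enumerate(strains):
                sample = rec.samples[s]
                sample["GT"] = (1,) if r.gt[i] else (0,)
                sample["GQ"] = int(r.gq[i])
                sample["DP"] = int(r.dp[i])
                alt_n = int(r.alt_reads[i])
                sample["AD"] = (int(r.dp[i]) - alt_n, alt_n)
            vcf.write(rec)


def read_vcf(
    path: str | os.PathLike,
) -> tuple[list[VariantRecord], tuple[str, ...]]:
    """Read a multi-sample VCF into :class:`VariantRecord` objects.

    Records that cannot be interpreted (missing genotype structure,
    unparseable fields) are returned flagged ``malformed`` so the filter
    stage can tally them rather than crash.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        strains = tuple(vcf.header.samples)
        n = len(strains)
        for rec in vcf:
            try:
                alts = rec.alts or ()
                alt = ",".join(alts)
                gt = np.zeros(n, dtype=bool)
                gq = np.full(n, np.nan)
                dp = np.full(n, np.nan)
                ar = np.full(n, np.nan)
                for i, s in enumerate(strains):
                    sample = rec.samples[s]
                    alleles = sample.get("GT") or ()
                    gt[i] = any(a is not None and a >= 1 for a in alleles)
                    if sample.get("GQ") is not None:
                        gq[i] = sample["GQ"]
                    if sample.get("DP") is not None:
                        dp[i] = sample["DP"]
                    ad = sample.get("AD")
                    if ad is not None and len(ad) > 1:
                        ar[i] = sum(x for x in ad[1:] if x is not None)
                mq = rec.info.get("MQ", np.nan)
                records.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    qual=rec.qual if rec.qual is not None else np.nan,
                    mq=float(mq) if mq is not None else np.nan,
                    strains=strains, gt=gt, gq=gq, dp=dp, alt_reads=ar,
                ))
            except (ValueError, TypeError, KeyError):
                records.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref or "N",
                    alt="?", qual=np.nan, mq=np.nan, strains=strains,
                    gt=np.zeros(n, dtype=bool), gq=np.full(n, np.nan),
                    dp=np.full(n, np.nan), alt_reads=np.full(n, np.nan),
                    malformed=True,
                ))
    return records, strains


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_tsv(
    df: pd.DataFrame, path: str | os.PathLike,
    seed: int | None = None, index: bool = False,
) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", comment="#", **kwargs)


def write_mask_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
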