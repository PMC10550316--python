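"""Readers and writers for the formats the pipeline consumes and emits.

Coordinate conventions are applied at the file boundary only: GFF3 is
1-based closed, VCF is 1-based, BED/bedGraph are 0-based half-open, and
everything in memory is 0-based half-open.

Internal tables (pileup, truth, candidates, features) are tab-separated
files with a one-line schema header of the form ``#somarna <schema> v1``;
per-read attribute vectors are comma-joined within a field.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from somarna.annotation import Gene, GenomeAnnotation, Region

SCHEMA_PREFIX = "#somarna"


class FormatError(ValueError):
    """Malformed record in an input file (carries file and line context)."""


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(chromosomes: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Emit genes and their UTR/exon children, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in annotation.chromosomes.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for gene in annotation.genes:
            attrs = f"ID={gene.gene_id}"
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "somarna",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for i, r in enumerate(gene.regions):
                rattrs = (
                    f"ID={gene.gene_id}.{i};Parent={gene.gene_id};"
                    f"unambiguous={int(r.unambiguous)}"
                )
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "somarna",
                            r.label,
                            str(r.start + 1),
                            str(r.end),
                            ".",
                            gene.strand,
                            ".",
                            rattrs,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str, chromosomes: dict[str, str] | None = None) -> GenomeAnnotation:
    """Parse the GFF3 subset emitted by :func:`write_gff3`.

    ``chromosomes`` (from the companion FASTA) may be supplied; otherwise the
    annotation carries empty sequences and only interval structure.
    """
    genes: dict[str, Gene] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = Gene(gene_id=gid, chrom=chrom, strand=strand, regions=[])
                order.append(gid)
            elif ftype in ("UTR", "exon"):
                parent = attr.get("Parent")
                if parent is None or parent not in genes:
                    raise FormatError(f"{path}:{lineno}: {ftype} without known Parent")
                genes[parent].regions.append(
                    Region(
                        start=start_i,
                        end=end_i,
                        label=ftype,
                        unambiguous=bool(int(attr.get("unambiguous", "1"))),
                    )
                )
    ann = GenomeAnnotation(
        chromosomes=chromosomes or {}, genes=[genes[g] for g in order]
    )
    return ann


# ---------------------------------------------------------------------------
# VCF

def write_vcf(records: pd.DataFrame, path: str, contigs: dict[str, int] | None = None) -> None:
    """Write germline variants as VCF 4.2.

    ``records`` needs columns chrom, pos (0-based), ref, alt; multi-allelic
    sites may be given as comma-joined ``alt``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=somarna\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = records.sort_values(["chrom", "pos"])
        for _, row in rows.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t.\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\n"
            )


def read_vcf_positions(path: str) -> pd.DataFrame:
    """Germline variant positions, one row per (chrom, pos, alt).

    Multi-allelic records are split into per-alt rows.  Positions are
    returned 0-based.
    """
    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos - 1, rec.ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# BED / bedGraph

def write_bed(intervals: pd.DataFrame, path: str) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str, 1: np.int64, 2: np.int64},
    )
    if (df["end"] <= df["start"]).any():
        bad = int(np.argmax((df["end"] <= df["start"]).to_numpy())) + 1
        raise FormatError(f"{path}: empty interval at data line {bad}")
    return df


def write_bedgraph(track: pd.DataFrame, path: str) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={0: str, 1: np.int64, 2: np.int64, 3: float},
    )
    return df


# ---------------------------------------------------------------------------
# Versioned TSV schemas

def write_table(df: pd.DataFrame, path: str, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} {schema} v1\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str, schema: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(f"{SCHEMA_PREFIX} {schema}"):
            raise FormatError(
                f"{path}:1: expected schema line '{SCHEMA_PREFIX} {schema} v1', "
                f"got {header!r}"
            )
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "accession": str})
    # attribute-vector fields come back as strings; empty cells become ""
    for col in df.columns:
        if col.startswith(("ref_", "alt_")) and col not in ("ref_count", "alt_count"):
            df[col] = df[col].fillna("").astype(str)
    return df


def join_vector(values: Iterable[int | float]) -> str:
    return ",".join(str(v) for v in values)


def split_vector(text: str, dtype=float) -> np.ndarray:
    if not text or text in ("nan", "."):
        return np.array([], dtype=dtype)
    return np.array([dtype(v) for v in text.split(",")])
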