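"""Readers and writers for the formats the pipeline touches.

VCF 4.x ingestion goes through cyvcf2; FASTA through Biopython; trees
through dendropy. Coordinate conventions: VCF and queries are 1-based,
conservation (BED) intervals 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CodingAnnotation,
    ConservationTrack,
    GenotypeMatrix,
    SampleTable,
    Transcript,
)

log = logging.getLogger(__name__)

_SNV_BASES = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# VCF

def read_vcf(
    path: str | os.PathLike,
    sample_filter: list[str] | None = None,
    callable_sites: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, keeping only biallelic SNVs.

    Multiallelic and indel records are counted and dropped. Genotypes other
    than diploid {0/0, 0/1, 1/0, 1/1} (phased or not) become missing; the
    coerced-call count is logged. A record with no GT field is a hard error.

    ``callable_sites`` supplies the per-sample denominator for diversity
    statistics; without it the matrix falls back to the per-sample count of
    non-missing genotyped sites and flags the fallback.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    all_samples = list(vcf.samples)
    if sample_filter is not None:
        missing = [s for s in sample_filter if s not in all_samples]
        if missing:
            raise KeyError(f"samples not present in VCF {path}: {missing}")
        keep_idx = [all_samples.index(s) for s in sample_filter]
        samples = list(sample_filter)
    else:
        keep_idx = list(range(len(all_samples)))
        samples = all_samples

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_rows: list[np.ndarray] = []
    dropped = {"multiallelic": 0, "indel_or_nonsnv": 0, "nonstandard_gt": 0}

    for rec in vcf:
        if "GT" not in (rec.FORMAT or []):
            raise ValueError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        if len(rec.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in _SNV_BASES or alt not in _SNV_BASES:
            dropped["indel_or_nonsnv"] += 1
            continue
        row = np.full(len(keep_idx), MISSING, dtype=np.int8)
        genos = rec.genotypes  # [a0, a1, phased] per sample
        for out_i, i in enumerate(keep_idx):
            g = genos[i]
            alleles = g[:-1]
            if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
                if not (len(alleles) == 2 and alleles[0] == -1 and alleles[1] == -1):
                    dropped["nonstandard_gt"] += 1
                continue  # half-calls, haploid, polyploid, ./. -> missing
            row[out_i] = int(alleles[0]) + int(alleles[1])  # 0/1/2 dosage == code
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        geno_rows.append(row)

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    genotypes = (
        np.stack(geno_rows, axis=1) if geno_rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    if dropped["multiallelic"] or dropped["indel_or_nonsnv"] or dropped["nonstandard_gt"]:
        log.info("read_vcf %s: dropped %s", path, dropped)

    callable_arr = None
    fallback = False
    if callable_sites is not None:
        callable_arr = np.asarray([callable_sites[s] for s in samples], dtype=np.int64)
    else:
        callable_arr = (genotypes != MISSING).sum(axis=1).astype(np.int64)
        fallback = True
        log.info("read_vcf %s: callable-site counts fall back to non-missing VCF sites", path)
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        genotypes=genotypes,
        callable_sites=callable_arr,
        callable_fallback=fallback,
        dropped=dropped,
    )


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike, contigs: dict[str, int] | None = None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=driftprint\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        sites = matrix.sites
        geno = matrix.genotypes
        for j in range(matrix.n_sites):
            gt = "\t".join(_GT_STRING[int(geno[i, j])] for i in range(matrix.n_samples))
            fh.write(
                f"{sites['chrom'].iat[j]}\t{sites['pos'].iat[j]}\t.\t"
                f"{sites['ref'].iat[j]}\t{sites['alt'].iat[j]}\t.\t.\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# Sample table

def read_sample_table(path: str | os.PathLike) -> SampleTable:
    """Tab-separated sample table: sample, population, life_history[, outgroup, callable_sites]."""
    t = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    return SampleTable(t)


def write_sample_table(table: SampleTable, path: str | os.PathLike) -> None:
    table.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Conservation track (BED 4-column)

def read_conservation(path: str | os.PathLike) -> ConservationTrack:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "score": float},
    )
    return ConservationTrack(frame)


def write_conservation(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Outgroup alleles

class OutgroupAlleles:
    """Per-site outgroup base map; returns None ('unknown') when uncovered."""

    def __init__(self, seqs: dict[str, str] | None = None, table: dict[tuple[str, int], str] | None = None):
        self._seqs = {k: v.upper() for k, v in (seqs or {}).items()}
        self._table = {k: v.upper() for k, v in (table or {}).items()}

    def base_at(self, chrom: str, pos: int) -> str | None:
        if self._table:
            b = self._table.get((chrom, pos))
            if b is not None:
                return b if b in _SNV_BASES else None
        seq = self._seqs.get(chrom)
        if seq is not None and 1 <= pos <= len(seq):
            b = seq[pos - 1]
            return b if b in _SNV_BASES else None
        return None


def read_outgroup_alleles(path: str | os.PathLike) -> OutgroupAlleles:
    """Read a reference-aligned FASTA or a 3-column chrom/pos/base table."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        seqs = {}
        for rec in SeqIO.parse(path, "fasta"):
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"malformed FASTA (no records): {path}")
        return OutgroupAlleles(seqs=seqs)
    t = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "base"],
                    dtype={"chrom": str, "pos": np.int64, "base": str})
    table = {(str(r.chrom), int(r.pos)): str(r.base) for r in t.itertuples()}
    return OutgroupAlleles(table=table)


def write_outgroup_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    rows.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Reference FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"malformed FASTA (no records): {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Coding annotation (GFF3 CDS subset)

def read_annotation(path: str | os.PathLike) -> CodingAnnotation:
    """Read CDS features from a GFF3 subset into transcripts.

    CDS rows sharing a Parent are grouped into one transcript; intervals are
    put in transcription order and the first CDS row's frame column anchors
    the reading frame.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            parent = attrs.get("Parent") or attrs.get("ID") or "unknown"
            rows.append((parent, f[0], f[6], int(f[3]), int(f[4]), f[7]))
    transcripts = []
    frame = pd.DataFrame(rows, columns=["tid", "chrom", "strand", "start", "end", "phase"])
    for tid, sub in frame.groupby("tid", sort=False):
        strand = sub["strand"].iloc[0]
        sub = sub.sort_values("start", ascending=(strand == "+"))
        phase = sub["phase"].iloc[0]
        transcripts.append(
            Transcript(
                transcript_id=str(tid),
                chrom=str(sub["chrom"].iloc[0]),
                strand=str(strand),
                intervals=[(int(a), int(b)) for a, b in zip(sub["start"], sub["end"])],
                frame=0 if phase in (".", "") else int(phase),
            )
        )
    return CodingAnnotation(transcripts)


def write_annotation(annotation: CodingAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in annotation.transcripts:
            for k, (a, b) in enumerate(t.intervals):
                phase = t.frame if k == 0 else 0
                fh.write(
                    f"{t.chrom}\tdriftprint\tCDS\t{a}\t{b}\t.\t{t.strand}\t{phase}\t"
                    f"Parent={t.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Newick trees (dendropy)

def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    """Serialize a tree with branch lengths and node-label supports.

    Duplicate tip labels are a hard error (the file would be ambiguous to
    any downstream reader).
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    Path(path).write_text(s)


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
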