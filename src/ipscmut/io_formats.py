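"""Readers and writers for the formats the pipeline touches.

FASTA parsing is delegated to Biopython, VCF to pysam, tabular catalogs to
pandas; this module adds the validation and coordinate bookkeeping the
pipeline relies on. All coordinates handed to callers are 1-based inclusive;
BED's 0-based half-open starts are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .core import (
    CANONICAL_KEYS,
    KEY_INDEX,
    MAX_INDEL_LENGTH,
    REGION_CLASSES,
    VALID_BASES,
    AnnotationInterval,
    ConsistencyError,
    FormatError,
    IndelRecord,
    MutationSet,
    ReferenceSequence,
    SignatureCatalog,
    SnvRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_signature_catalog",
    "write_signature_catalog",
    "read_bed",
    "read_gff3",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_fasta_lines(path: Path) -> None:
    """Pre-scan so format errors can name the offending line."""
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
                if len(stripped) == 1:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                continue
            if not seen_header:
                raise FormatError(
                    f"{path}: sequence data before any '>' header at line {lineno}"
                )
            bad = set(stripped.upper()) - VALID_BASES
            if bad:
                raise FormatError(
                    f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                )
    if not seen_header:
        raise FormatError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (multi-record) FASTA file.

    Sequences are uppercased and multi-line records concatenated; record
    order is preserved. Raises :class:`FormatError` (naming the line) on a
    malformed header or an illegal character.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    return [
        ReferenceSequence(name=rec.id, bases=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(sequences: list[ReferenceSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n")
            for i in range(0, seq.length, width):
                fh.write(seq.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _is_symbolic(alt: str | None) -> bool:
    if alt is None:
        return True
    return any(c in alt for c in "<>[].*") or alt == "" or not set(alt) <= set("ACGTN")


@dataclass
class VcfReadStats:
    """Per-file tally of rows the supported subset excludes."""

    n_symbolic_skipped: int = 0
    n_long_indel_skipped: int = 0


def read_vcf(
    path: str | Path, stats: VcfReadStats | None = None
) -> list[MutationSet]:
    """Read SNVs and short indels from a VCF 4.x file, one MutationSet per sample.

    Multi-allelic rows are split into one record per alternate allele. With
    sample columns present, a record is assigned to every sample whose GT
    carries that alternate (missing GT assigns to all samples); without
    sample columns a single set named after the file is returned. Symbolic/
    breakend alleles and indels beyond the 50-bp scope are skipped with a
    logged warning and counted in ``stats``.
    """
    path = Path(path)
    stats = stats if stats is not None else VcfReadStats()
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc

    with vf:
        sample_names = list(vf.header.samples)
        if not sample_names:
            sample_names = [path.stem]
        per_sample: dict[str, dict[str, list]] = {
            s: {"snvs": [], "indels": []} for s in sample_names
        }

        for rec in vf:
            ref = (rec.ref or "").upper()
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                if _is_symbolic(alt) or not set(ref) <= set("ACGT"):
                    stats.n_symbolic_skipped += 1
                    logger.warning(
                        "%s: skipping unsupported allele %s>%s at %s:%d",
                        path, ref, alt, rec.chrom, rec.pos,
                    )
                    continue
                alt = alt.upper()
                if len(ref) != len(alt) and abs(len(ref) - len(alt)) > MAX_INDEL_LENGTH:
                    stats.n_long_indel_skipped += 1
                    logger.warning(
                        "%s: skipping >%d bp indel at %s:%d",
                        path, MAX_INDEL_LENGTH, rec.chrom, rec.pos,
                    )
                    continue
                if len(ref) > 1 and len(ref) == len(alt):
                    stats.n_symbolic_skipped += 1
                    logger.warning(
                        "%s: skipping multi-nucleotide substitution at %s:%d",
                        path, rec.chrom, rec.pos,
                    )
                    continue

                if rec.samples:
                    carriers = []
                    for s in rec.samples.values():
                        gt = s.get("GT")
                        if gt is None or all(a is None for a in gt) or alt_index in gt:
                            carriers.append(s.name)
                else:
                    carriers = sample_names

                for sample in carriers:
                    if len(ref) == 1 and len(alt) == 1:
                        per_sample[sample]["snvs"].append(
                            SnvRecord(rec.chrom, rec.pos, ref, alt, sample)
                        )
                    else:
                        per_sample[sample]["indels"].append(
                            IndelRecord(rec.chrom, rec.pos, ref, alt, sample)
                        )

    return [
        MutationSet(sample=s, snvs=d["snvs"], indels=d["indels"])
        for s, d in per_sample.items()
    ]


def write_vcf(
    mutation_set: MutationSet,
    reference: ReferenceSequence | list[ReferenceSequence] | None,
    path: str | Path,
) -> None:
    """Write a MutationSet as VCF 4.2, sorted by (chrom, pos, ref, alt).

    When a reference is supplied, every record's REF allele is checked
    against it and a :class:`ConsistencyError` names the first mismatch.
    Round-trips through :func:`read_vcf` losslessly.
    """
    refs = (
        {}
        if reference is None
        else {r.name: r for r in ([reference] if isinstance(reference, ReferenceSequence) else reference)}
    )
    records = mutation_set.records()
    for rec in records:
        ref_seq = refs.get(rec.chrom)
        if ref_seq is None:
            continue
        end = rec.pos + len(rec.ref) - 1
        if end > ref_seq.length or ref_seq.slice(rec.pos, end) != rec.ref:
            raise ConsistencyError(
                f"record {rec.chrom}:{rec.pos} {rec.ref}>{rec.alt} "
                f"does not match reference {rec.chrom}"
            )

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = {r.chrom for r in records} | set(refs)
    for name in sorted(contigs):
        length = refs[name].length if name in refs else None
        if length is not None:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    sample = mutation_set.sample or "sample"
    header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            # de novo calls are modelled as heterozygous
            vrec.samples[sample]["GT"] = (0, 1)
            out.write(vrec)


# ---------------------------------------------------------------------------
# signature catalog TSV
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    """Read a catalog TSV: column 1 holds context keys like ``A[C>T]G``,
    every further column one signature. Rows may appear in any order but must
    cover the 96 types exactly once; signatures are renormalized to sum 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a key column plus >=1 signature column")
    keys = df.iloc[:, 0].tolist()
    unknown = [k for k in keys if k not in KEY_INDEX]
    if unknown:
        raise FormatError(f"{path}: unrecognized context keys {unknown[:5]}")
    counts = pd.Series(keys).value_counts()
    dupes = sorted(counts[counts > 1].index)
    if dupes:
        raise FormatError(f"{path}: duplicated context rows {dupes[:5]}")
    missing = sorted(set(CANONICAL_KEYS) - set(keys))
    if missing:
        raise FormatError(f"{path}: missing context rows {missing[:5]}")

    order = np.argsort([KEY_INDEX[k] for k in keys])
    signatures = {}
    for col in df.columns[1:]:
        vec = df[col].to_numpy(dtype=float)[order]
        signatures[str(col)] = vec
    return SignatureCatalog(signatures)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame({"MutationType": CANONICAL_KEYS})
    for name, vec in catalog.items():
        df[name] = vec
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals: BED and GFF3
# ---------------------------------------------------------------------------

_GFF3_CLASS_MAP = {
    "cds": "CDS",
    "five_prime_utr": "UTR",
    "three_prime_utr": "UTR",
    "utr": "UTR",
    "ncrna": "ncRNA",
    "lnc_rna": "ncRNA",
    "lincrna": "ncRNA",
    "mirna": "ncRNA",
    "rrna": "ncRNA",
    "trna": "ncRNA",
    "snorna": "ncRNA",
    "intron": "intron",
    "intergenic": "intergenic",
}


def read_bed(path: str | Path) -> list[AnnotationInterval]:
    """Read intervals from BED (0-based half-open; converted to 1-based
    inclusive). Column 4 must carry the region class; column 6, if present,
    the strand."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: need >=4 BED columns")
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if name not in REGION_CLASSES:
                raise FormatError(
                    f"{path}: line {lineno}: region class {name!r} not in {REGION_CLASSES}"
                )
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                AnnotationInterval(chrom, start_i + 1, end_i, name, strand)
            )
    return intervals


def read_gff3(path: str | Path) -> list[AnnotationInterval]:
    """Read region intervals from GFF3 (already 1-based inclusive).

    Feature types are mapped onto the five region classes; unmapped types
    (gene, mRNA, exon, ...) are ignored as grouping features.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            ftype = fields[2].lower()
            region_class = _GFF3_CLASS_MAP.get(ftype)
            if region_class is None:
                continue
            try:
                start_i, end_i = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            frame = None if fields[7] == "." else int(fields[7])
            intervals.append(
                AnnotationInterval(fields[0], start_i, end_i, region_class, fields[6], frame)
            )
    return intervals
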