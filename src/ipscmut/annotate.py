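"""Region and coding-consequence classification of mutations.

A deliberately small stand-in for full gene-based annotators: each mutation
gets exactly one region class (CDS > UTR > ncRNA > intron > intergenic
precedence across overlapping intervals), and SNVs inside a transcript's CDS
additionally get a codon-level consequence by translating the affected codon
before and after the substitution with the standard genetic code. Indels in
CDS are reported only as frameshift / in-frame by length mod 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .core import (
    AnnotationInterval,
    ConsistencyError,
    MutationSet,
    ParameterError,
    ReferenceSequence,
    SnvRecord,
    revcomp,
)

__all__ = [
    "TranscriptModel",
    "RegionClassTally",
    "classify_region",
    "snv_consequence",
    "tally_regions",
]

REGION_PRECEDENCE = ("CDS", "UTR", "ncRNA", "intron", "intergenic")
_RANK = {c: i for i, c in enumerate(REGION_PRECEDENCE)}

CONSEQUENCES = ("synonymous", "nonsynonymous", "stopgain", "stoploss")


@dataclass(frozen=True)
class TranscriptModel:
    """A minimal transcript: exons in genome order plus a CDS span.

    Exons are 1-based inclusive, non-overlapping and sorted by genomic
    start; ``cds_start``/``cds_end`` bound the translated region in genome
    coordinates (cds_start <= cds_end regardless of strand). The CDS length
    must be a whole number of codons.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    name: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = 0
        for start, end in exons:
            if start > end:
                raise ParameterError(f"exon {start}-{end} reversed")
            if start <= prev_end:
                raise ParameterError("exons must be sorted and non-overlapping")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise ParameterError("cds_start must be <= cds_end")
        if len(self._cds_positions()) % 3 != 0:
            raise ParameterError("CDS length must be divisible by 3")

    def _cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases, ascending."""
        pos = []
        for start, end in self.exons:
            lo = max(start, self.cds_start)
            hi = min(end, self.cds_end)
            if lo <= hi:
                pos.extend(range(lo, hi + 1))
        return pos

    def contains_cds(self, chrom: str, pos: int) -> bool:
        if chrom != self.chrom:
            return False
        return any(
            max(s, self.cds_start) <= pos <= min(e, self.cds_end)
            for s, e in self.exons
        )


@dataclass
class RegionClassTally:
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in REGION_PRECEDENCE}
    )
    coding_breakdown: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CONSEQUENCES}
    )
    indel_cds_breakdown: dict[str, int] = field(
        default_factory=lambda: {"frameshift": 0, "inframe": 0}
    )

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def classify_region(
    intervals: list[AnnotationInterval], chrom: str, pos: int
) -> str:
    """Region class of a position: the highest-precedence class among the
    covering intervals, or 'intergenic' when nothing covers it. Interval
    bounds are 1-based inclusive, so boundary positions are covered."""
    best = "intergenic"
    for iv in intervals:
        if iv.covers(chrom, pos) and _RANK[iv.region_class] < _RANK[best]:
            best = iv.region_class
    return best


def snv_consequence(
    transcript: TranscriptModel,
    reference: ReferenceSequence,
    snv: SnvRecord,
) -> str:
    """Codon-level consequence of an SNV inside the transcript's CDS.

    The CDS is assembled from the exons, reverse-complemented for minus-
    strand transcripts, and the codon containing the variant is translated
    before and after the substitution (standard genetic code).
    """
    if not transcript.contains_cds(snv.chrom, snv.pos):
        raise ParameterError(
            f"position {snv.chrom}:{snv.pos} is outside the transcript CDS"
        )
    if reference.base(snv.pos) != snv.ref:
        raise ConsistencyError(
            f"SNV {snv.chrom}:{snv.pos} REF {snv.ref} != reference base"
        )

    genome_positions = transcript._cds_positions()
    cds = "".join(reference.base(p) for p in genome_positions)
    idx = genome_positions.index(snv.pos)
    alt = snv.alt
    if transcript.strand == "-":
        cds = revcomp(cds)
        idx = len(cds) - 1 - idx
        alt = revcomp(alt)

    codon_i = idx // 3
    offset = idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())

    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


def tally_regions(
    intervals: list[AnnotationInterval],
    transcripts: list[TranscriptModel],
    mutation_set: MutationSet,
    reference: ReferenceSequence | dict[str, ReferenceSequence],
) -> RegionClassTally:
    """Assign every mutation exactly one region class and tally; SNVs in CDS
    get a consequence, CDS indels a frameshift/in-frame call."""
    refs = (
        reference
        if isinstance(reference, dict)
        else {reference.name: reference}
    )
    tally = RegionClassTally()
    for rec in mutation_set.records():
        region = classify_region(intervals, rec.chrom, rec.pos)
        tally.counts[region] += 1
        if region != "CDS":
            continue
        if isinstance(rec, SnvRecord):
            tx = next(
                (t for t in transcripts if t.contains_cds(rec.chrom, rec.pos)), None
            )
            if tx is None:
                # covered by a CDS interval but no transcript model: count the
                # dominant non-silent outcome cannot be derived; be explicit
                raise ParameterError(
                    f"CDS position {rec.chrom}:{rec.pos} has no transcript model"
                )
            consequence = snv_consequence(tx, refs[rec.chrom], rec)
            tally.coding_breakdown[consequence] += 1
        else:
            kind = "frameshift" if rec.length_change % 3 != 0 else "inframe"
            tally.indel_cds_breakdown[kind] += 1
    return tally
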