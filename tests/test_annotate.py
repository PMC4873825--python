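import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from ipscmut.core import (
    AnnotationInterval,
    IndelRecord,
    MutationSet,
    ParameterError,
    ReferenceSequence,
    SnvRecord,
    revcomp,
)
from ipscmut.annotate import (
    RegionClassTally,
    TranscriptModel,
    classify_region,
    snv_consequence,
    tally_regions,
)

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def translate_codon(codon: str) -> str:
    """Independent genetic-code lookup (stop rendered as '*')."""
    return standard_dna_table.forward_table.get(codon, "*")


def expected_consequence(codon: str, alt_codon: str) -> str:
    ref_aa, alt_aa = translate_codon(codon), translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stopgain"
    if ref_aa == "*":
        return "stoploss"
    return "nonsynonymous"


def one_codon_transcript(strand="+"):
    return TranscriptModel(chrom="t", strand=strand, exons=((1, 3),), cds_start=1, cds_end=3)


class TestClassifyRegion:
    def intervals(self):
        return [
            AnnotationInterval("c", 10, 20, "intron"),
            AnnotationInterval("c", 12, 15, "CDS"),
            AnnotationInterval("c", 30, 40, "UTR"),
        ]

    def test_precedence_cds_beats_intron(self):
        assert classify_region(self.intervals(), "c", 13) == "CDS"

    def test_uncovered_position_is_intergenic(self):
        assert classify_region(self.intervals(), "c", 25) == "intergenic"
        assert classify_region(self.intervals(), "other", 13) == "intergenic"

    def test_boundaries_are_inclusive(self):
        assert classify_region(self.intervals(), "c", 12) == "CDS"
        assert classify_region(self.intervals(), "c", 15) == "CDS"
        assert classify_region(self.intervals(), "c", 30) == "UTR"
        assert classify_region(self.intervals(), "c", 40) == "UTR"


class TestSnvConsequence:
    def test_third_position_synonymous(self):
        # GCT -> GCC: Ala -> Ala
        ref = ReferenceSequence("t", "GCT")
        call = snv_consequence(one_codon_transcript(), ref, SnvRecord("t", 3, "T", "C"))
        assert call == "synonymous"

    def test_start_codon_nonsynonymous(self):
        # ATG -> ATA: Met -> Ile
        ref = ReferenceSequence("t", "ATG")
        call = snv_consequence(one_codon_transcript(), ref, SnvRecord("t", 3, "G", "A"))
        assert call == "nonsynonymous"

    def test_stopgain(self):
        # TAC -> TAA: Tyr -> stop
        ref = ReferenceSequence("t", "TAC")
        call = snv_consequence(one_codon_transcript(), ref, SnvRecord("t", 3, "C", "A"))
        assert call == "stopgain"

    def test_stoploss(self):
        # TGA -> TGG: stop -> Trp
        ref = ReferenceSequence("t", "TGA")
        call = snv_consequence(one_codon_transcript(), ref, SnvRecord("t", 3, "A", "G"))
        assert call == "stoploss"

    def test_outside_cds_rejected(self):
        tx = TranscriptModel("t", "+", ((1, 3),), 1, 3)
        ref = ReferenceSequence("t", "ATGAAA")
        with pytest.raises(ParameterError):
            snv_consequence(tx, ref, SnvRecord("t", 5, "A", "G"))

    def test_exhaustive_576_codon_changes(self):
        """All 64 codons x 3 positions x 3 alts agree with direct genetic-code lookup."""
        tx = one_codon_transcript()
        for codon in ALL_CODONS:
            ref = ReferenceSequence("t", codon)
            for offset in range(3):
                for alt in BASES:
                    if alt == codon[offset]:
                        continue
                    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
                    got = snv_consequence(
                        tx, ref, SnvRecord("t", offset + 1, codon[offset], alt)
                    )
                    assert got == expected_consequence(codon, alt_codon), (codon, alt_codon)

    def test_minus_strand_equals_reverse_complement_construction(self):
        """A minus-strand call equals the plus-strand call on the revcomp layout."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            codon = ALL_CODONS[rng.integers(64)]
            offset = int(rng.integers(3))
            alt = BASES[rng.integers(4)]
            if alt == codon[offset]:
                continue
            # minus-strand transcript over the revcomp genome
            genome_minus = revcomp(codon)
            pos_minus = 3 - offset
            tx_minus = one_codon_transcript(strand="-")
            got_minus = snv_consequence(
                tx_minus,
                ReferenceSequence("t", genome_minus),
                SnvRecord("t", pos_minus, genome_minus[pos_minus - 1], revcomp(alt)),
            )
            tx_plus = one_codon_transcript(strand="+")
            got_plus = snv_consequence(
                tx_plus, ReferenceSequence("t", codon), SnvRecord("t", offset + 1, codon[offset], alt)
            )
            assert got_minus == got_plus

    def test_spliced_minus_strand_transcript(self):
        # genome: exon1 1-4, intron 5-7, exon2 8-10; CDS 2-9 on minus strand
        # minus-strand CDS = revcomp(genome[2..4] + genome[8..9]) wait: CDS bases
        # ascending are 2,3,4,8,9; spliced "CTGGC" -> revcomp "GCCAG"? sanity via call
        genome = ReferenceSequence("t", "ACTGTTTGCA")
        # CDS positions 2,3,4,8,9 have length 5: the model must reject it
        with pytest.raises(ParameterError):
            TranscriptModel("t", "-", ((1, 4), (8, 10)), 2, 9)
        # a valid 6-base spliced CDS: positions 2,3,4 + 8,9,10
        tx = TranscriptModel("t", "-", ((1, 4), (8, 10)), 2, 10)
        # genome CDS ascending = CTG|GCA; minus-strand mRNA = TGCCAG,
        # codon 1 TGC = Cys. Genome A>G at pos 10 is mRNA T>C at base 1:
        # TGC -> CGC = Arg, nonsynonymous
        call = snv_consequence(tx, genome, SnvRecord("t", 10, "A", "G"))
        assert call == "nonsynonymous"


class TestTallyRegions:
    def genome(self, length=20_000, seed=0):
        rng = np.random.default_rng(seed)
        return ReferenceSequence(
            "g", "".join(rng.choice(list("ACGT"), size=length))
        )

    def intervals(self):
        return [
            AnnotationInterval("g", 1, 2000, "CDS"),
            AnnotationInterval("g", 2001, 5000, "UTR"),
            AnnotationInterval("g", 5001, 8000, "ncRNA"),
            AnnotationInterval("g", 8001, 14000, "intron"),
        ]

    def test_empty_set_is_all_zero(self):
        tally = tally_regions(self.intervals(), [], MutationSet(sample="s"), self.genome())
        assert tally.n_classified == 0

    def test_constructed_intergenic_placement(self):
        ref = self.genome()
        snvs = [
            SnvRecord("g", p, ref.base(p), "A" if ref.base(p) != "A" else "C", "s")
            for p in range(15000, 15010)
        ]
        tally = tally_regions(self.intervals(), [], MutationSet(sample="s", snvs=snvs), ref)
        assert tally.counts["intergenic"] == 10
        assert tally.n_classified == 10

    def test_assignment_is_total_and_exclusive(self):
        ref = self.genome(seed=3)
        rng = np.random.default_rng(5)
        indels = []
        for pos in rng.choice(np.arange(1, 19999), size=100, replace=False):
            pos = int(pos)
            allele = ref.slice(pos, pos + 1)
            indels.append(IndelRecord("g", pos, allele, allele[0], "s"))
        tally = tally_regions(
            self.intervals(), [], MutationSet(sample="s", indels=indels), ref
        )
        assert tally.n_classified == 100

    def test_uniform_placement_matches_interval_fractions(self):
        """Uniformly placed mutations fall into region classes in proportion
        to interval length, within 3 multinomial sigma."""
        ref = self.genome(seed=8)
        rng = np.random.default_rng(9)
        n = 600
        indels = []
        for pos in rng.choice(np.arange(1, 19999), size=n, replace=False):
            pos = int(pos)
            allele = ref.slice(pos, pos + 1)
            indels.append(IndelRecord("g", pos, allele, allele[0], "s"))
        tally = tally_regions(
            self.intervals(), [], MutationSet(sample="s", indels=indels), ref
        )
        fractions = {
            "CDS": 0.1, "UTR": 0.15, "ncRNA": 0.15, "intron": 0.3, "intergenic": 0.3,
        }
        for cls, f in fractions.items():
            sigma = np.sqrt(f * (1 - f) / n)
            assert abs(tally.counts[cls] / n - f) <= 3 * sigma + 2 / n

    def test_cds_snvs_get_consequences_and_indels_frame_calls(self):
        ref = ReferenceSequence("g", "ATGGCTTAA" + "A" * 20)
        tx = TranscriptModel("g", "+", ((1, 9),), 1, 9)
        intervals = [AnnotationInterval("g", 1, 9, "CDS")]
        ms = MutationSet(
            sample="s",
            snvs=[SnvRecord("g", 6, "T", "C", "s")],  # GCT->GCC synonymous
            indels=[
                IndelRecord("g", 2, "TG", "T", "s"),        # -1: frameshift
                IndelRecord("g", 4, "G", "GAAA", "s"),      # +3: in-frame
            ],
        )
        tally = tally_regions(intervals, [tx], ms, ref)
        assert tally.counts["CDS"] == 3
        assert tally.coding_breakdown["synonymous"] == 1
        assert sum(tally.coding_breakdown.values()) == 1  # SNVs only
        assert tally.indel_cds_breakdown == {"frameshift": 1, "inframe": 1}

    def test_cds_snv_without_transcript_model_is_an_error(self):
        ref = self.genome()
        snv = SnvRecord("g", 100, ref.base(100), "A" if ref.base(100) != "A" else "C", "s")
        with pytest.raises(ParameterError):
            tally_regions(self.intervals(), [], MutationSet(sample="s", snvs=[snv]), ref)
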