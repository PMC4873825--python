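"""Core domain types shared across the package.

Coordinates are 1-based inclusive everywhere (VCF-native); BED input is
converted at the parsing boundary. Substitutions are reported under the
pyrimidine-strand convention: a mutation whose reference base is a purine is
reverse-complemented, so every one of the 96 trinucleotide mutation types has
a C or T reference base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")
DNA_BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class IpscmutError(Exception):
    """Base class for all package errors."""


class FormatError(IpscmutError):
    """A file does not conform to the expected format."""


class ParameterError(IpscmutError, ValueError):
    """A parameter is outside its documented domain."""


class ConsistencyError(IpscmutError):
    """A record contradicts the attached reference sequence."""


class GenerationError(IpscmutError):
    """The synthetic generator cannot satisfy its configuration."""


class UndefinedStatisticError(IpscmutError, ZeroDivisionError):
    """A statistic is undefined for the given (empty/zero) input."""


class CapacityError(IpscmutError):
    """An exact computation exceeds its configured state-space cap."""


class MissingKeyError(IpscmutError, KeyError):
    """A requested label/passage/key is absent."""


# ---------------------------------------------------------------------------
# sequence + mutation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSequence:
    """A named DNA sequence over {A,C,G,T,N}, addressed 1-based inclusive."""

    name: str
    bases: str

    def __post_init__(self):
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains illegal characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise ParameterError(f"position {pos} outside 1..{self.length}")
        return self.bases[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if not 1 <= start <= end <= self.length:
            raise ParameterError(f"interval {start}..{end} outside 1..{self.length}")
        return self.bases[start - 1 : end]

    def trinucleotide(self, pos: int) -> str | None:
        """The 3-mer centred on ``pos``, or None at the sequence ends."""
        if pos < 2 or pos > self.length - 1:
            return None
        return self.bases[pos - 2 : pos + 1]


@dataclass(frozen=True, order=True)
class SnvRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str = ""

    def __post_init__(self):
        if self.ref not in DNA_BASES or self.alt not in DNA_BASES:
            raise ParameterError(f"SNV alleles must be single A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ParameterError(f"SNV at {self.chrom}:{self.pos} has ref == alt")
        if self.pos < 1:
            raise ParameterError(f"SNV position must be >= 1, got {self.pos}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


MAX_INDEL_LENGTH = 50  # short-indel scope


@dataclass(frozen=True, order=True)
class IndelRecord:
    """VCF-style indel: ``pos`` is the 1-based anchor base shared by both alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str = ""

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ParameterError("indel alleles must be non-empty")
        if len(self.ref) == len(self.alt):
            raise ParameterError(f"indel at {self.chrom}:{self.pos} has equal allele lengths")
        if abs(len(self.ref) - len(self.alt)) > MAX_INDEL_LENGTH:
            raise ParameterError(
                f"indel at {self.chrom}:{self.pos} exceeds the {MAX_INDEL_LENGTH}-bp scope"
            )
        if self.pos < 1:
            raise ParameterError(f"indel position must be >= 1, got {self.pos}")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class MutationSet:
    """One sample's de novo calls: SNVs and short indels, deduplicated by site."""

    sample: str
    snvs: list[SnvRecord] = field(default_factory=list)
    indels: list[IndelRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        sites = [r.site for r in self.snvs] + [r.site for r in self.indels]
        if len(sites) != len(set(sites)):
            seen, dupes = set(), set()
            for s in sites:
                if s in seen:
                    dupes.add(s)
                seen.add(s)
            raise ParameterError(f"duplicate mutation sites: {sorted(dupes)}")

    @property
    def n_snv(self) -> int:
        return len(self.snvs)

    @property
    def n_indel(self) -> int:
        return len(self.indels)

    def records(self) -> list[SnvRecord | IndelRecord]:
        """All records sorted by (chrom, pos, ref, alt)."""
        return sorted(self.snvs + self.indels, key=lambda r: r.site)


# ---------------------------------------------------------------------------
# annotation intervals
# ---------------------------------------------------------------------------

REGION_CLASSES = ("CDS", "UTR", "ncRNA", "intron", "intergenic")


@dataclass(frozen=True)
class AnnotationInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    region_class: str
    strand: str = "."
    frame_offset: int | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ParameterError(f"interval start {self.start} > end {self.end}")
        if self.region_class not in REGION_CLASSES:
            raise ParameterError(f"unknown region class {self.region_class!r}")

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# the 96 trinucleotide mutation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MutationType96:
    """One of the 96 substitution types: pyrimidine ref, alt, and flanking bases.

    Canonical ordering is ref (C before T), then alt, then 5' base, then 3'
    base, each alphabetical — the ordering COSMIC-style catalogs use once
    sorted by substitution class.
    """

    ref_pyrimidine: str
    alt: str
    five_prime: str
    three_prime: str

    def __post_init__(self):
        if self.ref_pyrimidine not in PYRIMIDINES:
            raise ParameterError(f"reference base must be C or T, got {self.ref_pyrimidine}")
        if self.alt not in DNA_BASES or self.alt == self.ref_pyrimidine:
            raise ParameterError(f"invalid alt {self.alt} for ref {self.ref_pyrimidine}")
        if self.five_prime not in DNA_BASES or self.three_prime not in DNA_BASES:
            raise ParameterError("flanking bases must be A/C/G/T")

    @property
    def key(self) -> str:
        return f"{self.five_prime}[{self.ref_pyrimidine}>{self.alt}]{self.three_prime}"

    @property
    def context(self) -> str:
        """Pyrimidine-strand reference trinucleotide, e.g. 'TCA'."""
        return self.five_prime + self.ref_pyrimidine + self.three_prime

    @property
    def is_dipyrimidine(self) -> bool:
        """True when either immediate neighbour is a pyrimidine (C or T)."""
        return self.five_prime in PYRIMIDINES or self.three_prime in PYRIMIDINES

    @classmethod
    def from_key(cls, key: str) -> "MutationType96":
        if len(key) != 7 or key[1] != "[" or key[3] != ">" or key[5] != "]":
            # canonical key is e.g. "A[C>T]G"
            raise FormatError(f"malformed mutation-type key {key!r}")
        return cls(ref_pyrimidine=key[2], alt=key[4], five_prime=key[0], three_prime=key[6])


def _build_canonical() -> tuple[MutationType96, ...]:
    types = []
    for ref in ("C", "T"):
        for alt in sorted(set(DNA_BASES) - {ref}):
            for five, three in itertools.product(DNA_BASES, DNA_BASES):
                types.append(MutationType96(ref, alt, five, three))
    return tuple(types)


CANONICAL_TYPES: tuple[MutationType96, ...] = _build_canonical()
TYPE_INDEX: dict[MutationType96, int] = {t: i for i, t in enumerate(CANONICAL_TYPES)}
CANONICAL_KEYS: tuple[str, ...] = tuple(t.key for t in CANONICAL_TYPES)
KEY_INDEX: dict[str, int] = {k: i for i, k in enumerate(CANONICAL_KEYS)}

DIPYRIMIDINE_MASK = np.array([t.is_dipyrimidine for t in CANONICAL_TYPES])
CT_MASK = np.array(
    [t.ref_pyrimidine == "C" and t.alt == "T" for t in CANONICAL_TYPES]
)


# ---------------------------------------------------------------------------
# signature catalog
# ---------------------------------------------------------------------------

SIGNATURE_SUM_TOL = 1e-9


@dataclass
class SignatureCatalog:
    """Named mutational signatures: each a nonnegative 96-vector summing to 1.

    Insertion order is preserved and used for tie-breaking when ranking.
    """

    signatures: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, vec in self.signatures.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (96,):
                raise ParameterError(f"signature {name!r} must have 96 entries, got {arr.shape}")
            if np.any(arr < 0):
                raise ParameterError(f"signature {name!r} has negative weights")
            total = arr.sum()
            if total <= 0:
                raise ParameterError(f"signature {name!r} sums to zero")
            if abs(total - 1.0) > SIGNATURE_SUM_TOL:
                arr = arr / total
            clean[name] = arr
        self.signatures = clean

    def __len__(self) -> int:
        return len(self.signatures)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.signatures[name]
        except KeyError:
            raise MissingKeyError(f"signature {name!r} not in catalog") from None

    def names(self) -> list[str]:
        return list(self.signatures)

    def items(self):
        return self.signatures.items()
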