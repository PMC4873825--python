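"""Signature-driven synthetic reference sequences and de novo call sets.

The generator emulates what the analysis assumes about real iPSC call sets:
tens-to-hundreds of heterozygous de novo mutations per line, SNV contexts
drawn from a configurable 96-type signature (UV-like by default: C->T at
dipyrimidine sites), and a configurable indel fraction. It samples the
mutation *type* first and then a uniformly random matching context position,
so the realized spectrum tracks the input signature rather than
signature x context-frequency — which makes parameter recovery exact in
expectation and directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CANONICAL_TYPES,
    DIPYRIMIDINE_MASK,
    CT_MASK,
    DNA_BASES,
    PURINES,
    COMPLEMENT,
    GenerationError,
    IndelRecord,
    MutationSet,
    ParameterError,
    ReferenceSequence,
    SnvRecord,
    revcomp,
)

__all__ = [
    "GeneratorConfig",
    "generate_reference",
    "uv_signature",
    "flat_signature",
    "generate_mutation_set",
]


def flat_signature() -> np.ndarray:
    """The uniform null signature: every one of the 96 types gets 1/96."""
    return np.full(96, 1.0 / 96.0)


def uv_signature(dipyrimidine_mass: float = 0.9) -> np.ndarray:
    """A UV-like signature: ``dipyrimidine_mass`` spread uniformly over the
    12 C->T types with a pyrimidine 5' or 3' neighbour, the remainder
    uniformly over the other 84 types.

    With the default mass 0.9 the five largest entries are all
    C->T-at-dipyrimidine types, mimicking the skew UV photoproducts leave in
    nucleotide-excision-repair-deficient cells.
    """
    if not 0 < dipyrimidine_mass <= 1:
        raise ParameterError("dipyrimidine_mass must be in (0, 1]")
    target = CT_MASK & DIPYRIMIDINE_MASK
    sig = np.zeros(96)
    sig[target] = dipyrimidine_mass / target.sum()
    if dipyrimidine_mass < 1:
        sig[~target] = (1 - dipyrimidine_mass) / (~target).sum()
    return sig


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cell line.

    Defaults mirror the observed burden of a repair-deficient line (~229
    SNVs + 24 indels), a human-like GC content of 0.41, and a UV-like
    signature with 90% of its mass on C->T at dipyrimidine sites.
    """

    seq_length: int = 1_000_000
    gc_content: float = 0.41
    n_snv: int = 229
    n_indel: int = 24
    signature: np.ndarray = field(default_factory=uv_signature)
    indel_size_range: tuple[int, int] = (1, 10)
    seed: int = 0

    def __post_init__(self):
        if self.seq_length < 3:
            raise ParameterError("seq_length must be >= 3")
        if not 0 <= self.gc_content <= 1:
            raise ParameterError("gc_content must be in [0, 1]")
        if self.n_snv < 0 or self.n_indel < 0:
            raise ParameterError("mutation counts must be nonnegative")
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (96,) or np.any(sig < 0) or abs(sig.sum() - 1) > 1e-9:
            raise ParameterError("signature must be a nonnegative 96-vector summing to 1")
        self.signature = sig
        lo, hi = self.indel_size_range
        if not 1 <= lo <= hi <= 50:
            raise ParameterError("indel_size_range must satisfy 1 <= lo <= hi <= 50")


def generate_reference(config: GeneratorConfig, name: str = "chrS") -> ReferenceSequence:
    """I.i.d. bases with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2,
    reproducible for a fixed seed (dedicated substream, so the same config
    yields the same sequence whether or not mutations are generated)."""
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list(DNA_BASES)), size=config.seq_length, p=probs)
    return ReferenceSequence(name=name, bases="".join(bases))


def _context_positions(reference: ReferenceSequence) -> dict[str, np.ndarray]:
    """Map each pyrimidine-strand trinucleotide context (32 possible) to the
    1-based positions offering it. Ends and N-containing contexts excluded."""
    out: dict[str, list[int]] = {}
    b = reference.bases
    for pos in range(2, reference.length):
        tri = b[pos - 2 : pos + 1]
        if "N" in tri:
            continue
        if tri[1] in PURINES:
            tri = revcomp(tri)
        out.setdefault(tri, []).append(pos)
    return {k: np.array(v) for k, v in out.items()}


def generate_mutation_set(
    reference: ReferenceSequence, config: GeneratorConfig, sample: str = "synthetic"
) -> MutationSet:
    """Draw exactly ``n_snv`` SNVs and ``n_indel`` indels on ``reference``.

    SNVs: draw a 96-type from the signature, then a uniform position among
    those whose pyrimidine-strand trinucleotide matches the type's context,
    then apply the substitution (complemented when the reference base is a
    purine). Indels: uniform anchor position, uniform size in
    ``indel_size_range``, deletion or insertion with equal probability,
    uniform insert sequence. Sites never collide; output is deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    ctx_pos = _context_positions(reference)

    support = np.nonzero(config.signature > 0)[0]
    missing = [
        CANONICAL_TYPES[i].context
        for i in support
        if CANONICAL_TYPES[i].context not in ctx_pos
    ]
    if missing and config.n_snv > 0:
        raise GenerationError(
            f"reference offers no position for required context(s) {sorted(set(missing))[:5]}"
        )

    used: set[int] = set()
    budget = 1000 * max(config.n_snv + config.n_indel, 1)
    snvs: list[SnvRecord] = []
    type_draws = rng.choice(96, size=config.n_snv, p=config.signature)
    for t_idx in type_draws:
        mtype = CANONICAL_TYPES[t_idx]
        positions = ctx_pos[mtype.context]
        while True:
            if budget <= 0:
                raise GenerationError(
                    "site-collision retry budget exhausted; reference too short "
                    "for the requested mutation count"
                )
            budget -= 1
            pos = int(positions[rng.integers(len(positions))])
            if pos not in used:
                break
        used.add(pos)
        ref_base = reference.base(pos)
        alt = mtype.alt if ref_base not in PURINES else COMPLEMENT[mtype.alt]
        snvs.append(SnvRecord(reference.name, pos, ref_base, alt, sample))

    lo, hi = config.indel_size_range
    indels: list[IndelRecord] = []
    for _ in range(config.n_indel):
        size = int(rng.integers(lo, hi + 1))
        is_deletion = bool(rng.integers(2))
        while True:
            if budget <= 0:
                raise GenerationError(
                    "site-collision retry budget exhausted while placing indels"
                )
            budget -= 1
            # anchor needs a following run for deletions; avoid N anywhere in REF
            max_anchor = reference.length - size if is_deletion else reference.length
            if max_anchor < 1:
                raise GenerationError("reference shorter than requested deletion size")
            pos = int(rng.integers(1, max_anchor + 1))
            if pos in used:
                continue
            if is_deletion:
                allele = reference.slice(pos, pos + size)
                if "N" in allele:
                    continue
                ref_a, alt_a = allele, allele[0]
            else:
                anchor = reference.base(pos)
                if anchor == "N":
                    continue
                insert = "".join(rng.choice(np.array(list(DNA_BASES)), size=size))
                ref_a, alt_a = anchor, anchor + insert
            break
        used.add(pos)
        indels.append(IndelRecord(reference.name, pos, ref_a, alt_a, sample))

    return MutationSet(sample=sample, snvs=snvs, indels=indels)
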