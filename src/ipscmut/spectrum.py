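"""96-type trinucleotide mutation spectra and signature matching.

Every single-nucleotide substitution is classified by the trinucleotide in
which the mutated base sits. Substitutions at a purine reference base are
reverse-complemented first (pyrimidine-strand convention), giving
6 substitution classes x 16 flanking contexts = 96 mutation types. Spectra
are integer count vectors over those types; matching against a catalog of
normalized signatures uses cosine similarity, which is scale-invariant so
raw counts can be compared directly with unit-sum signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CANONICAL_KEYS,
    CANONICAL_TYPES,
    DIPYRIMIDINE_MASK,
    PURINES,
    PYRIMIDINES,
    TYPE_INDEX,
    ConsistencyError,
    MutationSet,
    MutationType96,
    ParameterError,
    ReferenceSequence,
    SignatureCatalog,
    UndefinedStatisticError,
    revcomp,
)

__all__ = [
    "Excluded",
    "TrinucleotideSpectrum",
    "classify_snv",
    "build_spectrum",
    "cosine_similarity",
    "rank_signatures",
    "ct_ga_fraction",
    "dipyrimidine_fraction",
    "MutationType96",
    "SignatureCatalog",
]


@dataclass(frozen=True)
class Excluded:
    """Marker returned when an SNV has no usable trinucleotide context."""

    reason: str


@dataclass
class TrinucleotideSpectrum:
    """Counts over the 96 canonical mutation types plus an exclusion tally."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=int))
    n_excluded: int = 0
    exclusion_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ParameterError(f"spectrum needs 96 bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ParameterError("spectrum counts must be nonnegative")

    @property
    def n_classified(self) -> int:
        return int(self.counts.sum())

    def count(self, mutation_type: MutationType96) -> int:
        return int(self.counts[TYPE_INDEX[mutation_type]])

    def frequencies(self) -> np.ndarray:
        if self.n_classified == 0:
            raise UndefinedStatisticError("empty spectrum has no frequencies")
        return self.counts / self.n_classified

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CANONICAL_KEYS), name="count")


def classify_snv(
    reference: ReferenceSequence, snv
) -> MutationType96 | Excluded:
    """Classify one SNV into its 96-type bin.

    The reference base at the SNV position must match the record's REF
    allele (:class:`ConsistencyError` otherwise). Positions at either end of
    the sequence, or whose context contains N, are excluded with a reason.
    """
    ref_base = reference.base(snv.pos)
    if ref_base != snv.ref:
        raise ConsistencyError(
            f"SNV {snv.chrom}:{snv.pos} REF {snv.ref} != reference base {ref_base}"
        )
    if snv.pos == 1:
        return Excluded("no 5' context")
    if snv.pos == reference.length:
        return Excluded("no 3' context")
    tri = reference.trinucleotide(snv.pos)
    if "N" in tri or snv.ref == "N":
        return Excluded("N in context")

    if snv.ref in PURINES:
        tri = revcomp(tri)
        alt = revcomp(snv.alt)
    else:
        alt = snv.alt
    return MutationType96(
        ref_pyrimidine=tri[1], alt=alt, five_prime=tri[0], three_prime=tri[2]
    )


def build_spectrum(
    reference: ReferenceSequence | dict[str, ReferenceSequence],
    mutation_set: MutationSet,
) -> TrinucleotideSpectrum:
    """Aggregate classify_snv over a MutationSet; indels are ignored.

    ``reference`` may be a single sequence or a name->sequence mapping for
    multi-contig call sets.
    """
    refs = (
        reference
        if isinstance(reference, dict)
        else {reference.name: reference}
    )
    spec = TrinucleotideSpectrum()
    for snv in mutation_set.snvs:
        try:
            ref_seq = refs[snv.chrom]
        except KeyError:
            raise ConsistencyError(f"no reference sequence named {snv.chrom!r}") from None
        result = classify_snv(ref_seq, snv)
        if isinstance(result, Excluded):
            spec.n_excluded += 1
            spec.exclusion_reasons[result.reason] = (
                spec.exclusion_reasons.get(result.reason, 0) + 1
            )
        else:
            spec.counts[TYPE_INDEX[result]] += 1
    return spec


def _as_vector(x) -> np.ndarray:
    if isinstance(x, TrinucleotideSpectrum):
        return x.counts.astype(float)
    return np.asarray(x, dtype=float)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two nonnegative 96-vectors (or spectra).

    Scale-invariant, so integer count spectra compare directly against
    unit-sum signatures. Raises on a zero vector, where the similarity is
    undefined.
    """
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ParameterError(f"shape mismatch {va.shape} vs {vb.shape}")
    if np.any(va < 0) or np.any(vb < 0):
        raise ParameterError("cosine similarity is defined here for nonnegative vectors")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedStatisticError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def rank_signatures(
    spectrum, catalog: SignatureCatalog
) -> list[tuple[str, float]]:
    """Rank catalog signatures by cosine similarity to ``spectrum``,
    descending; ties keep catalog order. The full list is returned."""
    if len(catalog) == 0:
        raise ParameterError("signature catalog is empty")
    sims = [(name, cosine_similarity(spectrum, vec)) for name, vec in catalog.items()]
    # stable sort preserves catalog order among ties
    return sorted(sims, key=lambda kv: -kv[1])


def ct_ga_fraction(mutation_set: MutationSet) -> float:
    """Fraction of SNVs that are C->T or G->A transitions, on raw alleles
    (before any strand collapse)."""
    if mutation_set.n_snv == 0:
        raise UndefinedStatisticError("C>T/G>A fraction undefined with no SNVs")
    hits = sum(
        1
        for s in mutation_set.snvs
        if (s.ref, s.alt) in {("C", "T"), ("G", "A")}
    )
    return hits / mutation_set.n_snv


def dipyrimidine_fraction(spectrum: TrinucleotideSpectrum) -> float:
    """Fraction of classified SNVs whose pyrimidine-strand 5' or 3'
    neighbour is itself a pyrimidine — the substrate of UV photoproducts."""
    if spectrum.n_classified == 0:
        raise UndefinedStatisticError("dipyrimidine fraction undefined for empty spectrum")
    return float(spectrum.counts[DIPYRIMIDINE_MASK].sum() / spectrum.n_classified)


def plot_spectrum(spectrum: TrinucleotideSpectrum, path, title: str = "") -> None:
    """Write a 96-bar spectrum chart (one colour per substitution class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [f"{t.ref_pyrimidine}>{t.alt}" for t in CANONICAL_TYPES]
    palette = {
        "C>A": "#03bcee", "C>G": "#010101", "C>T": "#e32926",
        "T>A": "#cac9c9", "T>C": "#a1ce63", "T>G": "#ebc6c4",
    }
    fig, ax = plt.subplots(figsize=(14, 3.5))
    ax.bar(range(96), spectrum.counts, color=[palette[c] for c in classes])
    ax.set_xticks(range(96))
    ax.set_xticklabels([t.context for t in CANONICAL_TYPES], rotation=90, fontsize=5)
    ax.set_ylabel("number of single-nucleotide mutations")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
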