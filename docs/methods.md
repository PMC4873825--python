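# Methods

## Mutation records and coordinates

All coordinates are 1-based inclusive (VCF-native); BED's 0-based half-open
starts are converted at the parsing boundary. SNVs are single-base
substitutions; indels are VCF-style anchored alleles with unequal lengths,
restricted to ≤ 50 bp of length change (the short-indel scope of exome-style
calling). Symbolic/breakend alleles, multi-nucleotide substitutions and
longer indels are skipped on read with a logged warning and a per-file
count, rather than aborting a whole call set. Multi-allelic rows are split
into one record per alternate allele so spectrum counting stays atomic.
Genotypes are parsed only to assign records to samples; no statistic here
uses zygosity.

## The 96-type spectrum

A substitution is keyed by (reference pyrimidine, alternate, 5′ base, 3′
base) after reverse-complementing any purine-reference record, the standard
pyrimidine-strand convention. Canonical ordering is reference C before T,
then alternate, 5′ and 3′ base alphabetically; keys render as `A[C>T]G`.
SNVs at a sequence end, or with N in the trinucleotide, are excluded and
tallied with a reason — conservation (classified + excluded = input SNVs)
is an invariant, not a best effort.

"Dipyrimidine" means: the mutated pyrimidine has at least one pyrimidine
immediate neighbour on the pyrimidine strand. This matches the substrate of
UV-induced pyrimidine dimers; of the 16 C>T contexts, 12 are dipyrimidine.

Signature matching uses cosine similarity on raw counts versus unit-sum
signatures (cosine is scale-invariant, so no renormalization is needed).
Ties in the ranking preserve catalog order. Cosine was chosen because it is
the community default for spectrum-to-signature comparison; no attempt is
made to reproduce any particular published catalog assignment, which would
require the exact catalog version and per-site mutation lists.

## Synthetic data generator

The generator defines the conditions the rest of the package is tested
under:

- Reference: i.i.d. bases, GC content 0.41 (human-like), default length
  1 Mb (tests use 50–200 kb for speed; at those lengths every one of the 32
  contexts occurs thousands of times, which is what matters).
- SNVs: default 229 per set, matching the observed burden of a
  nucleotide-excision-repair-deficient line; contexts follow a configurable
  96-type signature, by default a UV-like signature placing 90% of its mass
  uniformly on the 12 C>T-at-dipyrimidine types and the rest uniformly
  elsewhere.
- Indels: default 24 per set (indel fraction ≈ 9.5%), uniform positions,
  uniform sizes in 1–10 bp, deletion/insertion with equal probability,
  uniform insert sequence. No indel context model is imposed — none is
  established for this setting.

Sampling is type-first: draw a mutation type from the signature, then a
uniform position among those offering that type's pyrimidine-strand
context. A finite reference offers unequal context counts, so sampling
positions first would realize signature × context-frequency rather than the
signature itself; type-first sampling makes the expected realized spectrum
equal the input signature exactly, which is what makes parameter-recovery
tests sharp. Positions 1 and L are never used (no full context), sites never
collide (retry budget 1000 × total count, then a hard error), and a
requested context absent from the reference is an immediate error naming
the context.

Randomness: one `numpy` Generator seeded as `[seed, 0]` for the reference
and `[seed, 1]` for the mutation stream, so the same seed yields the same
reference whether or not mutations are drawn. Fixing the seed fixes the
output byte-for-byte through the VCF writer.

What the generator does *not* emulate: read-level errors, coverage, variant
allele fractions, germline background, mutation hotspots, or any
indel-context structure. Passing recovery tests therefore demonstrates the
pipeline's correctness on signature-structured input, not robustness to
caller artifacts.

## Colony-passaging clonality model

State: colonies per founder clone, starting at `n_colonies / n_clones0`
each (equal representation is enforced to be integral). One passage = draw
`n_picked` colonies without replacement — multivariate hypergeometric over
the clone composition, since colonies are physical objects picked from a
dish — then multiply each clone's picked count by `split_factor`. The clone
count at a passage is the number of distinct clones among the picked
colonies (identical to counting after splitting, which preserves clone
identity). Passage 0 is the starting condition; picks define passages 1…n.
Clone loss is irreversible, so per-trial clone counts are non-increasing —
asserted as an invariant.

The Monte Carlo engine loops trials with numpy's
`multivariate_hypergeometric`; 10,000 trials × 20 passages runs in a few
seconds.

The exact engine exploits clone exchangeability: after any passage the
state is fully described by the *multiset* of per-clone picked counts, an
integer partition of `n_picked` with at most `min(n_clones0, n_picked)`
parts (627 partitions for a pick of 20). For a state with clone groups of
equal colony counts, the transition law is assembled group-wise: for a
group of `m` clones with `a` colonies each, the weight of an unordered
per-clone pick multiset is the number of ordered clone assignments times
∏ C(a, cᵢ); group results are convolved under the constraint that total
picks equal `n_picked` and divided by C(total colonies, n_picked). The
transition matrix is passage-invariant and built lazily row-by-row with the
group enumerations memoized; 20 passages of the 627-state model complete in
about ten seconds. A configurable state cap raises a capacity error
(advising Monte Carlo) for models whose partition space would be too large.

The two engines are developed independently enough to serve as mutual
oracles: the test suite requires bin-by-bin agreement within three binomial
standard errors. Under the default parameters (140 colonies, 20 clones,
pick 20, split 7) the exact probability of descending from at most two
founder clones at passage 20 is 0.5968; the value quoted in the source
study for these conditions is 85%, which this implementation does not
reproduce under any reading of the stated procedure we examined (picking
with replacement, noisy expansion, population-fraction summaries, or
passage off-by-one all stay well away from it at passage 20; the computed
law reaches 0.85 only around passage 29). The package reports the computed
value.

## Burden statistics

Fold change is the ratio of mean per-line SNV counts (quoted to one
decimal). Indel fractions are pooled per class: ΣI / (ΣS + ΣI), quoted to
0.1%. A printed pooled fraction can be inverted to an integer indel total
via I = round(S·f/(1−f)) when a source quotes the fraction but not the
count; for the packaged fixture this reconstruction gives 72 ATM indels
(72/239 = 30.1%, the only self-consistent integer).

The Fisher exact test conditions on both margins; the two-sided p-value is
the total hypergeometric probability of all tables no more probable than
the observed one (probability-mass rule, with a 1+10⁻⁷ relative slack
guarding ties against roundoff — the convention of the major statistical
packages). Log-factorials via `gammaln` keep relative precision at
p ≈ 10⁻¹¹. When every table in the support qualifies, p is exactly 1 by the
law of total probability, and the implementation returns it as such.
p-values are clamped to (0, 1]. The test is validated against independent
hypergeometric enumeration and an established implementation on randomized
margins.

Because the exact conditional test is discrete, its null p-values are
mildly conservative rather than exactly uniform; the type-I test asserts
sub-uniformity within binomial noise plus a closeness-to-uniform sanity
bound, using per-line counts drawn from Poisson with identical means for
both classes (the generator itself emits exact configured counts, which
would make a two-class null comparison degenerate).

## Annotation

Region precedence is fixed as CDS > UTR > ncRNA > intron > intergenic
across all overlapping intervals and transcripts; positions covered by
nothing are intergenic. Interval bounds are inclusive on both ends.
Consequences translate the affected codon before and after substitution
with the standard genetic code; minus-strand transcripts are evaluated on
the reverse complement of the spliced CDS. Stopgain is any change producing
a stop, stoploss any change removing one; all 576 single-base codon changes
are checked exhaustively against a direct genetic-code lookup. Splice-site
and regulatory annotation are out of scope by design: a CDS SNV with no
covering transcript model is a hard error rather than a silent guess.

## Command-line interface

Each subcommand writes a `manifest.json` (package version, subcommand,
parameters, seed) beside its outputs; identical argv and seed give
byte-identical outputs. JSON reports carry a `schema_version` field
(currently 1). Logs go to stderr.

## Problem sizes

Default test and demonstration sizes — 50–200 kb references, 500–1000 SNVs,
10,000 Monte Carlo trials, 627-state exact DP — were chosen so every
distributional check has comfortable statistical power (multinomial /
binomial 3σ bands) while the whole suite runs in well under a minute per
module.
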