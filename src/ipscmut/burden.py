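"""Mutation-burden comparisons between repair-deficiency classes.

Per-line SNV/indel counts are compared between two labelled classes (e.g. a
nucleotide-excision-repair-deficient line set versus a double-strand-break-
repair-deficient one) via the mean fold change in SNV count, each class's
indel fraction, and a two-sided Fisher exact test on the pooled
class x mutation-kind 2x2 table. The Fisher test is implemented here from
first principles (log-factorial hypergeometric enumeration with the
probability-mass two-sided rule), since that contrast is the statistic this
package exists to compute.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MissingKeyError, ParameterError, UndefinedStatisticError

__all__ = [
    "BurdenRow",
    "BurdenTable",
    "ContingencyTable2x2",
    "read_burden_tsv",
    "load_paper_burden",
    "fold_change",
    "indel_fraction",
    "reconstruct_indel_total",
    "fisher_exact_two_sided",
    "compare_classes",
]


@dataclass(frozen=True)
class BurdenRow:
    sample: str
    label: str
    n_snv: int
    n_indel: int
    passage_number: int | None = None

    def __post_init__(self):
        if not self.label:
            raise ParameterError("burden row label must be non-empty")
        if self.n_snv < 0 or self.n_indel < 0:
            raise ParameterError("burden counts must be nonnegative")


@dataclass
class BurdenTable:
    rows: list[BurdenRow] = field(default_factory=list)

    def labels(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.label not in seen:
                seen.append(r.label)
        return seen

    def rows_for(self, label: str) -> list[BurdenRow]:
        rows = [r for r in self.rows if r.label == label]
        if not rows:
            raise MissingKeyError(f"no rows with label {label!r}")
        return rows

    def snv_counts(self, label: str) -> list[int]:
        return [r.n_snv for r in self.rows_for(label)]

    def totals(self, label: str) -> tuple[int, int]:
        rows = self.rows_for(label)
        return sum(r.n_snv for r in rows), sum(r.n_indel for r in rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample, r.label, r.n_snv, r.n_indel, r.passage_number)
                for r in self.rows
            ],
            columns=["sample", "label", "n_snv", "n_indel", "passage_number"],
        )


def read_burden_tsv(path: str | Path) -> BurdenTable:
    """Read a burden table TSV with columns sample, label, n_snv, n_indel
    and optionally passage_number. Lines starting with '#' are comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "label", "n_snv", "n_indel"}
    if not required <= set(df.columns):
        raise ParameterError(f"burden TSV needs columns {sorted(required)}")
    rows = []
    for _, r in df.iterrows():
        passage = None
        if "passage_number" in df.columns and pd.notna(r["passage_number"]):
            passage = int(r["passage_number"])
        rows.append(
            BurdenRow(str(r["sample"]), str(r["label"]), int(r["n_snv"]), int(r["n_indel"]), passage)
        )
    return BurdenTable(rows)


def load_paper_burden() -> BurdenTable:
    """The packaged fixture of published per-line burdens (see the file's
    comments for which entries are reconstructed rather than printed)."""
    resource = importlib.resources.files("ipscmut").joinpath("data/burden_paper.tsv")
    with importlib.resources.as_file(resource) as p:
        return read_burden_tsv(p)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Class x mutation-kind counts: rows are classes, columns (SNV, indel)."""

    a: int  # class A SNVs
    b: int  # class A indels
    c: int  # class B SNVs
    d: int  # class B indels

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ParameterError("contingency table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fold_change(group_a: list[int], group_b: list[int]) -> float:
    """Ratio of mean per-line counts, group A over group B (raw; round to
    one decimal when quoting)."""
    if not group_a or not group_b:
        raise ParameterError("both groups must be non-empty")
    mean_b = float(np.mean(group_b))
    if mean_b == 0:
        raise ParameterError("group B mean is zero; fold change undefined")
    return float(np.mean(group_a)) / mean_b


def indel_fraction(table: BurdenTable, label: str) -> float:
    """Pooled indel fraction for one class: sum(indel) / sum(snv + indel)."""
    n_snv, n_indel = table.totals(label)
    total = n_snv + n_indel
    if total == 0:
        raise UndefinedStatisticError(f"class {label!r} has no mutations")
    return n_indel / total


def reconstruct_indel_total(snv_total: int, indel_fraction_printed: float) -> int:
    """Invert a printed pooled indel fraction f = I/(S+I) to the integer
    indel total I = round(S*f/(1-f)) given the SNV total S."""
    if not 0 <= indel_fraction_printed < 1:
        raise ParameterError("fraction must be in [0, 1)")
    return round(snv_total * indel_fraction_printed / (1 - indel_fraction_printed))


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_TWO_SIDED_SLACK = 1 + 1e-7  # guards equal-probability tables against roundoff


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int, n: int) -> np.ndarray:
    """log P(top-left cell = a) for fixed margins, via log-factorials."""
    b = r1 - a
    c = c1 - a
    d = r2 - c
    logfact = gammaln(np.array([r1, r2, c1, n - c1], dtype=float) + 1).sum()
    return (
        logfact
        - gammaln(a + 1.0)
        - gammaln(b + 1.0)
        - gammaln(c + 1.0)
        - gammaln(d + 1.0)
        - gammaln(n + 1.0)
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact test on a 2x2 table.

    Conditions on both margins; the two-sided p is the total hypergeometric
    probability of every table at least as extreme as (i.e. no more probable
    than) the observed one, the probability-mass rule. Computed with
    log-factorials so even p ~ 1e-11 keeps full relative precision. Returns
    p clamped to (0, 1].
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table is possible
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1, n)
    log_obs = _log_hypergeom_pmf(np.array([table.a]), r1, r2, c1, n)[0]
    mask = logp <= log_obs + np.log(_TWO_SIDED_SLACK)
    if mask.all():
        return 1.0  # every table counts as extreme: total probability is 1
    # sum in linear space relative to the max for stability
    shift = logp[mask].max()
    p = float(np.exp(shift) * np.exp(logp[mask] - shift).sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# class comparison report
# ---------------------------------------------------------------------------

def compare_classes(table: BurdenTable, label_a: str, label_b: str) -> dict:
    """Bundle the burden contrast between two classes into one report dict.

    Contains per-class totals, the SNV fold change (A over B), both indel
    fractions, the pooled 2x2 table and its two-sided Fisher p, plus the
    one-decimal / percent / 2-significant-figure renderings used when
    quoting. Pure function of the table: identical inputs give identical
    output.
    """
    snv_a, indel_a = table.totals(label_a)
    snv_b, indel_b = table.totals(label_b)
    fold = fold_change(table.snv_counts(label_a), table.snv_counts(label_b))
    frac_a = indel_fraction(table, label_a)
    frac_b = indel_fraction(table, label_b)
    ct = ContingencyTable2x2(snv_a, indel_a, snv_b, indel_b)
    p = fisher_exact_two_sided(ct)
    return {
        "label_a": label_a,
        "label_b": label_b,
        "totals": {
            label_a: {"n_snv": snv_a, "n_indel": indel_a},
            label_b: {"n_snv": snv_b, "n_indel": indel_b},
        },
        "n_sites_total": snv_a + indel_a + snv_b + indel_b,
        "fold_change_snv": fold,
        "fold_change_snv_rounded": round(fold, 1),
        "indel_fraction": {label_a: frac_a, label_b: frac_b},
        "indel_percent_rounded": {
            label_a: round(100 * frac_a, 1),
            label_b: round(100 * frac_b, 1),
        },
        "contingency_table": [[snv_a, indel_a], [snv_b, indel_b]],
        "fisher_p_two_sided": p,
        "fisher_p_2sf": float(f"{p:.1e}"),
    }
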