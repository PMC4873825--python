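"""Colony-passaging clonality model: Monte Carlo and an exact oracle.

A culture starts as ``n_colonies`` colonies contributed equally by
``n_clones0`` independent founder clones. Each passage, ``n_picked``
colonies are drawn without replacement (a multivariate hypergeometric draw
over the clone composition) and each picked colony is split into
``split_factor`` new colonies, restoring the dish. Clones absent from a pick
are lost forever, so the number of surviving founder clones drifts downward.
The quantity of interest is the distribution of that clone count per
passage.

Two engines are provided. ``simulate_passages`` is a plain Monte Carlo over
trials. ``exact_distribution`` computes the same law with no randomness by
dynamic programming over unordered pick compositions: after any passage the
state is fully described by the multiset of per-clone picked counts (an
integer partition of ``n_picked``), because splitting is deterministic and
clones are exchangeable. Transition probabilities between partitions are
multivariate hypergeometric mass aggregated over clone relabelings.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import CapacityError, MissingKeyError, ParameterError

__all__ = [
    "PassagingModel",
    "CloneCountDistribution",
    "simulate_passages",
    "exact_distribution",
    "prob_at_most_k",
]


@dataclass(frozen=True)
class PassagingModel:
    """Parameters of the passaging bottleneck (defaults: the study's dish)."""

    n_colonies: int = 140
    n_clones0: int = 20
    n_picked: int = 20
    split_factor: int = 7

    def __post_init__(self):
        if min(self.n_colonies, self.n_clones0, self.n_picked, self.split_factor) < 1:
            raise ParameterError("all model parameters must be positive integers")
        if self.n_picked * self.split_factor != self.n_colonies:
            raise ParameterError(
                f"n_picked * split_factor must equal n_colonies "
                f"({self.n_picked} * {self.split_factor} != {self.n_colonies})"
            )
        if self.n_clones0 > self.n_picked:
            raise ParameterError("n_clones0 must not exceed n_picked")
        if self.n_colonies % self.n_clones0 != 0:
            raise ParameterError(
                "equal initial representation requires n_colonies divisible by n_clones0"
            )

    @property
    def colonies_per_clone0(self) -> int:
        return self.n_colonies // self.n_clones0


@dataclass
class CloneCountDistribution:
    """Per-passage probability vectors over clone counts 1..n_clones0.

    ``per_passage[p]`` is an array of length ``n_clones0 + 1`` whose entry k
    is P(exactly k distinct founder clones survive at passage p); entry 0 is
    always 0. ``n_trials`` is the Monte Carlo trial count, or the string
    ``"exact"`` for the DP engine.
    """

    model: PassagingModel
    per_passage: dict[int, np.ndarray] = field(default_factory=dict)
    n_trials: int | str = 0

    def passages(self) -> list[int]:
        return sorted(self.per_passage)

    def probabilities(self, passage: int) -> np.ndarray:
        try:
            return self.per_passage[passage]
        except KeyError:
            raise MissingKeyError(f"passage {passage} not in distribution") from None

    def to_frame(self):
        """Passages x clone-count probability table (the Fig-3A-style view)."""
        import pandas as pd

        rows = {p: self.per_passage[p][1:] for p in self.passages()}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = range(1, self.model.n_clones0 + 1)
        df.index.name = "passage"
        df.columns.name = "n_clones"
        return df


def prob_at_most_k(dist: CloneCountDistribution, passage: int, k: int) -> float:
    """Cumulative probability that at most ``k`` founder clones survive."""
    if not 1 <= k <= dist.model.n_clones0:
        raise ParameterError(f"k must be in 1..{dist.model.n_clones0}")
    probs = dist.probabilities(passage)
    return float(probs[: k + 1].sum())


# ---------------------------------------------------------------------------
# Monte Carlo engine
# ---------------------------------------------------------------------------

def simulate_passages(
    model: PassagingModel,
    n_passages: int,
    n_trials: int,
    seed: int,
    return_trajectories: bool = False,
):
    """Monte Carlo clone-count distributions for passages 0..n_passages.

    Each trial tracks the colony count per clone, draws ``n_picked``
    colonies without replacement each passage, and records the number of
    distinct clones among them. Deterministic given ``seed``. With
    ``return_trajectories`` the per-trial clone-count paths (trials x
    passages+1 array) are returned alongside the distribution.
    """
    if n_passages < 0:
        raise ParameterError("n_passages must be >= 0")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    m = model
    traj = np.empty((n_trials, n_passages + 1), dtype=np.int64)
    traj[:, 0] = m.n_clones0
    for t in range(n_trials):
        colonies = np.full(m.n_clones0, m.colonies_per_clone0, dtype=np.int64)
        for p in range(1, n_passages + 1):
            picked = rng.multivariate_hypergeometric(colonies, m.n_picked)
            colonies = picked * m.split_factor
            traj[t, p] = int((picked > 0).sum())

    dist = CloneCountDistribution(model=m, n_trials=n_trials)
    for p in range(n_passages + 1):
        vec = np.zeros(m.n_clones0 + 1)
        counts = np.bincount(traj[:, p], minlength=m.n_clones0 + 1)
        vec[: len(counts)] = counts / n_trials
        dist.per_passage[p] = vec
    if return_trajectories:
        return dist, traj
    return dist


# ---------------------------------------------------------------------------
# exact engine: DP over integer partitions of n_picked
# ---------------------------------------------------------------------------

def _bounded_partitions(total: int, max_parts: int, max_val: int):
    """Partitions of ``total`` into at most ``max_parts`` positive parts each
    <= ``max_val``, as descending tuples."""
    if total == 0:
        yield ()
        return
    if max_parts == 0 or max_val == 0:
        return
    for first in range(min(total, max_val), 0, -1):
        for rest in _bounded_partitions(total - first, max_parts - 1, first):
            yield (first,) + rest


@lru_cache(maxsize=None)
def _group_pick_weights(colonies_each: int, n_clones: int, cap: int):
    """For a group of ``n_clones`` exchangeable clones with ``colonies_each``
    colonies apiece: for every total j <= cap picked from the group, the
    unordered per-clone pick multisets and their combinatorial weights.

    The weight of a multiset is (#ordered assignments) x prod C(a, c_i):
    the number of ways to pick those colony counts from distinguishable
    colonies. Returns {j: [(parts_tuple, weight), ...]}.
    """
    a, m = colonies_each, n_clones
    out: dict[int, list[tuple[tuple[int, ...], int]]] = {}
    for j in range(0, min(m * a, cap) + 1):
        entries = []
        for parts in _bounded_partitions(j, m, a):
            mult = Counter(parts)
            n_zero = m - len(parts)
            ways = math.factorial(m) // math.factorial(n_zero)
            for v in mult.values():
                ways //= math.factorial(v)
            for c in parts:
                ways *= math.comb(a, c)
            entries.append((parts, ways))
        out[j] = entries
    return out


def _transition(colony_groups: list[tuple[int, int]], n_picked: int):
    """Distribution over pick partitions given clone groups.

    ``colony_groups``: list of (colonies_per_clone, n_clones). Returns
    {partition_of_n_picked: probability}; a partition's parts are the picked
    counts of the surviving clones, descending.
    """
    total_colonies = sum(a * m for a, m in colony_groups)
    dists = [_group_pick_weights(a, m, n_picked) for a, m in colony_groups]
    caps = [max(d) for d in dists]
    results: dict[tuple[int, ...], int] = {}

    def rec(i: int, picked: int, acc: tuple[int, ...], weight: int):
        if i == len(dists):
            if picked == n_picked:
                key = tuple(sorted(acc, reverse=True))
                results[key] = results.get(key, 0) + weight
            return
        remaining_cap = sum(caps[i + 1 :])
        for j, entries in dists[i].items():
            if picked + j > n_picked:
                break
            if picked + j + remaining_cap < n_picked:
                continue
            for parts, w in entries:
                rec(i + 1, picked + j, acc + parts, weight * w)

    rec(0, 0, (), 1)
    denom = math.comb(total_colonies, n_picked)
    return {k: w / denom for k, w in results.items()}


def exact_distribution(
    model: PassagingModel, n_passages: int, max_states: int = 200_000
) -> CloneCountDistribution:
    """Exact clone-count distributions for passages 0..n_passages.

    State space: integer partitions of ``n_picked`` (627 for a pick of 20).
    The passage-invariant transition matrix between partitions is built
    once; marginals over the partition length give the clone-count law.
    Raises :class:`CapacityError` when the partition space exceeds
    ``max_states`` (use the Monte Carlo engine instead).
    """
    if n_passages < 0:
        raise ParameterError("n_passages must be >= 0")
    m = model
    # at most n_clones0 clones can ever hold colonies, so pick partitions
    # never have more parts than that
    states = list(
        _bounded_partitions(m.n_picked, min(m.n_clones0, m.n_picked), m.n_picked)
    )
    if len(states) > max_states:
        raise CapacityError(
            f"{len(states)} pick partitions exceed the cap {max_states}; "
            "use simulate_passages"
        )
    index = {s: i for i, s in enumerate(states)}

    dist = CloneCountDistribution(model=m, n_trials="exact")
    start_vec = np.zeros(m.n_clones0 + 1)
    start_vec[m.n_clones0] = 1.0
    dist.per_passage[0] = start_vec
    if n_passages == 0:
        return dist

    # passage 1: transition from the equal-representation starting dish
    v = np.zeros(len(states))
    for partition, p in _transition(
        [(m.colonies_per_clone0, m.n_clones0)], m.n_picked
    ).items():
        v[index[partition]] = p

    transition_rows: list[dict[tuple[int, ...], float] | None] = [None] * len(states)

    def marginal(vec: np.ndarray) -> np.ndarray:
        out = np.zeros(m.n_clones0 + 1)
        for s, i in index.items():
            out[len(s)] += vec[i]
        return out

    dist.per_passage[1] = marginal(v)
    for passage in range(2, n_passages + 1):
        nv = np.zeros(len(states))
        for s, i in index.items():
            if v[i] == 0.0:
                continue
            row = transition_rows[i]
            if row is None:
                groups = [
                    (m.split_factor * part, mult)
                    for part, mult in Counter(s).items()
                ]
                row = _transition(groups, m.n_picked)
                transition_rows[i] = row
            for target, p in row.items():
                nv[index[target]] += v[i] * p
        v = nv
        dist.per_passage[passage] = marginal(v)
    return dist
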