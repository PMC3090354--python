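"""Pairwise domain co-occurrence context scores from architecture corpora.

A domain architecture is the ordered list of domain families on a protein,
repeats included. From a corpus of architectures we count, per family
pair, how often the two families co-occur on a protein, normalize the
counts into a probability table with a small pseudocount, and convert to
log-odds bits against a uniform null. The resulting network assigns

* every observed pair a score >= 0 (negative log-odds are floored to
  zero: observed pairs are never penalized), and
* every never-observed pair one shared negative penalty,
  ``-log_b(1 + c / alpha)``, where ``c`` is the corpus pair-count total.

Self-pairs (a family with a second copy of itself) are first-class, so
context between repeated domains is scored like any other pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "ArchitectureDB",
    "PairCounts",
    "ScoringParams",
    "ContextNetwork",
    "EmptyCorpusError",
    "filter_architectures",
    "pair_counts",
    "pair_probability",
    "context_score",
    "build_context_network",
    "shuffle_positive_scores",
    "positive_pair_set",
]


class EmptyCorpusError(ValueError):
    """The architecture corpus contains no families after filtering."""


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ArchitectureDB:
    """Protein -> ordered family list (repeats kept).

    The ordered list, including repeats, is the protein's architecture;
    two proteins share an architecture only if the lists are identical
    element-wise and in order.
    """

    architectures: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.architectures = {
            p: tuple(a) for p, a in self.architectures.items()
        }
        for p, arch in self.architectures.items():
            if not arch:
                raise ValueError(f"empty architecture for protein {p!r}")

    def family_universe(self) -> set[str]:
        out: set[str] = set()
        for arch in self.architectures.values():
            out.update(arch)
        return out

    def architecture_multiplicity(self) -> dict[tuple[str, ...], int]:
        """Number of proteins carrying each distinct architecture."""
        counts: dict[tuple[str, ...], int] = {}
        for arch in self.architectures.values():
            counts[arch] = counts.get(arch, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.architectures)

    def __iter__(self) -> Iterator[tuple[str, tuple[str, ...]]]:
        return iter(sorted(self.architectures.items()))


@dataclass
class PairCounts:
    """Normalized symmetric pair counts c_ij over a family universe.

    ``counts`` maps the unordered pair key (i, j), i <= j, to the
    symmetric matrix entry c_ij (equal to c_ji). The grand total ``c``
    sums over all *ordered* pairs including i = j, so off-diagonal
    entries contribute twice. Each multidomain protein with e_p domains
    contributes exactly e_p to ``c``.
    """

    counts: dict[tuple[str, str], float]
    families: tuple[str, ...]

    @property
    def n(self) -> int:
        """Family universe size."""
        return len(self.families)

    @property
    def total(self) -> float:
        """c = sum of c_ij over all ordered pairs (i, j)."""
        return sum(
            v if i == j else 2.0 * v for (i, j), v in self.counts.items()
        )

    def get(self, a: str, b: str) -> float:
        return self.counts.get(_pair_key(a, b), 0.0)


@dataclass(frozen=True)
class ScoringParams:
    """Regularization alpha (pseudocount mass) and log base b.

    alpha = 1 handles the zero-count case; b = 2 yields bit scores on the
    same scale as the HMM hit scores they are summed with.
    """

    alpha: float = 1.0
    base: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.base <= 1:
            raise ValueError("log base must be > 1")


@dataclass
class ContextNetwork:
    """Sparse symmetric family-pair score table C_ij in bits.

    ``scores`` holds every *observed* pair (c_ij > 0), all >= 0 after
    flooring. Every unobserved pair shares ``unobserved_penalty`` <= 0.
    """

    scores: dict[tuple[str, str], float]
    unobserved_penalty: float
    n: int
    c: float
    alpha: float = 1.0
    base: float = 2.0

    def score(self, a: str, b: str) -> float:
        return self.scores.get(_pair_key(a, b), self.unobserved_penalty)

    def is_observed(self, a: str, b: str) -> bool:
        return _pair_key(a, b) in self.scores

    @classmethod
    def zero(cls) -> "ContextNetwork":
        """A network scoring every pair 0 (no-context reduction)."""
        return cls(scores={}, unobserved_penalty=0.0, n=0, c=0.0)

    def __len__(self) -> int:
        return len(self.scores)


def filter_architectures(db: ArchitectureDB) -> ArchitectureDB:
    """Drop architectures observed in only one sequence.

    Singleton architectures are more likely erroneous; removing them also
    shrinks the family universe n used downstream. Idempotent.
    """
    mult = db.architecture_multiplicity()
    return ArchitectureDB(
        {p: a for p, a in db.architectures.items() if mult[a] >= 2}
    )


def pair_counts(db: ArchitectureDB) -> PairCounts:
    """Normalized pair counts from a (filtered) architecture corpus.

    Only multidomain proteins (e_p >= 2) contribute. With e_ip the count
    of family i on protein p and e_p the total:

        c_ij = sum_p e_ip * e_jp / (e_p - 1)          for i != j
        c_ii = sum_p e_ip * (e_ip - 1) / (e_p - 1)

    The denominator normalizes each protein's contribution so it totals
    exactly e_p over all ordered pairs, and the diagonal form keeps
    domains from pairing with themselves (a single copy of a family
    yields no self-context; repeats do).
    """
    counts: dict[tuple[str, str], float] = {}
    for p, arch in db.architectures.items():
        e_p = len(arch)
        if e_p < 2:
            continue
        fam_counts: dict[str, int] = {}
        for f in arch:
            fam_counts[f] = fam_counts.get(f, 0) + 1
        fams = sorted(fam_counts)
        denom = float(e_p - 1)
        for idx, fi in enumerate(fams):
            ei = fam_counts[fi]
            if ei >= 2:
                key = (fi, fi)
                counts[key] = counts.get(key, 0.0) + ei * (ei - 1) / denom
            for fj in fams[idx + 1 :]:
                key = (fi, fj)
                counts[key] = counts.get(key, 0.0) + ei * fam_counts[fj] / denom
    families = tuple(sorted(db.family_universe()))
    return PairCounts(counts=counts, families=families)


def pair_probability(
    counts: PairCounts, params: ScoringParams = ScoringParams()
) -> dict[tuple[str, str], float]:
    """Regularized co-occurrence probabilities p_ij.

        p_ij = (c_ij + alpha / n^2) / (c + alpha)

    summing to 1 over all ordered pairs (the alpha pseudocount is spread
    uniformly over the n^2 ordered pairs). Returns the unordered-key
    table of *observed* entries; the shared unobserved value is
    ``(alpha / n^2) / (c + alpha)``.
    """
    n = counts.n
    if n == 0:
        raise EmptyCorpusError("no families in the corpus")
    c = counts.total
    pseudo = params.alpha / (n * n)
    denom = c + params.alpha
    return {k: (v + pseudo) / denom for k, v in counts.counts.items()}


def context_score(
    counts: PairCounts, params: ScoringParams = ScoringParams()
) -> ContextNetwork:
    """Log-odds context network from pair counts.

    Raw score s_ij = log_b(p_ij / q_ij) against the uniform null
    q_ij = 1 / n^2 (random hits at permissive E-values land on families
    approximately uniformly). Zero-count pairs all reduce to the same
    closed-form penalty -log_b(1 + c / alpha), stored once; observed
    pairs with negative raw scores are floored to 0, so observed pairs
    are never penalized.
    """
    n = counts.n
    if n == 0:
        raise EmptyCorpusError("no families in the corpus")
    c = counts.total
    alpha, b = params.alpha, params.base
    log_b = math.log(b)
    penalty = -math.log1p(c / alpha) / log_b
    denom = c + alpha
    pseudo = alpha / (n * n)
    scores: dict[tuple[str, str], float] = {}
    for key, cij in counts.counts.items():
        if cij <= 0.0:
            continue
        p = (cij + pseudo) / denom
        raw = math.log(p * n * n) / log_b
        scores[key] = max(0.0, raw)
    return ContextNetwork(
        scores=scores,
        unobserved_penalty=min(0.0, penalty),
        n=n,
        c=c,
        alpha=alpha,
        base=b,
    )


def build_context_network(
    db: ArchitectureDB, params: ScoringParams = ScoringParams()
) -> ContextNetwork:
    """filter -> count -> score pipeline on a raw architecture corpus."""
    filtered = filter_architectures(db)
    if not filtered.architectures:
        raise EmptyCorpusError(
            "no architectures survive singleton filtering"
        )
    return context_score(pair_counts(filtered), params)


def shuffle_positive_scores(
    net: ContextNetwork, seed: int
) -> ContextNetwork:
    """Permute the observed-pair scores uniformly among the observed pairs.

    A control for whether the pair-specific score values matter beyond
    their overall distribution: the score multiset and the set of scored
    pairs are preserved, the assignment is randomized. The unobserved
    penalty is unchanged. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    pairs = sorted(net.scores)
    values = np.array([net.scores[k] for k in pairs], dtype=float)
    perm = rng.permutation(len(pairs))
    return ContextNetwork(
        scores={k: float(values[perm[i]]) for i, k in enumerate(pairs)},
        unobserved_penalty=net.unobserved_penalty,
        n=net.n,
        c=net.c,
        alpha=net.alpha,
        base=net.base,
    )


def positive_pair_set(net: ContextNetwork) -> set[tuple[str, str]]:
    """Family pairs with strictly positive context score.

    Pairs floored to zero are excluded; this is the positive network the
    filter-based context baselines consume.
    """
    return {k for k, s in net.scores.items() if s > 0.0}
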