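"""Non-context and filter-based context baselines.

The comparison ladder the exact optimizer is measured against:

* standard gathering-threshold filter (keep H >= T),
* the same with all thresholds uniformly shifted by delta bits,
* a plain domain E-value cutoff,
* CODD-style positive-context transfer (promote sub-threshold
  candidates co-occurring with trusted domains), and
* an nCODD variant adding a negative filter (remove members forming
  never-observed pairs with stronger members). The published rule for
  the negative step is not public; the variant here implements the
  documented "double positive and negative" semantics and is
  non-canonical.

Overlap resolution for the threshold filters is not pinned down by any
published rule; the greedy order is configurable (default: descending
normalized score for bit-score filters, ascending E-value for the
E-value filter), breaking ties on hit_id.
"""

from __future__ import annotations

from typing import Callable, Iterable

from .core import (
    DomainHit,
    NestingRules,
    ThresholdTable,
    hit_sort_key,
    normalized_score,
    overlap_allowed,
)
from .context import ContextNetwork

__all__ = [
    "standard_filter",
    "extended_ga_filter",
    "evalue_filter",
    "codd_filter",
    "ncodd_filter",
]


def _greedy_overlap_resolve(
    hits: Iterable[DomainHit],
    rules: NestingRules,
    key: Callable[[DomainHit], tuple],
) -> set[DomainHit]:
    """Admit hits in priority order, rejecting disallowed overlaps with kept ones."""
    kept: list[DomainHit] = []
    for h in sorted(hits, key=key):
        if all(overlap_allowed(h, k, rules) for k in kept):
            kept.append(h)
    return set(kept)


def standard_filter(
    candidates: Iterable[DomainHit],
    thresholds: ThresholdTable,
    rules: NestingRules,
) -> set[DomainHit]:
    """Curated per-family gathering-threshold filter: keep hits with H >= T.

    Disallowed overlaps among passers are resolved greedily by descending
    normalized score (tie: hit_id).
    """
    passers = [
        h for h in candidates if normalized_score(h, thresholds) >= 0.0
    ]
    return _greedy_overlap_resolve(
        passers,
        rules,
        key=lambda h: (-normalized_score(h, thresholds), h.hit_id),
    )


def extended_ga_filter(
    candidates: Iterable[DomainHit],
    thresholds: ThresholdTable,
    delta: float,
    rules: NestingRules,
) -> set[DomainHit]:
    """Standard filter with every threshold shifted to T_i + delta bits."""
    return standard_filter(candidates, thresholds.shifted(delta), rules)


def evalue_filter(
    candidates: Iterable[DomainHit],
    cutoff: float,
    rules: NestingRules,
) -> set[DomainHit]:
    """Keep hits with E-value <= cutoff; greedy overlap resolution by ascending E."""
    if cutoff <= 0:
        raise ValueError("E-value cutoff must be > 0")
    passers = [h for h in candidates if h.evalue <= cutoff]
    return _greedy_overlap_resolve(
        passers, rules, key=lambda h: (h.evalue, h.hit_id)
    )


def codd_filter(
    trusted: Iterable[DomainHit],
    candidates: Iterable[DomainHit],
    positive_pairs: set[tuple[str, str]],
    rules: NestingRules,
) -> set[DomainHit]:
    """Positive-context transfer filter.

    Starting from the trusted set G (threshold passers with no disallowed
    overlaps), each candidate d, in ascending E-value order (tie:
    hit_id), is transferred into the prediction set P iff d's family has
    positive context with the family of some member of *G* (promoted
    candidates do not themselves promote) and d has no disallowed
    overlap with any current member of P.
    """
    g = sorted(trusted, key=hit_sort_key)
    g_ids = {h.hit_id for h in g}

    def pair(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    p: list[DomainHit] = list(g)
    for d in sorted(candidates, key=lambda h: (h.evalue, h.hit_id)):
        if d.hit_id in g_ids:
            continue
        if not any(pair(d.family, t.family) in positive_pairs for t in g):
            continue
        if all(overlap_allowed(d, m, rules) for m in p):
            p.append(d)
    return set(p)


def ncodd_filter(
    trusted: Iterable[DomainHit],
    candidates: Iterable[DomainHit],
    positive_pairs: set[tuple[str, str]],
    network: ContextNetwork,
    thresholds: ThresholdTable,
    rules: NestingRules,
) -> set[DomainHit]:
    """Double positive-and-negative transfer filter (non-canonical variant).

    Runs :func:`codd_filter`, then iteratively removes any member —
    trusted members included — whose family forms a never-observed pair
    (penalized in ``network``) with the family of another member of
    strictly higher normalized score. Weakest violator first; repeats to
    a fixed point. Never adds hits beyond the positive step.
    """
    members = sorted(
        codd_filter(trusted, candidates, positive_pairs, rules),
        key=hit_sort_key,
    )
    while True:
        violators = []
        for h in members:
            ns_h = normalized_score(h, thresholds)
            for other in members:
                if other.hit_id == h.hit_id:
                    continue
                if normalized_score(other, thresholds) > ns_h and (
                    not network.is_observed(h.family, other.family)
                ):
                    violators.append(h)
                    break
        if not violators:
            return set(members)
        drop = min(
            violators,
            key=lambda h: (normalized_score(h, thresholds), h.hit_id),
        )
        members = [h for h in members if h.hit_id != drop.hit_id]
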