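"""Domain hit data model, coordinate conventions, and overlap legality.

Coordinates are 1-based inclusive throughout (HMMER envelope convention);
the envelope is the authoritative extent of a hit. Any shared residue
(overlap length >= 1) counts as an overlap. Overlapping hits are only
jointly selectable when their family pair is in the curated set of
allowed (nesting) overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "DomainHit",
    "ThresholdTable",
    "NestingRules",
    "MissingThresholdError",
    "SelectionViolation",
    "normalized_score",
    "intervals_overlap",
    "overlap_allowed",
    "validate_selection",
    "hit_sort_key",
]

#: tolerance absorbing float noise in threshold feasibility checks
FEASIBILITY_TOL = 1e-9


class MissingThresholdError(KeyError):
    """A hit's family has no entry in the threshold table."""


@dataclass(frozen=True)
class DomainHit:
    """One candidate domain occurrence on a protein.

    Parameters
    ----------
    protein : str
        Protein (sequence) identifier.
    family : str
        Domain family accession or name.
    start, end : int
        Envelope coordinates, 1-based inclusive, ``1 <= start <= end``.
    score : float
        Profile-HMM bit score H_i.
    evalue : float
        Domain E-value, non-negative.
    hit_id : str
        Stable identifier, unique per protein; used for deterministic
        ordering and tie-breaking. Auto-derived if empty.
    """

    protein: str
    family: str
    start: int
    end: int
    score: float
    evalue: float
    hit_id: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates [{self.start}, {self.end}] "
                f"(need 1 <= start <= end)"
            )
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError("score must be finite")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not self.hit_id:
            object.__setattr__(
                self,
                "hit_id",
                f"{self.protein}:{self.family}:{self.start}-{self.end}",
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def shifted(self, offset: int) -> "DomainHit":
        """Copy of this hit translated by ``offset`` residues."""
        return replace(
            self,
            start=self.start + offset,
            end=self.end + offset,
            hit_id=f"{self.hit_id}+{offset}" if offset else self.hit_id,
        )


def hit_sort_key(hit: DomainHit) -> tuple:
    """Canonical deterministic ordering: (protein, start, end, family, score, hit_id)."""
    return (hit.protein, hit.start, hit.end, hit.family, hit.score, hit.hit_id)


@dataclass
class ThresholdTable:
    """Per-family bit-score thresholds T_i (e.g. Pfam gathering thresholds).

    An optional global E-value cutoff marks the permissive candidate-pool
    boundary; it is applied when assembling selection problems, not here.
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    evalue_cutoff: Optional[float] = None

    def threshold(self, family: str) -> float:
        try:
            return self.thresholds[family]
        except KeyError:
            raise MissingThresholdError(
                f"no threshold for family {family!r}"
            ) from None

    def shifted(self, delta: float) -> "ThresholdTable":
        """All thresholds uniformly shifted by ``delta`` bits."""
        return ThresholdTable(
            {f: t + delta for f, t in self.thresholds.items()},
            self.evalue_cutoff,
        )

    def __contains__(self, family: str) -> bool:
        return family in self.thresholds

    def __len__(self) -> int:
        return len(self.thresholds)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class NestingRules:
    """Unordered family pairs whose members may legitimately overlap.

    Membership is symmetric by construction; which family nests inside
    which is not modelled (treated as an unordered relation).
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "NestingRules":
        return cls({_pair_key(a, b) for a, b in pairs})

    def add(self, a: str, b: str) -> None:
        self.pairs.add(_pair_key(a, b))

    def allows(self, a: str, b: str) -> bool:
        return _pair_key(a, b) in self.pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def normalized_score(hit: DomainHit, thresholds: ThresholdTable) -> float:
    """Bit score relative to the family threshold: H_i - T_i."""
    return hit.score - thresholds.threshold(hit.family)


def intervals_overlap(a: DomainHit, b: DomainHit) -> bool:
    """True iff the two hits share at least one residue.

    Both hits must lie on the same protein; 1-based inclusive coordinates,
    so [10, 20] and [20, 30] overlap while [10, 20] and [21, 30] do not.
    """
    if a.protein != b.protein:
        raise ValueError(
            f"hits on different proteins: {a.protein!r} vs {b.protein!r}"
        )
    return max(a.start, b.start) <= min(a.end, b.end)


def overlap_allowed(a: DomainHit, b: DomainHit, rules: NestingRules) -> bool:
    """True if the hits do not overlap, or overlap as an allowed nesting pair."""
    if not intervals_overlap(a, b):
        return True
    return rules.allows(a.family, b.family)


@dataclass(frozen=True)
class SelectionViolation:
    """One constraint violated by a selected set (data, not an exception)."""

    kind: str  # "overlap" | "threshold"
    hit_ids: tuple[str, ...]
    detail: str


def validate_selection(
    selected: Iterable[DomainHit],
    thresholds: ThresholdTable,
    rules: NestingRules,
    network,
) -> list[SelectionViolation]:
    """Check a selected set D against the model's two feasibility constraints.

    Returns one violation per disallowed overlapping pair, and one per
    member whose context-adjusted score S_{i,D} (normalized score plus the
    sum of context scores with the other non-overlapping members) falls
    below zero. An empty list means D is feasible. ``network`` needs a
    ``score(family_i, family_j) -> float`` method.
    """
    hits = sorted(selected, key=hit_sort_key)
    violations: list[SelectionViolation] = []
    for i, a in enumerate(hits):
        for b in hits[i + 1 :]:
            if not overlap_allowed(a, b, rules):
                violations.append(
                    SelectionViolation(
                        "overlap",
                        (a.hit_id, b.hit_id),
                        f"{a.family} [{a.start},{a.end}] overlaps "
                        f"{b.family} [{b.start},{b.end}] without an "
                        f"allowed-nesting rule",
                    )
                )
    for a in hits:
        s = normalized_score(a, thresholds)
        for b in hits:
            if b is a:
                continue
            if not intervals_overlap(a, b):
                s += network.score(a.family, b.family)
        if s < -FEASIBILITY_TOL:
            violations.append(
                SelectionViolation(
                    "threshold",
                    (a.hit_id,),
                    f"context-adjusted score {s:.6g} < 0 for {a.hit_id}",
                )
            )
    return violations
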