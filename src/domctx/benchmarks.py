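"""The two evaluation procedures: shuffled-sequence FDR and ortholog coherence.

FDR by shuffling
----------------
Each protein's residues are permuted uniformly (composition and length
preserved) and the shuffled copy is concatenated *after* the real
sequence, so that context-aware predictors can reward noise hits on the
shuffled half with real domains on the real half. Predictions landing on
the shuffled portion arise by chance alone; with R the number of
predictions per real protein and A the mean number per shuffled portion
(averaged over the shuffle replicates), FDR = A / R.

Ortholog coherence
------------------
Real domains are very likely conserved across orthologs. After mapping
hit coordinates onto the group's multiple alignment, a predicted
domain's coherence is the fraction of the other group members carrying
an overlapping same-family prediction; a method's score is the mean over
all predicted domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np

from .core import DomainHit

__all__ = [
    "ProteinRecord",
    "UndefinedFdrError",
    "shuffle_sequence",
    "concatenate_and_split",
    "attribute_hit",
    "run_fdr_experiment",
    "estimate_fdr",
    "new_domain_fdr",
    "map_to_alignment",
    "domain_coherence",
    "method_coherence",
    "RatePredictor",
]

#: characters treated as alignment gaps
GAP_CHARS = frozenset("-.")

#: default number of shuffle replicates per sequence
DEFAULT_N_SHUFFLES = 20

#: default maximum ortholog group size kept for coherence scoring
MAX_GROUP_SIZE = 13

Predictor = Callable[[str, str], Sequence[DomainHit]]
Attribution = Literal["majority", "strict"]


class UndefinedFdrError(ZeroDivisionError):
    """FDR is undefined (no real-sequence predictions, or no novel domains)."""


@dataclass
class ProteinRecord:
    """Per-protein benchmark counts.

    ``real_count`` (R): predictions on the real sequence alone.
    ``shuffled_mean`` (A): predictions attributed to the shuffled
    portion, averaged over the shuffle replicates.
    """

    protein: str
    real_count: float
    shuffled_mean: float


def shuffle_sequence(seq: str, rng: np.random.Generator | int) -> str:
    """Uniform random permutation of the residues of ``seq``.

    Preserves length and amino-acid composition. Deterministic for a
    given generator state or integer seed.
    """
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(len(chars))])


def concatenate_and_split(real: str, shuffled: str) -> tuple[str, int]:
    """Real sequence followed by its shuffled copy, plus the boundary.

    The boundary is len(real): residues 1..boundary are the real
    portion, boundary+1..2*boundary the shuffled portion.
    """
    if len(shuffled) != len(real):
        raise ValueError("shuffled sequence must match the real length")
    return real + shuffled, len(real)


def attribute_hit(
    start: int,
    end: int,
    boundary: int,
    mode: Attribution = "majority",
) -> str:
    """Assign a hit on the concatenated sequence to 'real' or 'shuffled'.

    "majority" (default): the portion holding > 50% of the envelope
    (ties go to the real portion). "strict": shuffled only if the
    envelope lies entirely past the boundary.
    """
    if mode == "strict":
        return "shuffled" if start > boundary else "real"
    length = end - start + 1
    past = max(0, end - boundary) - max(0, start - 1 - boundary)
    return "shuffled" if past * 2 > length else "real"


def run_fdr_experiment(
    proteome: Mapping[str, str],
    predictor: Predictor,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    attribution: Attribution = "majority",
) -> list[ProteinRecord]:
    """Run the shuffling benchmark for one predictor over a proteome.

    ``predictor(protein_id, sequence)`` returns the predicted hits on
    that sequence; for the replicate runs it receives the concatenated
    real+shuffled sequence under the id ``"<protein>|shuf<k>"`` and only
    hits attributed to the shuffled portion are counted. The real count
    comes from a run on the real sequence alone.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle replicate")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    for pid in sorted(proteome):
        seq = proteome[pid]
        real_hits = predictor(pid, seq)
        shuffled_total = 0
        for k in range(n_shuffles):
            concat, boundary = concatenate_and_split(
                seq, shuffle_sequence(seq, rng)
            )
            for h in predictor(f"{pid}|shuf{k}", concat):
                if attribute_hit(h.start, h.end, boundary, attribution) == "shuffled":
                    shuffled_total += 1
        records.append(
            ProteinRecord(
                protein=pid,
                real_count=float(len(real_hits)),
                shuffled_mean=shuffled_total / n_shuffles,
            )
        )
    return records


def estimate_fdr(records: Iterable[ProteinRecord]) -> float:
    """FDR = (mean shuffled-portion predictions) / (mean real predictions).

    A standard decoy approximation: shuffled-portion hits arise by
    chance alone, real-sequence hits count true and false together.
    """
    records = list(records)
    if not records:
        raise UndefinedFdrError("no records")
    mean_r = sum(r.real_count for r in records) / len(records)
    mean_a = sum(r.shuffled_mean for r in records) / len(records)
    if mean_r <= 0:
        raise UndefinedFdrError("no real-sequence predictions; FDR undefined")
    return mean_a / mean_r


def new_domain_fdr(a: float, r: float, a_neg: float, r_neg: float) -> float:
    """FDR of the *novel* domains a context method adds.

    ``a_neg``/``r_neg`` are the shuffled/real counts when only negative
    context acts (no rescue of sub-threshold candidates); the difference
    from the permissive-pool counts ``a``/``r`` isolates the newly
    predicted domains: (A - A_n) / (R - R_n).
    """
    if r <= r_neg:
        raise UndefinedFdrError(
            "no novel domains (R does not exceed the negative-only R)"
        )
    return (a - a_neg) / (r - r_neg)


def map_to_alignment(start: int, end: int, aligned_row: str) -> tuple[int, int]:
    """Map residue coordinates (1-based inclusive) to alignment columns.

    Gap characters ('-', '.') in the row consume columns but no
    residues. Raises if the hit extends past the row's residues.
    """
    if not (1 <= start <= end):
        raise ValueError("need 1 <= start <= end")
    col_of: list[int] = []
    for col, ch in enumerate(aligned_row, start=1):
        if ch not in GAP_CHARS:
            col_of.append(col)
            if len(col_of) >= end:
                break
    if len(col_of) < end:
        raise ValueError(
            f"hit [{start}, {end}] extends past the {len(col_of)} residues "
            f"of the aligned row"
        )
    return col_of[start - 1], col_of[end - 1]


def domain_coherence(
    hit: DomainHit,
    group_predictions: Mapping[str, Sequence[DomainHit]],
    alignment: Mapping[str, str],
    group: Sequence[str],
) -> float:
    """Fraction of the other group members matching this predicted domain.

    A member matches if it has at least one prediction of the *same
    family* whose alignment-column interval shares at least one column
    with the hit's mapped interval. In-paralogs in the group count in
    the denominator (group size - 1) like orthologs.
    """
    if hit.protein not in group:
        raise ValueError(f"{hit.protein!r} is not in the group")
    others = [p for p in group if p != hit.protein]
    if not others:
        raise ValueError("singleton group: coherence undefined")
    c_start, c_end = map_to_alignment(hit.start, hit.end, alignment[hit.protein])
    matched = 0
    for member in others:
        for other in group_predictions.get(member, ()):
            if other.family != hit.family:
                continue
            o_start, o_end = map_to_alignment(
                other.start, other.end, alignment[member]
            )
            if max(c_start, o_start) <= min(c_end, o_end):
                matched += 1
                break
    return matched / len(others)


def method_coherence(
    predictions: Mapping[str, Sequence[DomainHit]],
    groups: Mapping[str, Sequence[str]],
    alignments: Mapping[str, Mapping[str, str]],
    max_group_size: int = MAX_GROUP_SIZE,
) -> tuple[float, float]:
    """A method's coherence score and its prediction density.

    Returns the unweighted mean of per-domain coherence over every
    predicted domain instance in every kept group (size between 2 and
    ``max_group_size``), and the number of predicted domains per protein
    (total predictions / total member proteins).
    """
    scores: list[float] = []
    n_domains = 0
    n_proteins = 0
    for gid in sorted(groups):
        group = list(groups[gid])
        if len(group) < 2 or len(group) > max_group_size:
            continue
        aln = alignments[gid]
        n_proteins += len(group)
        for member in group:
            for hit in predictions.get(member, ()):
                scores.append(
                    domain_coherence(hit, predictions, aln, group)
                )
                n_domains += 1
    if not scores or n_proteins == 0:
        raise UndefinedFdrError("no predictions in any kept group")
    return sum(scores) / len(scores), n_domains / n_proteins


class RatePredictor:
    """Null predictor firing at a fixed expected rate per residue.

    Places Poisson-many fixed-width hits at uniform positions regardless
    of sequence content — a pure-noise control whose estimated FDR is 1
    in expectation. Deterministic per constructed seed.
    """

    def __init__(
        self,
        rate_per_residue: float,
        width: int = 30,
        family: str = "NOISE",
        seed: int = 0,
    ) -> None:
        if rate_per_residue <= 0:
            raise ValueError("rate must be > 0")
        self.rate = rate_per_residue
        self.width = width
        self.family = family
        self._rng = np.random.default_rng(seed)

    def __call__(self, protein_id: str, seq: str) -> list[DomainHit]:
        n = int(self._rng.poisson(self.rate * len(seq)))
        max_start = max(1, len(seq) - self.width + 1)
        hits = []
        for k in range(n):
            start = int(self._rng.integers(1, max_start + 1))
            end = min(len(seq), start + self.width - 1)
            hits.append(
                DomainHit(
                    protein=protein_id,
                    family=self.family,
                    start=start,
                    end=end,
                    score=0.0,
                    evalue=1.0,
                    hit_id=f"{protein_id}:n{k}",
                )
            )
        return hits
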