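"""Synthetic fixtures with known ground truth.

Generates architecture corpora with planted family-pair enrichments,
candidate hit tables with labelled true domains and decoys, random
proteomes, and ortholog groups with consistent alignments — everything
the scoring, selection and benchmark modules need, with no downloads.

Hit scores are simulated directly in bit-space relative to each
family's threshold T_i rather than via HMM emission: the method
consumes scores, not sequences. The true-domain score offset
distribution deliberately includes sub-threshold mass, so rescue of
weak domains by context is exercised; decoys always score below
threshold and carry families foreign to the protein's architecture, so
they mostly form never-observed (penalized) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import DomainHit, NestingRules, ThresholdTable
from .context import ArchitectureDB

__all__ = [
    "SimSpec",
    "simulate_architectures",
    "simulate_thresholds",
    "simulate_candidates",
    "simulate_proteome",
    "simulate_ortholog_groups",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimSpec:
    """Parameters of the synthetic study conditions.

    Defaults are sized so a corpus is informative yet cheap: 50
    families, 500 proteins, 10 planted pairs emitted ~10x more often
    than background architectures.
    """

    n_families: int = 50
    n_proteins: int = 500
    n_planted_pairs: int = 10
    planted_weight: float = 10.0
    n_background_templates: int = 40
    max_arch_len: int = 5
    repeat_prob: float = 0.05
    # hit-noise model (bit-space, relative to T_i)
    true_offset_mu: float = 3.0
    true_offset_sd: float = 4.0
    decoys_per_protein: float = 1.0
    domain_len: tuple[int, int] = (40, 120)
    gap_len: tuple[int, int] = (5, 30)
    # decoy acceptance tolerance for end-to-end comparisons (rate units)
    decoy_tolerance: float = 0.02
    # ortholog groups
    n_groups: int = 25
    group_size: int = 4
    mutation_rate: float = 0.05
    domain_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_prob", "mutation_rate", "domain_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def planted_pairs(self) -> list[tuple[str, str]]:
        """Disjoint enriched pairs: (F000,F001), (F002,F003), ..."""
        if 2 * self.n_planted_pairs > self.n_families:
            raise ValueError("not enough families for the planted pairs")
        fams = self.families()
        return [
            (fams[2 * k], fams[2 * k + 1])
            for k in range(self.n_planted_pairs)
        ]

    def families(self) -> list[str]:
        return [f"F{i:03d}" for i in range(self.n_families)]


def simulate_thresholds(spec: SimSpec) -> ThresholdTable:
    """Per-family gathering-style thresholds, uniform in [15, 30] bits."""
    rng = np.random.default_rng(spec.seed + 1)
    fams = spec.families()
    values = rng.uniform(15.0, 30.0, size=len(fams))
    return ThresholdTable(
        {f: float(t) for f, t in zip(fams, values)}, evalue_cutoff=1.0
    )


def simulate_architectures(spec: SimSpec) -> ArchitectureDB:
    """Architecture corpus with planted pair enrichments.

    Templates: one two-family template per planted pair (occasionally
    with one extra random family) plus random background templates of
    length 1..max_arch_len. Proteins are allocated across templates in
    proportion to their weights (planted_weight vs 1), every template at
    least twice, so each distinct architecture survives singleton
    filtering. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed + 2)
    fams = spec.families()
    templates: list[tuple[str, ...]] = []
    weights: list[float] = []
    for a, b in spec.planted_pairs():
        arch = [a, b]
        if rng.random() < 0.5:
            arch.append(str(rng.choice(fams)))
        templates.append(tuple(arch))
        weights.append(spec.planted_weight)
    for _ in range(spec.n_background_templates):
        length = int(rng.integers(1, spec.max_arch_len + 1))
        arch = [str(f) for f in rng.choice(fams, size=length)]
        if length >= 1 and rng.random() < spec.repeat_prob:
            arch.append(arch[int(rng.integers(0, length))])
        templates.append(tuple(arch))
        weights.append(1.0)

    w = np.asarray(weights)
    n_templates = len(templates)
    copies = np.full(n_templates, 2, dtype=int)  # survive the singleton filter
    remaining = spec.n_proteins - copies.sum()
    if remaining < 0:
        raise ValueError(
            f"n_proteins={spec.n_proteins} too small for "
            f"{n_templates} templates (need >= {2 * n_templates})"
        )
    extra = rng.multinomial(remaining, w / w.sum())
    copies += extra

    db: dict[str, tuple[str, ...]] = {}
    pid = 0
    for arch, k in zip(templates, copies):
        for _ in range(k):
            db[f"P{pid:05d}"] = arch
            pid += 1
    return ArchitectureDB(db)


def simulate_candidates(
    db: ArchitectureDB,
    thresholds: ThresholdTable,
    spec: SimSpec,
) -> tuple[list[DomainHit], dict[str, bool]]:
    """Candidate hit tables with labelled truth.

    True domains are laid left-to-right along each protein without
    overlaps, scored H = T + offset with offset ~ N(mu, sd) — around a
    quarter of true domains fall below threshold at the defaults, where
    only context can recover them. Decoys (Poisson-many per protein)
    get families absent from the architecture, random positions, and
    offsets uniform in (-0.9, -0.1), always sub-threshold but inside
    the default permissive E <= 1 pool. E-values are a monotone
    transform of the offset, evalue = 2^(-offset - 1).

    Returns the hits plus a hit_id -> is_true label map.
    """
    rng = np.random.default_rng(spec.seed + 3)
    all_fams = spec.families()
    hits: list[DomainHit] = []
    truth: dict[str, bool] = {}
    lo_d, hi_d = spec.domain_len
    lo_g, hi_g = spec.gap_len
    for protein, arch in db:
        pos = 1
        for k, fam in enumerate(arch):
            gap = int(rng.integers(lo_g, hi_g + 1))
            length = int(rng.integers(lo_d, hi_d + 1))
            start = pos + gap
            end = start + length - 1
            pos = end + 1
            offset = float(rng.normal(spec.true_offset_mu, spec.true_offset_sd))
            t = thresholds.threshold(fam)
            hit = DomainHit(
                protein=protein,
                family=fam,
                start=start,
                end=end,
                score=t + offset,
                evalue=_offset_to_evalue(offset),
                hit_id=f"{protein}:t{k}",
            )
            hits.append(hit)
            truth[hit.hit_id] = True
        protein_len = pos + int(rng.integers(lo_g, hi_g + 1))
        foreign = [f for f in all_fams if f not in arch]
        n_decoys = int(rng.poisson(spec.decoys_per_protein))
        for k in range(n_decoys):
            fam = str(rng.choice(foreign)) if foreign else str(rng.choice(all_fams))
            length = int(rng.integers(lo_d, hi_d + 1))
            start = int(rng.integers(1, max(2, protein_len - length + 1)))
            end = start + length - 1
            offset = float(rng.uniform(-0.9, -0.1))
            t = thresholds.threshold(fam)
            hit = DomainHit(
                protein=protein,
                family=fam,
                start=start,
                end=end,
                score=t + offset,
                evalue=_offset_to_evalue(offset),
                hit_id=f"{protein}:d{k}",
            )
            hits.append(hit)
            truth[hit.hit_id] = False
    return hits, truth


def _offset_to_evalue(offset: float) -> float:
    """Monotone score-to-E-value map: 0 bits over threshold -> E = 0.5."""
    return float(min(1e3, max(1e-30, 2.0 ** (-offset - 1.0))))


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 600),
    seed: int = 0,
) -> dict[str, str]:
    """Random i.i.d.-composition amino-acid sequences for the FDR benchmark."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out: dict[str, str] = {}
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        out[f"S{i:05d}"] = "".join(rng.choice(AMINO_ACIDS, size=length))
    return out


def simulate_ortholog_groups(
    spec: SimSpec,
    thresholds: Optional[ThresholdTable] = None,
) -> tuple[
    dict[str, list[str]],
    dict[str, dict[str, str]],
    dict[str, list[DomainHit]],
]:
    """Ortholog groups sharing one architecture, with consistent alignments.

    Each group draws an architecture, builds a parent sequence with
    domains placed at fixed coordinates, and derives members by point
    substitution at ``mutation_rate`` (no indels, so alignment rows are
    the member sequences themselves and coordinates transfer exactly).
    Every member gets an above-threshold prediction per domain, except
    domains dropped at ``domain_dropout`` — with zero dropout, every
    predicted domain has coherence exactly 1.

    Returns (groups, per-group alignments, per-protein predictions).
    """
    if spec.group_size < 2:
        raise ValueError("group size must be >= 2")
    thresholds = thresholds or simulate_thresholds(spec)
    rng = np.random.default_rng(spec.seed + 4)
    fams = spec.families()
    lo_d, hi_d = spec.domain_len
    lo_g, hi_g = spec.gap_len

    groups: dict[str, list[str]] = {}
    alignments: dict[str, dict[str, str]] = {}
    predictions: dict[str, list[DomainHit]] = {}
    for g in range(spec.n_groups):
        gid = f"OG{g:04d}"
        arch_len = int(rng.integers(1, spec.max_arch_len + 1))
        arch = [str(f) for f in rng.choice(fams, size=arch_len)]
        coords: list[tuple[int, int]] = []
        pos = 1
        for _ in arch:
            start = pos + int(rng.integers(lo_g, hi_g + 1))
            end = start + int(rng.integers(lo_d, hi_d + 1)) - 1
            coords.append((start, end))
            pos = end + 1
        seq_len = pos + int(rng.integers(lo_g, hi_g + 1))
        parent = rng.choice(AMINO_ACIDS, size=seq_len)

        members: list[str] = []
        rows: dict[str, str] = {}
        for m in range(spec.group_size):
            pid = f"{gid}m{m}"
            members.append(pid)
            seq = parent.copy()
            mask = rng.random(seq_len) < spec.mutation_rate
            seq[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
            rows[pid] = "".join(seq)
            member_hits: list[DomainHit] = []
            for k, (fam, (start, end)) in enumerate(zip(arch, coords)):
                if rng.random() < spec.domain_dropout:
                    continue
                t = thresholds.threshold(fam)
                offset = 1.0 + abs(float(rng.normal(3.0, 2.0)))
                member_hits.append(
                    DomainHit(
                        protein=pid,
                        family=fam,
                        start=start,
                        end=end,
                        score=t + offset,
                        evalue=_offset_to_evalue(offset),
                        hit_id=f"{pid}:t{k}",
                    )
                )
            predictions[pid] = member_hits
        groups[gid] = members
        alignments[gid] = rows
    return groups, alignments, predictions


def simulate_nesting(spec: SimSpec, n_pairs: int = 3) -> NestingRules:
    """A few allowed-overlap family pairs among the high-index families."""
    rng = np.random.default_rng(spec.seed + 5)
    fams = spec.families()
    rules = NestingRules()
    for _ in range(n_pairs):
        a, b = rng.choice(fams, size=2, replace=False)
        rules.add(str(a), str(b))
    return rules
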