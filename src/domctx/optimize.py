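"""Exact per-protein selection of candidate domains.

Given candidates P on one protein (permissive E-value pool), select the
subset D maximizing the total score — sum of normalized hit scores
H_i - T_i plus context scores C_ij over non-overlapping selected pairs —
subject to:

  (a) D contains only allowed overlaps (nesting pairs), and
  (b) every selected domain's context-adjusted score
      S_{i,D} = H_i - T_i + sum_{j in D, j non-overlapping i} C_ij
      is non-negative.

The search is cast as a 0/1 integer linear program with one variable per
candidate and one per non-overlapping candidate pair, solved exactly with
HiGHS (scipy.optimize.milp). A brute-force subset enumerator serves as
an independent oracle and as fallback on small instances.

Context edges exist only between non-overlapping pairs: allowed-nested
overlapping hits coexist but exchange no context.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import (
    FEASIBILITY_TOL,
    DomainHit,
    NestingRules,
    ThresholdTable,
    hit_sort_key,
    intervals_overlap,
    normalized_score,
    overlap_allowed,
)
from .context import ContextNetwork

__all__ = [
    "SelectionProblem",
    "Selection",
    "selection_score",
    "total_score",
    "solve_exact",
    "brute_force_oracle",
    "eliminate_candidates",
    "solve_proteins",
]

ORACLE_MAX_CANDIDATES = 25

ObjectiveMode = Literal["edge-once", "edge-twice"]


@dataclass
class SelectionProblem:
    """Per-protein instance: candidate pool, thresholds, rules, network.

    ``objective_mode`` controls how a context edge enters the objective:
    "edge-once" (default) counts each non-overlapping pair's C_ij once,
    matching the graph view of maximizing node plus edge weights;
    "edge-twice" counts it from both endpoints, matching a sum of the
    per-domain scores S_{i,D}. The feasibility constraint S_{i,D} >= 0
    is identical in both modes.
    """

    protein: str
    candidates: list[DomainHit]
    thresholds: ThresholdTable
    rules: NestingRules
    network: ContextNetwork
    objective_mode: ObjectiveMode = "edge-once"

    def __post_init__(self) -> None:
        for h in self.candidates:
            if h.protein != self.protein:
                raise ValueError(
                    f"candidate {h.hit_id} is on protein {h.protein!r}, "
                    f"not {self.protein!r}"
                )
        self.candidates = sorted(self.candidates, key=hit_sort_key)
        ids = [h.hit_id for h in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate hit_id among candidates")

    @property
    def edge_multiplier(self) -> float:
        return 2.0 if self.objective_mode == "edge-twice" else 1.0


@dataclass
class Selection:
    """A feasible chosen subset with its score decomposition."""

    protein: str
    chosen: list[DomainHit]
    per_domain_scores: dict[str, float]  # hit_id -> S_{i,D}
    total: float
    status: str = "optimal"  # "optimal" | "fallback"

    def hit_ids(self) -> tuple[str, ...]:
        return tuple(sorted(h.hit_id for h in self.chosen))


def selection_score(
    hit: DomainHit,
    selected: Sequence[DomainHit],
    thresholds: ThresholdTable,
    rules: NestingRules,
    network: ContextNetwork,
) -> float:
    """Context-adjusted score S_{i,D} of ``hit`` within the set ``selected``.

    Normalized score H_i - T_i plus the context score with every *other*
    selected hit that does not overlap it (distinct repeat hits of one
    family contribute the family's self-pair score). Overlapping
    partners — allowed nesting included — contribute nothing.
    """
    if not any(h is hit or h.hit_id == hit.hit_id for h in selected):
        raise ValueError("hit must be a member of the selected set")
    s = normalized_score(hit, thresholds)
    for other in selected:
        if other is hit or other.hit_id == hit.hit_id:
            continue
        if not intervals_overlap(hit, other):
            s += network.score(hit.family, other.family)
    return s


def total_score(selected: Sequence[DomainHit], problem: SelectionProblem) -> float:
    """Objective value of a set: node weights plus context-edge weights.

    Node weight is H_i - T_i; each non-overlapping unordered pair adds
    its C_ij once (default) or twice (edge-twice mode).
    """
    hits = sorted(selected, key=hit_sort_key)
    total = sum(normalized_score(h, problem.thresholds) for h in hits)
    mult = problem.edge_multiplier
    for i, a in enumerate(hits):
        for b in hits[i + 1 :]:
            if not intervals_overlap(a, b):
                total += mult * problem.network.score(a.family, b.family)
    return total


def _pair_structure(problem: SelectionProblem):
    """Classify candidate pairs: context edges, conflicts, neutral overlaps."""
    cands = problem.candidates
    edges: list[tuple[int, int, float]] = []  # non-overlapping: context edge
    conflicts: list[tuple[int, int]] = []  # disallowed overlap
    for i, a in enumerate(cands):
        for j in range(i + 1, len(cands)):
            b = cands[j]
            if intervals_overlap(a, b):
                if not problem.rules.allows(a.family, b.family):
                    conflicts.append((i, j))
                # allowed nesting: coexists, no context edge
            else:
                edges.append((i, j, problem.network.score(a.family, b.family)))
    return edges, conflicts


def _empty_selection(problem: SelectionProblem, status: str = "optimal") -> Selection:
    return Selection(problem.protein, [], {}, 0.0, status)


def _finalize(
    problem: SelectionProblem, chosen: list[DomainHit], status: str
) -> Selection:
    chosen = sorted(chosen, key=hit_sort_key)
    per_domain = {
        h.hit_id: selection_score(
            h, chosen, problem.thresholds, problem.rules, problem.network
        )
        for h in chosen
    }
    return Selection(
        protein=problem.protein,
        chosen=chosen,
        per_domain_scores=per_domain,
        total=total_score(chosen, problem),
        status=status,
    )


def solve_exact(problem: SelectionProblem) -> Selection:
    """Score-maximal feasible selection via 0/1 integer linear programming.

    Variables: x_i per candidate; x_ij per non-overlapping pair, coupled
    by x_ij <= x_i, x_ij <= x_j, x_ij >= x_i + x_j - 1. Disallowed
    overlaps force x_i + x_j <= 1. The per-domain threshold is enforced
    conditionally via big-M:

        (H_i - T_i) + sum_j C_ij x_ij >= -M_i (1 - x_i),
        M_i = |H_i - T_i| + sum_j |C_ij| + 1.

    Guaranteed score-equal to :func:`brute_force_oracle`. On solver
    failure, falls back to the oracle for instances of <= 25 candidates.
    """
    cands = problem.candidates
    n = len(cands)
    if n == 0:
        return _empty_selection(problem)

    edges, conflicts = _pair_structure(problem)
    n_edge = len(edges)
    nvar = n + n_edge
    node_w = np.array(
        [normalized_score(h, problem.thresholds) for h in cands], dtype=float
    )
    edge_w = np.array([w for _, _, w in edges], dtype=float)

    # milp minimizes: negate the maximization objective
    cost = np.concatenate([-node_w, -problem.edge_multiplier * edge_w])

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    r = 0

    def add_row(entries: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal r
        for c_idx, v in entries:
            rows.append(r)
            cols.append(c_idx)
            vals.append(v)
        lb.append(lo)
        ub.append(hi)
        r += 1

    for i, j in conflicts:
        add_row([(i, 1.0), (j, 1.0)], -np.inf, 1.0)

    incident: dict[int, list[int]] = {i: [] for i in range(n)}
    for e, (i, j, _) in enumerate(edges):
        ev = n + e
        incident[i].append(e)
        incident[j].append(e)
        add_row([(ev, 1.0), (i, -1.0)], -np.inf, 0.0)
        add_row([(ev, 1.0), (j, -1.0)], -np.inf, 0.0)
        add_row([(i, 1.0), (j, 1.0), (ev, -1.0)], -np.inf, 1.0)

    for i in range(n):
        big_m = abs(node_w[i]) + sum(abs(edge_w[e]) for e in incident[i]) + 1.0
        entries = [(n + e, float(edge_w[e])) for e in incident[i]]
        entries.append((i, -big_m))
        # C·x_e - M x_i >= -(H-T) - M  (slack tolerance absorbs float noise)
        add_row(entries, -node_w[i] - big_m - FEASIBILITY_TOL, np.inf)

    a_mat = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(r, nvar)
    )
    res = milp(
        c=cost,
        constraints=LinearConstraint(a_mat, np.array(lb), np.array(ub)),
        integrality=np.ones(nvar),
        bounds=Bounds(np.zeros(nvar), np.ones(nvar)),
    )
    if not res.success or res.x is None:
        if n <= ORACLE_MAX_CANDIDATES:
            sel = brute_force_oracle(problem)
            return replace(sel, status="fallback")
        raise RuntimeError(
            f"ILP solver failed on {problem.protein} "
            f"({n} candidates): {res.message}"
        )
    x = np.rint(res.x[:n]).astype(bool)
    chosen = [h for i, h in enumerate(cands) if x[i]]
    return _finalize(problem, chosen, "optimal")


def _feasible(
    subset: Sequence[DomainHit], problem: SelectionProblem
) -> bool:
    for i, a in enumerate(subset):
        for b in subset[i + 1 :]:
            if not overlap_allowed(a, b, problem.rules):
                return False
    for h in subset:
        if (
            selection_score(
                h, subset, problem.thresholds, problem.rules, problem.network
            )
            < -FEASIBILITY_TOL
        ):
            return False
    return True


def brute_force_oracle(problem: SelectionProblem) -> Selection:
    """Exhaustive enumeration over all subsets of the candidate pool.

    Independent of the ILP path; intended for verification and as a
    fallback. Ties in total score (within 1e-9) are broken by preferring
    the larger selection, then the lexicographically smallest sorted
    tuple of hit_ids (so a lone hit at exactly H = T is kept).
    """
    cands = problem.candidates
    if len(cands) > ORACLE_MAX_CANDIDATES:
        raise ValueError(
            f"{len(cands)} candidates exceed the oracle limit "
            f"({ORACLE_MAX_CANDIDATES})"
        )
    best_score = 0.0
    best: tuple[tuple[str, ...], list[DomainHit]] = ((), [])
    for k in range(1, len(cands) + 1):
        for combo in itertools.combinations(cands, k):
            subset = list(combo)
            if not _feasible(subset, problem):
                continue
            score = total_score(subset, problem)
            key = tuple(sorted(h.hit_id for h in subset))
            tied = abs(score - best_score) <= FEASIBILITY_TOL
            if (
                score > best_score + FEASIBILITY_TOL
                or (tied and len(subset) > len(best[1]))
                or (tied and len(subset) == len(best[1]) and key < best[0])
            ):
                best_score = score
                best = (key, subset)
    return _finalize(problem, best[1], "optimal")


def solve_proteins(
    hits: Sequence[DomainHit],
    thresholds: ThresholdTable,
    rules: NestingRules,
    network: ContextNetwork,
    evalue_cutoff: Optional[float] = 1.0,
    objective_mode: ObjectiveMode = "edge-once",
    preprocess: bool = True,
) -> dict[str, Selection]:
    """Select domains for every protein in a hit table independently.

    Hits are grouped per protein, restricted to the permissive candidate
    pool (E-value <= ``evalue_cutoff``, default 1), optionally pruned by
    :func:`eliminate_candidates`, and solved exactly.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        if evalue_cutoff is not None and h.evalue > evalue_cutoff:
            continue
        by_protein.setdefault(h.protein, []).append(h)
    out: dict[str, Selection] = {}
    for protein in sorted(by_protein):
        problem = SelectionProblem(
            protein=protein,
            candidates=by_protein[protein],
            thresholds=thresholds,
            rules=rules,
            network=network,
            objective_mode=objective_mode,
        )
        if preprocess:
            problem = eliminate_candidates(problem)
        out[protein] = solve_exact(problem)
    return out


def eliminate_candidates(problem: SelectionProblem) -> SelectionProblem:
    """Safe preprocessing: drop candidates that can never be selected.

    A candidate i with

        (H_i - T_i) + sum over non-overlapping candidates j of
        max(0, C_ij)  <  0

    cannot reach S_{i,D} >= 0 in any feasible D, since the sum is an
    upper bound on its achievable context. Removal may tighten the bound
    for the survivors, so iterate to a fixed point. The optimal score is
    provably unchanged.
    """
    cands = list(problem.candidates)
    changed = True
    while changed:
        changed = False
        keep: list[DomainHit] = []
        for h in cands:
            bound = normalized_score(h, problem.thresholds)
            for other in cands:
                if other is h:
                    continue
                if not intervals_overlap(h, other):
                    bound += max(
                        0.0, problem.network.score(h.family, other.family)
                    )
            if bound < -FEASIBILITY_TOL:
                changed = True
            else:
                keep.append(h)
        cands = keep
    return SelectionProblem(
        protein=problem.protein,
        candidates=cands,
        thresholds=problem.thresholds,
        rules=problem.rules,
        network=problem.network,
        objective_mode=problem.objective_mode,
    )
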