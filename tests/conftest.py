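import numpy as np
import pytest

from domctx.context import ArchitectureDB, ContextNetwork
from domctx.core import DomainHit, NestingRules, ThresholdTable


@pytest.fixture
def thresholds() -> ThresholdTable:
    return ThresholdTable({f: 20.0 for f in "ABCDEF"}, evalue_cutoff=1.0)


@pytest.fixture
def rules() -> NestingRules:
    return NestingRules.from_pairs([("E", "F")])


@pytest.fixture
def network() -> ContextNetwork:
    """Small hand-built network: one strong pair, one floored pair."""
    return ContextNetwork(
        scores={("A", "B"): 3.0, ("A", "C"): 0.0, ("A", "A"): 1.5},
        unobserved_penalty=-4.0,
        n=6,
        c=15.0,
    )


@pytest.fixture
def small_corpus() -> ArchitectureDB:
    return ArchitectureDB(
        {
            "p1": ("A", "B"),
            "p2": ("A", "B"),
            "p3": ("A", "A"),
            "p4": ("A", "A"),
            "p5": ("A", "B", "C"),
            "p6": ("A", "B", "C"),
        }
    )


def make_hit(
    protein="p",
    family="A",
    start=10,
    end=40,
    score=25.0,
    evalue=0.01,
    hit_id="",
) -> DomainHit:
    return DomainHit(protein, family, start, end, score, evalue, hit_id)


def random_problem(rng: np.random.Generator, n_candidates: int, families="ABCDEF"):
    """A random per-protein selection instance with mixed context signs,
    overlaps, and an allowed-nesting pair (E, F)."""
    from domctx.context import ContextNetwork
    from domctx.optimize import SelectionProblem

    fams = list(families)
    th = ThresholdTable({f: 20.0 for f in fams})
    rules = NestingRules.from_pairs([("E", "F")])
    scores = {}
    for i, a in enumerate(fams):
        for b in fams[i:]:
            if rng.random() < 0.5:
                scores[(a, b)] = float(rng.uniform(0.0, 5.0))
    net = ContextNetwork(
        scores=scores,
        unobserved_penalty=float(-rng.uniform(1.0, 6.0)),
        n=len(fams),
        c=10.0,
    )
    cands = []
    for k in range(n_candidates):
        start = int(rng.integers(1, 300))
        length = int(rng.integers(10, 80))
        cands.append(
            DomainHit(
                protein="p",
                family=str(rng.choice(fams)),
                start=start,
                end=start + length - 1,
                score=float(20.0 + rng.normal(1.0, 4.0)),
                evalue=float(rng.uniform(1e-6, 1.0)),
                hit_id=f"h{k:02d}",
            )
        )
    return SelectionProblem("p", cands, th, rules, net)
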