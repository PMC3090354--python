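"""Readers and writers for the package's tabular and sequence formats.

All bespoke tables are UTF-8, Unix-newline, TAB-separated; comment lines
start with '#'; floats are written with 17 significant digits so values
round-trip exactly. Writers emit rows in a canonical sort order, making
output byte-deterministic regardless of input order.

Formats
-------
hits            protein, family, start, end, score, evalue[, hit_id]
                (also: HMMER3 per-domain --domtblout, envelope coords)
thresholds      family, threshold
nesting         family_a, family_b
architectures   protein, comma-separated ordered family list
network         header '## n= c= alpha= b= unobserved_penalty=' then
                fam_i, fam_j, score (observed pairs only)
groups          group_id, comma-separated protein ids
predictions     protein, family, start, end, score, normalized,
                context_adjusted, method
FASTA           via Bio.SeqIO (proteomes and per-group alignments)
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DomainHit, NestingRules, ThresholdTable, hit_sort_key
from .context import ArchitectureDB, ContextNetwork
from .optimize import Selection

__all__ = [
    "ParseError",
    "read_hits",
    "read_domtblout",
    "write_hits",
    "read_thresholds",
    "write_thresholds",
    "read_nesting",
    "write_nesting",
    "read_architectures",
    "write_architectures",
    "read_network",
    "write_network",
    "read_groups",
    "write_groups",
    "read_fasta",
    "write_fasta",
    "write_predictions",
    "write_gff3",
    "write_bench",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input row, with file and line context."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _fmt(x: float) -> str:
    return format(x, ".17g")


def _data_lines(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------- hits


def read_hits(path: PathLike) -> list[DomainHit]:
    """Read the canonical 6/7-column TSV hit table.

    Columns: protein, family, start, end, score, evalue, optional
    hit_id (auto-derived when absent or '.'). Rows with end < start or
    a negative E-value are rejected with the offending line number.
    Output is sorted by (protein, start, end, family, score, hit_id).
    """
    hits: list[DomainHit] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) not in (6, 7):
            raise ParseError(
                path, lineno, f"expected 6 or 7 columns, got {len(parts)}"
            )
        try:
            hit_id = ""
            if len(parts) == 7 and parts[6] not in (".", ""):
                hit_id = parts[6]
            hits.append(
                DomainHit(
                    protein=parts[0],
                    family=parts[1],
                    start=int(parts[2]),
                    end=int(parts[3]),
                    score=float(parts[4]),
                    evalue=float(parts[5]),
                    hit_id=hit_id,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return sorted(hits, key=hit_sort_key)


def read_domtblout(path: PathLike, family_from: str = "query") -> list[DomainHit]:
    """Read a HMMER3 per-domain table (``--domtblout``).

    Whitespace-delimited, 22+ columns; envelope coordinates (columns 20
    and 21, 1-based) give the hit extent, the per-domain independent
    E-value (column 13) and per-domain bit score (column 14) the
    statistics. ``family_from`` is "query" for hmmsearch output (the
    profile is the query) or "target" for hmmscan output.
    """
    if family_from not in ("query", "target"):
        raise ValueError("family_from must be 'query' or 'target'")
    hits: list[DomainHit] = []
    per_protein_counter: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 22:
            raise ParseError(
                path, lineno, f"expected >= 22 columns, got {len(parts)}"
            )
        try:
            target, query = parts[0], parts[3]
            protein, family = (
                (target, query) if family_from == "query" else (query, target)
            )
            k = per_protein_counter.get(protein, 0)
            per_protein_counter[protein] = k + 1
            hits.append(
                DomainHit(
                    protein=protein,
                    family=family,
                    start=int(parts[19]),
                    end=int(parts[20]),
                    score=float(parts[13]),
                    evalue=float(parts[12]),
                    hit_id=f"{protein}:{k}",
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return sorted(hits, key=hit_sort_key)


def write_hits(hits: Iterable[DomainHit], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#protein\tfamily\tstart\tend\tscore\tevalue\thit_id\n")
        for h in sorted(hits, key=hit_sort_key):
            fh.write(
                f"{h.protein}\t{h.family}\t{h.start}\t{h.end}\t"
                f"{_fmt(h.score)}\t{_fmt(h.evalue)}\t{h.hit_id}\n"
            )


# ---------------------------------------------------------- thresholds


def read_thresholds(path: PathLike) -> ThresholdTable:
    table: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        family = parts[0]
        if family in table:
            raise ParseError(path, lineno, f"duplicate threshold for {family!r}")
        try:
            table[family] = float(parts[1])
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return ThresholdTable(table)


def write_thresholds(thresholds: ThresholdTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#family\tthreshold\n")
        for family in sorted(thresholds.thresholds):
            fh.write(f"{family}\t{_fmt(thresholds.thresholds[family])}\n")


# ------------------------------------------------------------- nesting


def read_nesting(path: PathLike) -> NestingRules:
    rules = NestingRules()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        rules.add(parts[0], parts[1])
    return rules


def write_nesting(rules: NestingRules, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#family_a\tfamily_b\n")
        for a, b in rules:
            fh.write(f"{a}\t{b}\n")


# ------------------------------------------------------- architectures


def read_architectures(path: PathLike) -> ArchitectureDB:
    archs: dict[str, tuple[str, ...]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        protein = parts[0]
        if protein in archs:
            raise ParseError(path, lineno, f"duplicate protein {protein!r}")
        fams = tuple(f for f in parts[1].split(",") if f)
        if not fams:
            raise ParseError(path, lineno, f"empty architecture for {protein!r}")
        archs[protein] = fams
    return ArchitectureDB(archs)


def write_architectures(db: ArchitectureDB, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#protein\tarchitecture\n")
        for protein, arch in db:
            fh.write(f"{protein}\t{','.join(arch)}\n")


# ------------------------------------------------------------- network


def read_network(path: PathLike) -> ContextNetwork:
    meta: dict[str, float] = {}
    scores: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##"):
                for tok in line[2:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = float(v)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    path, lineno, f"expected 3 columns, got {len(parts)}"
                )
            a, b = sorted((parts[0], parts[1]))
            if (a, b) in scores:
                raise ParseError(path, lineno, f"duplicate pair ({a}, {b})")
            try:
                scores[(a, b)] = float(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    for key in ("n", "c", "alpha", "b", "unobserved_penalty"):
        if key not in meta:
            raise ParseError(path, 1, f"missing metadata field {key!r}")
    return ContextNetwork(
        scores=scores,
        unobserved_penalty=meta["unobserved_penalty"],
        n=int(meta["n"]),
        c=meta["c"],
        alpha=meta["alpha"],
        base=meta["b"],
    )


def write_network(net: ContextNetwork, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"## n={net.n} c={_fmt(net.c)} alpha={_fmt(net.alpha)} "
            f"b={_fmt(net.base)} unobserved_penalty={_fmt(net.unobserved_penalty)}\n"
        )
        fh.write("#family_i\tfamily_j\tscore\n")
        for (a, b) in sorted(net.scores):
            fh.write(f"{a}\t{b}\t{_fmt(net.scores[(a, b)])}\n")


# -------------------------------------------------------------- groups


def read_groups(path: PathLike) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        gid = parts[0]
        if gid in groups:
            raise ParseError(path, lineno, f"duplicate group {gid!r}")
        members = [m for m in parts[1].split(",") if m]
        if not members:
            raise ParseError(path, lineno, f"empty group {gid!r}")
        groups[gid] = members
    return groups


def write_groups(groups: Mapping[str, Sequence[str]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#group_id\tmembers\n")
        for gid in sorted(groups):
            fh.write(f"{gid}\t{','.join(groups[gid])}\n")


# --------------------------------------------------------------- FASTA


def read_fasta(path: PathLike) -> dict[str, str]:
    """FASTA file -> id -> sequence (alignment rows keep their gaps)."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(sequences[sid]), id=sid, description="")
        for sid in sorted(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------- results / exports


def write_predictions(
    selections: Mapping[str, Selection],
    thresholds: ThresholdTable,
    path: PathLike,
    method: str = "context",
) -> None:
    """Selected domains as a TSV, one row per predicted domain."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "#protein\tfamily\tstart\tend\tscore\tnormalized\t"
            "context_adjusted\tmethod\n"
        )
        for protein in sorted(selections):
            sel = selections[protein]
            for h in sorted(sel.chosen, key=hit_sort_key):
                norm = h.score - thresholds.threshold(h.family)
                s_ctx = sel.per_domain_scores.get(h.hit_id, norm)
                fh.write(
                    f"{h.protein}\t{h.family}\t{h.start}\t{h.end}\t"
                    f"{_fmt(h.score)}\t{_fmt(norm)}\t{_fmt(s_ctx)}\t{method}\n"
                )


def write_gff3(
    selections: Mapping[str, Selection],
    path: PathLike,
    source: str = "domctx",
) -> None:
    """GFF3 export of predictions: one protein_match feature per domain."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for protein in sorted(selections):
            for h in sorted(selections[protein].chosen, key=hit_sort_key):
                attrs = f"ID={h.hit_id};Name={h.family}"
                fh.write(
                    f"{h.protein}\t{source}\tprotein_match\t{h.start}\t"
                    f"{h.end}\t{_fmt(h.score)}\t+\t.\t{attrs}\n"
                )


def write_bench(
    rows: Iterable[Mapping[str, object]],
    path: PathLike,
) -> None:
    """Benchmark results TSV: method, params, signal, metric, value."""
    cols = ("method", "params", "signal", "metric", "value")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in sorted(
            rows, key=lambda r: (str(r.get("method")), str(r.get("metric")))
        ):
            out = []
            for c in cols:
                v = row.get(c, ".")
                out.append(_fmt(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(out) + "\n")
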