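"""Enumeration and scanning of irregular G-quadruplex sequence motifs.

A putative quadruplex sequence (PQS) is modelled here as an ordered series of
guanine tracts separated by short non-guanine loops.  The classical PQS scheme
demands four tracts of three or more guanines; the families handled by this
module instead describe *irregular* motifs built from many short tracts:
``k`` tracts of at least two guanines plus ``m`` isolated single guanines, all
separated by loops of 1-2 non-G bases.  A family is enumerated by choosing
which of the ``k+m`` tract positions are relaxed to single guanines, giving
``C(k+m, m)`` distinct query patterns.

Matching is exact: a hit decomposes into the query's tracts and loops, loops
contain no guanine, and ``N`` matches nothing.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from Bio.Seq import Seq

__all__ = [
    "TractSpec",
    "MotifQuery",
    "QuerySet",
    "MotifHit",
    "Run",
    "TractDecomposition",
    "decompose_tracts",
    "enumerate_queries",
    "compile_query",
    "scan_sequence",
    "scan_fasta",
    "reverse_complement",
]

VALID_BASES = frozenset("ACGTN")
LOOP_ALPHABET = "ACT"  # non-guanine bases; N never matches a loop position

OverlapPolicy = Literal["grep_line", "leftmost_nonoverlap", "all_overlapping"]
Strand = Literal["fwd", "rev", "both"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TractSpec:
    """One guanine tract of a query.

    ``min_len`` guanines are required; ``open_ended`` means one or more
    guanines beyond the minimum are accepted (``G{min,}`` semantics), the
    closed form requires exactly ``min_len``.
    """

    min_len: int
    open_ended: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError(f"tract min_len must be >= 1, got {self.min_len}")


@dataclass(frozen=True)
class MotifQuery:
    """An ordered tract/loop pattern with a unique label."""

    tracts: tuple[TractSpec, ...]
    loop_min: int
    loop_max: int
    label: str

    def __post_init__(self) -> None:
        if len(self.tracts) < 2:
            raise ValueError("a query needs at least two tracts")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError(
                f"invalid loop bounds [{self.loop_min}, {self.loop_max}]"
            )
        if self.loop_max < 1:
            raise ValueError("loop_max must be positive")

    @property
    def isolated_positions(self) -> tuple[int, ...]:
        """1-based positions of tracts with min_len == 1."""
        return tuple(
            i + 1 for i, t in enumerate(self.tracts) if t.min_len == 1
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "loop_min": self.loop_min,
            "loop_max": self.loop_max,
            "tracts": [
                {"min_len": t.min_len, "open_ended": t.open_ended}
                for t in self.tracts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotifQuery":
        return cls(
            tracts=tuple(
                TractSpec(t["min_len"], t["open_ended"]) for t in d["tracts"]
            ),
            loop_min=d["loop_min"],
            loop_max=d["loop_max"],
            label=d["label"],
        )


@dataclass(frozen=True)
class QuerySet:
    queries: tuple[MotifQuery, ...]
    family_name: str

    def __post_init__(self) -> None:
        labels = [q.label for q in self.queries]
        if len(set(labels)) != len(labels):
            raise ValueError("query labels must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.queries)

    def __iter__(self) -> Iterator[MotifQuery]:
        return iter(self.queries)

    def to_dict(self) -> dict:
        return {
            "family_name": self.family_name,
            "queries": [q.to_dict() for q in self.queries],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuerySet":
        return cls(
            queries=tuple(MotifQuery.from_dict(q) for q in d["queries"]),
            family_name=d["family_name"],
        )


@dataclass(frozen=True)
class MotifHit:
    """An interval of a scanned sequence matching one query exactly.

    Coordinates are 0-based half-open on the forward strand; hits found on
    the reverse complement are reported with strand '-' and reflected
    coordinates.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    query_label: str
    matched_text: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit end must exceed start")
        if len(self.matched_text) != self.end - self.start:
            raise ValueError("matched_text length inconsistent with interval")

    @property
    def sort_key(self) -> tuple:
        return (self.sequence_id, self.start, self.query_label)


@dataclass(frozen=True)
class Run:
    base: str  # 'G' or 'other'
    length: int
    start: int


@dataclass(frozen=True)
class TractDecomposition:
    runs: tuple[Run, ...]
    g_run_lengths: tuple[int, ...]

    @property
    def n_guanines(self) -> int:
        return sum(self.g_run_lengths)

    def g_run_count(self, length: int) -> int:
        """Number of maximal G-runs of exactly the given length."""
        return sum(1 for n in self.g_run_lengths if n == length)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _validate_dna(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in VALID_BASES:
            raise ValueError(
                f"invalid character {ch!r} at position {i}: "
                "expected A/C/G/T/N"
            )
    return up


def decompose_tracts(seq: str) -> TractDecomposition:
    """Split a DNA string into maximal G-runs and non-G runs.

    Case-insensitive; ``N`` counts as non-G.  Raises ``ValueError`` on empty
    input or characters outside A/C/G/T/N (naming the offending position).
    """
    up = _validate_dna(seq)
    runs: list[Run] = []
    i = 0
    while i < len(up):
        is_g = up[i] == "G"
        j = i
        while j < len(up) and (up[j] == "G") == is_g:
            j += 1
        runs.append(Run("G" if is_g else "other", j - i, i))
        i = j
    g_lengths = tuple(r.length for r in runs if r.base == "G")
    return TractDecomposition(tuple(runs), g_lengths)


def enumerate_queries(
    n_tracts: int,
    n_isolated: int,
    loop_min: int = 1,
    loop_max: int = 2,
    allow_zero_loop: bool = False,
) -> QuerySet:
    """Enumerate one query per placement of the isolated single guanines.

    Every choice of ``n_isolated`` of the ``n_tracts`` positions is relaxed
    from ``G{2,}`` to ``G{1,}``, so the family contains ``C(n_tracts,
    n_isolated)`` queries, labelled deterministically in lexicographic order
    of the chosen positions.
    """
    if n_tracts < 2:
        raise ValueError("need at least two tracts")
    if not (0 <= n_isolated <= n_tracts):
        raise ValueError("n_isolated must satisfy 0 <= n_isolated <= n_tracts")
    min_loop = 0 if allow_zero_loop else 1
    if not (min_loop <= loop_min <= loop_max) or loop_max < 1:
        raise ValueError(f"invalid loop bounds [{loop_min}, {loop_max}]")

    n_g2 = n_tracts - n_isolated
    family = f"{n_g2}G2+{n_isolated}G1" if n_isolated else f"{n_tracts}G2"
    queries = []
    for combo in itertools.combinations(range(1, n_tracts + 1), n_isolated):
        iso = set(combo)
        tracts = tuple(
            TractSpec(min_len=1 if p in iso else 2, open_ended=True)
            for p in range(1, n_tracts + 1)
        )
        label = family
        if combo:
            label += ":" + "-".join(f"{p:02d}" for p in combo)
        queries.append(
            MotifQuery(tracts=tracts, loop_min=loop_min, loop_max=loop_max,
                       label=label)
        )
    return QuerySet(tuple(queries), family)


def compile_query(q: MotifQuery, strict_tracts: bool = False) -> re.Pattern:
    """Compile a query into a regular expression over {A,C,G,T}.

    Open-ended tracts become ``G{min,}``; in strict mode each tract is
    exactly ``G{min}`` and the whole match may not be flanked by a guanine,
    so every tract coincides with a maximal G-run.
    """
    loop = f"[{LOOP_ALPHABET}]{{{q.loop_min},{q.loop_max}}}"
    parts = []
    for t in q.tracts:
        if strict_tracts or not t.open_ended:
            parts.append(f"G{{{t.min_len}}}")
        else:
            parts.append(f"G{{{t.min_len},}}")
    body = loop.join(parts)
    if strict_tracts:
        body = f"(?<!G)(?:{body})(?!G)"
    return re.compile(body)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _matches_forward(
    seq: str,
    qs: QuerySet,
    policy: OverlapPolicy,
    strict_tracts: bool,
) -> Iterator[tuple[str, int, int]]:
    """Yield (label, start, end) on the given (already forward) string."""
    for q in qs:
        pat = compile_query(q, strict_tracts=strict_tracts)
        if policy == "leftmost_nonoverlap":
            for m in pat.finditer(seq):
                yield q.label, m.start(), m.end()
        elif policy == "all_overlapping":
            for pos in range(len(seq)):
                m = pat.match(seq, pos)
                if m:
                    yield q.label, pos, m.end()
        elif policy == "grep_line":
            # the whole string is one "line": grep reports it at most once
            m = pat.search(seq)
            if m:
                yield q.label, m.start(), m.end()
        else:
            raise ValueError(f"unknown overlap policy: {policy}")


def scan_sequence(
    seq: str,
    qs: QuerySet,
    overlap_policy: OverlapPolicy = "leftmost_nonoverlap",
    strand: Strand = "fwd",
    sequence_id: str = "seq",
    strict_tracts: bool = False,
) -> list[MotifHit]:
    """Scan one DNA string with every query of a set.

    ``all_overlapping`` reports every distinct (start, query) match;
    ``leftmost_nonoverlap`` uses leftmost non-overlapping greedy matching per
    query (grep -o semantics); ``grep_line`` treats the string as a single
    line and reports it at most once per query.  Reverse-strand hits are
    found on the reverse complement and reported in forward coordinates.
    """
    up = _validate_dna(seq) if seq else ""
    if not len(qs):
        raise ValueError("empty query set")
    hits: list[MotifHit] = []
    L = len(up)
    if strand in ("fwd", "both"):
        for label, s, e in _matches_forward(up, qs, overlap_policy,
                                            strict_tracts):
            hits.append(MotifHit(sequence_id, s, e, "+", label, up[s:e]))
    if strand in ("rev", "both"):
        rc = reverse_complement(up)
        for label, s, e in _matches_forward(rc, qs, overlap_policy,
                                            strict_tracts):
            hits.append(
                MotifHit(sequence_id, L - e, L - s, "-", label, rc[s:e])
            )
    hits.sort(key=lambda h: h.sort_key)
    return hits


def _mask_lowercase(raw: str) -> str:
    # soft-masked (lowercase) positions match neither tracts nor loops
    return "".join("N" if c.islower() else c for c in raw)


def scan_fasta(
    fasta_path,
    qs: QuerySet,
    overlap_policy: OverlapPolicy = "leftmost_nonoverlap",
    strand: Strand = "fwd",
    strict_tracts: bool = False,
    respect_softmask: bool = False,
):
    """Scan every record of a FASTA file; return (hits, per-query counts).

    With ``overlap_policy='grep_line'`` matching is performed line by line on
    the file's own line structure, reproducing UNIX ``grep`` over a wrapped
    FASTA: each matching line counts once per query and matches spanning a
    line break are not seen.  Other policies operate on the concatenated
    record sequence.

    Returns a list of :class:`MotifHit` and a ``pandas.DataFrame`` with
    columns ``query_label`` and ``n_hits`` (zero-count queries included).
    """
    import pandas as pd

    from .io import read_fasta, read_fasta_lines

    if not len(qs):
        raise ValueError("empty query set")
    hits: list[MotifHit] = []
    if overlap_policy == "grep_line":
        seen_ids: set[str] = set()
        for rec_id, line, offset in read_fasta_lines(fasta_path):
            if offset == 0:
                if rec_id in seen_ids:
                    raise ValueError(f"duplicated FASTA record id: {rec_id}")
                seen_ids.add(rec_id)
            text = _mask_lowercase(line) if respect_softmask else line.upper()
            if any(c not in VALID_BASES for c in text):
                bad = next(c for c in text if c not in VALID_BASES)
                raise ValueError(
                    f"invalid character {bad!r} in record {rec_id}"
                )
            segments = []
            if strand in ("fwd", "both"):
                segments.append(("+", text))
            if strand in ("rev", "both"):
                segments.append(("-", reverse_complement(text)))
            for st, segtext in segments:
                for label, s, e in _matches_forward(
                    segtext, qs, "grep_line", strict_tracts
                ):
                    if st == "+":
                        a, b = offset + s, offset + e
                        matched = text[s:e]
                    else:
                        a = offset + len(text) - e
                        b = offset + len(text) - s
                        matched = segtext[s:e]
                    hits.append(MotifHit(rec_id, a, b, st, label, matched))
    else:
        for rec_id, seq in read_fasta(
            fasta_path, respect_softmask=respect_softmask
        ):
            if not seq:
                continue
            text = _mask_lowercase(seq) if respect_softmask else seq
            hits.extend(
                scan_sequence(
                    text, qs, overlap_policy=overlap_policy, strand=strand,
                    sequence_id=rec_id, strict_tracts=strict_tracts,
                )
            )
    hits.sort(key=lambda h: h.sort_key)
    counts = {q.label: 0 for q in qs}
    for h in hits:
        counts[h.query_label] += 1
    summary = pd.DataFrame(
        {"query_label": list(counts), "n_hits": list(counts.values())}
    ).sort_values("query_label", ignore_index=True)
    return hits, summary
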