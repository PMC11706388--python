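"""Dot-bracket parsing and loop/stem decomposition of RNA secondary structures.

An RNA secondary structure is a set of base pairs over a sequence of
nucleotides.  Pseudoknot-free structures (no two pairs cross) decompose
uniquely into *stems* (maximal runs of consecutively nested base pairs) and
*loops* (the regions of unpaired nucleotides between stems): hairpin loops,
bulges, interior loops, multiloops, and the opening region that contains the
5' and 3' ends.  The unpaired nucleotides around a loop fall into *loop
groups*, the maximal runs delimited by the stems attached to the loop.

All positions are 1-based and intervals are closed on both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "SecondaryStructure",
    "Loop",
    "Stem",
    "Branch",
    "RegionDecomposition",
    "ParseError",
    "PseudoknotError",
    "parse_dot_bracket",
    "detect_pseudoknots",
    "strip_pseudoknots",
    "decompose",
    "read_structure_file",
    "write_dbn",
]

_OPEN_BRACKETS = "([{<"
_CLOSE_BRACKETS = ")]}>"
_RNA_ALPHABET = set("ACGUN")


class ParseError(ValueError):
    """Raised for malformed dot-bracket input."""


class PseudoknotError(ValueError):
    """Raised when crossing base pairs reach a pseudoknot-free-only routine."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A base-pair set over ``length`` nucleotides, positions 1-based.

    ``pairs`` holds tuples ``(i, j)`` with ``i < j``; each position occurs in
    at most one pair.  ``sequence`` is optional and, when present, has exactly
    ``length`` characters over A/C/G/U/N.
    """

    length: int
    pairs: frozenset[tuple[int, int]]
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position participates in more than one pair: ({i},{j})")
            seen.update((i, j))
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match structure length")

    @property
    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.update((i, j))
        return out

    @property
    def unpaired_positions(self) -> list[int]:
        paired = self.paired_positions
        return [p for p in range(1, self.length + 1) if p not in paired]

    def is_pseudoknot_free(self) -> bool:
        return not detect_pseudoknots(self)

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)


@dataclass
class Stem:
    """An uninterrupted run of nested base pairs.

    ``pairs`` is ordered outermost to innermost: ``(i, j), (i+1, j-1), ...``.
    A stem of ``size`` base pairs encloses ``size - 1`` stem regions (the
    spaces between consecutive pairs).  ``parent_loop``/``child_loop`` index
    the loop nearer to and away from the opening region.
    """

    index: int
    pairs: list[tuple[int, int]]
    parent_loop: int = -1
    child_loop: int = -1

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def n_stem_regions(self) -> int:
        return self.size - 1

    @property
    def outer_pair(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner_pair(self) -> tuple[int, int]:
        return self.pairs[-1]


@dataclass
class Loop:
    """A loop region: hairpin, bulge, interior, multiloop or opening.

    ``groups`` lists the maximal runs of unpaired positions around the loop in
    5'-to-3' order; empty runs between abutting stems are omitted.  ``size``
    is the total number of unpaired nucleotides.
    """

    index: int
    kind: str  # hairpin | bulge | interior | multiloop | opening
    unpaired_positions: list[int]
    groups: list[list[int]]
    bounding_stems: list[int]
    closing_stem: Optional[int] = None  # stem between this loop and the opening side

    @property
    def size(self) -> int:
        return len(self.unpaired_positions)

    @property
    def group_sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


@dataclass
class Branch:
    """A stem together with every region it subtends (away from the opening)."""

    stem: int
    loops: list[int]
    stems: list[int]
    is_linear: bool


@dataclass
class RegionDecomposition:
    """Full loop/stem decomposition of a pseudoknot-free structure."""

    structure: SecondaryStructure
    loops: list[Loop]
    stems: list[Stem]
    branches: list[Branch] = field(default_factory=list)

    @property
    def opening(self) -> Loop:
        return self.loops[0]

    def stem_sizes(self) -> list[int]:
        return [s.size for s in self.stems]

    def loop_sizes(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for lp in self.loops:
            out.setdefault(lp.kind, []).append(lp.size)
        return out

    def total_stem_regions(self) -> int:
        return sum(s.n_stem_regions for s in self.stems)

    def total_loop_groups(self) -> int:
        return sum(len(lp.groups) for lp in self.loops)

    def to_records(self) -> list[dict]:
        recs = []
        for lp in self.loops:
            recs.append(
                {
                    "region": "loop",
                    "kind": lp.kind,
                    "size": lp.size,
                    "groups": lp.group_sizes,
                    "stems": lp.bounding_stems,
                }
            )
        for st in self.stems:
            recs.append(
                {
                    "region": "stem",
                    "kind": "stem",
                    "size": st.size,
                    "groups": [],
                    "stems": [st.index],
                }
            )
        return recs

    def to_json(self) -> str:
        return json.dumps(self.to_records(), indent=2)

    def to_tsv(self) -> str:
        lines = ["region\tkind\tsize\tgroups\tstems"]
        for r in self.to_records():
            lines.append(
                "{region}\t{kind}\t{size}\t{g}\t{s}".format(
                    g=",".join(map(str, r["groups"])),
                    s=",".join(map(str, r["stems"])),
                    **r,
                )
            )
        return "\n".join(lines) + "\n"


def parse_dot_bracket(db: str, sequence: Optional[str] = None) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Round brackets are matched by a stack.  Extended bracket alphabets
    (``[]``, ``{}``, ``<>``) are accepted so that pseudoknotted annotations
    can be parsed and then screened with :func:`detect_pseudoknots`; each
    bracket family is matched with its own stack.

    Raises :class:`ParseError` naming the offending 1-based position for an
    unbalanced bracket, and for characters outside the dot-bracket alphabet.
    """
    if sequence is not None:
        sequence = sequence.upper().replace("T", "U")
        if len(sequence) != len(db):
            raise ParseError(
                f"sequence length {len(sequence)} does not match structure length {len(db)}"
            )
        bad = set(sequence) - _RNA_ALPHABET
        if bad:
            raise ParseError(f"invalid sequence characters: {sorted(bad)}")

    stacks: list[list[int]] = [[] for _ in _OPEN_BRACKETS]
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        if ch in _OPEN_BRACKETS:
            stacks[_OPEN_BRACKETS.index(ch)].append(pos)
        elif ch in _CLOSE_BRACKETS:
            stack = stacks[_CLOSE_BRACKETS.index(ch)]
            if not stack:
                raise ParseError(f"unmatched closing bracket {ch!r} at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise ParseError(f"invalid character {ch!r} at position {pos}")
    for bracket, stack in zip(_OPEN_BRACKETS, stacks):
        if stack:
            raise ParseError(f"unmatched opening bracket {bracket!r} at position {stack[-1]}")
    return SecondaryStructure(length=len(db), pairs=frozenset(pairs), sequence=sequence)


def detect_pseudoknots(
    ss: SecondaryStructure,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Return every crossing couple of base pairs ``((i,j),(k,l))`` with i<k<j<l.

    The list is empty iff the structure is pseudoknot-free.
    """
    ordered = sorted(ss.pairs)
    crossings = []
    for a in range(len(ordered)):
        i, j = ordered[a]
        for b in range(a + 1, len(ordered)):
            k, l = ordered[b]
            if k >= j:
                break
            if i < k < j < l:
                crossings.append(((i, j), (k, l)))
    return crossings


def strip_pseudoknots(ss: SecondaryStructure) -> SecondaryStructure:
    """Remove crossing pairs greedily: drop the later-opening pair of each crossing."""
    pairs = set(ss.pairs)
    while True:
        trial = SecondaryStructure(ss.length, frozenset(pairs), ss.sequence)
        crossings = detect_pseudoknots(trial)
        if not crossings:
            return trial
        drop = {max(c) for c in crossings}
        pairs -= drop


def decompose(ss: SecondaryStructure) -> RegionDecomposition:
    """Decompose a pseudoknot-free structure into loops, stems and branches.

    Every nucleotide is assigned to exactly one stem (if paired) or one loop
    (if unpaired).  Raises :class:`PseudoknotError` on crossing pairs.
    """
    if detect_pseudoknots(ss):
        raise PseudoknotError("structure contains crossing base pairs; strip or reject first")

    pair_of: dict[int, int] = {}
    for i, j in ss.pairs:
        pair_of[i] = j
        pair_of[j] = i

    ordered = sorted(ss.pairs)
    # Stems: maximal runs (i,j),(i+1,j-1),...
    pair_set = set(ordered)
    stems: list[Stem] = []
    stem_of_pair: dict[tuple[int, int], int] = {}
    for i, j in ordered:
        if (i - 1, j + 1) in pair_set:
            continue  # not the outer pair of its stem
        run = []
        a, b = i, j
        while (a, b) in pair_set:
            run.append((a, b))
            a, b = a + 1, b - 1
        idx = len(stems)
        stems.append(Stem(index=idx, pairs=run))
        for p in run:
            stem_of_pair[p] = idx

    loops: list[Loop] = []

    def make_loop(
        kind: str,
        runs: list[list[int]],
        bounding: list[int],
        closing: Optional[int],
    ) -> int:
        groups = [r for r in runs if r]
        unpaired = [p for r in groups for p in r]
        idx = len(loops)
        loops.append(
            Loop(
                index=idx,
                kind=kind,
                unpaired_positions=unpaired,
                groups=groups,
                bounding_stems=bounding,
                closing_stem=closing,
            )
        )
        return idx

    def child_stems_in(lo: int, hi: int) -> list[int]:
        """Outer pairs of stems whose span lies strictly inside (lo, hi), top level."""
        out = []
        p = lo + 1
        while p < hi:
            if p in pair_of and pair_of[p] > p:
                out.append(stem_of_pair[(p, pair_of[p])])
                p = pair_of[p] + 1
            else:
                p += 1
        return out

    def runs_between(lo: int, hi: int, cut_spans: list[tuple[int, int]]) -> list[list[int]]:
        """Maximal unpaired runs in (lo, hi) split by the cut spans (stems)."""
        runs: list[list[int]] = []
        cur: list[int] = []
        spans = sorted(cut_spans)
        si = 0
        p = lo + 1
        while p < hi:
            if si < len(spans) and p == spans[si][0]:
                runs.append(cur)
                cur = []
                p = spans[si][1] + 1
                si += 1
            else:
                cur.append(p)
                p += 1
        runs.append(cur)
        return runs

    # Opening region: everything outside all top-level stems.
    top_stems = child_stems_in(0, ss.length + 1)
    top_spans = [stems[s].outer_pair for s in top_stems]
    opening_runs = runs_between(0, ss.length + 1, top_spans)
    make_loop("opening", opening_runs, list(top_stems), closing=None)

    # One loop per stem, enclosed by its inner pair.
    stack = [(s, 0) for s in reversed(top_stems)]
    while stack:
        s_idx, parent_loop = stack.pop()
        stem = stems[s_idx]
        stem.parent_loop = parent_loop
        a, b = stem.inner_pair
        inner_stems = child_stems_in(a, b)
        inner_spans = [stems[s].outer_pair for s in inner_stems]
        runs = runs_between(a, b, inner_spans)
        if not inner_stems:
            kind = "hairpin"
        elif len(inner_stems) == 1:
            nonempty = [r for r in runs if r]
            kind = "interior" if len(nonempty) == 2 else "bulge"
        else:
            kind = "multiloop"
        loop_idx = make_loop(kind, runs, [s_idx] + inner_stems, closing=s_idx)
        stem.child_loop = loop_idx
        for child in reversed(inner_stems):
            stack.append((child, loop_idx))

    # Branches: the stem plus everything below it.
    branches: list[Branch] = []
    for stem in stems:
        sub_loops: list[int] = []
        sub_stems: list[int] = [stem.index]
        frontier = [stem.index]
        while frontier:
            s = frontier.pop()
            lp = stems[s].child_loop
            sub_loops.append(lp)
            for s2 in loops[lp].bounding_stems:
                if s2 != s:
                    sub_stems.append(s2)
                    frontier.append(s2)
        is_linear = all(loops[lp].kind != "multiloop" for lp in sub_loops)
        branches.append(Branch(stem=stem.index, loops=sub_loops, stems=sub_stems, is_linear=is_linear))

    return RegionDecomposition(structure=ss, loops=loops, stems=stems, branches=branches)


# ---------------------------------------------------------------------------
# File I/O


def _iter_dbn_records(lines: Iterable[str]) -> Iterator[tuple[str, Optional[str], str]]:
    """Yield (id, sequence-or-None, dot-bracket) from .dbn-style text.

    Accepts ``>id`` / sequence / structure triplets, ``>id`` / structure
    pairs, and bare one-structure-per-line input.
    """
    current_id: Optional[str] = None
    buf: list[str] = []
    n_anon = 0

    def flush() -> Iterator[tuple[str, Optional[str], str]]:
        nonlocal current_id, buf
        if current_id is None:
            return
        if len(buf) == 1:
            yield current_id, None, buf[0]
        elif len(buf) == 2:
            yield current_id, buf[0], buf[1]
        else:
            raise ParseError(f"record {current_id!r}: expected 1 or 2 lines, got {len(buf)}")
        current_id, buf = None, []

    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            yield from flush()
            current_id = line[1:].strip() or f"record_{n_anon}"
        elif current_id is not None:
            buf.append(line)
        else:
            n_anon += 1
            yield f"record_{n_anon}", None, line
    yield from flush()


def _iter_st_records(lines: Sequence[str], path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, dot-bracket) from bpRNA-style .st text.

    A record starts with ``#Name:`` header lines; the first two non-``#``
    lines are the sequence and the dot-bracket string, and any further
    annotation lines (structure-type string, segment lists) are skipped.
    """
    i, n = 0, len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        rec_id = f"{path}:{i + 1}"
        while i < n and lines[i].strip().startswith("#"):
            header = lines[i].strip()
            if header.lower().startswith("#name:"):
                rec_id = header.split(":", 1)[1].strip()
            i += 1
        body: list[str] = []
        while i < n and lines[i].strip() and not lines[i].strip().startswith("#"):
            body.append(lines[i].strip())
            i += 1
        if not body:
            continue
        if len(body) < 2:
            raise ParseError(f"record {rec_id!r}: .st record needs sequence and structure lines")
        yield rec_id, body[0], body[1]


def read_structure_file(
    path: str | Path, format: str = "dbn"
) -> list[tuple[str, SecondaryStructure]]:
    """Read structures from a .dbn or bpRNA-style .st file.

    Returns ``(record id, SecondaryStructure)`` tuples.  Malformed records
    raise :class:`ParseError` naming the record and position.
    """
    text = Path(path).read_text().splitlines()
    out: list[tuple[str, SecondaryStructure]] = []
    if format == "dbn":
        for rec_id, seq, db in _iter_dbn_records(text):
            try:
                out.append((rec_id, parse_dot_bracket(db, seq)))
            except ParseError as e:
                raise ParseError(f"record {rec_id!r}: {e}") from e
    elif format == "bpRNA_st":
        for rec_id, seq, db in _iter_st_records(text, str(path)):
            try:
                out.append((rec_id, parse_dot_bracket(db, seq)))
            except ParseError as e:
                raise ParseError(f"record {rec_id!r}: {e}") from e
    else:
        raise ValueError(f"unknown format {format!r}")
    return out


def write_dbn(records: Iterable[tuple[str, SecondaryStructure]], path: str | Path) -> None:
    """Write (id, structure) records as a .dbn file (id / sequence? / structure)."""
    with open(path, "w") as fh:
        for rec_id, ss in records:
            fh.write(f">{rec_id}\n")
            if ss.sequence is not None:
                fh.write(ss.sequence + "\n")
            fh.write(ss.to_dot_bracket() + "\n")
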