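"""Synthetic structures: a seeded generator, family sets, and a mock folder.

The random-structure generator emits pseudoknot-free dot-bracket strings with
controllable stem-length, loop-size, branching and bubble-density
distributions.  It emulates the two structural regimes contrasted by the
coefficient-sum analysis: linear branches with many short stems separated by
bulges and interior loops ("bubbles") versus branches with few long stems.
All randomness flows from one explicit seed per call; there is no global RNG
state.

``worked_example`` returns a 41-nt worked example whose decomposition realises
a fixed feature inventory (stems of 3+2+2+2+2 bp; opening of 3 nt with groups
1+2; an interior loop of 2 nt; a multiloop of 6 nt with groups 1+4+1; a 1-nt
bulge; hairpins of 3 and 4 nt) used throughout the tests and docs.

``mock_fold`` is a deterministic toy co-transcriptional folder: a stand-in
for an external kinetic folding program, producing one structure per
transcription step with the correct prefix length and no pseudoknots.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .structures import SecondaryStructure, parse_dot_bracket

__all__ = [
    "GeneratorParams",
    "worked_example",
    "random_structure",
    "random_rna",
    "family_set",
    "mock_fold",
    "mock_probability_track",
]

WORKED_EXAMPLE_DB = ".(((.((.((...))....((.((....)))).)).))).."

WORKED_EXAMPLE_FEATURES = {
    "length": 41,
    "n_pairs": 11,
    "stem_sizes": [2, 2, 2, 2, 3],  # sorted
    "loop_sizes": {
        "opening": [3],
        "interior": [2],
        "multiloop": [6],
        "hairpin": [3, 4],
        "bulge": [1],
    },
    "loop_groups": {
        "opening": [1, 2],
        "interior": [1, 1],
        "multiloop": [1, 4, 1],
        "bulge": [1],
        "hairpin": [[3], [4]],
    },
}


def worked_example() -> tuple[str, dict]:
    """The 41-nt worked-example dot-bracket and its expected decomposition summary."""
    return WORKED_EXAMPLE_DB, WORKED_EXAMPLE_FEATURES


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random pseudoknot-free structure generator.

    Sizes are in nucleotides (loops) or base pairs (stems); all ranges are
    closed.  ``bubble_density`` is the Poisson mean of the number of bubbles
    (bulges or interior loops) inserted along a linear branch, truncated at
    ``bubble_cap``.  ``branch_prob`` is the probability that a branch ends in
    a multiloop rather than a hairpin (up to ``max_depth`` nestings).
    """

    length: int = 200
    stem_min: int = 2
    stem_max: int = 4
    hairpin_min: int = 3
    hairpin_max: int = 5
    bulge_min: int = 1
    bulge_max: int = 2
    interior_min: int = 1
    interior_max: int = 2  # per side
    gap_min: int = 0
    gap_max: int = 3
    bubble_density: float = 2.0
    bubble_cap: int = 3
    branch_prob: float = 0.3
    multiloop_min: int = 2
    multiloop_max: int = 3
    max_depth: int = 3
    seed: int = 0

    def max_linear_nt(self) -> int:
        """Worst-case length of the linear part of one branch.

        A branch is only started (and a multiloop sub-branch only allocated)
        when this many nucleotides are still available, so no size draw is
        ever truncated and the requested distributions are realised exactly.
        """
        per_segment = 2 * self.stem_max
        per_bubble = 2 * self.interior_max
        return (
            (self.bubble_cap + 1) * per_segment
            + self.bubble_cap * per_bubble
            + self.hairpin_max
        )


def _check_feasible(p: GeneratorParams) -> None:
    if p.length < 1:
        raise ValueError("length must be >= 1")
    if not (1 <= p.stem_min <= p.stem_max):
        raise ValueError("invalid stem size range")
    if not (1 <= p.hairpin_min <= p.hairpin_max):
        raise ValueError("invalid hairpin size range")
    if p.bulge_min < 1 or p.interior_min < 1:
        raise ValueError("bubble sizes must be >= 1")


def _render_branch(
    p: GeneratorParams, rng: np.random.Generator, depth: int, budget: int
) -> str:
    """One branch within ``budget`` nt: a terminal loop wrapped in
    bubble-separated stems.

    The caller guarantees ``budget >= max_linear_nt()``, so stem, bubble and
    hairpin sizes are always drawn from their full requested ranges.  A
    multiloop terminal is chosen only when the remaining core budget can hold
    every sub-branch at its own worst case.
    """
    # linear part first: stems and bubbles, drawn untruncated
    wraps: list[tuple[str, str, str]] = []  # innermost first
    stem = _stem(p, rng)
    wraps.append((stem, "", ""))
    used = 2 * len(stem)
    n_bubbles = min(int(rng.poisson(p.bubble_density)), p.bubble_cap)
    for _ in range(n_bubbles):
        if rng.random() < 0.5:  # bulge, one side
            k = int(rng.integers(p.bulge_min, p.bulge_max + 1))
            left, right = ("." * k, "") if rng.random() < 0.5 else ("", "." * k)
        else:  # interior loop, both sides
            left = "." * int(rng.integers(p.interior_min, p.interior_max + 1))
            right = "." * int(rng.integers(p.interior_min, p.interior_max + 1))
        s = _stem(p, rng)
        wraps.append((s, left, right))
        used += 2 * len(s) + len(left) + len(right)

    core_budget = budget - used
    worst = p.max_linear_nt()
    multiloop_need = p.multiloop_min * worst + (p.multiloop_min + 1) * p.gap_max
    if (
        depth > 0
        and core_budget >= multiloop_need
        and rng.random() < p.branch_prob
    ):
        k_max = min(
            p.multiloop_max, (core_budget - p.gap_max) // (worst + p.gap_max)
        )
        k = int(rng.integers(p.multiloop_min, k_max + 1))
        parts = []
        remaining = core_budget
        for _ in range(k):
            gap = "." * int(rng.integers(p.gap_min, p.gap_max + 1))
            sub = _render_branch(p, rng, depth - 1, worst)
            parts.append(gap + sub)
            remaining -= len(gap) + len(sub)
        parts.append("." * int(rng.integers(p.gap_min, p.gap_max + 1)))
        core = "".join(parts)
    else:
        core = "." * int(rng.integers(p.hairpin_min, p.hairpin_max + 1))

    out = core
    for s, left, right in wraps:  # innermost stem wraps the terminal loop first
        out = "(" * len(s) + left + out + right + ")" * len(s)
    return out


def _stem(p: GeneratorParams, rng: np.random.Generator) -> str:
    return "s" * int(rng.integers(p.stem_min, p.stem_max + 1))


def random_structure(params: GeneratorParams) -> SecondaryStructure:
    """Draw one pseudoknot-free structure of exactly ``params.length`` nt.

    Branches are emitted into the opening region while the worst-case linear
    branch still fits the remaining budget (so no size draw is ever truncated
    and the marginals follow the requested distributions exactly); leftover
    positions stay unpaired in the opening region.
    """
    _check_feasible(params)
    rng = np.random.default_rng(params.seed)
    budget = params.length
    worst = params.max_linear_nt()
    parts: list[str] = []
    while budget >= worst + params.gap_max:
        gap = "." * int(rng.integers(params.gap_min, params.gap_max + 1))
        branch = _render_branch(params, rng, params.max_depth, budget - len(gap))
        parts.append(gap + branch)
        budget -= len(gap) + len(branch)
    parts.append("." * budget)
    db = "".join(parts)
    assert len(db) == params.length
    return parse_dot_bracket(db)


_BASES = "ACGU"


def random_rna(length: int, seed: int, gc: float = 0.5) -> str:
    """A random RNA sequence with the given GC content."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=p))


# ---------------------------------------------------------------------------
# Family sets for clustering benchmarks


def _render_template(
    stem_sizes: list[int],
    enclosing: int,
    gaps: list[int],
    hairpins: list[int],
    opening: tuple[int, int],
) -> str:
    """A structure with one enclosing stem around a multiloop of hairpin branches
    (or a single hairpin branch when there is one sub-branch)."""
    inner_parts = []
    for b, (s, h) in enumerate(zip(stem_sizes, hairpins)):
        inner_parts.append("." * gaps[b])
        inner_parts.append("(" * s + "." * h + ")" * s)
    inner_parts.append("." * gaps[len(stem_sizes)])
    inner = "".join(inner_parts)
    return (
        "." * opening[0]
        + "(" * enclosing
        + inner
        + ")" * enclosing
        + "." * opening[1]
    )


def family_set(
    n_families: int,
    per_family: int,
    seed: int,
    differ_in: str = "topology",
    jitter: int = 2,
    shift: int = 8,
) -> list[tuple[str, str, SecondaryStructure]]:
    """Labelled structures in ``n_families`` families for clustering tests.

    Each family shares a fixed loop-stem topology template; members jitter
    only in loop sizes (each loop grows by a uniform integer in
    ``[0, jitter]``).  With ``differ_in="topology"`` family ``f`` carries
    ``f + 2`` hairpin branches, so families differ in the loop-stem relation
    itself (type 1 trees separate them).  With ``differ_in="loop_size"`` all
    families share one topology and family ``f`` inflates every loop by
    ``f * shift`` nt, so only size-recording tree types can separate them.

    Returns ``(id, family_label, structure)`` tuples.
    """
    if n_families < 2:
        raise ValueError("need at least two families")
    if differ_in not in ("topology", "loop_size"):
        raise ValueError("differ_in must be 'topology' or 'loop_size'")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, SecondaryStructure]] = []

    shared_n_branches = 3
    shared_stems = [int(rng.integers(2, 5)) for _ in range(shared_n_branches)]
    shared_enclosing = int(rng.integers(2, 5))

    for f in range(n_families):
        label = f"family_{f}"
        if differ_in == "topology":
            n_branches = f + 2
            stems = [int(rng.integers(2, 5)) for _ in range(n_branches)]
            enclosing = int(rng.integers(2, 5))
            base_gap, base_hp, base_open = 1, 3, (1, 1)
            fam_shift = 0
        else:
            n_branches = shared_n_branches
            stems = shared_stems
            enclosing = shared_enclosing
            base_gap, base_hp, base_open = 1, 3, (1, 1)
            fam_shift = f * shift
        for m in range(per_family):
            j = lambda: int(rng.integers(0, jitter + 1))
            gaps = [base_gap + fam_shift + j() for _ in range(n_branches + 1)]
            hairpins = [base_hp + fam_shift + j() for _ in range(n_branches)]
            opening = (base_open[0] + fam_shift + j(), base_open[1] + fam_shift + j())
            db = _render_template(stems, enclosing, gaps, hairpins, opening)
            out.append((f"{label}_{m}", label, parse_dot_bracket(db)))
    return out


# ---------------------------------------------------------------------------
# Mock co-transcriptional folder


_COMPLEMENT = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


def _pair_accept(seed: int, i: int, p: int, bi: str, bp: str) -> bool:
    h = zlib.crc32(f"{seed}:{i}:{p}:{bi}{bp}".encode())
    return h % 4 != 0  # accept ~3/4 of complementary contacts


def _fold_prefix(seq: str, seed: int) -> SecondaryStructure:
    """Greedy seeded stack folding of a sequence; non-crossing by construction.

    Scanning 5' to 3', each nucleotide pairs with the innermost open position
    that is complementary, at least 4 nt upstream, and accepted by the seeded
    hash; open positions skipped over stay unpaired forever, so all pairs are
    nested.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for p, base in enumerate(seq, start=1):
        partner_depth = None
        for d in range(len(stack) - 1, -1, -1):
            i = stack[d]
            if (
                p - i >= 4
                and (seq[i - 1], base) in _COMPLEMENT
                and _pair_accept(seed, i, p, seq[i - 1], base)
            ):
                partner_depth = d
                break
        if partner_depth is not None:
            pairs.add((stack[partner_depth], p))
            del stack[partner_depth:]
        else:
            stack.append(p)
    return SecondaryStructure(length=len(seq), pairs=frozenset(pairs), sequence=seq)


def mock_fold(rna_segment: str, seed: int) -> list[SecondaryStructure]:
    """Deterministic toy co-transcriptional folding of one RNA segment.

    Step ``j`` (1-based) returns a pseudoknot-free structure on the ``j``-nt
    prefix, so a segment of ``m`` nt yields ``m`` structures with 1..m
    nucleotides.  Identical ``(segment, seed)`` input gives an identical
    series.
    """
    if len(rna_segment) < 1:
        raise ValueError("segment must have at least one nucleotide")
    rna_segment = rna_segment.upper().replace("T", "U")
    return [_fold_prefix(rna_segment[:j], seed) for j in range(1, len(rna_segment) + 1)]


def mock_probability_track(
    normalized_overlapping: np.ndarray,
    peak_probability: float,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """A synthetic per-nucleotide R-loop probability track.

    Built as a noisy affine image of a normalized overlapping coefficient-sum
    profile: ``clip(profile * peak_probability + N(0, noise_sd), 0, 1)``.
    Serves as a stand-in for an experimentally measured footprinting track in
    end-to-end pipeline tests.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(normalized_overlapping, dtype=float) * peak_probability
    return np.clip(base + rng.normal(0.0, noise_sd, size=base.shape), 0.0, 1.0)
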