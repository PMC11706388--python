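"""Sliding-window coefficient-sum pipeline for R-loop propensity.

The pipeline scans the RNA transcript of a plasmid amplicon with an m-nt
sliding window.  For every window start i (1 <= i <= n - m + 1) a
co-transcriptional folder supplies one secondary structure per transcription
step j = 1..m (the structure of the j-nt prefix of the window).  The type-k
tree-polynomial coefficient sum of the structure at (i, j) is s(i, j).  Per
step j, derived tracks are:

* normalized sum:        s(i, j) / max_l s(l, j), per window;
* overlapping sum:       per nucleotide p, the sum of s(i, j) over all
                         windows i covering p;
* normalized overlapping sum: overlapping / its maximum;
* scaled sum:            normalized overlapping x max of the experimental
                         R-loop probability track.

The scaled sum at a step is compared with the experimental per-nucleotide
R-loop probability by Pearson correlation; reporting typically focuses on
the last ten transcription steps, where the windows carry the most complete
structural information.

Windows are treated as mutually independent; plasmid topology (supercoiling
state) is metadata only and never enters the computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .polynomials import tree_polynomial
from .structures import SecondaryStructure, parse_dot_bracket, decompose
from .trees import build_tree

__all__ = [
    "AmpliconSpec",
    "StructureGrid",
    "SumTracks",
    "ProbabilityTrack",
    "dna_to_rna",
    "windows",
    "ingest_folding",
    "mock_structure_grid",
    "coefficient_sum_grid",
    "normalized_sum",
    "overlapping_sum",
    "scaled_sum",
    "correlate",
    "best_step_report",
    "read_probability_track",
]

_DNA = set("ACGTUN")


def dna_to_rna(dna: str, strand: str = "coding") -> str:
    """Transcribe a DNA string to RNA.

    ``strand="coding"`` (default) is the identity with T -> U; with
    ``strand="template"`` the input is read as the template strand and the
    reverse complement is transcribed.  Sequences already in the RNA alphabet
    pass through unchanged on the coding convention.
    """
    dna = dna.upper()
    bad = set(dna) - _DNA
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    if strand == "coding":
        return dna.replace("T", "U")
    if strand == "template":
        comp = {"A": "U", "T": "A", "U": "A", "G": "C", "C": "G", "N": "N"}
        return "".join(comp[b] for b in reversed(dna))
    raise ValueError("strand must be 'coding' or 'template'")


def windows(n: int, m: int) -> list[tuple[int, int]]:
    """All m-nt sliding-window intervals [i, i+m-1] over n nt, 1-based inclusive.

    There are exactly n - m + 1 of them.
    """
    if not 1 <= m <= n:
        raise ValueError(f"window length m={m} must satisfy 1 <= m <= n={n}")
    return [(i, i + m - 1) for i in range(1, n - m + 2)]


@dataclass(frozen=True)
class AmpliconSpec:
    """A plasmid and the amplicon interval analysed, 1-based inclusive."""

    plasmid_id: str
    sequence: str
    start: int
    end: int
    window: int = 200

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end <= len(self.sequence):
            raise ValueError("amplicon interval outside the plasmid sequence")
        if not 1 <= self.window <= self.n:
            raise ValueError("window length must be between 1 and the amplicon length")

    @property
    def n(self) -> int:
        return self.end - self.start + 1

    @property
    def amplicon_dna(self) -> str:
        return self.sequence[self.start - 1 : self.end]

    def amplicon_rna(self, strand: str = "coding") -> str:
        return dna_to_rna(self.amplicon_dna, strand)


@dataclass
class StructureGrid:
    """Structures indexed (i, j): window start i, transcription step j.

    The structure at (i, j) is the fold of the j-nt prefix of window i and
    has exactly j nucleotides.
    """

    n: int
    m: int
    structures: dict[tuple[int, int], SecondaryStructure]
    provenance: str = "unknown"

    @property
    def n_windows(self) -> int:
        return self.n - self.m + 1

    def validate(self) -> None:
        for i in range(1, self.n_windows + 1):
            for j in range(1, self.m + 1):
                ss = self.structures.get((i, j))
                if ss is None:
                    raise ValueError(f"missing structure at (i={i}, j={j})")
                if ss.length != j:
                    raise ValueError(
                        f"structure at (i={i}, j={j}) has {ss.length} nt, expected {j}"
                    )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} m={self.m} provenance={self.provenance}\n")
            fh.write("i\tj\tstructure\n")
            for (i, j), ss in sorted(self.structures.items()):
                fh.write(f"{i}\t{j}\t{ss.to_dot_bracket()}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "StructureGrid":
        lines = Path(path).read_text().splitlines()
        header = lines[0].lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        structures: dict[tuple[int, int], SecondaryStructure] = {}
        for line in lines[2:]:
            i, j, db = line.split("\t")
            structures[(int(i), int(j))] = parse_dot_bracket(db)
        return cls(
            n=int(meta["n"]),
            m=int(meta["m"]),
            structures=structures,
            provenance=meta.get("provenance", "file"),
        )


def mock_structure_grid(rna: str, m: int, seed: int) -> StructureGrid:
    """Fold every window of ``rna`` with the deterministic mock folder."""
    from .synthetic import mock_fold

    n = len(rna)
    structures: dict[tuple[int, int], SecondaryStructure] = {}
    for i, (lo, hi) in enumerate(windows(n, m), start=1):
        series = mock_fold(rna[lo - 1 : hi], seed)
        for j, ss in enumerate(series, start=1):
            structures[(i, j)] = ss
    grid = StructureGrid(n=n, m=m, structures=structures, provenance=f"mock(seed={seed})")
    grid.validate()
    return grid


def ingest_folding(
    folder: str | Path,
    n: int,
    m: int,
    rule: str = "occupancy",
) -> StructureGrid:
    """Adapter for external co-transcriptional folder output.

    Expects one file ``window_<i>.tsv`` per window start i under ``folder``,
    with tab-separated lines ``j  dot-bracket  [occupancy  [energy]]``.  When
    a step reports several coexisting structures, ``rule="occupancy"`` keeps
    the highest-occupancy one and ``rule="mfe"`` the lowest-energy one (the
    choice is recorded in provenance).  Missing steps or wrong prefix lengths
    raise a validation error naming (i, j).
    """
    if rule not in ("occupancy", "mfe"):
        raise ValueError("rule must be 'occupancy' or 'mfe'")
    folder = Path(folder)
    structures: dict[tuple[int, int], SecondaryStructure] = {}
    n_windows = n - m + 1
    for i in range(1, n_windows + 1):
        path = folder / f"window_{i}.tsv"
        if not path.exists():
            raise ValueError(f"missing folder output for window i={i}: {path}")
        candidates: dict[int, list[tuple[str, float, float]]] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            j = int(fields[0])
            db = fields[1]
            occ = float(fields[2]) if len(fields) > 2 else 1.0
            en = float(fields[3]) if len(fields) > 3 else 0.0
            candidates.setdefault(j, []).append((db, occ, en))
        for j in range(1, m + 1):
            if j not in candidates:
                raise ValueError(f"missing transcription step at (i={i}, j={j})")
            if rule == "occupancy":
                db = max(candidates[j], key=lambda t: t[1])[0]
            else:
                db = min(candidates[j], key=lambda t: t[2])[0]
            ss = parse_dot_bracket(db)
            if ss.length != j:
                raise ValueError(
                    f"structure at (i={i}, j={j}) has {ss.length} nt, expected {j}"
                )
            structures[(i, j)] = ss
    return StructureGrid(n=n, m=m, structures=structures, provenance=f"folder:{folder}({rule})")


# ---------------------------------------------------------------------------
# Coefficient sums and derived tracks


@dataclass
class SumTracks:
    """The s(i, j) coefficient-sum grid for one tree type, with derived tracks."""

    n: int
    m: int
    tree_type: int
    s: dict[tuple[int, int], int]

    @property
    def n_windows(self) -> int:
        return self.n - self.m + 1

    def column(self, j: int) -> list[int]:
        """s(., j) for window starts 1..n-m+1."""
        if not 1 <= j <= self.m:
            raise ValueError(f"step j={j} outside 1..{self.m}")
        return [self.s[(i, j)] for i in range(1, self.n_windows + 1)]

    def normalized(self, j: int) -> np.ndarray:
        return normalized_sum(self.column(j))

    def overlapping(self, j: int) -> list[int]:
        return overlapping_sum(self.column(j), self.n, self.m)

    def normalized_overlapping(self, j: int) -> np.ndarray:
        return normalized_sum(self.overlapping(j))

    def scaled(self, j: int, experimental: "ProbabilityTrack") -> np.ndarray:
        return scaled_sum(self.overlapping(j), experimental)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} m={self.m} tree_type={self.tree_type}\n")
            fh.write("i\tj\tsum\n")
            for (i, j), v in sorted(self.s.items()):
                fh.write(f"{i}\t{j}\t{v}\n")


def coefficient_sum_grid(grid: StructureGrid, tree_type: int) -> SumTracks:
    """s(i, j) = coefficient sum of the type-k tree-polynomial at every (i, j).

    Sums are exact arbitrary-precision integers.  Pseudoknot errors are
    re-raised with their (i, j) coordinate.
    """
    s: dict[tuple[int, int], int] = {}
    for (i, j), ss in grid.structures.items():
        try:
            poly = tree_polynomial(build_tree(decompose(ss), tree_type))
        except Exception as e:
            raise type(e)(f"at grid position (i={i}, j={j}): {e}") from e
        s[(i, j)] = poly.coefficient_sum()
    return SumTracks(n=grid.n, m=grid.m, tree_type=tree_type, s=s)


def normalized_sum(values: Iterable[int]) -> np.ndarray:
    """values / max(values), exact rational division then float.

    An all-zero column returns zeros with a warning.
    """
    vals = list(values)
    vmax = max(vals)
    if vmax == 0:
        warnings.warn("all-zero column; normalized sum is identically zero")
        return np.zeros(len(vals))
    if all(isinstance(v, int) for v in vals):
        return np.array([float(Fraction(v, vmax)) for v in vals])
    return np.asarray(vals, dtype=float) / float(vmax)


def overlapping_sum(column: list[int], n: int, m: int) -> list[int]:
    """Per-nucleotide overlapping sum at one step.

    Each window i contributes s(i, j) to every nucleotide in [i, i+m-1]; the
    value at nucleotide p is the sum over the windows covering p.  Exact
    integers (a sliding cumulative difference; O(n)).
    """
    n_windows = n - m + 1
    if len(column) != n_windows:
        raise ValueError(f"expected {n_windows} window sums, got {len(column)}")
    diff = [0] * (n + 1)
    for i, v in enumerate(column, start=1):
        diff[i - 1] += v
        if i - 1 + m <= n:
            diff[i - 1 + m] -= v
    out = []
    acc = 0
    for p in range(n):
        acc += diff[p]
        out.append(acc)
    return out


@dataclass(frozen=True)
class ProbabilityTrack:
    """Per-nucleotide probability of R-loop formation over the amplicon."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("track must be one-dimensional")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max(self) -> float:
        return float(self.values.max())


def read_probability_track(path: str | Path) -> ProbabilityTrack:
    """Read a 2-column (position, probability) TSV track; positions 1-based."""
    pos_vals: list[tuple[int, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        pos_vals.append((int(fields[0]), float(fields[1])))
    pos_vals.sort()
    n = pos_vals[-1][0]
    values = np.zeros(n)
    for p, v in pos_vals:
        values[p - 1] = v
    return ProbabilityTrack(values=values)


def scaled_sum(overlapping: list[int], experimental: ProbabilityTrack) -> np.ndarray:
    """Normalized overlapping sum rescaled to the experimental maximum.

    The maximum of the scaled track equals the maximum of the experimental
    probability track (when the overlapping sum is not identically zero).
    """
    if len(overlapping) != len(experimental):
        raise ValueError("overlapping sum and experimental track lengths differ")
    return normalized_sum(overlapping) * experimental.max


def correlate(scaled: np.ndarray, experimental: ProbabilityTrack) -> float:
    """Pearson correlation between a scaled-sum track and the experimental track.

    Positions where either track is undefined (NaN) are excluded pairwise.
    Returns NaN for constant input, with a warning.
    """
    x = np.asarray(scaled, dtype=float)
    y = experimental.values
    if len(x) != len(y):
        raise ValueError("track lengths differ")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant track; Pearson correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def best_step_report(
    tracks: SumTracks,
    experimental: ProbabilityTrack,
    steps: Optional[Iterable[int]] = None,
) -> dict:
    """PCC per transcription step and the best step in the given range.

    ``steps`` defaults to the last ten transcription steps (m-9 .. m), where
    the windows carry the most complete structures.  Cross-step selection is
    an explicit reporting operation: every per-step PCC is returned alongside
    the maximiser.
    """
    if steps is None:
        steps = range(max(1, tracks.m - 9), tracks.m + 1)
    steps = list(steps)
    pccs: dict[int, float] = {}
    for j in steps:
        pccs[j] = correlate(tracks.scaled(j, experimental), experimental)
    finite = {j: v for j, v in pccs.items() if not np.isnan(v)}
    best = max(finite, key=finite.get) if finite else None
    return {
        "tree_type": tracks.tree_type,
        "steps": steps,
        "pcc": pccs,
        "best_step": best,
        "best_pcc": pccs.get(best) if best is not None else float("nan"),
    }
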