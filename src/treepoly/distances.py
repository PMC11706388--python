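"""Canberra-style coefficient distances between tree-polynomials.

The distance between two same-type tree-polynomials is the sum, over every
cell of their coefficient tensors, of the relative coefficient difference
kappa(b, c) = |b - c| / (b + c) (and 0 when both coefficients vanish).  The
sum runs over the union of the two sparse supports: out-of-support cells
contribute kappa(0, 0) = 0, so the cubic dense tensor is never materialised.

Because P is a complete invariant, a distance of 0 between same-type
polynomials certifies isomorphic trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .polynomials import Polynomial

__all__ = ["kappa", "poly_distance", "pairwise_distances", "DistanceMatrix"]


def kappa(b: int, c: int) -> float:
    """Relative coefficient difference |b-c|/(b+c); 0 when both are zero."""
    if b < 0 or c < 0:
        raise ValueError("coefficients must be non-negative")
    if b == 0 and c == 0:
        return 0.0
    return float(Fraction(abs(b - c), b + c))


def _distance_fraction(p1: Polynomial, p2: Polynomial) -> Fraction:
    if p1.nvars != p2.nvars:
        raise ValueError("cannot compare polynomials of different arity")
    total = Fraction(0)
    support = set(p1.terms) | set(p2.terms)
    for exp in support:
        b = p1.terms.get(exp, 0)
        c = p2.terms.get(exp, 0)
        if b or c:
            total += Fraction(abs(b - c), b + c)
    return total


def poly_distance(p1: Polynomial, p2: Polynomial) -> float:
    """Coefficient-wise Canberra distance between two same-arity polynomials.

    Exact rational accumulation internally (coefficients can exceed float
    range); the result is returned as a float.
    """
    return float(_distance_fraction(p1, p2))


@dataclass
class DistanceMatrix:
    """A symmetric pairwise distance matrix with stable structure identifiers."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        ids = lines[0].split("\t")[1:]
        values = np.array(
            [[float(v) for v in line.split("\t")[1:]] for line in lines[1:]]
        )
        return cls(ids=ids, values=values)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(f"{rid:<10s} " + " ".join(f"{v:.10f}" for v in row) + "\n")


def pairwise_distances(
    polys: Sequence[Polynomial], ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """All pairwise polynomial distances among ``polys``.

    Computed pair by pair; the result does not depend on evaluation order or
    chunking, so callers may shard the upper triangle freely.
    """
    n = len(polys)
    if ids is None:
        ids = [str(i) for i in range(n)]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = poly_distance(polys[i], polys[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(ids), values=values)
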