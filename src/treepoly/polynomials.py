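"""Tree-distinguishing polynomials P and Q with sparse integer coefficients.

P is a complete invariant of rooted trees in two variables, computed bottom-up:
a leaf vertex gets x, and an internal vertex with children u_1..u_k gets
y + prod_i P(u_i).  Q generalises P to trees with artificial group vertices
(tree types 2 and 4): an artificial internal vertex gets z + prod instead of
y + prod, so the loop-group feature is carried by its own variable.
Substituting z := y in Q recovers P of the same tree.

Coefficients are non-negative arbitrary-precision integers; coefficient sums
grow exponentially with the number of bubbles in linear branches, so exact
integer arithmetic is mandatory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .trees import ARTIFICIAL_GROUP, RootedTree

__all__ = [
    "Polynomial",
    "poly_P",
    "poly_Q",
    "tree_polynomial",
    "coefficient_sum",
    "evaluate",
    "to_coeff_tensor",
]

_VAR_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class Polynomial:
    """A sparse polynomial in x, y (and optionally z) with integer coefficients.

    ``terms`` maps exponent tuples of length ``nvars`` to strictly positive
    integer coefficients (zero coefficients are never stored).
    """

    nvars: int
    terms: dict[tuple[int, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nvars not in (2, 3):
            raise ValueError("nvars must be 2 (P) or 3 (Q)")
        for exp, c in self.terms.items():
            if len(exp) != self.nvars:
                raise ValueError(f"exponent {exp} does not match nvars={self.nvars}")
            if c <= 0:
                raise ValueError("stored coefficients must be strictly positive")

    # -- constructors -------------------------------------------------------

    @classmethod
    def variable(cls, name: str, nvars: int) -> "Polynomial":
        exp = [0] * nvars
        exp[_VAR_NAMES.index(name)] = 1
        return cls(nvars, {tuple(exp): 1})

    # -- algebra ------------------------------------------------------------

    def __add__(self, other: "Polynomial") -> "Polynomial":
        if self.nvars != other.nvars:
            raise ValueError("cannot add polynomials of different arity")
        terms = dict(self.terms)
        for exp, c in other.terms.items():
            terms[exp] = terms.get(exp, 0) + c
        return Polynomial(self.nvars, {e: c for e, c in terms.items() if c})

    def __mul__(self, other: "Polynomial") -> "Polynomial":
        if self.nvars != other.nvars:
            raise ValueError("cannot multiply polynomials of different arity")
        terms: dict[tuple[int, ...], int] = {}
        for e1, c1 in self.terms.items():
            for e2, c2 in other.terms.items():
                e = tuple(a + b for a, b in zip(e1, e2))
                terms[e] = terms.get(e, 0) + c1 * c2
        return Polynomial(self.nvars, terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polynomial):
            return NotImplemented
        return self.nvars == other.nvars and self.terms == other.terms

    def __hash__(self) -> int:
        return hash((self.nvars, frozenset(self.terms.items())))

    # -- queries ------------------------------------------------------------

    @property
    def degree(self) -> int:
        return max((sum(e) for e in self.terms), default=0)

    def var_degree(self, name: str) -> int:
        i = _VAR_NAMES.index(name)
        return max((e[i] for e in self.terms), default=0)

    def coefficient(self, exp: tuple[int, ...]) -> int:
        return self.terms.get(exp, 0)

    def coefficient_sum(self) -> int:
        return sum(self.terms.values())

    def evaluate(self, x0, y0, z0=None):
        vals = (x0, y0) if self.nvars == 2 else (x0, y0, z0)
        if self.nvars == 3 and z0 is None:
            raise ValueError("3-variable polynomial needs a z value")
        total = 0
        for exp, c in self.terms.items():
            term = c
            for v, e in zip(vals, exp):
                term *= v**e
            total += term
        return total

    def substitute_z_with_y(self) -> "Polynomial":
        """Collapse z into y, reducing a Q polynomial to the P of the same tree."""
        if self.nvars == 2:
            return self
        terms: dict[tuple[int, ...], int] = {}
        for (i, j, k), c in self.terms.items():
            e = (i, j + k)
            terms[e] = terms.get(e, 0) + c
        return Polynomial(2, terms)

    def eliminate_z(self) -> "Polynomial":
        """Drop the z axis of a z-free 3-variable polynomial."""
        if self.nvars == 2:
            return self
        if any(e[2] for e in self.terms):
            raise ValueError("polynomial has z terms; use substitute_z_with_y or evaluate")
        return Polynomial(2, {(i, j): c for (i, j, _), c in self.terms.items()})

    def to_coeff_tensor(self) -> np.ndarray:
        """Dense (n+1)^nvars coefficient tensor, entry (i,j[,k]) = c^(i,j[,k]).

        Uses object dtype so arbitrary-precision coefficients survive.
        """
        n = self.degree
        shape = (n + 1,) * self.nvars
        tensor = np.zeros(shape, dtype=object)
        for exp, c in self.terms.items():
            tensor[exp] = c
        return tensor

    @classmethod
    def from_coeff_tensor(cls, tensor: np.ndarray) -> "Polynomial":
        terms = {
            tuple(int(i) for i in idx): int(c)
            for idx, c in np.ndenumerate(tensor)
            if c
        }
        return cls(tensor.ndim, terms)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "nvars": self.nvars,
                "terms": {",".join(map(str, e)): str(c) for e, c in sorted(self.terms.items())},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Polynomial":
        obj = json.loads(text)
        terms = {
            tuple(int(p) for p in e.split(",")): int(c) for e, c in obj["terms"].items()
        }
        return cls(obj["nvars"], terms)

    def to_monomial_text(self) -> str:
        """Human-readable monomial list, e.g. ``x^2 + x*y + 3*y``."""
        def fmt(exp: tuple[int, ...], c: int) -> str:
            parts = [] if c == 1 and any(exp) else [str(c)]
            for name, e in zip(_VAR_NAMES, exp):
                if e == 1:
                    parts.append(name)
                elif e > 1:
                    parts.append(f"{name}^{e}")
            return "*".join(parts) if parts else str(c)

        key = lambda item: (-sum(item[0]), tuple(-e for e in item[0]))
        return " + ".join(fmt(e, c) for e, c in sorted(self.terms.items(), key=key)) or "0"

    def to_coordinate_text(self) -> str:
        """MatrixMarket-like coordinate listing: one ``i j [k] c`` line per term."""
        lines = [f"% treepoly polynomial nvars={self.nvars} nterms={len(self.terms)}"]
        for e, c in sorted(self.terms.items()):
            lines.append(" ".join(map(str, (*e, c))))
        return "\n".join(lines) + "\n"


def _tree_poly(t: RootedTree, nvars: int) -> Polynomial:
    """Bottom-up recursion shared by P and Q (iterative, postorder)."""
    x = Polynomial.variable("x", nvars)
    y = Polynomial.variable("y", nvars)
    z = Polynomial.variable("z", nvars) if nvars == 3 else y
    vals: dict[int, Polynomial] = {}
    for v in t.postorder():
        kids = t.children[v]
        if not kids:
            vals[v] = x
            continue
        prod = vals[kids[0]]
        for c in kids[1:]:
            prod = prod * vals[c]
        head = z if (nvars == 3 and t.classes[v] == ARTIFICIAL_GROUP) else y
        vals[v] = head + prod
    return vals[t.root]


def poly_P(t: RootedTree) -> Polynomial:
    """The 2-variable complete tree invariant P(T, x, y).

    Leaf vertices contribute x; internal vertices y + product of children.
    Total on every tree type: vertex classes are ignored (an artificial
    internal vertex is treated like any internal vertex, which is exactly the
    z := y reduction of Q).  A childless root evaluates to x (the leaf rule
    takes precedence).
    """
    return _tree_poly(t, 2)


def poly_Q(t: RootedTree) -> Polynomial:
    """The 3-variable polynomial Q(T, x, y, z).

    Leaves contribute x; artificial group vertices z + product of children;
    loop and stem-region vertices y + product.  On a tree without artificial
    internal vertices Q has no z terms and coincides with P.
    """
    return _tree_poly(t, 3)


def tree_polynomial(t: RootedTree) -> Polynomial:
    """The polynomial paired with the tree's type: Q for types 2 and 4, else P."""
    return poly_Q(t) if t.tree_type in (2, 4) else poly_P(t)


def coefficient_sum(p: Polynomial) -> int:
    """Sum of all coefficients; equals evaluation at all variables = 1."""
    return p.coefficient_sum()


def evaluate(p: Polynomial, x0, y0, z0=None):
    return p.evaluate(x0, y0, z0)


def to_coeff_tensor(p: Polynomial) -> np.ndarray:
    return p.to_coeff_tensor()
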