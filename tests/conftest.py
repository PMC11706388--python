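"""Shared fixtures and oracles for the treepoly test suite."""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations_with_replacement

import pytest

from treepoly import decompose, parse_dot_bracket
from treepoly.synthetic import GeneratorParams, random_structure
from treepoly.synthetic import worked_example as _worked_example
from treepoly.trees import LOOP, RootedTree


@pytest.fixture(scope="session")
def worked_example():
    """The 41-nt worked example: (dot-bracket, expected-feature summary)."""
    return _worked_example()


@pytest.fixture(scope="session")
def worked_decomp(worked_example):
    db, _ = worked_example
    return decompose(parse_dot_bracket(db))


@pytest.fixture(scope="session")
def random_structures():
    """A seeded batch of generator structures reused across property tests."""
    return [
        random_structure(GeneratorParams(length=120, seed=seed)) for seed in range(60)
    ]


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive enumeration of unlabeled rooted trees.
# A rooted tree is encoded as the sorted tuple of its children's encodings;
# this nested-tuple form is itself a canonical form, independent of the
# package's AHU implementation.


@lru_cache(maxsize=None)
def all_rooted_trees(n: int) -> tuple:
    """All unlabeled rooted trees on exactly n vertices, as canonical tuples."""
    if n == 1:
        return ((),)
    results: set[tuple] = set()
    for parts in _partitions(n - 1):
        # parts is a non-increasing tuple of subtree sizes summing to n-1
        per_size: dict[int, int] = {}
        for s in parts:
            per_size[s] = per_size.get(s, 0) + 1
        choices_per_size = [
            list(combinations_with_replacement(all_rooted_trees(s), k))
            for s, k in sorted(per_size.items())
        ]
        for combo in _product_all(choices_per_size):
            children = tuple(sorted(t for group in combo for t in group))
            results.add(children)
    return tuple(sorted(results))


def _partitions(n: int, cap: int | None = None):
    if cap is None:
        cap = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, cap), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def _product_all(groups):
    if not groups:
        yield ()
        return
    for head in groups[0]:
        for tail in _product_all(groups[1:]):
            yield (head,) + tail


def tuple_to_tree(encoding: tuple) -> RootedTree:
    """Materialise a canonical nested tuple as a RootedTree (all loop class)."""
    t = RootedTree(classes=[LOOP], children=[[]])

    def attach(parent: int, enc: tuple) -> None:
        for child in enc:
            v = t.add_vertex(parent, LOOP)
            attach(v, child)

    attach(0, encoding)
    return t
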