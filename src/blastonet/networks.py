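"""Degree-distribution descriptors of contact networks and the
mean-contacts-per-blastomere biomarker.

A contact network on N cells is summarized by a length-N count vector whose
entry ``n`` is the number of cells with exactly ``n`` contacts (the degree
distribution written as counts).  Canonical 4-cell arrangements carry
nicknames; everything else maps to "Other".
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError, InvalidVectorError
from .meshes import ContactNetwork

__all__ = [
    "hickman_vector",
    "mean_contacts",
    "classify_arrangement_4cell",
    "arrangement_frequencies",
    "enumerate_possible_vectors",
    "is_graphical",
    "validate_hickman_vector",
    "ARRANGEMENT_NAMES_4CELL",
]

#: nickname taxonomy for 4-cell contact structures
ARRANGEMENT_NAMES_4CELL: dict[tuple, str] = {
    (0, 0, 0, 4): "Tetrahedral",
    (0, 0, 2, 2): "Pseudotetrahedral",
    (0, 0, 4, 0): "Planar",
    (0, 1, 2, 1): "Closed Y",
    (0, 2, 2, 0): "Linear",
}

OTHER_LABEL = "Other"


def hickman_vector(net: ContactNetwork) -> tuple[int, ...]:
    """Count vector of the network's degrees: entry n = number of nodes with
    exactly n contacts, for 0 <= n < N."""
    counts = np.bincount(net.degrees, minlength=net.n_nodes)
    return tuple(int(c) for c in counts[: net.n_nodes])


def mean_contacts(net: ContactNetwork) -> float:
    """Mean number of contacts per cell: 2|E| / N."""
    if net.n_nodes < 1:
        raise InvalidParameterError("network must have at least one node")
    return 2.0 * len(net.edges) / net.n_nodes


def is_graphical(degrees: Sequence[int]) -> bool:
    """Erdos-Gallai test: can this degree sequence be realized by a simple
    graph?"""
    d = sorted((int(x) for x in degrees), reverse=True)
    n = len(d)
    if n == 0:
        return False
    if any(x < 0 or x > n - 1 for x in d):
        return False
    if sum(d) % 2 != 0:
        return False
    prefix = 0
    for k in range(1, n + 1):
        prefix += d[k - 1]
        tail = sum(min(x, k) for x in d[k:])
        if prefix > k * (k - 1) + tail:
            return False
    return True


def _vector_degrees(vector: Sequence[int]) -> list[int]:
    degs: list[int] = []
    for n, count in enumerate(vector):
        degs.extend([n] * int(count))
    return degs


def validate_hickman_vector(vector: Sequence[int]) -> tuple[int, ...]:
    """Check length-N counts summing to N with a graphical implied degree
    multiset; return the canonical tuple form."""
    vec = tuple(int(x) for x in vector)
    n = len(vec)
    if n < 1 or any(x < 0 for x in vec):
        raise InvalidVectorError(f"invalid count vector {vec}")
    if sum(vec) != n:
        raise InvalidVectorError(f"counts of {vec} must sum to its length {n}")
    if not is_graphical(_vector_degrees(vec)):
        raise InvalidVectorError(f"{vec} implies a non-graphical degree sequence")
    return vec


def classify_arrangement_4cell(vector: Sequence[int]) -> str:
    """Map a 4-cell count vector to its arrangement nickname."""
    vec = tuple(int(x) for x in vector)
    if len(vec) != 4:
        raise InvalidVectorError(f"expected a length-4 vector, got length {len(vec)}")
    vec = validate_hickman_vector(vec)
    return ARRANGEMENT_NAMES_4CELL.get(vec, OTHER_LABEL)


def arrangement_frequencies(nets: Iterable[ContactNetwork]) -> pd.DataFrame:
    """Frequency table of count vectors over a collection of same-size
    networks, sorted by descending count with lexicographic vector
    tie-break."""
    vectors = []
    sizes = set()
    for net in nets:
        sizes.add(net.n_nodes)
        vectors.append(hickman_vector(net))
    if len(sizes) > 1:
        raise InvalidInputError(f"mixed network sizes: {sorted(sizes)}")
    if not vectors:
        return pd.DataFrame(columns=["vector", "count"])
    tally: dict[tuple, int] = {}
    for v in vectors:
        tally[v] = tally.get(v, 0) + 1
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"vector": [list(v) for v, _ in rows], "count": [c for _, c in rows]}
    )


def enumerate_possible_vectors(n: int) -> set[tuple[int, ...]]:
    """All count vectors realizable by some simple graph on n nodes.

    Enumerates candidate degree sequences (non-increasing, entries in
    [0, n-1]) and keeps the graphical ones — equivalent to brute force over
    all labelled graphs but feasible up to n = 8.
    """
    if not isinstance(n, int) or n < 1 or n > 8:
        raise InvalidParameterError(f"n must be an integer in [1, 8], got {n}")
    out: set[tuple[int, ...]] = set()

    def rec(seq: list[int], max_d: int):
        if len(seq) == n:
            if is_graphical(seq):
                counts = np.bincount(seq, minlength=n)[:n]
                out.add(tuple(int(c) for c in counts))
            return
        for d in range(max_d, -1, -1):
            rec(seq + [d], d)

    rec([], n - 1)
    return out
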