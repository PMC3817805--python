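"""Small built-in example constructions.

Micro-genomes exercising every occurrence pattern of the adjacency weight
table, and random matching instances for cross-checking the exact matcher
against brute-force enumeration.
"""

from __future__ import annotations

import numpy as np

from .types import DEFAULT_WEIGHT_TABLE

#: For each weight class: (orders, end pair of interest).  Orders are
#: genome -> chromosome -> [(marker, strand)].  The focal adjacency is
#: between marker "a" head and marker "b" tail throughout.
_FOCAL = (("a", "h"), ("b", "t"))


def weight_pattern_microgenomes() -> dict[str, dict]:
    """Hand-built three-genome layouts realising each weight class.

    The focal candidate joins a's head to b's tail (a+, b+ read order).
    Spacer markers x/y keep endpoints present-but-not-adjacent; the
    four-marker a,b,c,d layouts realise the inversion signature (a,b,c,d
    in one genome against a,-c,-b,d in another).
    """
    ab = [("a", "+"), ("b", "+")]
    abcd = [("a", "+"), ("b", "+"), ("c", "+"), ("d", "+")]
    inverted = [("a", "+"), ("c", "-"), ("b", "-"), ("d", "+")]
    cases = {
        "adj3": {
            "G1": {"c1": ab}, "G2": {"c1": ab}, "G3": {"c1": ab},
        },
        "adj2_missing": {
            "G1": {"c1": ab}, "G2": {"c1": ab}, "G3": {"c1": [("a", "+")]},
        },
        "adj2_present": {
            "G1": {"c1": ab}, "G2": {"c1": ab},
            "G3": {"c1": [("a", "+"), ("x", "+"), ("b", "+")]},
        },
        "inv_partial": {
            "G1": {"c1": abcd},
            "G2": {"c1": inverted},
            "G3": {"c1": [("c", "+"), ("d", "+")]},
        },
        "inv_full": {
            "G1": {"c1": abcd},
            "G2": {"c1": inverted},
            "G3": {
                "c1": [("c", "+"), ("d", "+")],
                "c2": [("a", "+")],
                "c3": [("b", "+")],
            },
        },
        "adj1_absent2": {
            "G1": {"c1": ab},
            "G2": {"c1": [("a", "+")]},
            "G3": {"c1": [("b", "+")]},
        },
        "adj1_mixed": {
            "G1": {"c1": ab},
            "G2": {"c1": [("a", "+"), ("x", "+"), ("b", "+")]},
            "G3": {"c1": [("a", "+")]},
        },
        "adj1_present2": {
            "G1": {"c1": ab},
            "G2": {"c1": [("a", "+"), ("x", "+"), ("b", "+")]},
            "G3": {"c1": [("a", "+"), ("y", "+"), ("b", "+")]},
        },
    }
    assert set(cases) == set(DEFAULT_WEIGHT_TABLE)
    return cases


def focal_pair():
    """The end pair whose weight the micro-genomes pin down."""
    return _FOCAL


def random_matching_instance(rng: np.random.Generator, max_ends: int = 12):
    """A random weighted-matching instance over few marker ends.

    Edges carry weights drawn from the weight table's values; used to
    compare the blossom matcher against exhaustive enumeration.
    """
    from .adjacency import AdjacencyCandidate
    from .types import end_pair

    n_markers = int(rng.integers(2, max_ends // 2 + 1))
    ends = [
        (f"m{i}", side) for i in range(n_markers) for side in ("t", "h")
    ]
    weights = sorted(DEFAULT_WEIGHT_TABLE.values())
    candidates = []
    seen = set()
    n_edges = int(rng.integers(1, 2 * n_markers + 1))
    for _ in range(n_edges):
        i, j = rng.choice(len(ends), size=2, replace=False)
        a, b = ends[int(i)], ends[int(j)]
        if a[0] == b[0]:
            continue
        pair = end_pair(a, b)
        if pair in seen:
            continue
        seen.add(pair)
        w = float(weights[int(rng.integers(0, len(weights)))])
        candidates.append(
            AdjacencyCandidate(pair, occurrence={}, weight=w)
        )
    return candidates
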