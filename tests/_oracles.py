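"""Independent brute-force oracles used by the test suite.

The alignment oracle enumerates every gapped alignment path explicitly (no
dynamic-programming matrix, no traceback) and scores it under the package's
affine convention: a gap of length k costs gap_open + k * gap_extend.  It is
exponential and only usable on short peptides, which is the point — it shares
nothing with the production aligner except the substitution matrix, loaded
here from Biopython rather than biotite.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(x: str, y: str) -> int:
    return int(_BLOSUM62[x, y])


def oracle_global(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best global alignment score by exhaustive path enumeration."""
    best = -math.inf
    open_cost = gap_open + gap_extend

    def rec(i: int, j: int, acc: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            if acc > best:
                best = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + blosum62(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, acc - (gap_extend if last == "D" else open_cost), "D")
        if j < len(b):
            rec(i, j + 1, acc - (gap_extend if last == "I" else open_cost), "I")

    rec(0, 0, 0.0, "M")
    return int(best)


def oracle_local(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best local alignment score: the maximum global score over all pairs of
    non-empty substrings, floored at 0 (the empty alignment)."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = oracle_global(a[i1:i2], b[j1:j2], gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


def random_binary_tree(rng, labels: list[str]):
    """A random rooted binary tree (skbio TreeNode) with uniform random
    branch lengths in [0.1, 1.0] — used to build additive distance matrices."""
    from skbio.tree import TreeNode

    nodes = [TreeNode(name=lb, length=round(0.1 + 0.9 * rng.random(), 3)) for lb in labels]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        x = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        y = nodes.pop(j)
        parent = TreeNode(length=round(0.1 + 0.9 * rng.random(), 3), children=[x, y])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def additive_distances(tree) -> tuple[list[str], list[list[float]]]:
    """Leaf labels and the patristic (path-length) distance matrix."""
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    return labels, [[float(dm[i, j]) for j in labels] for i in labels]
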