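"""Distance-based protein phylogenetics and nearest-reference clade calls.

Three uses: regulator homolog trees rooted on a MerR-family outgroup, the
chain-length-factor tree underlying product prediction, and the
known-vs-novel product call, which compares the nearest characterised
reference identity with an 88% cut-off (inclusive: identity >= 88 -> known).
Distances are p-distances (1 - identities/aligned columns) from global
alignments; trees come from neighbor joining, which recovers additive
distances exactly.  Labels are sorted lexicographically before agglomeration
so Q-matrix ties resolve deterministically.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .homolog_search import global_align

logger = logging.getLogger(__name__)

DEFAULT_KNOWN_CUTOFF = 88.0


def p_distance(a: str, b: str) -> float:
    """1 - identities/aligned_columns under optimal global alignment."""
    if not a or not b:
        raise ValueError("cannot compute distance of empty sequence")
    res = global_align(a, b)
    return 1.0 - res.identities / res.aligned_columns


def distance_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """All-pairs p-distance matrix over labelled sequences."""
    labels = sorted(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(d, labels)


def build_nj(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; unrooted tree, non-negative branch lengths.

    Input labels are reordered lexicographically so that agglomeration-order
    ties are broken the same way on every run; negative branch-length
    estimates (possible on non-additive input) are clamped to zero with a
    warning.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.warning("clamped %d negative NJ branch lengths to 0", clamped)
    return tree


def root_with_outgroup(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root at the midpoint of the outgroup's pendant edge."""
    try:
        leaf = tree.find(outgroup_label)
    except Exception as exc:
        raise ValueError(f"outgroup {outgroup_label!r} not in tree") from exc
    if not leaf.is_tip():
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf")
    return tree.root_at(leaf, above=True, reset=True)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to Newick with branch lengths; labels needing it are
    single-quoted (skbio's writer would mangle spaces to underscores)."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            s = _quote(node.name or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                s += _quote(node.name)
        if node.length is not None:
            s += f":{node.length:g}"
        return s

    return render(tree) + ";"


@dataclass(frozen=True)
class ReferenceSeq:
    ref_id: str
    sequence: str
    clade: str
    product: str


@dataclass(frozen=True)
class CladeAssignment:
    """Nearest-reference placement of a query CLF."""

    query_id: str
    nearest_ref_id: str
    nearest_identity: float
    clade_label: str
    product: str
    known_product: bool  # identity >= cutoff

    @property
    def product_call(self) -> str:
        return self.product if self.known_product else "novel"


def assign_clade(
    query: str,
    refs: Sequence[ReferenceSeq],
    cutoff: float = DEFAULT_KNOWN_CUTOFF,
    query_id: str = "query",
) -> CladeAssignment:
    """Assign the clade/product of the nearest reference by global identity.

    Ties on identity break by lexicographic reference id, so the result is
    invariant to panel order.
    """
    if not refs:
        raise ValueError("reference panel is empty")
    best: tuple[float, str, ReferenceSeq] | None = None
    for ref in refs:
        res = global_align(query, ref.sequence)
        ident = res.pct_identity
        key = (-ident, ref.ref_id)
        if best is None or key < (-best[0], best[1]):
            best = (ident, ref.ref_id, ref)
    identity, _, ref = best
    return CladeAssignment(
        query_id=query_id,
        nearest_ref_id=ref.ref_id,
        nearest_identity=identity,
        clade_label=ref.clade,
        product=ref.product,
        known_product=identity >= cutoff,
    )


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (convenience wrapper around skbio)."""
    return TreeNode.read(io.StringIO(text))
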