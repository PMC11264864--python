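"""p-distances, neighbor joining, rooting, and the 88% known/novel cut-off."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from zwminer.phylo import (
    CladeAssignment,
    ReferenceSeq,
    assign_clade,
    build_nj,
    distance_matrix,
    p_distance,
    parse_newick,
    root_with_outgroup,
    write_newick,
)
from zwminer.synthetic_data import mutate_protein

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def test_p_distance_identical_and_simple():
    assert p_distance("MKVLH", "MKVLH") == 0.0
    assert p_distance("AAAA", "AAAG") == pytest.approx(0.25)


def test_p_distance_symmetric(rng):
    for _ in range(50):
        a = "".join(rng.choice(list(AA20), size=rng.integers(5, 40)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(5, 40)))
        assert p_distance(a, b) == pytest.approx(p_distance(b, a))


def test_nj_three_taxa_closed_form():
    """Pendant lengths solve the three-point formulas exactly."""
    dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["A", "B", "C"])
    tree = build_nj(dm)
    lengths = {tip.name: tip.length for tip in tree.tips()}
    # a = (dAB + dAC - dBC)/2 etc.
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_nj_additive_four_taxa_exact_recovery():
    """Distances from ((A:1,B:2):1,(C:3,D:1)) are recovered exactly."""
    d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
         ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4}
    labels = ["A", "B", "C", "D"]
    m = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = d[(x, y)]
    tree = build_nj(DistanceMatrix(m, labels))
    true = parse_newick("((A:1,B:2):1,(C:3,D:1):0);")
    assert tree.compare_rfd(true) == 0.0
    lengths = {tip.name: tip.length for tip in tree.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0})


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        build_nj(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]))


def test_nj_deterministic_under_ties():
    """An equidistant matrix has many optimal joins; output is still fixed."""
    m = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(m, ["D", "B", "A", "C"])
    t1 = write_newick(build_nj(dm))
    t2 = write_newick(build_nj(DistanceMatrix(m, ["A", "C", "B", "D"]).filter(["D", "B", "A", "C"])))
    assert t1 == t2


def test_root_with_outgroup():
    tree = parse_newick("((A:1,B:2):1,C:3,D:1);")
    rooted = root_with_outgroup(tree, "D")
    children = rooted.children
    sides = [sorted(t.name for t in c.tips()) or [c.name] for c in children]
    assert ["D"] in sides
    assert sorted(t.name for t in rooted.tips()) == ["A", "B", "C", "D"]
    again = root_with_outgroup(rooted, "D")
    assert write_newick(again) == write_newick(rooted)


def test_root_missing_outgroup_errors():
    with pytest.raises(ValueError):
        root_with_outgroup(parse_newick("(A:1,B:1,C:1);"), "Z")


def test_newick_round_trip_and_quoting():
    tree = build_nj(DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                                   ["tip one", "B", "C"]))
    text = write_newick(tree)
    assert "'tip one'" in text
    back = parse_newick(text)
    assert sorted(t.name for t in back.tips()) == ["B", "C", "tip one"]


def _exact_identity_mutant(seq, identity_pct, rng):
    """Mutate exactly round(len*(1-identity)) positions (gapless identity)."""
    n = len(seq)
    k = round(n * (100 - identity_pct) / 100)
    pos = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = next(a for a in AA20 if a != seq[p])
    return "".join(out)


def test_known_novel_cutoff_boundary(rng):
    """Identities 87.0 / 88.0 / 95.0 against the nearest reference give
    novel / known / known (the cut-off is inclusive)."""
    ref_seq = "M" + "".join(rng.choice(list(AA20), size=399))  # length 400
    refs = [ReferenceSeq("REF_A", ref_seq, "angucycline", "oviedomycin")]
    for identity, expect_known in ((87.0, False), (88.0, True), (95.0, True)):
        query = _exact_identity_mutant(ref_seq, identity, rng)
        call = assign_clade(query, refs)
        assert call.nearest_identity == pytest.approx(identity)
        assert call.known_product is expect_known
        assert call.product_call == ("oviedomycin" if expect_known else "novel")


def test_assign_clade_panel_order_invariant(rng):
    seqs = ["M" + "".join(rng.choice(list(AA20), size=200)) for _ in range(4)]
    refs = [ReferenceSeq(f"R{i}", s, "clade", f"p{i}") for i, s in enumerate(seqs)]
    query = mutate_protein(seqs[2], 0.1, rng)
    fwd = assign_clade(query, refs)
    rev = assign_clade(query, list(reversed(refs)))
    assert fwd == rev
    assert fwd.nearest_ref_id == "R2"


def test_assign_clade_exact_reference_and_empty_panel():
    ref = ReferenceSeq("R", "MKVLHMKVLH", "angucycline", "urdamycin")
    call = assign_clade("MKVLHMKVLH", [ref])
    assert call.nearest_identity == 100.0 and call.known_product
    with pytest.raises(ValueError):
        assign_clade("MKVLH", [])


def test_clade_coherence_on_synthetic_cohort(rng):
    """Sequences generated from two divergent ancestors form monophyletic
    clades when within-clade divergence is far below between-clade."""
    anc1 = "M" + "".join(rng.choice(list(AA20), size=150))
    anc2 = mutate_protein(anc1, 0.6, rng)
    seqs = {}
    for i in range(4):
        seqs[f"a{i}"] = mutate_protein(anc1, 0.05, rng)
        seqs[f"b{i}"] = mutate_protein(anc2, 0.05, rng)
    tree = build_nj(distance_matrix(seqs))
    # monophyly on an unrooted tree: root outside the clade under test first
    for prefix, outgroup in (("a", "b0"), ("b", "a0")):
        rooted = root_with_outgroup(tree.copy(), outgroup)
        tips = [rooted.find(f"{prefix}{i}") for i in range(4)]
        lca = rooted.lowest_common_ancestor(tips)
        assert sorted(t.name for t in lca.tips()) == sorted(f"{prefix}{i}" for i in range(4))
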