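"""Marker-rule gene classification and cluster typing."""

import pytest

from zwminer import exemplars as ex
from zwminer.bgc_typing import T2PKS, classify_gene, detect_bgc, extract_parts
from zwminer.genbank_io import GeneFeature
from zwminer.homolog_search import HomologHit
from zwminer.pair_scan import RegulatorPair, intergenic_distance
from zwminer.synthetic_data import mutate_protein

from conftest import build_contig

AA20 = "ACDEFGHIKLMNPQRSTVWY"
PANEL = ex.default_marker_panel()


def _gene(locus, start, seq, strand=1):
    return (locus, start, start + 3 * (len(seq) + 1), strand, seq)


def _cluster_contig(include=("KS", "CLF", "ACP"), cycs=("TcmN", "TcmI"), gts=0,
                    spacing=400, extra_decoys=0, rng=None):
    """Assemble a pair + marker cluster with controllable membership."""
    clf_ref = ex.ANGUCYCLINE_REFERENCES[0]
    proteins = {
        "KS": dict(ex.MARKER_SEQUENCES[ex.KS_ALPHA])["KSalpha_syn"],
        "CLF": clf_ref.sequence,
        "ACP": dict(ex.MARKER_SEQUENCES[ex.ACP])["ACP_syn"],
    }
    genes = []
    pos = 1000
    for name in include:
        genes.append(_gene(name.lower(), pos, proteins[name]))
        pos = genes[-1][2] + spacing
    cyc_seqs = {
        "TcmN": ex.TCMN_DIDOMAIN_SEQ,
        "TcmI": dict(ex.MARKER_SEQUENCES[ex.CYC_TCMI])["TcmI_syn"],
        "OxyN": dict(ex.MARKER_SEQUENCES[ex.CYC_OXYN])["OxyN_syn"],
    }
    for i, cyc in enumerate(cycs):
        genes.append(_gene(f"cyc{i}", pos, cyc_seqs[cyc]))
        pos = genes[-1][2] + spacing
    for i in range(gts):
        genes.append(_gene(f"gt{i}", pos, dict(ex.MARKER_SEQUENCES[ex.GT])["GT_syn"]))
        pos = genes[-1][2] + spacing
    if extra_decoys and rng is not None:
        for i in range(extra_decoys):
            decoy = "M" + "".join(rng.choice(list(AA20), size=250))
            genes.append(_gene(f"d{i}", pos, decoy))
            pos = genes[-1][2] + spacing
    genes.append(_gene("z1", pos, ex.OVMZ_SEED_SEQ))
    pos = genes[-1][2] + 200
    genes.append(_gene("w1", pos, ex.OVMW_SEED_SEQ))
    return build_contig(genes, total_len=pos + 5000)


def _pair_on(contig):
    z, w = contig.feature_by_locus("z1"), contig.feature_by_locus("w1")
    mk = lambda f, seed: HomologHit(seed, contig.contig_id, f.locus_tag, 100.0, 100.0, 999)
    return RegulatorPair(contig.contig_id, mk(z, "z"), mk(w, "w"), z, w,
                         intergenic_distance(z, w), True, 500)


def test_classify_exact_clf_exemplar():
    feat = GeneFeature("g", 0, 3 * 404, 1, translation=ex.ANGUCYCLINE_REFERENCES[0].sequence)
    fams = dict(classify_gene(feat, PANEL))
    assert "CLF" in fams and fams["CLF"].pct_identity == 100.0


def test_classify_mutated_clf_recovered(rng):
    mut = mutate_protein(ex.ANGUCYCLINE_REFERENCES[0].sequence, 0.3, rng)
    feat = GeneFeature("g", 0, 3 * 404, 1, translation=mut)
    assert "CLF" in dict(classify_gene(feat, PANEL))


def test_classify_random_protein_hits_nothing(rng):
    for _ in range(30):
        decoy = "M" + "".join(rng.choice(list(AA20), size=int(rng.integers(130, 450))))
        feat = GeneFeature("g", 0, 3 * (len(decoy) + 1), 1, translation=decoy)
        assert classify_gene(feat, PANEL) == []


def test_t2pks_requires_complete_minimal_pks():
    """Removing any one of KSα/CLF/ACP breaks the T2PKS call (necessity)."""
    contig = _cluster_contig()
    bgc = detect_bgc(contig, _pair_on(contig), PANEL)
    assert bgc.type_label == T2PKS
    for drop in ("KS", "CLF", "ACP"):
        keep = tuple(x for x in ("KS", "CLF", "ACP") if x != drop)
        ablated = _cluster_contig(include=keep)
        assert detect_bgc(ablated, _pair_on(ablated), PANEL).type_label != T2PKS


def test_minimal_pks_colocation_limit():
    """The trio must sit within the minimal-PKS span to call T2PKS."""
    spread = _cluster_contig(spacing=6000)
    assert detect_bgc(spread, _pair_on(spread), PANEL).type_label != T2PKS
    assert detect_bgc(spread, _pair_on(spread), PANEL, span_flank=40000,
                      minimal_pks_span=40000).type_label == T2PKS


def test_pair_with_only_decoys_is_none(rng):
    genes = []
    pos = 1000
    for i in range(3):
        decoy = "M" + "".join(rng.choice(list(AA20), size=200))
        genes.append(_gene(f"d{i}", pos, decoy))
        pos = genes[-1][2] + 300
    genes.append(_gene("z1", pos, ex.OVMZ_SEED_SEQ))
    genes.append(_gene("w1", genes[-1][2] + 200, ex.OVMW_SEED_SEQ))
    contig = build_contig(genes, total_len=genes[-1][2] + 2000)
    assert detect_bgc(contig, _pair_on(contig), PANEL).type_label == "none"


def test_extract_parts_counts_and_didomain():
    contig = _cluster_contig(cycs=("TcmN", "TcmI"), gts=0)
    bgc = detect_bgc(contig, _pair_on(contig), PANEL)
    parts = extract_parts(bgc)
    assert parts.counts == {"CLF": 1, "KS": 1, "ACP": 1, "CYC": 2, "GT": 0}
    assert parts.cyc_subfamilies == {"TcmN-didomain", "TcmI"}


def test_extract_parts_gt_counted():
    contig = _cluster_contig(gts=1)
    parts = extract_parts(detect_bgc(contig, _pair_on(contig), PANEL))
    assert len(parts.gt) == 1


def test_extract_parts_rejects_non_t2pks():
    contig = _cluster_contig(include=("KS", "ACP"))
    bgc = detect_bgc(contig, _pair_on(contig), PANEL)
    with pytest.raises(ValueError):
        extract_parts(bgc)


def test_typing_deterministic(rng):
    contig = _cluster_contig(gts=1, extra_decoys=2, rng=rng)
    pair = _pair_on(contig)
    a = detect_bgc(contig, pair, PANEL)
    b = detect_bgc(contig, pair, PANEL)
    assert a.type_label == b.type_label
    assert a.member_loci == b.member_loci
    assert a.span == b.span
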