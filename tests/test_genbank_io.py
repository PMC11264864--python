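"""GenBank parsing, coordinate conventions, FASTA/TSV writing."""

import numpy as np
import pytest

from zwminer.genbank_io import (
    ContigRecord,
    GeneFeature,
    GenBankParseError,
    fasta_header,
    read_genbank,
    translate_cds,
    write_genbank,
    write_protein_fasta,
    write_tsv,
)
from zwminer.synthetic_data import generate_contig, GeneratorConfig, reverse_translate

from conftest import build_contig


def _contig_with_cds(rng):
    """Contig with CDS at GenBank positions 101..400, complement(501..800),
    901..1200 — i.e. 0-based half-open (100,400,+1), (500,800,-1), (900,1200,+1)."""
    from Bio.Seq import Seq

    prots = ["M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=98)) for _ in range(3)]
    cds = [reverse_translate(p, rng) for p in prots]  # 300 nt each
    seq = (
        "".join(rng.choice(list("ACGT"), size=100))
        + cds[0]
        + "".join(rng.choice(list("ACGT"), size=100))
        + str(Seq(cds[1]).reverse_complement())
        + "".join(rng.choice(list("ACGT"), size=100))
        + cds[2]
    )
    feats = [
        GeneFeature("g1", 100, 400, 1, translation=prots[0]),
        GeneFeature("g2", 500, 800, -1, translation=prots[1]),
        GeneFeature("g3", 900, 1200, 1, translation=prots[2], gene_functions="chain-length factor"),
    ]
    return ContigRecord(contig_id="FIX1", organism="Streptomyces sp. X",
                        taxonomy=["Bacteria", "Streptomyces"], sequence=seq, features=feats)


def test_coordinate_conversion_round_trip(tmp_path):
    """1-based inclusive GenBank positions become 0-based half-open internally,
    and writing then re-reading preserves coordinates, strands, translations."""
    rng = np.random.default_rng(5)
    contig = _contig_with_cds(rng)
    path = tmp_path / "fix.gbk"
    write_genbank([contig], path)
    # the flat file prints 1-based inclusive coordinates
    text = path.read_text()
    assert "101..400" in text
    assert "complement(501..800)" in text
    (back,) = read_genbank(path)
    got = [(f.start, f.end, f.strand) for f in back.features]
    assert got == [(100, 400, 1), (500, 800, -1), (900, 1200, 1)]
    assert [f.translation for f in back.features] == [f.translation for f in contig.features]
    for f in back.features:
        # translating the strand-corrected span reproduces the stored protein
        assert translate_cds(back.sequence[f.start:f.end], f.strand) == f.translation


def test_missing_translation_is_filled(tmp_path):
    """A CDS lacking /translation is translated from its span; 33 nt -> 10 aa."""
    rng = np.random.default_rng(6)
    prot = "MKVLHEAGWD"
    cds = reverse_translate(prot, rng)
    assert len(cds) == 33
    contig = ContigRecord(
        contig_id="FIX2", organism="Nocardia sp. Y", sequence="ACGT" * 10 + cds + "ACGT" * 10,
        features=[GeneFeature("g1", 40, 73, 1, translation=prot)],
    )
    path = tmp_path / "fix2.gbk"
    write_genbank([contig], path)
    stripped = "\n".join(
        ln for ln in path.read_text().splitlines() if "/translation" not in ln
    )
    path.write_text(stripped + "\n")
    (back,) = read_genbank(path)
    assert back.features[0].translation == prot
    assert len(back.features[0].translation) == 10


def test_internal_stop_feature_excluded(tmp_path, caplog):
    contig = ContigRecord(
        contig_id="FIX3", organism="X", sequence="ATGTAAATGAAATAA" + "ACGT" * 5,
        features=[GeneFeature("bad", 0, 15, 1, translation="")],
    )
    contig.features[0].translation = "M*MK"  # internal stop
    path = tmp_path / "fix3.gbk"
    write_genbank([contig], path)
    (back,) = read_genbank(path)
    assert back.features == []


def test_zero_cds_record(tmp_path):
    contig = ContigRecord(contig_id="EMPTY", organism="X", sequence="ACGT" * 50)
    path = tmp_path / "empty.gbk"
    write_genbank([contig], path)
    (back,) = read_genbank(path)
    assert back.contig_id == "EMPTY"
    assert back.features == []


def test_generator_round_trip(tmp_path):
    """Generator contigs survive write -> read with full fidelity."""
    cfg = GeneratorConfig(seed=3, n_contigs=1, p_pair=1.0)
    contig, _ = generate_contig(cfg, 0)
    path = tmp_path / "gen.gbk"
    write_genbank([contig], path)
    (back,) = read_genbank(path)
    assert back.sequence == contig.sequence
    assert [(f.locus_tag, f.start, f.end, f.strand, f.translation) for f in back.features] == [
        (f.locus_tag, f.start, f.end, f.strand, f.translation) for f in contig.features
    ]
    assert back.organism == contig.organism
    assert back.taxonomy == contig.taxonomy


def test_unreadable_file_is_fatal(tmp_path):
    bad = tmp_path / "bad.gbk"
    bad.write_text("this is not a genbank file\n")
    with pytest.raises(GenBankParseError):
        read_genbank(bad)


def test_protein_fasta_header_convention(tmp_path):
    contig = build_contig([("ttr4", 900, 1200, 1, "MKVLH")])
    contig.features[0].gene_functions = "chain-length factor"
    out = tmp_path / "p.faa"
    n = write_protein_fasta(contig.features, contig, out)
    assert n == 1
    lines = out.read_text().splitlines()
    assert lines[0] == ">CTG1|ttr4|901..1200(+)|chain-length factor"
    assert lines[1] == "MKVLH"


def test_protein_fasta_empty_and_order(tmp_path):
    contig = build_contig([("a", 0, 30, 1, "MAAA"), ("b", 100, 130, -1, "MCCC")])
    out = tmp_path / "p.faa"
    assert write_protein_fasta([], contig, out) == 0
    assert out.read_text() == ""
    assert write_protein_fasta(contig.features, contig, out) == 2
    headers = [l for l in out.read_text().splitlines() if l.startswith(">")]
    assert headers == [">" + fasta_header(f, contig) for f in contig.features]
    assert "(-)" in headers[1]


def test_write_tsv(tmp_path):
    out = tmp_path / "t.tsv"
    write_tsv([], out, columns=["a", "b"])
    assert out.read_text() == "a\tb\n"
    write_tsv([{"a": 1, "b": "x"}, {"a": 2, "b": "y"}], out)
    assert out.read_text() == "a\tb\n1\tx\n2\ty\n"
    with pytest.raises(ValueError):
        write_tsv([{"a": "has\ttab"}], out)
    with pytest.raises(ValueError):
        write_tsv([{"a": 1}, {"b": 2}], out)
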