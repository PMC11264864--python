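"""GenBank flat-file I/O and feature normalisation.

Coordinates are 0-based half-open internally; the GenBank convention
(1-based, inclusive) applies only at the file boundary.  Compound
(``join``/``complement``) CDS locations are collapsed to their outer
min-start/max-end span — bacterial CDS have no splicing semantics and the
downstream window arithmetic only needs gene intervals.  Translation uses the
bacterial/archaeal codon table (NCBI table 11); codons containing ambiguous
nucleotides translate to ``X`` rather than failing, and CDS whose translation
contains an internal stop are excluded with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CODON_TABLE = 11


class GenBankParseError(ValueError):
    """Raised when a GenBank file cannot be parsed."""


@dataclass
class GeneFeature:
    """A CDS feature on a contig.

    ``start``/``end`` are 0-based half-open nucleotide offsets; ``strand`` is
    +1 or -1; ``translation`` is the amino-acid sequence without the stop.
    """

    locus_tag: str
    start: int
    end: int
    strand: int
    product: str = ""
    gene_functions: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ContigRecord:
    """An annotated replicon: the unit scanned for pairs and clusters."""

    contig_id: str
    organism: str = ""
    taxonomy: list[str] = field(default_factory=list)
    sequence: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_tag))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_locus(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)


def translate_cds(nt: str, strand: int = 1) -> str:
    """Translate a CDS nucleotide span (table 11), strand-corrected.

    A trailing stop is stripped; alternative start codons are reported as the
    table-11 residue (the caller may plant M-initial proteins if it cares).
    Ambiguous codons give X.
    """
    seq = Seq(nt)
    if strand == -1:
        seq = seq.reverse_complement()
    aa = str(seq.translate(table=CODON_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def _feature_text(qualifiers: Mapping[str, list[str]], key: str) -> str:
    vals = qualifiers.get(key)
    return vals[0] if vals else ""


def read_genbank(path: str | Path) -> list[ContigRecord]:
    """Parse a GenBank flat file into :class:`ContigRecord` objects.

    Every CDS becomes a :class:`GeneFeature`; missing ``/translation``
    qualifiers are filled by translating the CDS span.  Features whose
    translation contains an internal stop are flagged and excluded.
    """
    path = Path(path)
    try:
        seqio_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenBankParseError(f"cannot parse {path}: {exc}") from exc
    if not seqio_records:
        raise GenBankParseError(f"no GenBank records in {path}")

    contigs = []
    for rec in seqio_records:
        sequence = str(rec.seq)
        features: list[GeneFeature] = []
        n_anon = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = int(feat.location.strand or 1)
            locus_tag = _feature_text(feat.qualifiers, "locus_tag")
            if not locus_tag:
                n_anon += 1
                locus_tag = f"{rec.id}_cds{n_anon:04d}"
            translation = _feature_text(feat.qualifiers, "translation")
            if not translation:
                translation = translate_cds(sequence[start:end], strand)
            if "*" in translation:
                logger.warning(
                    "%s: CDS %s has internal stop codon(s); excluded", path, locus_tag
                )
                continue
            features.append(
                GeneFeature(
                    locus_tag=locus_tag,
                    start=start,
                    end=end,
                    strand=strand,
                    product=_feature_text(feat.qualifiers, "product"),
                    gene_functions=_feature_text(feat.qualifiers, "gene_functions")
                    or _feature_text(feat.qualifiers, "function"),
                    translation=translation,
                )
            )
        contigs.append(
            ContigRecord(
                contig_id=rec.id,
                organism=rec.annotations.get("organism", ""),
                taxonomy=list(rec.annotations.get("taxonomy", [])),
                sequence=sequence,
                features=features,
            )
        )
    return contigs


def read_genbank_dir(directory: str | Path) -> list[ContigRecord]:
    """Parse every ``*.gb``/``*.gbk`` file in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".gb", ".gbk", ".gbff")
    )
    contigs: list[ContigRecord] = []
    for p in paths:
        contigs.extend(read_genbank(p))
    seen: set[str] = set()
    for c in contigs:
        if c.contig_id in seen:
            raise GenBankParseError(f"duplicate contig_id {c.contig_id!r} in {directory}")
        seen.add(c.contig_id)
    return contigs


def fasta_header(feature: GeneFeature, contig: ContigRecord) -> str:
    """``locus_info|locus_tag|start..end(strand)|gene_functions`` with the
    position printed in GenBank 1-based inclusive convention."""
    strand = "+" if feature.strand == 1 else "-"
    return (
        f"{contig.contig_id}|{feature.locus_tag}|"
        f"{feature.start + 1}..{feature.end}({strand})|{feature.gene_functions}"
    )


def write_protein_fasta(
    features: Sequence[GeneFeature], contig: ContigRecord, out: str | Path
) -> int:
    """Write feature translations as FASTA; returns the number written."""
    n = 0
    with open(out, "w", encoding="utf-8") as fh:
        for feat in features:
            if not feat.translation:
                raise ValueError(f"feature {feat.locus_tag} has no translation")
            fh.write(f">{fasta_header(feat, contig)}\n")
            for i in range(0, len(feat.translation), 60):
                fh.write(feat.translation[i : i + 60] + "\n")
            n += 1
    return n


def write_genbank(contigs: Sequence[ContigRecord], out: str | Path) -> None:
    """Write contigs as a GenBank flat file (one LOCUS per contig).

    The LOCUS date is pinned so that regenerating a cohort from the same seed
    gives byte-identical files.
    """
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    records = []
    for contig in contigs:
        rec = SeqRecord(Seq(contig.sequence), id=contig.contig_id, name=contig.contig_id)
        rec.description = f"{contig.organism} synthetic contig"
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["organism"] = contig.organism
        rec.annotations["source"] = contig.organism
        rec.annotations["taxonomy"] = list(contig.taxonomy)
        rec.annotations["date"] = "01-JAN-1980"
        rec.annotations["data_file_division"] = "BCT"
        rec.features.append(
            SeqFeature(
                FeatureLocation(0, len(contig.sequence)),
                type="source",
                qualifiers={"organism": [contig.organism]},
            )
        )
        for feat in contig.features:
            rec.features.append(
                SeqFeature(
                    FeatureLocation(feat.start, feat.end, strand=feat.strand),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [feat.locus_tag],
                        "product": [feat.product or "hypothetical protein"],
                        "gene_functions": [feat.gene_functions] if feat.gene_functions else [],
                        "transl_table": [str(CODON_TABLE)],
                        "translation": [feat.translation],
                    },
                )
            )
        records.append(rec)
    with open(out, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "genbank")


def write_tsv(rows: Iterable[Mapping[str, object]], out: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write flat records as a header-led TSV (UTF-8, newline-terminated).

    All rows must share one schema; fields containing tabs or newlines are
    rejected rather than quoted, keeping the artifact diff-able.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from zero rows")
        columns = list(rows[0].keys())
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            if set(row.keys()) != set(columns):
                raise ValueError(f"row schema {sorted(row)} != {sorted(columns)}")
            cells = []
            for col in columns:
                cell = str(row[col])
                if "\t" in cell or "\n" in cell:
                    raise ValueError(f"field {col!r} contains a delimiter: {cell!r}")
                cells.append(cell)
            fh.write("\t".join(cells) + "\n")
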