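"""Regulator-pair co-localization: the 500 bp window rule.

A contig carries a regulator pair when an OvmW homolog gene overlaps the
region extending a configurable flank (default 500 bp) upstream and
downstream of an OvmZ homolog gene.  Windows are built from gene boundaries,
overlap is interval overlap, and overlapping z/w genes (distance 0) count as
paired — operonic pairs are the biological signal.  Strand is reported but
not filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genbank_io import ContigRecord, GeneFeature
from .homolog_search import HomologHit

DEFAULT_FLANK = 500


@dataclass(frozen=True)
class GenomicWindow:
    contig_id: str
    start: int
    end: int

    def overlaps(self, start: int, end: int) -> bool:
        return start < self.end and self.start < end


@dataclass(frozen=True)
class RegulatorPair:
    """A co-localized OvmZ/OvmW homolog pair with its distance evidence."""

    contig_id: str
    z_hit: HomologHit
    w_hit: HomologHit
    z_feature: GeneFeature
    w_feature: GeneFeature
    intergenic_distance: int
    same_strand: bool
    window_flank: int


def window_of(feature: GeneFeature, flank: int, contig_len: int) -> GenomicWindow:
    """``[start - flank, end + flank)`` clamped to the contig."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomicWindow(
        contig_id="",
        start=max(0, feature.start - flank),
        end=min(contig_len, feature.end + flank),
    )


def intergenic_distance(a: GeneFeature, b: GeneFeature) -> int:
    """bp between the nearest gene ends; 0 when the intervals overlap."""
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def find_pairs(
    contig: ContigRecord,
    z_hits: Sequence[HomologHit],
    w_hits: Sequence[HomologHit],
    flank: int = DEFAULT_FLANK,
) -> list[RegulatorPair]:
    """Emit one pair per distinct (z locus, w locus) whose w gene overlaps
    the z window.  Multiple z hits each scan their own window; duplicate
    locus pairs are deduplicated."""
    pairs: list[RegulatorPair] = []
    seen: set[tuple[str, str]] = set()
    for z in sorted(z_hits, key=lambda h: h.locus_tag):
        z_feat = contig.feature_by_locus(z.locus_tag)
        window = window_of(z_feat, flank, len(contig))
        for w in sorted(w_hits, key=lambda h: h.locus_tag):
            if w.locus_tag == z.locus_tag:
                continue
            key = (z.locus_tag, w.locus_tag)
            if key in seen:
                continue
            w_feat = contig.feature_by_locus(w.locus_tag)
            if not window.overlaps(w_feat.start, w_feat.end):
                continue
            seen.add(key)
            pairs.append(
                RegulatorPair(
                    contig_id=contig.contig_id,
                    z_hit=z,
                    w_hit=w,
                    z_feature=z_feat,
                    w_feature=w_feat,
                    intergenic_distance=intergenic_distance(z_feat, w_feat),
                    same_strand=z_feat.strand == w_feat.strand,
                    window_flank=flank,
                )
            )
    return pairs


@dataclass(frozen=True)
class RecordSummary:
    """Record-level tallies: a *record* is a contig with >= 1 pair, counted
    separately from the distinct homolog gene counts (one contig can carry
    several w genes around one z gene)."""

    n_records: int
    n_z_genes: int
    n_w_genes: int


def summarize_records(
    pairs_by_contig: Mapping[str, Sequence[RegulatorPair]] | Iterable[RegulatorPair],
) -> RecordSummary:
    """Collapse pairs to record-level counts."""
    if isinstance(pairs_by_contig, Mapping):
        all_pairs = [p for ps in pairs_by_contig.values() for p in ps]
    else:
        all_pairs = list(pairs_by_contig)
    contigs = {p.contig_id for p in all_pairs}
    z_loci = {(p.contig_id, p.z_hit.locus_tag) for p in all_pairs}
    w_loci = {(p.contig_id, p.w_hit.locus_tag) for p in all_pairs}
    return RecordSummary(
        n_records=len(contigs), n_z_genes=len(z_loci), n_w_genes=len(w_loci)
    )
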