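"""Marker-rule cluster typing around a regulator pair.

A transparent, reduced stand-in for a full secondary-metabolite cluster
annotator: genes near the pair are classified against a marker panel by
alignment (annotation strings are never evidence, only labels), and the
cluster is typed T2PKS when the minimal PKS trio — ketosynthase KSα,
chain-length factor CLF and acyl carrier protein ACP — co-occurs within a
bounded span.  Coarse fallback labels (T3PKS, terpene, NRPS) come from single
anchor families; anything else with marker evidence is "other", a pair with
only decoy neighbours is "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .genbank_io import ContigRecord, GeneFeature
from .homolog_search import HomologHit, SeedQuery, search_homologs
from .pair_scan import RegulatorPair

DEFAULT_SPAN_FLANK = 15_000
DEFAULT_MINIMAL_PKS_SPAN = 10_000

T2PKS = "T2PKS"
T3PKS = "T3PKS"
TERPENE = "terpene"
NRPS = "NRPS"
OTHER = "other"
NONE = "none"

#: CYC subfamily labels as used in the prediction rules.
TCMN_DIDOMAIN = "TcmN-didomain"
TCMI = "TcmI"
TCMJ = "TcmJ"
OXYN = "OxyN"
SNOAL = "SnoaL"

_CYC_FAMILY_TO_SUBFAMILY = {
    "CYC_TcmI": TCMI,
    "CYC_TcmJ": TCMJ,
    "CYC_OxyN": OXYN,
    "CYC_SnoaL": SNOAL,
}


@dataclass(frozen=True)
class MarkerFamily:
    """One marker family: exemplar sequences plus detection thresholds."""

    name: str
    exemplars: list[tuple[str, str]]  # (exemplar_id, sequence)
    min_identity: float = 40.0
    min_coverage: float = 60.0

    def __post_init__(self) -> None:
        if not self.exemplars:
            raise ValueError(f"family {self.name} has no exemplars")
        for pct in (self.min_identity, self.min_coverage):
            if not (0 < pct <= 100):
                raise ValueError(f"family {self.name}: thresholds must be valid percents")


class MarkerPanel:
    """family name -> :class:`MarkerFamily`."""

    def __init__(self, families: Mapping[str, MarkerFamily]):
        self.families = dict(families)

    def __getitem__(self, name: str) -> MarkerFamily:
        return self.families[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.families)

    def seed_queries(self) -> list[SeedQuery]:
        seeds = []
        for fam in self.families.values():
            for ex_id, seq in fam.exemplars:
                seeds.append(
                    SeedQuery(
                        seed_id=f"{fam.name}::{ex_id}",
                        role=f"marker:{fam.name}",
                        sequence=seq,
                        min_identity=fam.min_identity,
                        min_query_coverage=fam.min_coverage,
                    )
                )
        return seeds


@dataclass
class BGCRecord:
    """A typed cluster span anchored on a regulator pair."""

    bgc_id: str
    contig_id: str
    span: tuple[int, int]
    type_label: str
    member_loci: list[str]
    marker_hits: dict[str, list[HomologHit]] = field(default_factory=dict)
    anchored_pair: RegulatorPair | None = None

    def loci_of(self, family: str) -> list[str]:
        return [h.locus_tag for h in self.marker_hits.get(family, [])]


def classify_gene(feature: GeneFeature, panel: MarkerPanel) -> list[tuple[str, HomologHit]]:
    """All marker families whose best exemplar alignment passes thresholds.

    Evidence is alignment-only; the feature's annotation text plays no role
    in the decision (it is at most a display label downstream).
    """
    if not feature.translation:
        raise ValueError(f"feature {feature.locus_tag} has no translation")
    pseudo = ContigRecord(
        contig_id="_query", sequence="N" * feature.length, features=[feature]
    )
    results: list[tuple[str, HomologHit]] = []
    for name in sorted(panel):
        fam = panel[name]
        best: HomologHit | None = None
        for hit in search_homologs(pseudo, _family_seeds(fam)):
            if best is None or hit.score > best.score:
                best = hit
        if best is not None:
            results.append((name, best))
    return results


def _family_seeds(fam: MarkerFamily) -> list[SeedQuery]:
    return [
        SeedQuery(
            seed_id=ex_id,
            role=f"marker:{fam.name}",
            sequence=seq,
            min_identity=fam.min_identity,
            min_query_coverage=fam.min_coverage,
        )
        for ex_id, seq in fam.exemplars
    ]


def cyc_subfamilies_of(gene_families: Mapping[str, set[str]]) -> dict[str, str]:
    """Map locus -> CYC subfamily from per-gene family hits.

    A gene hitting both the TcmN first-ring (N) and second-ring (C) domain
    exemplars is the TcmN didomain aromatase; single-domain CYC families map
    directly.
    """
    out: dict[str, str] = {}
    for locus, fams in gene_families.items():
        if "CYC_TcmN_N" in fams and "CYC_TcmN_C" in fams:
            out[locus] = TCMN_DIDOMAIN
            continue
        for fam_name, sub in _CYC_FAMILY_TO_SUBFAMILY.items():
            if fam_name in fams:
                out[locus] = sub
                break
    return out


def detect_bgc(
    contig: ContigRecord,
    pair: RegulatorPair,
    panel: MarkerPanel,
    span_flank: int = DEFAULT_SPAN_FLANK,
    minimal_pks_span: int = DEFAULT_MINIMAL_PKS_SPAN,
    bgc_id: str | None = None,
) -> BGCRecord:
    """Classify genes within ``span_flank`` of the pair and type the cluster.

    T2PKS requires KSα, CLF and ACP hits on loci whose joint span is at most
    ``minimal_pks_span`` (the dissociated minimal-PKS subunits are encoded
    side by side in real type II systems).
    """
    lo = min(pair.z_feature.start, pair.w_feature.start) - span_flank
    hi = max(pair.z_feature.end, pair.w_feature.end) + span_flank
    pair_loci = {pair.z_feature.locus_tag, pair.w_feature.locus_tag}

    marker_hits: dict[str, list[HomologHit]] = {}
    gene_families: dict[str, set[str]] = {}
    classified: list[GeneFeature] = []
    for feat in contig.features:
        if feat.end <= lo or feat.start >= hi or feat.locus_tag in pair_loci:
            continue
        fams = classify_gene(feat, panel)
        if fams:
            classified.append(feat)
            gene_families[feat.locus_tag] = {name for name, _ in fams}
            for name, hit in fams:
                marker_hits.setdefault(name, []).append(hit)

    type_label = _type_from_markers(contig, marker_hits, minimal_pks_span)

    members = sorted(
        pair_loci | {f.locus_tag for f in classified},
        key=lambda lt: contig.feature_by_locus(lt).start,
    )
    span_feats = [contig.feature_by_locus(lt) for lt in members]
    span = (min(f.start for f in span_feats), max(f.end for f in span_feats))
    return BGCRecord(
        bgc_id=bgc_id or f"{contig.contig_id}.pair.{pair.z_feature.locus_tag}",
        contig_id=contig.contig_id,
        span=span,
        type_label=type_label,
        member_loci=members,
        marker_hits={k: sorted(v, key=lambda h: h.locus_tag) for k, v in sorted(marker_hits.items())},
        anchored_pair=pair,
    )


def _type_from_markers(
    contig: ContigRecord, marker_hits: Mapping[str, list[HomologHit]], minimal_pks_span: int
) -> str:
    trio = ("KS_alpha", "CLF", "ACP")
    if all(marker_hits.get(f) for f in trio):
        for ks in marker_hits["KS_alpha"]:
            for clf in marker_hits["CLF"]:
                for acp in marker_hits["ACP"]:
                    feats = [
                        contig.feature_by_locus(h.locus_tag) for h in (ks, clf, acp)
                    ]
                    span = max(f.end for f in feats) - min(f.start for f in feats)
                    if span <= minimal_pks_span:
                        return T2PKS
    if marker_hits.get("KS_type3"):
        return T3PKS
    if marker_hits.get("terpene_cyclase"):
        return TERPENE
    if marker_hits.get("NRPS_C"):
        return NRPS
    if marker_hits:
        return OTHER
    return NONE


@dataclass
class PartsTable:
    """T2PKS parts: loci per family, CYC loci with subfamily labels."""

    clf: list[str]
    ks: list[str]
    acp: list[str]
    cyc: list[tuple[str, str]]  # (locus, subfamily)
    gt: list[str]

    @property
    def cyc_subfamilies(self) -> set[str]:
        return {sub for _, sub in self.cyc}

    @property
    def counts(self) -> dict[str, int]:
        return {
            "CLF": len(self.clf),
            "KS": len(self.ks),
            "ACP": len(self.acp),
            "CYC": len(self.cyc),
            "GT": len(self.gt),
        }


def extract_parts(bgc: BGCRecord) -> PartsTable:
    """Extract the product-relevant parts of a T2PKS cluster."""
    if bgc.type_label != T2PKS:
        raise ValueError(f"extract_parts requires a T2PKS cluster, got {bgc.type_label}")
    gene_families: dict[str, set[str]] = {}
    for fam, hits in bgc.marker_hits.items():
        for h in hits:
            gene_families.setdefault(h.locus_tag, set()).add(fam)
    cyc_map = cyc_subfamilies_of(gene_families)
    return PartsTable(
        clf=bgc.loci_of("CLF"),
        ks=bgc.loci_of("KS_alpha"),
        acp=bgc.loci_of("ACP"),
        cyc=sorted(cyc_map.items()),
        gt=bgc.loci_of("GT"),
    )
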