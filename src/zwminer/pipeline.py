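"""Pipeline orchestration: scan -> type -> assign -> predict -> report.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
chains them and writes diff-able plain-text artifacts (TSV tables, Newick
trees, a JSON summary).  Identical inputs and configuration give
byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import exemplars as ex
from .bgc_typing import (
    DEFAULT_MINIMAL_PKS_SPAN,
    DEFAULT_SPAN_FLANK,
    T2PKS,
    BGCRecord,
    MarkerPanel,
    detect_bgc,
    extract_parts,
)
from .genbank_io import ContigRecord, read_genbank_dir, write_tsv
from .homolog_search import SeedQuery, search_homologs
from .pair_scan import DEFAULT_FLANK, RegulatorPair, find_pairs, summarize_records
from .phylo import (
    DEFAULT_KNOWN_CUTOFF,
    CladeAssignment,
    ReferenceSeq,
    assign_clade,
    build_nj,
    distance_matrix,
    root_with_outgroup,
    write_newick,
)
from .product_caller import ProductCall, extract_genus, integrate, summarize_taxa

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs."""

    genbank_dir: str | Path
    out_dir: str | Path
    flank: int = DEFAULT_FLANK
    clf_cutoff: float = DEFAULT_KNOWN_CUTOFF
    span_flank: int = DEFAULT_SPAN_FLANK
    minimal_pks_span: int = DEFAULT_MINIMAL_PKS_SPAN
    seed_min_identity: float = 30.0
    seed_min_coverage: float = 60.0
    marker_min_identity: float = 40.0
    marker_min_coverage: float = 60.0
    build_trees: bool = True
    seeds: list[SeedQuery] | None = None
    panel: MarkerPanel | None = None
    clf_refs: list[ReferenceSeq] | None = None

    def resolved_seeds(self) -> list[SeedQuery]:
        if self.seeds is not None:
            return self.seeds
        return ex.default_seed_queries(self.seed_min_identity, self.seed_min_coverage)

    def resolved_panel(self) -> MarkerPanel:
        if self.panel is not None:
            return self.panel
        return ex.default_marker_panel(self.marker_min_identity, self.marker_min_coverage)

    def resolved_refs(self) -> list[ReferenceSeq]:
        if self.clf_refs is not None:
            return self.clf_refs
        return [
            ReferenceSeq(r.ref_id, r.sequence, r.clade, r.product)
            for r in ex.CLF_REFERENCES
        ]


def scan_stage(
    contigs: list[ContigRecord], seeds: list[SeedQuery], flank: int
) -> dict[str, list[RegulatorPair]]:
    """Homolog search plus the co-localization window rule, per contig."""
    pairs_by_contig: dict[str, list[RegulatorPair]] = {}
    for contig in sorted(contigs, key=lambda c: c.contig_id):
        hits = search_homologs(contig, seeds)
        z_hits = [h for h in hits if _role_of(seeds, h.seed_id) == "ovmZ"]
        w_hits = [h for h in hits if _role_of(seeds, h.seed_id) == "ovmW"]
        pairs = find_pairs(contig, z_hits, w_hits, flank)
        if pairs:
            pairs_by_contig[contig.contig_id] = pairs
    return pairs_by_contig


def _role_of(seeds: list[SeedQuery], seed_id: str) -> str:
    for s in seeds:
        if s.seed_id == seed_id:
            return s.role
    return ""


def type_stage(
    contigs_by_id: dict[str, ContigRecord],
    pairs_by_contig: dict[str, list[RegulatorPair]],
    panel: MarkerPanel,
    span_flank: int,
    minimal_pks_span: int,
) -> list[BGCRecord]:
    """One typed cluster per record (contig), anchored on its first pair."""
    bgcs = []
    for contig_id in sorted(pairs_by_contig):
        pair = sorted(
            pairs_by_contig[contig_id],
            key=lambda p: (p.z_feature.start, p.w_feature.start),
        )[0]
        contig = contigs_by_id[contig_id]
        bgcs.append(
            detect_bgc(
                contig,
                pair,
                panel,
                span_flank=span_flank,
                minimal_pks_span=minimal_pks_span,
                bgc_id=f"{contig_id}.bgc1",
            )
        )
    return bgcs


def assign_stage(
    bgcs: list[BGCRecord],
    contigs_by_id: dict[str, ContigRecord],
    refs: list[ReferenceSeq],
    cutoff: float,
) -> dict[str, CladeAssignment]:
    """Nearest-reference clade assignment for the first CLF of each T2PKS."""
    assignments: dict[str, CladeAssignment] = {}
    for bgc in bgcs:
        if bgc.type_label != T2PKS:
            continue
        parts = extract_parts(bgc)
        if not parts.clf:
            continue
        locus = parts.clf[0]
        seq = contigs_by_id[bgc.contig_id].feature_by_locus(locus).translation
        assignments[bgc.bgc_id] = assign_clade(
            seq, refs, cutoff=cutoff, query_id=f"{bgc.contig_id}|{locus}"
        )
    return assignments


def predict_stage(
    bgcs: list[BGCRecord], assignments: dict[str, CladeAssignment]
) -> list[ProductCall]:
    """Integrate CLF/CYC/GT evidence per cluster."""
    calls = []
    for bgc in bgcs:
        clf = assignments.get(bgc.bgc_id)
        if bgc.type_label == T2PKS:
            parts = extract_parts(bgc)
            cyc = parts.cyc_subfamilies
            gt = len(parts.gt)
        else:
            cyc, gt = set(), 0
        calls.append(integrate(bgc.bgc_id, clf, cyc, gt))
    return calls


def summarize(
    contigs: list[ContigRecord],
    pairs_by_contig: dict[str, list[RegulatorPair]],
    bgcs: list[BGCRecord],
    calls: list[ProductCall],
) -> dict:
    """Cohort-level tallies (the acceptance surface of an end-to-end run)."""
    contigs_by_id = {c.contig_id: c for c in contigs}
    rec = summarize_records(pairs_by_contig)
    genera = [
        extract_genus(contigs_by_id[cid].organism, contigs_by_id[cid].taxonomy)
        for cid in sorted(pairs_by_contig)
    ]
    taxa = summarize_taxa(genera)
    type_counts: dict[str, int] = {}
    for bgc in bgcs:
        type_counts[bgc.type_label] = type_counts.get(bgc.type_label, 0) + 1
    call_counts = {"angucycline": 0, "angucyclinone": 0, "not-applicable": 0}
    n_known = 0
    n_angucycline_clade = 0
    for call in calls:
        call_counts[call.glycosylation_call] += 1
        if call.known_product != "novel":
            n_known += 1
        if call.skeleton_call == "angucycline-clade":
            n_angucycline_clade += 1
    return {
        "n_contigs": len(contigs),
        "n_records": rec.n_records,
        "n_z_genes": rec.n_z_genes,
        "n_w_genes": rec.n_w_genes,
        "genus_counts": {g: c for g, (c, _) in sorted(taxa.items())},
        "genus_percents": {g: round(p, 2) for g, (_, p) in sorted(taxa.items())},
        "bgc_type_counts": dict(sorted(type_counts.items())),
        "n_t2pks": type_counts.get(T2PKS, 0),
        "product_calls": call_counts,
        "n_known_products": n_known,
        "n_angucycline_clade": n_angucycline_clade,
        "gt_positive_clusters": sum(1 for c in calls if c.gt_count >= 1),
    }


def _pair_rows(pairs_by_contig, contigs_by_id):
    rows = []
    for cid in sorted(pairs_by_contig):
        contig = contigs_by_id[cid]
        genus = extract_genus(contig.organism, contig.taxonomy)
        for p in pairs_by_contig[cid]:
            rows.append(
                {
                    "contig_id": cid,
                    "organism": contig.organism,
                    "genus": genus,
                    "z_locus": p.z_hit.locus_tag,
                    "w_locus": p.w_hit.locus_tag,
                    "z_identity": f"{p.z_hit.pct_identity:.2f}",
                    "w_identity": f"{p.w_hit.pct_identity:.2f}",
                    "distance": p.intergenic_distance,
                    "same_strand": p.same_strand,
                }
            )
    return rows


def _bgc_rows(bgcs):
    rows = []
    for bgc in bgcs:
        if bgc.type_label == T2PKS:
            parts = extract_parts(bgc)
            cyc = ",".join(sub for _, sub in parts.cyc)
            gt = len(parts.gt)
            clf = ",".join(parts.clf)
        else:
            cyc, gt, clf = "", 0, ""
        rows.append(
            {
                "bgc_id": bgc.bgc_id,
                "contig_id": bgc.contig_id,
                "type": bgc.type_label,
                "span_start": bgc.span[0],
                "span_end": bgc.span[1],
                "n_members": len(bgc.member_loci),
                "clf_loci": clf,
                "cyc_subfamilies": cyc,
                "gt_count": gt,
                "z_locus": bgc.anchored_pair.z_feature.locus_tag,
                "w_locus": bgc.anchored_pair.w_feature.locus_tag,
            }
        )
    return rows


def _assignment_rows(assignments):
    rows = []
    for bgc_id in sorted(assignments):
        a = assignments[bgc_id]
        rows.append(
            {
                "bgc_id": bgc_id,
                "query_id": a.query_id,
                "nearest_ref": a.nearest_ref_id,
                "identity": f"{a.nearest_identity:.2f}",
                "clade": a.clade_label,
                "known_product": a.known_product,
                "product": a.product_call,
            }
        )
    return rows


def _call_rows(calls):
    return [
        {
            "bgc_id": c.bgc_id,
            "skeleton_call": c.skeleton_call,
            "glycosylation_call": c.glycosylation_call,
            "known_product": c.known_product,
            "cyc_families": ",".join(sorted(c.cyc_families)),
            "gt_count": c.gt_count,
        }
        for c in calls
    ]


_PAIR_COLS = ["contig_id", "organism", "genus", "z_locus", "w_locus",
              "z_identity", "w_identity", "distance", "same_strand"]
_BGC_COLS = ["bgc_id", "contig_id", "type", "span_start", "span_end", "n_members",
             "clf_loci", "cyc_subfamilies", "gt_count", "z_locus", "w_locus"]
_ASSIGN_COLS = ["bgc_id", "query_id", "nearest_ref", "identity", "clade",
                "known_product", "product"]
_CALL_COLS = ["bgc_id", "skeleton_call", "glycosylation_call", "known_product",
              "cyc_families", "gt_count"]


def _write_trees(out_dir, contigs_by_id, pairs_by_contig, bgcs, refs):
    trees_dir = out_dir / "trees"
    trees_dir.mkdir(exist_ok=True)
    z_seqs = {ex.MERR_OUTGROUP_ID: ex.MERR_OUTGROUP_SEQ}
    for cid in sorted(pairs_by_contig):
        p = pairs_by_contig[cid][0]
        z_seqs[f"{cid}|{p.z_feature.locus_tag}"] = p.z_feature.translation
    if len(z_seqs) >= 4:
        tree = build_nj(distance_matrix(z_seqs))
        tree = root_with_outgroup(tree, ex.MERR_OUTGROUP_ID)
        (trees_dir / "ovmz_homologs.nwk").write_text(write_newick(tree) + "\n")
    clf_seqs = {r.ref_id: r.sequence for r in refs}
    for bgc in bgcs:
        if bgc.type_label != T2PKS:
            continue
        parts = extract_parts(bgc)
        if parts.clf:
            locus = parts.clf[0]
            seq = contigs_by_id[bgc.contig_id].feature_by_locus(locus).translation
            clf_seqs[f"{bgc.contig_id}|{locus}"] = seq
    if len(clf_seqs) >= 3:
        tree = build_nj(distance_matrix(clf_seqs))
        (trees_dir / "clf.nwk").write_text(write_newick(tree) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write artifacts; returns the summary dict.

    Raises ``FileNotFoundError`` for missing inputs and
    :class:`~zwminer.genbank_io.GenBankParseError` for unparseable ones; the
    CLI maps these to stable exit codes.
    """
    genbank_dir = Path(config.genbank_dir)
    if not genbank_dir.is_dir():
        raise FileNotFoundError(f"GenBank directory {genbank_dir} does not exist")
    contigs = read_genbank_dir(genbank_dir)
    if not contigs:
        raise FileNotFoundError(f"no GenBank files in {genbank_dir}")
    logger.info("parsed %d contigs", len(contigs))
    contigs_by_id = {c.contig_id: c for c in contigs}

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pairs_by_contig = scan_stage(contigs, config.resolved_seeds(), config.flank)
    logger.info("scan: %d records with pairs", len(pairs_by_contig))
    write_tsv(_pair_rows(pairs_by_contig, contigs_by_id), out_dir / "pairs.tsv", _PAIR_COLS)

    panel = config.resolved_panel()
    bgcs = type_stage(contigs_by_id, pairs_by_contig, panel,
                      config.span_flank, config.minimal_pks_span)
    logger.info("type: %d clusters", len(bgcs))
    write_tsv(_bgc_rows(bgcs), out_dir / "bgcs.tsv", _BGC_COLS)

    refs = config.resolved_refs()
    assignments = assign_stage(bgcs, contigs_by_id, refs, config.clf_cutoff)
    logger.info("assign: %d CLF assignments", len(assignments))
    write_tsv(_assignment_rows(assignments), out_dir / "assignments.tsv", _ASSIGN_COLS)

    calls = predict_stage(bgcs, assignments)
    write_tsv(_call_rows(calls), out_dir / "predictions.tsv", _CALL_COLS)

    if config.build_trees:
        _write_trees(out_dir, contigs_by_id, pairs_by_contig, bgcs, refs)

    summary = summarize(contigs, pairs_by_contig, bgcs, calls)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
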