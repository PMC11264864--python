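"""Seeded generator of GenBank cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-genus actinobacterial cohort in which a configurable fraction of
contigs carries a co-localized OvmZ/OvmW regulator pair, paired contigs carry
secondary-metabolite clusters of configurable type, T2PKS clusters carry a
minimal-PKS trio plus a controlled cyclase combination and optional
glycosyltransferase, and every planted protein is a substitution-mutated copy
of a packaged exemplar at a controlled divergence.  Decoy genes are random
proteins.  A machine-readable truth table records every planted element with
its realized (post-mutation) identity, so pipeline output can be compared to
truth exactly.

Defaults mirror the survey cohort the analysis targets: genus proportions
0.74/0.06/0.04/0.16 (Streptomyces-dominated), 60% of contigs paired, 80% of
T2PKS clusters carrying the TcmN-didomain + TcmI cyclase combination, and
11% of them glycosyltransferase-positive, with 13% of chain-length factors
close enough to a characterised reference to be called known.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import exemplars as ex
from .genbank_io import CODON_TABLE, ContigRecord, GeneFeature, write_genbank

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TAXONOMY = {
    "Streptomyces": ["Bacteria", "Actinomycetota", "Actinomycetes", "Kitasatosporales", "Streptomycetaceae", "Streptomyces"],
    "Nocardia": ["Bacteria", "Actinomycetota", "Actinomycetes", "Mycobacteriales", "Nocardiaceae", "Nocardia"],
    "Amycolatopsis": ["Bacteria", "Actinomycetota", "Actinomycetes", "Pseudonocardiales", "Pseudonocardiaceae", "Amycolatopsis"],
    "Actinomadura": ["Bacteria", "Actinomycetota", "Actinomycetes", "Streptosporangiales", "Thermomonosporaceae", "Actinomadura"],
    "Kitasatospora": ["Bacteria", "Actinomycetota", "Actinomycetes", "Kitasatosporales", "Streptomycetaceae", "Kitasatospora"],
    "Lentzea": ["Bacteria", "Actinomycetota", "Actinomycetes", "Pseudonocardiales", "Pseudonocardiaceae", "Lentzea"],
}

#: Cyclase-combination plans: label -> list of (family-exemplar key, subfamily)
_CYC_PLANS: dict[str, list[tuple[str, str]]] = {
    "TcmN+TcmI": [("TcmN-didomain", "TcmN-didomain"), ("TcmI", "TcmI")],
    "TcmN+OxyN": [("TcmN-didomain", "TcmN-didomain"), ("OxyN", "OxyN")],
    "TcmJ+SnoaL": [("TcmJ", "TcmJ"), ("SnoaL", "SnoaL")],
    "TcmI": [("TcmI", "TcmI")],
}

_CYC_SOURCES = {
    "TcmN-didomain": ex.TCMN_DIDOMAIN_SEQ,
    "TcmI": dict(ex.MARKER_SEQUENCES[ex.CYC_TCMI])["TcmI_syn"],
    "TcmJ": dict(ex.MARKER_SEQUENCES[ex.CYC_TCMJ])["TcmJ_syn"],
    "OxyN": dict(ex.MARKER_SEQUENCES[ex.CYC_OXYN])["OxyN_syn"],
    "SnoaL": dict(ex.MARKER_SEQUENCES[ex.CYC_SNOAL])["SnoaL_syn"],
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort."""

    seed: int = 0
    n_contigs: int = 200
    genus_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "Streptomyces": 0.74,
            "Nocardia": 0.06,
            "Amycolatopsis": 0.04,
            "Actinomadura": 0.06,
            "Kitasatospora": 0.05,
            "Lentzea": 0.05,
        }
    )
    p_pair: float = 0.6
    #: Z-W intergenic gap ranges (bp): strictly inside / strictly outside a
    #: 500 bp window, and the fraction of pairs planted outside.
    pair_gap_inside: tuple[int, int] = (0, 450)
    pair_gap_outside: tuple[int, int] = (550, 1800)
    fraction_outside: float = 0.0
    #: probability a non-paired contig carries a lone Z homolog (no W).
    p_lone_z: float = 0.3
    #: probability a paired contig carries a second W gene upstream of Z.
    p_extra_w: float = 0.0
    pair_divergence: float = 0.2
    marker_divergence: float = 0.15
    clf_known_divergence: tuple[float, float] = (0.02, 0.08)
    clf_novel_divergence: tuple[float, float] = (0.16, 0.26)
    p_known_product: float = 0.13
    cluster_type_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "t2pks": 0.26,
            "t3pks": 0.19,
            "terpene": 0.20,
            "nrps": 0.15,
            "none": 0.20,
        }
    )
    cyc_combination_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "TcmN+TcmI": 0.80,
            "TcmN+OxyN": 0.08,
            "TcmJ+SnoaL": 0.06,
            "TcmI": 0.06,
        }
    )
    p_gt: float = 0.11
    decoys_per_contig: tuple[int, int] = (3, 6)
    #: decoy protein length range; kept above the OvmW length window so that
    #: decoys cannot satisfy the small-protein seed filter.
    decoy_length: tuple[int, int] = (130, 450)
    intergenic_spacer: tuple[int, int] = (50, 300)
    codon_table: int = CODON_TABLE

    def validate(self) -> None:
        for name, probs in (
            ("genus_proportions", self.genus_proportions),
            ("cluster_type_fractions", self.cluster_type_fractions),
            ("cyc_combination_fractions", self.cyc_combination_fractions),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative entries")
        for p in (self.p_pair, self.fraction_outside, self.p_lone_z, self.p_extra_w,
                  self.p_known_product, self.p_gt):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` by a uniformly
    chosen *different* residue; length is preserved."""
    if not (0 <= rate <= 1):
        raise ValueError("mutation rate must be in [0, 1]")
    out = []
    for ch in seq:
        if rng.random() < rate:
            alts = [a for a in AMINO_ACIDS if a != ch]
            out.append(alts[rng.integers(len(alts))])
        else:
            out.append(ch)
    return "".join(out)


def realized_identity(original: str, mutated: str) -> float:
    """Percent of unchanged positions after mutation."""
    same = sum(1 for a, b in zip(original, mutated) if a == b)
    return 100.0 * same / len(original)


_table = CodonTable.unambiguous_dna_by_id[CODON_TABLE]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_table.stop_codons)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> CDS under table 11 with a trailing stop; translating the
    output returns the input exactly."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS.get(aa)
        if options is None:
            raise ValueError(f"invalid residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length - 1)
    )


def _choice(rng: np.random.Generator, fractions: dict[str, float]) -> str:
    keys = sorted(fractions)
    probs = np.array([fractions[k] for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


@dataclass
class _PlannedGene:
    name: str  # truth family label ("decoy", "ovmZ", "CLF", ...)
    protein: str
    strand: int
    product: str
    pre_gap: int | None = None  # spacer before this gene; None -> random


def _plan_contig(config: GeneratorConfig, rng: np.random.Generator, idx: int):
    """Decide everything random about one contig; returns (plan, truth)."""
    genus = _choice(rng, config.genus_proportions)
    truth: dict = {"genus": genus, "pair": None, "cluster": None}
    genes: list[_PlannedGene] = []

    has_pair = rng.random() < config.p_pair
    cluster_kind = None
    if has_pair:
        cluster_kind = _choice(rng, config.cluster_type_fractions)

    n_decoys = int(rng.integers(config.decoys_per_contig[0], config.decoys_per_contig[1] + 1))
    n_pre = n_decoys // 2
    for _ in range(n_pre):
        length = int(rng.integers(config.decoy_length[0], config.decoy_length[1] + 1))
        genes.append(_PlannedGene("decoy", _random_protein(rng, length),
                                  1 if rng.random() < 0.5 else -1, "hypothetical protein"))

    if has_pair:
        cluster_truth = _plan_cluster(config, rng, genes, cluster_kind)
        pair_truth = _plan_pair(config, rng, genes)
        truth["cluster"] = cluster_truth
        truth["pair"] = pair_truth
    elif rng.random() < config.p_lone_z:
        z_prot = mutate_protein(ex.OVMZ_SEED_SEQ, config.pair_divergence, rng)
        genes.append(_PlannedGene("ovmZ", z_prot, 1 if rng.random() < 0.5 else -1,
                                  "hypothetical protein"))
        truth["lone_z"] = True

    for _ in range(n_decoys - n_pre):
        length = int(rng.integers(config.decoy_length[0], config.decoy_length[1] + 1))
        genes.append(_PlannedGene("decoy", _random_protein(rng, length),
                                  1 if rng.random() < 0.5 else -1, "hypothetical protein"))
    return genus, genes, truth


def _plan_cluster(config, rng, genes: list[_PlannedGene], kind: str):
    """Append cluster marker genes (type-dependent) to the plan."""
    if kind == "none":
        return None
    if kind == "t3pks":
        seq = mutate_protein(dict(ex.MARKER_SEQUENCES[ex.KS_TYPE3])["KStype3_syn"],
                             config.marker_divergence, rng)
        genes.append(_PlannedGene("KS_type3", seq, 1, "type III polyketide synthase"))
        return {"type": "t3pks", "gt_count": 0}
    if kind == "terpene":
        seq = mutate_protein(dict(ex.MARKER_SEQUENCES[ex.TERPENE_CYCLASE])["TerpeneCyclase_syn"],
                             config.marker_divergence, rng)
        genes.append(_PlannedGene("terpene_cyclase", seq, 1, "terpene cyclase"))
        return {"type": "terpene", "gt_count": 0}
    if kind == "nrps":
        seq = mutate_protein(dict(ex.MARKER_SEQUENCES[ex.NRPS_C])["NRPSCdom_syn"],
                             config.marker_divergence, rng)
        genes.append(_PlannedGene("NRPS_C", seq, 1, "non-ribosomal peptide synthetase"))
        return {"type": "nrps", "gt_count": 0}

    # --- T2PKS: minimal PKS trio + CYC combination + optional GT ---
    ks = mutate_protein(dict(ex.MARKER_SEQUENCES[ex.KS_ALPHA])["KSalpha_syn"],
                        config.marker_divergence, rng)
    known = rng.random() < config.p_known_product
    lo, hi = config.clf_known_divergence if known else config.clf_novel_divergence
    clf_div = lo + (hi - lo) * rng.random()
    ref = ex.ANGUCYCLINE_REFERENCES[rng.integers(len(ex.ANGUCYCLINE_REFERENCES))]
    clf = mutate_protein(ref.sequence, clf_div, rng)
    clf_identity = realized_identity(ref.sequence, clf)
    acp = mutate_protein(dict(ex.MARKER_SEQUENCES[ex.ACP])["ACP_syn"],
                         config.marker_divergence, rng)

    genes.append(_PlannedGene("KS_alpha", ks, 1, "ketosynthase"))
    genes.append(_PlannedGene("CLF", clf, 1, "ketosynthase chain-length factor"))
    genes.append(_PlannedGene("ACP", acp, 1, "acyl carrier protein"))

    combo = _choice(rng, config.cyc_combination_fractions)
    subfamilies = []
    for source_key, subfamily in _CYC_PLANS[combo]:
        seq = mutate_protein(_CYC_SOURCES[source_key], config.marker_divergence, rng)
        genes.append(_PlannedGene(f"CYC:{subfamily}", seq, 1, "polyketide cyclase"))
        subfamilies.append(subfamily)

    gt_count = 1 if rng.random() < config.p_gt else 0
    for _ in range(gt_count):
        seq = mutate_protein(dict(ex.MARKER_SEQUENCES[ex.GT])["GT_syn"],
                             config.marker_divergence, rng)
        genes.append(_PlannedGene("GT", seq, 1, "glycosyltransferase"))

    return {
        "type": "t2pks",
        "cyc_combination": combo,
        "cyc_subfamilies": sorted(subfamilies),
        "gt_count": gt_count,
        "clf_ref": ref.ref_id,
        "clf_product": ref.product,
        "clf_identity": clf_identity,
        "known": clf_identity >= 88.0,
    }


def _plan_pair(config, rng, genes: list[_PlannedGene]):
    strand = 1 if rng.random() < 0.5 else -1
    z_prot = mutate_protein(ex.OVMZ_SEED_SEQ, config.pair_divergence, rng)
    w_prot = mutate_protein(ex.OVMW_SEED_SEQ, config.pair_divergence, rng)
    outside = rng.random() < config.fraction_outside
    lo, hi = config.pair_gap_outside if outside else config.pair_gap_inside
    gap = int(rng.integers(lo, hi + 1))

    # second W genes only accompany inside-window pairs, so that a pair
    # planted "outside" cannot be rescued by its extra W.
    extra_w = (not outside) and rng.random() < config.p_extra_w
    truth: dict = {
        "gap": gap,
        "inside_window": not outside,
        "strand": strand,
        "z_identity": realized_identity(ex.OVMZ_SEED_SEQ, z_prot),
        "w_identity": realized_identity(ex.OVMW_SEED_SEQ, w_prot),
        "extra_w": extra_w,
    }
    if extra_w:
        w2 = mutate_protein(ex.OVMW_SEED_SEQ, config.pair_divergence, rng)
        gap2 = int(rng.integers(config.pair_gap_inside[0], config.pair_gap_inside[1] + 1))
        genes.append(_PlannedGene("ovmW2", w2, strand, "MerR family transcriptional regulator"))
        genes.append(_PlannedGene("ovmZ", z_prot, strand, "OvmZ protein", pre_gap=gap2))
    else:
        genes.append(_PlannedGene("ovmZ", z_prot, strand, "OvmZ protein"))
    genes.append(_PlannedGene("ovmW", w_prot, strand,
                              "MerR family transcriptional regulator", pre_gap=gap))
    return truth


def generate_contig(config: GeneratorConfig, index: int) -> tuple[ContigRecord, dict]:
    """Deterministically generate contig ``index`` of the cohort."""
    rng = np.random.default_rng([config.seed, index])
    genus, plan, truth = _plan_contig(config, rng, index)
    contig_id = f"SYN{index:04d}"
    organism = f"{genus} sp. SYN{index:04d}"

    parts: list[str] = [_random_dna(rng, int(rng.integers(100, 300)))]
    pos = len(parts[0])
    features: list[GeneFeature] = []
    gene_truth: list[dict] = []
    locus_map: dict[str, str] = {}
    for i, g in enumerate(plan):
        gap = g.pre_gap if g.pre_gap is not None else int(
            rng.integers(config.intergenic_spacer[0], config.intergenic_spacer[1] + 1)
        )
        spacer = _random_dna(rng, gap)
        cds = reverse_translate(g.protein, rng)
        if g.strand == -1:
            cds_on_contig = str(Seq(cds).reverse_complement())
        else:
            cds_on_contig = cds
        start = pos + gap
        end = start + len(cds)
        locus = f"{contig_id}_{i + 1:03d}"
        features.append(
            GeneFeature(
                locus_tag=locus, start=start, end=end, strand=g.strand,
                product=g.product, gene_functions=g.name if g.name != "decoy" else "",
                translation=g.protein,
            )
        )
        gene_truth.append({"locus": locus, "family": g.name})
        locus_map[g.name] = locus
        parts.append(spacer)
        parts.append(cds_on_contig)
        pos = end
    parts.append(_random_dna(rng, int(rng.integers(100, 300))))
    sequence = "".join(parts)

    if truth["pair"] is not None:
        truth["pair"]["z_locus"] = locus_map["ovmZ"]
        truth["pair"]["w_locus"] = locus_map["ovmW"]
        if truth["pair"].pop("extra_w", False):
            truth["pair"]["extra_w_loci"] = [locus_map["ovmW2"]]
        else:
            truth["pair"]["extra_w_loci"] = []
    if truth["cluster"] is not None and truth["cluster"]["type"] == "t2pks":
        truth["cluster"]["clf_locus"] = locus_map["CLF"]
    truth.update({"contig_id": contig_id, "organism": organism, "genes": gene_truth})

    contig = ContigRecord(
        contig_id=contig_id,
        organism=organism,
        taxonomy=list(_TAXONOMY[genus]),
        sequence=sequence,
        features=features,
    )
    return contig, truth


def generate_cohort(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write one GenBank file per contig plus ``truth.json``; returns the
    truth table."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"config": asdict(config), "contigs": []}
    for i in range(config.n_contigs):
        contig, contig_truth = generate_contig(config, i)
        write_genbank([contig], out_dir / f"{contig.contig_id}.gbk")
        truth["contigs"].append(contig_truth)
    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth


def expected_tallies(truth: dict) -> dict:
    """Pipeline-summary tallies implied by a truth table (the oracle for
    end-to-end recovery tests).  Only pairs planted inside the window count
    as records."""
    type_map = {"t2pks": "T2PKS", "t3pks": "T3PKS", "terpene": "terpene", "nrps": "NRPS"}
    n_records = n_w = n_z = 0
    genus_counts: dict[str, int] = {}
    bgc_types: dict[str, int] = {}
    calls = {"angucycline": 0, "angucyclinone": 0, "not-applicable": 0}
    n_known = 0
    n_angucycline_clade = 0
    for c in truth["contigs"]:
        pair = c["pair"]
        if pair is None or not pair["inside_window"]:
            continue
        n_records += 1
        n_z += 1
        n_w += 1 + len(pair["extra_w_loci"])
        genus_counts[c["genus"]] = genus_counts.get(c["genus"], 0) + 1
        cluster = c["cluster"]
        label = type_map[cluster["type"]] if cluster else "none"
        bgc_types[label] = bgc_types.get(label, 0) + 1
        if cluster and cluster["type"] == "t2pks":
            calls["angucycline" if cluster["gt_count"] >= 1 else "angucyclinone"] += 1
            if cluster["known"]:
                n_known += 1
            if {"TcmN-didomain", "TcmI"} <= set(cluster["cyc_subfamilies"]):
                n_angucycline_clade += 1
        else:
            calls["not-applicable"] += 1
    return {
        "n_contigs": len(truth["contigs"]),
        "n_records": n_records,
        "n_z_genes": n_z,
        "n_w_genes": n_w,
        "genus_counts": dict(sorted(genus_counts.items())),
        "bgc_type_counts": dict(sorted(bgc_types.items())),
        "product_calls": calls,
        "n_known_products": n_known,
        "n_angucycline_clade": n_angucycline_clade,
    }
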