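"""Packaged seed, marker and reference panels.

The pipeline needs three kinds of protein panels:

* seed queries for the two regulators (an OvmZ-like ~213 aa protein and an
  OvmW-like small HTH protein of ~78 aa), plus a MerR-family outgroup used to
  root regulator trees;
* a marker panel for cluster typing: minimal type II PKS subunits
  (ketosynthase KSα, chain-length factor CLF, acyl carrier protein ACP),
  aromatase/cyclase subfamilies (TcmN first/second-ring didomain halves,
  TcmI, TcmJ, OxyN, SnoaL), glycosyltransferase, ketoreductase and oxygenase
  families, and coarse non-T2PKS anchors (type III KS, terpene cyclase,
  NRPS condensation domain);
* a labelled chain-length-factor reference panel for nearest-reference
  product-clade assignment.

All sequences are synthetic stand-ins (see :mod:`zwminer._exemplar_seqs`);
users can point the pipeline at their own FASTA panels instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _exemplar_seqs as _seqs
from .bgc_typing import MarkerFamily, MarkerPanel
from .homolog_search import SeedQuery

#: Marker-family names used throughout the typing rules.
KS_ALPHA = "KS_alpha"
CLF = "CLF"
ACP = "ACP"
CYC_TCMN_N = "CYC_TcmN_N"
CYC_TCMN_C = "CYC_TcmN_C"
CYC_TCMI = "CYC_TcmI"
CYC_TCMJ = "CYC_TcmJ"
CYC_OXYN = "CYC_OxyN"
CYC_SNOAL = "CYC_SnoaL"
GT = "GT"
KR = "KR"
OXYGENASE = "oxygenase"
KS_TYPE3 = "KS_type3"
TERPENE_CYCLASE = "terpene_cyclase"
NRPS_C = "NRPS_C"

OVMZ_SEED_ID = "OvmZ_syn"
OVMW_SEED_ID = "OvmW_syn"
MERR_OUTGROUP_ID = "SCO3413_MerR_syn"

OVMZ_SEED_SEQ = _seqs._OVMZ
OVMW_SEED_SEQ = _seqs._OVMW
MERR_OUTGROUP_SEQ = _seqs._MERR_OUTGROUP


@dataclass(frozen=True)
class ClfReference:
    """A characterised chain-length factor with its product label."""

    ref_id: str
    product: str
    clade: str
    sequence: str


CLF_REFERENCES: tuple[ClfReference, ...] = tuple(
    ClfReference(ref_id, product, clade, seq)
    for ref_id, product, clade, seq in _seqs._CLF_REFERENCE_DATA
)

#: References in the angucycline clade (used by the generator for planting).
ANGUCYCLINE_REFERENCES: tuple[ClfReference, ...] = tuple(
    r for r in CLF_REFERENCES if r.clade == "angucycline"
)

#: family -> exemplar amino-acid sequences
MARKER_SEQUENCES: dict[str, list[tuple[str, str]]] = {
    KS_ALPHA: [("KSalpha_syn", _seqs._KS_ALPHA)],
    CLF: [(r.ref_id, r.sequence) for r in CLF_REFERENCES],
    ACP: [("ACP_syn", _seqs._ACP)],
    CYC_TCMN_N: [("TcmN_Ndom_syn", _seqs._TCMN_N)],
    CYC_TCMN_C: [("TcmN_Cdom_syn", _seqs._TCMN_C)],
    CYC_TCMI: [("TcmI_syn", _seqs._TCMI)],
    CYC_TCMJ: [("TcmJ_syn", _seqs._TCMJ)],
    CYC_OXYN: [("OxyN_syn", _seqs._OXYN)],
    CYC_SNOAL: [("SnoaL_syn", _seqs._SNOAL)],
    GT: [("GT_syn", _seqs._GT)],
    KR: [("KR_syn", _seqs._KR)],
    OXYGENASE: [("Oxygenase_syn", _seqs._OXYGENASE)],
    KS_TYPE3: [("KStype3_syn", _seqs._KS_TYPE3)],
    TERPENE_CYCLASE: [("TerpeneCyclase_syn", _seqs._TERPENE_CYCLASE)],
    NRPS_C: [("NRPSCdom_syn", _seqs._NRPS_C)],
}

#: Concatenated TcmN didomain (first-ring + second-ring halves), the form in
#: which the generator plants it.
TCMN_DIDOMAIN_SEQ = _seqs._TCMN_N + _seqs._TCMN_C


def default_seed_queries(
    min_identity: float = 30.0,
    min_query_coverage: float = 60.0,
    ovmw_length_window: tuple[int, int] | None = (50, 120),
) -> list[SeedQuery]:
    """Seed queries for the regulator pair at conventional homology thresholds.

    The OvmW seed additionally restricts subject length to small HTH-protein
    sizes, since OvmW-family regulators are 60-80 aa proteins and short-protein
    alignments are identity-noisy.
    """
    return [
        SeedQuery(
            seed_id=OVMZ_SEED_ID,
            role="ovmZ",
            sequence=OVMZ_SEED_SEQ,
            min_identity=min_identity,
            min_query_coverage=min_query_coverage,
        ),
        SeedQuery(
            seed_id=OVMW_SEED_ID,
            role="ovmW",
            sequence=OVMW_SEED_SEQ,
            min_identity=min_identity,
            min_query_coverage=min_query_coverage,
            length_window=ovmw_length_window,
        ),
    ]


def default_marker_panel(
    min_identity: float = 40.0, min_coverage: float = 60.0
) -> MarkerPanel:
    """The packaged marker panel with uniform family thresholds."""
    families = {
        name: MarkerFamily(
            name=name,
            exemplars=list(pairs),
            min_identity=min_identity,
            min_coverage=min_coverage,
        )
        for name, pairs in MARKER_SEQUENCES.items()
    }
    return MarkerPanel(families)
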