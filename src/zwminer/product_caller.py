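"""Per-cluster product prediction and cohort summaries.

Three lines of evidence are integrated per T2PKS cluster:

* the chain-length-factor clade (nearest characterised reference, with the
  88% identity cut-off separating known from novel products);
* the cyclase complement — clusters carrying both a TcmN-type didomain
  aromatase and a TcmI-like cyclase sit in the angucycline clade, other
  combinations stay unresolved;
* glycosyltransferase presence — a glycosylated angucycline needs at least
  one GT gene, so GT-free clusters are called angucyclinones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .bgc_typing import TCMI, TCMN_DIDOMAIN
from .phylo import CladeAssignment

ANGUCYCLINE_CLADE = "angucycline-clade"
UNRESOLVED = "unresolved"
ANGUCYCLINE = "angucycline"
ANGUCYCLINONE = "angucyclinone"
NOT_APPLICABLE = "not-applicable"
NOVEL = "novel"


def cyc_combination_rule(cyc_families: set[str]) -> str:
    """Angucycline-clade skeleton iff the TcmN didomain and a TcmI-like
    cyclase co-occur; any other combination is unresolved."""
    if TCMN_DIDOMAIN in cyc_families and TCMI in cyc_families:
        return ANGUCYCLINE_CLADE
    return UNRESOLVED


def glycosylation_rule(gt_count: int, skeleton_evidence: bool) -> str:
    """angucycline iff >= 1 GT gene; angucyclinone iff none; not-applicable
    when there is no skeleton evidence to glycosylate."""
    if gt_count < 0:
        raise ValueError("gt_count must be >= 0")
    if not skeleton_evidence:
        return NOT_APPLICABLE
    return ANGUCYCLINE if gt_count >= 1 else ANGUCYCLINONE


@dataclass(frozen=True)
class ProductCall:
    """Integrated per-cluster prediction with its evidence."""

    bgc_id: str
    skeleton_call: str
    glycosylation_call: str
    known_product: str  # product name or "novel"
    clf_assignment: CladeAssignment | None = None
    cyc_families: frozenset[str] = field(default_factory=frozenset)
    gt_count: int = 0


def integrate(
    bgc_id: str,
    clf: CladeAssignment | None,
    cyc_families: Iterable[str],
    gt_count: int,
) -> ProductCall:
    """Combine CLF, CYC and GT evidence into one call.

    Skeleton evidence is the presence of a CLF; without it the cluster gets a
    not-applicable call with empty evidence.  The known-product name needs
    only the CLF cut-off, not CYC agreement.
    """
    cyc_set = frozenset(cyc_families)
    skeleton_evidence = clf is not None
    glyc = glycosylation_rule(gt_count, skeleton_evidence)
    if not skeleton_evidence:
        return ProductCall(
            bgc_id=bgc_id,
            skeleton_call=UNRESOLVED,
            glycosylation_call=NOT_APPLICABLE,
            known_product=NOVEL,
            clf_assignment=None,
            cyc_families=frozenset(),
            gt_count=gt_count,
        )
    return ProductCall(
        bgc_id=bgc_id,
        skeleton_call=cyc_combination_rule(set(cyc_set)),
        glycosylation_call=glyc,
        known_product=clf.product if clf.known_product else NOVEL,
        clf_assignment=clf,
        cyc_families=cyc_set,
        gt_count=gt_count,
    )


def extract_genus(organism: str, taxonomy: list[str]) -> str:
    """Genus from the lineage: the rank below the family (…aceae) entry, else
    the last lineage entry, else the first organism-name token."""
    for i, rank in enumerate(taxonomy):
        if rank.endswith("aceae") and i + 1 < len(taxonomy):
            return taxonomy[i + 1]
    if taxonomy:
        return taxonomy[-1]
    return organism.split()[0] if organism else ""


def summarize_taxa(genera: Iterable[str]) -> dict[str, tuple[int, float]]:
    """genus -> (count, percent); percents sum to 100 up to rounding."""
    counts: dict[str, int] = {}
    for g in genera:
        counts[g] = counts.get(g, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {
        g: (n, 100.0 * n / total)
        for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def bgc_type_matrix(records: Iterable[Mapping[str, str]]) -> pd.DataFrame:
    """genus x cluster-type count matrix from records carrying ``genus`` and
    ``type_label`` keys."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame(records)
    return (
        df.groupby(["genus", "type_label"]).size().unstack(fill_value=0).sort_index()
    )
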