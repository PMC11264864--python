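"""Pairwise protein alignment and seed-based homolog detection.

This is the in-package stand-in for a Blastp survey: every annotated protein
on a contig is aligned locally against each seed query, and hits are filtered
on percent identity and query coverage (plus an optional subject-length
window, useful for small HTH regulators).  Optimal affine-gap alignments are
computed with biotite's C kernels.

Gap-cost convention: a gap of length *k* costs ``gap_open + k * gap_extend``
(BLAST-style existence + per-residue cost).  Percent identity is
``100 * identities / aligned_columns`` where the denominator counts gap
columns, i.e. the Blastp statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import biotite.sequence as bseq
import biotite.sequence.align as balign

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@lru_cache(maxsize=8)
def _matrix(name: str) -> balign.SubstitutionMatrix:
    if name.upper() == "BLOSUM62":
        return balign.SubstitutionMatrix.std_protein_matrix()
    alph = bseq.ProteinSequence.alphabet
    return balign.SubstitutionMatrix(alph, alph, name)


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one pairwise alignment.

    ``aligned_columns`` counts gap columns; spans are 0-based half-open on
    the ungapped inputs.  A local alignment with no positive-scoring path is
    reported with score 0 and zero columns.
    """

    score: int
    identities: int
    aligned_columns: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def pct_identity(self) -> float:
        if self.aligned_columns == 0:
            return 0.0
        return 100.0 * self.identities / self.aligned_columns

    @property
    def is_empty(self) -> bool:
        return self.aligned_columns == 0


@dataclass(frozen=True)
class SeedQuery:
    """A seed protein with its detection thresholds."""

    seed_id: str
    role: str  # "ovmZ", "ovmW", or "marker:<family>"
    sequence: str
    min_identity: float = 30.0
    min_query_coverage: float = 60.0
    length_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("seed sequence must be non-empty")
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")
        if not (0 < self.min_query_coverage <= 100):
            raise ValueError("min_query_coverage must be in (0, 100]")


@dataclass(frozen=True)
class HomologHit:
    """A seed-vs-locus alignment passing the seed's thresholds."""

    seed_id: str
    contig_id: str
    locus_tag: str
    pct_identity: float
    query_coverage: float
    score: int


def _summarise(alignment: balign.Alignment, a: str, b: str) -> AlignmentResult:
    trace = alignment.trace
    if len(trace) == 0:
        return AlignmentResult(0, 0, 0, (0, 0), (0, 0))
    identities = 0
    for i, j in trace:
        if i >= 0 and j >= 0 and a[i] == b[j]:
            identities += 1
    qi = trace[:, 0][trace[:, 0] >= 0]
    sj = trace[:, 1][trace[:, 1] >= 0]
    return AlignmentResult(
        score=int(alignment.score),
        identities=identities,
        aligned_columns=len(trace),
        query_span=(int(qi.min()), int(qi.max()) + 1),
        subject_span=(int(sj.min()), int(sj.max()) + 1),
    )


def _align(
    a: str,
    b: str,
    matrix: str,
    gap_open: int,
    gap_extend: int,
    local: bool,
) -> AlignmentResult:
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    sa = bseq.ProteinSequence(a)
    sb = bseq.ProteinSequence(b)
    # biotite charges open for the first gap position and extend thereafter;
    # shift so a length-k gap costs open + k*extend as documented here.
    penalty = (-(gap_open + gap_extend), -gap_extend)
    alignment = balign.align_optimal(
        sa, sb, _matrix(matrix), gap_penalty=penalty, local=local, max_number=1
    )[0]
    return _summarise(alignment, a, b)


def local_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment under affine gap costs."""
    return _align(a, b, matrix, gap_open, gap_extend, local=True)


def global_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment under affine gap costs."""
    return _align(a, b, matrix, gap_open, gap_extend, local=False)


def search_homologs(contig, seeds, matrix: str = DEFAULT_MATRIX) -> list[HomologHit]:
    """Align every contig feature to every seed and return filtered hits.

    At most one hit per (seed, locus); hits sorted by descending score, then
    seed id and locus tag for determinism.
    """
    hits: list[HomologHit] = []
    for seed in seeds:
        qlen = len(seed.sequence)
        for feat in contig.features:
            if not feat.translation:
                continue
            if seed.length_window is not None:
                lo, hi = seed.length_window
                if not (lo <= len(feat.translation) <= hi):
                    continue
            res = local_align(seed.sequence, feat.translation, matrix=matrix)
            if res.is_empty:
                continue
            coverage = 100.0 * (res.query_span[1] - res.query_span[0]) / qlen
            if res.pct_identity >= seed.min_identity and coverage >= seed.min_query_coverage:
                hits.append(
                    HomologHit(
                        seed_id=seed.seed_id,
                        contig_id=contig.contig_id,
                        locus_tag=feat.locus_tag,
                        pct_identity=res.pct_identity,
                        query_coverage=coverage,
                        score=res.score,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.seed_id, h.locus_tag))
    return hits
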