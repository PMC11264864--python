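# Methods

## Co-localization model

The unit of analysis is an annotated contig. An OvmZ homolog is any CDS
whose translation aligns locally to the OvmZ seed at ≥ 30% identity
(identities / alignment columns, gap columns in the denominator — the
Blastp-style statistic) with ≥ 60% of the seed covered by the alignment.
OvmW homologs use the same thresholds plus a subject-length window of
50–120 aa, reflecting the 60–80 aa size of OvmW-family HTH proteins and the
identity noise of short-protein alignments. All thresholds are exposed in
configuration.

A regulator pair exists when the W gene interval overlaps the window
`[z_start − flank, z_end + flank)` built from the Z gene's boundaries
(default flank 500 bp), clamped to the contig. Design choices, made where
the window rule is ambiguous and testable via the flank/config knobs:

* the window is built from gene boundaries, not start codons or midpoints
  (the most permissive reading of "500 bp upstream and downstream");
* overlapping Z/W genes (intergenic distance 0) count as paired — operonic
  pairs are the biological signal;
* no same-strand requirement; strand agreement is reported, not filtered;
* one window per Z hit; duplicate (z locus, w locus) pairs deduplicated.

A *record* is a contig with ≥ 1 pair. Record counts and distinct homolog
gene counts are reported separately because one record can carry several W
genes around one Z gene.

## Alignment

Optimal affine-gap alignments (Smith–Waterman locally, Needleman–Wunsch
globally) are computed with biotite's C kernels under BLOSUM62 with gap
open 11 / extend 1, a gap of length *k* costing `11 + k`. The test suite
checks score optimality against an exhaustive brute-force enumeration of all
gapped alignment paths on short peptides (lengths ≤ 6, reduced and full
alphabets), using Biopython's independently packaged BLOSUM62. Traceback is
deterministic (biotite's own tie order); every downstream decision consumes
scores, identities, columns and spans, which are tie-independent in
practice and the only quantities under test. A local alignment whose best
score is 0 is reported as "no alignment". No E-value model is used:
single-proteome scans make database-size statistics meaningless.

## Cluster typing

Genes within `span_flank` (default 15 kb) of the pair are classified against
a marker panel by the same alignment machinery (family defaults: 40%
identity, 60% exemplar coverage). Annotation strings are never evidence.
The cluster is typed T2PKS iff KSα, CLF and ACP hits exist on loci whose
joint span is ≤ 10 kb (the minimal-PKS subunits are encoded side by side in
real type II systems; the exemplar cluster motivating the defaults is ~21 kb
with 18 ORFs). Ablating any trio member always changes the label — a tested
necessity property. Single-anchor fallbacks give T3PKS / terpene / NRPS;
marker evidence without an anchor gives "other"; none gives "none".

A gene hitting both the TcmN first-ring (N) and second-ring (C) domain
exemplars is labelled a TcmN didomain aromatase; TcmI/TcmJ/OxyN/SnoaL-like
cyclases map from their own families.

## Product prediction

* **Skeleton (cyclase rule):** TcmN-didomain ∧ TcmI ⇒ angucycline-clade;
  anything else unresolved (other combinations genuinely underdetermine the
  intermediate).
* **Glycosylation (GT rule):** with CLF evidence present, ≥ 1
  glycosyltransferase gene ⇒ angucycline, none ⇒ angucyclinone. Without CLF
  evidence the call is not-applicable rather than a vacuous angucyclinone.
* **Known vs novel (CLF rule):** global-alignment percent identity to the
  nearest characterised CLF reference, cut-off 88%, inclusive (≥ 88 ⇒ known,
  taking the reference's product name). Inclusivity is a package choice
  (exposed as config); the comparison uses full-length identity — alignment
  trimming is out of scope and a known caveat. Known-product naming needs
  only the CLF rule, not cyclase agreement.

The 2 (known/novel) × 4 (cyclase combinations) × 2 (GT absent/present)
decision grid is fully enumerated in tests; call tallies are conserved
(angucycline + angucyclinone + not-applicable = records).

## Phylogenetics

Distances are p-distances, `1 − identities/columns`, from global alignments.
Trees are neighbor joining (scikit-bio), which is exact on additive
distances — the acceptance surface is topology recovery (Robinson–Foulds 0 on
random additive matrices of 5–8 taxa), not likelihoods, so no substitution
model or ML search is used. Labels are sorted lexicographically before
agglomeration so ties resolve identically on every run; negative
branch-length estimates are clamped to 0 with a warning. Regulator trees are
rooted at the midpoint of the MerR-outgroup pendant edge. Bootstrap support
is omitted: support values are cosmetic to the prediction logic. Newick
output quotes labels containing spaces.

## Synthetic cohorts

The generator emits GenBank contigs assembled gene by gene (reverse
translation under NCBI codon table 11, random intergenic spacers of
50–300 bp) and a truth table recording every planted element with its
realized post-mutation identity. Defaults encode the survey's study
conditions and were fixed as such: 200 contigs; genus proportions 0.74
*Streptomyces* / 0.06 *Nocardia* / 0.04 *Amycolatopsis* / 0.16 other; 60% of
contigs paired; cluster types among paired contigs 26% T2PKS, 19% T3PKS, 20%
terpene, 15% NRPS, 20% bare; 80% of T2PKS clusters with TcmN+TcmI cyclases,
11% GT-positive, 13% of CLFs at known-product divergence (2–8% substitution,
realized identity ~92–98%) and the rest at novel divergence (16–26%,
identity ~74–84%) — ranges chosen to keep realized identities several
binomial standard deviations away from the 88% boundary so that the truth
table's known/novel labels are unambiguous. Planted pairs diverge 20% from
the seeds, markers 15%, both far inside detection thresholds. Pair gaps are
drawn from 0–450 bp ("strictly inside" a 500 bp window) or 550–1800 bp
("strictly outside") per configuration. Decoys are random proteins of
130–450 aa — deliberately above the OvmW length window so a decoy can never
satisfy the small-protein filter. Non-paired contigs carry a lone Z homolog
30% of the time, exercising pairing precision.

Mutation is substitution-only (each position replaced with probability
*rate* by a uniformly chosen different residue), keeping realized identity
analytically checkable; indels, GC skew, codon-usage structure and
genome-scale replicons are not emulated. Consequently, passing recovery
tests demonstrates the window arithmetic, threshold logic, typing rules and
decision table — not robustness to fragmented assemblies, frameshifts, or
real homology structure (real CLFs are homologous to KSα; the synthetic
families are mutually random). The packaged seed/marker/reference panels are
synthetic stand-ins with realistic lengths; users supply FASTA panels of
real sequences for real surveys.

Reproducibility: each contig's randomness comes from a stream keyed by
(seed, contig index); the same seed yields byte-identical GenBank files
(fixed LOCUS date) and byte-identical pipeline artifacts.

## Problem sizes and numerical choices

The shipped acceptance checks run at desk scale, chosen as the package's own
test conditions: 200-contig cohorts for end-to-end truth recovery, 50
contigs for the window-rule suite, 100 random trees for NJ consistency,
brute-force alignment oracles at lengths ≤ 6. Coordinates are 0-based
half-open internally (GenBank 1-based inclusive at the file boundary);
compound CDS locations collapse to their outer span (no bacterial splicing);
ambiguous codons translate to X; CDS with internal stops are excluded with a
warning. Percent ties in nearest-reference assignment break by lexicographic
reference id, making the assignment invariant to panel order.

## Known limitations

* Cluster boundaries are marker envelopes, not probabilistic boundary
  inference; RiPP and other specialised cluster classes beyond the coarse
  labels are not modelled.
* The survey's absolute database counts depend on the NCBI nr snapshot and
  annotator versions and are intentionally not reproduced; the pipeline
  reproduces the *logic* and measures recovery on cohorts whose composition
  mirrors the reported proportions.
* The 88% rule presumes identity to a characterised reference is a valid
  novelty proxy; with the synthetic reference panel this is exercised, not
  validated, biologically.
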