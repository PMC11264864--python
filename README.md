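# zwminer

Regulator-pair-guided genome mining for type II polyketide gene clusters.

## The problem

OvmZ and OvmW are a pair of interdependent transcriptional activators:
co-expressing both genes can awaken otherwise silent biosynthetic gene
clusters (BGCs) in actinobacteria, while either gene alone does nothing.
OvmZ has no conserved domain; OvmW is a small (60–80 aa) MerR-annotated
helix-turn-helix protein, and the two genes sit together in an operon.
Because the pair travels with the clusters it regulates, finding co-localized
*ovmZ*/*ovmW* homolog pairs in assembled genomes is a way to find activatable
clusters — and for type II PKS (T2PKS) clusters, the surrounding gene content
predicts what the awakened product would be.

`zwminer` implements that survey as a tested, offline pipeline over annotated
GenBank contigs:

1. **scan** — align every annotated protein against OvmZ/OvmW seed queries
   (Smith–Waterman, BLOSUM62, affine gaps, gap of length *k* costing
   `open + k·ext`), and report a *regulator pair* wherever an OvmW homolog
   gene overlaps the window extending 500 bp upstream and downstream of an
   OvmZ homolog gene. Records (contigs with ≥ 1 pair) are counted separately
   from homolog genes, since one record can carry two flanking *ovmW* genes.
2. **type** — classify genes within 15 kb of the pair against a marker panel
   (alignment evidence only) and call the cluster **T2PKS** when the minimal
   PKS trio — ketosynthase KSα, chain-length factor CLF, acyl carrier protein
   ACP — co-occurs within 10 kb; coarse labels (T3PKS, terpene, NRPS, other,
   none) otherwise.
3. **assign** — place each cluster's CLF by global-alignment percent identity
   to a panel of characterised CLFs. The CLF clade predicts the core
   skeleton; identity ≥ 88% to the nearest reference (inclusive) calls a
   *known* product, below it *novel*.
4. **predict** — integrate the evidence per cluster:
   * cyclase rule: TcmN-didomain **and** TcmI-like cyclases together ⇒
     angucycline-clade skeleton; other combinations unresolved;
   * glycosyltransferase rule: ≥ 1 GT gene ⇒ angucycline, none ⇒
     angucyclinone (aglycone), no CLF evidence ⇒ not-applicable.
5. **report** — cohort tallies: records, genus composition, cluster types,
   product calls.

Distance-based phylogenetics (p-distance + neighbor joining, optional
MerR-outgroup rooting) produces the regulator and CLF trees as Newick files.

Because a real survey's inputs (an NCBI Blastp run over hundreds of
nucleotide records) are not shippable, the package includes a first-class
**synthetic-cohort generator**: seeded GenBank cohorts with planted pairs at
controlled gap distances and divergences, T2PKS clusters with controlled
cyclase/GT composition, decoy genes and multi-genus labels, plus a
machine-readable `truth.json` — so recovery can be measured exactly.

## Worked example

```
$ zwminer simulate --seed 5 --n-contigs 30 --out demo
wrote 30 contigs to demo (19 with planted pairs)
$ zwminer run --genbank demo --out demo_out
```

The run prints the cohort summary (also written to `demo_out/summary.json`):

```
{
 "bgc_type_counts": {"NRPS": 1, "T2PKS": 4, "T3PKS": 5, "none": 3, "terpene": 6},
 "genus_percents": {"Lentzea": 10.53, "Nocardia": 10.53, "Streptomyces": 78.95},
 "n_contigs": 30,
 "n_records": 19,
 "n_w_genes": 19,
 "n_z_genes": 19,
 "n_t2pks": 4,
 "n_angucycline_clade": 3,
 "n_known_products": 0,
 "product_calls": {"angucycline": 0, "angucyclinone": 4, "not-applicable": 15}
}
```

Reading: 19 of 30 contigs carry a co-localized regulator pair ("records"),
~79% of them from *Streptomyces*; 4 records have a complete minimal-PKS
T2PKS cluster, of which 3 carry the TcmN-didomain + TcmI cyclase combination
(angucycline-clade skeleton); all 4 lack glycosyltransferases, so all are
predicted angucyclinones; no CLF reaches 88% identity to a characterised
reference, so all products are called novel. Per-pair and per-cluster detail
lands in `pairs.tsv`, `bgcs.tsv`, `assignments.tsv`, `predictions.tsv`, e.g.

```
bgc_id        skeleton_call      glycosylation_call  known_product  cyc_families        gt_count
SYN0002.bgc1  angucycline-clade  angucyclinone       novel          TcmI,TcmN-didomain  0
```

The same stages are available as a Python API (`zwminer.run_pipeline`,
`zwminer.find_pairs`, `zwminer.detect_bgc`, `zwminer.assign_clade`, …) and as
separate CLI subcommands chained through the TSV artifacts.

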