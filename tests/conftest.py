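import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from zwminer.genbank_io import ContigRecord, GeneFeature
from zwminer.synthetic_data import GeneratorConfig, generate_cohort


def build_contig(genes, contig_id="CTG1", organism="Streptomyces sp. T1",
                 taxonomy=None, total_len=None):
    """Assemble a ContigRecord from (locus, start, end, strand, translation)
    tuples with a placeholder nucleotide sequence (window arithmetic and
    alignment only need intervals and translations)."""
    feats = [
        GeneFeature(locus_tag=lt, start=s, end=e, strand=st, translation=tr)
        for lt, s, e, st, tr in genes
    ]
    length = total_len or (max(f.end for f in feats) + 500 if feats else 1000)
    return ContigRecord(
        contig_id=contig_id,
        organism=organism,
        taxonomy=taxonomy or ["Bacteria", "Actinomycetota", "Actinomycetes",
                              "Kitasatosporales", "Streptomycetaceae", "Streptomyces"],
        sequence="N" * length,
        features=feats,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240718)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 20-contig cohort with every contig paired, reused by several tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = GeneratorConfig(seed=11, n_contigs=20, p_pair=1.0)
    truth = generate_cohort(cfg, out)
    return out, truth
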