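import pytest

from scestruct.synthetic_data import (
    SyntheticConfig,
    annotations_from_truth,
    generate_study,
    write_bundle,
)
from scestruct.types import GenomicInterval, TranscriptModel, TranscriptSet


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study shared across tests."""
    cfg = SyntheticConfig(
        n_genes=40, sce_counts={9: 40, 15: 40, 30: 40}, seed=101
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def small_annotations(small_bundle):
    return annotations_from_truth(small_bundle)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    """The same study serialized to its on-disk formats."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_bundle, outdir)
    return paths


def _make_transcript(tid, gene, strand, blocks, cds, canonical=True):
    from Bio.Seq import Seq

    protein = str(Seq(cds).translate())
    assert "*" not in protein
    ivs = tuple(GenomicInterval("chrT", s, e, strand) for s, e in blocks)
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene,
        strand=strand,
        exons=ivs,
        cds_blocks=ivs,
        cds_sequence=cds,
        protein_sequence=protein,
        protein_id=tid + "_p",
        is_canonical=canonical,
    )


@pytest.fixture
def plus_transcript():
    """Two-exon plus-strand toy gene: CDS blocks (100,130) and (200,230)."""
    cds = "ATG" + "GCT" * 9 + "CCG" * 10  # 60 nt, 20 residues
    return _make_transcript("txp", "gplus", "+", [(100, 130), (200, 230)], cds)


@pytest.fixture
def minus_transcript():
    """Two-exon minus-strand toy gene; blocks in transcript order are the
    genomically-later block first."""
    cds = "ATG" + "AAA" * 9 + "GAA" * 10
    return _make_transcript("txm", "gminus", "-", [(400, 430), (300, 330)], cds)


@pytest.fixture
def toy_transcript_set(plus_transcript, minus_transcript):
    return TranscriptSet([plus_transcript, minus_transcript])
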