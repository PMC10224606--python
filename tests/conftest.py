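import pytest

from circscape.catalog import CircRNA
from circscape.intervals import GenomicInterval, TranscriptModel
from circscape.simulate import SynthConfig, simulate_all


def make_transcript(
    exon_spans,
    chrom="chr1",
    strand="+",
    transcript_id="TX1",
    gene_id="G1",
    gene_name="GENE1",
):
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_name=gene_name,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans),
    )


def make_circ(transcript, i, j, **kwargs):
    """CircRNA annotated over exons i..j (ascending genomic indices)."""
    iv = GenomicInterval(
        transcript.chrom,
        transcript.exons[i].start,
        transcript.exons[j].end,
        transcript.strand,
    )
    defaults = dict(
        interval=iv,
        detectors=frozenset({"circexplorer2", "ciri2"}),
        counts=(5, 5, 5),
        host_gene=transcript.gene_name,
        annotation="annotated",
        transcript_id=transcript.transcript_id,
        bs_exon_indices=(i, j),
    )
    defaults.update(kwargs)
    return CircRNA(**defaults)


@pytest.fixture(scope="session")
def five_exon_tx():
    # exons of 100 b separated by introns of 400/500/600/700 b
    return make_transcript(
        [(1000, 1100), (1500, 1600), (2100, 2200), (2800, 2900), (3600, 3700)]
    )


@pytest.fixture(scope="session")
def sim_config():
    return SynthConfig(seed=11, n_genes=40)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory, sim_config):
    outdir = tmp_path_factory.mktemp("sim")
    return simulate_all(sim_config, outdir)
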