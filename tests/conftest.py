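import pytest

from bfuscan.annotation import GeneRecord, GenomeAnnotation
from bfuscan.pipeline import PipelineConfig, run_pipeline
from bfuscan.synth import GeneratorConfig, generate_genome_set, write_bundle

# proteins used by hand-built genomes in tests: motif-free filler and the
# canonical A template (carries the three H-cluster motifs)
FILLER = "ACDEFGHIKLMNQR" * 10


def build_genome(genome_id, layout, proteins=None, domains=None, contig_id="c1",
                 contig_length=None):
    """Hand-build a one-contig genome from (gene_id, strand) pairs in
    coordinate order, with uniform 300-nt genes and 100-nt gaps."""
    proteins = proteins or {}
    domains = domains or {}
    genes = []
    pos = 101
    for rank, (gid, strand) in enumerate(layout, 1):
        genes.append(GeneRecord(gid, contig_id, pos, pos + 299, strand, rank))
        proteins.setdefault(gid, FILLER)
        pos += 400
    ann = GenomeAnnotation(
        genome_id=genome_id,
        contigs={contig_id: genes},
        proteins=proteins,
        domains=domains,
        contig_lengths={contig_id: contig_length or pos + 100},
    )
    return ann


@pytest.fixture(scope="session")
def default_run():
    """Default study conditions: 20 genomes x 3 clusters, uniform sub-type
    mix, seed 42; full in-memory pipeline run plus ground truth."""
    config = GeneratorConfig(seed=42)
    annotations, truths = generate_genome_set(config)
    summary = run_pipeline(
        PipelineConfig(write_reports=False), annotations=annotations
    )
    return annotations, truths, summary


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small on-disk bundle (6 genomes x 2 clusters, seed 11)."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = GeneratorConfig(n_genomes=6, clusters_per_genome=2, seed=11)
    annotations, truths = generate_genome_set(config)
    write_bundle(annotations, truths, outdir)
    return outdir, annotations, truths
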