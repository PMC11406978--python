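"""The synthetic-genome generator and its ground-truth bookkeeping."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from bfuscan.annotation import GenomeAnnotation
from bfuscan.motifs import DEFAULT_CATALOG, scan_motif
from bfuscan.subtypes import UNCLASSIFIED
from bfuscan.synth import (
    GeneratorConfig,
    PlantSpec,
    generate_genome_set,
    plant_cluster,
    read_truth,
    write_bundle,
)


def _plant(spec, seed=3):
    ann = GenomeAnnotation(genome_id="P001")
    rng = np.random.default_rng(seed)
    truth = plant_cluster(ann, spec, rng)
    return ann, truth


def _cluster_genes(ann, truth):
    """(role-bearing) genes of the planted contig in coordinate order."""
    genes = ann.contigs[truth.contig_id]
    return [(g, ann.domains_of(g.gene_id)) for g in genes]


class TestConfigValidation:
    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(subtype_mix={"I": 0.7, "II": 0.7})

    def test_bad_divergence_rejected(self):
        with pytest.raises(ValueError, match="divergence_between"):
            GeneratorConfig(divergence_between=0.9)

    def test_bad_plant_spec_rejected(self):
        with pytest.raises(ValueError, match="intervening_decoys"):
            PlantSpec(subtype="I", intervening_decoys=9)


class TestGenerateGenomeSet:
    def test_zero_genomes_empty_outputs(self):
        anns, truths = generate_genome_set(GeneratorConfig(n_genomes=0))
        assert anns == [] and truths == []

    def test_fixed_seed_byte_identical_bundles(self, tmp_path):
        for sub in ("one", "two"):
            config = GeneratorConfig(n_genomes=3, clusters_per_genome=2, seed=9)
            anns, truths = generate_genome_set(config)
            write_bundle(anns, truths, tmp_path / sub)
        files = sorted(p.name for p in (tmp_path / "one").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(tmp_path / "one" / name, tmp_path / "two" / name,
                               shallow=False), name

    def test_truth_table_size_and_round_trip(self, tmp_path):
        config = GeneratorConfig(n_genomes=4, clusters_per_genome=3, seed=2)
        anns, truths = generate_genome_set(config)
        assert len(truths) == 12
        write_bundle(anns, truths, tmp_path)
        assert read_truth(tmp_path / "truth.tsv") == truths

    def test_planted_bfua_carries_canonical_motifs(self):
        anns, truths = generate_genome_set(
            GeneratorConfig(n_genomes=3, clusters_per_genome=2, seed=21)
        )
        proteins = {}
        for ann in anns:
            proteins.update(ann.proteins)
        for t in truths:
            seq = proteins[t.anchor]
            starts = [scan_motif(seq, p)[0].start for p in DEFAULT_CATALOG]
            assert starts == sorted(starts)
            # the sub-type discriminating wildcard: Cys in IV, Ser elsewhere
            p1 = scan_motif(seq, DEFAULT_CATALOG[0])[0]
            fifth = p1.matched[4]
            assert fifth == ("C" if t.subtype == "IV" else "S")


class TestPlantCluster:
    def test_subtype_iii_minus_strand_layout(self):
        ann, truth = _plant(PlantSpec(subtype="III", strand="-"))
        genes = ann.contigs[truth.contig_id]
        roles = [
            ("C1" in ann.domains_of(g.gene_id) and "C")
            or (g.gene_id == truth.anchor and "A")
            or ("FMN" in ann.domains_of(g.gene_id) and "B")
            or "X"
            for g in genes
        ]
        core = [r for r in roles if r != "X"]
        # transcription order C,A,B on the minus strand = coordinate order B,A,C
        assert core == ["B", "A", "C"]
        assert all(g.strand == "-" for g in genes if g.gene_id == truth.anchor)

    def test_omitted_b_marks_expected_rejection(self):
        _, truth = _plant(PlantSpec(subtype="I", omit_subunit="B"))
        assert truth.expected_detected and not truth.expected_retained
        assert truth.expected_label == UNCLASSIFIED

    def test_omitted_d_shifts_expected_label_to_ii(self):
        _, truth = _plant(PlantSpec(subtype="I", omit_subunit="D"))
        assert truth.expected_retained and truth.expected_label == "II"

    def test_double_t_variant_brackets_the_cluster(self):
        ann, truth = _plant(PlantSpec(subtype="V", t_variant="double_T"))
        genes = ann.contigs[truth.contig_id]
        t_ranks = [g.rank for g in genes
                   if {"PAS", "His_kinase_dom"} & set(ann.domains_of(g.gene_id))]
        a_rank = ann.gene(truth.anchor).rank
        assert len(t_ranks) == 2
        assert min(t_ranks) < a_rank < max(t_ranks)
        assert truth.expected_label == UNCLASSIFIED

    def test_edge_truncation_marks_partial_gene(self):
        ann, truth = _plant(PlantSpec(subtype="II", strand="+", edge_truncate=True))
        genes = ann.contigs[truth.contig_id]
        last = genes[-1]
        assert last.partial
        assert last.end == ann.contig_lengths[truth.contig_id]
        # on the plus strand the last gene is C, so the cluster must be rejected
        assert not truth.expected_retained

    def test_strand_choice_preserves_canonical_role_order(self):
        from bfuscan.pipeline import analyze_genome

        for strand in "+-":
            ann, truth = _plant(PlantSpec(subtype="IV", strand=strand), seed=8)
            calls, _ = analyze_genome(ann)
            assert len(calls) == 1
            assert calls[0].cluster.role_string() == "ABCT"
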