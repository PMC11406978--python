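"""Neighborhood extraction, role assignment and canonical orientation."""

import pytest

from bfuscan._templates import TEMPLATE_A
from bfuscan.annotation import GeneRecord, GenomeAnnotation
from bfuscan.neighborhood import assign_role, canonical_order, extract_neighborhood

from conftest import build_genome

B_DOMAINS = ("FMN", "Nqo1", "B1", "B2", "B3", "B4", "B5")
C_DOMAINS = ("C1", "Nqo1")


def genome_with_roles(role_layout, strand="+", genome_id="t"):
    """Build a one-contig genome whose genes carry the given roles in
    coordinate order; the A gene gets the canonical motif-bearing template."""
    layout = [(f"g{i}", strand) for i in range(1, len(role_layout) + 1)]
    proteins, domains = {}, {}
    anchor = None
    for (gid, _), role in zip(layout, role_layout):
        if role == "A":
            proteins[gid] = TEMPLATE_A
            domains[gid] = ("2Fe", "A2", "A3", "A4")
            anchor = gid
        elif role == "B":
            domains[gid] = B_DOMAINS
        elif role == "C":
            domains[gid] = C_DOMAINS
        elif role == "D":
            domains[gid] = ("BfuD_like",)
        elif role == "T":
            domains[gid] = ("2Fe", "PAS")
    ann = build_genome(genome_id, layout, proteins, domains)
    return ann, anchor


def flip_contig(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Reverse-complement a one-contig genome: mirror coordinates, flip
    strands, recompute ranks."""
    (contig_id, genes), = ann.contigs.items()
    length = ann.contig_lengths[contig_id]
    flipped = []
    for g in reversed(genes):
        flipped.append(
            GeneRecord(
                g.gene_id, contig_id,
                start=length - g.end + 1, end=length - g.start + 1,
                strand="-" if g.strand == "+" else "+",
                rank=len(flipped) + 1, partial=g.partial,
            )
        )
    return GenomeAnnotation(
        genome_id=ann.genome_id,
        contigs={contig_id: flipped},
        proteins=dict(ann.proteins),
        domains=dict(ann.domains),
        contig_lengths=dict(ann.contig_lengths),
    )


class TestWindow:
    def test_full_window_offsets(self):
        layout = ["X"] * 20
        layout[5] = "A"  # rank 6
        ann, anchor = genome_with_roles(layout)
        cluster = extract_neighborhood(ann, anchor, window=5)
        assert sorted(m.offset for m in cluster.members) == list(range(-5, 6))
        assert not cluster.truncated

    def test_edge_clip_sets_truncated(self):
        layout = ["X"] * 20
        layout[1] = "A"  # rank 2
        ann, anchor = genome_with_roles(layout)
        cluster = extract_neighborhood(ann, anchor, window=5)
        assert sorted(m.offset for m in cluster.members) == list(range(-1, 6))
        assert cluster.truncated

    def test_window_monotonicity(self):
        layout = ["X"] * 15
        layout[7] = "A"
        ann, anchor = genome_with_roles(layout)
        for w in range(1, 7):
            small = {m.gene_id for m in extract_neighborhood(ann, anchor, window=w).members}
            big = {m.gene_id for m in extract_neighborhood(ann, anchor, window=w + 1).members}
            assert small <= big

    def test_unknown_anchor_raises(self):
        ann, _ = genome_with_roles(["A", "B", "C"])
        with pytest.raises(KeyError):
            extract_neighborhood(ann, "nope")

    def test_planted_cluster_with_decoys_has_all_subunits(self, default_run):
        annotations, truths, summary = default_run
        # planted sub-type IV clusters keep all four subunit roles among members
        anchors_iv = {t.anchor for t in truths if t.subtype == "IV" and t.anchor}
        seen = 0
        for call in summary.calls:
            if call.cluster.anchor in anchors_iv:
                roles = {m.role for m in call.cluster.members}
                assert {"A", "B", "C", "T"} <= roles
                seen += 1
        assert seen > 0


class TestAssignRole:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            (("FMN", "Nqo1", "B1", "B2", "B3", "B4", "B5"), "B"),
            ((), "X"),
            (("2Fe", "PAS"), "T"),
            (("2Fe", "His_kinase_dom"), "T"),
            (("C1", "Nqo1"), "C"),
            (("BfuD_like",), "D"),
            (("Nqo1",), "X"),
        ],
    )
    def test_role_rules(self, domains, expected):
        role, ambiguous = assign_role("g", domains, bfua_calls=())
        assert role == expected and not ambiguous

    def test_motif_call_wins_precedence(self):
        role, ambiguous = assign_role("g", ("FMN", "B1"), bfua_calls=("g",))
        assert role == "A" and ambiguous


class TestCanonicalOrder:
    def test_minus_strand_coordinate_cab_reads_bac(self):
        # coordinate order C,A,B on the minus strand is read B,A,C... i.e.
        # transcription direction right-to-left gives role string "BAC"
        ann, anchor = genome_with_roles(["C", "A", "B"], strand="-")
        cluster = extract_neighborhood(ann, anchor)
        assert canonical_order(cluster) == "BAC"
        assert cluster.figure_convention_string() == "CAB"

    def test_plus_strand_abc(self):
        ann, anchor = genome_with_roles(["A", "B", "C"], strand="+")
        assert canonical_order(extract_neighborhood(ann, anchor)) == "ABC"

    @pytest.mark.parametrize("layout", [["A", "B", "C"], ["C", "A", "B"],
                                        ["T", "A", "X", "B", "C"], ["A", "B", "D", "C"]])
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_strand_flip_invariance(self, layout, strand):
        ann, anchor = genome_with_roles(layout, strand=strand)
        flipped = flip_contig(ann)
        s1 = canonical_order(extract_neighborhood(ann, anchor))
        s2 = canonical_order(extract_neighborhood(flipped, anchor))
        assert s1 == s2

    def test_antisense_members_flagged_but_kept(self):
        ann, anchor = genome_with_roles(["A", "B", "C"])
        # flip just the B gene's strand
        (cid, genes), = ann.contigs.items()
        genes[1] = GeneRecord(genes[1].gene_id, cid, genes[1].start, genes[1].end,
                              "-", genes[1].rank)
        cluster = extract_neighborhood(ann, anchor)
        b = cluster.members_with_role("B")[0]
        assert b.antisense and canonical_order(cluster) == "ABC"
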