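"""Gene-neighborhood extraction and subunit role assignment.

Each BfuA candidate anchors a cluster consisting of every gene within five
genes up- or downstream on the same contig (the window counts genes, not
base pairs).  Member genes are assigned subunit roles from their declared
domain architectures; genes encoding anything else keep role ``X`` and are
kept in place so that patterns with interspersed genes remain classifiable.

The canonical reading direction of a cluster is the transcription direction
of its BfuA anchor, so the same physical cluster yields the same role
string regardless of which genomic strand carries it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import GenomeAnnotation
from .fes import B_SERIES
from .motifs import DEFAULT_CATALOG, MotifPattern, call_bfua

ROLES = ("A", "B", "C", "D", "T", "X")

__all__ = ["ClusterMember", "GeneCluster", "assign_role", "extract_neighborhood", "canonical_order"]


@dataclass(frozen=True)
class ClusterMember:
    gene_id: str
    role: str
    offset: int          # signed rank difference from the anchor (coordinate order)
    strand: str
    partial: bool
    domains: tuple[str, ...]
    antisense: bool      # on the strand opposite the anchor
    ambiguous: bool = False  # matched more than one role rule


@dataclass
class GeneCluster:
    """An anchored ±window neighborhood with role-labeled members.

    ``members`` are sorted in canonical reading order — the anchor strand's
    5'→3' direction.  ``truncated`` is set when the window was clipped at a
    contig end.
    """

    genome_id: str
    contig_id: str
    anchor: str
    members: list[ClusterMember]
    canonical_orientation: str
    truncated: bool = False
    window: int = 5

    @property
    def partial_members(self) -> list[str]:
        return [m.role for m in self.members if m.partial and m.role != "X"]

    def role_string(self, include_x: bool = False) -> str:
        """Non-X roles concatenated in canonical (transcription) order."""
        return "".join(m.role for m in self.members if include_x or m.role != "X")

    def figure_convention_string(self) -> str:
        """The role string read in the opposite direction (negative-strand
        display convention used in comparative figures)."""
        return self.role_string()[::-1]

    def members_with_role(self, role: str) -> list[ClusterMember]:
        return [m for m in self.members if m.role == role]

    def has_antisense_member(self) -> bool:
        return any(m.antisense for m in self.members if m.role != "X")


def assign_role(
    gene_id: str,
    domains: Sequence[str],
    bfua_calls: Iterable[str],
) -> tuple[str, bool]:
    """Assign a subunit role from motif calls and declared domains.

    Returns ``(role, ambiguous)``.  Rules, applied with precedence
    A > T > B > C > D:

    * ``A`` — the gene is a BfuA motif call;
    * ``T`` — an H-cluster label (``2Fe``) together with a sensor domain
      (``PAS`` or ``His_kinase_dom``): a group C3 sensory hydrogenase;
    * ``B`` — ``FMN`` plus at least one B-series FeS label;
    * ``C`` — ``C1`` without FMN or an H-cluster (accessory labels allowed);
    * ``D`` — the declared accessory-subunit label ``BfuD_like``;
    * ``X`` — anything else.
    """
    ds = set(domains)
    matches = []
    if gene_id in set(bfua_calls):
        matches.append("A")
    if "2Fe" in ds and ({"PAS", "His_kinase_dom"} & ds):
        matches.append("T")
    if "FMN" in ds and (set(B_SERIES) & ds):
        matches.append("B")
    if "C1" in ds and "FMN" not in ds and "2Fe" not in ds:
        matches.append("C")
    if "BfuD_like" in ds:
        matches.append("D")
    if not matches:
        return "X", False
    return matches[0], len(matches) > 1


def extract_neighborhood(
    annotation: GenomeAnnotation,
    anchor: str,
    window: int = 5,
    bfua_calls: Iterable[str] | None = None,
    catalog: Sequence[MotifPattern] = DEFAULT_CATALOG,
    max_mismatch: int = 0,
) -> GeneCluster:
    """Extract the ±``window`` gene neighborhood around a BfuA anchor.

    Members are all genes whose rank is within ``window`` of the anchor's
    rank on the same contig, clipped at contig ends (``truncated`` set when
    clipped).  When ``bfua_calls`` is not supplied it is computed from the
    annotation.
    """
    anchor_gene = annotation.gene(anchor)  # raises KeyError for unknown anchors
    if bfua_calls is None:
        bfua_calls = call_bfua(annotation, catalog, max_mismatch)
    bfua_set = set(bfua_calls)

    contig = annotation.contigs[anchor_gene.contig_id]
    n = len(contig)
    lo = anchor_gene.rank - window
    hi = anchor_gene.rank + window
    truncated = lo < 1 or hi > n
    lo, hi = max(lo, 1), min(hi, n)

    members = []
    for g in contig[lo - 1 : hi]:
        role, ambiguous = assign_role(g.gene_id, annotation.domains_of(g.gene_id), bfua_set)
        if g.gene_id != anchor and role == "A":
            # another BfuA candidate inside the window seeds its own cluster
            pass
        members.append(
            ClusterMember(
                gene_id=g.gene_id,
                role=role,
                offset=g.rank - anchor_gene.rank,
                strand=g.strand,
                partial=g.partial,
                domains=annotation.domains_of(g.gene_id),
                antisense=g.strand != anchor_gene.strand,
                ambiguous=ambiguous,
            )
        )
    if anchor_gene.strand == "-":
        members.reverse()
    return GeneCluster(
        genome_id=annotation.genome_id,
        contig_id=anchor_gene.contig_id,
        anchor=anchor,
        members=members,
        canonical_orientation=anchor_gene.strand,
        truncated=truncated,
        window=window,
    )


def canonical_order(cluster: GeneCluster) -> str:
    """Role string in the anchor strand's transcription direction."""
    return cluster.role_string()
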