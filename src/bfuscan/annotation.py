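"""Genome-bundle I/O: protein FASTA + GFF3 gene table + domain TSV.

A *genome bundle* is the trio of files this pipeline consumes per genome:

* ``<genome>.faa``      — protein sequences, one record per gene;
* ``<genome>.gff``      — GFF3 gene features with ``ID`` attributes that
  match the FASTA headers (1-based inclusive coordinates on disk);
* ``<genome>.domains.tsv`` — declared per-protein domain architecture,
  columns ``gene_id``, ``ordinal``, ``domain_label``; domain *detection*
  (HMM search against Pfam/CDD) happens upstream of this package, so the
  architectures are declared inputs.

Coordinates are kept 1-based inclusive on :class:`GeneRecord` to mirror the
GFF3 dialect; helpers that need 0-based half-open intervals convert locally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "GFFParseError",
    "ReconciliationError",
    "read_genome",
    "write_cluster_report",
    "read_cluster_report",
    "CLUSTER_REPORT_COLUMNS",
]


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 line; the message names the line number."""


class ReconciliationError(ValueError):
    """Raised when FASTA, GFF3 and domain-table gene identifiers disagree."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene model on a contig (1-based inclusive coordinates).

    ``rank`` is the 1-based position of the gene along its contig in
    coordinate order; neighborhood windows are counted in ranks, not base
    pairs.  ``partial`` marks a gene model truncated at a contig boundary.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank: int
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start ({self.end} < {self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end


@dataclass
class GenomeAnnotation:
    """Validated in-memory model of one annotated genome.

    ``contigs`` maps contig id to its genes ordered by rank; ``proteins``
    and ``domains`` are keyed by gene id.  ``contig_lengths`` is optional
    (used to flag genes abutting a contig terminus as partial).
    """

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    domains: dict[str, tuple[str, ...]] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, GeneRecord] = {}
        for contig_id, genes in self.contigs.items():
            for i, g in enumerate(genes, start=1):
                if g.rank != i:
                    raise ValueError(
                        f"{self.genome_id}/{contig_id}: ranks must be consecutive from 1 "
                        f"(gene {g.gene_id} has rank {g.rank} at position {i})"
                    )
                if g.gene_id in self._index:
                    raise ValueError(f"duplicate gene id {g.gene_id}")
                self._index[g.gene_id] = g
        for gid, seq in self.proteins.items():
            if gid not in self._index:
                raise ReconciliationError(
                    f"protein {gid} has no gene feature in genome {self.genome_id}"
                )
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise ValueError(f"protein {gid} contains non-canonical residues {sorted(bad)}")

    def add_contig(
        self,
        contig_id: str,
        genes: list[GeneRecord],
        proteins: Mapping[str, str],
        domains: Mapping[str, tuple[str, ...]],
        contig_length: int | None = None,
    ) -> None:
        """Register a new contig with its genes, proteins and domain rows."""
        if contig_id in self.contigs:
            raise ValueError(f"contig {contig_id} already present")
        for i, g in enumerate(genes, start=1):
            if g.rank != i:
                raise ValueError(f"{contig_id}: ranks must be consecutive from 1")
            if g.gene_id in self._index:
                raise ValueError(f"duplicate gene id {g.gene_id}")
        self.contigs[contig_id] = list(genes)
        for g in genes:
            self._index[g.gene_id] = g
        self.proteins.update(proteins)
        self.domains.update(domains)
        if contig_length is not None:
            self.contig_lengths[contig_id] = contig_length

    # -- lookups -----------------------------------------------------------

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r} in genome {self.genome_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def gene_ids(self) -> list[str]:
        """All gene ids in (contig, rank) order."""
        return [g.gene_id for contig in sorted(self.contigs) for g in self.contigs[contig]]

    def domains_of(self, gene_id: str) -> tuple[str, ...]:
        return self.domains.get(gene_id, ())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and self.contigs == other.contigs
            and self.proteins == other.proteins
            and self.domains == other.domains
        )


# ---------------------------------------------------------------------------
# readers


_GFF_COLS = 9


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"attribute {chunk!r} is not key=value")
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _read_gff(gff_path: Path) -> tuple[list[dict], dict[str, int]]:
    """Read gene features and ##sequence-region lengths from a GFF3 file."""
    features: list[dict] = []
    contig_lengths: dict[str, int] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise GFFParseError(
                    f"{gff_path.name}:{lineno}: expected {_GFF_COLS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_raw = cols
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
                attrs = _parse_gff_attributes(attr_raw)
            except ValueError as exc:
                raise GFFParseError(f"{gff_path.name}:{lineno}: {exc}") from None
            if "ID" not in attrs:
                raise GFFParseError(f"{gff_path.name}:{lineno}: feature lacks an ID attribute")
            if strand not in ("+", "-"):
                raise GFFParseError(
                    f"{gff_path.name}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            features.append(
                {
                    "gene_id": attrs["ID"],
                    "contig_id": seqid,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "partial_attr": attrs.get("partial", "").lower() in ("true", "1", "yes"),
                }
            )
    return features, contig_lengths


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    domains_path: str | Path,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read a genome bundle into a validated :class:`GenomeAnnotation`.

    Ranks are computed from coordinate order per contig regardless of the
    order of GFF3 rows.  A gene is flagged partial when its GFF3 attributes
    say ``partial=true`` or when it touches base 1 or the contig terminus
    (the ``##sequence-region`` length, when present).

    Raises
    ------
    GFFParseError
        for a malformed GFF3 line (message names the line number).
    ReconciliationError
        when FASTA/GFF3/domain-table gene identifiers do not reconcile;
        the message lists the orphans.
    """
    fasta_path, gff_path, domains_path = Path(fasta_path), Path(gff_path), Path(domains_path)
    for p in (fasta_path, gff_path, domains_path):
        if not p.exists():
            raise FileNotFoundError(p)
    if genome_id is None:
        genome_id = fasta_path.stem

    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    features, contig_lengths = _read_gff(gff_path)

    gff_ids = {f["gene_id"] for f in features}
    fasta_only = sorted(set(proteins) - gff_ids)
    gff_only = sorted(gff_ids - set(proteins))
    if fasta_only or gff_only:
        raise ReconciliationError(
            f"{genome_id}: protein/gene ID mismatch; "
            f"FASTA-only: {fasta_only or '[]'}, GFF-only: {gff_only or '[]'}"
        )

    # rank by coordinate order within each contig
    contigs: dict[str, list[GeneRecord]] = {}
    by_contig: dict[str, list[dict]] = {}
    for f in features:
        by_contig.setdefault(f["contig_id"], []).append(f)
    for contig_id, feats in by_contig.items():
        feats.sort(key=lambda f: (f["start"], f["end"], f["gene_id"]))
        clen = contig_lengths.get(contig_id)
        genes = []
        for rank, f in enumerate(feats, start=1):
            at_edge = f["start"] == 1 or (clen is not None and f["end"] >= clen)
            genes.append(
                GeneRecord(
                    gene_id=f["gene_id"],
                    contig_id=contig_id,
                    start=f["start"],
                    end=f["end"],
                    strand=f["strand"],
                    rank=rank,
                    partial=f["partial_attr"] or at_edge,
                )
            )
        contigs[contig_id] = genes

    domains: dict[str, tuple[str, ...]] = {}
    dom_df = pd.read_csv(domains_path, sep="\t", dtype={"gene_id": str, "domain_label": str})
    if len(dom_df):
        missing_cols = {"gene_id", "ordinal", "domain_label"} - set(dom_df.columns)
        if missing_cols:
            raise ValueError(f"{domains_path.name}: missing columns {sorted(missing_cols)}")
        unknown = sorted(set(dom_df["gene_id"]) - gff_ids)
        if unknown:
            raise ReconciliationError(
                f"{genome_id}: domain table references unknown gene ids: {unknown}"
            )
        for gid, grp in dom_df.groupby("gene_id", sort=False):
            domains[gid] = tuple(grp.sort_values("ordinal")["domain_label"])

    return GenomeAnnotation(
        genome_id=genome_id,
        contigs=contigs,
        proteins=proteins,
        domains=domains,
        contig_lengths=contig_lengths,
    )


# ---------------------------------------------------------------------------
# cluster report

#: Fixed column order of the cluster report written by
#: :func:`write_cluster_report` (one row per anchored cluster).
CLUSTER_REPORT_COLUMNS = [
    "genome_id",
    "contig_id",
    "anchor",
    "role_string",
    "subtype",
    "flags",
    "retained",
    "reasons",
    "capability",
    "capability_notes",
]


def write_cluster_report(calls: Sequence, path: str | Path, capability: Mapping | None = None) -> None:
    """Write one tab-separated row per sub-type call.

    ``calls`` are :class:`~bfuscan.subtypes.SubtypeCall` objects; ``capability``
    optionally maps anchor gene id to a
    :class:`~bfuscan.fes.CapabilityCall`.  Column order is
    :data:`CLUSTER_REPORT_COLUMNS`; list-valued fields are comma-joined.
    """
    capability = capability or {}
    rows = []
    for call in calls:
        cl = call.cluster
        cap = capability.get(cl.anchor)
        rows.append(
            {
                "genome_id": cl.genome_id,
                "contig_id": cl.contig_id,
                "anchor": cl.anchor,
                "role_string": cl.role_string(),
                "subtype": call.label,
                "flags": ",".join(sorted(call.flags)),
                "retained": call.retained,
                "reasons": ",".join(call.reasons),
                "capability": cap.verdict if cap is not None else "",
                "capability_notes": ",".join(cap.notes) if cap is not None else "",
            }
        )
    df = pd.DataFrame(rows, columns=CLUSTER_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cluster_report(path: str | Path) -> pd.DataFrame:
    """Re-parse a cluster report written by :func:`write_cluster_report`."""
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
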