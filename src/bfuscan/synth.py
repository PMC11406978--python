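"""Synthetic multi-contig genomes with planted hydrogenase gene clusters.

The generator emulates the statistical structure of real
metagenome-assembled genomes carrying Bfu gene clusters: multi-contig
genomes, clusters of the five organizational patterns on either strand,
decoy genes inside and around the cluster, contig-edge truncation,
omitted subunits, and sub-type-specific sequence divergence (so that
concatenated subunits cluster by sub-type in the phylogeny stage).  Every
planted cluster is recorded in a ground-truth table computed from the
realized layout, independently of the detection pipeline.

All subunit proteins derive from fixed per-role templates
(:mod:`bfuscan._templates`) by seeded substitution: a per-sub-type variant
is drawn once per run (default divergence 0.15), and each planted instance
diverges a little further from its variant (default 0.02).  Motif windows
in BfuA are masked from mutation, and the wildcard fifth position of P1 is
set to Cys in sub-type IV and Ser elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._templates import P1_POS5, P1_START, P2_START, P3_END, P3_START, TEMPLATES
from .annotation import GeneRecord, GenomeAnnotation
from .motifs import AA20, DEFAULT_CATALOG, scan_motif
from .subtypes import SUBTYPE_IV_EXCEPTION, SUBTYPE_PATTERNS, UNCLASSIFIED

__all__ = [
    "PlantSpec",
    "TruthRecord",
    "GeneratorConfig",
    "generate_genome_set",
    "plant_cluster",
    "write_bundle",
    "read_truth",
]

#: Canonical transcription-order gene content per sub-type.
SUBTYPE_ORDERS: dict[str, tuple[str, ...]] = {
    "I": ("A", "B", "D", "C"),
    "II": ("A", "B", "C"),
    "III": ("C", "A", "B"),
    "IV": ("A", "B", "C", "T"),
    "V": ("T", "A", "B", "C"),
}

#: Declared domain architectures per (role, sub-type); drawn from the
#: subunit structures of the five sub-types (sub-type II BfuB lacks
#: B3/B4/B5; sub-type III BfuB carries a double B5; sub-type I BfuB swaps
#: the B3/B4 domain for DPD_II + FAD; sub-type IV BfuA is M3c).
ROLE_DOMAINS: dict[tuple[str, str], tuple[str, ...]] = {
    ("A", "I"): ("2Fe", "A2", "A3", "A4"),
    ("A", "II"): ("2Fe", "A2", "A3", "A4"),
    ("A", "III"): ("2Fe", "A2", "A3", "A4"),
    ("A", "IV"): ("2Fe", "A1", "A2", "A3", "A4", "A5"),
    ("A", "V"): ("2Fe", "A2", "A3", "A4"),
    ("B", "I"): ("FMN", "Nqo1", "B1", "B2", "B5", "DPD_II", "FAD"),
    ("B", "II"): ("FMN", "Nqo1", "B1", "B2"),
    ("B", "III"): ("FMN", "Nqo1", "B1", "B2", "B3", "B4", "B5", "B5"),
    ("B", "IV"): ("FMN", "Nqo1", "B1", "B2", "B3", "B4", "B5"),
    ("B", "V"): ("FMN", "Nqo1", "B1", "B2", "B3", "B4", "B5"),
    ("C", "I"): ("C1", "Nqo1"),
    ("C", "II"): ("C1", "Nqo1"),
    ("C", "III"): ("C1", "Nqo1"),
    ("C", "IV"): ("C1", "Nqo1"),
    ("C", "V"): ("C1", "Nqo1"),
    ("D", "I"): ("BfuD_like",),
    ("T", "IV"): ("2Fe", "PAS"),
    ("T", "V"): ("2Fe", "His_kinase_dom"),
}

_A_MOTIF_MASK = frozenset(
    list(range(P1_START, P1_START + 9))
    + list(range(P2_START, P2_START + 9))
    + list(range(P3_START, P3_END))
)

_TRUNCATE_KEEP = 0.4  # fraction of an edge-truncated protein that survives


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: sub-type, strand, decoys, defects and T-variants."""

    subtype: str
    strand: str = "+"
    intervening_decoys: int = 0
    omit_subunit: str | None = None
    edge_truncate: bool = False
    t_variant: str | None = None  # downstream_adjacent_A (IV) or double_T (V)

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPE_ORDERS:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.intervening_decoys <= 5:
            raise ValueError("intervening_decoys must be in 0..5")
        if self.omit_subunit not in (None, "A", "B", "C", "D", "T"):
            raise ValueError(f"bad omit_subunit {self.omit_subunit!r}")
        if self.t_variant not in (None, "downstream_adjacent_A", "double_T"):
            raise ValueError(f"bad t_variant {self.t_variant!r}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted cluster, computed from the realized layout."""

    genome_id: str
    contig_id: str
    anchor: str            # empty when BfuA was omitted or truncated undetectable
    subtype: str
    strand: str
    expected_detected: bool
    expected_retained: bool
    expected_label: str
    flags: tuple[str, ...] = ()


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic genome set.

    Defaults produce clean, recoverable clusters: 20 genomes of 3 planted
    clusters each with a uniform sub-type mix, 0–2 decoy genes interleaved
    inside each cluster, an 8-gene decoy-only contig per genome, and
    template divergence 0.15 between sub-types / 0.02 within.
    """

    n_genomes: int = 20
    clusters_per_genome: int = 3
    subtype_mix: dict = field(
        default_factory=lambda: {s: 0.2 for s in SUBTYPE_ORDERS}
    )
    decoy_gene_count: int = 8
    max_intervening_decoys: int = 2
    divergence_between: float = 0.15
    divergence_within: float = 0.02
    decoy_p1_fraction: float = 0.1
    omit_b_fraction: float = 0.0
    omit_c_fraction: float = 0.0
    edge_truncate_fraction: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.subtype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_mix weights must sum to 1, got {total}")
        for name in ("divergence_between", "divergence_within"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if self.n_genomes < 0 or self.clusters_per_genome < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# sequence machinery


def _mutate(seq: str, proportion: float, rng: np.random.Generator,
            mask: frozenset = frozenset()) -> str:
    """Substitute ``round(proportion * n_mutable)`` positions, avoiding ``mask``."""
    mutable = [i for i in range(len(seq)) if i not in mask]
    k = int(round(proportion * len(mutable)))
    if k == 0:
        return seq
    chosen = rng.choice(len(mutable), size=k, replace=False)
    s = list(seq)
    for ci in chosen:
        i = mutable[ci]
        alternatives = [c for c in AA20 if c != s[i]]
        s[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(s)


def _subtype_variants(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    """Per-(role, sub-type) template variants at the between-sub-type divergence."""
    variants: dict[tuple[str, str], str] = {}
    for (role, subtype) in sorted(ROLE_DOMAINS):
        mask = _A_MOTIF_MASK if role == "A" else frozenset()
        seq = _mutate(TEMPLATES[role], config.divergence_between, rng, mask)
        if role == "A":
            fifth = "C" if subtype == "IV" else "S"
            seq = seq[:P1_POS5] + fifth + seq[P1_POS5 + 1 :]
        variants[(role, subtype)] = seq
    return variants


def _motif_free(seq: str) -> bool:
    return not any(scan_motif(seq, pat) for pat in DEFAULT_CATALOG)


def _decoy_protein(rng: np.random.Generator, with_p1: bool) -> str:
    """A random protein with no motif matches (optionally one isolated P1)."""
    while True:
        n = int(rng.integers(80, 201))
        seq = "".join(np.asarray(list(AA20))[rng.integers(0, 20, size=n)])
        if not _motif_free(seq):
            continue
        if with_p1:
            pos = int(rng.integers(10, n - 20))
            seq = seq[:pos] + "ATSCSPVWA" + seq[pos + 9 :]
            if scan_motif(seq, DEFAULT_CATALOG[1]) or scan_motif(seq, DEFAULT_CATALOG[2]):
                continue
        return seq


def _instance(role: str, subtype: str, variants: dict, config: GeneratorConfig,
              rng: np.random.Generator) -> str:
    mask = _A_MOTIF_MASK | {P1_POS5} if role == "A" else frozenset()
    return _mutate(variants[(role, subtype)], config.divergence_within, rng, mask)


# ---------------------------------------------------------------------------
# planting


def _transcription_order(spec: PlantSpec) -> list[str]:
    order = list(SUBTYPE_ORDERS[spec.subtype])
    if spec.t_variant == "downstream_adjacent_A" and spec.subtype == "IV":
        order = ["A", "T", "B", "C"]
    elif spec.t_variant == "double_T" and spec.subtype == "V":
        order = ["T", "A", "B", "C", "T"]
    if spec.omit_subunit in order:
        order.remove(spec.omit_subunit)
    return order


def plant_cluster(
    annotation: GenomeAnnotation,
    spec: PlantSpec,
    rng: np.random.Generator,
    variants: dict | None = None,
    config: GeneratorConfig | None = None,
    contig_id: str | None = None,
) -> TruthRecord:
    """Plant one gene cluster on a fresh contig of ``annotation``.

    Subunit genes are laid out in the spec's canonical transcription order
    on the spec's strand, with the requested number of decoy genes
    interleaved and 1–4 flanking decoys on each side.  Omission and
    edge-truncation defects are realized and recorded; the returned
    :class:`TruthRecord` (which carries the anchor gene id) states the
    expected downstream outcome, derived from the realized layout alone.
    """
    config = config or GeneratorConfig()
    if variants is None:
        variants = _subtype_variants(config, np.random.default_rng(config.seed))

    order = _transcription_order(spec)
    # interleave decoys at random interior positions (transcription order)
    slots: list[tuple[str, str]] = [("role", r) for r in order]
    for _ in range(spec.intervening_decoys):
        pos = int(rng.integers(1, len(slots)))  # strictly interior
        slots.insert(pos, ("decoy", ""))

    n_pre = int(rng.integers(1, 5))
    n_post = 0 if spec.edge_truncate else int(rng.integers(1, 5))
    layout = [("decoy", "")] * n_pre + slots + [("decoy", "")] * n_post
    # coordinate order: transcription order on '+', reversed on '-'
    if spec.strand == "-":
        layout = layout[::-1]

    contig_id = contig_id or f"{annotation.genome_id}_c{len(annotation.contigs) + 1}"
    gene_seqs: list[tuple[str, str, tuple[str, ...], str]] = []  # (role, seq, domains, strand)
    for kind, role in layout:
        if kind == "decoy":
            with_p1 = rng.random() < config.decoy_p1_fraction
            seq = _decoy_protein(rng, with_p1)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_seqs.append(("X", seq, (), strand))
        else:
            seq = _instance(role, spec.subtype, variants, config, rng)
            domains = ROLE_DOMAINS.get((role, spec.subtype), ())
            gene_seqs.append((role, seq, domains, spec.strand))

    # realize truncation of the last gene in coordinate order
    truncated_role = None
    if spec.edge_truncate:
        role, seq, domains, strand = gene_seqs[-1]
        keep = max(30, int(len(seq) * _TRUNCATE_KEEP))
        gene_seqs[-1] = (role, seq[:keep], domains, strand)
        truncated_role = role

    # coordinates
    base = annotation.genome_id.replace(" ", "_")
    start_counter = sum(len(g) for g in annotation.contigs.values())
    genes: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    domains_map: dict[str, tuple[str, ...]] = {}
    pos = 1
    anchor_id = ""
    role_by_gene: dict[str, str] = {}
    for idx, (role, seq, doms, strand) in enumerate(gene_seqs):
        pos += int(rng.integers(20, 201))
        gid = f"{base}_g{start_counter + idx + 1:04d}"
        length_nt = 3 * len(seq)
        end = pos + length_nt - 1
        partial = spec.edge_truncate and idx == len(gene_seqs) - 1
        genes.append(
            GeneRecord(gid, contig_id, pos, end, strand, rank=idx + 1, partial=partial)
        )
        proteins[gid] = seq
        if doms:
            domains_map[gid] = tuple(doms)
        role_by_gene[gid] = role
        if role == "A":
            anchor_id = gid
        pos = end
    contig_length = pos if spec.edge_truncate else pos + int(rng.integers(20, 201))

    annotation.add_contig(contig_id, genes, proteins, domains_map, contig_length)

    truth = _expected_outcome(spec, gene_seqs, genes, role_by_gene,
                              truncated_role, annotation.genome_id, contig_id, anchor_id)
    return truth


def _expected_outcome(spec, gene_seqs, genes, role_by_gene,
                      truncated_role, genome_id, contig_id, anchor_id) -> TruthRecord:
    """Derive the expected pipeline outcome from the realized layout.

    Uses only construction facts (known motif coordinates in the template,
    which genes were omitted/truncated, realized rank offsets), never the
    detection pipeline itself.
    """
    flags = []
    if spec.t_variant:
        flags.append(spec.t_variant)
    if spec.omit_subunit:
        flags.append(f"omit_{spec.omit_subunit}")
    if spec.edge_truncate:
        flags.append(f"truncated_{truncated_role}")

    roles_by_rank = [role_by_gene[g.gene_id] for g in genes]  # coordinate order
    if spec.strand == "-":
        roles_tx = roles_by_rank[::-1]
    else:
        roles_tx = roles_by_rank

    # detection: A present and, if truncated, still long enough to keep P3
    detected = "A" in roles_by_rank and anchor_id != ""
    if detected and truncated_role == "A":
        a_len = len(next(s for r, s, *_ in gene_seqs if r == "A"))
        detected = a_len >= P3_END
    if not detected:
        return TruthRecord(genome_id, contig_id, "", spec.subtype, spec.strand,
                           False, False, UNCLASSIFIED, tuple(flags))

    a_rank = roles_by_rank.index("A") + 1

    def intact_within(role: str) -> bool:
        if role not in roles_by_rank:
            return False
        if truncated_role == role:
            return False
        rank = roles_by_rank.index(role) + 1
        return abs(rank - a_rank) <= 5

    retained = intact_within("B") and intact_within("C")
    if not retained:
        return TruthRecord(genome_id, contig_id, anchor_id, spec.subtype, spec.strand,
                           True, False, UNCLASSIFIED, tuple(flags))

    # label from the realized non-decoy role string within the window,
    # read in transcription order
    a_tx = roles_tx.index("A") + 1
    window_roles = "".join(
        r for rk, r in enumerate(roles_tx, 1) if r != "X" and abs(rk - a_tx) <= 5
    )
    if window_roles.count("T") >= 2:
        label = UNCLASSIFIED
    elif window_roles == SUBTYPE_IV_EXCEPTION:
        label = "IV"
    else:
        label = next(
            (lab for lab, pat in SUBTYPE_PATTERNS.items() if window_roles == pat),
            UNCLASSIFIED,
        )
    return TruthRecord(genome_id, contig_id, anchor_id, spec.subtype, spec.strand,
                       True, True, label, tuple(flags))


# ---------------------------------------------------------------------------
# genome-set generation


def _draw_spec(config: GeneratorConfig, rng: np.random.Generator) -> PlantSpec:
    subtypes = sorted(config.subtype_mix)
    weights = np.array([config.subtype_mix[s] for s in subtypes])
    subtype = subtypes[int(rng.choice(len(subtypes), p=weights / weights.sum()))]
    strand = "+" if rng.random() < 0.5 else "-"
    decoys = int(rng.integers(0, config.max_intervening_decoys + 1))
    omit = None
    edge = False
    u = rng.random()
    if u < config.omit_b_fraction:
        omit = "B"
    elif u < config.omit_b_fraction + config.omit_c_fraction:
        omit = "C"
    elif u < config.omit_b_fraction + config.omit_c_fraction + config.edge_truncate_fraction:
        edge = True
    return PlantSpec(subtype=subtype, strand=strand, intervening_decoys=decoys,
                     omit_subunit=omit, edge_truncate=edge)


def generate_genome_set(
    config: GeneratorConfig,
) -> tuple[list[GenomeAnnotation], list[TruthRecord]]:
    """Generate the full synthetic genome set with its ground-truth table.

    Deterministic for a fixed ``config.seed``: one seeded generator drives
    every random choice, and sub-type template variants are drawn once per
    run before any genome is built.
    """
    rng = np.random.default_rng(config.seed)
    variants = _subtype_variants(config, rng)
    annotations: list[GenomeAnnotation] = []
    truths: list[TruthRecord] = []
    for gi in range(config.n_genomes):
        genome_id = f"G{gi + 1:03d}"
        ann = GenomeAnnotation(genome_id=genome_id)
        for _ in range(config.clusters_per_genome):
            spec = _draw_spec(config, rng)
            truths.append(plant_cluster(ann, spec, rng, variants=variants, config=config))
        _add_decoy_contig(ann, config, rng)
        annotations.append(ann)
    return annotations, truths


def _add_decoy_contig(ann: GenomeAnnotation, config: GeneratorConfig,
                      rng: np.random.Generator) -> None:
    if config.decoy_gene_count <= 0:
        return
    contig_id = f"{ann.genome_id}_c{len(ann.contigs) + 1}"
    start_counter = sum(len(g) for g in ann.contigs.values())
    genes, proteins = [], {}
    pos = 1
    for idx in range(config.decoy_gene_count):
        pos += int(rng.integers(20, 201))
        seq = _decoy_protein(rng, rng.random() < config.decoy_p1_fraction)
        gid = f"{ann.genome_id}_g{start_counter + idx + 1:04d}"
        end = pos + 3 * len(seq) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(gid, contig_id, pos, end, strand, rank=idx + 1))
        proteins[gid] = seq
        pos = end
    ann.add_contig(contig_id, genes, proteins, {}, pos + int(rng.integers(20, 201)))


# ---------------------------------------------------------------------------
# bundle writing


def write_bundle(
    annotations: Sequence[GenomeAnnotation],
    truths: Sequence[TruthRecord],
    outdir: str | Path,
) -> None:
    """Write a genome-bundle directory: per-genome FASTA + GFF3 + domain TSV
    plus ``truth.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ann in annotations:
        stem = outdir / ann.genome_id
        with open(f"{stem}.faa", "w") as fh:
            for contig in sorted(ann.contigs):
                for g in ann.contigs[contig]:
                    fh.write(f">{g.gene_id}\n{ann.proteins[g.gene_id]}\n")
        with open(f"{stem}.gff", "w") as fh:
            fh.write("##gff-version 3\n")
            for contig in sorted(ann.contigs):
                length = ann.contig_lengths.get(
                    contig, max(g.end for g in ann.contigs[contig]) + 1
                )
                fh.write(f"##sequence-region {contig} 1 {length}\n")
            for contig in sorted(ann.contigs):
                for g in ann.contigs[contig]:
                    attrs = f"ID={g.gene_id}" + (";partial=true" if g.partial else "")
                    fh.write(
                        f"{contig}\tbfuscan_synth\tgene\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
        with open(f"{stem}.domains.tsv", "w") as fh:
            fh.write("gene_id\tordinal\tdomain_label\n")
            for contig in sorted(ann.contigs):
                for g in ann.contigs[contig]:
                    for ordinal, lab in enumerate(ann.domains.get(g.gene_id, ()), 1):
                        fh.write(f"{g.gene_id}\t{ordinal}\t{lab}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "genome_id\tcontig_id\tanchor\tsubtype\tstrand\texpected_detected\t"
            "expected_retained\texpected_label\tflags\n"
        )
        for t in truths:
            fh.write(
                f"{t.genome_id}\t{t.contig_id}\t{t.anchor}\t{t.subtype}\t{t.strand}\t"
                f"{t.expected_detected}\t{t.expected_retained}\t{t.expected_label}\t"
                f"{','.join(t.flags)}\n"
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    """Re-parse a truth table written by :func:`write_bundle`."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            (gid, cid, anchor, subtype, strand, det, ret, label, flags) = (
                line.rstrip("\n").split("\t")
            )
            records.append(
                TruthRecord(gid, cid, anchor, subtype, strand,
                            det == "True", ret == "True", label,
                            tuple(f for f in flags.split(",") if f))
            )
    return records
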