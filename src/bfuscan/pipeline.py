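"""End-to-end orchestration over a genome-bundle directory.

Stages: motif scan → neighborhood extraction → intactness filter →
sub-type classification → capability rules → concatenated-subunit
phylogeny cross-check.  All randomness lives in the synthetic generator;
the analysis pipeline is fully deterministic, so re-running a bundle with
the same config reproduces every report byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, read_genome, write_cluster_report
from .fes import CapabilityCall, bifurcation_call, complement_from_architecture
from .motifs import DEFAULT_CATALOG, call_bfua
from .neighborhood import GeneCluster, extract_neighborhood
from .phylo import concat_abc, export_concat_fasta, kmer_distance, nj_tree, subtype_purity
from .subtypes import SubtypeCall, assign_subtype, summarize_subtypes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline", "analyze_genome",
           "capability_for_cluster", "discover_bundles"]


@dataclass
class PipelineConfig:
    input_dir: str | Path = "."
    output_dir: str | Path = "out"
    window: int = 5
    max_mismatch: int = 0
    k: int = 4
    run_phylogeny: bool = True
    write_reports: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_mismatch < 0 or self.k < 1:
            raise ValueError("max_mismatch must be >= 0 and k >= 1")


@dataclass
class RunSummary:
    genomes: int
    anchors: int
    clusters_retained: int
    subtype_counts: dict
    distinct_labels: int
    mean_purity: float | None
    calls: list = field(repr=False, default_factory=list)
    capability: dict = field(repr=False, default_factory=dict)
    purity: object = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "genomes": self.genomes,
            "anchors": self.anchors,
            "clusters_retained": self.clusters_retained,
            "subtype_counts": dict(self.subtype_counts),
            "distinct_labels": self.distinct_labels,
            "mean_purity": self.mean_purity,
        }


def capability_for_cluster(cluster: GeneCluster) -> CapabilityCall:
    """Capability verdict from a cluster's declared subunit architectures.

    The A-subunit modular-structure class is inferred from its declared
    labels (A1 and A5 present → M3c, else M3a); B and C labels come from
    the first member of each role in canonical order.
    """
    domains_by_subunit = {}
    for role in "ABC":
        members = cluster.members_with_role(role)
        if members:
            domains_by_subunit[role] = list(members[0].domains)
    a_labels = set(domains_by_subunit.get("A", ()))
    architecture = "M3c" if {"A1", "A5"} <= a_labels else "M3a"
    complement = complement_from_architecture(domains_by_subunit, architecture)
    return bifurcation_call(complement)


def analyze_genome(
    annotation: GenomeAnnotation,
    window: int = 5,
    max_mismatch: int = 0,
) -> tuple[list[SubtypeCall], dict]:
    """Scan, extract and classify every anchored cluster in one genome.

    Returns the sub-type calls and a capability map (anchor gene id →
    :class:`~bfuscan.fes.CapabilityCall`) for the retained clusters.
    """
    anchors = call_bfua(annotation, DEFAULT_CATALOG, max_mismatch)
    calls: list[SubtypeCall] = []
    capability: dict[str, CapabilityCall] = {}
    for anchor in anchors:
        cluster = extract_neighborhood(
            annotation, anchor, window=window, bfua_calls=anchors
        )
        call = assign_subtype(cluster)
        calls.append(call)
        if call.retained:
            capability[anchor] = capability_for_cluster(cluster)
        else:
            logger.debug("rejected %s/%s: %s", annotation.genome_id, anchor,
                         ",".join(call.reasons))
    logger.info("%s: %d anchors, %d retained", annotation.genome_id,
                len(anchors), sum(c.retained for c in calls))
    return calls, capability


def discover_bundles(input_dir: str | Path) -> list[tuple[str, Path, Path, Path]]:
    """Find genome bundles: ``<id>.faa`` + ``<id>.gff`` + ``<id>.domains.tsv``."""
    input_dir = Path(input_dir)
    bundles = []
    for faa in sorted(input_dir.glob("*.faa")):
        stem = faa.stem
        gff = input_dir / f"{stem}.gff"
        dom = input_dir / f"{stem}.domains.tsv"
        missing = [p.name for p in (gff, dom) if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"genome bundle {stem}: missing {', '.join(missing)}"
            )
        bundles.append((stem, faa, gff, dom))
    return bundles


def _front_matter(config: PipelineConfig) -> str:
    meta = {
        "bfuscan_version": __version__,
        "window": config.window,
        "max_mismatch": config.max_mismatch,
        "k": config.k,
    }
    return "".join(f"# {line}\n" for line in yaml.safe_dump(meta, sort_keys=True).strip().split("\n"))


def run_pipeline(
    config: PipelineConfig,
    annotations: Sequence[GenomeAnnotation] | None = None,
) -> RunSummary:
    """Run every stage over a bundle directory (or in-memory annotations).

    Writes ``clusters.tsv``, ``summary.yaml``, and — when at least three
    clusters are retained and the phylogeny stage is enabled —
    ``concat_abc.faa``, ``tree.nwk`` and ``purity.tsv`` under the output
    directory.  Reports carry a YAML front-matter block recording the
    configuration so every count is traceable to parameters.
    """
    if annotations is None:
        annotations = [
            read_genome(faa, gff, dom, genome_id=stem)
            for stem, faa, gff, dom in discover_bundles(config.input_dir)
        ]

    all_calls: list[SubtypeCall] = []
    capability: dict[str, CapabilityCall] = {}
    proteins: dict[str, str] = {}
    for ann in annotations:
        calls, caps = analyze_genome(ann, window=config.window,
                                     max_mismatch=config.max_mismatch)
        all_calls.extend(calls)
        capability.update(caps)
        proteins.update(ann.proteins)

    summary_tbl = summarize_subtypes(all_calls)
    retained = [c for c in all_calls if c.retained]

    purity = None
    mean_purity = None
    tree = None
    concats: dict[str, str] = {}
    if config.run_phylogeny and len(retained) >= 3:
        labels = {}
        for call in retained:
            label = f"{call.cluster.genome_id}|{call.cluster.anchor}"
            concats[label] = concat_abc(call.cluster, proteins)
            labels[label] = call.label
        dm = kmer_distance(concats, k=config.k)
        tree = nj_tree(dm)
        purity = subtype_purity(tree, labels)
        mean_purity = purity.mean_purity

    summary = RunSummary(
        genomes=len(annotations),
        anchors=len(all_calls),
        clusters_retained=len(retained),
        subtype_counts={k: int(v) for k, v in summary_tbl.overall.items()},
        distinct_labels=summary_tbl.distinct_labels,
        mean_purity=mean_purity,
        calls=all_calls,
        capability=capability,
        purity=purity,
    )

    if config.write_reports:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        fm = _front_matter(config)
        report_path = outdir / "clusters.tsv"
        with open(report_path, "w") as fh:
            fh.write(fm)
        # append the TSV body after the front matter
        tmp = outdir / ".clusters.body.tsv"
        write_cluster_report(all_calls, tmp, capability)
        with open(report_path, "a") as fh:
            fh.write(tmp.read_text())
        tmp.unlink()
        with open(outdir / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary.as_dict(), fh, sort_keys=True)
        if tree is not None:
            with open(outdir / "tree.nwk", "w") as fh:
                fh.write(str(tree).strip() + "\n")
            export_concat_fasta(concats, outdir / "concat_abc.faa")
            with open(outdir / "purity.tsv", "w") as fh:
                fh.write(fm)
                purity.per_subtype.to_csv(fh, sep="\t", index=False)
    return summary
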