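"""H-cluster binding-motif detection and conservation profiling.

The catalytic subunit (BfuA) of an [FeFe]-hydrogenase ligates the H-cluster
— a [4Fe-4S] cluster bridged via cysteine to a 2Fe sub-cluster — through
three conserved signature motifs, called P1, P2 and P3 in the hydrogenase
literature.  The catalog defaults are the degenerate patterns

* P1 ``xTSCxPxWx``
* P2 ``xxMPCxAKK``
* P3 ``ExMxCPGGCxxGxGQ``

where ``x`` matches any residue.  A protein is called a BfuA candidate when
it carries at least one match of each motif with the leftmost matches in
P1 < P2 < P3 order along the sequence.

Conservation over aligned motif instances is summarised the way sequence
logos are: per-column information content R_i = log2(20) − H_i bits, with
letter heights frequency × R_i.  No small-sample correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

AA20 = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "x"
MAX_BITS = math.log2(20)

__all__ = [
    "MotifPattern",
    "MotifHit",
    "ConservationProfile",
    "P1",
    "P2",
    "P3",
    "DEFAULT_CATALOG",
    "scan_motif",
    "call_bfua",
    "column_information",
]


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif over the 20 residue letters plus wildcard ``x``."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"pattern {self.name}: length must be >= 3")
        bad = set(self.pattern) - set(AA20) - {WILDCARD}
        if bad:
            raise ValueError(f"pattern {self.name}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)


P1 = MotifPattern("P1", "xTSCxPxWx")
P2 = MotifPattern("P2", "xxMPCxAKK")
P3 = MotifPattern("P3", "ExMxCPGGCxxGxGQ")

#: The three H-cluster binding motifs, in their order along BfuA.
DEFAULT_CATALOG: tuple[MotifPattern, ...] = (P1, P2, P3)


@dataclass(frozen=True)
class MotifHit:
    """A motif match; ``start`` is 1-based within the protein."""

    gene_id: str
    motif: str
    start: int
    matched: str
    mismatches: int


def scan_motif(
    sequence: str,
    pattern: MotifPattern,
    max_mismatch: int = 0,
    gene_id: str = "",
) -> list[MotifHit]:
    """Report every window whose non-wildcard mismatch count is within tolerance.

    ``X`` in the sequence counts as a mismatch at non-wildcard pattern
    positions.  Overlapping hits are all reported, sorted by start.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    m = len(pattern.pattern)
    fixed = [(i, c) for i, c in enumerate(pattern.pattern) if c != WILDCARD]
    hits: list[MotifHit] = []
    for pos in range(len(sequence) - m + 1):
        mismatches = 0
        for i, c in fixed:
            if sequence[pos + i] != c:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        if mismatches <= max_mismatch:
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    motif=pattern.name,
                    start=pos + 1,
                    matched=sequence[pos : pos + m],
                    mismatches=mismatches,
                )
            )
    return hits


def has_ordered_motifs(
    sequence: str,
    catalog: Sequence[MotifPattern] = DEFAULT_CATALOG,
    max_mismatch: int = 0,
) -> bool:
    """True when the leftmost P1/P2/P3 hits occur in strictly increasing order."""
    starts = []
    for pat in catalog:
        hits = scan_motif(sequence, pat, max_mismatch)
        if not hits:
            return False
        starts.append(hits[0].start)
    return all(a < b for a, b in zip(starts, starts[1:]))


def call_bfua(
    annotation: GenomeAnnotation,
    catalog: Sequence[MotifPattern] = DEFAULT_CATALOG,
    max_mismatch: int = 0,
) -> list[str]:
    """Gene ids of BfuA candidates, sorted by genome position.

    A gene qualifies iff its protein contains at least one hit of each
    catalog motif with the leftmost hits ordered along the sequence as the
    catalog lists them (P1 < P2 < P3).
    """
    names = [p.name for p in catalog]
    if len(set(names)) != len(names):
        raise ValueError("catalog motif names must be unique")
    called = []
    for gene_id in annotation.gene_ids():
        seq = annotation.proteins.get(gene_id)
        if seq and has_ordered_motifs(seq, catalog, max_mismatch):
            called.append(gene_id)
    return called


def motif_hits_table(
    annotation: GenomeAnnotation,
    catalog: Sequence[MotifPattern] = DEFAULT_CATALOG,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """All motif hits over all proteins, one row per hit."""
    rows = []
    for gene_id in annotation.gene_ids():
        seq = annotation.proteins.get(gene_id, "")
        for pat in catalog:
            for h in scan_motif(seq, pat, max_mismatch, gene_id=gene_id):
                rows.append(
                    (h.gene_id, h.motif, h.start, h.matched, h.mismatches)
                )
    return pd.DataFrame(rows, columns=["gene_id", "motif", "start", "matched", "mismatches"])


# ---------------------------------------------------------------------------
# conservation / sequence-logo arithmetic


@dataclass
class ConservationProfile:
    """Per-position residue frequencies, information content, letter heights.

    ``frequencies`` and ``heights`` are position × residue DataFrames over
    the 20 canonical residues; ``information`` holds R_i in bits.
    """

    motif: str
    frequencies: pd.DataFrame
    information: np.ndarray
    heights: pd.DataFrame

    def __len__(self) -> int:
        return len(self.information)

    def to_tsv(self, path) -> None:
        """Long-format logo table: position, residue, height, bits."""
        rows = []
        for pos in range(len(self)):
            for res in AA20:
                h = self.heights.iat[pos, AA20.index(res)]
                if h > 0:
                    rows.append((pos + 1, res, h, self.information[pos]))
        pd.DataFrame(rows, columns=["position", "residue", "height", "bits"]).to_csv(
            path, sep="\t", index=False
        )


def column_information(instances: Sequence[str], motif: str = "") -> ConservationProfile:
    """Logo statistics over equal-length aligned motif instances.

    Per position, R_i = log2(20) − H_i where H_i is the base-2 Shannon
    entropy of the residue frequencies; letter height = frequency × R_i.
    ``X`` residues are excluded from the counts at their column.
    """
    if not instances:
        raise ValueError("need at least one instance")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("instances must all have the same length")

    counts = np.zeros((length, 20))
    idx = {c: i for i, c in enumerate(AA20)}
    for s in instances:
        for pos, c in enumerate(s):
            if c in idx:
                counts[pos, idx[c]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.clip(MAX_BITS - entropy, 0.0, MAX_BITS)
    heights = freqs * info[:, None]

    cols = list(AA20)
    return ConservationProfile(
        motif=motif,
        frequencies=pd.DataFrame(freqs, columns=cols),
        information=info,
        heights=pd.DataFrame(heights, columns=cols),
    )
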