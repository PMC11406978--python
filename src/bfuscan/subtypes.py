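"""Intactness filtering and organizational sub-type classification.

Retained gene clusters — those encoding an intact bifurcating BfuB/BfuC
core within five genes of the catalytic bfuA gene — fall into five
organizational patterns of the encoding cluster, read in the anchor's
transcription direction with non-subunit (X) genes ignored:

=========  =============  ==================================
sub-type   role pattern   complex
=========  =============  ==================================
I          A B D C        tetrameric BfuABDC
II         A B C          trimeric BfuABC
III        C A B          trimeric, "BAC"-oriented reading
IV         A B C T        BfuABC + sensory BfuT downstream
V          T A B C        BfuABC + sensory BfuT upstream
=========  =============  ==================================

Sub-type IV admits one known exception: bfuT directly downstream of and
adjacent to bfuA (pattern A T B C), flagged ``T_downstream_of_A`` rather
than treated as a sixth sub-type.  Clusters with two T genes, with both D
and T, or matching no pattern are left ``unclassified`` with a
nearest-pattern reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .neighborhood import ClusterMember, GeneCluster

SUBTYPE_PATTERNS: dict[str, str] = {
    "I": "ABDC",
    "II": "ABC",
    "III": "CAB",
    "IV": "ABCT",
    "V": "TABC",
}
#: The sub-type IV variant with bfuT adjacent downstream of bfuA.
SUBTYPE_IV_EXCEPTION = "ATBC"

#: Guard precedence if a cluster ever matched several patterns (more
#: gene-rich patterns are more specific).
_PRECEDENCE = ("I", "IV", "V", "III", "II")

SUBTYPE_LABELS = ("I", "II", "III", "IV", "V")
UNCLASSIFIED = "unclassified"

__all__ = [
    "SubtypeCall",
    "SUBTYPE_PATTERNS",
    "SUBTYPE_LABELS",
    "UNCLASSIFIED",
    "intactness_filter",
    "assign_subtype",
    "summarize_subtypes",
]


@dataclass(frozen=True)
class SubtypeCall:
    """Retention verdict plus sub-type label and variant flags for a cluster."""

    cluster: GeneCluster
    retained: bool
    label: str
    flags: frozenset = frozenset()
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label != UNCLASSIFIED and not self.retained:
            raise ValueError("a labeled cluster must be retained")


def _intact_b(member: ClusterMember) -> bool:
    ds = set(member.domains)
    return not member.partial and "FMN" in ds and "B1" in ds


def _intact_c(member: ClusterMember) -> bool:
    return not member.partial and "C1" in set(member.domains)


def intactness_filter(cluster: GeneCluster) -> tuple[bool, list[str]]:
    """Retention rule: the cluster must encode an intact BfuB and BfuC.

    A B member is incomplete when partial or missing its FMN or B1 label; a
    C member is incomplete when partial or missing C1.  Reasons name every
    failed condition (``no_B``, ``incomplete_B``, ``no_C``, ``incomplete_C``).
    """
    reasons = []
    bs = cluster.members_with_role("B")
    cs = cluster.members_with_role("C")
    if not bs:
        reasons.append("no_B")
    elif not any(_intact_b(m) for m in bs):
        reasons.append("incomplete_B")
    if not cs:
        reasons.append("no_C")
    elif not any(_intact_c(m) for m in cs):
        reasons.append("incomplete_C")
    return (not reasons), reasons


def _nearest_pattern(roles: str) -> str:
    """Closest sub-type pattern by edit distance (ties by precedence)."""

    def edit(a: str, b: str) -> int:
        dp = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            prev, dp[0] = dp[0], i
            for j, cb in enumerate(b, 1):
                prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
        return dp[-1]

    return min(_PRECEDENCE, key=lambda lab: (edit(roles, SUBTYPE_PATTERNS[lab]),))


def assign_subtype(cluster: GeneCluster) -> SubtypeCall:
    """Filter a cluster and classify its organizational pattern.

    Pattern matching ignores interspersed X genes but requires all pattern
    roles within the extraction window.  BfuD presence/absence and bfuT
    placement are recorded as flags; they never create new labels.
    """
    retained, reasons = intactness_filter(cluster)
    flags: set[str] = set()
    if cluster.truncated:
        flags.add("truncated_window")
    if cluster.has_antisense_member():
        flags.add("antisense_member")

    if not retained:
        return SubtypeCall(cluster, False, UNCLASSIFIED, frozenset(flags), tuple(reasons))

    roles = cluster.role_string()
    n_t = roles.count("T")
    n_d = roles.count("D")
    if n_d:
        flags.add("D_present")
    if n_t >= 2:
        flags.add("double_T")
        return SubtypeCall(cluster, True, UNCLASSIFIED, frozenset(flags), ("double_T",))
    if n_d and n_t:
        return SubtypeCall(
            cluster, True, UNCLASSIFIED, frozenset(flags),
            ("both_D_and_T", f"nearest:{_nearest_pattern(roles)}"),
        )

    matched = [lab for lab, pat in SUBTYPE_PATTERNS.items() if roles == pat]
    if roles == SUBTYPE_IV_EXCEPTION:
        matched.append("IV")
        flags.add("T_downstream_of_A")
    if not matched:
        return SubtypeCall(
            cluster, True, UNCLASSIFIED, frozenset(flags),
            (f"nearest:{_nearest_pattern(roles)}",),
        )
    if len(matched) > 1:
        flags.add("multiply_matched")
    label = next(lab for lab in _PRECEDENCE if lab in matched)

    if label == "V":
        flags.add("T_upstream_of_A")
    if label in ("I", "II") and not n_d:
        # sub-type I clusters can lose the accessory D subunit; organizationally
        # such clusters read ABC and are labeled II, flagged for the report
        flags.add("D_absent")
    return SubtypeCall(cluster, True, label, frozenset(flags), ())


@dataclass
class SubtypeSummary:
    per_genome: pd.DataFrame
    overall: pd.Series
    distinct_labels: int
    flag_counts: pd.Series

    @property
    def n_retained(self) -> int:
        return int(self.overall.drop("not_retained", errors="ignore").sum())


def summarize_subtypes(calls: Sequence[SubtypeCall]) -> SubtypeSummary:
    """Per-genome and overall counts by label and flag.

    ``distinct_labels`` counts distinct sub-type labels I–V among retained
    clusters (``unclassified`` excluded).
    """
    label_cols = list(SUBTYPE_LABELS) + [UNCLASSIFIED, "not_retained"]
    rows = []
    flag_counter: dict[str, int] = {}
    for call in calls:
        key = call.label if call.retained else "not_retained"
        rows.append({"genome_id": call.cluster.genome_id, "outcome": key})
        for f in call.flags:
            flag_counter[f] = flag_counter.get(f, 0) + 1
    if rows:
        df = pd.DataFrame(rows)
        per_genome = (
            df.groupby(["genome_id", "outcome"]).size().unstack(fill_value=0)
            .reindex(columns=label_cols, fill_value=0)
        )
        overall = per_genome.sum(axis=0)
    else:
        per_genome = pd.DataFrame(columns=label_cols)
        overall = pd.Series(0, index=label_cols)
    distinct = int(sum(overall.get(lab, 0) > 0 for lab in SUBTYPE_LABELS))
    return SubtypeSummary(
        per_genome=per_genome,
        overall=overall,
        distinct_labels=distinct,
        flag_counts=pd.Series(flag_counter, dtype=int).sort_index(),
    )
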