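"""FeS/flavin complements and rule-based electron-bifurcation capability.

Electron-bifurcating BfuABC complexes split the electron pair generated by
H2 oxidation between a high-potential acceptor (NAD) and a low-potential
acceptor (ferredoxin).  Structural work on HydABC homologs places the
relevant cofactors on named sites: [2Fe-2S] clusters A1, A5, B2, B5, C1 and
[4Fe-4S] clusters A2, A3, A4, B1, B3, B4, plus the FMN at the bifurcation
site.  The rule engine here maps a declared domain architecture to that
cofactor complement and issues a *predicted* capability verdict:

* ``bifurcating`` — a complete B1–B5 set plus FMN in the B subunit and C1
  in the C subunit (the completeness reported necessary for activity);
* ``non_bifurcating`` — B3 or B4 absent with no FAD (the ferredoxin-
  interacting pair is missing, as in the non-bifurcating HydABC of
  *Syntrophomonas wolfei*);
* ``dual_center_candidate`` — a DPD_II domain (which carries two [4Fe-4S]
  clusters in place of B3/B4) together with an FAD/NAD(P)-binding domain:
  a possible second, flavin-only bifurcation center beside FMN-FeS;
* ``indeterminate`` — anything else, notably B5 absent with B1–B4 present
  (B5's role is contested in the structural literature).

All verdicts are architecture-based predictions, not biochemical calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "LABELS_2FE2S",
    "LABELS_4FE4S",
    "KNOWN_LABELS",
    "B_SERIES",
    "A_SERIES",
    "FeSComplement",
    "CapabilityCall",
    "complement_from_architecture",
    "bifurcation_call",
    "electron_path_check",
]

#: Named FeS sites by cluster type.
LABELS_2FE2S = frozenset({"A1", "A5", "B2", "B5", "C1"})
LABELS_4FE4S = frozenset({"A2", "A3", "A4", "B1", "B3", "B4"})
B_SERIES = ("B1", "B2", "B3", "B4", "B5")
A_SERIES = ("A1", "A2", "A3", "A4", "A5")

#: Every domain label the rule engine understands.  ``2Fe`` is the H-cluster
#: di-iron center; ``DPD_II`` is the dihydropyrimidine-dehydrogenase domain
#: carrying two [4Fe-4S] clusters; ``BfuD_like`` is the declared accessory
#: D-subunit architecture label.
KNOWN_LABELS = frozenset(
    {"2Fe", "FMN", "FAD", "Nqo1", "DPD_II", "PAS", "His_kinase_dom", "BfuD_like"}
    | LABELS_2FE2S
    | LABELS_4FE4S
)

#: A-subunit complements implied by the modular-structure class.  M3c (seen
#: only in sub-type IV BfuA) adds the accessory [2Fe-2S] pair A1/A5.
ARCHITECTURE_COMPLEMENTS: dict[str, tuple[str, ...]] = {
    "M3c": ("2Fe", "A1", "A2", "A3", "A4", "A5"),
    "M3a": ("2Fe", "A2", "A3", "A4"),
}


@dataclass
class FeSComplement:
    """Per-subunit cofactor inventory derived from declared domain labels."""

    subunit_labels: dict[str, tuple[str, ...]]
    architecture: str | None = None

    def labels(self, subunit: str | None = None) -> Counter:
        """Label multiset for one subunit, or pooled over all subunits."""
        if subunit is not None:
            return Counter(self.subunit_labels.get(subunit, ()))
        pooled: Counter = Counter()
        for labs in self.subunit_labels.values():
            pooled.update(labs)
        return pooled

    def count(self, cluster_type: str) -> int:
        """Number of FeS clusters of ``'2Fe-2S'`` or ``'4Fe-4S'`` type.

        DPD_II contributes two [4Fe-4S] clusters; duplicate labels count
        with multiplicity (a double B5 is two [2Fe-2S]).
        """
        pooled = self.labels()
        if cluster_type == "2Fe-2S":
            return sum(n for lab, n in pooled.items() if lab in LABELS_2FE2S)
        if cluster_type == "4Fe-4S":
            base = sum(n for lab, n in pooled.items() if lab in LABELS_4FE4S)
            return base + 2 * pooled.get("DPD_II", 0)
        raise ValueError(f"unknown cluster type {cluster_type!r}")

    @property
    def flavins(self) -> frozenset:
        pooled = self.labels()
        return frozenset(f for f in ("FMN", "FAD") if pooled.get(f, 0))

    def has(self, label: str) -> bool:
        return self.labels().get(label, 0) > 0


@dataclass(frozen=True)
class CapabilityCall:
    """A predicted bifurcation-capability verdict with its rationale codes."""

    verdict: str
    rationale: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


def complement_from_architecture(
    domains_by_subunit: Mapping[str, Sequence[str]],
    architecture: str | None = None,
) -> FeSComplement:
    """Build an :class:`FeSComplement` from per-subunit declared domains.

    When a modular-structure class (``M3a``/``M3c``) is given, the
    A-subunit complement is taken from it rather than from declared A
    domains (the class determines the accessory FeS set).  Unknown labels
    raise a :class:`ValueError` naming the offender.
    """
    if architecture is not None and architecture not in ARCHITECTURE_COMPLEMENTS:
        raise ValueError(f"unknown architecture {architecture!r} (expected M3a or M3c)")
    subunits: dict[str, tuple[str, ...]] = {}
    for subunit, labels in domains_by_subunit.items():
        for lab in labels:
            if lab not in KNOWN_LABELS:
                raise ValueError(f"unknown domain label {lab!r} on subunit {subunit}")
        subunits[subunit] = tuple(labels)
    if architecture is not None:
        subunits["A"] = ARCHITECTURE_COMPLEMENTS[architecture]
    return FeSComplement(subunit_labels=subunits, architecture=architecture)


def bifurcation_call(complement: FeSComplement) -> CapabilityCall:
    """Apply the capability rule table to a complement.

    A double B5 (as seen in sub-type III) is recorded as a note and never
    changes the verdict — its function is unresolved.
    """
    pooled = complement.labels()
    notes = []
    if pooled.get("B5", 0) >= 2:
        notes.append("double_B5")

    have = {lab for lab, n in pooled.items() if n}
    b_complete = all(b in have for b in B_SERIES)
    dpd_fad = "DPD_II" in have and "FAD" in have

    if dpd_fad:
        # DPD_II carries the two [4Fe-4S] clusters that replace B3/B4, and the
        # extra FAD domain is a possible second bifurcation center.
        return CapabilityCall(
            "dual_center_candidate",
            rationale=("dpd_ii_with_fad", "fad_center_beside_fmn_fes"),
            notes=tuple(notes),
        )
    if b_complete and "FMN" in have and "C1" in have:
        return CapabilityCall(
            "bifurcating", rationale=("b1_to_b5_complete", "fmn_present", "c1_present"),
            notes=tuple(notes),
        )
    missing_b34 = [b for b in ("B3", "B4") if b not in have]
    if missing_b34 and "FAD" not in have:
        return CapabilityCall(
            "non_bifurcating",
            rationale=tuple(f"missing_{b}" for b in missing_b34),
            notes=tuple(notes),
        )
    return CapabilityCall("indeterminate", rationale=("rule_table_unresolved",), notes=tuple(notes))


def electron_path_check(complement: FeSComplement) -> tuple[bool, list[str]]:
    """Check both proposed electron-transfer chains for completeness.

    Chain 1 (H2 to the bifurcation site): 2Fe → (A-series, when the A
    subunit is M3c) → B1 → FMN.  Chain 2 (to ferredoxin): C1 → B2 → B3 →
    B4.  Returns ``(path_ok, missing)`` with absent links listed in chain
    order.
    """
    have = {lab for lab, n in complement.labels().items() if n}
    chain1: list[str] = ["2Fe"]
    if complement.architecture == "M3c":
        chain1 += list(A_SERIES)
    chain1 += ["B1", "FMN"]
    chain2 = ["C1", "B2", "B3", "B4"]
    missing = [link for link in chain1 + chain2 if link not in have]
    return (not missing), missing
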