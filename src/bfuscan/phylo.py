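"""Sequence-level cross-check of the organizational sub-typing.

The five organizational patterns are expected to coincide with five
sequence clusters of the concatenated A+B+C subunits.  This module builds
that cross-check with alignment-free machinery: concatenate the three
subunit proteins in fixed A,B,C order, compute pairwise k-mer Jaccard
distances, run neighbor joining, and score how cleanly each sub-type label
sits in its own clade (monophyly/purity).

The distances are a deliberate simplification of maximum-likelihood
phylogenetics: the cross-check only needs sub-type-level clustering, not
publication-grade trees.  A FASTA export hook is provided for users who
want to feed the concatenates to an external ML tool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .annotation import GenomeAnnotation
from .neighborhood import GeneCluster

__all__ = [
    "concat_abc",
    "kmer_distance",
    "nj_tree",
    "subtype_purity",
    "PurityReport",
    "export_concat_fasta",
]


def concat_abc(cluster: GeneCluster, proteins: Mapping[str, str]) -> str:
    """Concatenate the A, B and C subunit proteins in that fixed order.

    The order is independent of gene order on the genome (a sub-type III
    cluster with gene order C,A,B still concatenates A+B+C).  When a role
    has several members the first in canonical order is used.
    """
    parts = []
    for role in "ABC":
        members = cluster.members_with_role(role)
        if not members:
            raise ValueError(f"cluster {cluster.anchor}: missing subunit {role}")
        parts.append(proteins[members[0].gene_id])
    return "".join(parts)


def kmer_distance(seqs: Mapping[str, str], k: int = 4) -> DistanceMatrix:
    """Pairwise 1 − Jaccard(k-mer sets) distances between sequences."""
    labels = list(seqs)
    sets = {}
    for lab in labels:
        s = seqs[lab]
        if len(s) < k:
            raise ValueError(f"sequence {lab!r} shorter than k={k}")
        sets[lab] = {s[i : i + k] for i in range(len(s) - k + 1)}
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = sets[labels[i]], sets[labels[j]]
        jac = len(a & b) / len(a | b)
        mat[i, j] = mat[j, i] = 1.0 - jac
    return DistanceMatrix(mat, ids=labels)


# ---------------------------------------------------------------------------
# neighbor joining

# NJ is re-derived here rather than delegated so the contract's determinism
# holds exactly: ties in the Q-criterion break to the lowest (i, j) index
# pair and negative branch lengths clamp to zero.  Tests cross-check the
# topology against an independent NJ implementation.


def _newick_escape(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining over a distance matrix.

    Requires n >= 3 taxa and a symmetric matrix (``DistanceMatrix``
    enforces symmetry).  Branch lengths are clamped at zero and written to
    6 decimals; the result is an unrooted tree represented with a trifurcating
    root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    d = dm.data.astype(float).copy()
    # nodes are newick fragments; order index doubles as the tie-break key
    nodes = [_newick_escape(str(i)) for i in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        merged = f"({nodes[i]}:{vi:.6f},{nodes[j]}:{vj:.6f})"
        # distances from the new node u to every remaining node
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        new_d[m - 2, : m - 2] = new_d[: m - 2, m - 2] = du[keep]
        d = new_d
        nodes = [nodes[x] for x in keep] + [merged]

    # three-point closed form for the final join
    (a, b, c) = (0, 1, 2)
    va = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    vb = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    vc = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    newick = (
        f"({nodes[a]}:{va:.6f},{nodes[b]}:{vb:.6f},{nodes[c]}:{vc:.6f});"
    )
    # convert_underscores off: taxon ids routinely contain underscores
    return TreeNode.read([newick], convert_underscores=False)


# ---------------------------------------------------------------------------
# monophyly / purity


@dataclass
class PurityReport:
    """Per-sub-type clade purity on an unrooted tree.

    ``purity`` for a sub-type is its size divided by the size of the
    smallest clade (either side of any edge) containing all its leaves;
    a sub-type is monophyletic iff its purity is 1.
    """

    per_subtype: pd.DataFrame  # columns: subtype, n, clade_size, purity, monophyletic
    mean_purity: float

    def monophyletic(self, subtype: str) -> bool:
        row = self.per_subtype[self.per_subtype["subtype"] == subtype]
        return bool(row["monophyletic"].iloc[0])


def subtype_purity(tree: TreeNode, labels: Mapping[str, str]) -> PurityReport:
    """Score how cleanly each sub-type clusters on the tree.

    Every edge of the unrooted tree splits the leaves in two; both sides of
    every split are candidate clades.  ``labels`` maps every leaf name to
    its sub-type; an unlabeled leaf raises a :class:`KeyError`.
    """
    leaves = [t.name for t in tree.tips()]
    unlabeled = [l for l in leaves if l not in labels]
    if unlabeled:
        raise KeyError(f"unlabeled leaves: {unlabeled}")
    all_leaves = frozenset(leaves)

    clades: set[frozenset] = {all_leaves}
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset([node.name])
        clades.add(side)
        clades.add(all_leaves - side)

    rows = []
    for subtype in sorted(set(labels[l] for l in leaves)):
        members = frozenset(l for l in leaves if labels[l] == subtype)
        best = min((c for c in clades if members <= c), key=len)
        purity = len(members) / len(best)
        rows.append(
            {
                "subtype": subtype,
                "n": len(members),
                "clade_size": len(best),
                "purity": purity,
                "monophyletic": purity == 1.0,
            }
        )
    df = pd.DataFrame(rows)
    return PurityReport(per_subtype=df, mean_purity=float(df["purity"].mean()))


def export_concat_fasta(seqs: Mapping[str, str], path) -> None:
    """Write concatenated subunit sequences for external phylogenetics tools."""
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n{seq}\n")
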