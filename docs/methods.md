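# Methods

## Scope and model

`bfuscan` classifies gene clusters encoding electron-bifurcating group A3
[FeFe]-hydrogenases (Bfu complexes). The underlying biological model has
three layers:

1. **Catalytic subunit identification.** The H-cluster — a [4Fe-4S]
   cluster bridged to a 2Fe sub-cluster — is ligated by three conserved
   signature motifs. A protein is a BfuA candidate iff it carries at least
   one zero-mismatch match of each of P1 (`xTSCxPxWx`), P2 (`xxMPCxAKK`)
   and P3 (`ExMxCPGGCxxGxGQ`), with the leftmost matches in P1 < P2 < P3
   order. `x` matches any residue; `X` in a sequence counts as a mismatch
   at non-wildcard positions.
2. **Organizational sub-typing.** A cluster is the ±5-gene neighborhood
   of a BfuA anchor (the window counts genes, not base pairs). Clusters
   missing an intact BfuB (FMN + B1 labels, gene not partial) or BfuC
   (C1 label, not partial) are not retained. Retained clusters are
   classified by the order of subunit roles read in the anchor's
   transcription direction, ignoring interspersed non-subunit genes:
   A B D C → I, A B C → II, C A B → III, A B C T → IV, T A B C → V, plus
   the known sub-type IV variant A T B C (flagged `T_downstream_of_A`).
3. **Capability prediction.** Declared domain architectures map to an
   FeS/flavin complement ([2Fe-2S] = A1, A5, B2, B5, C1; [4Fe-4S] = A2,
   A3, A4, B1, B3, B4; DPD_II contributes two [4Fe-4S]). The rule table:
   complete B1–B5 + FMN + C1 → `bifurcating`; DPD_II + FAD →
   `dual_center_candidate` (a possible flavin-only center beside the
   FMN–FeS center); B3 or B4 absent without FAD → `non_bifurcating`;
   anything else `indeterminate`. The electron-path check tests the
   2Fe → (A-series when M3c) → B1 → FMN and C1 → B2 → B3 → B4 chains.

All capability output is a structural prediction from declared domain
labels, never a biochemical result; reports carry a `predicted_` prefix.

## Interfaces and conventions

* Inputs per genome: protein FASTA, GFF3 gene features with `ID`
  attributes, and a TSV of declared domain architectures (`gene_id`,
  `ordinal`, `domain_label`). Domain detection (HMM search) is upstream
  of this package by design: architectures are declared inputs, which
  keeps the rule engine testable without external databases.
* Coordinates are 1-based inclusive on disk (GFF3 dialect) and on
  `GeneRecord`; helpers convert to 0-based half-open locally. Ranks are
  coordinate order per contig; reverse-strand genes are not re-ranked,
  because the neighborhood window is positional, not transcriptional.
* A gene is `partial` when its GFF3 attributes say so or when it touches
  base 1 or the `##sequence-region` terminus.
* Canonical cluster orientation is BfuA's transcription direction. The
  figure convention that displays clusters as if on the negative strand
  is available as `figure_convention_string()`; the two readings of the
  sub-type III arrangement ("CAB" vs "BAC") are one pattern under this
  convention.
* Subunit genes antisense to the anchor are accepted as members and
  flagged `antisense_member`; no same-strand requirement is imposed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window` | 5 genes | neighborhood half-width around *bfuA* |
| `max_mismatch` | 0 | motif-scan tolerance; a `--tolerant` scan reports near-misses at 1 mismatch separately without changing canonical calls |
| `k` | 4 residues | k-mer size for the alignment-free distance |
| `divergence_between` | 0.15 | substitution proportion between sub-type template variants |
| `divergence_within` | 0.02 | substitution proportion between instances of one sub-type |

The mismatch tolerance of the original motif screen is not documented
anywhere authoritative; 0 is the default and is exposed. Near-miss
reporting exists because sensory-group C1 sequences are known to match
the signatures only loosely — users can reproduce that judgement without
loosening the canonical call.

## Design choices where the design was open

* **Role assignment precedence** A > T > B > C > D, with an `ambiguous`
  flag when several rules match. The accessory D subunit has no
  established domain signature, so role D is keyed to a declared
  `BfuD_like` label.
* **D-less A B C clusters** are labelled II and flagged `D_absent`.
  Phylogenetically such clusters can belong with the sub-type I clade,
  but organization alone cannot see that; the flag lets a user with a
  tree override.
* **Double-T clusters** (T A B C T) are `unclassified` + `double_T`
  rather than forced into IV or V.
* **B5 absence with B1–B4 present** yields `indeterminate`, not
  `non_bifurcating`: B5's role in electron transfer is contested (gate
  vs dead end), and a double B5 is recorded as a note that never changes
  a verdict. One consequence: a complement with a complete electron path
  but no B5 and no FAD is `indeterminate`, so path completeness implies
  only that the verdict is not `non_bifurcating`.
* **DPD_II + FAD overrides the B3/B4-absence rule** — those clusters are
  dual-center candidates, not non-bifurcating, since DPD_II carries the
  two [4Fe-4S] clusters that replace B3/B4.
* **Neighbor joining is implemented in-package** with deterministic
  tie-breaks (lowest index pair on Q-criterion ties) and negative branch
  lengths clamped to zero, and is cross-checked against an independent
  NJ implementation in the tests. The alignment-free k-mer Jaccard
  distance stands in for maximum-likelihood phylogenetics deliberately:
  the cross-check needs sub-type-level clustering only. A FASTA export
  of the concatenates supports external ML tools.
* **Purity** of a sub-type is its size divided by the size of the
  smallest side, over both directions of every edge of the unrooted
  tree, containing all its leaves; monophyly ⇔ purity 1.

## The synthetic generator

The generator emulates the features of real MAG data this pipeline must
survive: multi-contig genomes, clusters on either strand, decoy genes
interleaved inside clusters (kept as X members), contig-edge truncation
producing partial genes, omitted subunits, and hierarchical sequence
divergence. It does **not** emulate nucleotide sequences, realistic
intergenic spacing, amino-acid composition bias, alignment-visible
homology structure, or horizontal-transfer history — so passing tests
demonstrate the correctness of the decision rules and the separability
of sub-types at the stated divergences, not performance on real
divergence patterns.

Subunit proteins derive from fixed hand-written templates (one per role;
the BfuA template carries the three motifs at known positions, masked
from mutation, with Ser at the discriminating fifth P1 position switched
to Cys for sub-type IV). Per-sub-type variants are drawn once per run at
`divergence_between`; each planted instance adds `divergence_within`.
Decoys are motif-free random sequences; a configurable fraction carries
an isolated P1 instance to exercise the all-three-motifs requirement.
Declared domain tables follow the five sub-type architectures (sub-type
II BfuB lacks B3/B4/B5; sub-type III BfuB carries a double B5; sub-type I
BfuB has DPD_II + FAD; sub-type IV BfuA is M3c).

The ground-truth table is computed from the realized layout alone (known
motif coordinates, which genes were omitted or truncated, realized rank
offsets) — never by running the detection pipeline.

Default study conditions: 20 genomes × 3 clusters, uniform sub-type mix,
0–2 interleaved decoys, one 8-gene decoy-only contig per genome,
divergence 0.15/0.02, seed 42. Under these conditions planted-label
recovery and mean sub-type purity are both 1.0, and these sizes keep the
full suite and the acceptance script in the seconds range. A single
seeded generator drives every random choice, so bundles are byte-stable
for a fixed seed.

## Numerical notes

* Information content uses base-2 Shannon entropy over the 20 canonical
  residues with no small-sample correction; `X` is excluded from column
  counts. Bounds: 0 (uniform column) to log₂20 ≈ 4.3219 (conserved).
* k-mer distance is 1 − Jaccard on k-mer *sets* (presence, not counts);
  it is a pseudometric — distinct sequences can be at distance 0.
* NJ branch lengths are written to 6 decimals; trees are serialized as
  newick with quoting that preserves underscores.
* Degenerate inputs: empty genomes, zero anchors and empty reports are
  valid and produce all-zero summaries; the phylogeny stage requires at
  least three retained clusters and is skipped otherwise.

## Known limitations

* Capability verdicts inherit every limitation of declared domain
  architectures; wrong or missing labels propagate directly.
* Organizational and sequence-based sub-typing can disagree on real
  data; the pipeline reports both (labels vs tree purity) and does not
  adjudicate.
* The integration-scale claim that real multi-cluster genomes show five
  and three distinct sub-types is checked on synthetic stand-in genomes
  mirroring those compositions; running on the real assemblies requires
  user-supplied gene calls and domain annotations.
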