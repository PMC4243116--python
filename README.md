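# apccooc — co-occurring conserved regions in protein families

`apccooc` finds conserved regions in a set of homologous protein sequences,
scores how often pairs of regions appear on the *same* sequences, groups the
regions into **Co-occurrence Clusters**, and checks whether clustered regions
sit close together in a 3D structure.  It is aimed at sequence-analysis
practitioners who want to go from a family FASTA file to a ranked list of
jointly acting functional regions without building a multiple sequence
alignment first.

## The method

1. **Pattern discovery.**  Every contiguous substring p = s¹s²…sⁿ with
   length in [min_len, max_len] and sequence-level support ≥ min_occurrence
   is enumerated.  Each pattern is scored with the standard residual
   z = (O − E)/√E, where O is its window count and
   E = W_n · Π_i f(p_i) its expectation under an order-0 background with
   residue frequencies f; patterns with z ≥ 1.96 are kept.  A pattern is
   then pruned as redundant when a retained super-pattern q ⊃ p keeps
   support(q) ≥ δ·support(p) (delta-closed pruning, default δ = 0.9).
2. **Aligned Pattern Clusters (APCs).**  Patterns are merged greedily by
   global alignment (match +1, mismatch 0, gap −0.5) into m×n matrices over
   Σ ∪ {−}; a merge must produce ≥ 3 consecutive agreeing columns, ≥ 1 fully
   conserved column, and positionally consistent spans on shared sequences.
   Each APC represents one conserved region; its consensus may carry the
   wildcard `*` at high-entropy interior columns.
3. **Co-occurrence graph.**  For APCs C¹, C² with covered-sequence sets
   Cseq¹, Cseq², the edge weight is the Jaccard index
   J = |Cseq¹ ∩ Cseq²| / |Cseq¹ ∪ Cseq²|.  Pairs are ranked by J with the
   union size |Cseq¹ ∪ Cseq²| as tie-break.
4. **Co-occurrence Clusters.**  The graph is partitioned by spectral
   clustering on the random-walk Laplacian L_rw = I − D⁻¹W (eigengap choice
   of k, k-means on the leading eigenvector coordinates), by k-medoids on
   the similarity matrix, or by cutting a maximum spanning tree.  Vertices
   with no positive co-occurrence become singleton clusters.
5. **3D validation.**  APC regions are located on a PDB chain, each region's
   Cα positions are averaged into a centroid, and the mean inter-centroid
   distance is compared with the structure-wide mean pairwise Cα distance.
   Functionally linked regions are expected to beat that baseline.

A seeded synthetic-family generator (planted motifs with configurable joint
or independent presence, substitution and indel noise, plus a paired
synthetic Cα structure) makes every stage testable end to end.

## Worked example

```python
from apccooc import (JointGroup, Motif, SyntheticSpec, build_graph,
                     cluster_patterns, discover_patterns, generate_family,
                     rank_pairs, spectral_cluster)

spec = SyntheticSpec(
    motifs=[Motif("KTLHGREVAW", 0.05), Motif("DFYPNCQMIG", 0.05),
            Motif("WSREKTYLVH", 0.05)],
    joint_groups=[JointGroup((0, 1), 0.7)],   # planted together
    independent_probs={2: 0.7},               # planted independently
    n_sequences=100, length=150, seed=1,
)
seqs, truth = generate_family(spec)
apcs = cluster_patterns(discover_patterns(seqs))
graph = build_graph(apcs)
for a, b, score, union in rank_pairs(graph):
    print(a, b, round(score, 3), union)
```

prints

```
APC1 APC3 0.918 73
APC1 APC2 0.578 90
APC2 APC3 0.573 89
```

APC1 and APC3 are the two jointly planted motifs: they share ~92% of their
sequences and top the ranking.  APC2 is the independently planted motif;
its ~0.57 scores are exactly what two independent 70%-presence regions are
expected to share (0.49/0.91).  `spectral_cluster(graph)` then reports the
Laplacian spectrum `[0, 1.385, 1.615]` and the cluster assignment, and
`examples/04_structure_validation.py` shows the 3D step: on a structure
with colocated planted regions the average APC centroid distance is
5.9 Å versus a 19.8 Å structure-wide baseline, while on a dispersed
structure it rises to 79.3 Å versus 58.4 Å.

The `examples/` directory contains one short script per capability; the
`apccooc` command-line tool (`simulate`, `discover`, `apc`, `cooccur`,
`cluster`, `validate3d`, `convert`) wraps the same functions for shell use.

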