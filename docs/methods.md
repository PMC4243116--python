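# Methods

This note records the model behind each pipeline stage, the parameters that
matter, the numerical conventions, and what the synthetic benchmark does and
does not establish.

## Sequence model and background

Input is a set of homologous protein sequences over the 20-letter alphabet
Σ.  Non-standard residues (B, J, O, U, X, Z) are rejected by default, or the
offending record is dropped with `skip_bad_records=True`; the significance
statistic assumes a 20-letter alphabet, so silently remapping letters would
bias it.  The background model is order-0: maximum-likelihood residue
frequencies f(σ) estimated from the input itself.  Positions are 0-based
half-open internally and 1-based inclusive in all user-facing output, which
matches residue-numbering conventions in the structural literature.

## Pattern discovery

Candidates are all contiguous substrings with length in [`min_len`,
`max_len`] (`max_len=None` removes the bound) and **support** — distinct
sequences containing ≥ 1 occurrence — at least `min_occurrence`.
Enumeration seeds with `min_len`-windows and extends only supported windows
one residue at a time; support is anti-monotone in length, so this prunes
without loss.  Overlapping self-occurrences are all recorded; support
de-duplicates per sequence.

Significance is the standard residual z = (O − E)/√E with O the total
window count, E = W_n · Π f(p_i), W_n the number of length-n windows in the
set.  The default cut z ≥ 1.96 is the two-sided 5% normal point; both the
statistic and the threshold are configurable.  This is a deliberately
simple, testable model of "statistically significant residue association";
it ignores inter-window dependence, which is acceptable at the support
levels the pipeline targets (tens of sequences).

Delta-closed pruning removes p when a retained, strictly longer pattern q
with p as contiguous substring keeps support(q) ≥ δ·support(p) (default
δ = 0.9).  Processing longest-first makes retention well defined and the
operation idempotent.  Only contiguous super-patterns are considered,
because patterns themselves are contiguous.

Defaults (`min_len=5`, `max_len=15`, `min_occurrence=20`, δ=0.9, z≥1.96)
suit compact, well-conserved families of ~70–300 sequences; larger families
warrant a proportionally larger `min_occurrence`.

## Aligned Pattern Clusters

APCs are built by greedy agglomerative merging starting from singleton
clusters.  Cluster-pair similarity is the global alignment of the two
consensi (match +1, mismatch 0, gap −0.5; score normalized by aligned
length and clipped at 0).  Among optimal alignments the one with fewer
gaps, then with gaps rightmost, is chosen, making alignment — and the whole
agglomeration — deterministic.  Greedy merging is a heuristic; no global
optimality over all merge orders is claimed.

A merge is admissible iff the merged matrix has:

* ≥ `min_consecutive_column_match` (default 3) consecutive columns in which
  all non-gap symbols agree **and both clusters contribute a symbol** — a
  one-sided run would let end-to-end alignments of unrelated patterns pass;
* ≥ `min_conserved_columns` (default 1) columns identical across all rows;
* positionally consistent spans: on every sequence both clusters cover,
  their matched spans must overlap by ≥ 1 position (disabled with
  `allow_relative_position_overlap=True`).  This encodes "one APC = one
  region": two pattern groups occupying disjoint stretches of the same
  sequences are two regions, however similar their symbols.

Matrix rows contain residues and `-` only, so stripping gaps from a row
always recovers the member pattern.  The wildcard `*` appears in the
*consensus*: when `max_column_entropy` is set, interior columns whose
non-gap Shannon entropy exceeds the cap are written as `*` (and matched as
"any residue" during structure mapping), while a boundary column above the
cap blocks the merge.  Merge ties are broken by larger combined coverage,
then lexicographically smaller merged consensus; final APC ids are assigned
by coverage size descending, then consensus.

## Co-occurrence graph

Edge weight between APCs is the Jaccard index of their covered-sequence
sets, with 0/0 defined as 0.  The diagonal of W is zero — self-similarity
is uninformative and degrees should count neighbours only.  Pairs are
reported sorted by score, then union size (a tied pair covering more
sequences ranks higher), then lexicographic id pair, a total deterministic
order.  An optional `edge_min` threshold sparsifies the graph; it is off by
default so that weak but real co-occurrence is never silently discarded.

## Clustering

**Spectral.**  Vertices of degree 0 are split off as singleton clusters
first (D⁻¹ is undefined for them, and an isolated region genuinely
co-occurs with nothing).  On the remainder, L_rw = I − D⁻¹W is
eigendecomposed via its symmetric similarity transform
L_sym = I − D^{-1/2} W D^{-1/2} (numpy `eigh`; real spectrum, stable), and
eigenvectors are mapped back with D^{-1/2} — the Shi–Malik convention;
rows are *not* renormalized.  k is the count of eigenvalues before the
largest consecutive gap, examined over the first min(|V|, 10) eigenvalues;
ties take the smaller k, and all-equal gaps fall back to k = 1.  The
embedding uses the first k eigenvector columns including the constant first
one (a harmless shift; `include_first_eigenvector=False` drops it).
k-means runs with a fixed seed (default 1) and 10 restarts.  Labels are
renumbered by cluster size descending.

The "best" (most connected) cluster is the one with the lowest mean
pairwise Euclidean distance between its members' embedding rows; singleton
clusters are excluded, and an all-singleton result is an error rather than
a silent answer.

**k-medoids.**  Similarity-maximizing PAM variant: assignment sends each
vertex to its highest-scoring medoid, the update picks the member
maximizing the summed score to the rest of its cluster, iterated to a fixed
point.  Medoids initialize to the first vertex of each connected component;
extra medoids (k above the component count) are added farthest-first.  All
tie-breaks are by vertex index, so the procedure is fully deterministic.
This is a local optimizer: on unstructured dense graphs it can converge
below the global optimum (the tests document this), while on graphs with
genuine component/block structure the component-seeded start reaches it.
When k is not given, candidates from the component count up to |V| are
compared by five internal validity indices — silhouette (on 1 − J
distances), Calinski–Harabasz and Davies–Bouldin (on a classical-MDS
embedding of the distances), the Dunn index, and the within/between mean
similarity ratio — combined by majority vote with ties to the smaller k.
The choice of these five indices is this package's own; where a
dissimilarity is required anywhere, 1 − J is used.

**MST hierarchical.**  A maximum spanning tree per component (Prim,
weight ties broken by lexicographic edge id), then the currently
minimal-weight tree edge is cut repeatedly until k clusters exist.  k below
the component count is unreachable and raises.

### A note on separating weakly attached singletons

The eigengap route cannot split off a single vertex whose edges are weak
but uniform: the cut equals that vertex's entire volume, so its normalized
cut is ≈ 1 regardless of edge weight, λ₂ stays large, and the eigengap
stays at k = 1.  A region that co-occurs with nothing separates cleanly
(it is a degree-0 isolate), but a region sharing, say, half its sequences
with every other region will not be peeled off by the eigengap — whereas
the k-medoids validity indices or an explicit k for the MST cut will
separate it.  The synthetic benchmark below exhibits exactly this regime.

## Structure validation

PDB files are parsed with gemmi: first model, waters and hetero compounds
excluded, one Cα per residue (highest-occupancy altloc), residues without
Cα skipped with a warning.  APC member patterns are scanned exactly against
a chain's one-letter sequence; the (possibly wildcarded) consensus is
scanned with `*` matching any residue; if nothing matches fully, maximal
partial matches of ≥ `min_partial` residues (default 5 — short enough to
catch region fragments, long enough to avoid chance 20-letter hits) are
accepted.  Overlapping matches merge into regions.  The mapped chain
defaults to the one with most full matches; when an APC matches several
disjoint regions, the region whose centroid lies nearest the mean centroid
of the other APCs is kept and the alternatives stay listed.  Author residue
numbers are retained alongside sequential indices.

The two summaries are the mean Euclidean distance over all unordered APC
centroid pairs and, as baseline, over all unordered Cα pairs of the
structure (all chains of the first model by default; a chain subset can be
passed, since for multi-chain entries the two conventions differ and both
are legitimate).  Both are rigid-motion invariant by construction, which
the tests assert numerically.

## Synthetic benchmark

The generator plants consensus motifs into i.i.d. background sequences
(uniform residue frequencies by default).  Motifs in a joint group are
implanted together with one per-sequence probability; independent motifs
are drawn separately.  Implantation replaces background residues, so the
truth positions are exact; substitutions hit each motif position
independently; optional indels touch only background positions so planted
copies stay intact.  With a fixed seed the FASTA and PDB outputs are
byte-identical across runs.

The default benchmark — three 10-residue motifs, two joint (p = 0.7), one
independent (p = 0.7), 100 sequences of length 150, substitution rate
0.05 — reflects a mid-sized family with clearly conserved regions: 10
residues is a typical conserved-block width, 0.05 per-position divergence
keeps ~60% of copies exact, and 70% presence models regions that are
characteristic but not universal.  These values were fixed once, up front.

The paired synthetic structure is a Cα pursuit path around a moving center:
inside a planted region the center pins to that motif's anchor (the region
coils into a ~4 Å ball), linkers take a 25 Å excursion between anchors so
the chain has real extent.  Consecutive Cα spacing is exactly 3.8 Å;
nothing else about the geometry is physical — no excluded volume, no
secondary structure, no realistic compactness.  "colocated" anchors lie on
a 3 Å circle (motif centroids well within 15 Å of each other); "dispersed"
anchors sit 60 Å apart (centroids ≥ 40 Å).

What passing synthetic tests shows: each stage implements its definition
correctly, the pipeline recovers planted conserved regions and their
co-occurrence ranking under realistic noise, and the 3D inequality runs in
the right direction for genuinely colocated vs dispersed regions.  What it
does not show: behaviour under phylogenetic correlation between sequences
(the generator draws sequences independently), alignment-free detection of
motifs with internal indels, or performance on real structures with missing
residues and crystal-contact artifacts.

## Known limitations

* The significance model is order-0; compositionally biased families will
  inflate z for biased motifs.
* Greedy APC agglomeration can commit to a locally best merge; constraints
  limit, but do not eliminate, order dependence.
* The eigengap will not separate weakly-but-uniformly attached single
  regions (see above); inspect the k-medoids model selection or force k
  when that regime is suspected.
* k-medoids is a local optimizer away from component-structured graphs.
* Structure mapping assumes the chain sequence contains the family motifs
  nearly verbatim; highly divergent reference structures need the partial
  match floor lowered, at increasing risk of spurious placements.
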