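"""Aligned Pattern Clusters (APCs).

An APC is an m x n matrix whose rows are discovered patterns aligned with
gaps so that columns line up homologous residues; it represents one conserved
region of the family together with its variation.  Clusters are built by
greedy agglomerative merging: the highest-similarity admissible pair of
clusters is merged until no admissible pair remains.

A merge is admissible only when the merged matrix shows a sufficiently long
run of agreeing columns involving both clusters, enough fully conserved
columns, and (by default) positionally consistent occupied regions on every
sequence both clusters cover -- i.e. the two clusters describe the same
region, not adjacent or conflicting ones.

Matrix rows contain only residues and the gap symbol "-"; removing gaps from
a row recovers the member pattern exactly.  The wildcard "*" appears in the
*consensus* string for interior columns whose entropy exceeds the configured
cap, marking positions that vary too much to call.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from functools import total_ordering

from .io_seq import GAP, WILDCARD, SequenceSet
from .patterns import Pattern, PatternSet


@dataclass
class ApcConstraints:
    """Admissibility constraints for merging patterns into one APC.

    min_consecutive_column_match : length of the required run of consecutive
        columns in which all non-gap symbols agree and both merge partners
        contribute a symbol.
    min_conserved_columns : number of columns that must be identical across
        all rows (no gaps).
    allow_relative_position_overlap : when False (default), two clusters may
        merge only if their matched spans overlap by at least one position on
        every sequence they both cover.
    max_column_entropy : optional cap in bits; interior consensus positions
        above the cap are wildcarded, and a merge is refused when a boundary
        column would exceed it.
    gap_penalty : alignment gap score (match +1, mismatch 0).
    """

    min_consecutive_column_match: int = 3
    min_conserved_columns: int = 1
    allow_relative_position_overlap: bool = False
    max_column_entropy: float | None = None
    gap_penalty: float = -0.5

    def __post_init__(self) -> None:
        if self.min_consecutive_column_match < 0 or self.min_conserved_columns < 0:
            raise ValueError("constraint counts must be >= 0")


def align_pattern_pair(p: Pattern | str, q: Pattern | str,
                       gap_penalty: float = -0.5) -> tuple[str, str, float]:
    """Global (Needleman-Wunsch) alignment of two patterns.

    Scoring: +1 identical column, 0 mismatch, ``gap_penalty`` per gap.
    Deterministic tie-break: among optimal alignments prefer fewer gaps,
    then gaps placed rightmost.  Returns the two gapped rows and a
    similarity in [0, 1]: optimal score divided by aligned length, clipped
    at 0.
    """
    a = p.symbols if isinstance(p, Pattern) else p
    b = q.symbols if isinstance(q, Pattern) else q
    if not a or not b:
        raise ValueError("patterns must be non-empty")
    la, lb = len(a), len(b)
    NEG = (-math.inf, 0)
    # DP over (score, -gap_count); lexicographic max implements the
    # fewer-gaps tie-break.
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F[0][0] = (0.0, 0)
    for i in range(1, la + 1):
        F[i][0] = (i * gap_penalty, -i)
    for j in range(1, lb + 1):
        F[0][j] = (j * gap_penalty, -j)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            match = 1.0 if ai == b[j - 1] else 0.0
            sd, gd = F[i - 1][j - 1]
            su, gu = F[i - 1][j]
            sl, gl = F[i][j - 1]
            F[i][j] = max(
                (sd + match, gd),
                (su + gap_penalty, gu - 1),
                (sl + gap_penalty, gl - 1),
            )
    # Traceback; preferring gap moves first while walking right-to-left
    # places tied gaps rightmost.
    rows_a: list[str] = []
    rows_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        best = F[i][j]
        if i > 0 and (F[i - 1][j][0] + gap_penalty, F[i - 1][j][1] - 1) == best:
            rows_a.append(a[i - 1]); rows_b.append(GAP); i -= 1
        elif j > 0 and (F[i][j - 1][0] + gap_penalty, F[i][j - 1][1] - 1) == best:
            rows_a.append(GAP); rows_b.append(b[j - 1]); j -= 1
        else:
            match = 1.0 if a[i - 1] == b[j - 1] else 0.0
            rows_a.append(a[i - 1]); rows_b.append(b[j - 1]); i -= 1; j -= 1
    row_a = "".join(reversed(rows_a))
    row_b = "".join(reversed(rows_b))
    score = F[la][lb][0]
    similarity = max(0.0, score / len(row_a))
    return row_a, row_b, similarity


def _column_entropy(column: str) -> float:
    """Shannon entropy (bits) of the non-gap symbols of one matrix column."""
    symbols = [ch for ch in column if ch != GAP]
    if not symbols:
        return 0.0
    counts = Counter(symbols)
    total = len(symbols)
    return -sum((c / total) * math.log2(c / total) for c in counts.values()) + 0.0


@total_ordering
@dataclass
class AlignedPatternCluster:
    """One conserved region: aligned patterns, coverage, per-column statistics."""

    id: str
    rows: list[str]
    members: list[Pattern]

    def __post_init__(self) -> None:
        n = len(self.rows[0]) if self.rows else 0
        if any(len(r) != n for r in self.rows):
            raise ValueError("rows must share one aligned length")
        for row, member in zip(self.rows, self.members):
            if row.replace(GAP, "") != member.symbols:
                raise ValueError(
                    f"row {row!r} does not reduce to member pattern {member.symbols!r}"
                )

    def __eq__(self, other) -> bool:
        return isinstance(other, AlignedPatternCluster) and self.id == other.id

    def __lt__(self, other) -> bool:
        return self.id < other.id

    def __hash__(self) -> int:
        return hash(self.id)

    @property
    def n_patterns(self) -> int:
        return len(self.members)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    @property
    def column_entropies(self) -> list[float]:
        return [_column_entropy(self.column(j)) for j in range(self.n_columns)]

    @property
    def covered_sequences(self) -> frozenset[str]:
        """Ids of sequences containing at least one member pattern."""
        out: set[str] = set()
        for m in self.members:
            out.update(m.support_set)
        return frozenset(out)

    def consensus(self, max_column_entropy: float | None = None) -> str:
        """Majority symbol per column; interior high-entropy columns become "*"."""
        out = []
        n = self.n_columns
        for j in range(n):
            col = self.column(j)
            ent = _column_entropy(col)
            if (max_column_entropy is not None and ent > max_column_entropy
                    and 0 < j < n - 1):
                out.append(WILDCARD)
                continue
            counts = Counter(ch for ch in col if ch != GAP)
            if not counts:
                out.append(GAP)
                continue
            top = max(counts.values())  # ties to lexicographically smallest symbol
            out.append(min(ch for ch, c in counts.items() if c == top))
        return "".join(out)

    def spans(self) -> dict[str, tuple[int, int]]:
        """Per covered sequence, the 0-based half-open span of the matched region."""
        spans: dict[str, tuple[int, int]] = {}
        for m in self.members:
            n = len(m.symbols)
            for sid, start in m.occurrences:
                lo, hi = spans.get(sid, (start, start + n))
                spans[sid] = (min(lo, start), max(hi, start + n))
        return spans

    def spans_1based(self) -> dict[str, tuple[int, int]]:
        """User-facing 1-based inclusive spans."""
        return {sid: (lo + 1, hi) for sid, (lo, hi) in self.spans().items()}


def apc_coverage(c: AlignedPatternCluster, seqs: SequenceSet) -> frozenset[str]:
    """Recompute coverage by scanning every sequence for every member pattern."""
    out: set[str] = set()
    for rec in seqs:
        for m in c.members:
            if m.symbols in rec.residues:
                out.add(rec.id)
                break
    return frozenset(out)


def _merge_rows(cluster_a: AlignedPatternCluster, cluster_b: AlignedPatternCluster,
                gap_penalty: float) -> tuple[list[str], float]:
    """Align the two consensi and expand both row sets onto the joint columns."""
    cons_a = cluster_a.consensus()
    cons_b = cluster_b.consensus()
    row_a, row_b, similarity = align_pattern_pair(cons_a, cons_b, gap_penalty)
    expanded: list[str] = []
    for rows, gapped in ((cluster_a.rows, row_a), (cluster_b.rows, row_b)):
        for row in rows:
            out = []
            k = 0
            for ch in gapped:
                if ch == GAP:
                    out.append(GAP)
                else:
                    out.append(row[k])
                    k += 1
            expanded.append("".join(out))
    return expanded, similarity


def _admissible(merged_rows: list[str], m_a: int,
                cluster_a: AlignedPatternCluster, cluster_b: AlignedPatternCluster,
                constraints: ApcConstraints) -> bool:
    n = len(merged_rows[0])
    rows_a, rows_b = merged_rows[:m_a], merged_rows[m_a:]

    # run of agreeing columns fed by both clusters
    run = best = 0
    for j in range(n):
        col_a = {r[j] for r in rows_a} - {GAP}
        col_b = {r[j] for r in rows_b} - {GAP}
        both = col_a and col_b
        agree = both and len(col_a | col_b) == 1
        run = run + 1 if agree else 0
        best = max(best, run)
    if best < constraints.min_consecutive_column_match:
        return False

    conserved = sum(
        1 for j in range(n)
        if GAP not in {r[j] for r in merged_rows}
        and len({r[j] for r in merged_rows}) == 1
    )
    if conserved < constraints.min_conserved_columns:
        return False

    if constraints.max_column_entropy is not None:
        for j in (0, n - 1):
            col = "".join(r[j] for r in merged_rows)
            if _column_entropy(col) > constraints.max_column_entropy:
                return False

    if not constraints.allow_relative_position_overlap:
        spans_a = cluster_a.spans()
        spans_b = cluster_b.spans()
        for sid in set(spans_a) & set(spans_b):
            lo_a, hi_a = spans_a[sid]
            lo_b, hi_b = spans_b[sid]
            if min(hi_a, hi_b) - max(lo_a, lo_b) < 1:
                return False
    return True


def cluster_patterns(patterns: PatternSet | list[Pattern],
                     constraints: ApcConstraints | None = None,
                     ) -> list[AlignedPatternCluster]:
    """Greedy agglomerative clustering of patterns into APCs.

    Starting from singleton clusters, repeatedly merge the highest-similarity
    admissible pair (ties: larger combined coverage, then lexicographically
    smallest merged consensus) until no admissible pair with positive
    similarity remains.  Returned APCs get deterministic ids APC1, APC2, ...
    ordered by coverage size descending then consensus.
    """
    constraints = constraints or ApcConstraints()
    plist = list(patterns.patterns if isinstance(patterns, PatternSet) else patterns)
    if not plist:
        raise ValueError("no patterns to cluster")
    clusters = [
        AlignedPatternCluster(id=f"tmp{i}", rows=[p.symbols], members=[p])
        for i, p in enumerate(plist)
    ]
    while len(clusters) > 1:
        best_choice = None
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                ca, cb = clusters[ia], clusters[ib]
                merged, similarity = _merge_rows(ca, cb, constraints.gap_penalty)
                if similarity <= 0.0:
                    continue
                if not _admissible(merged, ca.n_patterns, ca, cb, constraints):
                    continue
                combined_cov = len(ca.covered_sequences | cb.covered_sequences)
                cand_cluster = AlignedPatternCluster(
                    id="cand", rows=merged, members=ca.members + cb.members
                )
                key = (similarity, combined_cov, _NegStr(cand_cluster.consensus()))
                if best_choice is None or key > best_choice[0]:
                    best_choice = (key, ia, ib, cand_cluster)
        if best_choice is None:
            break
        _, ia, ib, merged_cluster = best_choice
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged_cluster)
    clusters.sort(key=lambda c: (-len(c.covered_sequences), c.consensus()))
    out = []
    for i, c in enumerate(clusters, start=1):
        out.append(AlignedPatternCluster(id=f"APC{i}", rows=c.rows, members=c.members))
    return out


class _NegStr(str):
    """String whose ordering is reversed, so lexicographically smallest wins a max()."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
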