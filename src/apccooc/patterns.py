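"""Discovery of statistically significant sequence patterns.

A pattern is a contiguous amino-acid string that recurs across the family.
Candidates are enumerated exhaustively within a length range, scored with a
standard residual against an order-0 (independent residue) background model,
and pruned of redundancy: a pattern is dropped when a longer pattern
containing it retains at least a ``delta`` fraction of its sequence-level
support (delta-closed pruning).

Support counts distinct sequences containing at least one occurrence; the raw
window count is kept separately for the significance residual.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from .io_seq import SequenceSet


@dataclass
class Pattern:
    """A contiguous sequence pattern with its occurrences across the family.

    ``occurrences`` holds (sequence id, 0-based start) for every window where
    the pattern occurs, including overlapping self-occurrences.  ``support``
    de-duplicates per sequence.
    """

    symbols: str
    occurrences: list[tuple[str, int]] = field(default_factory=list)
    significance: float | None = None
    pruned_by: str | None = None

    @property
    def support(self) -> int:
        return len({sid for sid, _ in self.occurrences})

    @property
    def support_set(self) -> frozenset[str]:
        return frozenset(sid for sid, _ in self.occurrences)

    @property
    def occurrence_count(self) -> int:
        return len(self.occurrences)

    def __len__(self) -> int:
        return len(self.symbols)

    def verify(self, seqs: SequenceSet) -> bool:
        """Check every recorded occurrence by substring equality."""
        n = len(self.symbols)
        return all(
            sid in seqs and seqs[sid].residues[start:start + n] == self.symbols
            for sid, start in self.occurrences
        )


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the pattern-discovery stage.

    Defaults follow the settings used for compact, highly conserved families:
    lengths 5..15, sequence-level support at least 20, delta 0.9 for
    redundancy pruning, and a two-sided 5% significance cut (z >= 1.96).
    ``max_len=None`` removes the upper length bound.
    """

    min_len: int = 5
    max_len: int | None = 15
    min_occurrence: int = 20
    delta: float = 0.9
    z_threshold: float = 1.96


@dataclass
class PatternSet:
    patterns: list[Pattern]
    config: DiscoveryConfig

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def symbols(self) -> list[str]:
        return [p.symbols for p in self.patterns]


def enumerate_candidates(seqs: SequenceSet, min_len: int,
                         max_len: int | None, min_occurrence: int) -> list[Pattern]:
    """Enumerate every contiguous substring with enough sequence-level support.

    Returns unscored patterns of length in [min_len, max_len] (max_len=None
    means unbounded) whose support is at least ``min_occurrence``, each with a
    complete occurrence list.  Output is sorted by length descending, then
    lexicographically, for deterministic downstream processing.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len is not None and max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    lengths = [len(rec) for rec in seqs]
    if lengths and min_len > min(lengths):
        warnings.warn("min_len exceeds the shortest sequence; it contributes no windows")
    longest = max(lengths, default=0)
    upper = longest if max_len is None else min(max_len, longest)

    # Seed with min_len windows; extend only supported windows length by
    # length (support is anti-monotone in length) to avoid the full O(L^2)
    # blow-up when max_len is unbounded.
    survivors: dict[str, list[tuple[str, int]]] = {}
    for n in range(min_len, upper + 1):
        if n == min_len:
            windows: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for rec in seqs:
                s = rec.residues
                for i in range(len(s) - n + 1):
                    windows[s[i:i + n]].append((rec.id, i))
            extended = windows
        else:
            extended = defaultdict(list)
            frontier = [(w, occ) for w, occ in survivors.items() if len(w) == n - 1]
            for w, occ in frontier:
                for sid, i in occ:
                    s = seqs[sid].residues
                    if i + n <= len(s):
                        extended[s[i:i + n]].append((sid, i))
        for w, occ in extended.items():
            if len({sid for sid, _ in occ}) >= min_occurrence:
                survivors[w] = occ
    result = [Pattern(symbols=w, occurrences=sorted(occ))
              for w, occ in survivors.items()]
    result.sort(key=lambda p: (-len(p.symbols), p.symbols))
    return result


def significance_score(p: Pattern, seqs: SequenceSet) -> float:
    """Standard residual of the pattern's window count under the background.

    z = (O - E) / sqrt(E) with O the total occurrence count over all windows,
    E = W_n * prod_i f(p_i) where W_n is the number of length-n windows in
    the set and f the maximum-likelihood residue frequencies.  Returns +inf
    (with a warning) when a residue of p is absent from the background.
    """
    n = len(p.symbols)
    if n < 1:
        raise ValueError("empty pattern")
    freqs = seqs.frequencies()
    prob = 1.0
    for ch in p.symbols:
        prob *= freqs.get(ch, 0.0)
    w_n = sum(max(0, len(rec) - n + 1) for rec in seqs)
    expected = w_n * prob
    observed = p.occurrence_count
    if expected == 0.0:
        warnings.warn(
            f"pattern {p.symbols!r} contains a residue absent from the background"
        )
        return math.inf
    return (observed - expected) / math.sqrt(expected)


def delta_closed_prune(patterns: list[Pattern], delta: float) -> list[Pattern]:
    """Remove patterns made redundant by a retained contiguous super-pattern.

    A pattern p is pruned iff some retained super-pattern q (p a proper
    contiguous substring of q) satisfies support(q) >= delta * support(p).
    Patterns are processed longest first so that retention is well defined:
    a pattern can only be pruned by a strictly longer, already retained one.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    ordered = sorted(patterns, key=lambda p: (-len(p.symbols), p.symbols))
    retained: list[Pattern] = []
    result: list[Pattern] = []
    for p in ordered:
        pruner = None
        for q in retained:
            if len(q.symbols) > len(p.symbols) and p.symbols in q.symbols \
                    and q.support >= delta * p.support:
                pruner = q
                break
        if pruner is None:
            p.pruned_by = None
            retained.append(p)
            result.append(p)
        else:
            p.pruned_by = pruner.symbols
    return result


def discover_patterns(seqs: SequenceSet,
                      config: DiscoveryConfig | None = None) -> PatternSet:
    """Full discovery stage: enumerate, significance-filter, delta-prune.

    The retained set is sorted by support descending, then lexicographically.
    """
    config = config or DiscoveryConfig()
    candidates = enumerate_candidates(
        seqs, config.min_len, config.max_len, config.min_occurrence
    )
    significant: list[Pattern] = []
    for p in candidates:
        p.significance = significance_score(p, seqs)
        if p.significance >= config.z_threshold:
            significant.append(p)
    retained = delta_closed_prune(significant, config.delta)
    retained.sort(key=lambda p: (-p.support, p.symbols))
    if not retained:
        warnings.warn("no significant patterns retained")
    return PatternSet(patterns=retained, config=config)
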